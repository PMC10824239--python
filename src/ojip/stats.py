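"""Group statistics: ANOVA with Dunnett many-to-one comparisons and threshold detection.

Every treatment group (graded root-cutting ratio, RCR) is compared against
the single control (CK) per parameter — optionally stratified by clock time —
with family-wise error controlled by Dunnett's procedure (two-sided,
multivariate-t based).  Adjusted p values are mapped onto four significance
tiers: * (p < 0.05), ** (p < 0.005), *** (p < 0.0005), **** (p < 0.0001).

The threshold RCR at which photosynthesis begins to change is located by a
persistence rule: the smallest RCR level at which every parameter of a chosen
core set (default Fm, Fv/Fm, PI_abs) is significant at that level and at all
larger levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import ExperimentDesign, angle_to_rcr  # noqa: F401  (re-exported API)
from .errors import OJIPError
from .jip import jip_table
from .transients import average_by_leaf, extract_cardinal_points

#: Significance tiers: adjusted-p cutpoints, most stringent first.
TIER_CUTPOINTS = (
    (1e-4, "****"),
    (5e-4, "***"),
    (5e-3, "**"),
    (5e-2, "*"),
)

#: Default core parameter set for threshold detection.
DEFAULT_THRESHOLD_PARAMETERS = ("fm", "fv_over_fm", "pi_abs")

#: Fixed substream for the multivariate-t integration inside Dunnett's test,
#: so results do not depend on call order or ambient RNG state.
_DUNNETT_RNG_SEED = 20230724

_STEP_TO_FIELD = {"O": "f0", "J": "fj", "I": "fi", "P": "fm"}


def tier_label(p_adjusted: float) -> str:
    """Map an adjusted p value onto the four-tier star notation ('ns' otherwise)."""
    if not np.isfinite(p_adjusted):
        return "ns"
    for cut, label in TIER_CUTPOINTS:
        if p_adjusted < cut:
            return label
    return "ns"


@dataclass
class GroupComparisonResult:
    """ANOVA + Dunnett outcome for one parameter (one stratum or pooled).

    ``table`` has one row per group (control included) with columns
    group, n, mean, sem, p_dunnett, tier, testable; the control row carries
    no p value.  ``n_excluded`` counts flagged-missing observations dropped
    per group.
    """

    parameter_name: str
    clock_time: int | None
    anova_f: float
    anova_p: float
    table: pd.DataFrame
    control: float
    n_excluded: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def tier_of(self, group: float) -> str:
        row = self.table.loc[self.table["group"] == group]
        if row.empty:
            raise KeyError(f"group {group} not in comparison result")
        return str(row["tier"].iloc[0])

    def significant_groups(self) -> list[float]:
        t = self.table
        mask = (t["group"] != self.control) & (t["tier"] != "ns") & t["testable"]
        return sorted(t.loc[mask, "group"].tolist())


def _dispersion(x: np.ndarray) -> float:
    """Levene-type group dispersion: mean absolute deviation from the median."""
    return float(np.mean(np.abs(x - np.median(x))))


def _compare_one(
    df: pd.DataFrame,
    value_col: str,
    group_col: str,
    control: float,
    parameter_name: str,
    clock_time: int | None,
) -> GroupComparisonResult:
    result_warnings: list[str] = []
    n_excluded: dict = {}
    samples: dict[float, np.ndarray] = {}
    for g, sub in df.groupby(group_col, sort=True):
        vals = sub[value_col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        n_excluded[float(g)] = int((~ok).sum())
        samples[float(g)] = vals[ok]

    if control not in samples:
        raise OJIPError(f"control group {control} absent from table")
    groups = sorted(samples)
    testable = {g: samples[g].size >= 2 for g in groups}
    if not testable[control]:
        raise OJIPError(f"control group {control} has fewer than 2 usable observations")
    treat = [g for g in groups if g != control and testable[g]]
    not_testable = [g for g in groups if g != control and not testable[g]]
    if not_testable:
        result_warnings.append(f"groups not testable (fewer than 2 observations): {not_testable}")
    if not treat:
        raise OJIPError("need at least one testable treatment group")

    anova_groups = [samples[control]] + [samples[g] for g in treat]
    anova = sps.f_oneway(*anova_groups)

    disp = [_dispersion(samples[g]) for g in [control] + treat]
    positive = [d for d in disp if d > 0]
    if positive and max(positive) / min(positive) > 4.0 and min(positive) == min(disp):
        msg = (
            f"{parameter_name}: group dispersion ratio {max(positive) / min(positive):.1f} "
            "exceeds 4; equal-variance Dunnett comparisons may be unreliable"
        )
        result_warnings.append(msg)
        warnings.warn(msg, stacklevel=3)

    dunnett = sps.dunnett(
        *[samples[g] for g in treat],
        control=samples[control],
        alternative="two-sided",
        rng=np.random.default_rng(_DUNNETT_RNG_SEED),
    )
    p_adj = dict(zip(treat, np.asarray(dunnett.pvalue, dtype=float)))

    rows = []
    for g in groups:
        vals = samples[g]
        n = vals.size
        p = p_adj.get(g, np.nan)
        rows.append(
            {
                "group": g,
                "n": n,
                "mean": float(np.mean(vals)) if n else np.nan,
                "sem": float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "p_dunnett": p,
                "tier": "ns" if g == control else tier_label(p),
                "testable": bool(testable[g]),
            }
        )
    return GroupComparisonResult(
        parameter_name=parameter_name,
        clock_time=clock_time,
        anova_f=float(anova.statistic),
        anova_p=float(anova.pvalue),
        table=pd.DataFrame(rows),
        control=control,
        n_excluded=n_excluded,
        warnings=result_warnings,
    )


def compare_to_control(
    table: pd.DataFrame,
    value_col: str,
    *,
    group_col: str = "rcr_percent",
    control: float = 0.0,
    stratify_by: str | None = None,
    parameter_name: str | None = None,
) -> GroupComparisonResult | list[GroupComparisonResult]:
    """One-way ANOVA plus two-sided Dunnett comparisons of each group against control.

    ``table`` holds one leaf-level observation per row.  Non-finite values
    (flagged-missing parameters) are excluded, with per-group exclusion
    counts reported.  With ``stratify_by`` set (e.g. ``"clock_time"``), one
    result is returned per stratum.
    """
    name = parameter_name or value_col
    if stratify_by is None:
        return _compare_one(table, value_col, group_col, control, name, None)
    results = []
    for stratum, sub in table.groupby(stratify_by, sort=True):
        results.append(_compare_one(sub, value_col, group_col, control, name, int(stratum)))
    return results


def step_intensity_table(transients, step: str) -> pd.DataFrame:
    """Leaf-level intensity of one cardinal step (O→F0, J→FJ, I→FI, P→Fm).

    Raw duplicate measurements are averaged to leaf level first.  Returns one
    row per leaf with the design labels and an ``intensity`` column, ready for
    :func:`compare_to_control`.
    """
    try:
        attr = _STEP_TO_FIELD[step.upper()]
    except (KeyError, AttributeError):
        raise OJIPError(f"unknown step {step!r}: expected one of O, J, I, P") from None
    rows = []
    for t in average_by_leaf(list(transients)):
        cp = extract_cardinal_points(t)
        m = t.meta
        rows.append(
            {
                "plant_id": m.plant_id,
                "rcr_percent": m.rcr_percent,
                "replicate": m.replicate,
                "day": m.day,
                "clock_time": m.clock_time,
                "step": step.upper(),
                "intensity": getattr(cp, attr),
            }
        )
    return pd.DataFrame(rows)


def detect_threshold_rcr(results: dict[str, GroupComparisonResult]) -> float | None:
    """Smallest RCR level at which every core parameter is persistently significant.

    A level r qualifies when, for every parameter in ``results``, the Dunnett
    tier is * or beyond at r and at every larger level.  Levels that are not
    testable for a parameter (too few usable observations after
    flagged-missing exclusion, e.g. an all-flat group) are skipped for that
    parameter rather than counted as evidence against persistence.  Returns
    None when no level qualifies.  A warning is emitted when the significance
    pattern is non-monotone (a significant level followed by a testable
    non-significant larger one), as happens with late-day self-recovery.
    """
    if not results:
        raise OJIPError("no comparison results supplied")
    levels: list[float] | None = None
    sig_all: dict[float, bool] = {}
    for name, res in results.items():
        t = res.table
        treat = sorted(g for g in t["group"] if g != res.control)
        if levels is None:
            levels = treat
        elif treat != levels:
            raise OJIPError(f"parameter {name}: group levels {treat} differ from {levels}")
        for g in treat:
            row = t.loc[t["group"] == g].iloc[0]
            if not bool(row["testable"]):
                continue  # no evidence either way for this parameter at g
            ok = row["tier"] != "ns"
            sig_all[g] = sig_all.get(g, True) and ok

    assert levels is not None
    # Levels untestable for every parameter are neutral: inherit persistence.
    flags = [sig_all.get(g, None) for g in levels]
    for i in range(len(flags) - 1, -1, -1):
        if flags[i] is None:
            flags[i] = flags[i + 1] if i + 1 < len(flags) else True
    if any(flags[i] and not flags[i + 1] for i in range(len(flags) - 1)):
        warnings.warn(
            "non-monotone significance pattern across RCR levels; "
            "the persistence rule ignores isolated significant levels",
            stacklevel=2,
        )
    threshold = None
    for i in range(len(levels) - 1, -1, -1):
        if flags[i]:
            threshold = levels[i]
        else:
            break
    return threshold


def parameter_comparisons(
    jip: pd.DataFrame,
    parameters,
    *,
    control: float = 0.0,
    stratify_by: str | None = None,
) -> dict:
    """Run compare_to_control for several JIP-table columns; keyed by parameter."""
    out = {}
    for p in parameters:
        if p not in jip.columns:
            raise OJIPError(f"parameter {p!r} not a column of the JIP table")
        out[p] = compare_to_control(
            jip, p, control=control, stratify_by=stratify_by, parameter_name=p
        )
    return out


def results_table(results) -> pd.DataFrame:
    """Flatten comparison results into one row per (parameter, clock_time, group)."""
    if isinstance(results, GroupComparisonResult):
        results = [results]
    flat: list[GroupComparisonResult] = []
    for r in results:
        flat.extend(r if isinstance(r, list) else [r])
    frames = []
    for r in flat:
        t = r.table.copy()
        t.insert(0, "parameter", r.parameter_name)
        t.insert(1, "clock_time", "pooled" if r.clock_time is None else r.clock_time)
        t["anova_F"] = r.anova_f
        t["anova_p"] = r.anova_p
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


#: Default stratum for threshold detection: the midday measurement, where
#: stress expression on the fluorescence transient is maximal.
DEFAULT_THRESHOLD_CLOCK_TIME = 13


def threshold_from_jip(
    jip: pd.DataFrame,
    *,
    parameters=DEFAULT_THRESHOLD_PARAMETERS,
    control: float = 0.0,
    clock_time: int | None = DEFAULT_THRESHOLD_CLOCK_TIME,
) -> float | None:
    """Threshold detection on a leaf-level JIP parameter table.

    By default the comparison is made within the midday stratum (13:00),
    where stress expression is maximal and group dispersions are most
    homogeneous; pass ``clock_time=None`` to pool all measurement times
    (pooling mixes flat-midday and recovered-evening curves of the severe
    groups, inflating the pooled variance of the classical Dunnett test).
    """
    sub = jip if clock_time is None else jip[jip["clock_time"] == clock_time]
    comps = parameter_comparisons(sub, parameters, control=control, stratify_by=None)
    return detect_threshold_rcr(comps)
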