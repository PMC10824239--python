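"""Reading, validation, averaging and cardinal-point extraction of OJIP transients.

An OJIP transient is the polyphasic fluorescence rise of a dark-adapted leaf
under saturating light, sampled on a log-dense time grid from tens of
microseconds to about a second.  The cardinal steps are O (20 µs, minimal
fluorescence F0 with all PSII reaction centers open), J (2 ms), I (30 ms) and
P (the maximum, Fm, with all centers closed); F at 300 µs feeds the initial
slope M0 of the JIP test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateCurveError,
    FormatError,
    GridMismatchError,
    OutOfRangeError,
    ValidationError,
)

#: Cardinal time marks in seconds.
T_O = 2e-5
T_300US = 3e-4
T_J = 2e-3
T_I = 3e-2

#: Default flat-curve threshold: flat iff Fv < EPS_FLAT * F0.
EPS_FLAT = 0.05

#: Structural bounds enforced at load time.
MIN_POINTS = 40
MAX_FIRST_SAMPLE_S = 2e-5
MIN_LAST_SAMPLE_S = 0.3

CSV_COLUMNS = [
    "plant_id",
    "rcr_percent",
    "replicate",
    "day",
    "clock_time",
    "measurement_index",
    "time_s",
    "fluorescence",
]

_META_KEYS = ("plant_id", "rcr_percent", "replicate", "day", "clock_time")


@dataclass(frozen=True)
class TransientMeta:
    """Experimental annotations of one measured induction curve.

    ``measurement_index`` distinguishes the two back-to-back measurements of a
    leaf; it is ``None`` once duplicates have been averaged.
    """

    plant_id: str
    rcr_percent: float
    replicate: int
    day: int
    clock_time: int
    measurement_index: int | None = None

    def leaf_key(self) -> tuple:
        """Identity of the leaf-level record, ignoring the duplicate index."""
        return (self.plant_id, self.rcr_percent, self.replicate, self.day, self.clock_time)


@dataclass
class OJIPTransient:
    """One dark-adapted fluorescence induction curve with its annotations."""

    time_s: np.ndarray
    fluorescence: np.ndarray
    meta: TransientMeta

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        validate_transient(self)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass(frozen=True)
class CardinalPoints:
    """Fluorescence at the cardinal steps of one transient.

    ``is_flat`` flags a degenerate (almost horizontal) curve whose variable
    fluorescence Fv = Fm − F0 is below ``eps_flat`` × F0; ratio parameters are
    undefined for such curves.
    """

    f0: float
    f300: float
    fj: float
    fi: float
    fm: float
    t_fm: float
    is_flat: bool


def validate_transient(t: OJIPTransient, label: str | None = None) -> None:
    """Enforce the structural invariants of a transient; raise ValidationError."""
    name = label or f"transient {t.meta.plant_id}/d{t.meta.day}/t{t.meta.clock_time}"
    ts, fl = t.time_s, t.fluorescence
    if ts.ndim != 1 or fl.ndim != 1 or ts.size != fl.size:
        raise ValidationError(f"{name}: time and fluorescence must be same-length 1-D series")
    if ts.size < MIN_POINTS:
        raise ValidationError(f"{name}: needs at least {MIN_POINTS} samples, got {ts.size}")
    if not np.all(np.isfinite(ts)) or not np.all(np.isfinite(fl)):
        raise ValidationError(f"{name}: non-finite values present")
    if np.any(np.diff(ts) <= 0):
        raise ValidationError(f"{name}: time_s must be strictly increasing")
    if ts[0] > MAX_FIRST_SAMPLE_S:
        raise ValidationError(
            f"{name}: first sample {ts[0]:g} s is after the O-step mark {MAX_FIRST_SAMPLE_S:g} s"
        )
    if ts[-1] < MIN_LAST_SAMPLE_S:
        raise ValidationError(
            f"{name}: last sample {ts[-1]:g} s ends before {MIN_LAST_SAMPLE_S:g} s"
        )
    if np.any(fl < 0):
        raise ValidationError(f"{name}: fluorescence must be non-negative")


def read_transients(path, *, validate_only: bool = False) -> list[OJIPTransient]:
    """Read transients from the long-format CSV dialect.

    One transient is assembled per (plant_id, rcr_percent, replicate, day,
    clock_time, measurement_index) label combination; rows are taken in file
    order and never re-sorted, so a non-monotone time column is an error that
    names the offending record.  Malformed numeric rows are reported with
    their 1-based file line numbers.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    bad_lines: list[int] = []
    for col in ("time_s", "fluorescence"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        bad_lines.extend(int(i) + 2 for i in bad)  # +2: header line + 1-based
        df[col] = coerced
    if bad_lines:
        raise FormatError(
            f"{path}: malformed numeric rows at line(s) {sorted(set(bad_lines))}"
        )

    transients: list[OJIPTransient] = []
    keys = list(_META_KEYS) + ["measurement_index"]
    for label, grp in df.groupby(keys, sort=True, dropna=False):
        meta = TransientMeta(
            plant_id=str(label[0]),
            rcr_percent=float(label[1]),
            replicate=int(label[2]),
            day=int(label[3]),
            clock_time=int(label[4]),
            measurement_index=None if pd.isna(label[5]) else int(label[5]),
        )
        t = OJIPTransient.__new__(OJIPTransient)
        t.time_s = grp["time_s"].to_numpy(dtype=float)
        t.fluorescence = grp["fluorescence"].to_numpy(dtype=float)
        t.meta = meta
        validate_transient(t, label=f"record {label}")
        transients.append(t)
    if not validate_only:
        return transients
    return transients


def write_transients(transients: Iterable[OJIPTransient], path) -> None:
    """Write transients to the long-format CSV dialect ("." decimal, header row)."""
    frames = []
    for t in transients:
        m = t.meta
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": m.plant_id,
                    "rcr_percent": m.rcr_percent,
                    "replicate": m.replicate,
                    "day": m.day,
                    "clock_time": m.clock_time,
                    "measurement_index": m.measurement_index,
                    "time_s": t.time_s,
                    "fluorescence": t.fluorescence,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")


def average_duplicates(t1: OJIPTransient, t2: OJIPTransient, *, grid_rtol: float = 1e-6) -> OJIPTransient:
    """Pointwise mean of the two duplicate measurements of one leaf.

    The raw curves are averaged before any parameter computation.  The two
    grids must agree within ``grid_rtol`` relative tolerance; no resampling is
    ever applied silently.
    """
    if t1.meta.leaf_key() != t2.meta.leaf_key():
        raise ValidationError(
            f"cannot average measurements of different leaves: {t1.meta} vs {t2.meta}"
        )
    if t1.time_s.size != t2.time_s.size or not np.allclose(
        t1.time_s, t2.time_s, rtol=grid_rtol, atol=0.0
    ):
        raise GridMismatchError(
            f"time grids of duplicate measurements differ beyond rtol={grid_rtol:g} "
            f"for leaf {t1.meta.leaf_key()}"
        )
    meta = dataclasses.replace(t1.meta, measurement_index=None)
    return OJIPTransient(
        time_s=t1.time_s.copy(),
        fluorescence=0.5 * (t1.fluorescence + t2.fluorescence),
        meta=meta,
    )


def average_by_leaf(transients: Sequence[OJIPTransient]) -> list[OJIPTransient]:
    """Group raw transients by leaf and average the duplicate measurements.

    Leaves with a single measurement pass through with the duplicate index
    cleared; leaves with more than two measurements are rejected.
    """
    by_leaf: dict[tuple, list[OJIPTransient]] = {}
    for t in transients:
        by_leaf.setdefault(t.meta.leaf_key(), []).append(t)
    out = []
    for key, group in by_leaf.items():
        if len(group) == 1:
            t = group[0]
            out.append(
                OJIPTransient(
                    t.time_s.copy(),
                    t.fluorescence.copy(),
                    dataclasses.replace(t.meta, measurement_index=None),
                )
            )
        elif len(group) == 2:
            out.append(average_duplicates(group[0], group[1]))
        else:
            raise ValidationError(f"leaf {key}: expected at most 2 measurements, got {len(group)}")
    return out


def _interp_log_time(t: OJIPTransient, mark_s: float) -> float:
    """F at a time mark, linear in log10(time) between bracketing samples."""
    ts = t.time_s
    if mark_s < ts[0] or mark_s > ts[-1]:
        raise OutOfRangeError(
            f"time mark {mark_s:g} s outside sampled range [{ts[0]:g}, {ts[-1]:g}] s"
        )
    return float(np.interp(np.log10(mark_s), np.log10(ts), t.fluorescence))


def extract_cardinal_points(t: OJIPTransient, *, eps_flat: float = EPS_FLAT) -> CardinalPoints:
    """Extract F0 (20 µs), F300µs, FJ (2 ms), FI (30 ms) and Fm (curve maximum).

    Interpolation is linear in log10(time); a grid point that coincides with a
    mark is returned exactly.  Fm is the global maximum of the sampled curve
    and t_Fm the time of its first occurrence.
    """
    f0 = _interp_log_time(t, T_O)
    f300 = _interp_log_time(t, T_300US)
    fj = _interp_log_time(t, T_J)
    fi = _interp_log_time(t, T_I)
    imax = int(np.argmax(t.fluorescence))
    fm = float(t.fluorescence[imax])
    t_fm = float(t.time_s[imax])
    is_flat = (fm - f0) < eps_flat * f0
    return CardinalPoints(f0=f0, f300=f300, fj=fj, fi=fi, fm=fm, t_fm=t_fm, is_flat=is_flat)


def relative_variable_fluorescence(t: OJIPTransient, cp: CardinalPoints) -> np.ndarray:
    """V(t) = (F(t) − F0)/(Fm − F0), the relative variable fluorescence series."""
    if cp.is_flat:
        raise DegenerateCurveError(
            f"flat curve (Fv < eps_flat * F0) for {t.meta.plant_id}: V(t) undefined"
        )
    return (t.fluorescence - cp.f0) / (cp.fm - cp.f0)
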