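"""Phenomenological energy pipeline models per excited leaf cross-section.

A pipeline model summarizes, for one treatment group, the membrane-level
energy fluxes of PSII per excited cross-section referenced to the O step
(CS0): absorption ABS/CS0, trapping TR0/CS0, electron transport ET0/CS0 and
dissipation DI0/CS0, together with the density of active reaction centers
relative to the control.  Rendered figures draw arrows whose widths are
proportional to the fluxes (normalized by the control's ABS/CS0) and a row of
circles, open for active and filled for inactive reaction centers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import OJIPError  # noqa: E402
from .jip import JIPParameters  # noqa: E402

_FLUX_FIELDS = ("abs_per_cs0", "tr0_per_cs0", "et0_per_cs0", "di0_per_cs0")

#: Deterministic SVG output: fixed hash salt, no embedded creation date.
matplotlib.rcParams["svg.hashsalt"] = "ojip"


@dataclass(frozen=True)
class EnergyPipelineModel:
    """Group-mean per-CS0 fluxes and active/inactive RC display counts."""

    group_label: float
    abs_cs0: float
    tr0_cs0: float
    et0_cs0: float
    di0_cs0: float
    rc_cs0: float
    rc_active_fraction: float
    n_circles_total: int
    n_circles_active: int

    @property
    def available(self) -> bool:
        return bool(np.isfinite(self.abs_cs0))


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records
        required = set(_FLUX_FIELDS) | {"rc_per_cs0", "flat", "vj_degenerate"}
        missing = required - set(df.columns)
        if missing:
            raise OJIPError(f"JIP record table missing columns: {sorted(missing)}")
        return df
    rows = []
    for p in records:
        if not isinstance(p, JIPParameters):
            raise OJIPError(f"expected JIPParameters records, got {type(p).__name__}")
        rows.append(
            {
                **{f: getattr(p, f) for f in _FLUX_FIELDS},
                "rc_per_cs0": p.rc_per_cs0,
                "flat": p.flat,
                "vj_degenerate": p.vj_degenerate,
            }
        )
    return pd.DataFrame(rows)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_pipeline_model(
    records,
    control_records,
    *,
    n_circles: int = 12,
    group_label: float = np.nan,
) -> EnergyPipelineModel:
    """Aggregate leaf-level JIP records of one group into a pipeline model.

    Means are taken over non-flagged records (neither flat nor VJ-degenerate),
    pooling replicates, days and clock times unless the caller pre-filters.
    The active-RC fraction is the group's mean RC/CS0 over the control's,
    clipped to [0, 1]; the control compared with itself has fraction 1.  A
    group whose records are all flagged yields a model with fluxes marked
    unavailable (NaN), never zeros.
    """
    if n_circles < 1:
        raise OJIPError("n_circles must be >= 1")
    df = _records_frame(records)
    cdf = _records_frame(control_records)
    if len(df) == 0 or len(cdf) == 0:
        raise OJIPError("need at least one record per collection")

    ok = ~(df["flat"].astype(bool) | df["vj_degenerate"].astype(bool))
    cok = ~(cdf["flat"].astype(bool) | cdf["vj_degenerate"].astype(bool))
    if not cok.any():
        raise OJIPError("control group has no non-flagged records")
    control_rc = float(cdf.loc[cok, "rc_per_cs0"].mean())

    if not ok.any():
        return EnergyPipelineModel(
            group_label=float(group_label),
            abs_cs0=np.nan,
            tr0_cs0=np.nan,
            et0_cs0=np.nan,
            di0_cs0=np.nan,
            rc_cs0=np.nan,
            rc_active_fraction=np.nan,
            n_circles_total=int(n_circles),
            n_circles_active=0,
        )

    sub = df.loc[ok]
    means = {f: float(sub[f].mean()) for f in _FLUX_FIELDS}
    rc = float(sub["rc_per_cs0"].mean())
    frac = float(np.clip(rc / control_rc, 0.0, 1.0))
    return EnergyPipelineModel(
        group_label=float(group_label),
        abs_cs0=means["abs_per_cs0"],
        tr0_cs0=means["tr0_per_cs0"],
        et0_cs0=means["et0_per_cs0"],
        di0_cs0=means["di0_per_cs0"],
        rc_cs0=rc,
        rc_active_fraction=frac,
        n_circles_total=int(n_circles),
        n_circles_active=_round_half_away(frac * n_circles),
    )


def arrow_specs(model: EnergyPipelineModel, *, reference_abs: float, max_width: float = 0.22):
    """Arrow geometry used by the renderer: (name, value, width) per flux.

    Widths are proportional to flux values normalized by ``reference_abs``
    (the control group's ABS/CS0), so the control's absorption arrow has the
    configured maximum width.
    """
    if not np.isfinite(reference_abs) or reference_abs <= 0:
        raise OJIPError("reference ABS/CS0 must be positive and finite")
    fluxes = [
        ("ABS", model.abs_cs0),
        ("TR", model.tr0_cs0),
        ("ET", model.et0_cs0),
        ("DI", model.di0_cs0),
    ]
    return [(name, val, max_width * val / reference_abs) for name, val in fluxes]


def render_pipeline(
    model: EnergyPipelineModel,
    out_path,
    *,
    reference_abs: float | None = None,
    max_width: float = 0.22,
) -> None:
    """Render a pipeline model as a deterministic figure (SVG recommended).

    Arrow widths are normalized by ``reference_abs`` (defaults to the model's
    own ABS/CS0); open/filled circles mark active/inactive reaction centers.
    An unavailable model (all records flagged) yields a placeholder figure
    with a warning annotation instead of misleading zero-width arrows.
    """
    fig, ax = plt.subplots(figsize=(4.0, 4.6))
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.axis("off")
    label = f"RCR {model.group_label:g}%" if np.isfinite(model.group_label) else "group"
    ax.set_title(f"Energy pipeline per CS0 — {label}", fontsize=11)

    if not model.available:
        ax.text(
            0.5,
            0.5,
            "fluxes unavailable\n(all leaf records flagged)",
            ha="center",
            va="center",
            fontsize=12,
            color="crimson",
            bbox=dict(boxstyle="round", facecolor="mistyrose", edgecolor="crimson"),
        )
        fig.savefig(out_path, metadata=_metadata(out_path))
        plt.close(fig)
        return

    ref = model.abs_cs0 if reference_abs is None else reference_abs
    specs = arrow_specs(model, reference_abs=ref, max_width=max_width)
    widths = {name: w for name, _, w in specs}
    values = {name: v for name, v, _ in specs}

    # Leaf slab.
    ax.add_patch(
        plt.Rectangle((0.15, 0.40), 0.70, 0.22, facecolor="#9ccc8f", edgecolor="k", lw=1.0)
    )
    # ABS: into the leaf from above; TR and ET: downward chain; DI: sideways loss.
    _arrow(ax, 0.30, 0.92, 0.30, 0.64, widths["ABS"], "#555555")
    _arrow(ax, 0.45, 0.40, 0.45, 0.20, widths["TR"], "#1f77b4")
    _arrow(ax, 0.62, 0.40, 0.62, 0.08, widths["ET"], "#2ca02c")
    _arrow(ax, 0.85, 0.51, 0.99, 0.73, widths["DI"], "#d62728")
    for name, x, y in (("ABS", 0.18, 0.80), ("TR", 0.36, 0.28), ("ET", 0.70, 0.22), ("DI", 0.80, 0.72)):
        ax.text(x, y, f"{name}\n{values[name]:.0f}", fontsize=9, ha="center", va="center")

    # Reaction-center circles: open = active, filled = inactive.
    n = model.n_circles_total
    xs = np.linspace(0.18, 0.82, n)
    for i, x in enumerate(xs):
        ax.add_patch(
            plt.Circle(
                (x, 0.51),
                0.022,
                facecolor="white" if i < model.n_circles_active else "black",
                edgecolor="black",
                lw=0.8,
            )
        )
    fig.savefig(out_path, metadata=_metadata(out_path))
    plt.close(fig)


def _metadata(out_path) -> dict | None:
    # Strip the volatile creation date so identical models give identical bytes.
    if str(out_path).lower().endswith(".svg"):
        return {"Date": None}
    if str(out_path).lower().endswith(".png"):
        return {"Software": None}
    return None


def _arrow(ax, x0, y0, x1, y1, width, color) -> None:
    width = max(width, 1e-4)
    ax.annotate(
        "",
        xy=(x1, y1),
        xytext=(x0, y0),
        arrowprops=dict(
            arrowstyle="simple,head_width={:.4f},head_length={:.4f},tail_width={:.4f}".format(
                max(1.8 * width, 0.02) * 30, 0.55, width * 30
            ),
            color=color,
            lw=0,
        ),
    )
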