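"""The JIP-test engine: derived PSII energy-flux parameters from cardinal points.

The JIP test converts the cardinal points of a dark-adapted OJIP transient
into specific (per reaction center, RC) and phenomenological (per excited
cross-section, CS0) energy fluxes of photosystem II:

* ``VJ = (F2ms − F0)/(Fm − F0)`` — relative variable fluorescence at the J
  step, a proxy for the fraction of reduced QA at 2 ms;
* ``M0 = 4 (F300µs − F0)/(Fm − F0)`` — approximated initial slope of the rise;
* per-RC fluxes ``TR0/RC = M0/VJ``, ``ET0/RC = (M0/VJ)(1 − VJ)``,
  ``ABS/RC = (M0/VJ)/(1 − F0/Fm)``, ``DI0/RC = ABS/RC − TR0/RC``;
* yields ``φP0 = TR0/ABS = 1 − F0/Fm`` (= Fv/Fm), ``ψ0 = ET0/TR0 = 1 − VJ``,
  ``φE0 = ET0/ABS = φP0 ψ0``;
* the absorption-based performance index
  ``PI_abs = (RC/ABS) · φP0/(1 − φP0) · ψ0/(1 − ψ0)``;
* per-CS0 fluxes anchored on the O-step approximation ``ABS/CS0 = F0``;
* RC densities ``RC/CS0 = F0/(ABS/RC)`` and ``RC/CSm = Fm/(ABS/RC)``;
* ``Sm`` — the normalized total complementary area above the curve, a proxy
  for the size of the electron-acceptor pool.

Degenerate inputs (flat curves, VJ at 0 or 1) propagate as flagged NaN,
never as infinities, so group statistics can exclude them explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .errors import DegenerateCurveError
from .transients import (
    T_O,
    CardinalPoints,
    OJIPTransient,
    _interp_log_time,
    average_by_leaf,
    extract_cardinal_points,
)

_VJ_TOL = 1e-12


@dataclass(frozen=True)
class JIPParameters:
    """Complete derived-parameter record for one (leaf-level) transient."""

    f0: float
    fm: float
    fv: float
    fv_over_fm: float = np.nan
    fv_over_f0: float = np.nan
    vj: float = np.nan
    m0: float = np.nan
    sm: float = np.nan
    abs_per_rc: float = np.nan
    tr0_per_rc: float = np.nan
    et0_per_rc: float = np.nan
    di0_per_rc: float = np.nan
    tr0_per_abs: float = np.nan
    et0_per_abs: float = np.nan
    et0_per_tr0: float = np.nan
    pi_abs: float = np.nan
    abs_per_cs0: float = np.nan
    tr0_per_cs0: float = np.nan
    et0_per_cs0: float = np.nan
    di0_per_cs0: float = np.nan
    rc_per_cs0: float = np.nan
    rc_per_csm: float = np.nan
    flat: bool = False
    vj_degenerate: bool = False


#: Numeric parameter column order used in tables and TSV output.
PARAMETER_COLUMNS = [f.name for f in fields(JIPParameters) if f.name not in ("flat", "vj_degenerate")]


def compute_sm(curve: OJIPTransient, cp: CardinalPoints) -> float:
    """Normalized total complementary area above the induction curve.

    Sm = ∫ (Fm − F(t)) dt / (Fm − F0), integrated by the trapezoidal rule in
    linear time from the 20 µs (O-step) mark to t_Fm.  Units: seconds.
    """
    if cp.is_flat:
        raise DegenerateCurveError("flat curve: Sm undefined")
    ts, fl = curve.time_s, curve.fluorescence
    inside = (ts > T_O) & (ts < cp.t_fm)
    t_grid = np.concatenate(([T_O], ts[inside], [cp.t_fm]))
    f_grid = np.concatenate(
        ([_interp_log_time(curve, T_O)], fl[inside], [_interp_log_time(curve, cp.t_fm)])
    )
    area = np.trapezoid(cp.fm - f_grid, t_grid)
    return float(area / (cp.fm - cp.f0))


def compute_jip(cp: CardinalPoints, curve: OJIPTransient | None = None) -> JIPParameters:
    """Compute the full JIP-test record from cardinal points (and curve, for Sm).

    Flat curves populate only F0, Fm and Fv and set the ``flat`` flag.  VJ at
    exactly 0 or 1 sets ``vj_degenerate``: well-defined limits are kept
    (ET0/RC → 0 at VJ = 1) and genuinely divergent quantities (per-RC fluxes
    at VJ = 0, PI at ψ0 ∈ {0, 1}) become NaN.
    """
    f0, fm = cp.f0, cp.fm
    fv = fm - f0
    if cp.is_flat:
        return JIPParameters(f0=f0, fm=fm, fv=fv, flat=True)

    vj = (cp.fj - f0) / fv
    m0 = 4.0 * (cp.f300 - f0) / fv
    phi_p0 = 1.0 - f0 / fm  # = Fv/Fm
    psi_0 = 1.0 - vj
    phi_e0 = phi_p0 * psi_0

    vj_degenerate = vj <= _VJ_TOL or vj >= 1.0 - _VJ_TOL
    if vj <= _VJ_TOL:
        # TR0/RC = M0/VJ diverges: per-RC fluxes and RC densities unavailable.
        tr0_rc = et0_rc = abs_rc = di0_rc = rc_cs0 = rc_csm = np.nan
    else:
        tr0_rc = m0 / vj
        et0_rc = tr0_rc * (1.0 - vj)
        abs_rc = tr0_rc / phi_p0
        di0_rc = abs_rc - tr0_rc
        rc_cs0 = f0 / abs_rc
        rc_csm = fm / abs_rc

    if vj_degenerate or psi_0 <= 0.0 or psi_0 >= 1.0 or not np.isfinite(abs_rc):
        pi_abs = np.nan
    else:
        pi_abs = (1.0 / abs_rc) * (phi_p0 / (1.0 - phi_p0)) * (psi_0 / (1.0 - psi_0))

    abs_cs0 = f0
    tr0_cs0 = phi_p0 * f0
    et0_cs0 = phi_e0 * f0
    di0_cs0 = f0 - tr0_cs0

    sm = compute_sm(curve, cp) if curve is not None else np.nan

    return JIPParameters(
        f0=f0,
        fm=fm,
        fv=fv,
        fv_over_fm=phi_p0,
        fv_over_f0=fv / f0,
        vj=vj,
        m0=m0,
        sm=sm,
        abs_per_rc=abs_rc,
        tr0_per_rc=tr0_rc,
        et0_per_rc=et0_rc,
        di0_per_rc=di0_rc,
        tr0_per_abs=phi_p0,
        et0_per_abs=phi_e0,
        et0_per_tr0=psi_0,
        pi_abs=pi_abs,
        abs_per_cs0=abs_cs0,
        tr0_per_cs0=tr0_cs0,
        et0_per_cs0=et0_cs0,
        di0_per_cs0=di0_cs0,
        rc_per_cs0=rc_cs0,
        rc_per_csm=rc_csm,
        flat=False,
        vj_degenerate=bool(vj_degenerate),
    )


def jip_table(transients, *, eps_flat: float | None = None, average: bool = True) -> pd.DataFrame:
    """Leaf-level JIP parameter table: one row per (averaged) transient.

    Raw duplicate measurements are averaged first when ``average`` is true.
    Columns: design labels, then every JIPParameters field (NaN for
    flagged-missing values) plus the two flags.
    """
    from .transients import EPS_FLAT

    eps = EPS_FLAT if eps_flat is None else eps_flat
    leaves = average_by_leaf(list(transients)) if average else list(transients)
    rows = []
    for t in leaves:
        cp = extract_cardinal_points(t, eps_flat=eps)
        p = compute_jip(cp, t if not cp.is_flat else None)
        row = {
            "plant_id": t.meta.plant_id,
            "rcr_percent": t.meta.rcr_percent,
            "replicate": t.meta.replicate,
            "day": t.meta.day,
            "clock_time": t.meta.clock_time,
        }
        row.update({name: getattr(p, name) for name in PARAMETER_COLUMNS})
        row["flat"] = p.flat
        row["vj_degenerate"] = p.vj_degenerate
        rows.append(row)
    return pd.DataFrame(rows)


def write_jip_table(table: pd.DataFrame, path) -> None:
    """Write a JIP parameter table as TSV with 'NA' for flagged-missing values."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
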