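"""Seeded synthetic OJIP transients with graded root-cutting stress phenomenology.

The generator emulates the experiment's design — 7 RCR groups (CK, 10, 20,
30, 50, 75, 100 %) × 3 replicate plants × 5 clock times (9:00–17:00) × 2 days,
two measurements per leaf — and its qualitative stress phenomenology, while
providing exact ground truth for every downstream stage.

Each noise-free curve is a sum of three logistic rises in log10 time,

    F(t) = F0_base · [1 + A · Σ_k w_k · s((log10 t − log10 τ_k) / σ_k)],

with phases k ∈ {OJ, JI, IP} at characteristic times τ_OJ ≈ 0.4 ms,
τ_JI ≈ 8 ms, τ_IP ≈ 80 ms.  The overall amplitude A is solved on the sampling
grid so that an unstressed, unmodulated curve hits the configured dark-adapted
Fv/Fm target exactly.  Stress enters as a multiplicative amplitude depression
d(r) — zero up to the configured onset RCR, growing beyond it — plus: near-total
amplitude collapse (flat curves) for the 75/100 % groups at midday, a partial
amplitude recovery at 17:00 for 50/75 % (but not 100 %), and a J-phase weight
inflation at 100 % RCR that raises VJ and lowers ψ0.  A deterministic diurnal
modulation with a midday minimum scales all groups alike.  Noise is per-point
multiplicative lognormal plus lognormal per-plant and per-day random effects.

Reproducibility: a single root seed; every random draw comes from a substream
keyed by the design labels of the curve (group, replicate, day, clock time,
measurement), so subsetting the design never changes individual curves.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .errors import ConfigError
from .jip import PARAMETER_COLUMNS, compute_jip
from .transients import OJIPTransient, TransientMeta, extract_cardinal_points

# Substream tags (arbitrary distinct constants mixed into the seed sequence).
_TAG_CURVE = 11
_TAG_PLANT = 13
_TAG_DAY = 17


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic experiment; defaults are the study conditions."""

    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    seed: int = 0

    # Sampling grid: log-spaced, covering all cardinal marks with margin.
    n_points: int = 70
    t_min_s: float = 2e-5
    t_max_s: float = 1.0

    # Phase model (logistic rises in log10 time).
    f0_base: float = 500.0
    fv_fm_target: float = 0.82
    tau_s: tuple[float, float, float] = (4e-4, 8e-3, 8e-2)
    sigma_decades: tuple[float, float, float] = (0.28, 0.25, 0.22)
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2)

    # Stress response.
    depression: dict[float, float] = field(
        default_factory=lambda: {50.0: 0.25, 75.0: 0.45, 100.0: 0.75}
    )
    w_oj_shift_full_removal: float = 0.15
    flat_groups: tuple[float, ...] = (75.0, 100.0)
    flat_clock_times: tuple[int, ...] = (13, 15)
    flat_factor: float = 0.01
    recovery_groups: tuple[float, ...] = (50.0, 75.0)
    recovery_clock_time: int = 17
    recovery_coef: float = 0.6

    # Diurnal modulation of amplitude (midday minimum; 9:00 is the reference).
    diurnal: dict[int, float] = field(
        default_factory=lambda: {9: 1.0, 11: 0.97, 13: 0.93, 15: 0.96, 17: 0.99}
    )

    # Noise model.
    sigma_noise: float = 0.03
    sigma_plant: float = 0.02
    sigma_day: float = 0.01

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(f"phase weights must be non-negative and sum to 1, got {self.weights}")
        tau = np.asarray(self.tau_s, float)
        if np.any(np.diff(tau) <= 0) or np.any(tau <= 0):
            raise ConfigError(f"phase times must be positive and strictly ordered, got {self.tau_s}")
        if np.any(np.asarray(self.sigma_decades, float) <= 0):
            raise ConfigError("phase widths must be positive")
        if not 0.0 < self.fv_fm_target < 1.0:
            raise ConfigError("fv_fm_target must lie in (0, 1)")
        if self.w_oj_shift_full_removal > self.weights[2]:
            raise ConfigError("w_oj_shift_full_removal exceeds the IP-phase weight")
        for name in ("sigma_noise", "sigma_plant", "sigma_day", "flat_factor"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        bad = [d for d in self.depression.values() if not 0.0 <= d <= 1.0]
        if bad:
            raise ConfigError(f"depression values must lie in [0, 1], got {bad}")
        missing = [c for c in self.design.clock_times if c not in self.diurnal]
        if missing:
            raise ConfigError(f"diurnal modulation missing clock times {missing}")

    def time_grid(self) -> np.ndarray:
        return np.geomspace(self.t_min_s, self.t_max_s, self.n_points)

    def group_weights(self, group: float, *, null: bool = False) -> tuple[float, float, float]:
        """Phase weights for a group: the OJ phase is inflated at full removal."""
        w = self.weights
        if null or group < 100.0 or self.w_oj_shift_full_removal == 0.0:
            return w
        s = self.w_oj_shift_full_removal
        return (w[0] + s, w[1], w[2] - s)


def phase_shape(time_s: np.ndarray, weights, tau_s, sigma_decades) -> np.ndarray:
    """Normalized rise shape g(t) ∈ [0, 1): weighted logistic steps in log10 t."""
    lt = np.log10(np.asarray(time_s, float))
    g = np.zeros_like(lt)
    for w, tau, sig in zip(weights, tau_s, sigma_decades):
        x = (lt - np.log10(tau)) / sig
        g += w / (1.0 + np.exp(-x))
    return g


def solve_amplitude(g: np.ndarray, fv_fm_target: float) -> float:
    """Amplitude A such that (Fm − F0)/Fm on the sampled shape equals the target.

    With F(t) = F0_base (1 + A g(t)), F0 = F(t_first) and Fm = F(t_last) (the
    noise-free shape is increasing), Fv/Fm = A (g_m − g_0) / (1 + A g_m).
    """
    g0, gm = float(g[0]), float(g[-1])
    denom = gm - g0 - fv_fm_target * gm
    if denom <= 0:
        raise ConfigError(
            f"fv_fm_target {fv_fm_target} unreachable for this phase shape (g0={g0:.4f}, gm={gm:.4f})"
        )
    return fv_fm_target / denom


def _effects(cfg: GeneratorConfig, group: float, clock: int, *, null: bool) -> dict:
    """Deterministic stress-effect descriptors for one (group, clock) condition."""
    if null or group == cfg.design.control:
        return {"depression": 0.0, "recovery_applied": 0, "flat_applied": 0, "w_oj_shift": 0.0}
    d = cfg.depression.get(group, 0.0)
    recovery = int(group in cfg.recovery_groups and clock == cfg.recovery_clock_time)
    if recovery:
        d *= 1.0 - cfg.recovery_coef
    flat = int(group in cfg.flat_groups and clock in cfg.flat_clock_times)
    shift = cfg.w_oj_shift_full_removal if group >= 100.0 else 0.0
    return {"depression": d, "recovery_applied": recovery, "flat_applied": flat, "w_oj_shift": shift}


def _condition_amplitude(cfg: GeneratorConfig, base_amp: float, clock: int, eff: dict) -> float:
    amp = base_amp * (1.0 - eff["depression"]) * cfg.diurnal[clock]
    if eff["flat_applied"]:
        amp *= cfg.flat_factor
    return amp


def _generate(cfg: GeneratorConfig, *, null: bool) -> tuple[list[OJIPTransient], pd.DataFrame]:
    design = cfg.design
    grid = cfg.time_grid()
    base_shape = phase_shape(grid, cfg.weights, cfg.tau_s, cfg.sigma_decades)
    base_amp = solve_amplitude(base_shape, cfg.fv_fm_target)
    seed = int(cfg.seed)
    if seed < 0:
        raise ConfigError("seed must be non-negative")

    shapes = {
        g: phase_shape(grid, cfg.group_weights(g, null=null), cfg.tau_s, cfg.sigma_decades)
        for g in design.groups
    }
    day_factor = {
        d: float(np.exp(np.random.default_rng([seed, _TAG_DAY, int(d)]).normal(0.0, cfg.sigma_day)))
        for d in design.days
    }

    truth_cache: dict[tuple[float, int], dict] = {}
    transients: list[OJIPTransient] = []
    truth_rows: list[dict] = []

    for group in design.groups:
        gshape = shapes[group]
        gcode = int(round(group * 10))  # integer-safe substream key
        for rep in range(1, design.replicates + 1):
            plant_id = f"RCR{group:g}-P{rep}"
            plant_factor = float(
                np.exp(
                    np.random.default_rng([seed, _TAG_PLANT, gcode, rep]).normal(0.0, cfg.sigma_plant)
                )
            )
            for day in design.days:
                for clock in design.clock_times:
                    eff = _effects(cfg, group, clock, null=null)
                    amp_det = _condition_amplitude(cfg, base_amp, clock, eff)
                    key = (group, clock)
                    if key not in truth_cache:
                        truth_cache[key] = _truth_record(grid, cfg.f0_base, amp_det, gshape)
                    meta_common = dict(
                        plant_id=plant_id,
                        rcr_percent=group,
                        replicate=rep,
                        day=int(day),
                        clock_time=int(clock),
                    )
                    row = dict(meta_common)
                    row.update(eff)
                    row.update(truth_cache[key])
                    truth_rows.append(row)

                    amp_leaf = amp_det * plant_factor * day_factor[day]
                    for meas in range(1, design.measurements_per_leaf + 1):
                        rng = np.random.default_rng(
                            [seed, _TAG_CURVE, gcode, rep, int(day), int(clock), meas]
                        )
                        noise = np.exp(rng.normal(0.0, cfg.sigma_noise, grid.size))
                        fl = cfg.f0_base * (1.0 + amp_leaf * gshape) * noise
                        transients.append(
                            OJIPTransient(
                                time_s=grid.copy(),
                                fluorescence=fl,
                                meta=TransientMeta(measurement_index=meas, **meta_common),
                            )
                        )
    return transients, pd.DataFrame(truth_rows)


def _truth_record(grid: np.ndarray, f0_base: float, amp: float, gshape: np.ndarray) -> dict:
    """Noise-free cardinal points and JIP parameters for one condition."""
    t = OJIPTransient(
        time_s=grid.copy(),
        fluorescence=f0_base * (1.0 + amp * gshape),
        meta=TransientMeta("truth", 0.0, 1, 1, 9),
    )
    cp = extract_cardinal_points(t)
    p = compute_jip(cp, t if not cp.is_flat else None)
    rec = {f"true_{name}": getattr(p, name) for name in PARAMETER_COLUMNS}
    rec["true_flat"] = p.flat
    return rec


def generate_experiment(cfg: GeneratorConfig) -> tuple[list[OJIPTransient], pd.DataFrame]:
    """Generate the full stressed experiment and its per-leaf ground-truth table.

    Returns the raw transients (two per leaf) and a DataFrame with one row per
    leaf holding the applied effect sizes and the noise-free cardinal points
    and JIP parameters of that leaf's condition.
    """
    return _generate(cfg, null=False)


def generate_null_experiment(cfg: GeneratorConfig) -> tuple[list[OJIPTransient], pd.DataFrame]:
    """Same design labels and noise, but every group drawn from the control model."""
    return _generate(cfg, null=True)
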