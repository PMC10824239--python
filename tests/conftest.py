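"""Shared fixtures: analytic curves and small synthetic experiments."""

import numpy as np
import pytest

from ojip import (
    GeneratorConfig,
    OJIPTransient,
    TransientMeta,
    generate_experiment,
    jip_table,
)

#: Anchor points of the worked curve: exact values at the cardinal marks.
WORKED_ANCHORS = {
    2e-5: 500.0,
    3e-4: 900.0,
    2e-3: 1500.0,
    3e-2: 2200.0,
    1.0: 2500.0,
}


def make_transient(time_s, fluor, *, rcr=0.0, rep=1, day=1, clock=9, meas=None, plant="P1"):
    return OJIPTransient(
        time_s=np.asarray(time_s, float),
        fluorescence=np.asarray(fluor, float),
        meta=TransientMeta(
            plant_id=plant,
            rcr_percent=rcr,
            replicate=rep,
            day=day,
            clock_time=clock,
            measurement_index=meas,
        ),
    )


def log_grid(n=70, t_min=2e-5, t_max=1.0, include=()):
    """Log-spaced grid optionally forced to contain specific sample times."""
    g = np.geomspace(t_min, t_max, n)
    if len(include):
        g = np.unique(np.concatenate([g, np.asarray(include, float)]))
    return g


@pytest.fixture(scope="session")
def worked_curve():
    """Piecewise log-linear curve passing exactly through the worked anchors.

    Because cardinal extraction interpolates linearly in log10 time, the
    extracted marks reproduce the anchor values exactly.
    """
    anchors_t = np.array(sorted(WORKED_ANCHORS))
    anchors_f = np.array([WORKED_ANCHORS[t] for t in anchors_t])
    grid = log_grid(include=anchors_t)
    fl = np.interp(np.log10(grid), np.log10(anchors_t), anchors_f)
    return make_transient(grid, fl)


@pytest.fixture(scope="session")
def default_experiment():
    """One full synthetic experiment at generator defaults (seed 42)."""
    return generate_experiment(GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def default_jip_table(default_experiment):
    transients, _ = default_experiment
    return jip_table(transients)
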