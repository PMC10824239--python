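"""Experimental design of the graded root-cutting experiment.

Roots are severed over a set cutting angle of the 360° root circle; the root
cutting ratio (RCR) is that angle expressed as a percentage.  The design has a
control (CK, RCR 0 %), five angle-defined treatment groups and a full-removal
group, each with three replicate plants, measured at five clock times on two
days, twice per leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError

#: Cutting angle (degrees) per angle-defined treatment group.
CUTTING_ANGLES_DEG = {10.0: 36.0, 20.0: 72.0, 30.0: 108.0, 50.0: 180.0, 75.0: 270.0}


def angle_to_rcr(angle_deg: float) -> float:
    """Root cutting ratio (percent of the root circle) for a cutting angle.

    rcr = angle/360 × 100, for angles in [0, 360] degrees.
    """
    if not 0.0 <= angle_deg <= 360.0:
        raise ConfigError(f"cutting angle {angle_deg!r} outside [0, 360] degrees")
    return angle_deg / 360.0 * 100.0


@dataclass(frozen=True)
class ExperimentDesign:
    """Ordered RCR levels, replication and measurement schedule."""

    groups: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 50.0, 75.0, 100.0)
    replicates: int = 3
    clock_times: tuple[int, ...] = (9, 11, 13, 15, 17)
    days: tuple[int, ...] = (1, 2)
    measurements_per_leaf: int = 2
    control: float = 0.0

    def __post_init__(self) -> None:
        if self.control not in self.groups:
            raise ConfigError(f"control group {self.control} not among groups {self.groups}")
        if self.replicates < 1 or self.measurements_per_leaf < 1:
            raise ConfigError("replicates and measurements_per_leaf must be >= 1")
        for g in self.groups:
            if not 0.0 <= g <= 100.0:
                raise ConfigError(f"RCR level {g} outside [0, 100] %")
            angle = CUTTING_ANGLES_DEG.get(g)
            if angle is not None and angle_to_rcr(angle) != g:
                raise ConfigError(f"group {g} % inconsistent with cutting angle {angle}°")

    @property
    def n_leaves(self) -> int:
        return len(self.groups) * self.replicates * len(self.clock_times) * len(self.days)

    @property
    def n_transients(self) -> int:
        return self.n_leaves * self.measurements_per_leaf
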