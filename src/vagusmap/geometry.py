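"""Nerve/cuff geometry and angular conventions.

All lengths are SI meters internally; center-of-mass tables are exported in
micrometers.  Angles follow the mathematical convention: degrees
counterclockwise from the 3 o'clock direction (+x).  The cuff opening is
fixed at 90 degrees (12 o'clock, ventral).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: number of cuff electrodes around the ring
N_ELECTRODES = 14
#: skip of the current-injection protocol (electrodes 4 positions apart)
PROTOCOL_SKIP = 4
#: angular pitch between neighbouring electrodes, degrees
ELECTRODE_PITCH_DEG = 360.0 / N_ELECTRODES
#: angle of the cuff opening (ventral), degrees
CUFF_OPENING_DEG = 90.0


def clock_to_deg(hour: float) -> float:
    """Map a clock-face hour to math-convention degrees (12 o'clock = 90)."""
    return (90.0 - 30.0 * hour) % 360.0


def wrap_deg(angle: float | np.ndarray) -> np.ndarray | float:
    """Wrap an angle difference into (-180, 180] degrees."""
    return -((180.0 - np.asarray(angle)) % 360.0 - 180.0)


def electrode_angles_deg(n_electrodes: int = N_ELECTRODES) -> np.ndarray:
    """Center angles of the cuff electrodes, degrees CCW from +x.

    The electrodes are evenly spaced; the gap between the last and first
    electrode is centered on the cuff opening at 90 degrees.
    """
    pitch = 360.0 / n_electrodes
    return (CUFF_OPENING_DEG + pitch * (np.arange(n_electrodes) + 0.5)) % 360.0


@dataclass(frozen=True)
class NerveGeometry:
    """Cylindrical nerve-in-saline model geometry and conductivities.

    The nerve is a 3 mm diameter cylinder; the saline bath is an annular
    external domain (8 mm outer / 5 mm inner diameter) in contact with the
    nerve at its longitudinal extremities.  Conductivities are uniform per
    region.
    """

    nerve_diameter: float = 3e-3
    nerve_length: float = 18e-3
    saline_outer_diameter: float = 8e-3
    saline_inner_diameter: float = 5e-3
    sigma_nerve: float = 0.3
    sigma_saline: float = 1.4

    def __post_init__(self) -> None:
        for name in ("nerve_diameter", "nerve_length", "saline_outer_diameter",
                     "saline_inner_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma_nerve <= 0 or self.sigma_saline <= 0:
            raise ValueError("conductivities must be positive")
        if self.saline_inner_diameter < self.nerve_diameter:
            raise ValueError("saline inner diameter must be >= nerve diameter")

    @property
    def nerve_radius(self) -> float:
        return 0.5 * self.nerve_diameter
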