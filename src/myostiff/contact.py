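"""Spherical-indenter contact mechanics shared by the simulator and the estimator.

The Hertz model for a rigid sphere of radius ``r`` pressed a depth ``delta``
into an incompressible elastic half-space of Young's modulus ``E`` gives

    F(delta) = (4/3) * E / (1 - nu**2) * sqrt(r) * delta**1.5

All quantities are SI (N, m, Pa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProbeParams", "hertz_force", "hertz_prefactor"]


@dataclass(frozen=True)
class ProbeParams:
    """AFM probe calibration.

    Parameters
    ----------
    spring_constant : float
        Cantilever spring constant in N/m.
    tip_radius : float
        Spherical tip radius in m.
    poisson_ratio : float
        Poisson ratio of the sample; 0.5 for incompressible soft tissue.
    """

    spring_constant: float
    tip_radius: float
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError(f"spring_constant must be > 0, got {self.spring_constant}")
        if self.tip_radius <= 0:
            raise ValueError(f"tip_radius must be > 0, got {self.tip_radius}")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError(f"poisson_ratio must be in [0, 0.5], got {self.poisson_ratio}")


def hertz_prefactor(E: float, probe: ProbeParams) -> float:
    """Return C such that F = C * delta**1.5 for the spherical Hertz contact."""
    return (4.0 / 3.0) * E / (1.0 - probe.poisson_ratio**2) * np.sqrt(probe.tip_radius)


def hertz_force(delta, E: float, probe: ProbeParams):
    """Hertz contact force (N) at indentation depth ``delta`` (m); vectorized."""
    delta = np.asarray(delta, dtype=float)
    return hertz_prefactor(E, probe) * np.clip(delta, 0.0, None) ** 1.5
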