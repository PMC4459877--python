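"""Physical constants and geometry of the hit-target model.

The model treats the radiosensitive structure as a sphere of effective
volume ``V`` and density ``rho`` in which an absorbed dose ``D`` (Gy,
i.e. J/kg) deposits on average ``V*rho*D/epsilon`` complete "hits",
where ``epsilon`` is the energy required for one complete hit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

#: 1 electron-volt in joules, to the two significant figures conventionally
#: used when quoting D37-derived target sizes.
EV_J = 1.6e-19

#: Density of water, kg/m^3 — the standard assumption for biological targets.
WATER_DENSITY = 1000.0


@dataclass(frozen=True)
class TargetPhysics:
    """Energy-per-hit and medium density defining the hit scale.

    Parameters
    ----------
    epsilon_j : float
        Mean energy (J) that must be absorbed by the target to register one
        complete hit. Default 1 eV: with this choice the published
        D37-to-diameter conversions for cells, viruses and seeds are
        reproduced (see :mod:`targetkit.datasets`).
    rho_kg_m3 : float
        Target density (kg/m^3), default water.
    """

    epsilon_j: float = EV_J
    rho_kg_m3: float = WATER_DENSITY

    def __post_init__(self) -> None:
        if not (self.epsilon_j > 0):
            raise ValueError(f"epsilon_j must be positive, got {self.epsilon_j!r}")
        if not (self.rho_kg_m3 > 0):
            raise ValueError(f"rho_kg_m3 must be positive, got {self.rho_kg_m3!r}")


#: Module-wide default physics (epsilon = 1 eV, rho = water).
DEFAULT_PHYSICS = TargetPhysics()


@dataclass(frozen=True)
class TargetGeometry:
    """Effective target volume and its sphere-equivalent diameter.

    The target is modelled as a sphere, so the diameter is always
    ``(6 V / pi)**(1/3)``; construct instances through
    :meth:`from_volume` or :meth:`from_diameter` to keep the two fields
    consistent.
    """

    volume_m3: float
    diameter_m: float

    def __post_init__(self) -> None:
        if not (self.volume_m3 > 0):
            raise ValueError(f"volume_m3 must be positive, got {self.volume_m3!r}")
        expected = sphere_diameter(self.volume_m3)
        if not math.isclose(self.diameter_m, expected, rel_tol=1e-9):
            raise ValueError(
                f"diameter_m {self.diameter_m!r} inconsistent with volume "
                f"{self.volume_m3!r} (expected {expected!r})"
            )

    @classmethod
    def from_volume(cls, volume_m3: float) -> "TargetGeometry":
        if not (volume_m3 > 0):
            raise ValueError(f"volume_m3 must be positive, got {volume_m3!r}")
        return cls(volume_m3=volume_m3, diameter_m=sphere_diameter(volume_m3))

    @classmethod
    def from_diameter(cls, diameter_m: float) -> "TargetGeometry":
        if not (diameter_m > 0):
            raise ValueError(f"diameter_m must be positive, got {diameter_m!r}")
        volume = math.pi / 6.0 * diameter_m**3
        return cls(volume_m3=volume, diameter_m=diameter_m)

    @property
    def diameter_nm(self) -> float:
        return self.diameter_m * 1e9


def sphere_diameter(volume_m3: float) -> float:
    """Diameter of a sphere of the given volume: ``(6 V / pi)**(1/3)``."""
    return (6.0 * volume_m3 / math.pi) ** (1.0 / 3.0)


def round_sig(x: float, digits: int = 3) -> float:
    """Round ``x`` to ``digits`` significant figures (presentation only)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - int(math.floor(math.log10(abs(x)))))
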