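"""Closed-form target-theory mathematics.

A dose ``D`` (Gy) delivered to an effective target of volume ``V`` and
density ``rho`` deposits on average

    m = V * rho * D / epsilon

complete hits. Hit counts are Poisson distributed with mean ``m``, so a
target that tolerates up to ``k`` hits survives (here: the sprout still
elongates) with probability

    S_k(m) = exp(-m) * sum_{n=0}^{k} m^n / n!

i.e. the Poisson CDF at ``k``. The characteristic dose D37 is the dose at
which survival falls to exp(-1) ~= 37%; under the no-hit model (k = 0)
the mean hit number at D37 is exactly 1, which ties D37 to geometry:

    V = epsilon / (rho * D37).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

from scipy import optimize, stats

from .physics import TargetGeometry, TargetPhysics

#: The survival level that defines D37: exp(-1) ~= 0.3679, printed as 37%.
SURVIVAL_AT_D37 = math.exp(-1.0)


@dataclass(frozen=True)
class HitModelSpec:
    """Number of complete hits the target tolerates before losing function.

    ``hits_tolerated = 0`` is the classical single-hit ("no hit" survives)
    model; ``1`` means survival requires at most one hit ("no + one hit");
    and so on.
    """

    hits_tolerated: int = 0

    def __post_init__(self) -> None:
        k = self.hits_tolerated
        if not isinstance(k, int) or isinstance(k, bool) or k < 0:
            raise ValueError(f"hits_tolerated must be a non-negative integer, got {k!r}")


KLike = Union[int, HitModelSpec]


def _as_k(spec: KLike) -> int:
    if isinstance(spec, HitModelSpec):
        return spec.hits_tolerated
    return HitModelSpec(spec).hits_tolerated


@dataclass(frozen=True)
class HitDistribution:
    """Poisson hit-count distribution at a given mean hit number."""

    mean_hits: float

    def pmf(self, n: int) -> float:
        return hit_pmf(self.mean_hits, n)

    def survival(self, spec: KLike = 0) -> float:
        return survival_probability(self.mean_hits, spec)


@dataclass(frozen=True)
class EnlargementResult:
    """Solution of the k-hit D37 condition ``S_k(x*) = exp(-1)``.

    ``threshold`` is the mean hit number x* at D37 under the k-hit model;
    ``ratio`` is x* relative to the single-hit threshold of 1 — at a fixed
    D37 the effective volume scales with the mean hit number, so ``ratio``
    is the factor by which the k-hit target volume exceeds the single-hit
    one.
    """

    hits_tolerated: int
    threshold: float
    ratio: float
    residual: float


def mean_hits(physics: TargetPhysics, volume_m3: float, dose_gy: float) -> float:
    """Average number of complete hits: ``V * rho * D / epsilon``.

    Linear in both volume and dose; dimensionless.
    """
    if not (volume_m3 > 0):
        raise ValueError(f"volume_m3 must be positive, got {volume_m3!r}")
    if dose_gy < 0:
        raise ValueError(f"dose_gy must be non-negative, got {dose_gy!r}")
    return volume_m3 * physics.rho_kg_m3 * dose_gy / physics.epsilon_j


def hit_pmf(mean: float, n: int) -> float:
    """Probability of exactly ``n`` hits at mean hit number ``mean``.

    Poisson pmf ``mean**n * exp(-mean) / n!``, evaluated in log space so
    large ``n`` and ``mean`` are handled without overflow.
    """
    if mean < 0:
        raise ValueError(f"mean must be non-negative, got {mean!r}")
    if not isinstance(n, (int,)) or isinstance(n, bool) or n < 0:
        raise ValueError(f"n must be a non-negative integer, got {n!r}")
    return float(stats.poisson.pmf(n, mean))


def survival_probability(mean: float, spec: KLike = 0) -> float:
    """Probability of at most ``k`` hits: ``exp(-m) * sum_{n<=k} m^n/n!``.

    Equals the Poisson CDF at ``k``; strictly decreasing in ``mean`` for
    mean > 0 and non-decreasing in ``k``.
    """
    if mean < 0:
        raise ValueError(f"mean must be non-negative, got {mean!r}")
    k = _as_k(spec)
    return float(stats.poisson.cdf(k, mean))


def d37_to_volume(physics: TargetPhysics, d37_gy: float) -> TargetGeometry:
    """Effective target geometry implied by a D37 dose.

    At D37 the single-hit model requires a mean hit number of exactly 1,
    so ``V = epsilon / (rho * D37)``; the sphere-equivalent diameter is
    ``(6 V / pi)**(1/3)``.
    """
    if not (d37_gy > 0):
        raise ValueError(f"d37_gy must be positive, got {d37_gy!r}")
    volume = physics.epsilon_j / (physics.rho_kg_m3 * d37_gy)
    return TargetGeometry.from_volume(volume)


def volume_to_d37(physics: TargetPhysics, geometry: TargetGeometry) -> float:
    """Inverse of :func:`d37_to_volume`: ``D37 = epsilon / (rho * V)``."""
    if not (geometry.volume_m3 > 0):
        raise ValueError(f"volume must be positive, got {geometry.volume_m3!r}")
    return physics.epsilon_j / (physics.rho_kg_m3 * geometry.volume_m3)


def k_hit_threshold(spec: KLike = 1, tolerance: float = 1e-10) -> EnlargementResult:
    """Mean hit number at which the k-hit survival curve crosses exp(-1).

    Solves ``S_k(x) = exp(-1)`` for the unique root x* > 0 by bracketed
    root finding on [k, k+10]; the root exists and is unique because S_k
    is continuous and strictly decreasing with S_k(k) > exp(-1) > S_k(k+10).
    For k = 0 the root is exactly 1; for k = 1 it is 2.146..., the factor
    by which a two-hit target volume must exceed the one-hit volume to
    show the same D37.
    """
    if not (0 < tolerance <= 1e-6):
        raise ValueError(f"tolerance must be in (0, 1e-6], got {tolerance!r}")
    k = _as_k(spec)
    if k == 0:
        return EnlargementResult(hits_tolerated=0, threshold=1.0, ratio=1.0, residual=0.0)

    def f(x: float) -> float:
        return survival_probability(x, k) - SURVIVAL_AT_D37

    root = float(optimize.brentq(f, k, k + 10.0, xtol=min(tolerance, 1e-12)))
    residual = abs(f(root))
    if residual > tolerance:
        raise RuntimeError(
            f"k_hit_threshold residual {residual:.3e} exceeds tolerance {tolerance:.3e}"
        )
    return EnlargementResult(hits_tolerated=k, threshold=root, ratio=root / 1.0, residual=residual)


def cross_section_to_diameter(sigma_m2: float) -> float:
    """Diameter (m) of a circle with area ``sigma_m2``: ``2 * sqrt(sigma/pi)``.

    Used for the nuclear cross-section analogy: a large interaction
    cross-section plays the same role as a large effective target area.
    """
    if not (sigma_m2 > 0):
        raise ValueError(f"sigma_m2 must be positive, got {sigma_m2!r}")
    return 2.0 * math.sqrt(sigma_m2 / math.pi)


def d37_mean_hits(physics: TargetPhysics, d37_gy: float, dose_gy: float) -> float:
    """Mean hit number at ``dose_gy`` for a single-hit target with the given D37.

    Convenience composition of :func:`d37_to_volume` and :func:`mean_hits`;
    equals ``dose / d37`` independently of the physics constants.
    """
    geometry = d37_to_volume(physics, d37_gy)
    return mean_hits(physics, geometry.volume_m3, dose_gy)
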