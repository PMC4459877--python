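"""Closed-form hit statistics: pmf, cumulative survival, thresholds, geometry."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetkit import (
    DEFAULT_PHYSICS,
    SURVIVAL_AT_D37,
    HitModelSpec,
    TargetGeometry,
    TargetPhysics,
    cross_section_to_diameter,
    d37_to_volume,
    hit_pmf,
    k_hit_threshold,
    mean_hits,
    round_sig,
    survival_probability,
    volume_to_d37,
)


def poisson_cumulative_oracle(mean: float, k: int) -> float:
    """Independent route: explicit fsum of exp(n ln m - m - lgamma(n+1))."""
    if mean == 0:
        return 1.0
    return math.fsum(
        math.exp(n * math.log(mean) - mean - math.lgamma(n + 1)) for n in range(k + 1)
    )


class TestMeanHits:
    def test_unit_mean_at_d37(self):
        # V = eps/(rho*D37) makes the mean hit number exactly 1 at D37
        for d37 in (2.6, 985.0, 8740.0):
            volume = DEFAULT_PHYSICS.epsilon_j / (DEFAULT_PHYSICS.rho_kg_m3 * d37)
            assert mean_hits(DEFAULT_PHYSICS, volume, d37) == pytest.approx(1.0, rel=1e-12)

    def test_zero_dose_and_linearity(self):
        v = 1e-25
        assert mean_hits(DEFAULT_PHYSICS, v, 0.0) == 0.0
        m1 = mean_hits(DEFAULT_PHYSICS, v, 7.0)
        assert mean_hits(DEFAULT_PHYSICS, v, 14.0) == pytest.approx(2 * m1, rel=1e-12)
        assert mean_hits(DEFAULT_PHYSICS, 2 * v, 7.0) == pytest.approx(2 * m1, rel=1e-12)

    @pytest.mark.parametrize("volume,dose", [(-1e-25, 1.0), (0.0, 1.0), (1e-25, -1.0)])
    def test_rejects_bad_inputs(self, volume, dose):
        with pytest.raises(ValueError):
            mean_hits(DEFAULT_PHYSICS, volume, dose)


class TestHitPmf:
    @pytest.mark.parametrize(
        "mean,n,expected",
        [
            (0.0, 0, 1.0),
            (1.0, 0, math.exp(-1)),
            (2.0, 1, 2.0 * math.exp(-2)),  # direct factorial evaluation
        ],
    )
    def test_examples(self, mean, n, expected):
        assert hit_pmf(mean, n) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mean,n", [(-0.1, 0), (1.0, -1), (1.0, 1.5)])
    def test_rejects_bad_inputs(self, mean, n):
        with pytest.raises(ValueError):
            hit_pmf(mean, n)

    @pytest.mark.parametrize("mean", [0.1, 1.0, 10.0, 100.0])
    def test_normalization_adaptive_truncation(self, mean):
        n_max = int(mean + 20 * math.sqrt(mean) + 30)
        total = math.fsum(hit_pmf(mean, n) for n in range(n_max))
        assert abs(total - 1.0) < 1e-12

    def test_stable_for_large_n(self):
        # far tail must underflow gracefully, not overflow
        assert 0.0 <= hit_pmf(5.0, 500) < 1e-300


class TestSurvival:
    @pytest.mark.parametrize("k", [0, 1, 3, 10])
    @pytest.mark.parametrize("mean", [0.0, 0.1, 1.0, 2.5, 17.0, 50.0])
    def test_matches_explicit_cumulative_sum(self, mean, k):
        assert survival_probability(mean, k) == pytest.approx(
            poisson_cumulative_oracle(mean, k), abs=1e-12
        )

    def test_examples(self):
        assert survival_probability(1.0, 0) == pytest.approx(math.exp(-1), rel=1e-12)
        assert round(survival_probability(1.0, 0), 2) == 0.37
        for k in range(5):
            assert survival_probability(0.0, k) == 1.0
        assert survival_probability(2.146, 1) == pytest.approx(math.exp(-1), abs=1e-3)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        m=st.floats(min_value=0.5, max_value=40.0),
        delta=st.floats(min_value=1e-3, max_value=5.0),
        k=st.integers(min_value=0, max_value=8),
    )
    def test_strictly_decreasing_in_mean_increasing_in_k(self, m, delta, k):
        assert survival_probability(m + delta, k) < survival_probability(m, k)
        assert survival_probability(m, k + 1) > survival_probability(m, k)

    def test_d37_identity_any_d37(self):
        # the d37-implied mean is 1, where the no-hit model gives exp(-1) exactly
        for d37 in (0.5, 2.6, 985.0, 1e4):
            geometry = d37_to_volume(DEFAULT_PHYSICS, d37)
            m = mean_hits(DEFAULT_PHYSICS, geometry.volume_m3, d37)
            assert survival_probability(m, 0) == pytest.approx(SURVIVAL_AT_D37, rel=1e-12)


class TestGeometry:
    @pytest.mark.parametrize(
        "d37,diameter_nm",
        [(2.60, 49.0), (2700.0, 4.84), (550.0, 8.22), (6.00, 37.1)],
    )
    def test_published_diameters(self, d37, diameter_nm):
        geometry = d37_to_volume(DEFAULT_PHYSICS, d37)
        assert round_sig(geometry.diameter_nm, 3) == diameter_nm

    def test_cube_root_scaling(self):
        d1 = d37_to_volume(DEFAULT_PHYSICS, 100.0).diameter_nm
        d8 = d37_to_volume(DEFAULT_PHYSICS, 800.0).diameter_nm
        assert d8 == pytest.approx(d1 / 2.0, rel=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(d37=st.floats(min_value=1.0, max_value=1e4))
    def test_volume_round_trip(self, d37):
        geometry = d37_to_volume(DEFAULT_PHYSICS, d37)
        assert volume_to_d37(DEFAULT_PHYSICS, geometry) == pytest.approx(d37, rel=1e-12)

    def test_diameter_scaling_invariant(self):
        # diameter * d37^(1/3) is the same constant for every input
        values = [
            d37_to_volume(DEFAULT_PHYSICS, d).diameter_nm * d ** (1 / 3)
            for d in (2.40, 2.60, 20.3, 550.0, 2700.0, 8740.0)
        ]
        assert max(values) - min(values) < 1e-9 * values[0]

    def test_diameter_3_27_nm_implies_d37_8740(self):
        geometry = TargetGeometry.from_diameter(3.27e-9)
        assert volume_to_d37(DEFAULT_PHYSICS, geometry) == pytest.approx(8740.0, rel=2e-3)

    def test_custom_physics(self):
        doubled = TargetPhysics(epsilon_j=2 * DEFAULT_PHYSICS.epsilon_j)
        ratio = (
            d37_to_volume(doubled, 100.0).diameter_nm
            / d37_to_volume(DEFAULT_PHYSICS, 100.0).diameter_nm
        )
        assert ratio == pytest.approx(2 ** (1 / 3), rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            d37_to_volume(DEFAULT_PHYSICS, 0.0)
        with pytest.raises(ValueError):
            TargetGeometry.from_volume(-1.0)
        with pytest.raises(ValueError):
            TargetPhysics(epsilon_j=-1.0)


class TestKHitThreshold:
    def test_single_hit_threshold_is_one(self):
        res = k_hit_threshold(0)
        assert res.threshold == 1.0 and res.ratio == 1.0

    def test_two_hit_enlargement(self):
        res = k_hit_threshold(HitModelSpec(1))
        assert res.threshold == pytest.approx(2.146193220620582, abs=1e-9)
        assert res.ratio == res.threshold

    def test_three_hit_threshold(self):
        # frozen from the explicit-sum oracle solved by bisection
        assert k_hit_threshold(2).threshold == pytest.approx(3.2582524688670405, abs=1e-9)

    @pytest.mark.parametrize("k", range(7))
    def test_root_reproduces_survival_level(self, k):
        res = k_hit_threshold(k, tolerance=1e-10)
        assert abs(survival_probability(res.threshold, k) - SURVIVAL_AT_D37) <= 1e-10

    def test_thresholds_strictly_increasing(self):
        ts = [k_hit_threshold(k).threshold for k in range(8)]
        assert all(b > a for a, b in zip(ts, ts[1:]))

    def test_tolerance_validation(self):
        with pytest.raises(ValueError):
            k_hit_threshold(1, tolerance=1e-3)


class TestCrossSection:
    def test_cobalt_59_analogy(self):
        # 37 barns -> ~69 on the 1e-15 m scale
        d = cross_section_to_diameter(37e-28)
        assert round(d / 1e-15) == 69

    def test_area_scaling_and_round_trip(self):
        d = cross_section_to_diameter(1e-20)
        assert cross_section_to_diameter(4e-20) == pytest.approx(2 * d, rel=1e-12)
        assert math.pi * (d / 2) ** 2 == pytest.approx(1e-20, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cross_section_to_diameter(0.0)
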