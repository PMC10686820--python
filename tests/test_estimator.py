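"""The interval CFU estimator, its error metric and detection limit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gva import (
    ColonySet,
    ConeGeometry,
    convergence_trace,
    estimate_cfu,
    factor_off,
    limit_of_detection,
    sample_first_positions,
)
from gva.simulator import replicate_rngs

# hand evaluation: positions 9/18/27 mm, interval [9, 27) holds N=2 colonies,
# probability mass (27^3 - 9^3)/36^3 = 0.40625, gel volume 0.15 mL, dilution 100
HAND_ESTIMATE = 2.0 / (0.15 * 0.40625) * 100.0


@pytest.fixture
def three_colonies(p200):
    return ColonySet("t1", [9.0, 18.0, 27.0], p200, dilution_factor=100.0)


class TestEstimate:
    def test_interval_mode_hand_value(self, three_colonies):
        est = estimate_cfu(three_colonies, k=3)
        assert est.n_counted == 2
        assert est.interval_mm == (9.0, 27.0)
        assert est.cfu_per_ml_sample == pytest.approx(HAND_ESTIMATE)
        assert est.cfu_per_ml_gel == pytest.approx(HAND_ESTIMATE / 100.0)

    def test_full_volume_is_count_over_volume(self, three_colonies):
        est = estimate_cfu(three_colonies, k="all", mode="full_volume")
        assert est.cfu_per_ml_sample == pytest.approx(3.0 / 0.15 * 100.0)

    def test_empty_set_flags_below_lod(self, p200):
        est = estimate_cfu(ColonySet("t", [], p200))
        assert est.below_lod and est.cfu_per_ml_sample is None
        assert est.upper_bound_cfu_per_ml == pytest.approx(100.0 / 0.15)

    def test_single_colony_interval_mode_errors(self, p200):
        with pytest.raises(ValueError, match="full_volume"):
            estimate_cfu(ColonySet("t", [10.0], p200), k=1)

    def test_tied_first_last_is_degenerate(self, p200):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_cfu(ColonySet("t", [10.0, 10.0], p200), k=2)

    def test_unknown_mode_rejected(self, three_colonies):
        with pytest.raises(ValueError):
            estimate_cfu(three_colonies, mode="closed_interval")

    def test_radial_coordinates_do_not_change_estimate(self, p200, rng):
        pos = np.sort(rng.uniform(1.0, 35.0, size=12))
        bare = ColonySet("t", pos, p200)
        withyz = ColonySet("t", pos, p200, y_mm=rng.normal(size=12), z_mm=rng.normal(size=12))
        for mode in ("interval", "tip_anchored", "full_volume"):
            a = estimate_cfu(bare, k=10, mode=mode).cfu_per_ml_sample
            b = estimate_cfu(withyz, k=10, mode=mode).cfu_per_ml_sample
            assert a == b  # bit-for-bit

    def test_dilution_scale_equivariance(self, p200, rng):
        pos = np.sort(rng.uniform(1.0, 35.0, size=8))
        base = estimate_cfu(ColonySet("t", pos, p200, dilution_factor=2.0), k=8)
        scaled = estimate_cfu(ColonySet("t", pos, p200, dilution_factor=16.0), k=8)
        assert scaled.cfu_per_ml_sample == base.cfu_per_ml_sample * 8.0  # exact: powers of 2

    def test_tip_anchored_uses_apex_interval(self, three_colonies):
        est = estimate_cfu(three_colonies, k=3, mode="tip_anchored")
        assert est.interval_mm == (0.0, 27.0)
        assert est.cfu_per_ml_sample == pytest.approx(2.0 / (0.15 * (27.0 / 36.0) ** 3) * 100.0)


class TestTrace:
    def test_trace_matches_estimator_at_each_k(self, three_colonies):
        trace = convergence_trace(three_colonies)
        assert [k for k, _ in trace] == [2, 3]
        assert trace[-1][1] == pytest.approx(HAND_ESTIMATE)
        assert trace[0][1] == estimate_cfu(three_colonies, k=2).cfu_per_ml_sample

    def test_single_colony_gives_empty_trace(self, p200):
        assert convergence_trace(ColonySet("t", [5.0], p200)) == []

    def test_estimate_can_carry_trace(self, three_colonies):
        est = estimate_cfu(three_colonies, k=3, with_trace=True)
        assert len(est.convergence_trace) == 2


@pytest.mark.parametrize(
    "calc, actual, expected",
    [(100.0, 100.0, 1.0), (200.0, 100.0, 2.0), (50.0, 100.0, 1.5)],
)
def test_factor_off_examples(calc, actual, expected):
    assert factor_off(calc, actual) == pytest.approx(expected)


def test_factor_off_rejects_nonpositive_truth():
    with pytest.raises(ValueError):
        factor_off(10.0, 0.0)


@settings(derandomize=True, max_examples=50)
@given(
    calc=st.floats(min_value=1e-3, max_value=1e9),
    actual=st.floats(min_value=1e-3, max_value=1e9),
)
def test_factor_off_at_least_one(calc, actual):
    fo = factor_off(calc, actual)
    assert fo >= 1.0
    if calc == actual:
        assert fo == 1.0


@pytest.mark.parametrize(
    "volume_uL, dilution, expected",
    [(150.0, 100.0, 2000.0 / 3.0), (1000.0, 1.0, 1.0), (150.0, 1.0, 20.0 / 3.0)],
)
def test_limit_of_detection(volume_uL, dilution, expected):
    geom = ConeGeometry("circular_cone", 36.0, volume_uL)
    assert limit_of_detection(geom, dilution) == pytest.approx(expected)


def test_lod_rounds_to_667(p200):
    assert round(limit_of_detection(p200, 100.0)) == 667


def test_full_volume_oracle_equivalence(p200, rng):
    """Whole-vessel mode equals count/volume x dilution exactly, any input."""
    for n in (1, 5, 40):
        pos = np.sort(rng.uniform(0.0, 36.0, size=n))
        cs = ColonySet("t", pos, p200, dilution_factor=100.0)
        est = estimate_cfu(cs, k="all", mode="full_volume")
        assert est.cfu_per_ml_sample == n / 0.15 * 100.0


def test_interval_mass_monotone_in_width(p200):
    from gva import axial_cdf

    widths = [(12.0, 15.0), (12.0, 20.0), (10.0, 20.0), (5.0, 30.0)]
    masses = [axial_cdf(p200, b) - axial_cdf(p200, a) for a, b in widths]
    assert all(m > 0 for m in masses)
    assert masses == sorted(masses)


def test_median_recovery_within_factor_two_across_densities(p200):
    """First-10-colony estimates recover seeded densities over 4 decades."""
    for density in (1e3, 1e5, 1e7):
        fo = []
        for rng in replicate_rngs(99, 300):
            pos = sample_first_positions(density, p200, 10, rng)
            if pos.size < 10:
                continue
            est = estimate_cfu(ColonySet("s", pos, p200, dilution_factor=1.0), k=10)
            fo.append(factor_off(est.cfu_per_ml_gel, density))
        assert np.median(fo) < 2.0
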