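"""Missed-colony / apex-offset perturbations and replicate noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gva import (
    ColonySet,
    PerturbationSpec,
    drop_colonies,
    error_sweep,
    estimate_cfu,
    offset_tip,
    replicate_cv,
)


@pytest.fixture
def fifteen(p200, rng):
    return ColonySet("t", np.sort(rng.uniform(0.5, 35.5, 15)), p200, dilution_factor=1.0)


class TestDrop:
    def test_zero_missing_is_identity(self, fifteen):
        out = drop_colonies(fifteen, PerturbationSpec(n_missing=0))
        assert out is fifteen
        assert estimate_cfu(out, k=10).cfu_per_ml_sample == estimate_cfu(fifteen, k=10).cfu_per_ml_sample

    def test_uniform_random_keeps_sorted_subset(self, fifteen, rng):
        out = drop_colonies(fifteen, PerturbationSpec(n_missing=10), rng=rng)
        assert out.n_colonies == 5
        assert np.all(np.diff(out.positions_mm) >= 0)
        assert np.all(np.isin(out.positions_mm, fifteen.positions_mm))

    def test_nearest_tip_first_moves_x1(self, fifteen):
        out = drop_colonies(fifteen, PerturbationSpec(3, "nearest_tip_first"))
        assert np.array_equal(out.positions_mm, fifteen.positions_mm[3:])

    def test_farthest_first_keeps_head(self, fifteen):
        out = drop_colonies(fifteen, PerturbationSpec(3, "farthest_first"))
        assert np.array_equal(out.positions_mm, fifteen.positions_mm[:12])

    def test_too_few_remaining_errors(self, fifteen):
        with pytest.raises(ValueError, match="at least 2"):
            drop_colonies(fifteen, PerturbationSpec(n_missing=14))

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            PerturbationSpec(1, "psychic")


class TestOffset:
    def test_zero_offset_identity(self, fifteen):
        assert offset_tip(fifteen, 0.0) is fifteen

    def test_positive_offset_shifts_everything(self, fifteen):
        out = offset_tip(fifteen, 4.0)
        assert np.allclose(out.positions_mm, np.clip(fifteen.positions_mm + 4.0, 0, 36.0))

    def test_negative_offset_clips_at_apex(self, p200):
        cs = ColonySet("t", [1.0, 2.0, 30.0], p200)
        out = offset_tip(cs, -4.0)
        assert out.positions_mm[0] == 0.0 and out.positions_mm[-1] == 26.0

    def test_offset_beyond_length_rejected(self, fifteen):
        with pytest.raises(ValueError):
            offset_tip(fifteen, 36.0)


class TestCV:
    def test_identical_replicates_have_zero_cv(self):
        assert replicate_cv([1000.0] * 4) == 0.0

    def test_two_replicate_hand_value(self):
        # sample sd sqrt(((800-1000)^2+(1200-1000)^2)/1)=282.84 over mean 1000
        assert replicate_cv([800.0, 1200.0]) == pytest.approx(0.282842712, rel=1e-8)

    @pytest.mark.parametrize("bad", [[1000.0], [100.0, -5.0]])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            replicate_cv(bad)

    @settings(derandomize=True, max_examples=40)
    @given(
        x=st.lists(st.floats(min_value=1.0, max_value=1e6), min_size=2, max_size=8),
        c=st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, x, c):
        assert replicate_cv(np.asarray(x) * c) == pytest.approx(replicate_cv(x), rel=1e-9, abs=1e-12)

    def test_cv_decreases_with_density(self, p200):
        """Poisson counting noise: quadruplicate CV shrinks as density grows.

        Whole-cone counts make the mechanism explicit — replicate scatter is
        pure Poisson noise in the colony number, so CV ~ 1/sqrt(density x V).
        """
        from gva import SimulationConfig, sample_colonies
        from gva.simulator import replicate_rngs

        cvs = []
        for i, density in enumerate((200.0, 2e4)):
            ests = [
                estimate_cfu(sample_colonies(SimulationConfig(density, p200), rng=rng,
                                             with_radial=False),
                             k="all", mode="full_volume").cfu_per_ml_gel
                for rng in replicate_rngs(31 + i, 40)
            ]
            quads = np.reshape(ests, (10, 4))
            cvs.append(np.mean([replicate_cv(q) for q in quads]))
        assert cvs[1] < cvs[0]


class TestSweep:
    def test_unperturbed_cell_matches_baseline(self, p200):
        tab = error_sweep([1e4], missing_grid=[0], offset_grid=[0.0], n_reps=200, seed=9, geom=p200)
        assert len(tab) == 1
        baseline = tab.iloc[0]
        tab2 = error_sweep([1e4], missing_grid=[0, 5], offset_grid=[0.0], n_reps=200, seed=9, geom=p200)
        same = tab2[(tab2.n_missing == 0)].iloc[0]
        assert same.mean_factor_off == baseline.mean_factor_off  # paired, bit-for-bit

    def test_error_monotone_in_missing_colonies(self, p200):
        tab = error_sweep([1e5], missing_grid=[0, 5, 10], offset_grid=[0.0],
                          n_reps=500, seed=13, geom=p200)
        m = tab.sort_values("n_missing")
        se = (m.sd_factor_off / np.sqrt(m.n_tips)).max()
        assert np.all(np.diff(m.mean_factor_off) > -se)

    def test_high_density_more_sensitive_to_offset(self, p200):
        tab = error_sweep([1e3, 1e7], missing_grid=[0], offset_grid=[4.0],
                          n_reps=400, seed=17, geom=p200)
        by = tab.set_index("density")["mean_factor_off"]
        assert by[1e7] > by[1e3]

    def test_empty_grid_rejected(self, p200):
        with pytest.raises(ValueError):
            error_sweep([1e4], missing_grid=[], offset_grid=[0.0], geom=p200)
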