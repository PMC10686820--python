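"""Synthetic tip rendering and image-based colony recovery.

A coarse 25 µm/px bench profile keeps images small; all tolerances are in
pixels so the checks transfer to finer optics unchanged.
"""

import numpy as np
import pytest

from gva import ColonySet, SimulationConfig, factor_off, sample_colonies
from gva.imaging import (
    OPTICS_PROFILES,
    OpticsProfile,
    SegmentationError,
    colony_radius_um,
    detect_colonies,
    generate_tip_image,
    image_to_estimate,
    segment_tip,
)
from gva.simulator import replicate_rngs

BENCH = OpticsProfile(pixel_size_um=25.0)


@pytest.fixture
def separated_tip(p200):
    """20 well-separated on-axis colonies, noise-free, untilted."""
    pos = np.linspace(6.0, 34.0, 20)
    cs = ColonySet("t", pos, p200, dilution_factor=1.0)
    return cs, generate_tip_image(cs, BENCH, tilt_deg=0.0)


class TestRender:
    def test_empty_tip_renders_silhouette_only(self, p200):
        img = generate_tip_image(ColonySet("t", [], p200), BENCH)
        assert img.truth_positions_mm.size == 0
        levels = np.unique(img.pixels)
        assert levels.size == 2  # background + gel, no colony level

    def test_builtin_optics_profiles(self):
        assert OPTICS_PROFILES["canon"].pixel_size_um == 6.6
        assert OPTICS_PROFILES["iphone12"].pixel_size_um == 13.7

    def test_colony_size_shrinks_with_density(self):
        assert colony_radius_um(1e6) < colony_radius_um(1e4) < colony_radius_um(0.0)

    def test_resolution_warning_on_coarse_optics(self, p200, rng):
        cs = sample_colonies(SimulationConfig(2e5, p200), rng=rng)
        fine = generate_tip_image(cs, OpticsProfile(pixel_size_um=13.7), tilt_deg=0.0)
        coarse = generate_tip_image(cs, OpticsProfile(pixel_size_um=40.0), tilt_deg=0.0)
        assert not fine.resolution_warning
        assert coarse.resolution_warning

    def test_render_deterministic_given_rng(self, p200, rng):
        cs = sample_colonies(SimulationConfig(1e3, p200), rng=rng)
        a = generate_tip_image(cs, BENCH, rng=np.random.default_rng(5))
        b = generate_tip_image(cs, BENCH, rng=np.random.default_rng(5))
        assert np.array_equal(a.pixels, b.pixels)


class TestSegmentTip:
    @pytest.mark.parametrize("tilt", [0.0, 3.0, -2.5])
    def test_apex_and_angle_recovered(self, p200, rng, tilt):
        cs = sample_colonies(SimulationConfig(1e3, p200), rng=rng)
        img = generate_tip_image(cs, BENCH, tilt_deg=tilt)
        seg = segment_tip(img)
        assert abs(seg.axis_angle_deg - tilt) <= 0.5
        assert np.hypot(seg.apex_px[0] - img.apex_px[0], seg.apex_px[1] - img.apex_px[1]) <= 2.0

    def test_blank_image_errors(self):
        with pytest.raises(SegmentationError):
            segment_tip(np.full((200, 100), 0.85))

    def test_noise_tolerated(self, p200, rng):
        cs = sample_colonies(SimulationConfig(1e3, p200), rng=rng)
        img = generate_tip_image(cs, OpticsProfile(pixel_size_um=25.0, noise_sd=0.02),
                                 rng=rng, tilt_deg=1.5)
        seg = segment_tip(img)
        assert abs(seg.axis_angle_deg - 1.5) <= 0.5


class TestDetect:
    def test_round_trip_counts_and_positions(self, separated_tip):
        cs, img = separated_tip
        res = detect_colonies(img)
        assert res.n_colonies == 20
        tol_mm = 2.0 * BENCH.pixel_size_mm
        assert np.max(np.abs(res.positions_mm - cs.positions_mm)) <= tol_mm

    def test_empty_tip_detects_nothing(self, p200):
        img = generate_tip_image(ColonySet("t", [], p200), BENCH)
        assert detect_colonies(img).n_colonies == 0

    def test_level5_window_and_cap(self, p200, rng):
        cs = sample_colonies(SimulationConfig(1e6, p200), rng=rng)
        img = generate_tip_image(cs, BENCH, tilt_deg=0.0)
        res = detect_colonies(img, routine_level=5)
        assert res.n_colonies <= 30
        assert np.all(res.positions_mm <= 36.0 / 20.0 + 1e-9)

    @pytest.mark.parametrize("pixel_um", [25.0, 50.0])
    def test_no_spurious_detections_on_noise_free_images(self, p200, rng, pixel_um):
        """Lower resolution can only lose colonies (noise-free): every
        detection matches a true colony and the count never exceeds truth."""
        cs = sample_colonies(SimulationConfig(1e4, p200), rng=rng)
        img = generate_tip_image(cs, OpticsProfile(pixel_size_um=pixel_um), tilt_deg=0.0)
        res = detect_colonies(img)
        assert 0 < res.n_colonies <= cs.n_colonies
        tol_mm = 3.0 * pixel_um / 1000.0
        for det in res.positions_mm:
            assert np.min(np.abs(cs.positions_mm - det)) <= tol_mm

    def test_curation_add_and_remove(self, separated_tip):
        _, img = separated_tip
        base = detect_colonies(img)
        pruned = detect_colonies(img, remove_px=[tuple(base.centers_px[0])])
        assert pruned.n_colonies == base.n_colonies - 1
        readded = detect_colonies(
            img, remove_px=[tuple(base.centers_px[0])], add_px=[tuple(base.centers_px[0])]
        )
        assert readded.n_colonies == base.n_colonies

    def test_plain_array_requires_pixel_size(self, separated_tip):
        _, img = separated_tip
        with pytest.raises(ValueError, match="pixel_size_um"):
            detect_colonies(img.pixels)


class TestEndToEnd:
    def test_estimate_recovers_density(self, p200):
        fos = []
        for rng in replicate_rngs(61, 8):
            cs = sample_colonies(SimulationConfig(1e4, p200), rng=rng)
            img = generate_tip_image(cs, BENCH, rng=rng)
            est = image_to_estimate(img, dilution_factor=1.0, k=10)
            fos.append(factor_off(est.cfu_per_ml_sample, 1e4))
        assert np.median(fos) <= 1.5

    def test_below_lod_tip(self, p200):
        img = generate_tip_image(ColonySet("t", [], p200), BENCH)
        est = image_to_estimate(img, dilution_factor=100.0)
        assert est.below_lod

    def test_estimate_invariant_to_tilt(self, p200, rng):
        cs = sample_colonies(SimulationConfig(1e4, p200), rng=rng)
        e0 = image_to_estimate(generate_tip_image(cs, BENCH, tilt_deg=0.0), dilution_factor=1.0)
        e3 = image_to_estimate(generate_tip_image(cs, BENCH, tilt_deg=3.0), dilution_factor=1.0)
        assert e3.cfu_per_ml_sample == pytest.approx(e0.cfu_per_ml_sample, rel=0.2)
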