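"""Fiber segmentation, filtering, CSA statistics and group comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage.draw import disk as draw_disk

from ovimyo.morphometry import (
    ImageGrid,
    MorphometryConfig,
    circularity,
    classify_region,
    compare_groups,
    fiber_typing,
    hypertrophy_fraction,
    preprocess,
    segment_fibers,
    summarize,
)
from ovimyo.synthetic import FiberMosaicSpec, make_atpase_image, make_fiber_mosaic


class TestPreprocess:
    def test_noiseless_mosaic_exact_interior(self, noiseless_mosaic):
        _, image, label_map, _ = noiseless_mosaic
        cfg = MorphometryConfig(gaussian_sigma_px=0.0)
        binary = preprocess(image, cfg)
        np.testing.assert_array_equal(binary.pixels > 0, label_map > 0)

    def test_noisy_mosaic_small_disagreement(self):
        spec = FiberMosaicSpec(n_fibers=30, mean_area_px=3000, noise_sd=10.0, seed=8)
        image, label_map, _ = make_fiber_mosaic(spec)
        binary = preprocess(image, MorphometryConfig())
        disagree = np.mean((binary.pixels > 0) != (label_map > 0))
        assert disagree < 0.02

    def test_constant_image_is_an_error(self):
        with pytest.raises(ValueError, match="no contrast"):
            preprocess(ImageGrid(np.full((10, 10), 7)), MorphometryConfig())

    def test_rgb_converted_by_luminance(self, noiseless_mosaic):
        _, image, _, _ = noiseless_mosaic
        rgb = np.repeat(np.asarray(image.pixels)[..., None], 3, axis=2)
        cfg = MorphometryConfig(gaussian_sigma_px=0.0)
        np.testing.assert_array_equal(
            preprocess(ImageGrid(rgb), cfg).pixels,
            preprocess(image, cfg).pixels,
        )


class TestSegmentation:
    def test_recovers_all_mosaic_fibers(self, noiseless_mosaic, default_config):
        spec, image, _, _ = noiseless_mosaic
        regions = segment_fibers(preprocess(image, default_config), default_config)
        accepted = [r for r in regions if r.accepted]
        assert len(accepted) == spec.n_fibers

    def test_opening_splits_bridged_disks(self):
        mask = np.zeros((120, 220), dtype=np.uint8)
        for center in ((60, 60), (60, 160)):
            rr, cc = draw_disk(center, 30)
            mask[rr, cc] = 1
        mask[59:61, 60:160] = 1  # 2-px bridge
        cfg = MorphometryConfig(adhesion_opening_radius_px=3)
        regions = segment_fibers(ImageGrid(mask), cfg)
        accepted = [r for r in regions if r.accepted]
        assert len(accepted) == 2

    def test_empty_image_gives_empty_list(self, default_config):
        assert segment_fibers(ImageGrid(np.zeros((20, 20))), default_config) == []

    def test_holes_filled(self):
        mask = np.zeros((120, 120), dtype=np.uint8)
        rr, cc = draw_disk((60, 60), 40)
        mask[rr, cc] = 1
        mask[55:65, 55:65] = 0  # interior hole
        cfg = MorphometryConfig(fill_holes=True, adhesion_opening_radius_px=0)
        (region,) = segment_fibers(ImageGrid(mask), cfg)
        assert region.pixel_count == int((draw_disk((60, 60), 40)[0]).size)


class TestRegionFilter:
    @pytest.mark.parametrize(
        "area,circ,border,expected_status,expected_reason",
        [
            (1399, 0.8, False, "rejected", "too_small"),
            (1400, 0.8, False, "accepted", None),
            (80000, 0.8, False, "accepted", None),
            (80001, 0.8, False, "rejected", "too_large"),
            (5000, 0.19, False, "rejected", "non_circular"),
            (5000, 0.2, False, "accepted", None),
            (5000, 1.0, False, "accepted", None),
            (1399, 0.1, True, "rejected", "border_touching"),  # first check wins
        ],
    )
    def test_interval_bounds_and_reason_order(
        self, default_config, area, circ, border, expected_status, expected_reason
    ):
        status, reason = classify_region(area, circ, border, default_config)
        assert (status, reason) == (expected_status, expected_reason)

    @given(
        area=st.integers(min_value=1, max_value=120_000),
        circ=st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_literal_interval_check(self, area, circ):
        cfg = MorphometryConfig()
        status, _ = classify_region(area, circ, False, cfg)
        literal = (1400 <= area <= 80000) and (0.2 <= circ <= 1.0)
        assert (status == "accepted") == literal


class TestCircularity:
    def test_ideal_disk_is_exactly_one(self):
        r = 17.3
        assert circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0, abs=1e-12)

    def test_rectangle_closed_form(self):
        assert circularity(1000, 220) == pytest.approx(4 * np.pi * 1000 / 220**2, abs=1e-12)
        assert circularity(1000, 220) == pytest.approx(0.2596, abs=1e-4)

    def test_digitized_disk_within_band(self):
        mask = np.zeros((160, 160), dtype=np.uint8)
        rr, cc = draw_disk((80, 80), 50)
        mask[rr, cc] = 1
        cfg = MorphometryConfig(area_min_px=100, adhesion_opening_radius_px=0)
        (region,) = segment_fibers(ImageGrid(mask), cfg)
        assert 0.85 <= region.circularity <= 1.05

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            circularity(0, 10)
        with pytest.raises(ValueError):
            circularity(10, 0)

    def test_invariant_under_translation_and_rotation(self):
        base = np.zeros((200, 200), dtype=np.uint8)
        rr, cc = draw_disk((70, 80), 35)
        base[rr, cc] = 1
        base[60:80, 80:140] = 1  # asymmetric blob
        cfg = MorphometryConfig(area_min_px=10, adhesion_opening_radius_px=0)

        def circ_of(mask):
            (region,) = segment_fibers(ImageGrid(mask), cfg)
            return region.circularity

        reference = circ_of(base)
        assert circ_of(np.roll(base, (15, -20), axis=(0, 1))) == pytest.approx(
            reference, abs=1e-12
        )
        assert circ_of(np.rot90(base)) == pytest.approx(reference, abs=1e-12)


def _region(label, area, circ=0.9):
    from ovimyo.morphometry import FiberRegion

    return FiberRegion(
        label=label, pixel_count=area, perimeter_px=10.0, circularity=circ,
        centroid=(0.0, 0.0), status="accepted",
    )


class TestSummarize:
    def test_hypertrophy_fraction_example(self):
        assert hypertrophy_fraction([10, 15, 20], 14.2877) == pytest.approx(2 / 3)

    def test_fraction_endpoints(self):
        values = [3.0, 5.0, 9.0]
        assert hypertrophy_fraction(values, -np.inf) == 1.0
        assert hypertrophy_fraction(values, np.inf) == 0.0
        assert hypertrophy_fraction(values, 3.0) == pytest.approx(2 / 3)  # strict >

    @given(
        st.lists(st.floats(min_value=0, max_value=1e5), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_fraction_non_increasing_in_threshold(self, values):
        grid = np.linspace(-1, 1e5 + 1, 25)
        fractions = [hypertrophy_fraction(values, t) for t in grid]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_summary_over_accepted_only(self):
        regions = [_region(1, 10), _region(2, 15), _region(3, 20)]
        regions[2].status = "rejected"
        regions[2].reason = "too_large"
        summary = summarize(regions)
        assert summary.n_accepted == 2
        assert summary.mean_csa == pytest.approx(12.5)

    def test_empty_summary_not_nan_crash(self):
        summary = summarize([])
        assert summary.n_accepted == 0
        assert summary.mean_csa is None
        assert summary.hypertrophy_fraction(1.0) is None

    def test_calibrated_units(self):
        summary = summarize([_region(1, 100)], um_per_px=0.5)
        assert summary.units == "um2"
        assert summary.mean_csa == pytest.approx(25.0)

    def test_mosaic_mean_csa_near_generator_target(self, noiseless_mosaic, default_config):
        spec, image, _, _ = noiseless_mosaic
        regions = segment_fibers(preprocess(image, default_config), default_config)
        summary = summarize(regions)
        assert abs(summary.mean_csa / spec.mean_area_px - 1) < 0.1


class TestFiberTyping:
    def test_known_proportion_recovered_exactly(self):
        image, _ = make_atpase_image(0.4, n_fibers=50, seed=9)
        result = fiber_typing(image)
        assert result.proportion_slow == pytest.approx(0.40)
        assert result.n_total == 50

    @pytest.mark.parametrize("proportion,expected", [(0.0, 0.0), (1.0, 1.0)])
    def test_single_class_extremes_warn(self, proportion, expected):
        image, _ = make_atpase_image(proportion, n_fibers=30, seed=10)
        with pytest.warns(UserWarning, match="unimodal"):
            result = fiber_typing(image)
        assert result.proportion_slow == expected


class TestCompareGroups:
    def test_identical_groups_give_t0_p1(self):
        stat, p = compare_groups([[1, 2, 3], [1, 2, 3]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-3, 4)
        b = 10 + rng.normal(0, 1e-3, 4)
        _, p = compare_groups([a, b])
        assert p < 1e-3

    def test_degenerate_constant_data_warns_p1(self):
        with pytest.warns(UserWarning):
            stat, p = compare_groups([[5, 5, 5], [5, 5, 5]])
        assert (stat, p) == (0.0, 1.0)

    def test_anova_requires_multiple_groups_and_t_exactly_two(self):
        with pytest.raises(ValueError):
            compare_groups([[1, 2, 3]])
        with pytest.raises(ValueError):
            compare_groups([[1, 2], [3, 4], [5, 6]], design="two_sample_t")

    def test_anova_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            groups = [rng.normal(0, 1, 5) for _ in range(3)]
            _, p = compare_groups(groups, design="one_way_anova")
            rejections += p < 0.05
        assert 0.03 <= rejections / reps <= 0.07
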