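"""Tests for the synthetic tissue, patch, viewport and cohort generators."""

import numpy as np
import pytest
from scipy import ndimage

from melanopath import palette as P
from melanopath import synthio
from melanopath.instances import Box, InstanceSet
from melanopath.synthio.tissue import _band_rows


class TestTissue:
    def test_seed_determinism_byte_for_byte(self):
        params = synthio.TissueParams(seed=7, n_mitoses=2)
        a = synthio.gen_tissue_image(params)
        b = synthio.gen_tissue_image(params)
        assert a[0].tobytes() == b[0].tobytes()
        assert a[1].tobytes() == b[1].tobytes()
        assert [x.box if hasattr(x, "box") else x for x in a[2].boxes] == \
            [x for x in b[2].boxes]

    def test_no_nests_requested_means_no_nest_labels(self):
        params = synthio.TissueParams(n_epidermal_nests=0, n_dermal_nests=0)
        _, mask, _ = synthio.gen_tissue_image(params)
        assert not np.isin(mask, (P.DMN, P.EPN)).any()

    def test_dermal_nest_component_count_matches_request(self):
        # oracle: flood-fill component labeling of the DMN class
        params = synthio.TissueParams(seed=3, n_dermal_nests=5,
                                      image_height=160, image_width=160)
        _, mask, _ = synthio.gen_tissue_image(params)
        _, n = ndimage.label(mask == P.DMN,
                             structure=np.ones((3, 3), dtype=int))
        assert n == 5

    def test_nest_containment_in_parent_bands(self):
        params = synthio.TissueParams(seed=11, n_dermal_nests=3,
                                      n_epidermal_nests=2)
        _, mask, _ = synthio.gen_tissue_image(params)
        bands = _band_rows(params)
        rows_dmn = np.nonzero((mask == P.DMN).any(axis=1))[0]
        rows_epn = np.nonzero((mask == P.EPN).any(axis=1))[0]
        de_top, de_bot = bands[P.DE]
        ep_top, ep_bot = bands[P.EP]
        assert rows_dmn.min() >= de_top and rows_dmn.max() < de_bot
        assert rows_epn.min() >= ep_top and rows_epn.max() < ep_bot

    def test_oversized_nest_radius_rejected(self):
        params = synthio.TissueParams(image_height=64, image_width=64,
                                      band_fractions=(0.2, 0.2, 0.5, 0.1),
                                      nest_radius_range=(10, 12))
        with pytest.raises(ValueError, match="radius"):
            synthio.gen_tissue_image(params)

    def test_each_instance_box_covers_nucleus_pixels(self):
        params = synthio.TissueParams(seed=5, noise_sd=0.0)
        img, _, inst = synthio.gen_tissue_image(params)
        color = np.array(P.MELANOCYTE_COLOR)
        assert len(inst) == params.n_melanocytes
        for b in inst.boxes:
            window = img[b.y0:b.y1, b.x0:b.x1]
            assert (window == color).all(axis=2).any()

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            synthio.TissueParams(band_fractions=(-0.1, 0.3, 0.3, 0.3))
        with pytest.raises(ValueError):
            synthio.TissueParams(band_fractions=(0.5, 0.3, 0.3, 0.3))
        with pytest.raises(ValueError):
            synthio.TissueParams(n_melanocytes=-1)


class TestVirtualStain:
    def test_empty_instances_leave_no_stain_color(self):
        img, _, _ = synthio.gen_tissue_image(synthio.TissueParams(seed=1))
        out = synthio.gen_virtual_stain_pair(img, InstanceSet())
        assert not (out == np.array(P.SOX10_COLOR)).all(axis=2).any()

    def test_deterministic_application(self):
        img, _, inst = synthio.gen_tissue_image(synthio.TissueParams(seed=2))
        a = synthio.gen_virtual_stain_pair(img, inst)
        b = synthio.gen_virtual_stain_pair(img, inst)
        assert (a == b).all()

    def test_single_box_pixel_count(self):
        # oracle: a 10x10 box recolors exactly 100 pixels
        img = np.full((40, 40, 3), 200, dtype=np.uint8)
        inst = InstanceSet(boxes=[Box(5, 8, 15, 18)], labels=["melanocyte"])
        out = synthio.gen_virtual_stain_pair(img, inst)
        assert int((out == np.array(P.SOX10_COLOR)).all(axis=2).sum()) == 100

    def test_out_of_bounds_box_rejected(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        inst = InstanceSet(boxes=[Box(10, 10, 25, 15)], labels=["melanocyte"])
        with pytest.raises(ValueError, match="bounds"):
            synthio.gen_virtual_stain_pair(img, inst)


class TestPatchDataset:
    def test_counts_match_ratio(self):
        patches, labels = synthio.gen_patch_dataset(100, 3, seed=0)
        assert int(labels.sum()) == 100
        assert int((labels == 0).sum()) == 300

    def test_patch_shape_is_101(self):
        patches, _ = synthio.gen_patch_dataset(2, 1, seed=0)
        assert patches.shape[1:] == (101, 101, 3)

    def test_seed_reproducibility(self):
        a = synthio.gen_patch_dataset(5, 2, seed=9)
        b = synthio.gen_patch_dataset(5, 2, seed=9)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_classes_have_distinct_mean_intensity(self):
        patches, labels = synthio.gen_patch_dataset(20, 1, seed=4)
        mit = patches[labels == 1].mean()
        nor = patches[labels == 0].mean()
        assert mit < nor  # mitotic chromatin is darker


class TestViewportGenerator:
    def test_pan_only_keeps_single_zoom(self):
        params = synthio.BehaviorParams(p_zoom_in=0.0, p_zoom_out=0.0,
                                        p_pan=1.0, n_viewports=40, seed=0)
        log = synthio.gen_viewport_log(params, [], (1000, 800))
        assert len({v.zoom for v in log.viewports}) == 1

    def test_single_viewport_log_is_valid(self):
        params = synthio.BehaviorParams(n_viewports=1, seed=0)
        log = synthio.gen_viewport_log(params, [], (1000, 800))
        assert len(log.viewports) == 1

    def test_zoom_in_fraction_converges(self):
        # symmetric walk: realized zoom-ins converge to the drawn probability
        params = synthio.BehaviorParams(p_zoom_in=0.5, p_zoom_out=0.5,
                                        p_pan=0.0, n_viewports=5000, seed=2)
        from melanopath.viewbehave import magnification_pct
        log = synthio.gen_viewport_log(params, [], (1000, 800))
        assert abs(magnification_pct(log) - 50.0) < 3.0

    def test_timestamps_strictly_increasing_and_size_inverse_to_zoom(self):
        params = synthio.BehaviorParams(n_viewports=200, seed=3)
        log = synthio.gen_viewport_log(params, [], (1000, 800))
        ts = [v.timestamp_s for v in log.viewports]
        assert all(b > a for a, b in zip(ts, ts[1:]))
        for v in log.viewports:
            assert v.width == pytest.approx(1000 / v.zoom)
            assert v.height == pytest.approx(800 / v.zoom)

    def test_roi_outside_extent_rejected(self):
        params = synthio.BehaviorParams(seed=0)
        roi = [(900, 700), (1200, 700), (1200, 900), (900, 900)]
        with pytest.raises(ValueError, match="extent"):
            synthio.gen_viewport_log(params, [roi], (1000, 800))

    def test_probability_validation(self):
        with pytest.raises(ValueError):
            synthio.BehaviorParams(p_zoom_in=0.5, p_zoom_out=0.5, p_pan=0.5)


class TestCohort:
    def test_row_count(self):
        spec = synthio.CohortSpec(n_pathologists=4, n_cases=36, seed=0)
        df = synthio.gen_interpretation_cohort(
            spec, synthio.BehaviorParams(n_viewports=5))
        assert len(df) == 144

    def test_null_model_accuracy_near_half(self):
        spec = synthio.CohortSpec(n_pathologists=10, n_cases=500, beta=0.0,
                                  intercept=0.0, pathologist_sd=0.0, seed=1)
        df = synthio.gen_interpretation_cohort(
            spec, synthio.BehaviorParams(n_viewports=5))
        assert abs(df["accuracy"].mean() - 0.5) < 0.03

    def test_planted_effect_orders_quartiles(self):
        spec = synthio.CohortSpec(n_pathologists=10, n_cases=200, beta=1.0,
                                  effect_variable="total_time",
                                  pathologist_sd=0.0, seed=2)
        df = synthio.gen_interpretation_cohort(
            spec, synthio.BehaviorParams(n_viewports=10))
        q = df["total_time"].quantile([0.25, 0.75])
        top = df[df["total_time"] >= q[0.75]]["accuracy"].mean()
        bottom = df[df["total_time"] <= q[0.25]]["accuracy"].mean()
        assert top > bottom

    def test_unknown_effect_variable_rejected(self):
        with pytest.raises(ValueError, match="behavior variable"):
            synthio.CohortSpec(effect_variable="not_a_field")


class TestMultiscale:
    def test_scales_have_expected_relative_sizes(self):
        img, _, _ = synthio.gen_tissue_image(
            synthio.TissueParams(image_height=100, image_width=100))
        views = synthio.render_multiscale(img)
        assert views["12.5x"].shape == (100, 100, 3)
        assert views["10x"].shape == (80, 80, 3)
        assert views["7.5x"].shape == (60, 60, 3)

    def test_crossscale_cohort_cues_are_scale_specific(self):
        cases = synthio.gen_crossscale_cohort(4, seed=0)
        by_label = {}
        for c in cases:
            by_label.setdefault(c.label, []).append(c)
        # coarse cue shifts the 7.5x red channel only for classes with cue A
        red_0 = np.mean([c.images["7.5x"][..., 0].mean()
                         for c in by_label[0]])
        red_2 = np.mean([c.images["7.5x"][..., 0].mean()
                         for c in by_label[2]])
        assert red_2 > red_0 + 5
        # fine cue darkens the 12.5x rendering only for classes with cue B
        dark_0 = np.mean([c.images["12.5x"].mean() for c in by_label[0]])
        dark_1 = np.mean([c.images["12.5x"].mean() for c in by_label[1]])
        assert dark_1 < dark_0 - 2
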