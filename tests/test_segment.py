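"""Segmentation, object features and two-tier classification."""

import numpy as np
import pytest

from acqua.errors import ConfigError
from acqua.segment import (area_fractions, binarize, classify_objects,
                           compute_features, label_objects)
from conftest import straight_bar


def make_blob(canvas, r0, c0, h, w):
    canvas[r0:r0 + h, c0:c0 + w] = True
    return canvas


class TestBinarize:
    def test_bimodal_image_separates_exactly(self, rng):
        img = (rng.uniform(size=(32, 32)) > 0.6).astype(float)
        mask = binarize(img, method="otsu")
        assert np.array_equal(mask, img == 1.0)

    def test_all_zero_image_gives_empty_mask(self):
        assert not binarize(np.zeros((16, 16)), method="otsu").any()

    def test_fixed_method_requires_threshold(self):
        with pytest.raises(ConfigError):
            binarize(np.zeros((4, 4)), method="fixed")

    def test_two_level_image_with_noise_recovers_truth(self, rng):
        truth = np.zeros((64, 64), dtype=bool)
        truth[20:40, 10:50] = True
        img = np.where(truth, 0.9, 0.1) + rng.normal(0, 0.02, size=truth.shape)
        mask = binarize(np.clip(img, 0, 1), method="otsu")
        agreement = (mask == truth).mean()
        assert agreement >= 0.99


class TestLabelObjects:
    def test_two_disjoint_blobs_give_two_objects(self):
        m = np.zeros((40, 40), dtype=bool)
        make_blob(m, 2, 2, 10, 10)
        make_blob(m, 25, 25, 10, 10)
        objs = label_objects(m, min_object_area=30, closing_radius=0)
        assert len(objs.objects) == 2
        assert sorted(o.label for o in objs.objects) == [1, 2]

    def test_small_blob_removed_by_area_filter(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5, 5:8] = True  # 3 px
        objs = label_objects(m, min_object_area=10, closing_radius=0)
        assert objs.objects == []

    def test_border_flag(self):
        m = np.zeros((30, 30), dtype=bool)
        m[0:6, 0:10] = True
        objs = label_objects(m, min_object_area=10, closing_radius=0)
        assert objs.objects[0].touches_border


class TestClassification:
    def test_long_bar_is_filamentous(self):
        objs = label_objects(straight_bar(height=4, width=200), min_object_area=30,
                             closing_radius=0)
        compute_features(objs)
        classify_objects(objs, min_elongation=5.0)
        assert objs.objects[0].is_filamentous
        assert objs.objects[0].elongation > 5

    def test_disc_is_not_filamentous(self):
        m = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[0:40, 0:40]
        m[(yy - 20) ** 2 + (xx - 20) ** 2 <= 100] = True
        objs = label_objects(m, min_object_area=30, closing_radius=0)
        compute_features(objs)
        classify_objects(objs, min_elongation=5.0)
        assert not objs.objects[0].is_filamentous

    def test_of_interest_requires_length_and_width_gates(self):
        # 200 px bar at 0.32 um/px is 64 um long, 4 px wide is ~1.3 um: fails width gate
        objs = label_objects(straight_bar(height=4, width=200), min_object_area=30,
                             closing_radius=0)
        compute_features(objs)
        classify_objects(objs, min_elongation=5.0, min_length_um=50.0,
                         width_range_um=(2.0, 12.0), um_per_px=0.32)
        assert objs.objects[0].is_filamentous and not objs.objects[0].is_of_interest
        # widen the acceptance band: now of interest
        classify_objects(objs, min_elongation=5.0, min_length_um=50.0,
                         width_range_um=(0.5, 12.0), um_per_px=0.32)
        assert objs.objects[0].is_of_interest

    def test_rejects_bad_calibration(self):
        objs = label_objects(straight_bar(), min_object_area=30, closing_radius=0)
        compute_features(objs)
        with pytest.raises(ConfigError):
            classify_objects(objs, um_per_px=0.0)

    def test_monotone_in_min_elongation(self):
        m = np.zeros((120, 260), dtype=bool)
        make_blob(m, 5, 5, 4, 200)
        make_blob(m, 30, 5, 8, 60)
        make_blob(m, 60, 5, 20, 20)
        objs = label_objects(m, min_object_area=30, closing_radius=0)
        compute_features(objs)
        counts = []
        for thr in (1.0, 3.0, 5.0, 10.0, 60.0):
            classify_objects(objs, min_elongation=thr)
            counts.append(sum(o.is_filamentous for o in objs.objects))
        assert counts == sorted(counts, reverse=True)

    def test_noise_removal_leaves_other_features_unchanged(self):
        m = np.zeros((120, 260), dtype=bool)
        make_blob(m, 5, 5, 4, 200)
        make_blob(m, 60, 60, 12, 12)
        both = label_objects(m, min_object_area=30, closing_radius=0)
        compute_features(both)
        bar_only = label_objects(straight_bar(height=4, width=200), min_object_area=30,
                                 closing_radius=0)
        compute_features(bar_only)
        a = next(o for o in both.objects if o.area_px == 800)
        b = bar_only.objects[0]
        assert a.skeleton_length_px == b.skeleton_length_px
        assert a.mean_width_px == pytest.approx(b.mean_width_px)


class TestAreaFractions:
    def _objs(self, flags_areas):
        m = np.zeros((200, 60), dtype=bool)
        r = 2
        for i, (_, area) in enumerate(flags_areas):
            make_blob(m, r, 2, area // 10, 10)
            r += area // 10 + 8
        objs = label_objects(m, min_object_area=10, closing_radius=0)
        for o, (interest, _) in zip(sorted(objs.objects, key=lambda o: o.label), flags_areas):
            o.is_of_interest = interest
            o.is_filamentous = interest
        return objs

    def test_simple_arithmetic(self):
        objs = self._objs([(True, 60), (False, 40)])
        assert area_fractions(objs)["filament_area_fraction"] == pytest.approx(60.0)

    def test_all_of_interest_is_100(self):
        objs = self._objs([(True, 60), (True, 40)])
        assert area_fractions(objs)["filament_area_fraction"] == pytest.approx(100.0)

    def test_no_objects_gives_missing_value(self):
        objs = label_objects(np.zeros((10, 10), dtype=bool), min_object_area=5)
        out = area_fractions(objs)
        assert np.isnan(out["filament_area_fraction"])

    def test_invariant_to_scene_rotation(self):
        m = np.zeros((80, 120), dtype=bool)
        make_blob(m, 5, 5, 4, 60)
        make_blob(m, 40, 40, 12, 12)

        def frac(mask):
            objs = label_objects(mask, min_object_area=10, closing_radius=0)
            compute_features(objs)
            classify_objects(objs, min_elongation=5.0, min_length_um=1.0,
                             width_range_um=(0.1, 50.0))
            return area_fractions(objs)["filament_area_fraction"]

        assert frac(m) == pytest.approx(frac(np.rot90(m)))
        assert frac(m) == pytest.approx(frac(np.roll(m, 7, axis=1)))
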