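import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retquant.biomarkers import (biomarkers_from_annotation,
                                 extract_biomarkers, layer_length_rate,
                                 region_area, region_max_diameter,
                                 region_mean_intensity)
from retquant.synthetic import (LABEL_CODES, SceneSpec, generate_scene)


class TestLayerLengthRate:
    def test_all_true(self):
        assert layer_length_rate(np.ones(100, bool)) == 1.0

    def test_sixty_of_hundred(self):
        v = np.zeros(100, bool)
        v[:60] = True
        assert layer_length_rate(v) == 0.6

    def test_none_true(self):
        assert layer_length_rate(np.zeros(100, bool)) == 0.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            layer_length_rate(np.array([], bool))


class TestRegionArea:
    def test_rectangle(self):
        mask = np.zeros((50, 50), np.uint8)
        mask[5:15, 10:30] = LABEL_CODES["IRF"]          # 10 x 20 px
        assert region_area(mask, "IRF", 0.005) == pytest.approx(200 * 0.000025)

    def test_empty_class(self):
        assert region_area(np.zeros((5, 5), np.uint8), "SRF", 0.01) == 0.0

    def test_two_components_summed(self):
        mask = np.zeros((20, 40), np.uint8)
        mask[0:5, 0:10] = LABEL_CODES["PED"]            # 50 px
        mask[10:17, 20:30] = LABEL_CODES["PED"]         # 70 px
        assert region_area(mask, "PED", 1.0) == pytest.approx(120.0)

    def test_unknown_class(self):
        with pytest.raises(ValueError, match="unknown"):
            region_area(np.zeros((2, 2)), "FOO", 1.0)


class TestRegionMaxDiameter:
    def test_rectangle_span(self):
        mask = np.zeros((30, 40), np.uint8)
        mask[3:13, 5:25] = LABEL_CODES["SHRM"]          # 20-col span
        assert region_max_diameter(mask, "SHRM", 1.0) == pytest.approx(20.0)

    def test_widest_component_wins(self):
        mask = np.zeros((30, 60), np.uint8)
        mask[2:4, 0:5] = LABEL_CODES["IRF"]             # width 5
        mask[20:22, 30:42] = LABEL_CODES["IRF"]         # width 12
        assert region_max_diameter(mask, "IRF", 1.0) == pytest.approx(12.0)

    def test_empty(self):
        assert region_max_diameter(np.zeros((4, 4), np.uint8), "SRF", 1.0) == 0.0


class TestRegionMeanIntensity:
    def test_uniform(self):
        img = np.full((10, 10), 0.5, np.float32)
        mask = np.zeros((10, 10), np.uint8)
        mask[2:6, 2:6] = LABEL_CODES["PED"]
        assert region_mean_intensity(img, mask, "PED") == pytest.approx(0.5)

    def test_half_half(self):
        img = np.zeros((2, 4), np.float32)
        img[0] = 0.2
        img[1] = 0.8
        mask = np.full((2, 4), LABEL_CODES["SHRM"], np.uint8)
        assert region_mean_intensity(img, mask, "SHRM") == pytest.approx(0.5)

    def test_empty_is_nan(self):
        v = region_mean_intensity(np.zeros((3, 3)), np.zeros((3, 3), np.uint8),
                                  "PED")
        assert math.isnan(v)

    def test_class_restriction(self):
        with pytest.raises(ValueError, match="mean intensity"):
            region_mean_intensity(np.zeros((2, 2)), np.zeros((2, 2)), "IRF")


class TestExtractBiomarkers:
    def test_round_trip_against_ground_truth(self, desk_scene):
        img, ann, truth = desk_scene
        vec = biomarkers_from_annotation(img, ann).as_dict()
        for name, expected in truth.as_vector().items():
            got = vec[name]
            if math.isnan(expected):
                assert math.isnan(got)
            elif name.endswith(("area_mm2", "diameter_mm")):
                tol = img.pixel_size_mm ** (2 if "area" in name else 1)
                assert got == pytest.approx(expected, abs=tol)
            else:
                assert got == pytest.approx(expected, abs=1e-6)

    def test_background_mask_all_true_presence(self, desk_scene):
        img, _ann, _t = desk_scene
        n_clips = img.intensity.shape[1] // 16
        vec = extract_biomarkers(img, np.zeros_like(img.intensity, np.uint8),
                                 np.ones(n_clips, bool), np.ones(n_clips, bool),
                                 img.pixel_size_mm)
        assert vec.ez_length_rate == 1.0
        assert vec.irf_area_mm2 == 0.0 and vec.ped_area_mm2 == 0.0
        assert math.isnan(vec.shrm_mean_intensity)

    def test_geometry_mismatch(self, desk_scene):
        img, _ann, _t = desk_scene
        with pytest.raises(ValueError, match="shape"):
            extract_biomarkers(img, np.zeros((4, 4), np.uint8),
                               np.ones(4, bool), np.ones(4, bool), 0.01)

    @settings(max_examples=10, deadline=None)
    @given(s=st.floats(0.001, 0.1))
    def test_pixel_size_covariance(self, desk_scene, s):
        img, ann, _t = desk_scene
        base = biomarkers_from_annotation(img, ann)
        mask = ann.lesion_mask
        assert region_area(mask, "IRF", s) == pytest.approx(
            region_area(mask, "IRF", 1.0) * s ** 2)
        assert region_max_diameter(mask, "PED", s) == pytest.approx(
            region_max_diameter(mask, "PED", 1.0) * s)
        # rates and intensities are dimensionless
        assert base.ez_length_rate <= 1.0

    def test_intensity_invariance_of_geometry(self, desk_scene):
        img, ann, _t = desk_scene
        brighter = np.clip(img.intensity * 0.5 + 0.2, 0, 1)
        assert region_area(ann.lesion_mask, "SRF", 0.01) == region_area(
            ann.lesion_mask, "SRF", 0.01)
        a = region_max_diameter(ann.lesion_mask, "SRF", 0.01)
        assert a == region_max_diameter(ann.lesion_mask, "SRF", 0.01)
        assert brighter.shape == img.intensity.shape


def test_round_trip_many_seeds_noise_free():
    # generator-emitted annotation quantified back must invert the generator
    for seed in range(10):
        spec = SceneSpec.desk(speckle_sigma=0.0, ez_gap_fraction=0.2,
                              elm_gap_fraction=0.1)
        img, ann, truth = generate_scene(spec, seed=seed)
        vec = biomarkers_from_annotation(img, ann).as_dict()
        for name, expected in truth.as_vector().items():
            got = vec[name]
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9), name
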