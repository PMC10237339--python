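"""Morphometric variables, fractal dimension, intensity bimodality, disruption."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from nmjkit.image_sim import NMJImage, build_image_scenario, generate_nmj
from nmjkit.morphometry import (
    FractalConfig,
    analyze_image,
    box_counts,
    classify_disruption,
    core_variables,
    derived_variables,
    fractal_dimension,
    huang_threshold,
    intensity_bimodality,
    segment_achr,
    to_uint8,
)


def _image_from_array(arr, pixel_size=1.0):
    return NMJImage(pixels=arr.astype(np.uint8), pixel_size=pixel_size, metadata={})


class TestHuangThreshold:
    def test_separates_bimodal_histogram(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.uniform(size=(200, 200)) < 0.3,
                       rng.normal(180, 8, (200, 200)),
                       rng.normal(20, 5, (200, 200)))
        t = huang_threshold(np.clip(img, 0, 255).astype(np.uint8))
        assert 30 <= t < 160  # background tops out near 40, label starts ~150

    def test_uniform_image_is_degenerate(self):
        assert huang_threshold(np.full((10, 10), 7, dtype=np.uint8)) == 7


class TestSegmentation:
    def test_clean_pretzel_jaccard(self, clean_image):
        """Receptor mask overlaps ground truth with Jaccard >= 0.9."""
        img, truth = clean_image
        seg = segment_achr(img)
        inter = (seg.achr_mask & truth.achr_mask).sum()
        union = (seg.achr_mask | truth.achr_mask).sum()
        assert inter / union >= 0.9

    def test_blank_image_errors(self):
        with pytest.raises(ValueError):
            segment_achr(_image_from_array(np.full((64, 64), 10)))

    def test_two_disjoint_squares_give_two_clusters(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(10, 3, (128, 128))  # textured background
        arr[20:40, 20:40] = 200
        arr[80:100, 80:100] = 200
        seg = segment_achr(_image_from_array(np.clip(arr, 0, 255)))
        # one square becomes the main endplate, the other a separate component
        total = seg.cluster_labels.max() + seg.satellite_labels.max()
        assert total == 2

    def test_achr_subset_of_endplate(self, clean_image):
        seg = segment_achr(clean_image[0])
        assert not (seg.achr_mask & ~seg.endplate_mask).any()


class TestCoreVariables:
    def test_filled_square_geometry(self):
        """Hand-built 10x10 square mask: exact areas and corner-to-corner Feret."""
        from nmjkit.morphometry import SegmentationResult
        m = np.zeros((64, 64), dtype=bool)
        m[20:30, 20:30] = True
        per = m & ~(np.roll(m, 1, 0) & np.roll(m, -1, 0)
                    & np.roll(m, 1, 1) & np.roll(m, -1, 1))
        seg = SegmentationResult(achr_mask=m, endplate_mask=m,
                                 cluster_labels=m.astype(int), perimeter_mask=per,
                                 satellite_labels=np.zeros_like(m, dtype=int),
                                 threshold_value=0.0, image8=m.astype(np.uint8) * 200)
        a, b, c, d, e, f = core_variables(seg, 1.0)
        assert a == 100.0 and d == 100.0
        assert f == 1
        assert b == pytest.approx(10 * np.sqrt(2))  # corner-to-corner Feret

    def test_filled_square_through_segmentation(self):
        arr = np.full((64, 64), 5)
        arr[20:30, 20:30] = 220  # 10 x 10 px at 1 µm/px
        seg = segment_achr(_image_from_array(arr, pixel_size=1.0))
        a, b, c, d, e, f = core_variables(seg, 1.0)
        # 3x3 pre-smoothing dilates a sharp square by about one pixel per side
        assert d == pytest.approx(100.0, rel=0.5)
        assert f == 1
        assert a >= d

    def test_zero_pixel_size_errors(self, clean_image):
        seg = segment_achr(clean_image[0])
        with pytest.raises(ValueError):
            core_variables(seg, 0.0)

    def test_endplate_contains_achr_on_synthetic(self, diseased_image):
        seg = segment_achr(diseased_image[0])
        a, b, c, d, e, f = core_variables(seg, diseased_image[0].pixel_size)
        assert a >= d > 0


class TestDerivedVariables:
    @pytest.mark.parametrize("f, j", [(1, 0.0), (4, 0.75), (10, 0.9)])
    def test_fragmentation(self, f, j):
        assert derived_variables(10.0, 5.0, f)[3] == pytest.approx(j)

    def test_full_occupancy(self):
        g, h, i, j = derived_variables(7.0, 7.0, 1)
        assert h == 0.0
        assert i == pytest.approx(100.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            derived_variables(10.0, 5.0, 0)
        with pytest.raises(ValueError):
            derived_variables(4.0, 5.0, 1)

    @given(a=st.floats(10, 1000), ratio=st.floats(0.1, 1.0), f=st.integers(1, 40))
    @settings(max_examples=100, deadline=None)
    def test_identities(self, a, ratio, f):
        """Exact identities: g = d/f, h = a - d, j = 1 - 1/f."""
        d = a * ratio
        g, h, i, j = derived_variables(a, d, f)
        assert g == d / f
        assert h == a - d
        assert i == (a / d) * 100.0
        assert j == 1.0 - 1.0 / f


class TestFractalDimension:
    def test_straight_line_is_smooth(self):
        m = np.zeros((512, 512), dtype=bool)
        m[256, 64:464] = True
        assert fractal_dimension(m) == pytest.approx(1.0, abs=0.05)

    def test_filled_square_perimeter_is_smooth(self):
        sq = np.zeros((512, 512), dtype=bool)
        sq[100:300, 100:300] = True
        per = sq & ~(np.roll(sq, 1, 0) & np.roll(sq, -1, 0)
                     & np.roll(sq, 1, 1) & np.roll(sq, -1, 1))
        assert fractal_dimension(per) == pytest.approx(1.0, abs=0.05)

    def test_translation_invariance_by_box_multiples(self, clean_image):
        seg = segment_achr(clean_image[0])
        d0 = fractal_dimension(seg.perimeter_mask)
        shifted = np.roll(seg.perimeter_mask, (64, 128), axis=(0, 1))
        assert fractal_dimension(shifted) == pytest.approx(d0, abs=1e-12)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            fractal_dimension(np.zeros((64, 64), dtype=bool))

    def test_too_few_usable_sizes_errors(self):
        m = np.zeros((512, 512), dtype=bool)
        m[10, 10:20] = True  # 10-px speck: counts collapse immediately
        with pytest.raises(ValueError):
            fractal_dimension(m)

    def test_box_counts_halve_for_a_line(self):
        m = np.zeros((256, 256), dtype=bool)
        m[0, 0:256] = True
        counts = box_counts(m, [1, 2, 4, 8])
        assert list(counts) == [256, 128, 64, 32]

    def test_bounded_above_by_two(self):
        rng = np.random.default_rng(1)
        noise = rng.uniform(size=(512, 512)) < 0.4  # dense speckle, worst case
        assert fractal_dimension(noise) <= 2.0 + 1e-9


class TestIntensityBimodality:
    def test_uniformly_bright_nmj_has_no_dim_area(self, clean_image):
        res = intensity_bimodality(clean_image[0])
        assert res["dim_area_fraction"] < 0.05

    def test_dim_fraction_recovery(self):
        """60% dim label is recovered within 5 percentage points."""
        sc = replace(build_image_scenario(20, "SOD1"),
                     floccular_fraction=0.0, n_extrajunctional=0)
        ests = [intensity_bimodality(generate_nmj(sc, 700 + s)[0])["dim_area_fraction"]
                for s in range(10)]
        assert np.mean(ests) == pytest.approx(0.60, abs=0.05)

    def test_monotone_in_generator_dim_fraction(self):
        """valley/peak count ratio rises with the generator dim fraction
        (bright-peak-dominant regime, dim fractions up to ~0.7)."""
        sc = replace(build_image_scenario(20, "SOD1"),
                     floccular_fraction=0.0, n_extrajunctional=0)
        ratios = []
        for dim in (0.2, 0.4, 0.6):
            vals = [intensity_bimodality(
                generate_nmj(replace(sc, dim_fraction=dim), 800 + s)[0])["valley_peak_ratio"]
                for s in range(4)]
            ratios.append(np.mean(vals))
        assert ratios[0] < ratios[1] < ratios[2]

    def test_no_signal_errors(self):
        dark = _image_from_array(np.full((64, 64), 5))
        with pytest.raises(ValueError, match="no AChR signal"):
            intensity_bimodality(dark, roi=(0, 0, 64, 64))


class TestClassifyDisruption:
    def test_clean_pretzel_mostly_undisrupted(self):
        sc = replace(build_image_scenario(12, "WT"), dim_fraction=0.0,
                     floccular_fraction=0.0, n_extrajunctional=0)
        ok = 0
        for s in range(20):
            img, _ = generate_nmj(sc, 900 + s)
            cat, extra, _ = classify_disruption(img, segment_achr(img))
            ok += (cat == "none" and not extra)
        assert ok >= 18  # >= 90% of replicates

    def test_majority_floccular_detected(self):
        sc = replace(build_image_scenario(20, "SOD1"),
                     floccular_fraction=0.7, n_extrajunctional=0)
        cats = []
        for s in range(10):
            img, _ = generate_nmj(sc, 950 + s)
            cats.append(classify_disruption(img, segment_achr(img))[0])
        assert np.mean([c == "gt50" for c in cats]) >= 0.8

    def test_satellites_detected(self, diseased_image):
        img, _ = diseased_image
        _, extra, _ = classify_disruption(img, segment_achr(img))
        assert extra

    def test_category_accuracy(self):
        """Confusion over the three categories >= 85% on labelled output."""
        sc = build_image_scenario(20, "SOD1")
        correct = total = 0
        for want, ff in [("none", 0.0), ("lt50", 0.25), ("gt50", 0.70)]:
            for s in range(8):
                img, _ = generate_nmj(
                    replace(sc, floccular_fraction=ff, n_extrajunctional=0), 1000 + s)
                cat, _, _ = classify_disruption(img, segment_achr(img))
                correct += (cat == want)
                total += 1
        assert correct / total >= 0.85


class TestAnalyzeImage:
    def test_full_record(self, diseased_image):
        img, _ = diseased_image
        rec = analyze_image(img)
        assert rec.h_unoccupied_area == rec.a_endplate_area - rec.d_achr_area
        assert rec.g_avg_cluster_area == rec.d_achr_area / rec.f_n_clusters
        assert rec.j_fragmentation == 1 - 1 / rec.f_n_clusters
        assert rec.i_compactness >= 100.0          # (a/d)*100, as printed
        assert rec.compactness_achr_over_endplate <= 100.0
        assert rec.fractal_dimension <= 2.0
        assert 0 <= rec.dim_area_fraction <= 1
        assert rec.floccular_category in ("none", "lt50", "gt50")
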