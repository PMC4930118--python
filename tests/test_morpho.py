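"""Image pipeline: enhancement contracts, segmentation/classification
accuracy against generator truth, metric conventions and area analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from conftest import detection_scores, match_cells
from npcquant.morpho import (
    AnnulusSpec,
    MorphoConfig,
    NucleusRecord,
    actin_area,
    cell_metrics,
    classify_cell,
    density_match,
    enhance_marker,
    enhance_nuclear,
    extract_soma,
    feature_matrix,
    group_fold_change,
    measure_image,
    normalize_channel,
    segment_nuclei,
)
from npcquant.simulate import ImageSimSpec, gen_actin_field, gen_image


class TestNormalizeChannel:
    def test_constant_image_maps_to_zeros(self):
        assert (normalize_channel(np.full((32, 32), 7.0)) == 0).all()

    def test_output_range_contract(self):
        rng = np.random.default_rng(0)
        out = normalize_channel(rng.normal(50, 20, (64, 64)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_percentile_endpoints_on_ramp(self):
        ramp = np.tile(np.arange(256.0), (4, 1))
        out = normalize_channel(ramp)
        lo, hi = np.percentile(ramp, [1, 99])
        expected = np.clip((ramp - lo) / (hi - lo), 0, 1)
        np.testing.assert_allclose(out, expected)


class TestEnhanceNuclear:
    def test_blank_image_stays_blank(self):
        out = enhance_nuclear(np.zeros((64, 64)))
        assert np.allclose(out, 0.0)

    def test_single_band_reduces_to_dog(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 1, (64, 64))
        out = enhance_nuclear(img, band_sigmas=[(1.0, 4.0)])
        dog = np.clip(gaussian_filter(img, 1.0) - gaussian_filter(img, 4.0), 0, None)
        np.testing.assert_allclose(out, dog)

    def test_background_gradient_suppressed(self):
        # nucleus on a gradient: off-nucleus response must be weak
        img = np.zeros((128, 128))
        rr, cc = draw_ellipse(64, 64, 10, 10, shape=img.shape)
        img[rr, cc] = 1.0
        img = gaussian_filter(img, 1.5)
        yy, xx = np.mgrid[0:128, 0:128]
        img = img + 0.3 * xx / 127
        out = enhance_nuclear(img, nucleus_radius=10)
        nucleus_mask = np.zeros_like(img, dtype=bool)
        nucleus_mask[rr, cc] = True
        far = ~nucleus_mask & (np.hypot(yy - 64, xx - 64) > 30)
        assert out[far].mean() < 0.1 * out[nucleus_mask].mean()

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            enhance_nuclear(np.zeros((8, 8)), band_sigmas=[(4.0, 2.0)])


class TestEnhanceMarker:
    def test_smooth_gradient_removed(self):
        _, xx = np.mgrid[0:128, 0:128]
        img = normalize_channel(0.5 * xx / 127)
        out = enhance_marker(img, sigma=20)
        assert out.max() < 0.02

    def test_impulse_preserved(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        out = enhance_marker(img, sigma=10)
        assert out[32, 32] > 0.9

    def test_ring_on_gradient_retained(self):
        yy, xx = np.mgrid[0:128, 0:128]
        img = 0.2 * xx / 127
        rr, cc = draw_ellipse(64, 64, 14, 14, shape=img.shape)
        ring = np.zeros_like(img, dtype=bool)
        ring[rr, cc] = True
        rr, cc = draw_ellipse(64, 64, 9, 9, shape=img.shape)
        ring[rr, cc] = False
        img[ring] += 1.0
        out = enhance_marker(img, sigma=20)
        background = ~ring & (np.hypot(yy - 64, xx - 64) > 25)
        assert out[ring].mean() >= 10 * max(out[background].mean(), 1e-9)


class TestSegmentNuclei:
    def test_blank_field_empty(self):
        assert segment_nuclei(np.zeros((64, 64))) == []

    def test_default_field_recall_precision(self, default_field):
        image, truth = default_field
        cells = measure_image(image.nuclear, image.red, image.green)
        scores = detection_scores(cells, truth.cells)
        assert scores["recall"] >= 0.95
        assert scores["precision"] >= 0.95

    def test_speckle_noise_sieved_out(self):
        # paired fields: speckles below min_area must not add detections
        spec = ImageSimSpec(n_cells=20, noise_sd=0.0, seed=6)
        image, _ = gen_image(spec)
        clean = measure_image(image.nuclear)
        rng = np.random.default_rng(0)
        noisy = image.nuclear.copy()
        for _ in range(30):
            y, x = rng.integers(5, 507, 2)
            noisy[y : y + 2, x : x + 2] += 1.0
        speckled = measure_image(noisy)
        assert len(speckled) == len(clean)

    def test_mean_diameter_relative_error(self, default_field):
        image, truth = default_field
        cells = measure_image(image.nuclear)
        err = abs(cells["diameter"].mean() - truth.cells["diameter"].mean())
        assert err / truth.cells["diameter"].mean() <= 0.10


class TestClassifyCell:
    def test_zero_marker_channels_negative(self, default_field):
        image, _ = default_field
        cells = measure_image(image.nuclear, np.zeros_like(image.nuclear),
                              np.zeros_like(image.nuclear))
        assert (cells["classification"] == "negative").all()

    def test_classification_accuracy_200_cells(self):
        spec = ImageSimSpec(width=1200, height=1200, n_cells=200,
                            p_marker_red=0.6, p_marker_green=0.3, seed=10)
        image, truth = gen_image(spec)
        cells = measure_image(image.nuclear, image.red, image.green)
        scores = detection_scores(cells, truth.cells)
        assert scores["accuracy"] >= 0.95

    def test_red_ring_cell_red_positive(self):
        spec = ImageSimSpec(n_cells=5, p_marker_red=1.0, p_marker_green=0.0,
                            seed=11)
        image, _ = gen_image(spec)
        cells = measure_image(image.nuclear, image.red, image.green)
        assert (cells["classification"] == "red_positive").all()


class TestExtractSoma:
    def _one_cell(self):
        spec = ImageSimSpec(n_cells=1, p_marker_red=1.0, p_marker_green=0.0,
                            aspect_mean=1.0, aspect_sd=0.0, noise_sd=0.0,
                            background_gradient_amp=0.0, seed=12)
        image, truth = gen_image(spec)
        nuc_enh = enhance_nuclear(normalize_channel(image.nuclear))
        nuclei = segment_nuclei(nuc_enh)
        red_enh = enhance_marker(normalize_channel(image.red))
        return nuclei[0], red_enh, truth

    def test_soma_contains_nucleus_centroid(self):
        nucleus, red_enh, _ = self._one_cell()
        annulus = AnnulusSpec(inner_margin=2, width=8)
        soma = extract_soma(nucleus, red_enh, annulus)
        assert soma is not None
        from matplotlib.path import Path

        assert Path(soma).contains_point(nucleus.centroid)

    def test_soma_area_close_to_nucleus_plus_ring(self):
        nucleus, red_enh, truth = self._one_cell()
        annulus = AnnulusSpec(inner_margin=2, width=8)
        soma = extract_soma(nucleus, red_enh, annulus)
        # shoelace area of the soma polygon
        x, y = soma[:, 0], soma[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        d = truth.cells["diameter"].iloc[0]
        r_in = d / 2 + 1
        expected = np.pi * (r_in + 6.0) ** 2  # nucleus + ring annulus
        assert area == pytest.approx(expected, rel=0.25)

    def test_no_marker_flagged_absent(self):
        nucleus, red_enh, _ = self._one_cell()
        assert extract_soma(nucleus, np.zeros_like(red_enh)) is None


class TestCellMetrics:
    def test_circle(self):
        rec = NucleusRecord(1, (0, 0), np.pi * 100, 20.0, 20.0, 0.0, 1.0,
                            np.zeros((4, 2)))
        d, a = cell_metrics(rec)
        assert d == pytest.approx(20.0)
        assert a == pytest.approx(1.0)

    def test_ellipse_closed_form(self):
        rec = NucleusRecord(1, (0, 0), 157.0, 20.0, 10.0, 0.0, 0.9,
                            np.zeros((4, 2)))
        d, a = cell_metrics(rec)
        assert d == pytest.approx(np.sqrt(200), abs=1e-9)
        assert a == pytest.approx(2.0)

    def test_arithmetic_convention(self):
        rec = NucleusRecord(1, (0, 0), 157.0, 20.0, 10.0, 0.0, 0.9,
                            np.zeros((4, 2)))
        d, _ = cell_metrics(rec, convention="arithmetic")
        assert d == pytest.approx(15.0)

    def test_degenerate_ellipse_rejected(self):
        rec = NucleusRecord(1, (0, 0), 1.0, 5.0, 0.0, 0.0, 0.9, np.zeros((4, 2)))
        with pytest.raises(ValueError):
            cell_metrics(rec)

    def test_aspect_ratio_at_least_one(self, default_field):
        image, _ = default_field
        cells = measure_image(image.nuclear)
        assert (cells["aspect"] >= 1.0).all()


class TestFeatureMatrix:
    def test_empty_image_contributes_zero_counts(self):
        fm = feature_matrix({"im1": pd.DataFrame(
            columns=["cx", "cy", "area", "major", "minor", "diameter", "aspect",
                     "classification"])})
        assert (fm["count"] == 0).all()

    def test_counts_partition_cells(self, default_field):
        image, _ = default_field
        cells = measure_image(image.nuclear, image.red, image.green)
        fm = feature_matrix({"f": cells})
        assert fm["count"].sum() == len(cells)

    def test_sd_absent_for_singletons(self):
        cells = pd.DataFrame(
            {"cx": [1], "cy": [1], "area": [100], "major": [12], "minor": [10],
             "diameter": [11.0], "aspect": [1.2],
             "classification": ["red_positive"]}
        )
        fm = feature_matrix({"im": cells})
        row = fm[fm["classification"] == "red_positive"].iloc[0]
        assert row["count"] == 1 and np.isnan(row["diameter_sd"])


class TestScaling:
    def test_metrics_scale_with_2x_upsampling(self):
        spec = ImageSimSpec(n_cells=25, noise_sd=0.0, seed=13)
        image, _ = gen_image(spec)
        base = measure_image(image.nuclear)
        up = np.kron(image.nuclear, np.ones((2, 2)))
        scaled = measure_image(up, config=MorphoConfig(
            nucleus_radius=20.0,
            accept={"min_area": 160.0, "max_area": 20000.0, "min_circularity": 0.5},
        ))
        assert len(scaled) == len(base)
        assert scaled["diameter"].mean() / base["diameter"].mean() == \
            pytest.approx(2.0, rel=0.05)
        assert scaled["area"].mean() / base["area"].mean() == \
            pytest.approx(4.0, rel=0.05)


class TestActinArea:
    def test_blank_actin_zero_area(self):
        image, _ = gen_actin_field(n_cells=5, seed=1)
        out = actin_area(np.zeros_like(image.actin), image.nuclear)
        assert out["total_area"] == 0

    def test_painted_area_recovered(self):
        image, truth = gen_actin_field(n_cells=20, seed=2)
        out = actin_area(image.actin, image.nuclear)
        assert out["total_area"] == pytest.approx(truth["painted_area"], rel=0.05)
        assert out["cell_count"] == truth["n_cells"]
        assert out["mean_area_per_cell"] == out["total_area"] / out["cell_count"]

    def test_mean_area_invariant_to_cell_count(self):
        means = []
        for n in (15, 30):
            image, _ = gen_actin_field(n_cells=n, width=800, height=800, seed=3)
            means.append(actin_area(image.actin, image.nuclear)["mean_area_per_cell"])
        assert means[1] == pytest.approx(means[0], rel=0.05)

    def test_zero_nuclei_mean_absent(self):
        image, truth = gen_actin_field(n_cells=5, seed=4)
        out = actin_area(image.actin, np.zeros_like(image.nuclear))
        assert out["mean_area_per_cell"] is None


class TestDensityMatch:
    def test_identical_distributions_keep_everything(self):
        counts = {"a1": 10, "a2": 20, "b1": 11, "b2": 21}
        groups = {"a1": "ctl", "a2": "ctl", "b1": "sz", "b2": "sz"}
        kept = density_match(counts, groups, bin_width=10)
        assert kept == {"ctl": ["a1", "a2"], "sz": ["b1", "b2"]}

    def test_disjoint_densities_empty(self):
        counts = {"a1": 5, "b1": 100}
        groups = {"a1": "ctl", "b1": "sz"}
        with pytest.warns(UserWarning):
            kept = density_match(counts, groups, bin_width=10)
        assert kept == {"ctl": [], "sz": []}

    def test_mixed_case_hand_enumeration(self):
        # bins of 10: ctl bins {0:[a1], 2:[a2,a3]}, sz bins {2:[b1], 5:[b2,b3]}
        counts = {"a1": 5, "a2": 25, "a3": 27, "b1": 22, "b2": 55, "b3": 58}
        groups = {"a1": "ctl", "a2": "ctl", "a3": "ctl",
                  "b1": "sz", "b2": "sz", "b3": "sz"}
        kept = density_match(counts, groups, bin_width=10)
        assert kept == {"ctl": ["a2", "a3"], "sz": ["b1"]}


class TestNullGroupComparison:
    def test_same_spec_groups_fold_near_one(self):
        # two groups drawn from one spec: diameter and aspect folds ~1
        per_image = {}
        groups = {}
        for g, label in enumerate(["ctl", "sz"]):
            for i in range(4):
                spec = ImageSimSpec(n_cells=50, seed=100 + 10 * g + i)
                image, _ = gen_image(spec)
                img_id = f"{label}{i}"
                per_image[img_id] = measure_image(image.nuclear, image.red,
                                                  image.green)
                groups[img_id] = label
        report = group_fold_change(per_image, groups)
        folds = report.set_index("metric")["fold"]
        assert 0.95 <= folds["diameter"] <= 1.05
        assert 0.97 <= folds["aspect"] <= 1.03


class TestMatching:
    def test_match_cells_flags_unmatched(self, default_field):
        image, truth = default_field
        cells = measure_image(image.nuclear)
        fake = pd.concat(
            [cells, pd.DataFrame([{"cx": 1.0, "cy": 1.0, "area": 100.0,
                                   "major": 10.0, "minor": 10.0, "diameter": 10.0,
                                   "aspect": 1.0, "classification": "negative"}])],
            ignore_index=True,
        )
        matched = match_cells(fake, truth.cells)
        assert (matched["truth_idx"] < 0).sum() >= 1
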