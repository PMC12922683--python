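import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from cytoplex.core import RegionOfInterest
from cytoplex.discs import (ClassifierConfig, DetectionParams, PanelConfig,
                            UncorrectableROIError, apply_exclusions,
                            classify_discs, classify_pixels, cleanup_mask,
                            compute_features, detect_cells, detect_cells_iba1,
                            diffuse_correction, expand_to_discs, measure_discs,
                            normalize_upper_quartile, run_pipeline, summarize,
                            train_pixel_classifier)
from cytoplex.synthetic import (CellClassSpec, TissueSimConfig,
                                annotation_mask_for_channel,
                                annotation_mask_high_low, generate_tissue_image)

from conftest import plane

FAST_CFG = ClassifierConfig(scales_um=(0.5, 1.0, 2.0), max_samples_per_class=4000,
                            max_iter=150)


class TestComputeFeatures:
    def test_constant_image(self):
        cfg = ClassifierConfig(features=("gaussian", "laplacian_of_gaussian",
                                         "gradient_magnitude"), scales_um=(1.0, 2.0))
        fs = compute_features(plane(np.full((32, 32), 5.0)), cfg)
        gaussian = fs.data[fs.names.index("gaussian@1.0um")]
        np.testing.assert_allclose(gaussian, 5.0, atol=1e-6)
        log = fs.data[fs.names.index("laplacian_of_gaussian@1.0um")]
        np.testing.assert_allclose(log, 0.0, atol=1e-6)
        grad = fs.data[fs.names.index("gradient_magnitude@2.0um")]
        np.testing.assert_allclose(grad, 0.0, atol=1e-6)

    def test_local_normalization_of_constant_is_zero(self):
        cfg = ClassifierConfig(features=("gaussian",), scales_um=(1.0,),
                               local_normalization_scale_um=4.0)
        fs = compute_features(plane(np.full((32, 32), 3.0)), cfg)
        np.testing.assert_allclose(fs.data, 0.0, atol=1e-10)

    def test_impulse_matches_dense_convolution_oracle(self):
        img = np.zeros((33, 33))
        img[16, 16] = 1.0
        cfg = ClassifierConfig(features=("gaussian",), scales_um=(1.0,))
        fs = compute_features(plane(img, pixel_size_um=1.0), cfg)
        # dense separable Gaussian at three probe pixels (truncate = 6σ)
        r = int(6.0 * 1.0 + 0.5)
        x = np.arange(-r, r + 1)
        k = np.exp(-0.5 * x ** 2)
        k /= k.sum()
        for (pr, pc) in [(16, 16), (16, 17), (15, 15)]:
            expected = k[pr - 16 + r] * k[pc - 16 + r]
            assert fs.data[0][pr, pc] == pytest.approx(expected, abs=1e-10)

    def test_oversized_scale_errors(self):
        cfg = ClassifierConfig(features=("gaussian",), scales_um=(64.0,))
        with pytest.raises(ValueError, match="scale"):
            compute_features(plane(np.zeros((16, 16)), pixel_size_um=0.5), cfg)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(features=())
        with pytest.raises(ValueError):
            ClassifierConfig(scales_um=(2.0, 1.0))
        with pytest.raises(ValueError):
            ClassifierConfig(features=("warp",))


def _separable_scene(seed=0):
    """Two-band image: left dark, right bright — linearly separable."""
    rng = np.random.default_rng(seed)
    img = rng.normal(0.0, 0.05, (64, 64))
    img[:, 32:] += 5.0
    ann = np.zeros((64, 64), dtype=np.int32)
    ann[:, :16] = 1
    ann[:, 48:] = 2
    return plane(img), ann


class TestPixelClassifier:
    def test_separable_training_accuracy(self):
        p, ann = _separable_scene()
        fs = compute_features(p, FAST_CFG)
        model = train_pixel_classifier(fs, ann, FAST_CFG)
        assert model.training_accuracy >= 0.99

    def test_single_class_annotation_errors(self):
        p, ann = _separable_scene()
        ann[ann == 2] = 0
        fs = compute_features(p, FAST_CFG)
        with pytest.raises(ValueError, match="2 classes"):
            train_pixel_classifier(fs, ann, FAST_CFG)

    def test_seeded_determinism(self):
        p, ann = _separable_scene()
        fs = compute_features(p, FAST_CFG)
        m1 = train_pixel_classifier(fs, ann, FAST_CFG)
        m2 = train_pixel_classifier(fs, ann, FAST_CFG)
        np.testing.assert_array_equal(m1.predict(fs), m2.predict(fs))


class TestCleanupAndClassify:
    def test_all_background_features_empty_mask(self):
        p, ann = _separable_scene()
        fs = compute_features(p, FAST_CFG)
        model = train_pixel_classifier(fs, ann, FAST_CFG)
        blank = compute_features(plane(np.zeros((64, 64))), FAST_CFG)
        labels = classify_pixels(model, blank)
        assert not (labels == 2).any()

    def test_small_speck_removed(self):
        # 5 μm² = 20 px at 0.5 μm/px, below the 10 μm² minimum
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:14, 10:15] = True
        out = cleanup_mask(mask, min_object_um2=10.0, min_hole_um2=20.0,
                           pixel_size_um=0.5)
        assert not out.any()

    def test_large_object_kept(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:20, 10:20] = True  # 25 μm²
        out = cleanup_mask(mask, 10.0, 20.0, 0.5)
        assert out.sum() == 100

    def test_small_hole_filled(self):
        # 15 μm² hole (60 px) inside a large object, below the 20 μm² minimum
        mask = np.ones((64, 64), dtype=bool)
        mask[20:26, 20:30] = False
        out = cleanup_mask(mask, 10.0, 20.0, 0.5)
        assert out.all()

    def test_large_hole_preserved(self):
        # 25 μm² hole (100 px) stays open
        mask = np.ones((64, 64), dtype=bool)
        mask[20:30, 20:30] = False
        out = cleanup_mask(mask, 10.0, 20.0, 0.5)
        assert not out[22, 22]


@pytest.fixture(scope="module")
def detection_scene():
    cfg = TissueSimConfig(
        cell_classes=[CellClassSpec("n", "M", "somatic", 4.0, 40, soma_margin_um=2.0)],
        image_size_px=(384, 384), nucleus_area_um2_range=(30.0, 80.0),
        control_background=0.1, seed=21)
    return cfg, *generate_tissue_image(cfg)


class TestDetectCells:
    def test_blank_plane_no_cells(self):
        labels = detect_cells(plane(np.zeros((64, 64))))
        assert not labels.any()

    def test_simulator_field_recovery(self, detection_scene):
        cfg, stack, gt, masks = detection_scene
        labels = detect_cells(stack.plane("DAPI"))
        n = labels.max()
        assert n >= 0.98 * len(gt)
        _, areas = np.unique(labels[labels > 0], return_counts=True)
        areas_um2 = areas * 0.25
        assert (areas_um2 >= 10.0).all() and (areas_um2 <= 100.0).all()

    def test_oversized_blob_rejected_without_split(self):
        img = np.zeros((128, 128))
        rr, cc = np.ogrid[:128, :128]
        img[(rr - 64) ** 2 + (cc - 64) ** 2 <= 14 ** 2] = 2.0  # ~154 μm²
        params = DetectionParams(split_by_shape=False)
        labels = detect_cells(plane(img), params)
        assert labels.max() == 0

    def test_empty_within_mask_zero_detections(self):
        img = np.ones((64, 64))
        labels = detect_cells(plane(img), within=np.zeros((64, 64), dtype=bool))
        assert not labels.any()

    def test_iba1_mode_no_signal(self):
        labels = detect_cells_iba1(plane(np.zeros((64, 64))), DetectionParams(),
                                   np.zeros((64, 64), dtype=bool))
        assert not labels.any()


class TestExpandToDiscs:
    def test_zero_expansion_is_identity(self):
        nuclei = np.zeros((32, 32), dtype=np.int32)
        nuclei[10:15, 10:15] = 1
        np.testing.assert_array_equal(expand_to_discs(nuclei, 0.0, 0.5), nuclei)

    def test_circle_matches_bruteforce_distance_oracle(self):
        # nucleus: discrete disk radius 3 μm (6 px), expansion 2 μm (4 px)
        nuclei = np.zeros((64, 64), dtype=np.int32)
        rr, cc = np.ogrid[:64, :64]
        nucleus = (rr - 32) ** 2 + (cc - 32) ** 2 <= 6 ** 2
        nuclei[nucleus] = 1
        discs = expand_to_discs(nuclei, 2.0, 0.5)
        pts = np.argwhere(nucleus)
        grid = np.stack(np.meshgrid(np.arange(64), np.arange(64), indexing="ij"), -1)
        d = np.sqrt(((grid[:, :, None, :] - pts[None, None, :, :]) ** 2).sum(-1)).min(-1)
        expected = d <= 4.0
        np.testing.assert_array_equal(discs > 0, expected)

    def test_disc_radius_area_ratio(self):
        nuclei = np.zeros((64, 64), dtype=np.int32)
        rr, cc = np.ogrid[:64, :64]
        nucleus = (rr - 32) ** 2 + (cc - 32) ** 2 <= 6 ** 2
        nuclei[nucleus] = 1
        discs = expand_to_discs(nuclei, 2.0, 0.5)
        ratio = (discs > 0).sum() / nucleus.sum()
        assert ratio == pytest.approx(25.0 / 9.0, rel=0.15)

    def test_two_nuclei_disjoint_equidistant_boundary(self):
        nuclei = np.zeros((64, 64), dtype=np.int32)
        nuclei[30:34, 20:24] = 1
        nuclei[30:34, 30:34] = 2  # 3 μm apart at 0.5 μm/px
        discs = expand_to_discs(nuclei, 2.0, 0.5)
        # labels disjoint by construction of a label grid; each disc keeps its
        # pixels closer to its own nucleus
        d1 = ndi.distance_transform_edt(nuclei != 1)
        d2 = ndi.distance_transform_edt(nuclei != 2)
        assert (d1[discs == 1] <= d2[discs == 1] + 1e-9).all()
        assert (d2[discs == 2] <= d1[discs == 2] + 1e-9).all()

    def test_disc_contains_nucleus(self):
        nuclei = np.zeros((32, 32), dtype=np.int32)
        nuclei[5:9, 5:9] = 1
        discs = expand_to_discs(nuclei, 1.0, 0.5)
        assert (discs[nuclei == 1] == 1).all()


class TestClassifyDiscs:
    def _records(self):
        discs = np.zeros((32, 32), dtype=np.int32)
        discs[4:10, 4:10] = 1
        discs[20:26, 20:26] = 2
        return measure_discs(plane(np.ones((32, 32))), discs)

    def test_centroid_inside_positive(self):
        rec = self._records()
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:10, 4:10] = True
        out = classify_discs(rec, {"A": mask})
        assert out.loc[out.disc_id == 1, "pos_A"].item()
        assert not out.loc[out.disc_id == 2, "pos_A"].item()

    def test_centroid_one_pixel_outside_negative(self):
        rec = self._records()
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:10, 4:6] = True  # positive area misses centroid (6.5, 6.5)
        out = classify_discs(rec, {"A": mask})
        assert not out["pos_A"].any()

    def test_multi_positive_excluded_from_single_positive_summary(self):
        rec = self._records()
        full = np.ones((32, 32), dtype=bool)
        out = classify_discs(rec, {"A": full, "B": full})
        assert (out.n_positive == 2).all()
        assert out["marker"].isna().all()
        out["normalized"] = 1.0
        assert summarize(out).empty


class TestDiffuseCorrection:
    def _setup(self, diffuse, seed=30):
        cfg = TissueSimConfig(
            cell_classes=[CellClassSpec("n", "M", "somatic", 6.0, 25)],
            image_size_px=(320, 320), diffuse_level=diffuse,
            control_background=0.2, seed=seed)
        stack, gt, masks = generate_tissue_image(cfg)
        target = stack.plane("TARGET")
        records = measure_discs(target, masks["somas"])
        low_mask = masks["somas"] == 0
        return cfg, target, records, low_mask

    def test_low_median_recovers_diffuse_level(self):
        cfg, target, records, low_mask = self._setup(diffuse=1.5)
        roi = RegionOfInterest.full(target.shape)
        low_median, out = diffuse_correction(target, roi, low_mask, records)
        assert low_median == pytest.approx(1.5 + 0.2, rel=0.02)
        assert out.corrected_mean.mean() == pytest.approx(6.0, rel=0.05)

    def test_zero_diffuse_correction_near_zero(self):
        cfg, target, records, low_mask = self._setup(diffuse=0.0)
        roi = RegionOfInterest.full(target.shape)
        low_median, out = diffuse_correction(target, roi, low_mask, records)
        assert low_median == pytest.approx(0.2, rel=0.02)
        np.testing.assert_allclose(out.corrected_mean, out.raw_mean - low_median)

    def test_per_roi_medians_independent(self):
        cfg1, t1, r1, lm1 = self._setup(diffuse=0.5, seed=31)
        cfg2, t2, r2, lm2 = self._setup(diffuse=2.0, seed=32)
        m1, _ = diffuse_correction(t1, RegionOfInterest.full(t1.shape), lm1, r1)
        m2, _ = diffuse_correction(t2, RegionOfInterest.full(t2.shape), lm2, r2)
        assert m2 - m1 == pytest.approx(1.5, abs=0.1)

    def test_empty_low_class_errors(self):
        cfg, target, records, low_mask = self._setup(diffuse=0.0)
        with pytest.raises(UncorrectableROIError):
            diffuse_correction(target, RegionOfInterest.full(target.shape),
                               np.zeros(target.shape, dtype=bool), records)


def _records_with(corrected, source="DAPI"):
    return pd.DataFrame({
        "disc_id": range(1, len(corrected) + 1),
        "subject_id": "s1", "region": "r", "source": source,
        "corrected_mean": corrected,
    })


class TestNormalizeUpperQuartile:
    def test_stated_percentile_rule(self):
        q3, out = normalize_upper_quartile(_records_with([1.0, 2.0, 3.0, 4.0]))
        assert q3 == pytest.approx(3.25)
        assert out.normalized.iloc[-1] == pytest.approx(4.0 / 3.25)

    def test_all_equal_normalized_to_one(self):
        q3, out = normalize_upper_quartile(_records_with([2.0] * 5))
        np.testing.assert_allclose(out.normalized, 1.0)

    def test_scale_invariance(self):
        vals = [1.0, 2.5, 3.0, 7.0]
        _, out1 = normalize_upper_quartile(_records_with(vals))
        _, out2 = normalize_upper_quartile(_records_with([9.0 * v for v in vals]))
        np.testing.assert_allclose(out1.normalized, out2.normalized)

    def test_iba1_discs_use_dapi_denominator(self):
        rec = pd.concat([_records_with([1.0, 2.0, 3.0, 4.0]),
                         _records_with([6.5], source="IBA1")], ignore_index=True)
        q3, out = normalize_upper_quartile(rec)
        assert q3 == pytest.approx(3.25)  # unaffected by the IBA1 disc
        assert out.loc[out.source == "IBA1", "normalized"].item() == pytest.approx(2.0)

    def test_too_few_discs_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            normalize_upper_quartile(_records_with([1.0, 2.0, 3.0]))

    def test_degenerate_quartile_errors(self):
        with pytest.raises(ValueError, match="upper quartile"):
            normalize_upper_quartile(_records_with([-1.0, -2.0, -3.0, -4.0]))

    def test_idempotence_on_normalized_records(self):
        _, out = normalize_upper_quartile(_records_with([1.0, 2.0, 3.0, 4.0]))
        rescaled = out.rename(columns={"corrected_mean": "old"}).assign(
            corrected_mean=lambda d: d.normalized)
        q3, _ = normalize_upper_quartile(rescaled)
        assert q3 == pytest.approx(1.0)


def _flagged_records():
    rec = pd.DataFrame({
        "disc_id": range(1, 7),
        "subject_id": "s1",
        "region": ["SP", "SP", "CC", "CC", "CC", "SP"],
        "source": "DAPI",
        "normalized": [1.0, 0.5, 0.4, 0.6, 0.2, 0.9],
        "pos_ALDH1L1": [True, False, False, False, False, False],
        "pos_CAMK2A": [False, True, True, True, False, True],
        "n_positive": [1, 1, 1, 1, 0, 2],
    })
    rec["marker"] = [
        "ALDH1L1", "CAMK2A", "CAMK2A", "CAMK2A", None, None]
    return rec


class TestApplyExclusionsAndSummarize:
    def test_rule_removes_matching_discs(self):
        out, counts = apply_exclusions(_flagged_records(),
                                       {"SP": ["ALDH1L1"], "CC": ["CAMK2A"]})
        assert counts["SP:ALDH1L1"] == 1
        assert counts["CC:CAMK2A"] == 2
        assert not ((out.region == "CC") & out.pos_CAMK2A).any()

    def test_empty_rulebook_keeps_single_positives(self):
        rec = _flagged_records()
        out, counts = apply_exclusions(rec, {})
        assert counts["multi_positive"] == 1
        assert len(out) == len(rec) - 1

    def test_unknown_marker_errors(self):
        with pytest.raises(ValueError, match="unknown marker"):
            apply_exclusions(_flagged_records(), {"SP": ["NOPE"]})

    def test_summarize_single_disc_sem_missing(self):
        rec = _flagged_records()
        out = summarize(rec)
        row = out[(out.region == "SP") & (out.marker == "ALDH1L1")]
        assert row["mean"].item() == 1.0
        assert np.isnan(row["sem"].item())

    def test_summarize_empty_class_has_no_row(self):
        out = summarize(_flagged_records())
        assert not ((out.region == "SP") & (out.marker == "NOPE")).any()

    def test_summarize_mean_over_discs(self):
        out = summarize(_flagged_records())
        row = out[(out.region == "CC") & (out.marker == "CAMK2A")]
        assert row["mean"].item() == pytest.approx(0.5)
        assert row["n_discs"].item() == 2


@pytest.fixture(scope="module")
def mini_pipeline():
    classes = [
        CellClassSpec("neuron", "NEURON_M", "somatic", 10.0, 12),
        CellClassSpec("glia", "GLIA_M", "somatic", 2.0, 12),
    ]
    cfg = TissueSimConfig(cell_classes=classes, image_size_px=(320, 320),
                          nucleus_area_um2_range=(25.0, 55.0),
                          control_background=0.2, seed=17)
    stack, gt, masks = generate_tissue_image(cfg)
    panel = PanelConfig(marker_configs={c.marker_channel: FAST_CFG for c in classes},
                        highlow_config=ClassifierConfig(
                            features=("gaussian", "laplacian_of_gaussian", "weighted_std"),
                            scales_um=(0.5, 1.0, 2.0, 4.0),
                            local_normalization_scale_um=32.0,
                            max_samples_per_class=4000, max_iter=150))
    anns = {c.marker_channel: annotation_mask_for_channel(masks, c.marker_channel)
            for c in classes}
    records, info = run_pipeline(stack, panel=panel, marker_annotations=anns,
                                 highlow_annotation=annotation_mask_high_low(masks))
    return cfg, gt, masks, records, info


class TestPipelineInvariants:
    def test_discs_disjoint_and_contain_nuclei(self, mini_pipeline):
        _, _, _, _, info = mini_pipeline
        nuclei, discs = info["nuclei"], info["discs"]
        covered = nuclei > 0
        assert (discs[covered] == nuclei[covered]).all()

    def test_planted_ranking_recovered(self, mini_pipeline):
        _, _, _, records, _ = mini_pipeline
        summ = summarize(records).set_index("marker")["mean"]
        assert summ["NEURON_M"] > summ["GLIA_M"]

    def test_training_accuracy_reported(self, mini_pipeline):
        _, _, _, _, info = mini_pipeline
        for model in info["models"].values():
            assert model.training_accuracy > 0.95
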