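"""Multi-scale pixel features, forest training/prediction, binarization."""

import numpy as np
import pytest

from plateseg.containers import ProjectedImage
from plateseg.pixel_classifier import (FeatureConfig, PixelAnnotation,
                                       PixelLabel,
                                       baseline_threshold_segmentation,
                                       compute_pixel_features, mask_iou,
                                       predict_probability,
                                       probability_to_mask,
                                       train_pixel_classifier)

from conftest import make_rendered


class TestComputePixelFeatures:
    def test_default_bank_has_48_planes(self):
        config = FeatureConfig()
        assert config.n_planes == 48
        feats = compute_pixel_features(np.random.default_rng(0).random((32, 32)),
                                       config)
        assert feats.shape == (48, 32, 32)

    def test_constant_image(self):
        feats = compute_pixel_features(
            np.full((40, 40), 7.0),
            FeatureConfig(scales=(1.0, 2.0)))
        names = FeatureConfig(scales=(1.0, 2.0)).plane_names()
        for plane, name in zip(feats, names):
            if name.startswith("smoothed"):
                assert np.allclose(plane, 7.0)
            else:
                # derivative-based features vanish on a constant image up to
                # truncated-kernel residue (the DoG pair leaves ~1e-4 of the
                # intensity)
                assert np.allclose(plane, 0.0, atol=7.0 * 1e-3)

    def test_smoothed_point_source_matches_gaussian_kernel(self):
        s = 2.0
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        feats = compute_pixel_features(img, FeatureConfig(
            scales=(s,), feature_kinds=("smoothed",)))
        yy, xx = np.mgrid[-20:21, -20:21]
        kernel = np.exp(-(yy**2 + xx**2) / (2 * s**2)) / (2 * np.pi * s**2)
        assert np.allclose(feats[0], kernel, atol=1e-4)

    def test_translation_equivariance_interior(self):
        rng = np.random.default_rng(3)
        img = rng.random((64, 64))
        shifted = np.roll(img, (5, 7), axis=(0, 1))
        config = FeatureConfig(scales=(1.0, 1.6))
        a = compute_pixel_features(img, config)
        b = compute_pixel_features(shifted, config)
        # compare interiors far from both images' borders
        assert np.allclose(np.roll(a, (5, 7), axis=(1, 2))[:, 20:44, 20:44],
                           b[:, 20:44, 20:44], atol=1e-8)

    def test_oversized_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            compute_pixel_features(np.ones((16, 16)),
                                   FeatureConfig(scales=(10.0,)))


class TestTrainPredict:
    def test_training_pixel_accuracy_is_perfect_when_separable(self):
        from plateseg.pixel_classifier import ForestParams
        from plateseg.synthetic import sample_pixel_annotations

        scene, image = make_rendered(45, shape=(256, 256), counts=(3, 3, 3))
        anns = sample_pixel_annotations(scene, n_signal=300, n_background=300,
                                        rng_seed=9, image_id=image.source_id)
        clf = train_pixel_classifier([image], anns,
                                     forest_params=ForestParams(n_trees=20),
                                     rng_seed=1)
        assert clf.provenance["n_signal"] == 300
        feats = compute_pixel_features(image, clf.feature_config)
        correct = total = 0
        for ann in anns:
            coords = np.array(ann.coordinates)
            X = feats[:, coords[:, 0], coords[:, 1]].T
            pred = clf.model.predict(X)
            correct += int((pred == int(ann.label)).sum())
            total += len(coords)
        assert correct == total

    def test_prediction_probabilities_and_determinism(
            self, trained_pixel_classifier):
        _, image = make_rendered(40, shape=(256, 256), counts=(3, 3, 3))
        p1 = predict_probability(trained_pixel_classifier, image)
        p2 = predict_probability(trained_pixel_classifier, image)
        assert p1.shape == image.shape
        assert p1.min() >= 0 and p1.max() <= 1
        assert np.array_equal(p1, p2)

    def test_single_class_annotations_rejected(self):
        _, image = make_rendered(41, shape=(256, 256), counts=(2, 2, 2))
        anns = [PixelAnnotation(image.source_id, [(5, 5), (6, 6)],
                                PixelLabel.SIGNAL)]
        with pytest.raises(ValueError, match="BACKGROUND"):
            train_pixel_classifier([image], anns)

    def test_out_of_bounds_annotation_rejected(self):
        _, image = make_rendered(42, shape=(256, 256), counts=(2, 2, 2))
        anns = [
            PixelAnnotation(image.source_id, [(5, 5)], PixelLabel.SIGNAL),
            PixelAnnotation(image.source_id, [(999, 0)], PixelLabel.BACKGROUND),
        ]
        with pytest.raises(ValueError, match="outside"):
            train_pixel_classifier([image], anns)


class TestProbabilityToMask:
    def test_zero_probability_gives_empty_mask(self):
        mask = probability_to_mask(np.zeros((20, 20)))
        assert not mask.data.any()

    def test_min_area_filter(self):
        prob = np.zeros((30, 30))
        prob[5:8, 5:8] = 1.0  # a 9-px blob
        assert not probability_to_mask(prob, min_area=20).data.any()
        assert probability_to_mask(prob, min_area=5).data.sum() == 9

    def test_monotone_in_threshold(self):
        prob = np.random.default_rng(5).random((40, 40))
        lo = probability_to_mask(prob, threshold=0.3, min_area=0,
                                 fill_holes=False)
        hi = probability_to_mask(prob, threshold=0.7, min_area=0,
                                 fill_holes=False)
        assert np.all(lo.data | ~hi.data)  # hi subset of lo

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            probability_to_mask(np.zeros((5, 5)), threshold=0.0)

    def test_scene_mask_iou_against_truth(self, trained_pixel_classifier):
        scene, image = make_rendered(50, shape=(256, 256), counts=(3, 3, 3))
        prob = predict_probability(trained_pixel_classifier, image)
        mask = probability_to_mask(prob)
        assert mask_iou(mask, scene.truth_labels.data > 0) >= 0.9


class TestBaseline:
    def test_exact_on_clean_two_level_image(self):
        truth = np.zeros((64, 64), bool)
        truth[10:30, 15:40] = True
        img = np.where(truth, 200.0, 10.0)
        mask = baseline_threshold_segmentation(
            ProjectedImage(img), min_area=0, smooth_sigma=0.0)
        assert np.array_equal(mask.data, truth)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            baseline_threshold_segmentation(ProjectedImage(np.full((20, 20), 3.0)))
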