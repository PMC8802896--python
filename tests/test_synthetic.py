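"""Synthetic scene generator: shape statistics, clustering, rendering."""

import math

import numpy as np
import pytest
from scipy import ndimage as ndi

from plateseg.containers import MorphClass
from plateseg.morphology import circularity, contour_perimeter
from plateseg.synthetic import (DEFAULT_CLASS_PARAMS, ClassShapeParams,
                                RenderSpec, SceneSpec, generate_scene,
                                generate_shape, render_stack,
                                sample_platelet_records)

from conftest import make_scene

EIGHT = np.ones((3, 3), int)
FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


class TestGenerateShape:
    def test_unspread_disk_area(self):
        # fixed 1.5 µm radius at 0.1 µm/px is a 15 px disk: pi*15^2 ~ 707
        params = ClassShapeParams(radius_um=(1.5, 1.5), irregularity=(0.0, 0.0))
        mask = generate_shape(MorphClass.UNSPREAD, params, rng_seed=1)
        _, n = ndi.label(mask, structure=FOUR)
        assert n == 1
        assert 600 <= mask.sum() <= 800

    def test_partial_less_circular_than_convex_hull(self):
        from skimage.morphology import convex_hull_image

        params = ClassShapeParams(radius_um=(1.8, 1.8), n_filopodia=(5, 5),
                                  filopodium_length_um=(1.5, 1.5))
        mask = generate_shape(MorphClass.PARTIAL, params, rng_seed=2)
        hull = convex_hull_image(mask)
        c_mask = circularity(mask.sum(), contour_perimeter(mask))
        c_hull = circularity(hull.sum(), contour_perimeter(hull))
        assert c_mask < c_hull

    def test_seeded_determinism(self):
        a = generate_shape(MorphClass.SPREAD, rng_seed=7)
        b = generate_shape(MorphClass.SPREAD, rng_seed=7)
        assert np.array_equal(a, b)

    def test_degenerate_radius_rejected(self):
        params = ClassShapeParams(radius_um=(0.05, 0.05))
        with pytest.raises(ValueError, match="radius"):
            generate_shape(MorphClass.UNSPREAD, params, rng_seed=0)

    def test_every_class_single_4connected_component(self):
        for cls in MorphClass:
            for seed in range(5):
                mask = generate_shape(cls, rng_seed=seed)
                _, n = ndi.label(mask, structure=FOUR)
                assert n == 1, f"{cls.name} seed {seed}"

    def test_class_ordering_over_many_shapes(self):
        """Median area SPREAD > PARTIAL > UNSPREAD; circularity U > P."""
        records = sample_platelet_records(100, rng_seed=7)
        med_area = {c: records.loc[records.true_class == int(c), "area_px"].median()
                    for c in MorphClass}
        med_circ = {c: records.loc[records.true_class == int(c),
                                   "circularity"].median()
                    for c in MorphClass}
        assert med_area[MorphClass.SPREAD] > med_area[MorphClass.PARTIAL]
        assert med_area[MorphClass.PARTIAL] > med_area[MorphClass.UNSPREAD]
        assert med_circ[MorphClass.UNSPREAD] > med_circ[MorphClass.PARTIAL]


class TestGenerateScene:
    def test_count_conservation_no_clusters(self):
        scene = make_scene(3, shape=(448, 448), counts=(5, 5, 5), n_clusters=0)
        assert scene.truth_labels.n_labels == 15
        _, n = ndi.label(scene.truth_labels.data > 0, structure=EIGHT)
        assert n == 15
        assert len(scene.truth_seeds) == 0

    def test_touching_clusters_merge_components(self):
        spec = SceneSpec(image_shape=(384, 384),
                         counts={MorphClass.SPREAD: 4,
                                 MorphClass.UNSPREAD: 0,
                                 MorphClass.PARTIAL: 0},
                         n_touching_clusters=2, cluster_size_range=(2, 2),
                         rng_seed=4)
        scene = generate_scene(spec)
        assert scene.truth_labels.n_labels == 4
        _, n = ndi.label(scene.truth_labels.data > 0, structure=EIGHT)
        assert n == 2
        assert len(scene.truth_seeds) == 4

    def test_empty_scene(self):
        spec = SceneSpec(counts={c: 0 for c in MorphClass},
                         n_touching_clusters=0, rng_seed=0)
        scene = generate_scene(spec)
        assert scene.truth_labels.n_labels == 0
        assert len(scene.truth_seeds) == 0

    def test_labels_consecutive_and_classed(self, small_scene):
        labels = small_scene.truth_labels
        present = sorted(np.unique(labels.data).tolist())
        assert present == list(range(0, labels.n_labels + 1))
        assert set(small_scene.truth_classes) == set(range(1, labels.n_labels + 1))

    def test_seeds_on_distinct_objects(self):
        scene = make_scene(5, shape=(384, 384), n_clusters=2)
        owners = [int(scene.truth_labels.data[p]) for p in scene.truth_seeds]
        assert 0 not in owners
        assert len(set(owners)) == len(owners)

    def test_infeasible_placement_reports_progress(self):
        spec = SceneSpec(image_shape=(96, 96),
                         counts={MorphClass.SPREAD: 30,
                                 MorphClass.UNSPREAD: 0,
                                 MorphClass.PARTIAL: 0},
                         n_touching_clusters=0, rng_seed=0)
        with pytest.raises(RuntimeError, match="placed"):
            generate_scene(spec)

    def test_scene_determinism(self):
        a = make_scene(9)
        b = make_scene(9)
        assert np.array_equal(a.truth_labels.data, b.truth_labels.data)
        assert a.truth_seeds.points == b.truth_seeds.points
        assert a.truth_classes == b.truth_classes


class TestRenderStack:
    def test_degenerate_blur_profile(self, small_scene):
        spec = RenderSpec(n_slices=3, focus_index=1, base_sigma=0.0,
                          blur_sigma_step=0.0, noise_sd=0.0)
        stack = render_stack(small_scene, spec)
        assert np.array_equal(stack.data[0], stack.data[1])
        assert np.array_equal(stack.data[1], stack.data[2])

    def test_gradient_energy_peaks_at_focus(self, small_scene):
        stack = render_stack(small_scene,
                             RenderSpec(n_slices=9, focus_index=4,
                                        noise_sd=0.0, rng_seed=0))
        energies = []
        for i in range(9):
            gy, gx = np.gradient(stack.data[i])
            energies.append(np.sum(gy**2 + gx**2))
        assert int(np.argmax(energies)) == 4

    def test_render_determinism_and_clipping(self, small_scene):
        spec = RenderSpec(noise_sd=50.0, rng_seed=3)
        a = render_stack(small_scene, spec)
        b = render_stack(small_scene, spec)
        assert np.array_equal(a.data, b.data)
        assert a.data.min() >= 0

    def test_focus_index_validation(self):
        with pytest.raises(ValueError):
            RenderSpec(n_slices=3, focus_index=5)
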