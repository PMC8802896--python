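import numpy as np
import pytest

from plateseg.containers import MorphClass
from plateseg.focus import project
from plateseg.synthetic import (RenderSpec, SceneSpec, generate_scene,
                                render_stack, sample_pixel_annotations)


def make_scene(seed: int, shape=(320, 320), counts=(4, 4, 4),
               n_clusters: int = 1, cluster_range=(2, 2)) -> "SceneSpec":
    spec = SceneSpec(
        image_shape=shape,
        counts={MorphClass.UNSPREAD: counts[0],
                MorphClass.PARTIAL: counts[1],
                MorphClass.SPREAD: counts[2]},
        n_touching_clusters=n_clusters,
        cluster_size_range=cluster_range,
        rng_seed=seed,
    )
    return generate_scene(spec)


def make_rendered(seed: int, noise_sd: float = 5.0, **scene_kwargs):
    """A (scene, focus-projected image) pair with the given noise level."""
    scene = make_scene(seed, **scene_kwargs)
    stack = render_stack(scene, RenderSpec(noise_sd=noise_sd,
                                           rng_seed=seed + 1000))
    image = project(stack)
    image.source_id = f"scene{seed}"
    return scene, image


@pytest.fixture(scope="session")
def small_scene():
    return make_scene(2, shape=(256, 256), counts=(3, 3, 3))


@pytest.fixture(scope="session")
def trained_pixel_classifier():
    """A forest trained on two small synthetic images (kept small for speed)."""
    from plateseg.pixel_classifier import ForestParams, train_pixel_classifier

    images, annotations = [], []
    for i, seed in enumerate((11, 12)):
        scene, image = make_rendered(seed, shape=(256, 256), counts=(3, 3, 3))
        image.source_id = f"train{i}"
        images.append(image)
        annotations.extend(sample_pixel_annotations(
            scene, n_signal=400, n_background=400, rng_seed=seed,
            image_id=f"train{i}"))
    return train_pixel_classifier(images, annotations,
                                  forest_params=ForestParams(n_trees=30),
                                  rng_seed=0)
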