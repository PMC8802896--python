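"""Ground-truthed synthetic platelet scenes and defocus z-stack rendering.

Real platelet-spreading assays image fluorescently labelled (e.g. F-actin)
platelets settling on a protein-coated surface.  This module builds fake
fields of view with known per-cell ground truth so that every downstream
stage — focus selection, pixel classification, seeded watershed separation,
morphometry and object classification — can be exercised and scored without
any real microscopy data.

Three morphology classes are modelled with simple parametric shapes:

* ``UNSPREAD``   — near-circular disk with a slightly noisy radius
                   (resting platelets are 2–4 µm discoid cells);
* ``PARTIAL``    — medium disk with thin radial filopodia (2–3 px wide
                   dilated line segments);
* ``SPREAD``     — large blob whose radius is perturbed by a few low-order
                   Fourier harmonics ("Fourier blob"), mimicking a smooth
                   irregular lamellipodial outline up to ~8 µm across.

Scenes can contain touching clusters: members are placed with centre
distance below the sum of their radii and contested pixels are assigned to
the nearest member centre, which gives a well-defined ground-truth split
for watershed testing.  Rendering converts the label image into a z-stack
in which defocus is emulated by extra Gaussian blur per slice away from the
focal plane, plus additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage import draw, morphology as skmorph

from .containers import ImageStack, LabeledSegmentation, MorphClass, SeedSet

__all__ = [
    "ClassShapeParams",
    "SceneSpec",
    "RenderSpec",
    "SyntheticScene",
    "generate_shape",
    "generate_scene",
    "render_stack",
    "sample_pixel_annotations",
    "sample_platelet_records",
    "DEFAULT_CLASS_PARAMS",
]

_MAX_PLACEMENT_RETRIES = 100


@dataclass(frozen=True)
class ClassShapeParams:
    """Shape parameter ranges for one morphology class.

    Radii and filopodium lengths are in micrometres; the number of
    filopodia is an inclusive integer range; ``irregularity`` is the
    relative amplitude of the radial Fourier perturbation.
    """

    radius_um: tuple[float, float]
    irregularity: tuple[float, float] = (0.02, 0.06)
    n_harmonics: tuple[int, int] = (2, 4)
    n_filopodia: tuple[int, int] = (0, 0)
    filopodium_length_um: tuple[float, float] = (0.0, 0.0)
    filopodium_width_px: int = 3


#: Default per-class shape distributions.  Unspread platelets are 2–4 µm
#: diameter disks; partially spread cells are slightly larger with 3–8 thin
#: filopodia; fully spread cells reach ~5–8 µm across with a smooth
#: irregular outline.  Only the between-class orderings of area and
#: circularity are meaningful, not the absolute values.
DEFAULT_CLASS_PARAMS: dict[MorphClass, ClassShapeParams] = {
    MorphClass.UNSPREAD: ClassShapeParams(radius_um=(1.0, 2.0)),
    MorphClass.PARTIAL: ClassShapeParams(
        radius_um=(1.2, 2.2),
        irregularity=(0.03, 0.08),
        n_filopodia=(3, 8),
        filopodium_length_um=(0.8, 2.0),
    ),
    MorphClass.SPREAD: ClassShapeParams(
        radius_um=(2.5, 4.0), irregularity=(0.10, 0.25), n_harmonics=(2, 6)
    ),
}


@dataclass
class SceneSpec:
    """Recipe for one synthetic field of view."""

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # µm per pixel
    counts: Mapping[MorphClass, int] = field(
        default_factory=lambda: {
            MorphClass.UNSPREAD: 10,
            MorphClass.PARTIAL: 10,
            MorphClass.SPREAD: 10,
        }
    )
    n_touching_clusters: int = 2
    cluster_size_range: tuple[int, int] = (2, 3)
    class_params: Mapping[MorphClass, ClassShapeParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.counts = {MorphClass.from_any(k): int(v) for k, v in self.counts.items()}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("object counts must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        lo, hi = self.cluster_size_range
        if lo < 2 or hi < lo:
            raise ValueError("cluster sizes must be >= 2 and ordered")
        if self.n_touching_clusters < 0:
            raise ValueError("n_touching_clusters must be non-negative")

    @property
    def n_objects(self) -> int:
        return sum(self.counts.values())


@dataclass
class RenderSpec:
    """How to turn a scene into a noisy defocus z-stack.

    Slice ``i`` receives Gaussian blur of sigma
    ``base_sigma + blur_sigma_step * |i - focus_index|`` followed by
    additive Gaussian noise; intensities are in arbitrary camera units.
    """

    n_slices: int = 9
    focus_index: int = 4
    base_sigma: float = 1.0
    blur_sigma_step: float = 1.0
    foreground_intensity: float = 200.0
    background_intensity: float = 10.0
    noise_sd: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("need at least one slice")
        if not 0 <= self.focus_index < self.n_slices:
            raise ValueError("focus_index outside the stack")
        if self.blur_sigma_step < 0 or self.base_sigma < 0:
            raise ValueError("blur sigmas must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticScene:
    """A generated scene: ground-truth labels, classes and cluster seeds."""

    truth_labels: LabeledSegmentation
    truth_classes: dict[int, MorphClass]
    truth_seeds: SeedSet
    spec: SceneSpec


# ---------------------------------------------------------------------------
# shape generation


def _radial_blob(radius_px: float, irregularity: float, n_harmonics: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Rasterize a star-convex blob r(theta) = r0 * (1 + sum_k a_k cos(k t + p_k))."""
    ks = np.arange(1, n_harmonics + 1)
    # split the total amplitude across harmonics, decaying with order
    amps = rng.uniform(0.3, 1.0, size=n_harmonics) / ks
    amps *= irregularity / max(amps.sum(), 1e-12)
    phases = rng.uniform(0, 2 * np.pi, size=n_harmonics)

    r_max = radius_px * (1 + irregularity)
    half = int(np.ceil(r_max)) + 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    theta = np.arctan2(yy, xx)
    r_theta = radius_px * (
        1.0 + sum(a * np.cos(k * theta + p) for a, k, p in zip(amps, ks, phases))
    )
    return np.hypot(yy, xx) <= r_theta


def generate_shape(
    morph_class: MorphClass,
    params: ClassShapeParams | None = None,
    rng_seed: int | np.random.Generator = 0,
    pixel_size: float = 0.1,
) -> np.ndarray:
    """Draw one binary platelet shape of the given morphology class.

    Returns a tight boolean canvas containing a single 4-connected
    component.  The same (class, params, seed) always yields the same mask.
    """
    morph_class = MorphClass.from_any(morph_class)
    if params is None:
        params = DEFAULT_CLASS_PARAMS[morph_class]
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed

    radius_um = rng.uniform(*params.radius_um)
    radius_px = radius_um / pixel_size
    if radius_px <= 1:
        raise ValueError(
            f"degenerate radius {radius_px:.2f} px (<= 1); "
            "increase radius_um or decrease pixel_size"
        )
    irregularity = rng.uniform(*params.irregularity)
    n_harm = int(rng.integers(params.n_harmonics[0], params.n_harmonics[1] + 1))
    mask = _radial_blob(radius_px, irregularity, n_harm, rng)

    n_filo = int(rng.integers(params.n_filopodia[0], params.n_filopodia[1] + 1))
    if n_filo > 0:
        length_px = rng.uniform(*params.filopodium_length_um, size=n_filo) / pixel_size
        angles = rng.uniform(0, 2 * np.pi, size=n_filo)
        reach = int(np.ceil(radius_px * (1 + irregularity) + length_px.max())) + 3
        pad = reach - mask.shape[0] // 2
        if pad > 0:
            mask = np.pad(mask, pad)
        centre = mask.shape[0] // 2
        filo = np.zeros_like(mask)
        for ln, ang in zip(length_px, angles):
            tip_r = radius_px + ln
            r1 = centre + int(round(tip_r * np.sin(ang)))
            c1 = centre + int(round(tip_r * np.cos(ang)))
            rr, cc = draw.line(centre, centre, r1, c1)
            keep = (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
            filo[rr[keep], cc[keep]] = True
        width = max(params.filopodium_width_px, 2)
        filo = skmorph.dilation(filo, skmorph.disk((width - 1) // 2 or 1))
        mask = mask | filo

    # star-convex construction keeps the shape connected, but enforce the
    # 4-connectivity contract anyway (a 1-px-wide diagonal filopodium stub
    # could otherwise detach)
    lab, n = ndi.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))

    # crop to a tight bounding box with a 1-px margin
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    return np.pad(mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1], 1)


# ---------------------------------------------------------------------------
# scene assembly


def _paste_bbox(shape: np.ndarray, top: int, left: int) -> tuple[slice, slice]:
    return slice(top, top + shape.shape[0]), slice(left, left + shape.shape[1])


def _can_place(occupied_dil: np.ndarray, shape: np.ndarray, top: int, left: int) -> bool:
    h, w = shape.shape
    if top < 0 or left < 0 or top + h > occupied_dil.shape[0] or left + w > occupied_dil.shape[1]:
        return False
    return not np.any(occupied_dil[top:top + h, left:left + w] & shape)


def _compose_cluster(
    members: list[tuple[MorphClass, np.ndarray]], rng: np.random.Generator
) -> tuple[np.ndarray, list[MorphClass]]:
    """Overlap member shapes and split contested pixels by nearest centre.

    Returns a small labelled canvas (values 1..k in member order) whose
    foreground is a single 8-connected component.
    """
    radii = [max(m.shape) / 2 for _, m in members]
    side = int(2 * sum(2 * r + 2 for r in radii))
    for _ in range(_MAX_PLACEMENT_RETRIES):
        canvas_masks: list[np.ndarray] = []
        centres: list[tuple[float, float]] = []
        ok = True
        for i, (_, m) in enumerate(members):
            cm = np.zeros((side, side), bool)
            if i == 0:
                cy, cx = side // 2, side // 2
            else:
                # touch/overlap an already placed member
                j = int(rng.integers(0, i))
                d = (radii[i] + radii[j]) * rng.uniform(0.70, 0.95)
                ang = rng.uniform(0, 2 * np.pi)
                cy = int(round(centres[j][0] + d * np.sin(ang)))
                cx = int(round(centres[j][1] + d * np.cos(ang)))
            top, left = cy - m.shape[0] // 2, cx - m.shape[1] // 2
            if top < 0 or left < 0 or top + m.shape[0] > side or left + m.shape[1] > side:
                ok = False
                break
            cm[_paste_bbox(m, top, left)] = m
            canvas_masks.append(cm)
            centres.append((cy, cx))
        if not ok:
            continue

        union = np.logical_or.reduce(canvas_masks)
        lab8, n8 = ndi.label(union, structure=np.ones((3, 3)))
        if n8 != 1:
            continue
        # nearest-centre assignment of every foreground pixel
        fg = np.argwhere(union)
        cys = np.array([c[0] for c in centres])
        cxs = np.array([c[1] for c in centres])
        d2 = (fg[:, 0:1] - cys) ** 2 + (fg[:, 1:2] - cxs) ** 2
        owner = np.argmin(d2, axis=1)
        # a pixel can only belong to a member whose own mask covers it
        covered = np.stack([cm[fg[:, 0], fg[:, 1]] for cm in canvas_masks], axis=1)
        d2 = np.where(covered, d2, np.inf)
        owner = np.argmin(d2, axis=1)
        labelled = np.zeros((side, side), np.int32)
        labelled[fg[:, 0], fg[:, 1]] = owner + 1
        # every member must survive with an interior core
        sizes = [int((labelled == i + 1).sum()) for i in range(len(members))]
        if min(sizes) < 30:
            continue
        rows = np.any(union, axis=1).nonzero()[0]
        cols = np.any(union, axis=0).nonzero()[0]
        labelled = labelled[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        return np.pad(labelled, 1), [cls for cls, _ in members]
    raise RuntimeError("could not compose a touching cluster after bounded retries")


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Place shapes into a field of view without unplanned contact.

    Singleton objects keep a >=1 px gap from everything else; touching
    clusters are composed first (members overlapping, contested pixels to
    the nearest centre) and then placed as one piece.  Raises if placement
    fails after 100 retries per object, reporting how many were placed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    labels = np.zeros(spec.image_shape, np.int32)
    occupied_dil = np.zeros(spec.image_shape, bool)  # foreground dilated by 1

    # draw the full object pool, then carve cluster members from it
    pool: list[MorphClass] = []
    for cls in (MorphClass.UNSPREAD, MorphClass.PARTIAL, MorphClass.SPREAD):
        pool.extend([cls] * spec.counts.get(cls, 0))
    rng.shuffle(pool)  # type: ignore[arg-type]

    cluster_sizes: list[int] = []
    remaining = len(pool)
    for _ in range(spec.n_touching_clusters):
        size = int(rng.integers(spec.cluster_size_range[0],
                                spec.cluster_size_range[1] + 1))
        if size > remaining:
            raise ValueError(
                f"not enough objects ({remaining} left) for a cluster of {size}"
            )
        cluster_sizes.append(size)
        remaining -= size

    idx = 0
    placements: list[tuple[np.ndarray, list[MorphClass]]] = []
    for size in cluster_sizes:
        members = []
        for _ in range(size):
            cls = pool[idx]
            idx += 1
            members.append((cls, generate_shape(cls, spec.class_params[cls],
                                                rng, spec.pixel_size)))
        placements.append(_compose_cluster(members, rng))
    for cls in pool[idx:]:
        shape = generate_shape(cls, spec.class_params[cls], rng, spec.pixel_size)
        placements.append((shape.astype(np.int32), [cls]))

    truth_classes: dict[int, MorphClass] = {}
    seed_points: list[tuple[int, int]] = []
    next_label = 1
    n_placed = 0
    for piece, classes in placements:
        union = piece > 0
        placed = False
        for _ in range(_MAX_PLACEMENT_RETRIES):
            top = int(rng.integers(0, max(1, spec.image_shape[0] - piece.shape[0] + 1)))
            left = int(rng.integers(0, max(1, spec.image_shape[1] - piece.shape[1] + 1)))
            if not _can_place(occupied_dil, union, top, left):
                continue
            sl = _paste_bbox(piece, top, left)
            local_ids = range(1, len(classes) + 1)
            for lid, cls in zip(local_ids, classes):
                labels[sl][piece == lid] = next_label
                truth_classes[next_label] = cls
                if len(classes) > 1:  # cluster member: record an interior seed
                    member = np.zeros(spec.image_shape, bool)
                    member[sl] = piece == lid
                    dist = ndi.distance_transform_edt(member)
                    r, c = np.unravel_index(int(np.argmax(dist)), dist.shape)
                    seed_points.append((int(r), int(c)))
                next_label += 1
            region = np.zeros(spec.image_shape, bool)
            region[sl] = union
            occupied_dil |= ndi.binary_dilation(region, structure=np.ones((3, 3)))
            placed = True
            n_placed += len(classes)
            break
        if not placed:
            raise RuntimeError(
                f"placement failed after {_MAX_PLACEMENT_RETRIES} retries: "
                f"placed {n_placed} of {spec.n_objects} objects; "
                "reduce counts or enlarge image_shape"
            )

    return SyntheticScene(
        truth_labels=LabeledSegmentation(labels, pixel_size=spec.pixel_size),
        truth_classes=truth_classes,
        truth_seeds=SeedSet(seed_points),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# rendering


def scene_intensity(scene: SyntheticScene, render: RenderSpec) -> np.ndarray:
    """Noise- and blur-free intensity image of a scene."""
    fg = scene.truth_labels.data > 0
    return np.where(fg, render.foreground_intensity,
                    render.background_intensity).astype(np.float64)


def render_stack(scene: SyntheticScene, render: RenderSpec) -> ImageStack:
    """Render a scene as a defocus z-stack with additive Gaussian noise.

    Slice ``i`` is the clean scene image blurred with
    ``base_sigma + blur_sigma_step * |i - focus_index|`` plus noise of the
    configured standard deviation; intensities are clipped at zero.
    """
    rng = np.random.default_rng(render.rng_seed)
    clean = scene_intensity(scene, render)
    slices = []
    for i in range(render.n_slices):
        sigma = render.base_sigma + render.blur_sigma_step * abs(i - render.focus_index)
        img = ndi.gaussian_filter(clean, sigma) if sigma > 0 else clean.copy()
        if render.noise_sd > 0:
            img = img + rng.normal(0.0, render.noise_sd, size=img.shape)
        slices.append(np.clip(img, 0, None))
    return ImageStack(np.stack(slices), pixel_size=scene.spec.pixel_size)


# ---------------------------------------------------------------------------
# direct sampling of labelled morphology records


def sample_platelet_records(
    n_per_class: int,
    rng_seed: int = 0,
    pixel_size: float = 0.1,
    class_params: Mapping[MorphClass, ClassShapeParams] | None = None,
):
    """Generate labelled morphology records without rendering full scenes.

    Draws ``n_per_class`` shapes per morphology class, measures each one in
    isolation, and returns a feature table with a ``true_class`` column of
    integer class codes — the fastest way to produce a large annotated
    training set for the object classifier.
    """
    import pandas as pd

    from .morphology import compute_features

    class_params = class_params or DEFAULT_CLASS_PARAMS
    rng = np.random.default_rng(rng_seed)
    frames = []
    for cls in MorphClass:
        for i in range(n_per_class):
            shape = generate_shape(cls, class_params[cls], rng, pixel_size)
            labels = LabeledSegmentation(shape.astype(np.int32),
                                         pixel_size=pixel_size)
            rec = compute_features(labels, pixel_size,
                                   image_id=f"sample_{cls.name}_{i}")
            rec["true_class"] = int(cls)
            frames.append(rec)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sparse annotations from ground truth


def sample_pixel_annotations(
    scene: SyntheticScene,
    n_signal: int = 500,
    n_background: int = 500,
    rng_seed: int | np.random.Generator = 0,
    image_id: str = "",
):
    """Sample sparse signal/background training pixels from the ground truth.

    Emulates the scribbles a user would paint during interactive learning:
    signal pixels come from the 1-px-eroded true foreground and background
    pixels from outside the 1-px-dilated foreground.  The standoff is
    symmetric about the object boundary — a user's clicks avoid the
    ambiguous edge band equally from both sides — which keeps the learned
    decision boundary centred on the true outline.
    """
    from .pixel_classifier import PixelAnnotation, PixelLabel

    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    fg = scene.truth_labels.data > 0
    core = ndi.binary_erosion(fg, iterations=1)
    if not core.any():
        core = fg
    bg = ~ndi.binary_dilation(fg, iterations=1)

    def _sample(mask: np.ndarray, n: int) -> list[tuple[int, int]]:
        coords = np.argwhere(mask)
        if len(coords) == 0:
            return []
        take = rng.choice(len(coords), size=min(n, len(coords)), replace=False)
        return [tuple(map(int, coords[i])) for i in take]

    return [
        PixelAnnotation(image_id=image_id, coordinates=_sample(core, n_signal),
                        label=PixelLabel.SIGNAL),
        PixelAnnotation(image_id=image_id, coordinates=_sample(bg, n_background),
                        label=PixelLabel.BACKGROUND),
    ]
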