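"""End-to-end orchestration: simulate → project → segment → split →
measure → classify → summarize, driven by a single JSON-serialisable
configuration with reproducible seeds.

Two entry points:

* :func:`simulate_dataset` writes a complete synthetic experiment to disk
  (stacks, truth labels, seed/annotation/class CSVs, manifest) so the file
  pipeline can be exercised exactly as it would be on real data.
* :func:`run_pipeline` consumes such a directory (or any directory with
  the same layout produced from real microscopy) and writes every stage's
  output plus a JSON run log.

True classes for object-classifier training are supplied as an annotation
label image plus a classes CSV; they are transferred onto the pipeline's
own segmentation by majority pixel overlap, which is how a manual
annotation layer is reconciled with an automatic segmentation in
practice.
"""

from __future__ import annotations

import json
import logging
import platform
from itertools import zip_longest
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as psio
from .containers import MorphClass, SeedSet
from .focus import project
from .morphology import compute_features
from .object_classifier import (DEFAULT_ABLATION_ARMS, classify,
                                confusion_matrix, feature_ablation,
                                overall_accuracy, split_train_validation,
                                train_object_classifier)
from .pixel_classifier import (FeatureConfig, ForestParams,
                               predict_probability, probability_to_mask,
                               train_pixel_classifier)
from .separation import seeded_split
from .summary import compare_conditions, summarize
from .synthetic import (DEFAULT_CLASS_PARAMS, ClassShapeParams, RenderSpec,
                        SceneSpec, generate_scene, render_stack,
                        sample_pixel_annotations)

logger = logging.getLogger("plateseg")

__all__ = ["SimulateConfig", "simulate_dataset", "PipelineConfig",
           "run_pipeline"]


# ---------------------------------------------------------------------------
# synthetic experiment writer


@dataclass
class ConditionSpec:
    """One experimental condition in a simulated experiment."""

    name: str
    n_replicates: int = 3
    images_per_replicate: int = 1
    counts: dict = field(default_factory=lambda: {
        "UNSPREAD": 8, "PARTIAL": 8, "SPREAD": 8})
    n_touching_clusters: int = 2
    cluster_size_range: tuple[int, int] = (2, 2)
    radius_scale: float = 1.0  # shrinks/grows every class's radius range


@dataclass
class SimulateConfig:
    """Recipe for a multi-condition, multi-replicate synthetic experiment."""

    conditions: list[ConditionSpec]
    image_shape: tuple[int, int] = (384, 384)
    pixel_size: float = 0.1
    render: RenderSpec = field(default_factory=RenderSpec)
    n_training_images: int = 8
    rng_seed: int = 0

    @staticmethod
    def from_json(path: str | Path) -> "SimulateConfig":
        raw = json.loads(Path(path).read_text())
        conditions = [ConditionSpec(**{**c, "cluster_size_range":
                                       tuple(c.get("cluster_size_range", (2, 2)))})
                      for c in raw.pop("conditions")]
        render = RenderSpec(**raw.pop("render", {}))
        raw["image_shape"] = tuple(raw.get("image_shape", (384, 384)))
        return SimulateConfig(conditions=conditions, render=render, **raw)


def _scaled_params(scale: float) -> dict[MorphClass, ClassShapeParams]:
    if scale == 1.0:
        return dict(DEFAULT_CLASS_PARAMS)
    out = {}
    for cls, p in DEFAULT_CLASS_PARAMS.items():
        lo, hi = p.radius_um
        flo, fhi = p.filopodium_length_um
        out[cls] = ClassShapeParams(
            radius_um=(lo * scale, hi * scale),
            irregularity=p.irregularity,
            n_harmonics=p.n_harmonics,
            n_filopodia=p.n_filopodia,
            filopodium_length_um=(flo * scale, fhi * scale),
            filopodium_width_px=p.filopodium_width_px,
        )
    return out


def simulate_dataset(config: SimulateConfig, out_dir: str | Path) -> Path:
    """Write a ground-truthed synthetic experiment to ``out_dir``.

    Produces per-image ``<id>_stack.tif`` and ``<id>_truth_labels.tif``,
    plus ``manifest.csv``, ``seeds.csv``, ``classes.csv`` (truth classes
    keyed to the truth label image), ``pixel_annotations.csv`` for the
    training images, and a ``simulation.json`` echo of the recipe.
    Training images are taken round-robin across conditions and
    replicates, mirroring the advice to select them across treatments.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    seeds_by_image: dict[str, SeedSet] = {}
    classes_by_image: dict[str, dict[int, MorphClass]] = {}
    image_index = 0
    per_image: list[tuple[str, object]] = []  # (image_id, scene)

    for cond in config.conditions:
        params = _scaled_params(cond.radius_scale)
        for rep in range(1, cond.n_replicates + 1):
            for k in range(cond.images_per_replicate):
                image_id = f"{cond.name}_r{rep}_i{k}"
                scene_seed = (config.rng_seed * 100003 + image_index * 7919) % (2**31)
                spec = SceneSpec(
                    image_shape=config.image_shape,
                    pixel_size=config.pixel_size,
                    counts={MorphClass.from_any(c): n
                            for c, n in cond.counts.items()},
                    n_touching_clusters=cond.n_touching_clusters,
                    cluster_size_range=tuple(cond.cluster_size_range),
                    class_params=params,
                    rng_seed=scene_seed,
                )
                scene = generate_scene(spec)
                render = RenderSpec(**{**config.render.__dict__,
                                       "rng_seed": scene_seed + 1})
                stack = render_stack(scene, render)
                psio.write_stack(out_dir / f"{image_id}_stack.tif", stack)
                psio.write_labels(out_dir / f"{image_id}_truth_labels.tif",
                                  scene.truth_labels)
                seeds_by_image[image_id] = scene.truth_seeds
                classes_by_image[image_id] = dict(scene.truth_classes)
                manifest_rows.append({
                    "image_id": image_id,
                    "stack_path": f"{image_id}_stack.tif",
                    "condition": cond.name,
                    "replicate": rep,
                    "annotation_labels_path": f"{image_id}_truth_labels.tif",
                })
                per_image.append((image_id, scene))
                image_index += 1

    # round-robin training-image selection across conditions
    by_cond: dict[str, list[str]] = {}
    for row, (image_id, _) in zip(manifest_rows, per_image):
        by_cond.setdefault(row["condition"], []).append(image_id)
    interleaved = [i for tup in zip_longest(*by_cond.values())
                   for i in tup if i is not None]
    training_ids = set(interleaved[:config.n_training_images])
    annotations = []
    for idx, (image_id, scene) in enumerate(per_image):
        if image_id in training_ids:
            ann_seed = (config.rng_seed * 99991 + idx * 10007 + 13) % (2**31)
            annotations.extend(sample_pixel_annotations(
                scene, rng_seed=ann_seed, image_id=image_id))

    manifest = pd.DataFrame(manifest_rows)
    manifest["is_training"] = manifest["image_id"].isin(training_ids)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    psio.write_seeds_csv(out_dir / "seeds.csv", seeds_by_image)
    psio.write_classes_csv(out_dir / "classes.csv", classes_by_image)
    psio.write_pixel_annotations_csv(out_dir / "pixel_annotations.csv",
                                     annotations)
    echo = {
        "image_shape": list(config.image_shape),
        "pixel_size": config.pixel_size,
        "rng_seed": config.rng_seed,
        "n_training_images": config.n_training_images,
        "render": {k: v for k, v in config.render.__dict__.items()},
        "conditions": [c.__dict__ for c in config.conditions],
    }
    (out_dir / "simulation.json").write_text(json.dumps(echo, indent=2,
                                                        default=list))
    return out_dir


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass
class PipelineConfig:
    """Everything needed for a full reproducible run."""

    data_dir: str | Path
    out_dir: str | Path
    pixel_size: float = 0.1
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    pixel_forest: ForestParams = field(default_factory=ForestParams)
    object_forest: ForestParams = field(default_factory=ForestParams)
    probability_threshold: float = 0.5
    min_area_px: int = 50
    validation_fraction: float = 0.20
    rng_seed: int = 0
    half_window: int = 2
    run_ablation: bool = True

    @staticmethod
    def from_json(path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "feature_config" in raw:
            fc = raw.pop("feature_config")
            raw["feature_config"] = FeatureConfig(
                scales=tuple(fc.get("scales", FeatureConfig().scales)),
                feature_kinds=tuple(fc.get("feature_kinds",
                                           FeatureConfig().feature_kinds)))
        for key in ("pixel_forest", "object_forest"):
            if key in raw:
                raw[key] = ForestParams(**raw[key])
        return PipelineConfig(**raw)


def _transfer_classes(pipeline_labels, annotation_labels,
                      class_map: dict[int, MorphClass],
                      min_overlap: float = 0.5) -> dict[int, MorphClass]:
    """Map annotated classes onto pipeline labels by majority pixel overlap."""
    out: dict[int, MorphClass] = {}
    pl = pipeline_labels.data
    al = annotation_labels.data
    for lab in range(1, pipeline_labels.n_labels + 1):
        sel = al[pl == lab]
        sel = sel[sel > 0]
        if sel.size == 0:
            continue
        vals, counts = np.unique(sel, return_counts=True)
        best = int(vals[np.argmax(counts)])
        if best in class_map and counts.max() / (pl == lab).sum() >= min_overlap:
            out[lab] = class_map[best]
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full workflow and write every stage's artifacts.

    Stage order: focus projection → pixel-classifier training (on the
    manifest's training images) → probability prediction and binarization
    → seeded watershed splitting → per-platelet morphometry → object
    classification with stratified hold-out validation (confusion matrix,
    accuracy, feature ablation) → per-replicate summaries and
    between-condition statistics.  Any stage failure aborts with the stage
    name and offending image id.
    """
    data_dir = Path(config.data_dir)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = pd.read_csv(data_dir / "manifest.csv", dtype={"image_id": str})
    seeds_by_image = (psio.read_seeds_csv(data_dir / "seeds.csv")
                      if (data_dir / "seeds.csv").exists() else {})
    classes_by_image = (psio.read_classes_csv(data_dir / "classes.csv")
                        if (data_dir / "classes.csv").exists() else {})
    annotations = (psio.read_pixel_annotations_csv(
        data_dir / "pixel_annotations.csv")
        if (data_dir / "pixel_annotations.csv").exists() else [])

    def stage(name: str, image_id: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage {name!r} failed on image {image_id!r}: {exc}"
            ) from exc

    # 1. focus-aware projection
    projected = {}
    for _, row in manifest.iterrows():
        image_id = str(row["image_id"])
        stack = stage("load", image_id, lambda r=row: psio.read_stack(
            data_dir / r["stack_path"], pixel_size=config.pixel_size,
            source_id=str(r["image_id"])))
        projected[image_id] = stage("project", image_id,
                                    lambda s=stack: project(s, config.half_window))
        logger.info("projected %s: focus slice %d", image_id,
                    projected[image_id].focus_index)

    # 2. pixel classifier
    annotated_ids = {a.image_id for a in annotations if a.coordinates}
    training_images = [projected[i] for i in projected if i in annotated_ids]
    if not training_images:
        raise RuntimeError("pipeline stage 'train-pixel': no images with "
                           "pixel annotations found")
    pixel_clf = train_pixel_classifier(
        training_images, [a for a in annotations if a.image_id in projected],
        config.feature_config, config.pixel_forest, rng_seed=config.rng_seed)
    pixel_clf.save(out_dir / "pixel_classifier.joblib")

    # 3–5. segment, split, measure
    all_records = []
    platelet_counts = {}
    for image_id, image in projected.items():
        prob = stage("segment", image_id,
                     lambda im=image: predict_probability(pixel_clf, im))
        mask = probability_to_mask(prob, config.probability_threshold,
                                   config.min_area_px,
                                   pixel_size=config.pixel_size,
                                   source_id=image_id)
        seeds = seeds_by_image.get(image_id, SeedSet([], image_id=image_id))
        on_mask = SeedSet([p for p in seeds if mask.data[p]],
                          image_id=image_id)
        labels = stage("split", image_id,
                       lambda m=mask, s=on_mask: seeded_split(m, s))
        psio.write_labels(out_dir / f"{image_id}_labels.tif", labels)
        records = stage("features", image_id,
                        lambda l=labels: compute_features(
                            l, config.pixel_size, image_id=image_id))
        # attach manual class annotations by majority overlap, if present
        row = manifest.loc[manifest["image_id"] == image_id].iloc[0]
        ann_path = row.get("annotation_labels_path")
        if (isinstance(ann_path, str) and ann_path
                and image_id in classes_by_image
                and bool(row.get("is_training", True))):
            ann_labels = psio.read_labels(data_dir / ann_path,
                                          pixel_size=config.pixel_size)
            mapping = _transfer_classes(labels, ann_labels,
                                        classes_by_image[image_id])
            records["true_class"] = records["label_id"].map(
                {k: int(v) for k, v in mapping.items()})
        else:
            records["true_class"] = np.nan
        all_records.append(records)
        platelet_counts[image_id] = int(len(records))
    records = pd.concat(all_records, ignore_index=True)

    # 6. object classifier with hold-out validation
    labelled = records.dropna(subset=["true_class"]).copy()
    labelled["true_class"] = labelled["true_class"].astype(int)
    if len(labelled) == 0:
        raise RuntimeError("pipeline stage 'train-objects': no objects with "
                           "class annotations")
    train, val = split_train_validation(
        labelled, config.validation_fraction, rng_seed=config.rng_seed)
    obj_clf = train_object_classifier(train, forest_params=config.object_forest,
                                      rng_seed=config.rng_seed)
    obj_clf.save(out_dir / "object_classifier.joblib")
    val_pred = classify(obj_clf, val)
    cm = confusion_matrix(val_pred["true_class"], val_pred["predicted_class"])
    cm.to_frame().to_csv(out_dir / "confusion_matrix.csv")
    accuracy = overall_accuracy(cm)
    if config.run_ablation:
        ablation = feature_ablation(labelled, DEFAULT_ABLATION_ARMS,
                                    config.validation_fraction,
                                    rng_seed=config.rng_seed,
                                    forest_params=config.object_forest)
        ablation.to_csv(out_dir / "ablation.csv", index=False)

    # 7. classify everything and summarize per replicate
    records = classify(obj_clf, records)
    records.to_csv(out_dir / "records.csv", index=False)
    summaries = summarize(records, manifest)
    summaries.to_csv(out_dir / "summary.csv", index=False)

    comparison_rows = []
    n_conditions = manifest["condition"].nunique()
    enough_reps = (manifest.groupby("condition")["replicate"].nunique() >= 2).all()
    if n_conditions >= 2 and enough_reps:
        for metric in ("mean_area_um2", "mean_circularity",
                       "percent_unspread", "percent_partial",
                       "percent_spread"):
            report = compare_conditions(summaries, metric)
            for _, prow in report.pairwise.iterrows():
                comparison_rows.append({"metric": metric,
                                        "anova_p": report.anova_p,
                                        **prow.to_dict()})
    pd.DataFrame(comparison_rows).to_csv(out_dir / "comparisons.csv",
                                         index=False)

    run_log = {
        "rng_seed": config.rng_seed,
        "python": platform.python_version(),
        "n_images": int(len(manifest)),
        "platelets_per_image": platelet_counts,
        "n_annotated_objects": int(len(labelled)),
        "holdout_accuracy": accuracy,
        "probability_threshold": config.probability_threshold,
        "min_area_px": config.min_area_px,
        "validation_fraction": config.validation_fraction,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                     sort_keys=True))
    return out_dir
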