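"""Random-forest classification of platelets into spreading sub-types.

Platelets are grouped into three morphological classes — unspread,
partially spread and fully spread — from per-object shape features (area,
circularity, solidity, axis lengths, ...), not pixel intensities, so the
classifier transfers across stains and imaging modalities.  Manually
chosen thresholds on area or circularity alone are avoided: the forest
combines all features, and :func:`feature_ablation` quantifies how much
accuracy single-feature rules give up.

Validation follows the standard hold-out protocol: a stratified 20% of
the annotated platelets is reserved, never seen during training, and the
classifier is scored on it via a confusion matrix and overall accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .containers import MorphClass
from .morphology import FEATURE_COLUMNS
from .pixel_classifier import ForestParams

__all__ = [
    "TrainedObjectClassifier",
    "ConfusionMatrix",
    "split_train_validation",
    "train_object_classifier",
    "classify",
    "confusion_matrix",
    "overall_accuracy",
    "feature_ablation",
    "DEFAULT_ABLATION_ARMS",
]

#: The four standard ablation arms: each single headline feature, the
#: pair, and the full shape-feature set.
DEFAULT_ABLATION_ARMS: list[tuple[str, ...]] = [
    ("area_um2",),
    ("circularity",),
    ("area_um2", "circularity"),
    tuple(FEATURE_COLUMNS),
]


def _as_codes(values) -> np.ndarray:
    return np.array([int(MorphClass.from_any(v)) for v in values])


def split_train_validation(
    records: pd.DataFrame,
    validation_fraction: float = 0.20,
    rng_seed: int = 0,
    stratified: bool = True,
    class_column: str = "true_class",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition labelled records into disjoint train / validation sets.

    Stratified by class: each class contributes its nearest-integer share
    of the validation set, with any rounding remainder assigned to the
    largest class.  Deterministic for a fixed ``rng_seed``.
    """
    if not 0 < validation_fraction < 1:
        raise ValueError("validation_fraction must lie in (0, 1)")
    if class_column not in records.columns:
        raise ValueError(f"records lack a {class_column!r} column")
    rng = np.random.default_rng(rng_seed)
    y = _as_codes(records[class_column])

    if not stratified:
        n_val = int(np.floor(validation_fraction * len(records) + 0.5))
        order = rng.permutation(len(records))
        val_idx = np.sort(order[:n_val])
        train_idx = np.sort(order[n_val:])
        return records.iloc[train_idx].copy(), records.iloc[val_idx].copy()

    class_counts = {c: int((y == c).sum()) for c in np.unique(y)}
    small = [c for c, n in class_counts.items() if n < 2]
    if small:
        names = [MorphClass(c).name for c in small]
        raise ValueError(f"stratified split needs >= 2 records per class; "
                         f"classes too small: {names}")
    n_val_per = {c: int(np.floor(validation_fraction * n + 0.5))
                 for c, n in class_counts.items()}
    target_total = int(np.floor(validation_fraction * len(records) + 0.5))
    largest = max(class_counts, key=lambda c: (class_counts[c], -c))
    n_val_per[largest] += target_total - sum(n_val_per.values())
    n_val_per[largest] = int(np.clip(n_val_per[largest], 0, class_counts[largest]))

    val_mask = np.zeros(len(records), bool)
    for c, n_val in n_val_per.items():
        idx = np.nonzero(y == c)[0]
        chosen = rng.choice(idx, size=n_val, replace=False)
        val_mask[chosen] = True
    return records.iloc[~val_mask].copy(), records.iloc[val_mask].copy()


@dataclass
class TrainedObjectClassifier:
    """A fitted morphology forest with its feature list and provenance."""

    model: RandomForestClassifier
    feature_names: tuple[str, ...]
    classes: tuple[MorphClass, ...]
    forest_params: ForestParams
    rng_seed: int
    provenance: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, Path(path))

    @staticmethod
    def load(path: str | Path) -> "TrainedObjectClassifier":
        obj = joblib.load(Path(path))
        if not isinstance(obj, TrainedObjectClassifier):
            raise TypeError(f"{path} does not contain a TrainedObjectClassifier")
        return obj


def train_object_classifier(
    train: pd.DataFrame,
    features: tuple[str, ...] | list[str] | None = None,
    forest_params: ForestParams | None = None,
    rng_seed: int = 0,
    class_column: str = "true_class",
) -> TrainedObjectClassifier:
    """Fit a random forest on the selected shape features only."""
    features = tuple(features) if features else tuple(FEATURE_COLUMNS)
    unknown = [f for f in features if f not in train.columns]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown}")
    forest_params = forest_params or ForestParams()
    y = _as_codes(train[class_column])
    if len(np.unique(y)) < 1 or len(train) == 0:
        raise ValueError("training set is empty")
    X = train.loc[:, list(features)].to_numpy(dtype=np.float64)
    model = RandomForestClassifier(
        n_estimators=forest_params.n_trees,
        max_depth=forest_params.max_depth,
        random_state=rng_seed,
        n_jobs=1,
    )
    model.fit(X, y)
    provenance = {
        "n_per_class": {MorphClass(c).name: int((y == c).sum())
                        for c in np.unique(y)},
        "n_train": int(len(train)),
    }
    return TrainedObjectClassifier(
        model=model,
        feature_names=features,
        classes=tuple(MorphClass(c) for c in model.classes_),
        forest_params=forest_params,
        rng_seed=rng_seed,
        provenance=provenance,
    )


def classify(classifier: TrainedObjectClassifier,
             records: pd.DataFrame,
             attach_probabilities: bool = False) -> pd.DataFrame:
    """Predict a morphology class for every record.

    Returns a copy of ``records`` with a ``predicted_class`` column of
    integer class codes (and optionally per-class probability columns).
    """
    out = records.copy()
    if len(records) == 0:
        out["predicted_class"] = pd.Series([], dtype=int)
        return out
    missing = [f for f in classifier.feature_names if f not in records.columns]
    if missing:
        raise ValueError(f"records lack classifier feature column(s): {missing}")
    X = records.loc[:, list(classifier.feature_names)].to_numpy(dtype=np.float64)
    out["predicted_class"] = classifier.model.predict(X).astype(int)
    if attach_probabilities:
        proba = classifier.model.predict_proba(X)
        for j, c in enumerate(classifier.classes):
            out[f"prob_{c.name.lower()}"] = proba[:, j]
    return out


@dataclass
class ConfusionMatrix:
    """True-class x predicted-class count table (rows = true)."""

    classes: tuple[MorphClass, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        names = [c.name for c in self.classes]
        return pd.DataFrame(self.counts, index=pd.Index(names, name="true"),
                            columns=pd.Index(names, name="predicted"))


def confusion_matrix(true_classes, predicted_classes,
                     classes: tuple[MorphClass, ...] | None = None
                     ) -> ConfusionMatrix:
    """Count agreement and disagreement between annotation and prediction."""
    t = _as_codes(true_classes)
    p = _as_codes(predicted_classes)
    if len(t) != len(p):
        raise ValueError(f"length mismatch: {len(t)} true vs {len(p)} predicted")
    classes = classes or tuple(MorphClass)
    index = {int(c): i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of on-diagonal (correctly classified) objects."""
    total = int(cm.counts.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / total)


def feature_ablation(
    records: pd.DataFrame,
    subsets: list[tuple[str, ...]] | None = None,
    validation_fraction: float = 0.20,
    rng_seed: int = 0,
    forest_params: ForestParams | None = None,
    class_column: str = "true_class",
) -> pd.DataFrame:
    """Hold-out accuracy for several feature subsets on one shared split.

    All arms are trained on the same stratified train split and scored on
    the same validation split so that differences isolate the feature
    effect.  Defaults to the four standard arms: area only, circularity
    only, both, and all shape features.
    """
    subsets = subsets if subsets is not None else list(DEFAULT_ABLATION_ARMS)
    train, val = split_train_validation(
        records, validation_fraction=validation_fraction,
        rng_seed=rng_seed, class_column=class_column)
    rows = []
    for subset in subsets:
        clf = train_object_classifier(train, features=subset,
                                      forest_params=forest_params,
                                      rng_seed=rng_seed,
                                      class_column=class_column)
        pred = classify(clf, val)
        cm = confusion_matrix(pred[class_column], pred["predicted_class"])
        rows.append({
            "features": "+".join(subset),
            "n_features": len(subset),
            "accuracy": overall_accuracy(cm),
        })
    return pd.DataFrame(rows)
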