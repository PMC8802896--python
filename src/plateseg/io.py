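"""File-format glue: TIFF images, CSV tables, model files.

All images travel as TIFF (stacks as multi-page, labels as 16-bit,
masks as 8-bit 0/255, probability maps as 32-bit float) via tifffile;
all tables are UTF-8 CSV with a header row.  Seed and annotation CSVs use
0-based (row, col) pixel coordinates.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import (BinaryMask, ImageStack, LabeledSegmentation,
                         MorphClass, SeedSet)
from .pixel_classifier import PixelAnnotation, PixelLabel

__all__ = [
    "read_stack", "write_stack",
    "read_labels", "write_labels",
    "read_mask", "write_mask",
    "write_probability",
    "read_seeds_csv", "write_seeds_csv",
    "read_classes_csv", "write_classes_csv",
    "read_pixel_annotations_csv", "write_pixel_annotations_csv",
]


def read_stack(path: str | Path, pixel_size: float | None = None,
               source_id: str | None = None) -> ImageStack:
    data = tifffile.imread(str(path))
    return ImageStack(np.asarray(data),
                      pixel_size=pixel_size,
                      source_id=source_id if source_id is not None
                      else Path(path).stem)


def write_stack(path: str | Path, stack: ImageStack) -> None:
    tifffile.imwrite(str(path), stack.data.astype(np.float32),
                     photometric="minisblack")


def read_labels(path: str | Path, pixel_size: float | None = None,
                source_id: str = "") -> LabeledSegmentation:
    data = tifffile.imread(str(path))
    return LabeledSegmentation(data.astype(np.int32), pixel_size=pixel_size,
                               source_id=source_id)


def write_labels(path: str | Path, labels: LabeledSegmentation) -> None:
    if labels.n_labels > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit TIFF")
    tifffile.imwrite(str(path), labels.data.astype(np.uint16))


def read_mask(path: str | Path, pixel_size: float | None = None,
              source_id: str = "") -> BinaryMask:
    data = tifffile.imread(str(path))
    return BinaryMask(data > 0, pixel_size=pixel_size, source_id=source_id)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    tifffile.imwrite(str(path), (mask.data.astype(np.uint8) * 255))


def write_probability(path: str | Path, prob: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(prob, dtype=np.float32))


# -- seeds ------------------------------------------------------------------

def write_seeds_csv(path: str | Path,
                    seeds_by_image: dict[str, SeedSet]) -> None:
    rows = [{"image_id": image_id, "row": r, "col": c}
            for image_id, seeds in seeds_by_image.items()
            for r, c in seeds]
    pd.DataFrame(rows, columns=["image_id", "row", "col"]).to_csv(
        path, index=False)


def read_seeds_csv(path: str | Path) -> dict[str, SeedSet]:
    df = pd.read_csv(path, dtype={"image_id": str})
    out: dict[str, SeedSet] = {}
    for image_id, grp in df.groupby("image_id", sort=False):
        out[str(image_id)] = SeedSet(
            points=list(zip(grp["row"].astype(int), grp["col"].astype(int))),
            image_id=str(image_id))
    return out


# -- per-object class annotations ------------------------------------------

def write_classes_csv(path: str | Path,
                      classes_by_image: dict[str, dict[int, MorphClass]]) -> None:
    rows = [{"image_id": image_id, "label_id": lab, "class": cls.name}
            for image_id, mapping in classes_by_image.items()
            for lab, cls in mapping.items()]
    pd.DataFrame(rows, columns=["image_id", "label_id", "class"]).to_csv(
        path, index=False)


def read_classes_csv(path: str | Path) -> dict[str, dict[int, MorphClass]]:
    df = pd.read_csv(path, dtype={"image_id": str})
    out: dict[str, dict[int, MorphClass]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["image_id"]), {})[int(row["label_id"])] = \
            MorphClass.from_any(row["class"])
    return out


# -- sparse pixel annotations ----------------------------------------------

def write_pixel_annotations_csv(path: str | Path,
                                annotations: list[PixelAnnotation]) -> None:
    rows = [{"image_id": ann.image_id, "row": r, "col": c,
             "label": ann.label.name}
            for ann in annotations for r, c in ann.coordinates]
    pd.DataFrame(rows, columns=["image_id", "row", "col", "label"]).to_csv(
        path, index=False)


def read_pixel_annotations_csv(path: str | Path) -> list[PixelAnnotation]:
    df = pd.read_csv(path, dtype={"image_id": str})
    out: list[PixelAnnotation] = []
    for (image_id, label), grp in df.groupby(["image_id", "label"], sort=False):
        out.append(PixelAnnotation(
            image_id=str(image_id),
            coordinates=list(zip(grp["row"].astype(int),
                                 grp["col"].astype(int))),
            label=PixelLabel[str(label).upper()]))
    return out
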