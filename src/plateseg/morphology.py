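"""Per-platelet morphological measurements from a labelled segmentation.

One record (DataFrame row) is produced per label.  Area is pixel count
scaled by the squared pixel size; the perimeter is the total length of the
sub-pixel marching-squares contour of the object (including hole
contours), which keeps the circularity of digitized disks near 1 and of
digitized squares near the continuous pi/4 — plain boundary-pixel counting
biases both.  Circularity is the standard 4*pi*A/P**2, clamped to 1
because digitization can push near-circular blobs slightly above.

Objects touching the image border are flagged (``touches_border``) so that
truncated platelets can be excluded from summaries.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from skimage import measure as skmeasure

from .containers import LabeledSegmentation

__all__ = ["compute_features", "circularity", "contour_perimeter",
           "FEATURE_COLUMNS"]

#: Shape features used for object classification (intensity-free, so the
#: classifier is independent of the staining protocol).
FEATURE_COLUMNS = [
    "area_um2",
    "perimeter_um",
    "circularity",
    "convex_area_um2",
    "solidity",
    "eccentricity",
    "major_axis_um",
    "minor_axis_um",
    "extent",
    "aspect_ratio",
]


def circularity(area: float, perimeter: float) -> float:
    """Circularity 4*pi*A/P**2, clamped to <= 1.

    1 for a perfect circle, approaching 0 for elongated or spiky shapes.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def contour_perimeter(mask: np.ndarray) -> float:
    """Sub-pixel perimeter: total marching-squares contour length at 0.5."""
    padded = np.pad(np.asarray(mask, dtype=float), 1)
    total = 0.0
    for contour in skmeasure.find_contours(padded, 0.5):
        diffs = np.diff(contour, axis=0)
        total += float(np.hypot(diffs[:, 0], diffs[:, 1]).sum())
    return total


def compute_features(labels: LabeledSegmentation,
                     pixel_size: float | None = None,
                     image_id: str | None = None) -> pd.DataFrame:
    """Measure every labelled platelet; returns one row per label.

    ``pixel_size`` (µm/px) defaults to the segmentation's own; lengths are
    reported in µm and areas in µm² alongside raw pixel counts.  An empty
    labelling yields an empty frame with the full column set.
    """
    px = pixel_size if pixel_size is not None else labels.pixel_size
    if px is None or px <= 0:
        raise ValueError("a positive pixel_size (µm/px) is required")
    image_id = image_id if image_id is not None else labels.source_id

    columns = (["image_id", "label_id", "area_px"] + FEATURE_COLUMNS
               + ["centroid_row", "centroid_col", "touches_border"])
    rows_out = []
    nrows, ncols = labels.shape
    for prop in skmeasure.regionprops(labels.data):
        rmin, cmin, rmax, cmax = prop.bbox
        perim_px = contour_perimeter(prop.image)
        area_px = int(prop.area)
        minor_px = float(prop.axis_minor_length)
        major_px = float(prop.axis_major_length)
        # floor the minor axis at one pixel so thin objects keep a finite
        # aspect ratio
        aspect = major_px / max(minor_px, 1.0)
        rows_out.append({
            "image_id": image_id,
            "label_id": int(prop.label),
            "area_px": area_px,
            "area_um2": area_px * px**2,
            "perimeter_um": perim_px * px,
            "circularity": circularity(area_px, perim_px),
            "convex_area_um2": int(prop.area_convex) * px**2,
            "solidity": float(prop.solidity),
            "eccentricity": float(prop.eccentricity),
            "major_axis_um": major_px * px,
            "minor_axis_um": minor_px * px,
            "extent": float(prop.extent),
            "aspect_ratio": aspect,
            "centroid_row": float(prop.centroid[0]),
            "centroid_col": float(prop.centroid[1]),
            "touches_border": bool(rmin == 0 or cmin == 0
                                   or rmax == nrows or cmax == ncols),
        })
    if not rows_out:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows_out, columns=columns)
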