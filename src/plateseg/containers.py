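"""Core in-memory containers shared across the pipeline stages.

All image-like containers wrap a numpy array together with the physical
pixel size (micrometres per pixel) and a free-form provenance string
(``source_id``) so that every per-platelet measurement can be traced back
to the field of view it came from.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MorphClass",
    "ImageStack",
    "ProjectedImage",
    "BinaryMask",
    "LabeledSegmentation",
    "SeedSet",
]


class MorphClass(enum.IntEnum):
    """Platelet spreading morphology sub-type.

    ``UNSPREAD`` cells are small and near-circular, ``PARTIAL`` cells have
    extended filopodia, and ``SPREAD`` cells have formed large lamellipodia.
    Integer codes are stable (0/1/2) and used for serialization.
    """

    UNSPREAD = 0
    PARTIAL = 1
    SPREAD = 2

    @classmethod
    def from_any(cls, value: "MorphClass | int | str") -> "MorphClass":
        """Coerce an int code, name string or MorphClass into a MorphClass."""
        if isinstance(value, cls):
            return value
        if isinstance(value, (int, np.integer)):
            return cls(int(value))
        if isinstance(value, str):
            return cls[value.strip().upper()]
        raise TypeError(f"cannot interpret {value!r} as a MorphClass")


@dataclass
class ImageStack:
    """A 3D grayscale volume (z, row, col), e.g. a fluorescence z-stack."""

    data: np.ndarray
    pixel_size: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:  # single-plane acquisitions are allowed
            self.data = self.data[np.newaxis]
        if self.data.ndim != 3:
            raise ValueError(f"stack must be 2D or 3D, got ndim={self.data.ndim}")
        if self.data.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


@dataclass
class ProjectedImage:
    """A 2D image produced by focus-aware maximal projection of a stack."""

    data: np.ndarray
    focus_index: int = 0
    window: tuple[int, int] = (0, 0)  # inclusive slice-index interval used
    pixel_size: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("projected image must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """Foreground/background mask of platelet pixels."""

    data: np.ndarray
    pixel_size: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class LabeledSegmentation:
    """Per-platelet integer labeling; 0 is background, labels run 1..n_labels."""

    data: np.ndarray
    pixel_size: float | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("labeling must be 2D")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = self.data.astype(np.int32, copy=False)
        present = np.unique(self.data)
        present = present[present > 0]
        n = int(present.max()) if present.size else 0
        if present.size != n:
            raise ValueError("labels must be consecutive 1..n_labels")

    @property
    def n_labels(self) -> int:
        m = int(self.data.max()) if self.data.size else 0
        return m

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class SeedSet:
    """User-clicked centre points of touching platelets (0-based row, col)."""

    points: list[tuple[int, int]] = field(default_factory=list)
    image_id: str = ""

    def __post_init__(self) -> None:
        self.points = [(int(r), int(c)) for r, c in self.points]

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def check_bounds(self, shape: Sequence[int]) -> None:
        rows, cols = shape[0], shape[1]
        bad = [p for p in self.points if not (0 <= p[0] < rows and 0 <= p[1] < cols)]
        if bad:
            raise ValueError(f"seed points outside image bounds {rows}x{cols}: {bad}")
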