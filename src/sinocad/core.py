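"""Shared data containers for the detection pipeline.

Coordinate conventions used throughout the package: volumes are indexed
``(z, y, x)``, 0-based, with half-open bounding boxes; masks live on the
same grid as the volume they annotate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CTVolume:
    """A 3-D intensity grid in HU-like units with voxel spacing in mm."""

    intensities: np.ndarray          # (nz, ny, nx) float
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError("volume must be 3-D (z, y, x)")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class ROIPatch:
    """A centered, mask-isolated, square candidate patch.

    ``pixels`` is the patch intensity grid (background outside the candidate
    set to zero); ``roi_id`` identifies the source candidate so that every
    representation of one ROI (image, sinogram, channel stack) can be kept
    on the same side of a train/test split.
    """

    pixels: np.ndarray
    roi_id: str
    label: int | None = None          # 1 = nodule, 0 = non-nodule
    normalized: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("ROI patch must be a square 2-D grid")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class CandidateRecord:
    """One initial nodule candidate: mask, bounding box, patch and score."""

    mask: np.ndarray                  # boolean, same grid as the volume
    bounding_box: tuple[int, int, int, int, int, int]   # z0,z1,y0,y1,x0,x1 half-open
    patch: ROIPatch
    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


def minmax_normalize(a: np.ndarray) -> np.ndarray:
    """Per-array min-max scaling to [0, 1]; constant arrays map to zeros."""
    a = np.asarray(a, dtype=np.float64)
    lo, hi = a.min(), a.max()
    if hi - lo <= 0:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)
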