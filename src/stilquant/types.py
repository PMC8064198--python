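"""Shared domain types and semantic class codes.

Pixel coordinates are row-major, 0-based ``(row, col)`` throughout; every
mask shares the frame of its companion tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

# Semantic classes produced by segment annotation (estimated maps).
NUCLEUS = 0
CYTOPLASM = 1
STROMA = 2
OTHER = 3

SEMANTIC_NAMES = {NUCLEUS: "nucleus", CYTOPLASM: "cytoplasm", STROMA: "stroma", OTHER: "other"}

# Ground-truth classes used by the tile simulator (finer: the two nucleus
# kinds are distinguished so detection can be scored against truth).
GT_TUMOR_NUCLEUS = 0
GT_LYMPH_NUCLEUS = 1
GT_CYTOPLASM = 2
GT_STROMA = 3
GT_BACKGROUND = 4

GT_NAMES = {
    GT_TUMOR_NUCLEUS: "tumor_nucleus",
    GT_LYMPH_NUCLEUS: "lymphocyte_nucleus",
    GT_CYTOPLASM: "cytoplasm",
    GT_STROMA: "stroma",
    GT_BACKGROUND: "background",
}


@dataclass
class RGBTile:
    """An 8-bit RGB image tile.

    Parameters
    ----------
    pixels : (H, W, 3) uint8 array
        Intensities in [0, 255].
    pixel_size_um : float, optional
        Micrometers per pixel, if known.
    """

    pixels: np.ndarray
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"tile must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"tile must be at least 32 x 32, got {px.shape[:2]}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabelMask:
    """An integer label image plus a code -> class-name legend."""

    labels: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"labels contain codes missing from legend: {sorted(missing)}")


@dataclass
class SemanticMap:
    """Per-pixel semantic class labels for one tile.

    ``labels`` takes values in {NUCLEUS, CYTOPLASM, STROMA, OTHER};
    ``provenance`` records the quantization-class -> semantic-class mapping
    that produced it.
    """

    labels: np.ndarray
    provenance: dict[int, int] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape
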