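"""Stromal TIL scoring: tumor-region identification, stromal restriction,
and the sTIL percentage.

sTIL is the ratio of the stromal-lymphocyte area to the total stromal
area, restricted to the tumor regions. A lymphocyte is stromal when the
substrate under its nucleus centroid is stroma: the substrate map fills
every cell-class pixel (nucleus, cytoplasm) with the nearest non-cell
semantic class, so "the stroma the cell sits on" is well defined. The
denominator counts stroma-class pixels inside the tumor region plus the
pixels occupied by stromal lymphocytes there (lymphocyte-covered stroma
belongs to both the numerator and the denominator), which bounds the
percentage by 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from .nuclei import Lymphocyte, NucleusObject
from .simtiles import disc_close, disc_dilate
from .types import CYTOPLASM, NUCLEUS, STROMA, SemanticMap


class EmptyDenominatorError(ValueError):
    """No stroma inside the tumor region: the tile cannot be scored and is
    flagged for exclusion (like a low-quality slide)."""


@dataclass
class STILResult:
    """The sTIL score of one tile (or one patient after aggregation)."""

    tile_id: str
    stromal_til_area: int
    stroma_area: int
    stil_percent: float
    tumor_region_source: str  # provided | derived | ground_truth
    n_lymphocytes: int = 0
    n_stromal_lymphocytes: int = 0


@dataclass
class TumorRegionParams:
    density_radius: float = 35.0  # disc radius around non-lymphocyte nuclei
    closing_radius: float = 60.0


def identify_tumor_regions(
    semantic: SemanticMap,
    other_nuclei: Sequence[NucleusObject],
    params: Optional[TumorRegionParams] = None,
    provided_mask: Optional[np.ndarray] = None,
    source: str = "derived",
) -> tuple[np.ndarray, str]:
    """Tumor-region mask: the provided mask when given, else a density
    heuristic (union of discs at non-lymphocyte nucleus centroids, closed
    and hole-filled)."""
    if provided_mask is not None:
        return provided_mask.astype(bool), source if source != "derived" else "provided"
    params = params or TumorRegionParams()
    seeds = np.zeros(semantic.shape, dtype=bool)
    for n in other_nuclei:
        r, c = int(round(n.centroid[0])), int(round(n.centroid[1]))
        seeds[r, c] = True
    if not seeds.any():
        return np.zeros(semantic.shape, dtype=bool), "derived"
    mask = disc_dilate(seeds, params.density_radius)
    mask = disc_close(mask, params.closing_radius)
    return ndi.binary_fill_holes(mask), "derived"


def substrate_map(semantic: SemanticMap) -> np.ndarray:
    """Semantic map with every cell-class pixel replaced by the nearest
    non-cell class (stroma/other), via the Euclidean distance transform."""
    labels = semantic.labels
    cellish = (labels == NUCLEUS) | (labels == CYTOPLASM)
    if not cellish.any():
        return labels.copy()
    if cellish.all():
        raise EmptyDenominatorError("no non-cell pixels to define a substrate")
    _, (ir, ic) = ndi.distance_transform_edt(cellish, return_indices=True)
    return labels[ir, ic]


def compute_stil(
    lymphocytes: Sequence[Lymphocyte],
    semantic: SemanticMap,
    tumor_mask: np.ndarray,
    cell_label_img: np.ndarray,
    label_img: np.ndarray,
    tile_id: str = "tile",
    tumor_region_source: str = "derived",
) -> STILResult:
    """Score one tile.

    A lymphocyte is stromal iff its nucleus centroid falls on a stromal
    substrate pixel inside the tumor mask; its whole pixel set (nucleus +
    cytoplasm), clipped to the mask, enters the numerator and the
    denominator.
    """
    tumor_mask = tumor_mask.astype(bool)
    if not tumor_mask.any():
        raise EmptyDenominatorError(f"{tile_id}: empty tumor region")
    stroma_px = int(((semantic.labels == STROMA) & tumor_mask).sum())
    sub = substrate_map(semantic)
    in_mask_counts = np.bincount(
        cell_label_img[tumor_mask].ravel(), minlength=int(cell_label_img.max()) + 1
    )
    numerator = 0
    n_stromal = 0
    for ly in lymphocytes:
        r, c = (int(round(x)) for x in ly.nucleus.centroid)
        if not (tumor_mask[r, c] and sub[r, c] == STROMA):
            continue
        n_stromal += 1
        numerator += int(in_mask_counts[ly.nucleus.index])
    denominator = stroma_px + numerator
    if denominator == 0:
        raise EmptyDenominatorError(f"{tile_id}: no stroma inside the tumor region")
    return STILResult(
        tile_id=tile_id,
        stromal_til_area=numerator,
        stroma_area=denominator,
        stil_percent=100.0 * numerator / denominator,
        tumor_region_source=tumor_region_source,
        n_lymphocytes=len(lymphocytes),
        n_stromal_lymphocytes=n_stromal,
    )


def aggregate_patient_stil(results: Sequence[STILResult], patient_id: str = "patient") -> STILResult:
    """Area-weighted pooled ratio over a patient's valid tiles."""
    valid = [r for r in results if r.stroma_area > 0]
    if not valid:
        raise EmptyDenominatorError(f"{patient_id}: no valid tiles")
    num = sum(r.stromal_til_area for r in valid)
    den = sum(r.stroma_area for r in valid)
    return STILResult(
        tile_id=patient_id,
        stromal_til_area=num,
        stroma_area=den,
        stil_percent=100.0 * num / den,
        tumor_region_source=valid[0].tumor_region_source,
        n_lymphocytes=sum(r.n_lymphocytes for r in valid),
        n_stromal_lymphocytes=sum(r.n_stromal_lymphocytes for r in valid),
    )
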