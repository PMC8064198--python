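"""Nucleus segmentation and the five lymphocyte-identification features.

From the semantic map's nucleus class, connected components become
candidate nuclei; each carries the five features used to recognize
lymphocyte nuclei among all detected nuclei:

i.   relative size — nucleus area over the median nuclear area on the tile;
ii.  roundness — the 4*pi*A/P^2 circularity (1 for a perfect disc);
iii. eccentricity — sqrt(1 - l2/l1) from the central second moments;
iv.  nucleus-to-cell size ratio — nucleus area over the cell area obtained
     by growing the nucleus through adjacent cytoplasm-class pixels;
v.   staining variation — the standard deviation of luminance
     (0.299 R + 0.587 G + 0.114 B) over the nucleus pixels.

A nucleus is called a lymphocyte when all five criteria hold; the
combination is conjunctive and every cut-off is configurable. Digital
discs can have circularity slightly above 1, hence the tolerance in the
roundness invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .types import CYTOPLASM, NUCLEUS, RGBTile, SemanticMap

LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class NucleusObject:
    """One connected nuclear region with its morphometric features."""

    index: int
    area: int
    perimeter: float
    centroid: tuple[float, float]
    roundness: float
    eccentricity: float
    staining_sd: float
    relative_size: float = float("nan")
    cell_area: int = 0
    nucleus_to_cell_ratio: float = float("nan")
    bbox: tuple[int, int, int, int] = (0, 0, 0, 0)


@dataclass
class LymphocyteThresholds:
    """Conjunctive cut-offs for lymphocyte-nucleus identification.

    A nucleus is a lymphocyte iff relative_size <= max_relative_size,
    roundness >= min_roundness, eccentricity <= max_eccentricity,
    nucleus_to_cell_ratio >= min_nucleus_cell_ratio and
    staining_sd <= max_staining_sd.
    """

    max_relative_size: float = 2.0
    min_roundness: float = 0.8
    max_eccentricity: float = 0.8
    min_nucleus_cell_ratio: float = 0.5
    max_staining_sd: float = 20.0


@dataclass
class Lymphocyte:
    """A lymphocyte assembled from its nucleus and attributed cytoplasm."""

    nucleus: NucleusObject
    cytoplasm_pixels: tuple[np.ndarray, np.ndarray]

    @property
    def total_area(self) -> int:
        return self.nucleus.area + len(self.cytoplasm_pixels[0])


def extract_nuclei(
    semantic: SemanticMap,
    tile: Optional[RGBTile] = None,
    min_area: int = 15,
    connectivity: int = 2,
) -> tuple[list[NucleusObject], np.ndarray]:
    """Connected components of the nucleus class, with features.

    Components below ``min_area`` are discarded. Returns the nuclei (with
    shape/stain features and relative size filled) and the label image
    (0 = background, k = nucleus index k).
    """
    nucleus_mask = semantic.labels == NUCLEUS
    lab = cc_label(nucleus_mask, connectivity=connectivity)
    luma = None
    if tile is not None:
        luma = tile.pixels.astype(float) @ LUMA
    nuclei: list[NucleusObject] = []
    keep_map = np.zeros(lab.max() + 1, dtype=np.int32)
    for prop in regionprops(lab):
        if prop.area < min_area:
            continue
        perim = prop.perimeter
        roundness = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        if luma is not None:
            vals = luma[tuple(prop.coords.T)]
            staining_sd = float(vals.std())
        else:
            staining_sd = 0.0
        nuclei.append(
            NucleusObject(
                index=len(nuclei) + 1,
                area=int(prop.area),
                perimeter=float(perim),
                centroid=tuple(prop.centroid),
                roundness=float(roundness),
                eccentricity=float(prop.eccentricity),
                staining_sd=staining_sd,
                bbox=tuple(prop.bbox),
            )
        )
        keep_map[prop.label] = len(nuclei)
    label_img = keep_map[lab]
    if nuclei:
        med = float(np.median([n.area for n in nuclei]))
        for n in nuclei:
            n.relative_size = n.area / med
    # re-sort by centroid (row, col) so downstream claim order is spatial
    order = np.argsort([n.centroid[0] * semantic.shape[1] + n.centroid[1] for n in nuclei])
    remap = np.zeros(len(nuclei) + 1, dtype=np.int32)
    sorted_nuclei = []
    for new_idx, old_pos in enumerate(order, start=1):
        n = nuclei[old_pos]
        remap[n.index] = new_idx
        n.index = new_idx
        sorted_nuclei.append(n)
    return sorted_nuclei, remap[label_img]


def compute_shape_features(nucleus: NucleusObject, tile: RGBTile, label_img: np.ndarray) -> NucleusObject:
    """Recompute the stain feature for one nucleus from the tile (shape
    features are filled during extraction)."""
    coords = np.nonzero(label_img == nucleus.index)
    if len(coords[0]) < 2:
        raise ValueError("degenerate nucleus below the size filter")
    luma = tile.pixels[coords].astype(float) @ LUMA
    nucleus.staining_sd = float(luma.std())
    return nucleus


def attribute_cells(
    nuclei: list[NucleusObject],
    semantic: SemanticMap,
    label_img: np.ndarray,
    max_dilation: int = 3,
) -> np.ndarray:
    """Grow every nucleus through adjacent cytoplasm-class pixels.

    Simultaneous unit dilations (8-connectivity), ``max_dilation`` rounds;
    growth is confined to cytoplasm-class pixels and stops at other
    classes and at pixels already claimed by another cell. Conflicts in
    one round go to the lower nucleus index (nuclei are indexed in
    centroid order). Returns the cell label image and fills ``cell_area``
    and ``nucleus_to_cell_ratio``.
    """
    if max_dilation < 0:
        raise ValueError("max_dilation must be >= 0")
    cells = label_img.astype(np.int32).copy()
    growable = semantic.labels == CYTOPLASM
    n = len(nuclei)
    footprint = np.ones((3, 3), dtype=bool)
    for _ in range(max_dilation):
        # min-label dilation: invert so grey_dilation's max picks the lowest index
        inv = np.where(cells > 0, n + 1 - cells, 0)
        grown = ndi.grey_dilation(inv, footprint=footprint)
        candidates = (cells == 0) & growable & (grown > 0)
        if not candidates.any():
            break
        cells[candidates] = n + 1 - grown[candidates]
    counts = np.bincount(cells.ravel(), minlength=n + 1)
    for nucleus in nuclei:
        nucleus.cell_area = int(counts[nucleus.index])
        nucleus.nucleus_to_cell_ratio = nucleus.area / nucleus.cell_area
    return cells


def classify_lymphocytes(
    nuclei: list[NucleusObject],
    thresholds: Optional[LymphocyteThresholds] = None,
) -> tuple[list[NucleusObject], list[NucleusObject]]:
    """Split nuclei into (lymphocyte, other) by the five conjunctive criteria."""
    if not nuclei:
        raise ValueError("at least one nucleus is required (median size undefined)")
    t = thresholds or LymphocyteThresholds()
    lymph, other = [], []
    for n in nuclei:
        is_lymph = (
            n.relative_size <= t.max_relative_size
            and n.roundness >= t.min_roundness
            and n.eccentricity <= t.max_eccentricity
            and n.nucleus_to_cell_ratio >= t.min_nucleus_cell_ratio
            and n.staining_sd <= t.max_staining_sd
        )
        (lymph if is_lymph else other).append(n)
    return lymph, other


def assemble_lymphocytes(
    lymph_nuclei: list[NucleusObject],
    cell_label_img: np.ndarray,
    label_img: np.ndarray,
) -> list[Lymphocyte]:
    """Build Lymphocyte objects from nuclei and their attributed cytoplasm."""
    out = []
    for n in lymph_nuclei:
        cyto = np.nonzero((cell_label_img == n.index) & (label_img != n.index))
        out.append(Lymphocyte(nucleus=n, cytoplasm_pixels=cyto))
    return out
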