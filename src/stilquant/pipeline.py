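"""End-to-end tile scoring: quantization -> lymphocyte detection -> sTIL."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .nuclei import (
    Lymphocyte,
    LymphocyteThresholds,
    NucleusObject,
    assemble_lymphocytes,
    attribute_cells,
    classify_lymphocytes,
    extract_nuclei,
)
from .quantize import QuantizationConfig, annotate_segments, quantize, select_num_classes
from .scoring import STILResult, TumorRegionParams, compute_stil, identify_tumor_regions
from .types import RGBTile, SemanticMap


@dataclass
class PipelineConfig:
    quantization: QuantizationConfig = field(default_factory=QuantizationConfig)
    lymphocyte_thresholds: LymphocyteThresholds = field(default_factory=LymphocyteThresholds)
    tumor_region: TumorRegionParams = field(default_factory=TumorRegionParams)
    min_nucleus_area: int = 15
    connectivity: int = 2
    max_dilation: int = 3


@dataclass
class TileScore:
    """Everything the pipeline derived for one tile."""

    result: STILResult
    K: int
    semantic: SemanticMap
    nuclei: list[NucleusObject]
    lymphocytes: list[Lymphocyte]
    tumor_mask: np.ndarray


def score_tile(
    tile: RGBTile,
    tumor_mask: Optional[np.ndarray] = None,
    tumor_mask_source: str = "provided",
    config: Optional[PipelineConfig] = None,
    seed: int = 0,
    tile_id: str = "tile",
) -> TileScore:
    """Run the full three-step algorithm on one tile.

    When ``tumor_mask`` is given (an expert or ground-truth annotation) it
    takes precedence over the density-derived region and its source is
    recorded in the result.
    """
    config = config or PipelineConfig()
    K, scheme = select_num_classes(tile, seed=seed, config=config.quantization)
    labels = quantize(tile, scheme)
    semantic = annotate_segments(labels, scheme, config.quantization.semantic_prototypes)
    nuclei, label_img = extract_nuclei(
        semantic, tile, min_area=config.min_nucleus_area, connectivity=config.connectivity
    )
    if nuclei:
        cell_label_img = attribute_cells(nuclei, semantic, label_img, config.max_dilation)
        lymph_nuclei, other_nuclei = classify_lymphocytes(nuclei, config.lymphocyte_thresholds)
        lymphocytes = assemble_lymphocytes(lymph_nuclei, cell_label_img, label_img)
    else:
        cell_label_img = label_img
        other_nuclei = []
        lymphocytes = []
    mask, source = identify_tumor_regions(
        semantic,
        other_nuclei,
        params=config.tumor_region,
        provided_mask=tumor_mask,
        source=tumor_mask_source,
    )
    result = compute_stil(
        lymphocytes,
        semantic,
        mask,
        cell_label_img,
        label_img,
        tile_id=tile_id,
        tumor_region_source=source,
    )
    return TileScore(
        result=result,
        K=K,
        semantic=semantic,
        nuclei=nuclei,
        lymphocytes=lymphocytes,
        tumor_mask=mask,
    )
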