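#!/usr/bin/env python
"""Render a small panel of synthetic H&E-like tiles with ground truth.

Writes tile PNGs, semantic/tumor-region mask PNGs and a truth JSON per
replicate under results/tiles/. These tiles stand in for the study's
H&E slides, which are not deposited; their true sTIL spans the range the
scoring pipeline must handle.
"""
import argparse
import json
from pathlib import Path

import numpy as np

from stilquant.io import write_mask, write_tile
from stilquant.simtiles import TileSimConfig, render_tile
from stilquant.types import GT_NAMES, LabelMask

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=Path, default=Path("results/tiles"))
parser.add_argument("--n-tiles", type=int, default=8)
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

targets = np.linspace(5, 60, args.n_tiles)
seeds = np.random.default_rng(args.seed).integers(0, 2**31 - 1, size=args.n_tiles)
for i, (target, seed) in enumerate(zip(targets, seeds)):
    tile, gt = render_tile(TileSimConfig(target_stil_percent=float(target)), seed=int(seed))
    stem = args.out / f"tile{i:02d}"
    write_tile(stem.with_suffix(".png"), tile)
    write_mask(Path(f"{stem}_semantic.png"), LabelMask(gt.semantic, GT_NAMES))
    write_mask(
        Path(f"{stem}_tumor_region.png"),
        LabelMask(gt.tumor_region.astype(np.uint8), {0: "outside", 1: "tumor_region"}),
    )
    truth = {
        "seed": int(seed),
        "target_stil_percent": float(target),
        "true_stil_percent": gt.true_stil_percent,
        "n_lymphocytes": gt.n_lymphocytes,
        "n_lymphocytes_in_region": gt.n_lymphocytes_in_region,
        "n_tumor_nuclei": gt.n_tumor_nuclei,
    }
    Path(f"{stem}_truth.json").write_text(json.dumps(truth, indent=1))
    print(f"tile{i:02d}: true sTIL {gt.true_stil_percent:5.1f}%  "
          f"({gt.n_lymphocytes} lymphocytes, {gt.n_tumor_nuclei} tumor nuclei)")
print(f"wrote {args.n_tiles} tiles under {args.out}")
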