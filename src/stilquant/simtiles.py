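"""Synthetic H&E-like tile generator with ground-truth masks.

Tiles emulate the qualitative contrasts the scoring pipeline relies on:
tumor nests (cytoplasm-colored blobs) containing large, elongated,
variably stained tumor nuclei; stroma between and around the nests; small,
round, darkly and evenly stained lymphocyte nuclei wrapped in a thin
cytoplasm rim, sitting on the stroma; and near-white background patches.
The tumor region is the union of dilated nests, so stroma exists both
inside and outside it and the "limited to the tumor region" restriction is
actually exercised.

The color model is per-pixel RGB = class prototype + independent Gaussian
channel noise, clipped to [0, 255]: each class has a unimodal, GMM-
recoverable signature in every channel. Prototypes are chosen so that the
three channel levels of one tissue class lie closer to each other than to
any other class's levels, which makes the class structure recoverable by
per-channel mixture decomposition.

``true_stil_percent`` follows the same counting convention as the scoring
module: lymphocyte pixels lying on stromal substrate inside the tumor
region count in the numerator and the denominator; the denominator is the
stromal substrate (visible stroma plus lymphocyte-covered stroma) inside
the tumor region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import convex_hull_image

from .types import (
    GT_BACKGROUND,
    GT_CYTOPLASM,
    GT_LYMPH_NUCLEUS,
    GT_STROMA,
    GT_TUMOR_NUCLEUS,
    RGBTile,
)

# Default stain prototypes (mean RGB). Channel levels within one class are
# deliberately closer to each other than to any other class's levels.
DEFAULT_COLORS: dict[str, tuple[int, int, int]] = {
    "nucleus": (60, 48, 78),  # dark blue-purple hematoxylin
    "cytoplasm": (128, 112, 138),  # light purple
    "stroma": (205, 172, 188),  # eosin pink
    "background": (250, 247, 252),  # near-white
}


class PlacementError(RuntimeError):
    """Requested object density could not be placed without overlap."""

    def __init__(self, kind: str, requested: float, achieved: float):
        self.kind = kind
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place requested {kind} (requested {requested:.3g}, achieved {achieved:.3g})"
        )


@dataclass
class TileSimConfig:
    """Parameters of one synthetic tile.

    Densities are per 10^4 pixels of the relevant substrate (nest pixels
    for tumor nuclei, stromal pixels for lymphocytes).
    ``target_stil_percent``, when set, overrides ``lymphocyte_density``
    inside the tumor region: lymphocytes are added until they cover that
    percentage of the in-region stromal substrate.
    """

    height: int = 512
    width: int = 512
    tumor_nest_count: int = 6
    nest_radius: tuple[float, float] = (30.0, 45.0)
    nest_layout: str = "ring"  # "ring": nests around the tile center, or "random"
    tumor_region_dilation: int = 8
    tumor_region_closing: int = 60
    tumor_nucleus_density: float = 10.0
    lymphocyte_density: float = 8.0
    outside_lymphocyte_density: float = 2.0
    target_stil_percent: Optional[float] = None
    lymph_radius: tuple[float, float] = (3.5, 5.0)
    tumor_nucleus_minor: tuple[float, float] = (5.0, 7.0)
    tumor_nucleus_axis_ratio: tuple[float, float] = (1.8, 2.4)
    n_background_blobs: int = 3
    background_blob_radius: tuple[float, float] = (18.0, 36.0)
    colors: dict[str, tuple[int, int, int]] = field(default_factory=lambda: dict(DEFAULT_COLORS))
    noise_sd: float = 7.0
    tumor_nucleus_noise_sd: float = 15.0
    lymphocyte_noise_sd: float = 4.0
    full_tile_tumor_region: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("tile must be at least 32 x 32")
        for name, lo_hi in (
            ("nest_radius", self.nest_radius),
            ("lymph_radius", self.lymph_radius),
            ("tumor_nucleus_minor", self.tumor_nucleus_minor),
            ("tumor_nucleus_axis_ratio", self.tumor_nucleus_axis_ratio),
        ):
            if not (0 < lo_hi[0] <= lo_hi[1]):
                raise ValueError(f"{name} must be a positive (lo, hi) range, got {lo_hi}")
        if min(self.tumor_nucleus_density, self.lymphocyte_density, self.outside_lymphocyte_density) < 0:
            raise ValueError("densities must be >= 0")
        # size separation between lymphocyte nuclei and tumor nuclei is real
        if self.lymph_radius[1] >= self.tumor_nucleus_minor[0] * self.tumor_nucleus_axis_ratio[0]:
            raise ValueError("lymphocyte max radius must be below tumor nucleus min major semi-axis")
        names = list(self.colors)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                gap = max(abs(x - y) for x, y in zip(self.colors[a], self.colors[b]))
                if gap < 20:
                    raise ValueError(f"color prototypes {a!r} and {b!r} differ by < 20 in every channel")


@dataclass
class GroundTruth:
    """Per-pixel truth for one synthetic tile."""

    semantic: np.ndarray  # H x W codes in GT_* (partition of all pixels)
    tumor_region: np.ndarray  # bool
    stroma_substrate: np.ndarray  # bool: stromal substrate incl. under lymphocytes
    lymphocyte_mask: np.ndarray  # bool: union of lymphocyte nucleus + rim pixels
    true_stil_percent: float
    n_tumor_nuclei: int = 0
    n_lymphocytes: int = 0
    n_lymphocytes_in_region: int = 0
    lymph_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    lymph_radii: np.ndarray = field(default_factory=lambda: np.empty(0))
    tumor_nucleus_centers: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def recompute_stil(self) -> float:
        """Recount ``true_stil_percent`` from the emitted masks."""
        denom = int((self.stroma_substrate & self.tumor_region).sum())
        if denom == 0:
            return float("nan")
        num = int((self.lymphocyte_mask & self.stroma_substrate & self.tumor_region).sum())
        return 100.0 * num / denom


def disc_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """Binary dilation by a Euclidean disc, via the distance transform
    (O(HW) regardless of radius)."""
    if not mask.any():
        return mask.copy()
    return ndi.distance_transform_edt(~mask) <= radius


def disc_close(mask: np.ndarray, radius: float) -> np.ndarray:
    """Binary closing by a Euclidean disc via two distance transforms."""
    grown = disc_dilate(mask, radius)
    if not (~grown).any():
        return grown
    return ndi.distance_transform_edt(grown) > radius


def _disc_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dr * dr + dc * dc <= radius * radius
    return np.stack([dr[keep], dc[keep]], axis=1)


def _ellipse_offsets(minor: float, major: float, theta: float) -> np.ndarray:
    r = int(np.ceil(major))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    c, s = np.cos(theta), np.sin(theta)
    u = c * dc + s * dr  # along major axis
    v = -s * dc + c * dr
    keep = (u / major) ** 2 + (v / minor) ** 2 <= 1.0
    return np.stack([dr[keep], dc[keep]], axis=1)


def _paint(mask_or_img: np.ndarray, center: tuple[int, int], offsets: np.ndarray, value) -> None:
    rr = offsets[:, 0] + center[0]
    cc = offsets[:, 1] + center[1]
    keep = (rr >= 0) & (rr < mask_or_img.shape[0]) & (cc >= 0) & (cc < mask_or_img.shape[1])
    mask_or_img[rr[keep], cc[keep]] = value


def _fits(allowed: np.ndarray, center: tuple[int, int], offsets: np.ndarray) -> bool:
    rr = offsets[:, 0] + center[0]
    cc = offsets[:, 1] + center[1]
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= allowed.shape[0] or cc.max() >= allowed.shape[1]:
        return False
    return bool(allowed[rr, cc].all())


def _hex_sites(shape: tuple[int, int], spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Hexagonal lattice sites covering the tile, with random offset/rotation."""
    h, w = shape
    diag = int(np.hypot(h, w)) + int(2 * spacing)
    rows = np.arange(-diag, diag, spacing * np.sqrt(3) / 2)
    pts = []
    for i, r in enumerate(rows):
        offset = (spacing / 2) if i % 2 else 0.0
        cols = np.arange(-diag, diag, spacing) + offset
        pts.append(np.stack([np.full_like(cols, r), cols], axis=1))
    pts = np.concatenate(pts)
    theta = rng.uniform(0, np.pi / 3)
    c, s = np.cos(theta), np.sin(theta)
    rot = pts @ np.array([[c, -s], [s, c]])
    rot += rng.uniform(0, spacing, size=2) + np.array([h / 2, w / 2])
    sites = np.round(rot).astype(int)
    keep = (sites[:, 0] >= 0) & (sites[:, 0] < h) & (sites[:, 1] >= 0) & (sites[:, 1] < w)
    sites = sites[keep]
    return sites[rng.permutation(len(sites))]


def _place_lymphocyte(
    semantic: np.ndarray,
    lymph_mask: np.ndarray,
    free: np.ndarray,
    stroma_static: np.ndarray,
    center: tuple[int, int],
    radius: float,
    rim: float = 1.0,
    clip_rim: bool = False,
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Try to place one lymphocyte (nucleus disc + thin cytoplasm rim).

    ``free`` marks stromal pixels not yet claimed by any cell. The nucleus
    plus a 1 px clearance ring must sit on stromal substrate
    (``stroma_static``) so nuclei never abut other tissue directly. With
    ``clip_rim`` the rim is painted only on still-free stromal pixels
    (first-claim semantics in dense infiltrates); otherwise the whole cell
    footprint plus clearance must fit.
    Returns the painted cell pixel coordinates, or None if it did not fit.
    """
    cell = _disc_offsets(radius + rim)
    nucleus = _disc_offsets(radius)
    if clip_rim:
        if not (_fits(free, center, nucleus) and _fits(stroma_static, center, _disc_offsets(radius + 1.0))):
            return None
        rr = cell[:, 0] + center[0]
        cc = cell[:, 1] + center[1]
        ok = (rr >= 0) & (rr < free.shape[0]) & (cc >= 0) & (cc < free.shape[1])
        rr, cc = rr[ok], cc[ok]
        claim = free[rr, cc]
        rr, cc = rr[claim], cc[claim]
    else:
        if not (_fits(free, center, cell) and _fits(stroma_static, center, _disc_offsets(radius + rim + 1.0))):
            return None
        rr = cell[:, 0] + center[0]
        cc = cell[:, 1] + center[1]
    semantic[rr, cc] = GT_CYTOPLASM
    _paint(semantic, center, nucleus, GT_LYMPH_NUCLEUS)
    lymph_mask[rr, cc] = True
    free[rr, cc] = False
    return rr, cc


def render_tile(config: TileSimConfig, seed: Optional[int] = None) -> tuple[RGBTile, GroundTruth]:
    """Render one tile and its ground truth. Deterministic given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.height, config.width
    semantic = np.full((h, w), GT_STROMA, dtype=np.int8)

    # --- tumor nests and tumor region -------------------------------------
    nest_mask = np.zeros((h, w), dtype=bool)
    if config.nest_layout == "ring" and config.tumor_nest_count > 0:
        # nests around the tile center: the enclosed stromal lake gives the
        # tumor region a wide interior stroma compartment
        ring_r = 0.35 * min(h, w)
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(config.tumor_nest_count):
            r = rng.uniform(*config.nest_radius)
            ang = phase + 2 * np.pi * i / config.tumor_nest_count + rng.uniform(-0.15, 0.15)
            cr = int(h / 2 + ring_r * np.sin(ang) * rng.uniform(0.9, 1.1))
            cc = int(w / 2 + ring_r * np.cos(ang) * rng.uniform(0.9, 1.1))
            _paint(nest_mask, (cr, cc), _disc_offsets(r), True)
    else:
        for _ in range(config.tumor_nest_count):
            r = rng.uniform(*config.nest_radius)
            cr = int(rng.uniform(r * 0.5, h - r * 0.5))
            cc = int(rng.uniform(r * 0.5, w - r * 0.5))
            _paint(nest_mask, (cr, cc), _disc_offsets(r), True)
    semantic[nest_mask] = GT_CYTOPLASM
    if config.full_tile_tumor_region:
        tumor_region = np.ones((h, w), dtype=bool)
    elif nest_mask.any():
        if config.nest_layout == "ring":
            # the hull of the nest ring always encloses the stromal lake
            tumor_region = disc_dilate(convex_hull_image(nest_mask), config.tumor_region_dilation)
        else:
            tumor_region = disc_dilate(nest_mask, config.tumor_region_dilation)
            tumor_region = disc_close(tumor_region, config.tumor_region_closing)
            tumor_region = ndi.binary_fill_holes(tumor_region)
    else:
        tumor_region = np.zeros((h, w), dtype=bool)

    # --- background patches on out-of-region stroma -----------------------
    outside = ~tumor_region & ~nest_mask
    for _ in range(config.n_background_blobs):
        if not outside.any():
            break
        for _try in range(50):
            cr, cc = int(rng.integers(h)), int(rng.integers(w))
            if outside[cr, cc]:
                offs = _disc_offsets(rng.uniform(*config.background_blob_radius))
                rr = np.clip(offs[:, 0] + cr, 0, h - 1)
                ccs = np.clip(offs[:, 1] + cc, 0, w - 1)
                ok = outside[rr, ccs]
                semantic[rr[ok], ccs[ok]] = GT_BACKGROUND
                break

    stroma_substrate = semantic == GT_STROMA  # frozen before any cell placement

    # --- tumor nuclei inside nests ----------------------------------------
    nest_area = int(nest_mask.sum())
    n_tumor = int(round(config.tumor_nucleus_density * nest_area / 1e4))
    nest_free = nest_mask.copy()  # nest pixels not yet claimed by a nucleus (+1 px gap)
    tumor_centers: list[tuple[int, int]] = []
    fails = 0
    while len(tumor_centers) < n_tumor and fails < 300 * max(n_tumor, 1):
        cr, cc = int(rng.integers(h)), int(rng.integers(w))
        if not nest_mask[cr, cc]:
            fails += 1
            continue
        minor = rng.uniform(*config.tumor_nucleus_minor)
        major = minor * rng.uniform(*config.tumor_nucleus_axis_ratio)
        theta = rng.uniform(0, np.pi)
        body = _ellipse_offsets(minor, major, theta)
        guard = _ellipse_offsets(minor + 1.5, major + 1.5, theta)
        if _fits(nest_free, (cr, cc), guard):
            _paint(semantic, (cr, cc), body, GT_TUMOR_NUCLEUS)
            _paint(nest_free, (cr, cc), guard, False)
            tumor_centers.append((cr, cc))
        else:
            fails += 1
    if n_tumor and len(tumor_centers) < 0.8 * n_tumor:
        raise PlacementError("tumor nuclei", n_tumor, len(tumor_centers))

    # --- lymphocytes --------------------------------------------------------
    lymph_mask = np.zeros((h, w), dtype=bool)
    free = stroma_substrate.copy()
    lymph_centers: list[tuple[int, int]] = []
    lymph_radii: list[float] = []

    in_region_stroma = stroma_substrate & tumor_region
    denom = int(in_region_stroma.sum())

    def place_random(target_count: int, where: np.ndarray) -> int:
        placed = 0
        fails = 0
        while placed < target_count and fails < 300 * max(target_count, 1):
            cr, cc = int(rng.integers(h)), int(rng.integers(w))
            if not where[cr, cc]:
                fails += 1
                continue
            r = rng.uniform(*config.lymph_radius)
            if _place_lymphocyte(semantic, lymph_mask, free, stroma_substrate, (cr, cc), r) is not None:
                lymph_centers.append((cr, cc))
                lymph_radii.append(r)
                placed += 1
            else:
                fails += 1
        return placed

    if config.target_stil_percent is not None and denom > 0:
        target_px = config.target_stil_percent / 100.0 * denom
        mean_cell = np.pi * (np.mean(config.lymph_radius) + 1.0) ** 2
        frac = target_px / denom
        covered = 0
        if frac <= 0.30:
            # sequential random placement is feasible at low coverage
            fails = 0
            while covered < target_px and fails < 20000:
                cr, cc = int(rng.integers(h)), int(rng.integers(w))
                if not in_region_stroma[cr, cc]:
                    fails += 1
                    continue
                r = rng.uniform(*config.lymph_radius)
                painted = _place_lymphocyte(semantic, lymph_mask, free, stroma_substrate, (cr, cc), r)
                if painted is not None:
                    lymph_centers.append((cr, cc))
                    lymph_radii.append(r)
                    covered += int(in_region_stroma[painted].sum())
                else:
                    fails += 1
        else:
            # dense clusters: same-size lymphocytes on a hexagonal lattice,
            # rims clipped first-claim where neighbors touch, so coverages
            # beyond the random-sequential jamming limit are reachable
            r = 4.5
            spacing = 2.0 * (r + 1.5) + 0.5
            for cr, cc in _hex_sites((h, w), spacing, rng):
                if covered >= target_px:
                    break
                if not in_region_stroma[cr, cc]:
                    continue
                painted = _place_lymphocyte(
                    semantic, lymph_mask, free, stroma_substrate, (cr, cc), r, rim=1.5, clip_rim=True
                )
                if painted is not None:
                    lymph_centers.append((cr, cc))
                    lymph_radii.append(r)
                    covered += int(in_region_stroma[painted].sum())
            # random top-up into lattice gaps and boundary bands
            fails = 0
            while covered < target_px and fails < 20000:
                cr, cc = int(rng.integers(h)), int(rng.integers(w))
                if not in_region_stroma[cr, cc]:
                    fails += 1
                    continue
                rr = rng.uniform(*config.lymph_radius)
                painted = _place_lymphocyte(
                    semantic, lymph_mask, free, stroma_substrate, (cr, cc), rr, rim=1.5, clip_rim=True
                )
                if painted is not None:
                    lymph_centers.append((cr, cc))
                    lymph_radii.append(rr)
                    covered += int(in_region_stroma[painted].sum())
                else:
                    fails += 1
        achieved = 100.0 * covered / denom
        if achieved < config.target_stil_percent - max(2.0, 100.0 * mean_cell / denom):
            raise PlacementError("target sTIL percent", config.target_stil_percent, achieved)
    elif config.lymphocyte_density > 0 and denom > 0:
        want = int(round(config.lymphocyte_density * denom / 1e4))
        got = place_random(want, in_region_stroma)
        if want and got < 0.8 * want:
            raise PlacementError("lymphocytes", want, got)
    n_in_region = len(lymph_centers)

    out_stroma = stroma_substrate & ~tumor_region
    if config.outside_lymphocyte_density > 0 and out_stroma.sum() > 0:
        want_out = int(round(config.outside_lymphocyte_density * out_stroma.sum() / 1e4))
        place_random(want_out, out_stroma)

    # --- render RGB ---------------------------------------------------------
    pixels = np.empty((h, w, 3), dtype=np.float64)
    class_color = {
        GT_TUMOR_NUCLEUS: ("nucleus", config.tumor_nucleus_noise_sd),
        GT_LYMPH_NUCLEUS: ("nucleus", config.lymphocyte_noise_sd),
        GT_CYTOPLASM: ("cytoplasm", config.noise_sd),
        GT_STROMA: ("stroma", config.noise_sd),
        GT_BACKGROUND: ("background", config.noise_sd),
    }
    for code, (proto, sd) in class_color.items():
        sel = semantic == code
        n = int(sel.sum())
        if n == 0:
            continue
        pixels[sel] = np.asarray(config.colors[proto], dtype=float) + rng.normal(0.0, sd, size=(n, 3))
    tile = RGBTile(pixels=np.clip(pixels, 0, 255).astype(np.uint8))

    num = int((lymph_mask & stroma_substrate & tumor_region).sum())
    true_stil = 100.0 * num / denom if denom > 0 else float("nan")
    gt = GroundTruth(
        semantic=semantic,
        tumor_region=tumor_region,
        stroma_substrate=stroma_substrate,
        lymphocyte_mask=lymph_mask,
        true_stil_percent=true_stil,
        n_tumor_nuclei=len(tumor_centers),
        n_lymphocytes=len(lymph_centers),
        n_lymphocytes_in_region=n_in_region,
        lymph_centers=np.asarray(lymph_centers, dtype=int).reshape(-1, 2),
        lymph_radii=np.asarray(lymph_radii),
        tumor_nucleus_centers=np.asarray(tumor_centers, dtype=int).reshape(-1, 2),
    )
    return tile, gt
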