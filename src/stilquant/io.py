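"""Readers/writers for tiles, masks and cohort tables, plus the cohort
exclusion accounting.

Images are 8-bit RGB PNG or TIFF; label masks are single-channel PNG with a
JSON sidecar legend. Cohort tables are delimited text with a declared
schema; validation never silently imputes — offending rows are either
rejected with their row numbers or raise, depending on ``strict``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .types import LabelMask, RGBTile


class FormatError(ValueError):
    """Raised for unreadable or out-of-contract image files."""


class SchemaError(ValueError):
    """Raised when a mandatory cohort column is absent."""


class CohortValidationError(ValueError):
    """Raised (strict mode) when cohort rows fail validation."""

    def __init__(self, problems: list[tuple[int, str]]):
        self.problems = problems
        lines = "; ".join(f"row {r}: {msg}" for r, msg in problems[:10])
        super().__init__(f"{len(problems)} invalid row(s): {lines}")


# ---------------------------------------------------------------------------
# images


def read_tile(path: str | Path) -> RGBTile:
    """Read an 8-bit RGB PNG/TIFF tile; non-conforming files raise FormatError."""
    path = Path(path)
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                if im.mode != "RGB":
                    raise FormatError(f"{path.name}: expected RGB image, got mode {im.mode!r}")
                arr = np.asarray(im)
    except FormatError:
        raise
    except Exception as exc:  # unreadable file
        raise FormatError(f"{path.name}: unreadable image ({exc})") from exc
    arr = np.asarray(arr)
    if arr.dtype != np.uint8:
        raise FormatError(
            f"{path.name}: expected 8-bit samples, got {arr.dtype.itemsize * 8}-bit ({arr.dtype})"
        )
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path.name}: expected RGB (H x W x 3), got shape {arr.shape}")
    return RGBTile(pixels=arr)


def write_tile(path: str | Path, tile: RGBTile) -> None:
    """Write a tile losslessly (PNG or TIFF by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, tile.pixels)
    else:
        Image.fromarray(tile.pixels, mode="RGB").save(path)


def _legend_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".legend.json")


def write_mask(path: str | Path, mask: LabelMask) -> None:
    """Write a label mask as single-channel PNG + JSON sidecar legend."""
    path = Path(path)
    labels = mask.labels
    if labels.max(initial=0) > 255 or labels.min(initial=0) < 0:
        raise ValueError("label codes must fit in uint8 for PNG storage")
    Image.fromarray(labels.astype(np.uint8), mode="L").save(path)
    with open(_legend_path(path), "w") as fh:
        json.dump({str(k): v for k, v in mask.legend.items()}, fh, indent=1)


def read_mask(path: str | Path) -> LabelMask:
    path = Path(path)
    with Image.open(path) as im:
        if im.mode != "L":
            raise FormatError(f"{path.name}: expected single-channel mask, got mode {im.mode!r}")
        labels = np.asarray(im).astype(np.int64)
    with open(_legend_path(path)) as fh:
        legend = {int(k): v for k, v in json.load(fh).items()}
    return LabelMask(labels=labels, legend=legend)


# ---------------------------------------------------------------------------
# cohort tables


@dataclass
class CohortSchema:
    """Declared layout of a cohort table.

    ``snp_alleles`` maps each genotype column to its (A, B) allele pair;
    genotype cells must read "X/Y" with both alleles drawn from that pair.
    Missing values are a single sentinel: empty field or "NA".
    """

    snp_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)
    required: Sequence[str] = (
        "id",
        "age",
        "sex",
        "bmi",
        "treatment",
        "grade",
        "tea",
        "stil",
        "dfs_time",
        "dfs_event",
    )
    categorical: dict[str, Sequence[str]] = field(default_factory=dict)

    MISSING = ("", "NA")


@dataclass
class CohortTable:
    """Patients x {covariates, genotypes, DFS time/event} plus a rejection report."""

    data: pd.DataFrame
    schema: CohortSchema
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)


def _validate_row(row: pd.Series, schema: CohortSchema) -> Optional[str]:
    for col in ("stil", "dfs_time", "age"):
        if col in row and not pd.isna(row[col]):
            try:
                float(row[col])
            except (TypeError, ValueError):
                return f"unparseable {col}: {row[col]!r}"
    if not pd.isna(row.get("dfs_time")) and float(row["dfs_time"]) < 0:
        return f"dfs_time must be >= 0, got {row['dfs_time']}"
    ev = row.get("dfs_event")
    if pd.isna(ev):
        return "missing dfs_event"
    try:
        ev = int(ev)
    except (TypeError, ValueError):
        return f"unparseable dfs_event: {ev!r}"
    if ev not in (0, 1):
        return f"dfs_event must be 0/1, got {ev}"
    if not pd.isna(row.get("stil")) and not (0.0 <= float(row["stil"]) <= 100.0):
        return f"stil must lie in [0,100], got {row['stil']}"
    for snp, alleles in schema.snp_alleles.items():
        g = row.get(snp)
        if pd.isna(g):
            continue
        parts = str(g).split("/")
        if len(parts) != 2 or not all(p in alleles for p in parts):
            return f"genotype {g!r} for {snp} not drawn from alleles {alleles}"
    return None


def read_cohort(path: str | Path, schema: CohortSchema, strict: bool = True) -> CohortTable:
    """Read and validate a delimited cohort table.

    Missing mandatory columns raise :class:`SchemaError`. Rows failing
    validation raise :class:`CohortValidationError` when ``strict`` is true,
    otherwise they are dropped and reported in ``CohortTable.rejected``
    (1-based data row numbers).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, na_values=list(CohortSchema.MISSING), keep_default_na=False)
    missing_cols = [c for c in list(schema.required) + list(schema.snp_alleles) if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory column(s): {missing_cols}")
    problems: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        msg = _validate_row(row, schema)
        if msg is not None:
            problems.append((i + 1, msg))
            keep[i] = False
    if problems and strict:
        raise CohortValidationError(problems)
    out = df.loc[keep].reset_index(drop=True)
    out["dfs_event"] = out["dfs_event"].astype(int)
    return CohortTable(data=out, schema=schema, rejected=problems)


def write_cohort(path: str | Path, table: CohortTable | pd.DataFrame) -> None:
    df = table.data if isinstance(table, CohortTable) else table
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# exclusion accounting


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """Percentage of ``total`` rounded to ``ndigits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


@dataclass
class ExclusionReport:
    n_total: int
    n_lost_to_followup: int
    n_low_image_quality: int
    n_excluded: int
    retained: int
    pct_lost_to_followup: float
    pct_low_image_quality: float


def apply_exclusions(
    ledger: pd.DataFrame | None = None,
    *,
    n_total: int | None = None,
    n_lost: int | None = None,
    n_low_quality: int | None = None,
) -> ExclusionReport:
    """Account for cohort exclusions (lost to follow-up, low image quality).

    Accepts either a per-patient ledger with boolean columns
    ``lost_to_followup``/``low_image_quality`` or the three counts directly
    (flags assumed disjoint; a patient carrying both flags counts once).
    """
    if ledger is not None:
        lost = ledger["lost_to_followup"].astype(bool)
        lowq = ledger["low_image_quality"].astype(bool)
        n_total = len(ledger)
        n_lost = int(lost.sum())
        n_low_quality = int((lowq & ~lost).sum())
    if n_total is None or n_lost is None:
        raise ValueError("either a ledger or explicit counts are required")
    n_low_quality = n_low_quality or 0
    if min(n_total, n_lost, n_low_quality) < 0:
        raise ValueError("counts must be non-negative")
    excluded = n_lost + n_low_quality
    if excluded > n_total:
        raise ValueError("exclusions exceed cohort size")
    return ExclusionReport(
        n_total=n_total,
        n_lost_to_followup=n_lost,
        n_low_image_quality=n_low_quality,
        n_excluded=excluded,
        retained=n_total - excluded,
        pct_lost_to_followup=percent(n_lost, n_total),
        pct_low_image_quality=percent(n_low_quality, n_total),
    )
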