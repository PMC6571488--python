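"""Marker identification from parental allele counts, and bulk allele frequencies.

A genetic marker is a site where the two (haploid, hence effectively
homozygous) parental lines carry different near-fixed alleles.  A site
qualifies when

* each parent has total read depth >= ``min_depth`` (default 5x),
* each parent's major allele is supported by >= ``purity`` of its reads
  (default 0.9, tolerating sequencing error while excluding ambiguous
  sites), and
* the two parental major alleles differ.

The depth threshold is applied to each parent separately.  Alleles are
strings, so indel alleles are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MapFormatError, ValidationError
from .io_map import FIXED_COLUMNS, MarkerTable, count_columns

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 5
DEFAULT_PURITY = 0.9


@dataclass
class ParentalSiteCounts:
    """Per-site allele read counts for the two parental lines."""

    chrom: str
    pos: int
    allele_counts_p1: dict[str, int]
    allele_counts_p2: dict[str, int]


def _major(counts: dict[str, int]) -> tuple[str | None, int, int]:
    """(major allele, its count, total depth); ties broken lexicographically."""
    depth = sum(counts.values())
    if depth == 0:
        return None, 0, 0
    allele = min(counts, key=lambda a: (-counts[a], a))
    return allele, counts[allele], depth


def call_markers(
    sites: list[ParentalSiteCounts],
    min_depth: int = DEFAULT_MIN_DEPTH,
    purity: float = DEFAULT_PURITY,
) -> list[tuple[str, int, str, str]]:
    """Return (chrom, pos, allele_p1, allele_p2) for every qualifying site,
    sorted by (chrom, pos) with chromosomes in first-seen input order."""
    if min_depth < 1:
        raise ValidationError("min_depth must be >= 1")
    if not 0.5 < purity <= 1.0:
        raise ValidationError("purity must be in (0.5, 1]")
    out = []
    for s in sites:
        if any(c < 0 for c in s.allele_counts_p1.values()) or any(
            c < 0 for c in s.allele_counts_p2.values()
        ):
            raise ValidationError(f"negative allele count at {s.chrom}:{s.pos}")
        a1, c1, d1 = _major(s.allele_counts_p1)
        a2, c2, d2 = _major(s.allele_counts_p2)
        if d1 < min_depth or d2 < min_depth:
            continue
        if c1 < purity * d1 or c2 < purity * d2:
            continue
        if a1 == a2:
            continue
        out.append((s.chrom, s.pos, a1, a2))
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(s.chrom for s in sites))}
    out.sort(key=lambda m: (chrom_order[m[0]], m[1]))
    return out


def read_parental_counts(path: str | Path) -> list[ParentalSiteCounts]:
    """Load long-format parental counts: TSV ``chrom pos allele count parent``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "allele": str})
    required = {"chrom", "pos", "allele", "count", "parent"}
    if set(df.columns) != required:
        raise MapFormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}"
        )
    if not set(df["parent"]).issubset({"P1", "P2"}):
        raise MapFormatError(f"{path}: parent column must be P1 or P2")
    sites: dict[tuple[str, int], ParentalSiteCounts] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos))
        site = sites.setdefault(
            key, ParentalSiteCounts(row.chrom, int(row.pos), {}, {})
        )
        target = site.allele_counts_p1 if row.parent == "P1" else site.allele_counts_p2
        target[row.allele] = target.get(row.allele, 0) + int(row.count)
    return list(sites.values())


def pool_replicates(table: MarkerTable) -> MarkerTable:
    """Sum replicate counts element-wise into a single-replicate table."""
    if table.n_replicates == 1:
        return MarkerTable(table.data.copy(), table.bulks, 1)
    df = table.data[list(FIXED_COLUMNS)].copy()
    for b in table.bulks:
        for suffix in ("p1", "p2"):
            cols = [f"{b}{r}_{suffix}" for r in range(1, table.n_replicates + 1)]
            df[f"{b}1_{suffix}"] = table.data[cols].sum(axis=1)
    df = df[list(FIXED_COLUMNS) + count_columns(table.bulks, 1)]
    return MarkerTable(df, table.bulks, 1)


def allele_frequencies(table: MarkerTable) -> pd.DataFrame:
    """Per-marker P1-allele frequency and pooled depth per bulk.

    Requires a pooled (single replicate per bulk) table; frequencies are
    NaN where the bulk has zero depth at the marker.
    """
    if table.n_replicates != 1:
        raise ValidationError("pool replicates before computing allele frequencies")
    out = table.data[["chrom", "pos"]].copy()
    for b in table.bulks:
        p1 = table.data[f"{b}1_p1"].to_numpy(dtype=float)
        p2 = table.data[f"{b}1_p2"].to_numpy(dtype=float)
        depth = p1 + p2
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(depth > 0, p1 / depth, np.nan)
        out[f"f_{b}"] = f
        out[f"depth_{b}"] = depth.astype(int)
    n_missing = int(out[[f"f_{b}" for b in table.bulks]].isna().any(axis=1).sum())
    if n_missing:
        log.info("%d markers have zero depth in at least one bulk", n_missing)
    return out
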