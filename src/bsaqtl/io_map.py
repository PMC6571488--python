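"""Reading and writing the tabular inputs of a bulk-segregant QTL scan.

The central exchange format is the *map file*: a TSV with one row per
genetic marker carrying the two parental alleles and per-bulk, per-replicate
read counts supporting each allele.  The dialect used here (the "bsaqtl map
dialect") is::

    chrom  pos  allele_p1  allele_p2  H1_p1  H1_p2  [H2_p1 H2_p2 ...] [L1_p1 L1_p2 ...]

i.e. four fixed columns followed, for each bulk ``b`` in ``H`` (high) and
optionally ``L`` (low) and each replicate ``r`` in ``1..R``, by the pair
``{b}{r}_p1 {b}{r}_p2``.  Coordinates are 1-based and inclusive.  Chromosome
names are opaque strings (no "chr" normalization is attempted).

This dialect is self-describing and lossless but is not guaranteed to be
byte-compatible with map files produced by other BSA pipelines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .errors import MapFormatError, ValidationError
from .gstat import KernelSpec

FIXED_COLUMNS = ("chrom", "pos", "allele_p1", "allele_p2")
_COUNT_COL_RE = re.compile(r"^([HL])(\d+)_(p1|p2)$")

ChromLengths = dict  # chrom -> length (bp); insertion order is genome order


def count_columns(bulks: Iterable[str], n_replicates: int) -> list[str]:
    """Canonical order of count columns for the given design."""
    cols = []
    for b in bulks:
        for r in range(1, n_replicates + 1):
            cols += [f"{b}{r}_p1", f"{b}{r}_p2"]
    return cols


@dataclass
class MarkerTable:
    """Per-marker allele counts for one bulk-segregant experiment.

    ``data`` holds one row per marker with the fixed columns plus the
    count columns in canonical order.  Rows are sorted by (chrom, pos);
    positions are strictly increasing within each chromosome.
    """

    data: pd.DataFrame
    bulks: tuple[str, ...] = ("H", "L")
    n_replicates: int = 1

    @property
    def count_cols(self) -> list[str]:
        return count_columns(self.bulks, self.n_replicates)

    def __len__(self) -> int:
        return len(self.data)

    def sort(self) -> "MarkerTable":
        """Return a copy sorted by (chrom, pos); chromosome names sort
        lexicographically so the canonical order is input-order-independent."""
        df = (
            self.data.sort_values(["chrom", "pos"], kind="stable")
            .reset_index(drop=True)
        )
        return MarkerTable(df, self.bulks, self.n_replicates)

    def validate(self) -> "MarkerTable":
        df = self.data
        expected = list(FIXED_COLUMNS) + self.count_cols
        if list(df.columns) != expected:
            raise MapFormatError(
                f"marker table columns {list(df.columns)} != expected {expected}"
            )
        if (df["pos"] < 1).any():
            bad = df.loc[df["pos"] < 1].iloc[0]
            raise ValidationError(f"non-positive position {bad['pos']} on {bad['chrom']}")
        same = df["allele_p1"] == df["allele_p2"]
        if same.any():
            bad = df.loc[same].iloc[0]
            raise ValidationError(
                f"identical parental alleles at {bad['chrom']}:{bad['pos']}"
            )
        for col in self.count_cols:
            if (df[col] < 0).any():
                raise ValidationError(f"negative count in column {col}")
        dup = df.duplicated(subset=["chrom", "pos"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValidationError(f"duplicate marker at {bad['chrom']}:{bad['pos']}")
        for _, grp in df.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValidationError("positions not sorted within a chromosome")
        return self

    def equals(self, other: "MarkerTable") -> bool:
        return (
            self.bulks == other.bulks
            and self.n_replicates == other.n_replicates
            and self.data.equals(other.data)
        )


def _infer_design(columns: list[str]) -> tuple[tuple[str, ...], int]:
    """Infer (bulks, n_replicates) from a map-file header."""
    if list(columns[:4]) != list(FIXED_COLUMNS):
        raise MapFormatError(
            f"map header must start with {FIXED_COLUMNS}, got {columns[:4]}"
        )
    bulks: dict[str, set[int]] = {}
    for col in columns[4:]:
        m = _COUNT_COL_RE.match(col)
        if m is None:
            raise MapFormatError(f"unrecognized count column {col!r}")
        bulks.setdefault(m.group(1), set()).add(int(m.group(2)))
    if not bulks:
        raise MapFormatError("map file has no count columns")
    reps = {frozenset(v) for v in bulks.values()}
    if len(reps) != 1:
        raise MapFormatError("bulks carry different replicate sets")
    (rep_ids,) = reps
    n_rep = max(rep_ids)
    if rep_ids != set(range(1, n_rep + 1)):
        raise MapFormatError(f"replicate ids must be 1..R, got {sorted(rep_ids)}")
    bulk_order = tuple(b for b in ("H", "L") if b in bulks)
    if set(bulks) - {"H", "L"}:
        raise MapFormatError(f"unknown bulk ids {set(bulks) - {'H', 'L'}}")
    if "H" not in bulks:
        raise MapFormatError("map file must contain the H bulk")
    return bulk_order, n_rep


def read_map(path: str | Path, design: "RunConfig | None" = None) -> MarkerTable:
    """Load and validate a map file; rows are re-sorted by (chrom, pos).

    ``design`` is optional: when given, the file's inferred bulk/replicate
    layout is checked against it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    bulks, n_rep = _infer_design(list(df.columns))
    if design is not None:
        want = ("H", "L") if design.design == 2 else ("H",)
        if bulks != want or n_rep != design.n_replicates:
            raise ValidationError(
                f"map layout bulks={bulks} R={n_rep} does not match configured "
                f"design={design.design}-bulk R={design.n_replicates}"
            )
    int_cols = ["pos"] + count_columns(bulks, n_rep)
    for col in int_cols:
        try:
            df[col] = df[col].astype("int64")
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise MapFormatError(
                f"{path}: line {bad + 2}: non-integer value {df[col].iloc[bad]!r} "
                f"in column {col}"
            ) from None
        if col != "pos" and (df[col] < 0).any():
            bad = df.index[df[col] < 0][0]
            raise MapFormatError(
                f"{path}: line {bad + 2}: negative count {df[col].iloc[bad]} "
                f"in column {col}"
            )
    table = MarkerTable(df, bulks, n_rep).sort()
    return table.validate()


def write_map(table: MarkerTable, path: str | Path) -> None:
    """Write a map file; ``read_map`` on the result reproduces ``table`` exactly."""
    table.validate()
    table.data.to_csv(path, sep="\t", index=False)


def read_lengths(path: str | Path) -> ChromLengths:
    """Load a two-column chromosome-length TSV (chrom, length in bp)."""
    lengths: ChromLengths = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MapFormatError(f"{path}: line {lineno}: expected 2 columns")
            chrom, raw = parts
            if chrom in lengths:
                raise ValidationError(f"{path}: duplicate chromosome {chrom!r}")
            try:
                length = int(raw)
            except ValueError:
                raise MapFormatError(
                    f"{path}: line {lineno}: non-integer length {raw!r}"
                ) from None
            if length <= 0:
                raise ValidationError(f"{path}: non-positive length for {chrom!r}")
            lengths[chrom] = length
    return lengths


def write_lengths(lengths: ChromLengths, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def check_lengths_cover(table: MarkerTable, lengths: ChromLengths) -> None:
    """Every marker chromosome must be declared with length >= max marker pos."""
    for chrom, grp in table.data.groupby("chrom", sort=False):
        if chrom not in lengths:
            raise ValidationError(
                f"chromosome {chrom!r} absent from length file "
                f"(available: {sorted(lengths)})"
            )
        if lengths[chrom] < grp["pos"].max():
            raise ValidationError(
                f"chromosome {chrom!r} length {lengths[chrom]} < max marker "
                f"position {grp['pos'].max()}"
            )


@dataclass
class RunConfig:
    """Scan configuration.

    Defaults mirror the reference workflow's printed worked example:
    tricube kernel of full width 33,750 bp, 2-bulk design, coverage
    threshold 10 for the scan.  Marker *calling* uses its own default
    of 5x (see ``bsaqtl.markers``).
    """

    design: int = 2  # 1- or 2-bulk
    n_replicates: int = 1
    kernel: KernelSpec = field(default_factory=KernelSpec)
    min_depth: int = 10
    fdr_alpha: float = 0.05
    chrom_filter: str | list[str] = "all"
    emit_raw_g: bool = False
    replicate_mode: str = "pool"  # "pool" counts or "mean" of per-replicate G
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.design not in (1, 2):
            raise ValidationError("design must be 1 or 2")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.min_depth < 1:
            raise ValidationError("min_depth must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must be in (0, 1)")
        if self.kernel.width <= 0:
            raise ValidationError("kernel width must be positive")
        if self.replicate_mode not in ("pool", "mean"):
            raise ValidationError("replicate_mode must be 'pool' or 'mean'")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a flat YAML key-value file."""
    with open(path) as fh:
        raw: Mapping = yaml.safe_load(fh) or {}
    kw = dict(raw)
    kernel_kw = {}
    for key in ("kernel_kind", "kernel_width"):
        if key in kw:
            kernel_kw[key.removeprefix("kernel_")] = kw.pop(key)
    if kernel_kw:
        kw["kernel"] = KernelSpec(**kernel_kw)
    unknown = set(kw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    flat = {
        "design": cfg.design,
        "n_replicates": cfg.n_replicates,
        "kernel_kind": cfg.kernel.kind,
        "kernel_width": cfg.kernel.width,
        "min_depth": cfg.min_depth,
        "fdr_alpha": cfg.fdr_alpha,
        "chrom_filter": cfg.chrom_filter,
        "emit_raw_g": cfg.emit_raw_g,
        "replicate_mode": cfg.replicate_mode,
        "seed": cfg.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(flat, fh, sort_keys=False)
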