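"""Forward simulation of a two-parent haploid yeast cross with bulk selection.

The simulator produces everything a bulk-segregant QTL scan consumes —
a map file, a chromosome-length file — plus the ground truth needed to
validate the scan end to end.  The model:

* N haploid segregants; each chromosome is a mosaic of the two parental
  haplotypes with a Poisson number of crossovers (no interference),
  breakpoints uniform, so every marker is P1/P2 with probability 1/2.
* Phenotype y_i = sum over causal loci of beta * x_i + epsilon_i, with
  x in {0, 1} (1 = P1 allele at the marker nearest the locus) and
  standard-normal noise; effect sizes beta are in noise-s.d. units.
* Extreme-phenotype bulks: top-k (H) and, for 2-bulk designs, bottom-k (L)
  segregants, ties broken by segregant index.
* Sequencing: per marker/bulk/replicate, depth ~ Poisson(lambda) and
  P1-supporting reads ~ Binomial(depth, f(1-eps) + (1-f)eps), where f is
  the bulk's true P1-allele frequency and eps a symmetric error rate.

Defaults mimic an S. cerevisiae cross: 16 chromosomes with the SacCer3
lengths, ~0.35 cM/kb recombination, bulks of 50 segregants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_map import ChromLengths, MarkerTable, count_columns, write_lengths, write_map
from .markers import ParentalSiteCounts

#: SacCer3 nuclear chromosome lengths (bp)
YEAST_CHROM_LENGTHS: ChromLengths = {
    "chrI": 230_218, "chrII": 813_184, "chrIII": 316_620, "chrIV": 1_531_933,
    "chrV": 576_874, "chrVI": 270_161, "chrVII": 1_090_940, "chrVIII": 562_643,
    "chrIX": 439_888, "chrX": 745_751, "chrXI": 666_816, "chrXII": 1_078_177,
    "chrXIII": 924_431, "chrXIV": 784_333, "chrXV": 1_091_291, "chrXVI": 948_066,
}

#: expected crossovers per bp per meiosis (~0.35 cM/kb, yeast genome average)
CROSSOVERS_PER_BP = 3.5e-6


@dataclass
class CrossConfig:
    """Parameters of one simulated bulk-segregant experiment."""

    chrom_lengths: ChromLengths = field(
        default_factory=lambda: dict(YEAST_CHROM_LENGTHS)
    )
    marker_spacing: int = 1_500
    n_segregants: int = 500
    bulk_size: int = 50
    design: int = 2
    n_replicates: int = 1
    causal_loci: list[tuple[str, int, float]] = field(default_factory=list)
    recomb_rate: float | None = None  # crossovers/chromosome; None = length-proportional
    mean_depth: float = 40.0
    seq_error: float = 0.001
    seed: int = 0

    def validate(self) -> "CrossConfig":
        if self.design not in (1, 2):
            raise ValidationError("design must be 1 or 2")
        need = 2 * self.bulk_size if self.design == 2 else self.bulk_size
        if need > self.n_segregants:
            raise ValidationError(
                f"bulks need {need} segregants but only {self.n_segregants} simulated"
            )
        if self.mean_depth <= 0:
            raise ValidationError("mean_depth must be positive")
        if not 0 <= self.seq_error < 0.5:
            raise ValidationError("seq_error must be in [0, 0.5)")
        if self.marker_spacing < 1:
            raise ValidationError("marker_spacing must be >= 1")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        for chrom, pos, _ in self.causal_loci:
            if chrom not in self.chrom_lengths:
                raise ValidationError(f"causal locus on unknown chromosome {chrom!r}")
            if not 1 <= pos <= self.chrom_lengths[chrom]:
                raise ValidationError(
                    f"causal locus {chrom}:{pos} outside chromosome length"
                )
        return self

    def expected_crossovers(self, chrom: str) -> float:
        if self.recomb_rate is not None:
            return self.recomb_rate
        return self.chrom_lengths[chrom] * CROSSOVERS_PER_BP


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated map file."""

    causal_loci: list[tuple[str, int, float]]
    markers: pd.DataFrame          # chrom, pos
    f_H: np.ndarray                # true P1-allele frequency in the H bulk
    f_L: np.ndarray | None         # same for L (2-bulk designs)
    genotypes: np.ndarray | None = None  # N x M, 1 = P1 allele

    def frame(self) -> pd.DataFrame:
        df = self.markers.copy()
        df["f_H"] = self.f_H
        if self.f_L is not None:
            df["f_L"] = self.f_L
        return df


def marker_positions(cfg: CrossConfig) -> pd.DataFrame:
    """Evenly spaced marker grid: spacing, 2*spacing, ... per chromosome."""
    rows = []
    for chrom, length in cfg.chrom_lengths.items():
        for pos in range(cfg.marker_spacing, length + 1, cfg.marker_spacing):
            rows.append((chrom, pos))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def simulate_segregants(
    cfg: CrossConfig, rng: np.random.Generator, markers: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Genotypes of N recombinant segregants at every marker.

    Returns (markers, genotype matrix) with genotypes in {0, 1}
    (1 = P1 allele).  Each segregant/chromosome draws a Poisson crossover
    count, places breakpoints uniformly, and alternates parental phase,
    starting from a fair coin — so P(P1) = 1/2 marginally everywhere.
    """
    cfg.validate()
    if markers is None:
        markers = marker_positions(cfg)
    n = cfg.n_segregants
    geno = np.empty((n, len(markers)), dtype=np.uint8)
    col = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=float)
        length = cfg.chrom_lengths[chrom]
        lam = cfg.expected_crossovers(chrom)
        n_xo = rng.poisson(lam, size=n)
        start = rng.integers(0, 2, size=n)
        block = np.empty((n, len(pos)), dtype=np.uint8)
        for i in range(n):
            if n_xo[i] == 0:
                block[i] = start[i]
            else:
                bp = np.sort(rng.uniform(0, length, size=n_xo[i]))
                block[i] = (start[i] + np.searchsorted(bp, pos)) % 2
        geno[:, col : col + len(pos)] = block
        col += len(pos)
    return markers.reset_index(drop=True), geno


def assign_phenotypes(
    genotypes: np.ndarray,
    markers: pd.DataFrame,
    causal_loci: list[tuple[str, int, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive phenotype: each causal locus acts through its nearest marker."""
    y = rng.standard_normal(genotypes.shape[0])
    for chrom, pos, beta in causal_loci:
        j = nearest_marker(markers, chrom, pos)
        y = y + beta * genotypes[:, j]
    return y


def nearest_marker(markers: pd.DataFrame, chrom: str, pos: int) -> int:
    sub = markers.loc[markers["chrom"] == chrom]
    if sub.empty:
        raise ValidationError(f"no markers on chromosome {chrom!r}")
    return int((sub["pos"] - pos).abs().idxmin())


def select_bulks(
    phenotypes: np.ndarray, k: int, design: int = 2
) -> dict[str, np.ndarray]:
    """Extreme-phenotype bulks: H = top-k, L = bottom-k (2-bulk designs).

    Ties are broken by segregant index (lower index goes to the lower
    bulk), making selection deterministic.
    """
    n = len(phenotypes)
    if (2 * k if design == 2 else k) > n:
        raise ValidationError("bulk size too large for the segregant count")
    order = np.lexsort((np.arange(n), phenotypes))  # ascending, index-stable
    bulks = {"H": np.sort(order[n - k :])}
    if design == 2:
        bulks["L"] = np.sort(order[:k])
    return bulks


def sample_reads(
    bulks: dict[str, np.ndarray],
    genotypes: np.ndarray,
    markers: pd.DataFrame,
    cfg: CrossConfig,
    rng: np.random.Generator,
    keep_genotypes: bool = False,
) -> tuple[MarkerTable, TruthRecord]:
    """Binomial read sampling over the selected bulks -> map table + truth."""
    m = len(markers)
    df = markers.copy()
    df["allele_p1"] = "A"
    df["allele_p2"] = "G"
    truth_f: dict[str, np.ndarray] = {}
    bulk_ids = ("H", "L") if cfg.design == 2 else ("H",)
    for b in bulk_ids:
        f = genotypes[bulks[b]].mean(axis=0)
        truth_f[b] = f
        p_read = f * (1 - cfg.seq_error) + (1 - f) * cfg.seq_error
        for r in range(1, cfg.n_replicates + 1):
            depth = rng.poisson(cfg.mean_depth, size=m)
            n_p1 = rng.binomial(depth, p_read)
            df[f"{b}{r}_p1"] = n_p1
            df[f"{b}{r}_p2"] = depth - n_p1
    cols = ["chrom", "pos", "allele_p1", "allele_p2"] + count_columns(
        bulk_ids, cfg.n_replicates
    )
    table = MarkerTable(df[cols], bulk_ids, cfg.n_replicates).sort().validate()
    truth = TruthRecord(
        causal_loci=list(cfg.causal_loci),
        markers=markers[["chrom", "pos"]].copy(),
        f_H=truth_f["H"],
        f_L=truth_f.get("L"),
        genotypes=genotypes if keep_genotypes else None,
    )
    return table, truth


def simulate_cross(
    cfg: CrossConfig, keep_genotypes: bool = False
) -> tuple[MarkerTable, ChromLengths, TruthRecord]:
    """Run the full simulation pipeline for one seeded configuration."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    markers, geno = simulate_segregants(cfg, rng)
    y = assign_phenotypes(geno, markers, cfg.causal_loci, rng)
    bulks = select_bulks(y, cfg.bulk_size, cfg.design)
    table, truth = sample_reads(bulks, geno, markers, cfg, rng, keep_genotypes)
    return table, dict(cfg.chrom_lengths), truth


def write_outputs(
    cfg: CrossConfig,
    map_path: str | Path,
    lengths_path: str | Path,
    truth_path: str | Path,
) -> None:
    """Simulate and write map, chromosome-length and truth TSVs."""
    table, lengths, truth = simulate_cross(cfg)
    write_map(table, map_path)
    write_lengths(lengths, lengths_path)
    tf = truth.frame()
    tf["causal_beta"] = np.nan
    for chrom, pos, beta in truth.causal_loci:
        tf.loc[nearest_marker(truth.markers, chrom, pos), "causal_beta"] = beta
    tf.to_csv(truth_path, sep="\t", index=False)


def simulate_parental_counts(
    cfg: CrossConfig, rng: np.random.Generator | None = None
) -> list[ParentalSiteCounts]:
    """Parental sequencing counts at the marker grid, for marker-calling tests.

    Parent 1 is fixed for "A", parent 2 for "G"; reads flip to the other
    allele at the sequencing-error rate.  Depths are Poisson(mean_depth).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    markers = marker_positions(cfg)
    m = len(markers)
    d1 = rng.poisson(cfg.mean_depth, size=m)
    d2 = rng.poisson(cfg.mean_depth, size=m)
    e1 = rng.binomial(d1, cfg.seq_error)
    e2 = rng.binomial(d2, cfg.seq_error)
    sites = []
    for i, row in enumerate(markers.itertuples(index=False)):
        c1 = {"A": int(d1[i] - e1[i])}
        if e1[i]:
            c1["G"] = int(e1[i])
        c2 = {"G": int(d2[i] - e2[i])}
        if e2[i]:
            c2["A"] = int(e2[i])
        sites.append(ParentalSiteCounts(row.chrom, row.pos, c1, c2))
    return sites
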