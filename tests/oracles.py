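"""Independent oracles and random-fixture builders used across the suite.

Everything here deliberately avoids the code paths it checks: the G-test
oracle goes through scipy's contingency machinery, the BH oracle applies
the step-up rule literally, and the variant oracle rebuilds and translates
the entire mutant CDS instead of editing codons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy.stats import chi2_contingency, power_divergence

from bsaqtl import GeneModel, MarkerTable, VariantCall
from bsaqtl.io_map import count_columns

_COMP = str.maketrans("ACGT", "TGCA")


def g_oracle(n1, n2, n3, n4) -> float:
    """2x2 log-likelihood-ratio statistic via scipy's contingency test."""
    res = chi2_contingency(
        [[n1, n2], [n3, n4]], lambda_="log-likelihood", correction=False
    )
    return float(res.statistic)


def g_one_bulk_oracle(n1, n2, f0=0.5) -> float:
    n = n1 + n2
    stat, _ = power_divergence(
        [n1, n2], f_exp=[f0 * n, (1 - f0) * n], lambda_="log-likelihood"
    )
    return float(stat)


def mutual_information_nats(n1, n2, n3, n4) -> float:
    """Mutual information of the empirical 2x2 joint distribution."""
    p = np.array([[n1, n2], [n3, n4]], dtype=float)
    total = p.sum()
    p /= total
    px, py = p.sum(axis=1), p.sum(axis=0)
    mi = 0.0
    for i in range(2):
        for j in range(2):
            if p[i, j] > 0:
                mi += p[i, j] * np.log(p[i, j] / (px[i] * py[j]))
    return mi


def smooth_oracle(pos, g, kind, width) -> np.ndarray:
    """Brute-force kernel-weighted mean, written from the definition."""
    h = width / 2.0
    pos, g = np.asarray(pos, float), np.asarray(g, float)
    out = np.empty(len(g))
    for j in range(len(g)):
        num = den = 0.0
        for k in range(len(g)):
            d = abs(pos[k] - pos[j])
            if d > h:
                continue
            u = d / h
            if kind == "tricube":
                w = (1 - u**3) ** 3
            elif kind == "triangular":
                w = 1 - u
            else:
                w = 1.0
            num += w * g[k]
            den += w
        out[j] = num / den
    return out


def bh_stepup_oracle(p) -> np.ndarray:
    """Benjamini-Hochberg q-values by the literal step-up recipe."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


def classify_oracle(v: VariantCall, gene: GeneModel, genome: dict[str, str]) -> str:
    """Full-CDS-rebuild-and-translate classification of one variant."""

    def in_cds(p: int) -> bool:
        return v.chrom == gene.chrom and any(a <= p <= b for a, b in gene.cds)

    if len(v.ref) != len(v.alt):
        if len(v.ref) > len(v.alt):
            span = (v.pos + len(v.alt), v.pos + len(v.ref) - 1)
        else:
            span = (v.pos, v.pos + 1)
        touches = v.chrom == gene.chrom and any(
            a <= span[1] and span[0] <= b for a, b in gene.cds
        )
        if not touches:
            return "noncoding"
        return "frameshift" if abs(len(v.ref) - len(v.alt)) % 3 else "inframe_indel"

    changed_in_cds = [
        v.pos + i
        for i in range(len(v.ref))
        if v.ref[i].upper() != v.alt[i].upper() and in_cds(v.pos + i)
    ]
    if not changed_in_cds:
        return "noncoding"

    def extract(seq: str) -> str:
        s = "".join(seq[a - 1 : b] for a, b in sorted(gene.cds))
        return s.translate(_COMP)[::-1] if gene.strand == "-" else s

    ref_seq = genome[v.chrom]
    mut_seq = ref_seq[: v.pos - 1] + v.alt.upper() + ref_seq[v.pos - 1 + len(v.ref) :]
    old = str(Seq(extract(ref_seq)).translate())
    new = str(Seq(extract(mut_seq)).translate())
    diffs = [(o, n) for o, n in zip(old, new) if o != n]
    if any(n == "*" and o != "*" for o, n in diffs):
        return "stop_gain"
    if any(o == "*" and n != "*" for o, n in diffs):
        return "stop_loss"
    if diffs:
        return "nonsynonymous"
    return "synonymous"


def random_gene_and_genome(rng: np.random.Generator):
    """A random genome with one random multi-exon coding gene on it."""
    n_exons = int(rng.integers(1, 4))
    cursor = int(rng.integers(10, 40))
    cds = []
    for _ in range(n_exons):
        length = int(rng.integers(6, 60))
        cds.append((cursor, cursor + length - 1))
        cursor += length + int(rng.integers(5, 30))
    # trim the last exon so the total CDS length is a codon multiple
    total = sum(b - a + 1 for a, b in cds)
    trim = total % 3
    a, b = cds[-1]
    cds[-1] = (a, b - trim)
    genome_len = cds[-1][1] + int(rng.integers(10, 40))
    seq = "".join(rng.choice(list("ACGT"), size=genome_len))
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel("gene1", "chr1", strand, cds)
    return gene, {"chr1": seq}


def random_substitution(rng: np.random.Generator, genome: dict[str, str]) -> VariantCall:
    seq = genome["chr1"]
    pos = int(rng.integers(1, len(seq) + 1))
    ref = seq[pos - 1]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return VariantCall("chr1", pos, ref, str(alt), "P1")


def random_indel(rng: np.random.Generator, genome: dict[str, str]) -> VariantCall:
    seq = genome["chr1"]
    size = int(rng.integers(1, 5))
    if rng.random() < 0.5:  # insertion after the anchor base
        pos = int(rng.integers(1, len(seq) + 1))
        ref = seq[pos - 1]
        alt = ref + "".join(rng.choice(list("ACGT"), size=size))
    else:  # deletion anchored at pos
        pos = int(rng.integers(1, len(seq) - size))
        ref = seq[pos - 1 : pos + size]
        alt = ref[0]
    return VariantCall("chr1", pos, ref, alt, "P2")


def random_marker_table(
    rng: np.random.Generator,
    n_rows: int = 30,
    bulks=("H", "L"),
    n_replicates: int = 1,
    n_chroms: int = 3,
) -> MarkerTable:
    chroms = [f"chr{i+1}" for i in range(n_chroms)]
    rows = []
    for chrom in chroms:
        positions = np.sort(
            rng.choice(np.arange(1, 10_000), size=n_rows // n_chroms, replace=False)
        )
        for pos in positions:
            alleles = rng.choice(list("ACGT"), size=2, replace=False)
            rows.append((chrom, int(pos), alleles[0], alleles[1]))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "allele_p1", "allele_p2"])
    for col in count_columns(bulks, n_replicates):
        df[col] = rng.integers(0, 100, size=len(df))
    return MarkerTable(df, tuple(bulks), n_replicates).sort().validate()
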