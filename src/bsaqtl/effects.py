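"""Coding-consequence classification of parental variants and QTL annotation.

Variants between the two parental lines are classified against gene models
(CDS intervals) and the reference genome into the classes a BSA study
reports per parent: stop gain, stop loss, frameshift, non-synonymous,
in-frame indel, synonymous, or noncoding.  Splice sites, UTRs and
promoters all count as noncoding — only exonic (CDS) consequences are
annotated.  Translation uses the standard nuclear genetic code, with
reverse-complementation for minus-strand genes.

Precomputed deleteriousness scores (e.g. SNAP) are consumed as a
user-supplied (chrom, pos, alt, score) table and joined onto
non-synonymous variants; they are never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gffutils
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from cyvcf2 import VCF

from .errors import MapFormatError, ValidationError
from .scan import QTLRegion

log = logging.getLogger(__name__)


class EffectClass(str, Enum):
    stop_gain = "stop_gain"
    stop_loss = "stop_loss"
    frameshift = "frameshift"
    nonsynonymous = "nonsynonymous"
    inframe_indel = "inframe_indel"
    synonymous = "synonymous"
    noncoding = "noncoding"


#: most to least severe; used to pick one class per variant across gene models
SEVERITY_ORDER = [
    EffectClass.stop_gain,
    EffectClass.stop_loss,
    EffectClass.frameshift,
    EffectClass.nonsynonymous,
    EffectClass.inframe_indel,
    EffectClass.synonymous,
    EffectClass.noncoding,
]
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}


@dataclass
class GeneModel:
    """A coding gene: CDS intervals in genomic coordinates (1-based, inclusive,
    ascending); ``strand`` orients the transcript."""

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for (a, b), (c, d) in zip(self.cds, self.cds[1:]):
            if c <= b:
                raise ValidationError(f"{self.gene_id}: overlapping CDS intervals")
        if any(a > b or a < 1 for a, b in self.cds):
            raise ValidationError(f"{self.gene_id}: malformed CDS interval")
        if self.cds_length % 3 != 0:
            log.warning(
                "%s: CDS length %d not divisible by 3", self.gene_id, self.cds_length
            )

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    def genomic_to_cds(self, pos: int) -> int | None:
        """Map a genomic position to a 0-based CDS coordinate (transcript
        orientation), or None when outside every CDS interval."""
        offset = 0
        for a, b in self.cds:
            if a <= pos <= b:
                fwd = offset + (pos - a)
                return fwd if self.strand == "+" else self.cds_length - 1 - fwd
            offset += b - a + 1
        return None

    def cds_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.chrom][a - 1 : b] for a, b in self.cds)
        return seq if self.strand == "+" else str(Seq(seq).reverse_complement())

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and any(
            a <= end and start <= b for a, b in self.cds
        )


@dataclass
class VariantCall:
    """One parental variant in VCF-style anchoring (ref/alt strings at pos)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    parent: str  # "P1" or "P2"

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref == alt")
        if self.parent not in ("P1", "P2"):
            raise ValidationError(f"{self.chrom}:{self.pos}: parent must be P1 or P2")

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


def read_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA reference as {chrom: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def check_ref(v: VariantCall, genome: dict[str, str]) -> None:
    if v.chrom not in genome:
        raise ValidationError(f"chromosome {v.chrom!r} absent from genome FASTA")
    seq = genome[v.chrom]
    if v.pos < 1 or v.pos + len(v.ref) - 1 > len(seq):
        raise ValidationError(f"{v.chrom}:{v.pos}: position outside genome")
    found = seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
    if found != v.ref.upper():
        raise ValidationError(
            f"{v.chrom}:{v.pos}: REF {v.ref!r} does not match genome ({found!r})"
        )


def classify_variant(
    v: VariantCall, gene: GeneModel, genome: dict[str, str]
) -> EffectClass:
    """Coding consequence of one variant against one gene model.

    Substitutions are classified by rewriting only the affected codons;
    indels inside the CDS by their length modulo 3.  A variant touching no
    CDS base of the gene is noncoding.
    """
    check_ref(v, genome)
    if v.chrom != gene.chrom:
        return EffectClass.noncoding
    if v.is_indel:
        # bases affected: for a deletion the removed span; for an insertion
        # the junction after the anchor base
        if len(v.ref) > len(v.alt):
            start, end = v.pos + len(v.alt), v.pos + len(v.ref) - 1
        else:
            start, end = v.pos, v.pos + 1
        if not gene.overlaps(v.chrom, start, end):
            return EffectClass.noncoding
        shift = abs(len(v.ref) - len(v.alt)) % 3
        return EffectClass.frameshift if shift else EffectClass.inframe_indel
    # substitution (possibly multi-base): collect in-CDS substituted bases
    hits = []
    for i, (rbase, abase) in enumerate(zip(v.ref.upper(), v.alt.upper())):
        if rbase == abase:
            continue
        c = gene.genomic_to_cds(v.pos + i)
        if c is not None:
            hits.append((c, abase))
    if not hits:
        return EffectClass.noncoding
    cds = gene.cds_sequence(genome)
    codons = {c // 3 for c, _ in hits}
    mutant = list(cds)
    for c, abase in hits:
        mutant[c] = abase if gene.strand == "+" else str(Seq(abase).complement())
    gained = lost = changed = False
    for ci in codons:
        old = str(Seq(cds[3 * ci : 3 * ci + 3]).translate())
        new = str(Seq("".join(mutant[3 * ci : 3 * ci + 3])).translate())
        if new == old:
            continue
        if new == "*" and old != "*":
            gained = True
        elif old == "*" and new != "*":
            lost = True
        else:
            changed = True
    if gained:
        return EffectClass.stop_gain
    if lost:
        return EffectClass.stop_loss
    if changed:
        return EffectClass.nonsynonymous
    return EffectClass.synonymous


def classify_variants(
    variants: list[VariantCall],
    genes: list[GeneModel],
    genome: dict[str, str],
) -> pd.DataFrame:
    """Classify every variant against every overlapping gene model.

    Returns one row per variant with the most severe class across models
    (``effect``), the gene carrying it, and all per-model classes.
    """
    rows = []
    for v in variants:
        per_gene = {
            g.gene_id: classify_variant(v, g, genome)
            for g in genes
            if g.chrom == v.chrom
        }
        coding = {gid: e for gid, e in per_gene.items() if e != EffectClass.noncoding}
        if coding:
            gid, eff = min(coding.items(), key=lambda kv: (_SEVERITY_RANK[kv[1]], kv[0]))
        else:
            gid, eff = "", EffectClass.noncoding
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "parent": v.parent,
                "gene": gid,
                "effect": eff.value,
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "parent", "gene", "effect"]
    )


def summarize_mutation_types(classified: pd.DataFrame) -> pd.DataFrame:
    """Count (and fraction of) each effect class per parental line."""
    classes = [c.value for c in SEVERITY_ORDER]
    rows = []
    for parent in ("P1", "P2"):
        sub = classified.loc[classified["parent"] == parent]
        counts = sub["effect"].value_counts()
        total = len(sub)
        for cls in classes:
            n = int(counts.get(cls, 0))
            rows.append(
                {
                    "parent": parent,
                    "effect": cls,
                    "count": n,
                    "fraction": n / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str})
    required = {"chrom", "pos", "alt", "score"}
    if not required.issubset(df.columns):
        raise MapFormatError(f"{path}: score table needs columns {sorted(required)}")
    if df.duplicated(subset=["chrom", "pos", "alt"]).any():
        raise ValidationError(f"{path}: duplicate (chrom, pos, alt) score keys")
    return df


def join_scores(classified: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Left-join deleteriousness scores onto non-synonymous variants.

    Unmatched variants keep a missing score; score rows whose key matches
    only variants of other classes are ignored with a warning.
    """
    if scores.duplicated(subset=["chrom", "pos", "alt"]).any():
        raise ValidationError("duplicate (chrom, pos, alt) score keys")
    out = classified.copy()
    nonsyn = out["effect"] == EffectClass.nonsynonymous.value
    merged = out.loc[nonsyn].merge(
        scores[["chrom", "pos", "alt", "score"]], on=["chrom", "pos", "alt"], how="left"
    )
    out["score"] = pd.NA
    out.loc[nonsyn, "score"] = merged["score"].to_numpy()
    other = out.loc[~nonsyn].merge(
        scores[["chrom", "pos", "alt", "score"]], on=["chrom", "pos", "alt"], how="inner"
    )
    if len(other):
        log.warning(
            "%d score(s) matched non-nonsynonymous variants and were ignored",
            len(other),
        )
    return out


def annotate_regions(
    regions: list[QTLRegion],
    genes: list[GeneModel],
    classified: pd.DataFrame,
) -> pd.DataFrame:
    """Per QTL region: overlapping genes and the contained classified variants.

    Regions without genes or variants are kept (empty annotation), one row
    per region x gene x variant combination at minimum one row per region.
    """
    rows = []
    for r in regions:
        hit_genes = [
            g.gene_id for g in genes if g.overlaps(r.chrom, r.start, r.end)
        ]
        inside = classified.loc[
            (classified["chrom"] == r.chrom)
            & (classified["pos"] >= r.start)
            & (classified["pos"] <= r.end)
        ]
        base = {
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "peak_pos": r.peak_pos,
            "genes": ";".join(hit_genes),
        }
        if inside.empty:
            rows.append({**base, "pos": pd.NA, "ref": "", "alt": "", "parent": "",
                         "gene": "", "effect": "", "score": pd.NA})
        else:
            for v in inside.to_dict("records"):
                rows.append({**base, "pos": v["pos"], "ref": v["ref"],
                             "alt": v["alt"], "parent": v["parent"],
                             "gene": v["gene"], "effect": v["effect"],
                             "score": v.get("score", pd.NA)})
    cols = ["chrom", "start", "end", "peak_pos", "genes", "pos", "ref", "alt",
            "parent", "gene", "effect", "score"]
    return pd.DataFrame(rows, columns=cols)


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Extract gene models (CDS grouped by Parent) from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    by_parent: dict[str, GeneModel] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent", [cds.id or "unnamed"])
        for pid in parents:
            model = by_parent.get(pid)
            if model is None:
                by_parent[pid] = model = GeneModel(pid, cds.seqid, cds.strand, [])
            if cds.strand != model.strand or cds.seqid != model.chrom:
                raise ValidationError(f"{pid}: CDS segments disagree on strand/chrom")
            model.cds.append((cds.start, cds.end))
    models = []
    for m in by_parent.values():
        # re-validate after accumulating intervals
        models.append(GeneModel(m.gene_id, m.chrom, m.strand, m.cds))
    return models


def read_vcf_variants(path: str | Path, parent: str | None = None) -> list[VariantCall]:
    """Read variants from a VCF; parent comes from a PARENT info tag unless
    given explicitly for the whole file."""
    out = []
    for rec in VCF(str(path)):
        p = parent or rec.INFO.get("PARENT")
        if p is None:
            raise MapFormatError(
                f"{path}: {rec.CHROM}:{rec.POS}: no PARENT tag and no "
                "--parent override"
            )
        for alt in rec.ALT:
            out.append(VariantCall(rec.CHROM, rec.POS, rec.REF, alt, p))
    return out
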