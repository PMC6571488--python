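import numpy as np
import pandas as pd
import pytest

from bsaqtl import (
    EffectClass,
    GeneModel,
    VariantCall,
    annotate_regions,
    classify_variant,
    classify_variants,
    join_scores,
    read_genome,
    read_gff3_genes,
    read_score_table,
    read_vcf_variants,
    summarize_mutation_types,
)
from bsaqtl.errors import ValidationError
from bsaqtl.scan import QTLRegion

from oracles import (
    classify_oracle,
    random_gene_and_genome,
    random_indel,
    random_substitution,
)

# plus-strand toy gene: CDS = ATG TGG TAA at genomic 3..11
GENOME = {"chr1": "CCATGTGGTAACC"}
GENE = GeneModel("g1", "chr1", "+", [(3, 11)])


def var(pos, ref, alt, parent="P1", chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, parent)


class TestClassifyVariant:
    def test_stop_gain(self):
        # CDS position 6: TGG (Trp) -> TGA (stop)
        assert classify_variant(var(8, "G", "A"), GENE, GENOME) == EffectClass.stop_gain

    def test_synonymous(self):
        genome = {"chr1": "CCATGTTATAACC"}  # CDS ATG TTA TAA
        gene = GeneModel("g1", "chr1", "+", [(3, 11)])
        # CDS position 6: TTA (Leu) -> TTG (Leu)
        assert classify_variant(var(8, "A", "G"), gene, genome) == EffectClass.synonymous

    def test_nonsynonymous(self):
        # CDS position 4: TGG -> AGG (Trp -> Arg)
        assert (
            classify_variant(var(6, "T", "A"), GENE, GENOME)
            == EffectClass.nonsynonymous
        )

    def test_stop_loss(self):
        # CDS position 9: TAA (stop) -> TAC (Tyr)
        assert classify_variant(var(11, "A", "C"), GENE, GENOME) == EffectClass.stop_loss

    def test_one_bp_insertion_is_frameshift(self):
        assert (
            classify_variant(var(5, "G", "GT"), GENE, GENOME) == EffectClass.frameshift
        )

    def test_three_bp_deletion_is_inframe(self):
        assert (
            classify_variant(var(4, "TGTG", "T"), GENE, GENOME)
            == EffectClass.inframe_indel
        )

    def test_outside_cds_is_noncoding(self):
        assert classify_variant(var(1, "C", "T"), GENE, GENOME) == EffectClass.noncoding
        assert classify_variant(var(13, "C", "A"), GENE, GENOME) == EffectClass.noncoding

    def test_insertion_outside_cds_is_noncoding(self):
        assert (
            classify_variant(var(12, "C", "CAT"), GENE, GENOME) == EffectClass.noncoding
        )

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValidationError, match="chr1:8"):
            classify_variant(var(8, "T", "A"), GENE, GENOME)

    def test_minus_strand_stop_gain(self):
        # same codon content as the stop-gain case, built on the - strand
        genome = {"chr1": "GGTTACCACATGG"}  # revcomp of CCATGTGGTAACC
        gene = GeneModel("g1", "chr1", "-", [(3, 11)])
        # genomic pos 6 C->T is the revcomp of the +-strand 8 G->A
        assert classify_variant(var(6, "C", "T"), gene, genome) == EffectClass.stop_gain

    def test_strand_symmetry_random(self, rng):
        comp = str.maketrans("ACGT", "TGCA")
        for _ in range(50):
            gene, genome = random_gene_and_genome(rng)
            if gene.strand == "-":
                continue
            v = random_substitution(rng, genome)
            fwd = classify_variant(v, gene, genome)
            # mirror everything through reverse complement
            seq = genome["chr1"]
            L = len(seq)
            rc = seq.translate(comp)[::-1]
            rc_cds = sorted((L - b + 1, L - a + 1) for a, b in gene.cds)
            rc_gene = GeneModel("g1", "chr1", "-", rc_cds)
            rc_v = VariantCall(
                "chr1", L - v.pos + 1,
                v.ref.translate(comp), v.alt.translate(comp), v.parent,
            )
            assert classify_variant(rc_v, rc_gene, {"chr1": rc}) == fwd

    def test_agrees_with_full_rebuild_oracle(self, rng):
        for _ in range(150):
            gene, genome = random_gene_and_genome(rng)
            v = (
                random_substitution(rng, genome)
                if rng.random() < 0.7
                else random_indel(rng, genome)
            )
            assert classify_variant(v, gene, genome).value == classify_oracle(
                v, gene, genome
            )


class TestSummaries:
    def test_counts_and_fractions(self):
        classified = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "pos": [1, 2, 3, 4],
                "ref": list("ACGT"),
                "alt": list("CGTA"),
                "parent": ["P1"] * 4,
                "gene": ["g1"] * 4,
                "effect": ["synonymous"] * 3 + ["stop_gain"],
            }
        )
        summary = summarize_mutation_types(classified)
        p1 = summary.loc[summary["parent"] == "P1"].set_index("effect")
        assert p1.loc["synonymous", "count"] == 3
        assert p1.loc["stop_gain", "count"] == 1
        assert p1.loc["synonymous", "fraction"] == pytest.approx(0.75)
        assert p1["count"].sum() == 4  # conservation

    def test_empty_input_gives_zero_table(self):
        empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "parent", "effect"])
        summary = summarize_mutation_types(empty)
        assert (summary["count"] == 0).all()

    def test_permutation_invariance(self, rng):
        effects = ["synonymous", "nonsynonymous", "frameshift", "stop_gain"]
        classified = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(40),
                "ref": "A",
                "alt": "G",
                "parent": np.where(np.arange(40) % 2 == 0, "P1", "P2"),
                "effect": [effects[i % 4] for i in range(40)],
            }
        )
        shuffled = classified.sample(frac=1, random_state=3).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            summarize_mutation_types(classified), summarize_mutation_types(shuffled)
        )


class TestScores:
    def classified(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "pos": [10, 20, 30],
                "ref": ["A", "C", "G"],
                "alt": ["G", "T", "A"],
                "parent": ["P1", "P1", "P2"],
                "gene": ["g1", "g1", "g2"],
                "effect": ["nonsynonymous", "nonsynonymous", "synonymous"],
            }
        )

    def test_matching_key_attached_others_missing(self):
        scores = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [10], "alt": ["G"], "score": [0.83]}
        )
        out = join_scores(self.classified(), scores)
        assert out.loc[0, "score"] == pytest.approx(0.83)
        assert pd.isna(out.loc[1, "score"])
        assert len(out) == 3  # unmatched variants retained

    def test_score_for_synonymous_variant_ignored(self, caplog):
        scores = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [30], "alt": ["A"], "score": [0.5]}
        )
        with caplog.at_level("WARNING"):
            out = join_scores(self.classified(), scores)
        assert pd.isna(out.loc[2, "score"])
        assert "ignored" in caplog.text

    def test_duplicate_score_keys_rejected(self):
        scores = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [10, 10], "alt": ["G", "G"],
             "score": [0.1, 0.2]}
        )
        with pytest.raises(ValidationError):
            join_scores(self.classified(), scores)


class TestAnnotateRegions:
    def region(self, start, end):
        return QTLRegion("chr1", start, end, (start + end) // 2, 5.0, 0.01, 3)

    def test_overlapping_gene_listed(self):
        gene = GeneModel("g1", "chr1", "+", [(400, 900)])
        out = annotate_regions([self.region(100, 500)], [gene], pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "parent", "gene", "effect"]))
        assert out.iloc[0]["genes"] == "g1"

    def test_non_overlapping_gene_absent(self):
        gene = GeneModel("g1", "chr1", "+", [(600, 900)])
        out = annotate_regions([self.region(100, 500)], [gene], pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "parent", "gene", "effect"]))
        assert out.iloc[0]["genes"] == ""

    def test_empty_region_kept(self):
        out = annotate_regions([self.region(100, 500)], [], pd.DataFrame(
            columns=["chrom", "pos", "ref", "alt", "parent", "gene", "effect"]))
        assert len(out) == 1

    def test_contained_variants_attached(self):
        classified = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [250, 800],
                "ref": ["A", "C"],
                "alt": ["G", "T"],
                "parent": ["P1", "P1"],
                "gene": ["g1", "g1"],
                "effect": ["nonsynonymous", "synonymous"],
            }
        )
        out = annotate_regions([self.region(100, 500)], [], classified)
        assert list(out["pos"]) == [250]


class TestFileFormats:
    @pytest.fixture
    def toy_files(self, tmp_path):
        fasta = tmp_path / "genome.fa"
        fasta.write_text(">chr1\nCCATGTGGTAACCCCATGTTATAACC\n")
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\ttoy\tgene\t3\t11\t.\t+\t.\tID=gene1\n"
            "chr1\ttoy\tmRNA\t3\t11\t.\t+\t.\tID=mRNA1;Parent=gene1\n"
            "chr1\ttoy\tCDS\t3\t11\t.\t+\t0\tID=cds1;Parent=mRNA1\n"
            "chr1\ttoy\tgene\t16\t24\t.\t+\t.\tID=gene2\n"
            "chr1\ttoy\tmRNA\t16\t24\t.\t+\t.\tID=mRNA2;Parent=gene2\n"
            "chr1\ttoy\tCDS\t16\t24\t.\t+\t0\tID=cds2;Parent=mRNA2\n"
        )
        vcf = tmp_path / "vars.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=PARENT,Number=1,Type=String,Description="parental line">\n'
            "##contig=<ID=chr1,length=26>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t8\t.\tG\tA\t.\t.\tPARENT=P1\n"
            "chr1\t21\t.\tA\tG\t.\t.\tPARENT=P2\n"
        )
        return fasta, gff, vcf

    def test_end_to_end_classification(self, toy_files):
        fasta, gff, vcf = toy_files
        genome = read_genome(fasta)
        genes = read_gff3_genes(gff)
        variants = read_vcf_variants(vcf)
        assert {g.gene_id for g in genes} == {"mRNA1", "mRNA2"}
        classified = classify_variants(variants, genes, genome)
        by_pos = classified.set_index("pos")
        assert by_pos.loc[8, "effect"] == "stop_gain"
        assert by_pos.loc[21, "effect"] == "synonymous"
        assert by_pos.loc[8, "parent"] == "P1"

    def test_score_table_reader_rejects_duplicates(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text(
            "chrom\tpos\talt\tscore\nchr1\t8\tA\t0.9\nchr1\t8\tA\t0.8\n"
        )
        with pytest.raises(ValidationError):
            read_score_table(path)

    def test_most_severe_class_wins_across_models(self):
        # overlapping frames: synonymous in gene a (TTA->TTG), nonsynonymous
        # in gene b (TAT->TGT); the per-variant row keeps the severer class
        genome = {"chr1": "CCATGTTATAACC"}
        g_a = GeneModel("a", "chr1", "+", [(3, 11)])
        g_b = GeneModel("b", "chr1", "+", [(7, 12)])
        v = VariantCall("chr1", 8, "A", "G", "P1")
        table = classify_variants([v], [g_a, g_b], genome)
        assert table.iloc[0]["effect"] == "nonsynonymous"
        assert table.iloc[0]["gene"] == "b"
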