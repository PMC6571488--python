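"""Coding-consequence classification of parental variants.

A 13-bp toy genome carries one gene (CDS = ATG TGG TAA).  Three variants
show the main consequence classes: a substitution creating a premature
stop, a synonymous change in a second toy gene, and a 1-bp insertion
shifting the reading frame.
"""

from bsaqtl import (
    GeneModel,
    VariantCall,
    classify_variants,
    summarize_mutation_types,
)

genome = {"chr1": "CCATGTGGTAACCCCATGTTATAACC"}
genes = [
    GeneModel("YTOY001", "chr1", "+", [(3, 11)]),   # ATG TGG TAA
    GeneModel("YTOY002", "chr1", "+", [(16, 24)]),  # ATG TTA TAA
]
variants = [
    VariantCall("chr1", 8, "G", "A", "P1"),    # TGG -> TGA : Trp -> stop
    VariantCall("chr1", 21, "A", "G", "P2"),   # TTA -> TTG : Leu -> Leu
    VariantCall("chr1", 5, "G", "GT", "P1"),   # 1-bp insertion in the CDS
]

classified = classify_variants(variants, genes, genome)
print(classified.to_string(index=False))

print("\nper-parent mutation-type summary (nonzero rows):")
summary = summarize_mutation_types(classified)
print(summary.loc[summary["count"] > 0].to_string(index=False))
print("stop gains and frameshifts are the classes most likely to break a gene")
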