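"""Marker identification from parental sequencing counts.

A site becomes a genetic marker when both parents are sequenced deeply
enough (default 5x), each parent's reads agree on one allele (>= 90%
purity), and the two parental alleles differ.
"""

from bsaqtl import ParentalSiteCounts, call_markers

sites = [
    # clean fixed difference -> marker
    ParentalSiteCounts("chrI", 1_000, {"A": 12}, {"G": 14}),
    # parent 1 under-sequenced (4 < 5 reads) -> rejected
    ParentalSiteCounts("chrI", 2_000, {"A": 4}, {"G": 14}),
    # parent 1 ambiguous (50/50 reads) -> rejected
    ParentalSiteCounts("chrI", 3_000, {"A": 6, "G": 6}, {"G": 12}),
    # same major allele in both parents -> not informative
    ParentalSiteCounts("chrI", 4_000, {"T": 20}, {"T": 18, "C": 1}),
    # indel allele difference -> marker (alleles are strings)
    ParentalSiteCounts("chrI", 5_000, {"AT": 9}, {"A": 11}),
]

markers = call_markers(sites, min_depth=5, purity=0.9)
print(f"{len(markers)} markers called from {len(sites)} candidate sites:")
for chrom, pos, a1, a2 in markers:
    print(f"  {chrom}:{pos}  P1={a1}  P2={a2}")
print("only sites with deep, pure, and different parental alleles survive")
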