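"""The G statistic and tricube smoothing on hand-sized numbers.

G is the log-likelihood-ratio test of allele x bulk independence on the
2x2 table of allele counts: 0 when both bulks have the same allele
frequency, large when they diverge.  G' averages G over a physical
window so single noisy markers cannot dominate.
"""

import numpy as np

from bsaqtl import KernelSpec, g_statistic, kernel_weight, smooth

# identical allele frequencies in both bulks -> no evidence
print("G(10,10 | 10,10) =", g_statistic(10, 10, 10, 10))
# perfectly opposed bulks at depth 20+20 -> maximal evidence
print("G(20,0 | 0,20)  =", round(g_statistic(20, 0, 0, 20), 4), "(= 80 ln 2)")
# intermediate divergence
print("G(15,5 | 5,15)  =", round(g_statistic(15, 5, 5, 15), 4))

spec = KernelSpec("tricube", 33_750.0)
print("\ntricube weight at 0 bp:", kernel_weight(0.0, spec))
print("tricube weight at half-window/2:", kernel_weight(spec.half_width / 2, spec))

pos = np.arange(0, 60_000, 3_000, dtype=float)
g = np.zeros(len(pos))
g[10] = 50.0  # one extreme marker at pos 30,000
gprime = smooth(pos, g, spec)
print("\nraw G at the spike:", g[10], "-> smoothed G':", round(gprime[10], 2))
print(
    "neighbours inherit part of the signal:",
    [round(x, 2) for x in gprime[8:13]],
)
print("smoothing spreads one marker's evidence over its physical window")
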