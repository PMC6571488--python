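"""The G statistic and its kernel-smoothed form G'.

For each marker the 2x2 table of (P1 allele, P2 allele) read counts in the
high and low bulks is scored with the log-likelihood-ratio statistic of
allele x bulk independence,

    G = 2 * sum_i n_i * ln(n_i / nhat_i),

where nhat_i is the independence expectation (row sum * column sum / total)
and 0*ln(0) = 0.  Raw G is noisy at the scale of single markers because its
variance tracks local read depth, so it is averaged along the chromosome
with a physical-distance kernel (tricube by default) to give G', the
quantity the QTL scan thresholds.

All logarithms are natural (nats), matching the classical G-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import xlogy

#: full window span (bp) of the default smoothing kernel
DEFAULT_KERNEL_WIDTH = 33_750.0

KERNEL_KINDS = ("tricube", "uniform", "triangular")


@dataclass(frozen=True)
class KernelSpec:
    """Smoothing kernel: ``kind`` and full window span ``width`` in bp.

    The kernel's support is +- ``width``/2 around the focal marker
    (``width`` is the FULL span, so the half-width h = width/2).
    """

    kind: str = "tricube"
    width: float = DEFAULT_KERNEL_WIDTH

    def __post_init__(self) -> None:
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")
        if self.width <= 0:
            raise ValueError("kernel width must be positive")

    @property
    def half_width(self) -> float:
        return self.width / 2.0


def kernel_weight(d, spec: KernelSpec):
    """Kernel weight at physical distance ``d`` >= 0 bp (vectorized).

    tricube: (1 - (d/h)^3)^3, uniform: 1, triangular: 1 - d/h,
    all truncated to 0 beyond the half-width h.
    """
    d = np.asarray(d, dtype=float)
    h = spec.half_width
    u = np.minimum(d / h, 1.0)
    if spec.kind == "tricube":
        w = (1.0 - u**3) ** 3
    elif spec.kind == "triangular":
        w = 1.0 - u
    else:  # uniform
        w = np.where(d <= h, 1.0, 0.0)
    w = np.where(d > h, 0.0, w)
    return w if w.ndim else float(w)


def g_statistic(n1, n2, n3, n4):
    """Two-bulk G statistic from the 2x2 count table (vectorized).

    ``(n1, n2)`` are reads supporting the P1/P2 allele in the high bulk,
    ``(n3, n4)`` the same in the low bulk.  Returns NaN wherever a bulk
    has zero total depth (undefined marker — callers must exclude or
    flag such markers, never treat them as G = 0).
    """
    n1, n2, n3, n4 = (np.asarray(x, dtype=float) for x in (n1, n2, n3, n4))
    obs = np.stack([n1, n2, n3, n4])
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row_h, row_l = n1 + n2, n3 + n4
    col_p1, col_p2 = n1 + n3, n2 + n4
    total = row_h + row_l
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = np.stack(
            [row_h * col_p1, row_h * col_p2, row_l * col_p1, row_l * col_p2]
        ) / total
        g = 2.0 * (xlogy(obs, obs) - xlogy(obs, exp)).sum(axis=0)
    g = np.where((row_h == 0) | (row_l == 0), np.nan, g)
    # guard tiny negative round-off
    g = np.where(g < 0, 0.0, g)
    return g if g.ndim else float(g)


def g_statistic_one_bulk(n1, n2, f0: float = 0.5):
    """One-bulk goodness-of-fit G against an expected P1-allele fraction.

    With a single selected bulk there is no contrast pool; the statistic
    tests the observed allele counts against the Mendelian expectation
    (``f0`` = 0.5 for a 1:1 haploid segregation).  NaN where depth is zero.
    """
    if not 0.0 < f0 < 1.0:
        raise ValueError("f0 must be in (0, 1)")
    n1, n2 = np.asarray(n1, dtype=float), np.asarray(n2, dtype=float)
    if (n1 < 0).any() or (n2 < 0).any():
        raise ValueError("counts must be non-negative")
    n = n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        g = 2.0 * (
            xlogy(n1, n1) - xlogy(n1, f0 * n) + xlogy(n2, n2) - xlogy(n2, (1 - f0) * n)
        )
    g = np.where(n == 0, np.nan, np.where(g < 0, 0.0, g))
    return g if g.ndim else float(g)


def smooth(pos, g, spec: KernelSpec):
    """Kernel-weighted mean of G over each marker's physical window.

    ``pos`` must be sorted ascending and belong to a single chromosome —
    windows never cross chromosome boundaries, so callers smooth each
    chromosome separately (see :func:`smooth_by_chrom`).  Markers with
    NaN G are ignored as neighbours and get NaN G'.
    """
    pos = np.asarray(pos, dtype=float)
    g = np.asarray(g, dtype=float)
    if len(pos) != len(g):
        raise ValueError("pos and g must have equal length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    h = spec.half_width
    out = np.full(len(g), np.nan)
    lo = np.searchsorted(pos, pos - h, side="left")
    hi = np.searchsorted(pos, pos + h, side="right")
    for j in range(len(g)):
        if math.isnan(g[j]):
            continue
        sl = slice(lo[j], hi[j])
        gk = g[sl]
        ok = ~np.isnan(gk)
        w = kernel_weight(np.abs(pos[sl][ok] - pos[j]), spec)
        out[j] = float(np.dot(w, gk[ok]) / w.sum())
    return out


def smooth_by_chrom(df, spec: KernelSpec, g_col: str = "G", out_col: str = "Gprime"):
    """Add a smoothed column to a (chrom, pos, G) DataFrame, per chromosome."""
    df = df.copy()
    df[out_col] = np.nan
    for _, idx in df.groupby("chrom", sort=False).groups.items():
        sub = df.loc[idx]
        df.loc[idx, out_col] = smooth(sub["pos"].to_numpy(), sub[g_col].to_numpy(), spec)
    return df
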