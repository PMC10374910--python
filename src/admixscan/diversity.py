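"""Windowed nucleotide diversity (pi) and Weir–Cockerham Fst.

pi is the unbiased mean number of pairwise differences per site computed
from haplotype counts, summed per window and divided by the covered window
length in bp. Fst uses the Weir & Cockerham (1984) variance-components
estimator per site, combined per window as a ratio of sums.
"""

from __future__ import annotations

from math import ceil

import numpy as np
import pandas as pd

from .panel import GenotypePanel, HaplotypePanel, WindowGrid


def per_site_pi(n: int, k: int) -> float:
    """Unbiased per-site pi: 2k(n-k) / (n(n-1)) for k derived copies of n."""
    if n < 2:
        raise ValueError("need at least two haplotypes")
    if not 0 <= k <= n:
        raise ValueError("allele count outside [0, n]")
    return 2.0 * k * (n - k) / (n * (n - 1))


def windowed_pi(panel: HaplotypePanel, grid: WindowGrid) -> pd.DataFrame:
    """Per-window pi per bp; the terminal truncated window uses its actual
    covered length."""
    if panel.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    n = panel.n_haplotypes
    k = panel.alleles.sum(axis=0).astype(float)
    site_pi = 2.0 * k * (n - k) / (n * (n - 1))
    members = grid.assign(panel.variants["chrom"].to_numpy(),
                          panel.variants["pos"].to_numpy())
    rows = []
    for (c, start, end), idx in zip(grid.windows.itertuples(index=False), members):
        rows.append((c, start, end, len(idx),
                     site_pi[idx].sum() / (end - start)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps", "pi"])


def _pop_site_stats(g: GenotypePanel):
    gt = g.genotypes
    called = gt != -1
    n = called.sum(axis=0).astype(float)  # diploids with data
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, gt, 0).sum(axis=0) / (2.0 * n)
        h = np.where(called, gt == 1, False).sum(axis=0) / n
    return n, p, h


def wc_site_components(ga: GenotypePanel, gb: GenotypePanel):
    """Weir–Cockerham (1984) per-site variance components (a, b, c) for two
    populations; Fst per site = a / (a + b + c)."""
    n1, p1, h1 = _pop_site_stats(ga)
    n2, p2, h2 = _pop_site_stats(gb)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2.0
    bad = (n1 < 1) | (n2 < 1) | ~np.isfinite(a)
    a = np.where(bad, 0.0, a)
    b = np.where(bad, 0.0, b)
    c = np.where(bad, 0.0, c)
    return a, b, c


def wc_fst_window(pop_a, pop_b, grid: WindowGrid,
                  min_snps: int = 4) -> pd.DataFrame:
    """Windowed ratio-of-sums Weir–Cockerham Fst.

    Accepts haplotype or genotype panels (haplotypes are paired into their
    diploid genotypes first). A window is valid when it has >= ``min_snps``
    SNPs and a positive denominator sum.
    """
    ga = pop_a.to_genotypes() if isinstance(pop_a, HaplotypePanel) else pop_a
    gb = pop_b.to_genotypes() if isinstance(pop_b, HaplotypePanel) else pop_b
    if not ga.variants[["chrom", "pos"]].equals(gb.variants[["chrom", "pos"]]):
        raise ValueError("populations must share the variant axis")
    a, b, c = wc_site_components(ga, gb)
    members = grid.assign(ga.variants["chrom"].to_numpy(),
                          ga.variants["pos"].to_numpy())
    rows = []
    for (ch, start, end), idx in zip(grid.windows.itertuples(index=False),
                                     members):
        num = a[idx].sum()
        den = (a[idx] + b[idx] + c[idx]).sum()
        est = num / den if den > 0 else np.nan
        rows.append((ch, start, end, len(idx), est,
                     den > 0 and len(idx) >= min_snps))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "fst", "valid"])


def top_percentile_windows(windows: pd.DataFrame, value_col: str,
                           pct: float = 1.0, min_snps: int = 4,
                           side: str = "high") -> pd.DataFrame:
    """The top (or bottom) ``pct`` percent of valid windows by ``value_col``.

    Validity: >= ``min_snps`` SNPs and a finite value. Ties at the cut are
    all included, so the returned count may exceed ceil(pct% * n_valid).
    """
    import warnings

    valid = windows[(windows["n_snps"] >= min_snps)
                    & np.isfinite(windows[value_col])]
    n_valid = len(valid)
    if n_valid == 0:
        return valid
    if n_valid < 100:
        warnings.warn(f"only {n_valid} valid windows for a {pct}% cut")
    n_top = ceil(pct / 100.0 * n_valid)
    vals = valid[value_col].to_numpy()
    if side == "high":
        cut = np.sort(vals)[::-1][n_top - 1]
        sel = valid[value_col] >= cut
    elif side == "low":
        cut = np.sort(vals)[n_top - 1]
        sel = valid[value_col] <= cut
    else:
        raise ValueError("side must be 'high' or 'low'")
    return valid[sel]
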