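"""Independent brute-force oracles used to validate the implementations.

Each oracle is written as a literal, slow transcription of the defining
rules, sharing no code with the package internals.
"""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_exact_brute(n_rr: int, n_ra: int, n_aa: int) -> float:
    """Exact HWE p-value by full enumeration with rational arithmetic."""
    n = n_rr + n_ra + n_aa
    n_r = 2 * n_rr + n_ra
    n_a = 2 * n_aa + n_ra
    rare = min(n_r, n_a)
    if rare == 0:
        return 1.0

    def prob(h):
        rr = (n_r - h) // 2
        aa = (n_a - h) // 2
        num = Fraction(factorial(n), factorial(rr) * factorial(h) * factorial(aa))
        num *= 2 ** h
        num *= Fraction(factorial(n_r) * factorial(n_a), factorial(2 * n))
        return num

    hets = range(rare % 2, rare + 1, 2)
    probs = {h: prob(h) for h in hets}
    p_obs = probs[n_ra]
    return float(min(1, sum(p for p in probs.values() if p <= p_obs)))


def ehh_pair_brute(alleles: np.ndarray, rows, focal: int, other: int) -> float:
    """EHH by enumerating all haplotype pairs: the fraction of pairs of
    ``rows`` identical over the inclusive variant span [focal..other]."""
    lo, hi = min(focal, other), max(focal, other)
    rows = list(rows)
    n_same = 0
    n_pairs = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            n_pairs += 1
            if np.array_equal(alleles[rows[i], lo:hi + 1],
                              alleles[rows[j], lo:hi + 1]):
                n_same += 1
    return n_same / n_pairs


def pi_pairwise_brute(alleles: np.ndarray) -> float:
    """Sum over sites of mean pairwise differences, by explicit pair loops."""
    n = alleles.shape[0]
    total = 0.0
    n_pairs = n * (n - 1) / 2
    for i in range(n):
        for j in range(i + 1, n):
            total += int((alleles[i] != alleles[j]).sum())
    return total / n_pairs


def wc_fst_brute(g1: np.ndarray, g2: np.ndarray) -> float:
    """Weir & Cockerham (1984) ratio-of-sums Fst for two populations,
    transcribed symbol by symbol from the published estimator (r = 2
    populations; missing genotypes coded -1 are excluded per site)."""
    assert g1.shape[1] == g2.shape[1]
    num_sum = 0.0
    den_sum = 0.0
    r = 2
    for s in range(g1.shape[1]):
        x1 = g1[:, s][g1[:, s] >= 0]
        x2 = g2[:, s][g2[:, s] >= 0]
        n1, n2 = len(x1), len(x2)
        if n1 < 1 or n2 < 1:
            continue
        p1 = x1.sum() / (2 * n1)
        p2 = x2.sum() / (2 * n2)
        h1 = (x1 == 1).sum() / n1
        h2 = (x2 == 1).sum() / n2
        n_bar = (n1 + n2) / r
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - (n1 ** 2 + n2 ** 2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        if n_c == 0:
            continue
        a = (n_bar / n_c) * (s2 - (1 / (n_bar - 1)) *
                             (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2
                                     - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2
        num_sum += a
        den_sum += a + b + c
    return num_sum / den_sum if den_sum > 0 else float("nan")


def roh_segments_brute(gv: np.ndarray, pos: np.ndarray, *, window: int = 100,
                       het_allowed: int = 3, miss_allowed: int = 5,
                       hit_fraction: float = 0.05, min_snps: int = 100,
                       density_bp_per_snp: float = 50_000.0,
                       max_gap_bp: int = 1_000_000):
    """Literal rule-by-rule ROH scan: enumerate every window, apply the
    window-homozygosity rule, per-SNP hit rates, run splitting and filters.

    Returns (start, end, n_hom_snps) tuples with 0-based half-open bp.
    """
    n = len(gv)
    if n < window:
        return []
    hom_windows = []
    for w0 in range(n - window + 1):
        chunk = gv[w0:w0 + window]
        n_het = int((chunk == 1).sum())
        n_miss = int((chunk == -1).sum())
        hom_windows.append(n_het <= het_allowed and n_miss <= miss_allowed)
    in_run = []
    for i in range(n):
        overlapping = [w for w in range(max(0, i - window + 1),
                                        min(i, n - window) + 1)]
        hits = sum(1 for w in overlapping if hom_windows[w])
        in_run.append(hits / len(overlapping) >= hit_fraction)
    # consecutive in-run indices, split at bp gaps
    segments = []
    run = []
    for i in range(n):
        if in_run[i]:
            if run and pos[i] - pos[run[-1]] > max_gap_bp:
                segments.append(run)
                run = []
            run.append(i)
        else:
            if run:
                segments.append(run)
                run = []
    if run:
        segments.append(run)
    out = []
    for seg in segments:
        n_hom = sum(1 for i in seg if gv[i] in (0, 2))
        if n_hom < min_snps:
            continue
        start = int(pos[seg[0]]) - 1
        end = int(pos[seg[-1]])
        if (end - start) / n_hom > density_bp_per_snp:
            continue
        out.append((start, end, n_hom))
    return out
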