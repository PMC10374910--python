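"""Numba kernels for the extended-haplotype-homozygosity walks.

The walk refines a partition of the member haplotypes SNP by SNP away from
the focal site; EHH at each step is the probability that two distinct
member haplotypes fall in the same partition cell,
``sum_c n_c(n_c-1) / (m(m-1))``. ``ehh_arm`` returns the decay curve for
one arm; the ``*_kernel`` functions integrate both arms (trapezoid over bp)
for every SNP of a panel in one pass.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def ehh_arm(H, rows, init_labels, focal, last, step, pos, max_gap, floor):
    """Walk from ``focal`` toward ``last`` (inclusive) in direction ``step``.

    Returns (variant indices, EHH values) including the focal point first.
    Stops at the chromosome bound, when EHH drops below ``floor`` (the
    crossing point is kept), or before an inter-SNP gap > ``max_gap`` bp.
    """
    m = len(rows)
    cap = abs(last - focal) + 1
    idxs = np.empty(cap, np.int64)
    ehhs = np.empty(cap, np.float64)
    labels = init_labels.copy()
    counts = np.zeros(m, np.int64)
    for i in range(m):
        counts[labels[i]] += 1
    denom = m * (m - 1)
    s = 0
    for c in counts:
        s += c * (c - 1)
    e = s / denom
    idxs[0] = focal
    ehhs[0] = e
    k = 1
    j = focal
    if e < floor or e == 0.0:
        return idxs[:1], ehhs[:1]
    remap = np.empty(2 * m, np.int64)
    while j != last:
        nxt = j + step
        gap = pos[nxt] - pos[j] if step > 0 else pos[j] - pos[nxt]
        if gap > max_gap:
            break
        for i in range(2 * m):
            remap[i] = -1
        nlab = 0
        for i in range(m):
            counts[i] = 0
        for i in range(m):
            key = 2 * labels[i] + H[rows[i], nxt]
            v = remap[key]
            if v == -1:
                remap[key] = nlab
                v = nlab
                nlab += 1
            labels[i] = v
            counts[v] += 1
        s = 0
        for ci in range(nlab):
            s += counts[ci] * (counts[ci] - 1)
        e = s / denom
        idxs[k] = nxt
        ehhs[k] = e
        k += 1
        j = nxt
        if e < floor or e == 0.0:
            break
    return idxs[:k], ehhs[:k]


@njit(cache=True)
def _walk_integral(H, rows, init_labels, focal, last, step, pos, max_gap,
                   floor, labels, counts, remap):
    """Trapezoidal integral of one EHH arm on the raw (unnormalized) scale.

    ``labels``/``counts``/``remap`` are scratch buffers of sizes m, m, 2m.
    """
    m = len(rows)
    for i in range(m):
        labels[i] = init_labels[i]
        counts[i] = 0
    for i in range(m):
        counts[labels[i]] += 1
    denom = m * (m - 1)
    s = 0
    for i in range(m):
        s += counts[i] * (counts[i] - 1)
    e = s / denom
    if e < floor or e == 0.0:
        return 0.0
    total = 0.0
    prev_e = e
    prev_pos = pos[focal]
    j = focal
    while j != last:
        nxt = j + step
        gap = pos[nxt] - pos[j] if step > 0 else pos[j] - pos[nxt]
        if gap > max_gap:
            break
        for i in range(2 * m):
            remap[i] = -1
        nlab = 0
        for i in range(m):
            counts[i] = 0
        for i in range(m):
            key = 2 * labels[i] + H[rows[i], nxt]
            v = remap[key]
            if v == -1:
                remap[key] = nlab
                v = nlab
                nlab += 1
            labels[i] = v
            counts[v] += 1
        s = 0
        for ci in range(nlab):
            s += counts[ci] * (counts[ci] - 1)
        e = s / denom
        d = pos[nxt] - prev_pos if step > 0 else prev_pos - pos[nxt]
        total += d * (e + prev_e) / 2.0
        prev_e = e
        prev_pos = pos[nxt]
        j = nxt
        if e < floor or e == 0.0:
            break
    return total


@njit(cache=True)
def ihs_ihh_kernel(H, anc_allele, chrom_lo, chrom_hi, pos, max_gap, floor):
    """Per-SNP iHH for ancestral- and derived-allele carriers."""
    n_hap, n_var = H.shape
    ihh_a = np.full(n_var, np.nan)
    ihh_d = np.full(n_var, np.nan)
    rows_a = np.empty(n_hap, np.int64)
    rows_d = np.empty(n_hap, np.int64)
    zeros = np.zeros(n_hap, np.int64)
    labels = np.empty(n_hap, np.int64)
    counts = np.empty(n_hap, np.int64)
    remap = np.empty(2 * n_hap, np.int64)
    for j in range(n_var):
        na = 0
        nd = 0
        a = anc_allele[j]
        for h in range(n_hap):
            if H[h, j] == a:
                rows_a[na] = h
                na += 1
            else:
                rows_d[nd] = h
                nd += 1
        if na < 2 or nd < 2:
            continue
        ihh_a[j] = (_walk_integral(H, rows_a[:na], zeros[:na], j, chrom_lo[j],
                                   -1, pos, max_gap, floor, labels, counts, remap)
                    + _walk_integral(H, rows_a[:na], zeros[:na], j, chrom_hi[j],
                                     1, pos, max_gap, floor, labels, counts, remap))
        ihh_d[j] = (_walk_integral(H, rows_d[:nd], zeros[:nd], j, chrom_lo[j],
                                   -1, pos, max_gap, floor, labels, counts, remap)
                    + _walk_integral(H, rows_d[:nd], zeros[:nd], j, chrom_hi[j],
                                     1, pos, max_gap, floor, labels, counts, remap))
    return ihh_a, ihh_d


@njit(cache=True)
def ies_kernel(H, chrom_lo, chrom_hi, pos, max_gap, floor):
    """Per-SNP site-EHH integrals over all haplotypes.

    Returns (iES normalized to 1 at the focal SNP, focal homozygosity e0).
    The floor applies on the normalized scale (truncation at
    EHHS/EHHS(0) < floor).
    """
    n_hap, n_var = H.shape
    ies = np.full(n_var, np.nan)
    e0s = np.full(n_var, np.nan)
    rows = np.arange(n_hap)
    init = np.empty(n_hap, np.int64)
    labels = np.empty(n_hap, np.int64)
    counts = np.empty(n_hap, np.int64)
    remap = np.empty(2 * n_hap, np.int64)
    denom = n_hap * (n_hap - 1)
    for j in range(n_var):
        n1 = 0
        for h in range(n_hap):
            init[h] = H[h, j]
            n1 += H[h, j]
        e0 = (n1 * (n1 - 1) + (n_hap - n1) * (n_hap - n1 - 1)) / denom
        if e0 == 0.0:
            continue
        raw = (_walk_integral(H, rows, init, j, chrom_lo[j], -1, pos,
                              max_gap, floor * e0, labels, counts, remap)
               + _walk_integral(H, rows, init, j, chrom_hi[j], 1, pos,
                                max_gap, floor * e0, labels, counts, remap))
        ies[j] = raw / e0
        e0s[j] = e0
    return ies, e0s
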