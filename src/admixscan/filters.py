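"""Variant and sample preparation: quality filters, LD pruning, relatedness,
ancestral-allele assignment.

These reproduce the usual VCFtools/PLINK preparation semantics: a hard MAF
cut, per-variant missingness, an exact Hardy-Weinberg test, a site-quality
floor, greedy windowed ``indep-pairwise`` LD pruning and method-of-moments
PI_HAT relatedness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .panel import GenotypePanel


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed
    that of the observed configuration (plain tail sum, no mid-p).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("at least one genotype required")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_ref, n_alt)
    if rare == 0:
        return 1.0
    # P(het = h | allele counts) ∝ exp(logp(h)); h has the parity of `rare`
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (n_ref - hets) // 2
    hom_a = (n_alt - hets) // 2
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(hom_r + 1) - gammaln(hom_a + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.nonzero(hets == n_het)[0][0]]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_pvalues(g: GenotypePanel) -> np.ndarray:
    gt = g.genotypes
    n_rr = (gt == 0).sum(axis=0)
    n_ra = (gt == 1).sum(axis=0)
    n_aa = (gt == 2).sum(axis=0)
    out = np.ones(g.n_variants)
    for j in range(g.n_variants):
        tot = n_rr[j] + n_ra[j] + n_aa[j]
        out[j] = hwe_exact_test(int(n_rr[j]), int(n_ra[j]), int(n_aa[j])) \
            if tot >= 1 else 1.0
    return out


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    removed_maf: int
    removed_missing: int
    removed_hwe: int
    removed_qual: int


def apply_variant_filters(g: GenotypePanel, maf_min: float = 0.1,
                          miss_max: float = 0.1, hwe_p_min: float = 0.01,
                          qual_min: float = 100.0,
                          hwe_panel: GenotypePanel | None = None):
    """Keep variants passing all of MAF/missingness/HWE/quality.

    Returns ``(filtered_panel, FilterReport)``; removal counts are tallied
    per filter independently (a variant may fail several). ``hwe_panel``
    restricts the Hardy-Weinberg test to one population's genotypes (same
    variant axis) — pooling diverged populations violates HWE by
    construction (Wahlund effect).
    """
    maf = g.maf()
    ok_maf = ~(maf < maf_min)  # NaN-frequency (all-missing) sites fail missingness
    ok_miss = g.missing_fraction() <= miss_max
    ok_hwe = hwe_pvalues(hwe_panel if hwe_panel is not None else g) >= hwe_p_min
    ok_qual = g.variants["qual"].to_numpy() >= qual_min
    keep = ok_maf & ok_miss & ok_hwe & ok_qual & ~np.isnan(maf)
    report = FilterReport(
        n_input=g.n_variants, n_kept=int(keep.sum()),
        removed_maf=int((~ok_maf).sum()), removed_missing=int((~ok_miss).sum()),
        removed_hwe=int((~ok_hwe).sum()), removed_qual=int((~ok_qual).sum()))
    if report.n_kept == 0:
        warnings.warn("variant filtering removed every variant")
    return g.take_variants(np.nonzero(keep)[0]), report


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared genotype correlation, pairwise-complete over missing calls."""
    ok = (x != -1) & (y != -1)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy)
    return float(r * r)


def ld_prune(g: GenotypePanel, window_snps: int = 20, step_snps: int = 4,
             r2_max: float = 0.6) -> np.ndarray:
    """Greedy windowed LD pruning (PLINK ``--indep-pairwise`` semantics).

    Slides a ``window_snps`` window by ``step_snps`` within each chromosome;
    whenever two surviving variants in a window have genotype r² > r2_max,
    the one with the lower MAF (tie: the later position) is pruned.
    Returns the surviving variant indices, order preserved.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must be in (0, 1]")
    if g.n_variants < 2:
        return np.arange(g.n_variants)
    maf = g.maf()
    gt = g.genotypes
    removed = np.zeros(g.n_variants, dtype=bool)
    chroms = g.variants["chrom"].to_numpy()
    bounds = []
    s = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[s]:
            bounds.append((s, i))
            s = i
    for lo, hi in bounds:
        w = lo
        while True:
            w_hi = min(w + window_snps, hi)
            live = [j for j in range(w, w_hi) if not removed[j]]
            block = gt[:, live]
            r2mat = None
            if len(live) >= 2 and not (block == -1).any():
                x = block.astype(float)
                with np.errstate(invalid="ignore"):
                    r2mat = np.corrcoef(x.T) ** 2
                r2mat = np.nan_to_num(r2mat)  # monomorphic columns -> r2 = 0
            for ai in range(len(live)):
                a = live[ai]
                if removed[a]:
                    continue
                for bi in range(ai + 1, len(live)):
                    b = live[bi]
                    if removed[a] or removed[b]:
                        continue
                    r2 = (r2mat[ai, bi] if r2mat is not None
                          else _pairwise_r2(gt[:, a], gt[:, b]))
                    if r2 > r2_max:
                        if maf[a] < maf[b]:
                            removed[a] = True
                        elif maf[b] < maf[a]:
                            removed[b] = True
                        else:  # equal MAF: drop the later position
                            removed[b] = True
            if w_hi >= hi:
                break
            w += step_snps
    return np.nonzero(~removed)[0]


@dataclass
class PihatEstimate:
    pihat: float
    p_ibd: tuple[float, float, float]
    n_sites: int
    low_information: bool  # fewer than 50 informative sites


def pihat_relatedness(g: GenotypePanel, sample_a: str, sample_b: str) -> PihatEstimate:
    """Method-of-moments genome-wide IBD sharing (PLINK's PI_HAT).

    Expected identity-by-state counts under IBD state 0/1/2, computed from
    whole-panel allele frequencies, are inverted to P(IBD=0,1,2); the result
    is truncated to [0, 1] and renormalised. PI_HAT = P(IBD2) + P(IBD1)/2.
    """
    ia, ib = g.sample_rows([sample_a, sample_b])
    ga = g.genotypes[ia]
    gb = g.genotypes[ib]
    p = g.alt_frequency()
    ok = (ga != -1) & (gb != -1) & ~np.isnan(p) & (p > 0) & (p < 1)
    ga, gb, p = ga[ok].astype(int), gb[ok].astype(int), p[ok]
    q = 1.0 - p
    n = len(p)
    ibs = 2 - np.abs(ga - gb)
    ibs0_obs = float((ibs == 0).sum())
    ibs1_obs = float((ibs == 1).sum())
    # expected per-site IBS probabilities given IBD state
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e1_ibs1 = 2 * p * q
    if n == 0 or e0_ibs0.sum() == 0:
        raise ValueError("no informative sites for PI_HAT")
    p0 = ibs0_obs / e0_ibs0.sum()
    p1 = (ibs1_obs - p0 * e0_ibs1.sum()) / e1_ibs1.sum()
    p2 = 1.0 - p0 - p1
    probs = np.clip([p0, p1, p2], 0.0, 1.0)
    total = probs.sum()
    probs = probs / total if total > 0 else np.array([1.0, 0.0, 0.0])
    return PihatEstimate(pihat=float(probs[2] + 0.5 * probs[1]),
                         p_ibd=tuple(float(x) for x in probs),
                         n_sites=n, low_information=n < 50)


def relatedness_matrix(g: GenotypePanel) -> np.ndarray:
    """Symmetric PI_HAT matrix over all sample pairs (diagonal = 1)."""
    n = g.n_samples
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pihat_relatedness(
                g, g.samples[i], g.samples[j]).pihat
    return m


def prune_related_samples(g: GenotypePanel, pihat_max: float = 0.05):
    """Drop one sample from each pair with PI_HAT above the threshold.

    Greedy: repeatedly remove the sample involved in the most over-threshold
    pairs (tie: later panel order), mirroring the usual PLINK workflow.
    Returns (kept sample list, PI_HAT matrix).
    """
    m = relatedness_matrix(g)
    active = np.ones(g.n_samples, dtype=bool)
    over = (m > pihat_max) & ~np.eye(g.n_samples, dtype=bool)
    while True:
        counts = (over & active[None, :] & active[:, None]).sum(axis=1)
        counts[~active] = 0
        if counts.max() == 0:
            break
        worst = int(np.nonzero(counts == counts.max())[0][-1])
        active[worst] = False
    return [s for s, a in zip(g.samples, active) if a], m


def assign_ancestral_alleles(g: GenotypePanel) -> GenotypePanel:
    """Set ancestral = dataset-wide majority allele (ties: the REF allele).

    Returns a panel whose variant table carries the updated
    ``ancestral_is_alt`` flags; DAF = 1 - freq(ancestral allele).
    """
    f_alt = g.alt_frequency()
    variants = g.variants.copy()
    variants["ancestral_is_alt"] = f_alt > 0.5
    out = GenotypePanel(variants, g.genotypes, list(g.samples), g.panel)
    return out


def derived_allele_frequency(variants, alt_freq: np.ndarray) -> np.ndarray:
    anc_alt = variants["ancestral_is_alt"].to_numpy()
    return np.where(anc_alt, 1.0 - alt_freq, alt_freq)
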