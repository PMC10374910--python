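"""Extended-haplotype-homozygosity scans: EHH/EHHS decay, iHS, Rsb, XP-EHH.

Scores are transformed to two-sided -log10 p values assuming a standard
Gaussian null: p = -log10[1 - 2|Phi(x) - 0.5|] = -log10[2(1 - Phi(|x|))].
Walks truncate at chromosome ends, when EHH falls below ``ehh_floor``
(default 0.05), or at inter-SNP gaps wider than ``max_gap`` (default
500 kb). Integration is trapezoidal over physical distance in bp.

Sign convention for the cross-population statistics: positive standardized
Rsb/XP-EHH means longer haplotypes in the target population, i.e. selection
in the target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._ehh_kernels import ehh_arm, ies_kernel, ihs_ihh_kernel
from .panel import HaplotypePanel, WindowGrid

MAX_GAP_BP = 500_000
EHH_FLOOR = 0.05
P_THRESHOLD = 6.0
MIN_OUTLIER_SNPS = 5


def neglog10_two_sided(score) -> np.ndarray:
    """-log10[1 - 2|Phi(x) - 0.5|], computed stably for large |x|."""
    s = np.abs(np.asarray(score, dtype=float))
    return -(np.log(2.0) + norm.logsf(s)) / np.log(10.0)


@dataclass
class EhhDecay:
    """EHH decay around one focal SNP, per carrier class.

    Each arm is a pair of arrays (variant indices, EHH values) starting at
    the focal SNP; values for the pooled class ("all") are normalized to 1
    at the focal SNP (site-EHH, Tang-style) unless stated otherwise.
    """

    focal_index: int
    arms: dict  # class -> {"left": (idx, ehh), "right": (idx, ehh)}


class _PanelView:
    """Cached arrays for repeated per-SNP walks over one panel."""

    def __init__(self, panel: HaplotypePanel):
        self.alleles = panel.alleles
        self.pos = panel.variants["pos"].to_numpy().astype(np.int64)
        self.anc_alt = panel.variants["ancestral_is_alt"].to_numpy()
        n = len(self.pos)
        self.chrom_lo = np.empty(n, np.int64)
        self.chrom_hi = np.empty(n, np.int64)
        for s in panel.chrom_slices().values():
            self.chrom_lo[s] = s.start
            self.chrom_hi[s] = s.stop - 1

    def class_rows(self, focal: int, carrier_class: str) -> np.ndarray:
        allele = self.alleles[:, focal]
        anc_allele = 1 if self.anc_alt[focal] else 0
        if carrier_class == "ancestral":
            return np.nonzero(allele == anc_allele)[0].astype(np.int64)
        if carrier_class == "derived":
            return np.nonzero(allele != anc_allele)[0].astype(np.int64)
        if carrier_class == "all":
            return np.arange(self.alleles.shape[0], dtype=np.int64)
        raise ValueError(f"unknown carrier class {carrier_class!r}")

    def arms(self, focal: int, carrier_class: str, max_gap: int,
             ehh_floor: float, normalize: bool):
        rows = self.class_rows(focal, carrier_class)
        if len(rows) < 2:
            return None  # score undefined at this SNP
        if carrier_class == "all":
            init = self.alleles[rows, focal].astype(np.int64)
            e0 = _partition_ehh(init)
            if e0 == 0.0:
                return None
            floor = ehh_floor * e0 if normalize else ehh_floor
        else:
            init = np.zeros(len(rows), np.int64)
            e0 = 1.0
            floor = ehh_floor
        left = ehh_arm(self.alleles, rows, init, focal, self.chrom_lo[focal],
                       -1, self.pos, max_gap, floor)
        right = ehh_arm(self.alleles, rows, init, focal, self.chrom_hi[focal],
                        1, self.pos, max_gap, floor)
        if carrier_class == "all" and normalize:
            left = (left[0], left[1] / e0)
            right = (right[0], right[1] / e0)
        return {"left": left, "right": right}

    def ihh(self, focal: int, carrier_class: str, max_gap: int,
            ehh_floor: float, normalize: bool = True):
        arms = self.arms(focal, carrier_class, max_gap, ehh_floor, normalize)
        if arms is None:
            return None
        total = 0.0
        p0 = self.pos[focal]
        for side in ("left", "right"):
            idx, e = arms[side]
            if len(idx) >= 2:
                d = np.abs(self.pos[idx] - p0).astype(float)
                total += float(np.trapezoid(e, d))
        return total


def ehh_at(panel: HaplotypePanel, focal_index: int, carrier_class: str,
           max_gap: int = MAX_GAP_BP, ehh_floor: float = EHH_FLOOR,
           normalize: bool = True):
    """EHH decay arms for one carrier class at one focal SNP.

    For "ancestral"/"derived" the focal allele is shared by the whole class,
    so EHH(focal) = 1. For "all" (EHHS) the partition starts split by the
    focal allele; with ``normalize`` the curve is rescaled to 1 at the focal
    SNP and the floor applies on the normalized scale.
    """
    return _PanelView(panel).arms(focal_index, carrier_class, max_gap,
                                  ehh_floor, normalize)


def _partition_ehh(labels: np.ndarray) -> float:
    m = len(labels)
    _, counts = np.unique(labels, return_counts=True)
    return float((counts * (counts - 1)).sum() / (m * (m - 1)))


def ehh_decay(panel: HaplotypePanel, focal_index: int, **kw) -> EhhDecay:
    arms = {}
    for cls in ("ancestral", "derived", "all"):
        a = ehh_at(panel, focal_index, cls, **kw)
        if a is not None:
            arms[cls] = a
    return EhhDecay(focal_index, arms)


def integrate_ihh(arms, pos: np.ndarray, focal_index: int) -> float:
    """Trapezoidal integral of both EHH arms over physical distance (bp)."""
    total = 0.0
    p0 = pos[focal_index]
    for side in ("left", "right"):
        idx, e = arms[side]
        if len(idx) < 2:
            continue
        d = np.abs(pos[idx] - p0).astype(float)
        total += float(np.trapezoid(e, d))
    return total


def ehhs_at(panel: HaplotypePanel, focal_index: int, **kw):
    """Site-EHH (pooled over alleles) decay arms; see :func:`ehh_at`."""
    return ehh_at(panel, focal_index, "all", **kw)


def integrate_ies(panel: HaplotypePanel, focal_index: int,
                  max_gap: int = MAX_GAP_BP, ehh_floor: float = EHH_FLOOR,
                  normalize: bool = True):
    """iES: trapezoidal integral of EHHS over both arms (bp units)."""
    return _PanelView(panel).ihh(focal_index, "all", max_gap, ehh_floor,
                                 normalize)


# ---------------------------------------------------------------------------
# scans


def _daf(panel: HaplotypePanel) -> np.ndarray:
    f_alt = panel.alleles.mean(axis=0)
    anc_alt = panel.variants["ancestral_is_alt"].to_numpy()
    return np.where(anc_alt, 1.0 - f_alt, f_alt)


def ihs_scan(panel: HaplotypePanel, max_gap: int = MAX_GAP_BP,
             ehh_floor: float = EHH_FLOOR, daf_bin_width: float = 0.05,
             min_bin_snps: int = 10) -> pd.DataFrame:
    """Within-population iHS scan.

    raw iHS = ln(iHH_ancestral / iHH_derived), standardized to mean 0 / sd 1
    within derived-allele-frequency bins, then transformed to two-sided
    -log10 p. Monomorphic SNPs and SNPs with an undefined or zero integral
    are reported with a ``reason`` code and NaN scores.
    """
    daf = _daf(panel)
    n = panel.n_variants
    view = _PanelView(panel)
    anc_allele = np.where(view.anc_alt, 1, 0).astype(np.uint8)
    ihh_a, ihh_d = ihs_ihh_kernel(panel.alleles, anc_allele, view.chrom_lo,
                                  view.chrom_hi, view.pos, max_gap, ehh_floor)
    raw = np.full(n, np.nan)
    reason = np.array([""] * n, dtype=object)
    mono = ~((daf > 0.0) & (daf < 1.0))
    small = np.isnan(ihh_a) & ~mono
    zero = (~np.isnan(ihh_a)) & ((ihh_a == 0.0) | (ihh_d == 0.0))
    ok = ~mono & ~small & ~zero
    reason[mono] = "monomorphic"
    reason[small] = "class_too_small"
    reason[zero] = "zero_ihh"
    raw[ok] = np.log(ihh_a[ok] / ihh_d[ok])
    ihh_a = np.where(ok, ihh_a, np.nan)
    ihh_d = np.where(ok, ihh_d, np.nan)
    std = _standardize_by_daf(raw, daf, daf_bin_width, min_bin_snps)
    out = pd.DataFrame({
        "chrom": panel.variants["chrom"], "pos": panel.variants["pos"],
        "daf": daf, "ihh_a": ihh_a, "ihh_d": ihh_d, "raw": raw, "std": std,
        "neglog10p": np.where(np.isnan(std), np.nan, neglog10_two_sided(std)),
        "reason": reason})
    return out


def _standardize_by_daf(raw: np.ndarray, daf: np.ndarray, width: float,
                        min_bin_snps: int) -> np.ndarray:
    """Bin by DAF (bins of ``width``); merge under-filled bins rightward."""
    ok = ~np.isnan(raw)
    n_bins = int(np.ceil(1.0 / width))
    bin_of = np.minimum((daf / width).astype(int), n_bins - 1)
    counts = np.bincount(bin_of[ok], minlength=n_bins)
    # merge: map each raw bin to a merged-bin id, accumulating rightward
    merged_id = np.zeros(n_bins, dtype=int)
    cur, acc = 0, 0
    for b in range(n_bins):
        merged_id[b] = cur
        acc += counts[b]
        if acc >= min_bin_snps:
            cur += 1
            acc = 0
    if acc > 0 and cur > 0:  # trailing underfull bin joins the previous one
        merged_id[merged_id == cur] = cur - 1
    std = np.full(len(raw), np.nan)
    groups = merged_id[bin_of]
    for gid in np.unique(groups[ok]):
        sel = ok & (groups == gid)
        mu = raw[sel].mean()
        sd = raw[sel].std()
        std[sel] = (raw[sel] - mu) / sd if sd > 0 else 0.0
    return std


def site_ies_table(panel: HaplotypePanel, max_gap: int = MAX_GAP_BP,
                   ehh_floor: float = EHH_FLOOR):
    """Per-SNP site-EHH integrals: (iES normalized at the focal SNP, focal
    homozygosity e0). The unnormalized (Sabeti-style) integral is their
    product."""
    view = _PanelView(panel)
    ies, e0 = ies_kernel(panel.alleles, view.chrom_lo, view.chrom_hi,
                         view.pos, max_gap, ehh_floor)
    ies[ies <= 0] = np.nan
    return ies, e0


def _standardize_genomewide(raw: np.ndarray, center: str = "median") -> np.ndarray:
    ok = ~np.isnan(raw)
    if not ok.any():
        return raw.copy()
    c = np.median(raw[ok]) if center == "median" else raw[ok].mean()
    sd = raw[ok].std()
    if sd == 0:
        out = np.where(ok, 0.0, np.nan)
        return out
    return (raw - c) / sd


def _cross_population_scan(panel_target: HaplotypePanel,
                           panel_reference: HaplotypePanel,
                           normalize_ehhs: bool, max_gap: int,
                           ehh_floor: float, center: str,
                           ies_target=None, ies_reference=None) -> pd.DataFrame:
    if not panel_target.variants[["chrom", "pos"]].equals(
            panel_reference.variants[["chrom", "pos"]]):
        raise ValueError("target and reference panels must share the variant axis")
    nt, e0t = (site_ies_table(panel_target, max_gap, ehh_floor)
               if ies_target is None else ies_target)
    nr, e0r = (site_ies_table(panel_reference, max_gap, ehh_floor)
               if ies_reference is None else ies_reference)
    ies_t = nt if normalize_ehhs else nt * e0t
    ies_r = nr if normalize_ehhs else nr * e0r
    with np.errstate(invalid="ignore"):
        raw = np.where(np.isnan(ies_t) | np.isnan(ies_r), np.nan,
                       np.log(ies_t / ies_r))
    std = _standardize_genomewide(raw, center)
    return pd.DataFrame({
        "chrom": panel_target.variants["chrom"],
        "pos": panel_target.variants["pos"],
        "daf": _daf(panel_target),
        "ies_target": ies_t, "ies_reference": ies_r,
        "raw": raw, "std": std,
        "neglog10p": np.where(np.isnan(std), np.nan, neglog10_two_sided(std))})


def rsb_scan(panel_target: HaplotypePanel, panel_reference: HaplotypePanel,
             max_gap: int = MAX_GAP_BP, ehh_floor: float = EHH_FLOOR,
             center: str = "median", ies_target=None,
             ies_reference=None) -> pd.DataFrame:
    """Rsb: ln(iES_target / iES_reference) with focal-normalized site-EHH,
    standardized genome-wide (median-centred by default)."""
    return _cross_population_scan(panel_target, panel_reference, True,
                                  max_gap, ehh_floor, center,
                                  ies_target, ies_reference)


def xpehh_scan(panel_target: HaplotypePanel, panel_reference: HaplotypePanel,
               max_gap: int = MAX_GAP_BP, ehh_floor: float = EHH_FLOOR,
               center: str = "median", framing: str = "site",
               ies_target=None, ies_reference=None) -> pd.DataFrame:
    """XP-EHH: cross-population log-ratio of integrated haplotype homozygosity.

    With the default "site" framing both populations integrate pooled-allele
    EHH from the focal SNP without focal normalization (Sabeti-style; the
    walk truncation is still relative to the focal homozygosity, so the
    integral equals e0 x the normalized iES); the "derived" framing
    integrates derived-carrier EHH in both populations.
    """
    if framing == "site":
        return _cross_population_scan(panel_target, panel_reference, False,
                                      max_gap, ehh_floor, center,
                                      ies_target, ies_reference)
    if framing != "derived":
        raise ValueError("framing must be 'site' or 'derived'")
    if not panel_target.variants[["chrom", "pos"]].equals(
            panel_reference.variants[["chrom", "pos"]]):
        raise ValueError("target and reference panels must share the variant axis")
    n = panel_target.n_variants
    ihh_t = np.full(n, np.nan)
    ihh_r = np.full(n, np.nan)
    vt, vr = _PanelView(panel_target), _PanelView(panel_reference)
    for j in range(n):
        a = vt.ihh(j, "derived", max_gap, ehh_floor)
        b = vr.ihh(j, "derived", max_gap, ehh_floor)
        if a and b:
            ihh_t[j], ihh_r[j] = a, b
    raw = np.log(ihh_t / ihh_r)
    std = _standardize_genomewide(raw, center)
    return pd.DataFrame({
        "chrom": panel_target.variants["chrom"],
        "pos": panel_target.variants["pos"],
        "daf": _daf(panel_target),
        "ies_target": ihh_t, "ies_reference": ihh_r,
        "raw": raw, "std": std,
        "neglog10p": np.where(np.isnan(std), np.nan, neglog10_two_sided(std))})


def classify_outlier_windows(scores: pd.DataFrame, grid: WindowGrid,
                             p_threshold: float = P_THRESHOLD,
                             min_snps: int = MIN_OUTLIER_SNPS) -> pd.DataFrame:
    """Flag windows containing >= ``min_snps`` SNPs with -log10 p exceeding
    ``p_threshold``; the sign summary is the median standardized score of
    the outlier SNPs in the window."""
    members = grid.assign(scores["chrom"].to_numpy(), scores["pos"].to_numpy())
    neglog = scores["neglog10p"].to_numpy()
    std = scores["std"].to_numpy()
    rows = []
    for (c, start, end), idx in zip(grid.windows.itertuples(index=False), members):
        out_mask = neglog[idx] > p_threshold
        n_out = int(np.nansum(out_mask))
        sign = float(np.median(std[idx][out_mask])) if n_out else np.nan
        rows.append((c, start, end, len(idx), n_out, n_out >= min_snps, sign))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       "n_outliers", "flagged", "sign"])


def relaxed_replication_preset(chrom_lengths: dict[str, int]):
    """The relaxed scheme: 1-Mb sliding windows with 500-kb step, threshold
    -log10 p = 4, a single outlier SNP sufficing."""
    from .panel import build_window_grid
    grid = build_window_grid(chrom_lengths, 1_000_000, 500_000)
    return {"grid": grid, "p_threshold": 4.0, "min_snps": 1}
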