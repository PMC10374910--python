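"""Runs of homozygosity: sliding-window detection and ROH islands.

The detector follows the PLINK ``--homozyg`` semantics: slide a window of
``window_size_snps`` SNPs one SNP at a time; a window is homozygous if it
contains at most ``window_het_allowed`` heterozygous and
``window_missing_allowed`` missing calls; a SNP belongs to a run when at
least ``window_hit_fraction`` of the windows overlapping it are homozygous.
Runs are split at inter-SNP gaps wider than ``max_gap_kb`` and must satisfy
the minimum-SNP and density constraints. Islands are intervals where the
per-bp coverage by individual ROH reaches ``island_threshold`` of samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel


@dataclass
class RohParams:
    min_snps: int = 100          # homozyg-snp
    density_kb_per_snp: float = 50.0  # homozyg-density
    max_gap_kb: float = 1000.0   # homozyg-gap
    window_het_allowed: int = 3  # homozyg-window-het
    window_missing_allowed: int = 5  # homozyg-window-missing
    window_size_snps: int = 100
    window_hit_fraction: float = 0.05  # PLINK homozyg-window-threshold default

    def __post_init__(self):
        if min(self.min_snps, self.window_size_snps) <= 0 or \
                self.density_kb_per_snp < 1 or self.max_gap_kb <= 0:
            raise ValueError("invalid ROH parameters")


def scan_roh(g: GenotypePanel, sample: str,
             params: RohParams | None = None) -> pd.DataFrame:
    """Per-individual ROH segments (chrom, 0-based half-open start/end).

    ``n_snps`` counts the homozygous non-missing calls inside the segment;
    missing and heterozygous calls never count toward the minimum-SNP or
    density requirements.
    """
    params = params or RohParams()
    row = g.sample_rows([sample])[0]
    chroms = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    segments = []
    for chrom in pd.unique(chroms):
        sel = np.nonzero(chroms == chrom)[0]
        gv = g.genotypes[row, sel]
        cpos = pos[sel]
        n = len(gv)
        w = params.window_size_snps
        if n < w:
            warnings.warn(f"chromosome {chrom} has fewer than {w} SNPs; skipped")
            continue
        het = (gv == 1).astype(np.int64)
        miss = (gv == -1).astype(np.int64)
        chet = np.concatenate([[0], np.cumsum(het)])
        cmiss = np.concatenate([[0], np.cumsum(miss)])
        n_win = n - w + 1
        win_het = chet[w:] - chet[:-w]
        win_miss = cmiss[w:] - cmiss[:-w]
        hom_win = ((win_het <= params.window_het_allowed)
                   & (win_miss <= params.window_missing_allowed)).astype(np.int64)
        chom = np.concatenate([[0], np.cumsum(hom_win)])
        i = np.arange(n)
        lo = np.maximum(0, i - w + 1)
        hi = np.minimum(i, n_win - 1)
        total = hi - lo + 1
        hits = chom[hi + 1] - chom[lo]
        in_run = hits / total >= params.window_hit_fraction
        segments.extend(_runs_to_segments(
            in_run, gv, cpos, chrom, sample, params))
    return pd.DataFrame(segments, columns=["sample", "chrom", "start", "end",
                                           "n_snps", "length"])


def _runs_to_segments(in_run, gv, cpos, chrom, sample, params):
    max_gap = int(params.max_gap_kb * 1000)
    out = []
    idx = np.nonzero(in_run)[0]
    if len(idx) == 0:
        return out
    # split consecutive in-run SNP indices at index breaks or bp gaps
    breaks = np.nonzero((np.diff(idx) > 1)
                        | (np.diff(cpos[idx]) > max_gap))[0]
    for chunk in np.split(idx, breaks + 1):
        hom = (gv[chunk] == 0) | (gv[chunk] == 2)
        n_hom = int(hom.sum())
        if n_hom < params.min_snps:
            continue
        start = int(cpos[chunk[0]]) - 1
        end = int(cpos[chunk[-1]])
        length = end - start
        if length / n_hom > params.density_kb_per_snp * 1000:
            continue
        out.append((sample, chrom, start, end, n_hom, length))
    return out


def scan_roh_all(g: GenotypePanel, params: RohParams | None = None) -> pd.DataFrame:
    frames = [scan_roh(g, s, params) for s in g.samples]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample", "chrom", "start", "end", "n_snps", "length"])


def summarize_roh(segments: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Per-individual ROH count and cumulative length (Mb)."""
    rows = []
    samples = samples if samples is not None else sorted(
        segments["sample"].unique())
    for s in samples:
        sub = segments[segments["sample"] == s]
        rows.append((s, len(sub), sub["length"].sum() / 1e6))
    return pd.DataFrame(rows, columns=["sample", "n_roh", "total_mb"])


def roh_islands(segments: pd.DataFrame, n_samples: int,
                island_threshold: float = 0.30) -> pd.DataFrame:
    """Maximal intervals where ROH coverage reaches the threshold fraction.

    Coverage at a bp is the fraction of individuals whose ROH spans it; the
    reported island fraction is the minimum coverage across the island (the
    fraction guaranteed to share the whole interval).
    """
    if n_samples < 2:
        raise ValueError("need at least two samples for islands")
    rows = []
    for chrom in sorted(segments["chrom"].unique()):
        sub = segments[segments["chrom"] == chrom]
        rows.extend(_islands_from_steps(sub, chrom, n_samples, island_threshold))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "fraction"])


def _islands_from_steps(sub: pd.DataFrame, chrom, n_samples, threshold):
    edges = np.unique(np.concatenate([sub["start"].to_numpy(),
                                      sub["end"].to_numpy()]))
    if len(edges) < 2:
        return []
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    cov = np.zeros(len(edges) - 1, dtype=int)
    for s, e in zip(starts, ends):
        i0 = np.searchsorted(edges, s)
        i1 = np.searchsorted(edges, e)
        cov[i0:i1] += 1
    frac = cov / n_samples
    ok = frac >= threshold
    out = []
    i = 0
    while i < len(ok):
        if ok[i]:
            j = i
            while j + 1 < len(ok) and ok[j + 1]:
                j += 1
            out.append((chrom, int(edges[i]), int(edges[j + 1]),
                        float(frac[i:j + 1].min())))
            i = j + 1
        else:
            i += 1
    return out
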