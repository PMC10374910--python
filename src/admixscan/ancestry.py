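"""Local-ancestry dosage tracks, global summaries, and ancestry-excess windows.

Dosage tracks give, per SNP and admixed individual, the probability of
descending from each of the three source ancestries (AFT, EUT, IND). They
are consumed as input — either the simulator's truth or the output of an
external local-ancestry inference run (a 0–2 diploid scale is rescaled on
load).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import SOURCES, WindowGrid


@dataclass
class AncestryDosageTrack:
    variants: pd.DataFrame  # chrom, pos (aligned to the panel's variant axis)
    samples: list[str]
    dosages: np.ndarray  # (n_var, n_samples, 3) in SOURCES order, rows sum to 1
    source_tag: str = "truth"

    def __post_init__(self):
        d = np.asarray(self.dosages, dtype=float)
        if d.shape != (len(self.variants), len(self.samples), 3):
            raise ValueError("dosage array shape inconsistent")
        sums = d.sum(axis=2)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("ancestry dosages must sum to 1 per SNP per individual")
        self.dosages = d

    def take_variants(self, idx) -> "AncestryDosageTrack":
        idx = np.asarray(idx)
        return AncestryDosageTrack(self.variants.iloc[idx].reset_index(drop=True),
                                   list(self.samples), self.dosages[idx],
                                   self.source_tag)


def load_dosages(path, variants: pd.DataFrame, reorder: bool = True,
                 source_tag: str = "external-inference") -> AncestryDosageTrack:
    """Read a wide dosage TSV (chrom, pos, then ``sample:ANCESTRY`` columns).

    A 0–2 diploid scale is detected from the mean per-individual sum and
    halved; per-row sums outside [0.98, 1.02] after rescaling raise an error
    naming the row. Variant order is aligned to ``variants`` — reordered if
    ``reorder`` else an error — never silently misaligned.
    """
    df = pd.read_csv(path, sep="\t")
    sample_cols = [c for c in df.columns if ":" in c]
    samples = list(dict.fromkeys(c.split(":")[0] for c in sample_cols))
    d = np.empty((len(df), len(samples), 3))
    _warn_unrecognised_columns(samples, sample_cols)
    for si, s in enumerate(samples):
        for ai, a in enumerate(SOURCES):
            col = f"{s}:{a}"
            if col not in df.columns:
                raise ValueError(f"dosage file lacks column {col}")
            d[:, si, ai] = df[col].to_numpy()
    mean_sum = d.sum(axis=2).mean()
    if 1.5 <= mean_sum <= 2.5:
        d /= 2.0  # diploid 0–2 scale
    sums = d.sum(axis=2)
    bad = np.abs(sums - 1.0) > 0.02
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(f"dosage row {i} (sample {samples[j]}) sums to "
                         f"{sums[i, j]:.4f}, outside [0.98, 1.02]")
    d /= sums[:, :, None]  # exact renormalization

    key_file = list(zip(df["chrom"].astype(str), df["pos"].astype(int)))
    key_panel = list(zip(variants["chrom"].astype(str), variants["pos"].astype(int)))
    if key_file != key_panel:
        index = {k: i for i, k in enumerate(key_file)}
        missing = [k for k in key_panel if k not in index]
        if missing:
            raise ValueError(f"dosage file lacks {len(missing)} panel variants "
                             f"(first: {missing[0]})")
        if not reorder:
            raise ValueError("dosage variant order differs from panel order")
        order = np.array([index[k] for k in key_panel])
        d = d[order]
    return AncestryDosageTrack(variants[["chrom", "pos"]].reset_index(drop=True),
                               samples, d, source_tag)


def _warn_unrecognised_columns(samples, sample_cols):
    expected = {f"{s}:{a}" for s in samples for a in SOURCES}
    extra = set(sample_cols) - expected
    if extra:
        warnings.warn(f"ignoring unrecognised dosage columns: {sorted(extra)}")


def global_ancestry(track: AncestryDosageTrack):
    """Genome-wide and per-chromosome mean dosage per individual.

    Returns (genome_df, per_chrom_df); per-chromosome means are SNP-weighted
    so they average back to the genome-wide mean.
    """
    cols = [f"mean_{a}" for a in SOURCES]
    genome = pd.DataFrame(track.dosages.mean(axis=0), index=track.samples,
                          columns=cols)
    genome.index.name = "sample"
    rows = []
    chroms = track.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        m = track.dosages[sel].mean(axis=0)
        for si, s in enumerate(track.samples):
            rows.append((s, chrom, int(sel.sum()), *m[si]))
    per_chrom = pd.DataFrame(rows, columns=["sample", "chrom", "n_snps", *cols])
    return genome.reset_index(), per_chrom


def ancestry_window_means(track: AncestryDosageTrack,
                          grid: WindowGrid) -> pd.DataFrame:
    members = grid.assign(track.variants["chrom"].to_numpy(),
                          track.variants["pos"].to_numpy())
    rows = []
    for (c, start, end), idx in zip(grid.windows.itertuples(index=False),
                                    members):
        if len(idx) == 0:
            rows.append((c, start, end, 0, np.nan, np.nan, np.nan))
        else:
            m = track.dosages[idx].mean(axis=(0, 1))
            rows.append((c, start, end, len(idx), *m))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                       *(f"mean_{a}" for a in SOURCES)])


def ancestry_excess_windows(track: AncestryDosageTrack, grid: WindowGrid,
                            pct: float = 1.0,
                            margin_sd: float = 2.0) -> pd.DataFrame:
    """Per-window mean dosages with excess flags per ancestry.

    A window shows "sudden increase" of an ancestry when its mean exceeds
    the chromosome mean by ``margin_sd`` chromosome-level standard
    deviations of the window means, or when it is among the genome-wide top
    ``pct``% windows for that ancestry (either suffices).
    """
    df = ancestry_window_means(track, grid)
    from math import ceil
    n_windows = int(df["n_snps"].gt(0).sum())
    if n_windows < 100:
        warnings.warn(f"only {n_windows} windows with data for a {pct}% cut")
    for a in SOURCES:
        col = f"mean_{a}"
        vals = df[col].to_numpy()
        ok = np.isfinite(vals)
        top = np.zeros(len(df), bool)
        if ok.sum():
            n_top = ceil(pct / 100.0 * ok.sum())
            cut = np.sort(vals[ok])[::-1][n_top - 1]
            top[ok] = vals[ok] >= cut
        sudden = np.zeros(len(df), bool)
        for chrom in df["chrom"].unique():
            sel = (df["chrom"] == chrom).to_numpy() & ok
            if sel.sum() < 2:
                continue
            mu = vals[sel].mean()
            sd = vals[sel].std()
            # strict: a window equal to the chromosome mean (e.g. a uniform
            # track, sd = 0) shows no increase
            sudden[sel] = vals[sel] > mu + margin_sd * sd
        df[f"top_{a}"] = top
        df[f"sudden_{a}"] = sudden
        df[f"excess_{a}"] = top | sudden
    return df
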