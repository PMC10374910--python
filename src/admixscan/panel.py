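"""Core data containers for phased haplotype and genotype panels.

Coordinates follow the usual mixed convention: VCF positions are 1-based,
window intervals are 0-based half-open ``[start, end)`` (BED-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANCESTRY_GROUPS = ("TARGET", "AFT", "EUT", "IND", "OTHER")
#: The three source ancestries of the admixture model, in canonical order.
SOURCES = ("AFT", "EUT", "IND")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "ancestral_is_alt"]


def make_variant_table(chrom, pos, ref=None, alt=None, qual=None,
                       ancestral_is_alt=None) -> pd.DataFrame:
    """Assemble a variant table, validating the biallelic-SNP invariants."""
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    chrom = np.asarray(chrom if not np.isscalar(chrom) else [chrom] * n)
    ref = np.asarray(ref if ref is not None else ["A"] * n)
    alt = np.asarray(alt if alt is not None else ["C"] * n)
    qual = np.asarray(qual if qual is not None else np.full(n, 1000.0), dtype=float)
    anc = np.asarray(
        ancestral_is_alt if ancestral_is_alt is not None else np.zeros(n, bool))
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                       "qual": qual, "ancestral_is_alt": anc})
    _check_variants(df)
    return df


def _check_variants(df: pd.DataFrame) -> None:
    if (df["pos"] < 1).any():
        raise ValueError("variant positions must be >= 1 (1-based)")
    if (df["ref"] == df["alt"]).any():
        raise ValueError("ref and alt alleles must differ")
    bad = ~(df["ref"].str.len().eq(1) & df["alt"].str.len().eq(1))
    if bad.any():
        raise ValueError("only biallelic SNPs are allowed (single-nucleotide alleles)")
    for _, sub in df.groupby("chrom", sort=False):
        if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
            raise ValueError("variant positions must be strictly increasing per chromosome")


@dataclass
class SamplePanel:
    """Sample sheet: one row per sample with population and ancestry group."""

    table: pd.DataFrame  # columns: sample, population, group

    def __post_init__(self):
        t = self.table
        if t["sample"].duplicated().any():
            raise ValueError("duplicate sample ids in panel")
        bad = ~t["group"].isin(ANCESTRY_GROUPS)
        if bad.any():
            raise ValueError(f"unknown ancestry groups: {sorted(t.loc[bad, 'group'].unique())}")
        self.table = t.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample"])

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample"])

    @classmethod
    def read_tsv(cls, path) -> "SamplePanel":
        t = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"sample", "population", "group"} - set(t.columns)
        if missing:
            raise ValueError(f"panel file lacks columns: {sorted(missing)}")
        return cls(t[["sample", "population", "group"]])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypePanel:
    """Phased 0/1 allele matrix, shape (n_haplotypes, n_variants).

    Two consecutive rows per diploid sample; no missing entries.
    """

    variants: pd.DataFrame
    alleles: np.ndarray
    sample_of_haplotype: list[str]
    panel: SamplePanel | None = None

    def __post_init__(self):
        _check_variants(self.variants)
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotypes x variants)")
        if self.alleles.shape != (len(self.sample_of_haplotype), len(self.variants)):
            raise ValueError("allele matrix shape inconsistent with variants/haplotypes")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be 0/1 (phased, complete)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    @property
    def samples(self) -> list[str]:
        # preserve first-appearance order
        seen, out = set(), []
        for s in self.sample_of_haplotype:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    def haplotype_rows(self, samples: Iterable[str]) -> np.ndarray:
        wanted = set(samples)
        return np.array([i for i, s in enumerate(self.sample_of_haplotype)
                         if s in wanted], dtype=np.int64)

    def subset_group(self, group: str) -> "HaplotypePanel":
        """Haplotypes of all samples belonging to one ancestry group."""
        if self.panel is None:
            raise ValueError("no sample panel attached")
        rows = self.haplotype_rows(self.panel.samples_in_group(group))
        return HaplotypePanel(self.variants, self.alleles[rows],
                              [self.sample_of_haplotype[i] for i in rows], self.panel)

    def take_variants(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(self.variants.iloc[idx].reset_index(drop=True),
                              self.alleles[:, idx], list(self.sample_of_haplotype),
                              self.panel)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous variant-index slice per chromosome."""
        out: dict[str, slice] = {}
        chroms = self.variants["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out

    def to_genotypes(self) -> "GenotypePanel":
        n_hap, n_var = self.alleles.shape
        g = self.alleles.reshape(n_hap // 2, 2, n_var).sum(axis=1).astype(np.int8)
        return GenotypePanel(self.variants, g, self.samples, self.panel)


@dataclass
class GenotypePanel:
    """Diploid genotypes in {0, 1, 2}; -1 encodes a missing call."""

    variants: pd.DataFrame
    genotypes: np.ndarray  # (n_samples, n_variants), int8
    samples: list[str]
    panel: SamplePanel | None = None

    def __post_init__(self):
        _check_variants(self.variants)
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.samples), len(self.variants)):
            raise ValueError("genotype matrix shape inconsistent")
        if not np.isin(self.genotypes, (-1, 0, 1, 2)).all():
            raise ValueError("genotypes must be in {0,1,2} or -1 for missing")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def missing_fraction(self) -> np.ndarray:
        return (self.genotypes == -1).mean(axis=0)

    def alt_frequency(self) -> np.ndarray:
        """Per-variant ALT allele frequency over non-missing genotypes."""
        g = self.genotypes
        obs = g != -1
        called = obs.sum(axis=0)
        alt = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(called > 0, alt / (2.0 * called), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def sample_rows(self, samples: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in panel: {missing}")
        return np.array([index[s] for s in samples], dtype=np.int64)

    def subset_group(self, group: str) -> "GenotypePanel":
        if self.panel is None:
            raise ValueError("no sample panel attached")
        rows = self.sample_rows(self.panel.samples_in_group(group))
        return GenotypePanel(self.variants, self.genotypes[rows],
                             [self.samples[i] for i in rows], self.panel)

    def take_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(self.variants.iloc[idx].reset_index(drop=True),
                             self.genotypes[:, idx], list(self.samples), self.panel)


@dataclass
class WindowGrid:
    """Half-open genomic windows tiling each chromosome from coordinate 0."""

    scheme: str  # "nonoverlapping" | "sliding"
    width: int
    step: int
    windows: pd.DataFrame = field(repr=False)  # columns: chrom, start, end

    def __len__(self):
        return len(self.windows)

    def assign(self, chrom: np.ndarray, pos: np.ndarray) -> list[np.ndarray]:
        """For each window, indices of the (1-based) positions falling in it.

        Positions must be sorted within each chromosome (panel invariant).
        """
        chrom = np.asarray(chrom)
        pos0 = np.asarray(pos, dtype=np.int64) - 1  # 0-based for half-open test
        by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for c in pd.unique(chrom):
            idx = np.nonzero(chrom == c)[0]
            by_chrom[c] = (idx, pos0[idx])
        out = []
        for c, start, end in self.windows.itertuples(index=False):
            if c not in by_chrom:
                out.append(np.empty(0, dtype=np.int64))
                continue
            idx, p = by_chrom[c]
            lo, hi = np.searchsorted(p, [start, end])
            out.append(idx[lo:hi])
        return out


def build_window_grid(chrom_lengths: dict[str, int], width: int,
                      step: int | None = None) -> WindowGrid:
    """Tile chromosomes with half-open windows of ``width`` bp.

    ``step`` defaults to ``width`` (nonoverlapping); the terminal window is
    truncated at the chromosome end.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    step = width if step is None else step
    if step <= 0 or step > width:
        raise ValueError("step must be in (0, width]")
    rows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            rows.append((chrom, start, min(start + width, length)))
            start += step
    scheme = "nonoverlapping" if step == width else "sliding"
    return WindowGrid(scheme, width, step,
                      pd.DataFrame(rows, columns=["chrom", "start", "end"]))
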