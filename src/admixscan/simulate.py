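"""Synthetic three-way admixed haplotypes with truth ancestry and planted sweeps.

The generator emulates the study design the scans are meant for: three
diverged source ancestry groups (AFT, EUT, IND), a target population formed
by ~70 generations of admixture with configurable proportions, local LD in
the sources, and an optional hard selective sweep in which a haplotype of
one ancestry rises to high frequency in the target.

Source allele frequencies follow the Balding–Nichols model around a shared
base frequency; source haplotypes are drawn by a template-copying process
that induces block-wise LD; admixed haplotypes are ancestry mosaics with
Poisson tract breakpoints. The sweep is imposed by copy-replacement of a
donor haplotype over exponentially-decaying tract lengths centred on the
core — giving the characteristic geometry (long shared haplotypes, reduced
diversity, local ancestry excess, distorted SFS) without forward simulation.

All randomness flows from a single seed; identical seeds give identical
datasets (byte-identical emitted files).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SOURCES, HaplotypePanel, SamplePanel, make_variant_table
from .io import write_phased_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class AncestryModel:
    """Divergence model of the three source groups (Balding–Nichols F)."""

    divergence: dict[str, float] = field(
        default_factory=lambda: {"AFT": 0.1, "EUT": 0.1, "IND": 0.1})
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    n_haplotypes: dict[str, int] = field(
        default_factory=lambda: {"AFT": 20, "EUT": 20, "IND": 20})

    def __post_init__(self):
        for g, f in self.divergence.items():
            if not f >= 0:
                raise ValueError(f"divergence F must be >= 0 (group {g})")
        lo, hi = self.base_freq_range
        if not (0 < lo < hi < 1):
            raise ValueError("base frequencies must be bounded away from 0/1")


@dataclass
class AdmixtureConfig:
    """Target population: ancestry proportions and admixture age."""

    proportions: dict[str, float] = field(
        default_factory=lambda: {"AFT": 0.35, "EUT": 0.29, "IND": 0.36})
    generations: int = 70
    recomb_rate_per_bp: float = 1e-8  # 1 cM/Mb
    n_admixed: int = 20  # diploid individuals

    def __post_init__(self):
        if abs(sum(self.proportions.values()) - 1.0) > 1e-9:
            raise ValueError("ancestry proportions must sum to 1")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class SweepConfig:
    """Hard sweep planted on a donor-ancestry haplotype."""

    chrom: str = "1"
    core_pos: int = 12_500_000  # 1-based bp
    donor: str = "IND"
    f_sweep: float = 0.9
    # Per carrier, the donor tract extends core_min_bp plus an Exponential
    # (mean tract_decay_bp) on each side: hard sweeps leave a core segment
    # shared by every carrier (no recombinant near the selected site
    # survives the sweep) and exponentially decaying flanks.
    tract_decay_bp: float | None = 1_000_000  # None = whole chromosome
    core_min_bp: float = 500_000

    def __post_init__(self):
        if not 0 < self.f_sweep <= 1:
            raise ValueError("f_sweep must be in (0, 1]")
        if self.core_min_bp < 0:
            raise ValueError("core_min_bp must be nonnegative")


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 25_000_000, "2": 25_000_000})
    snp_density: float = 0.001  # SNPs per bp (1 per kb)
    ld_block_bp: float = 50_000
    copy_mutation_rate: float = 0.005
    fresh_template_prob: float = 0.15
    cross_copy_prob: float = 0.6  # shared ancestral haplotypes across groups
    ancestry: AncestryModel = field(default_factory=AncestryModel)
    admixture: AdmixtureConfig = field(default_factory=AdmixtureConfig)
    sweep: SweepConfig | None = field(default_factory=SweepConfig)


@dataclass
class TruthTracks:
    """Ground truth for the admixed haplotypes.

    ``tracts`` tile each chromosome (0-based half-open bp) per haplotype;
    ``ancestry_of_hap`` codes the ancestry (index into SOURCES) of every
    haplotype at every SNP; dosages are derived from it.
    """

    tracts: pd.DataFrame  # hap, sample, chrom, start, end, ancestry
    ancestry_of_hap: np.ndarray  # (n_hap, n_var) uint8, index into SOURCES
    samples: list[str]
    sweep: dict | None = None

    def dosages(self) -> np.ndarray:
        """(n_var, n_samples, 3) per-SNP per-individual ancestry dosage."""
        n_hap, n_var = self.ancestry_of_hap.shape
        n_s = n_hap // 2
        per_hap = np.stack([(self.ancestry_of_hap == a) for a in range(3)],
                           axis=-1).astype(float)  # (hap, var, 3)
        d = per_hap.reshape(n_s, 2, n_var, 3).mean(axis=1)  # (sample, var, 3)
        return np.ascontiguousarray(d.transpose(1, 0, 2))


def draw_positions(chrom_lengths: dict[str, int], density: float,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Jittered-grid SNP positions: ~`density` SNPs/bp, no duplicate sites."""
    chroms, poss = [], []
    for chrom, length in chrom_lengths.items():
        spacing = 1.0 / density
        n = int(length * density)
        pos = (np.arange(n) * spacing
               + rng.uniform(0, spacing, size=n)).astype(np.int64) + 1
        pos = pos[pos <= length]
        chroms.extend([chrom] * len(pos))
        poss.append(pos)
    pos = np.concatenate(poss)
    ref_i = rng.integers(0, 4, size=len(pos))
    alt_i = (ref_i + rng.integers(1, 4, size=len(pos))) % 4
    return make_variant_table(np.array(chroms), pos,
                              _BASES[ref_i], _BASES[alt_i],
                              np.full(len(pos), 1000.0))


def simulate_source_frequencies(model: AncestryModel, variants: pd.DataFrame,
                                rng: np.random.Generator) -> pd.DataFrame:
    """Balding–Nichols frequencies: per SNP a base p, per group a Beta draw
    with mean p and variance F·p·(1−p)."""
    n = len(variants)
    lo, hi = model.base_freq_range
    base = rng.uniform(lo, hi, size=n)
    out = {"base": base}
    for group in SOURCES:
        f = model.divergence[group]
        if f < 1e-12:
            freq = base.copy()
        else:
            a = base * (1 - f) / f
            b = (1 - base) * (1 - f) / f
            freq = rng.beta(a, b)
        out[group] = np.clip(freq, 1e-3, 1 - 1e-3)
    return pd.DataFrame(out)


def _block_bounds(length: int, mean_bp: float, rng: np.random.Generator):
    """Exponential-length blocks tiling [0, length)."""
    edges = [0]
    while edges[-1] < length:
        edges.append(edges[-1] + max(1, int(rng.exponential(mean_bp))))
    edges[-1] = length
    return edges


def simulate_source_haplotypes(freqs: pd.DataFrame, variants: pd.DataFrame,
                               model: AncestryModel, cfg: SimulationConfig,
                               rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Template-copying haplotypes with block-wise LD per source group.

    Within blocks of ~``ld_block_bp``, each new haplotype either draws fresh
    Bernoulli(freq) alleles or copies a previously generated haplotype with
    a small per-SNP flip probability; marginal frequencies track ``freqs``.
    Block boundaries (the recombination structure) are shared across groups,
    and with probability ``cross_copy_prob`` a copy is taken from another
    group's haplotypes — real diverged populations retain long shared
    ancestral haplotypes, and cross-population haplotype-homozygosity
    contrasts are meaningless without that sharing.
    """
    chroms = variants["chrom"].to_numpy()
    pos0 = variants["pos"].to_numpy() - 1
    groups = list(SOURCES)
    n_of = {g: model.n_haplotypes[g] for g in groups}
    out = {g: np.zeros((n_of[g], len(variants)), dtype=np.uint8)
           for g in groups}
    f_of = {g: freqs[g].to_numpy() for g in groups}
    for chrom in pd.unique(chroms):
        cmask = np.nonzero(chroms == chrom)[0]
        cpos = pos0[cmask]
        edges = _block_bounds(int(cpos[-1]) + 1, cfg.ld_block_bp, rng)
        for b0, b1 in zip(edges[:-1], edges[1:]):
            lo, hi = np.searchsorted(cpos, [b0, b1])
            idx = cmask[lo:hi]
            if len(idx) == 0:
                continue
            done: list[tuple[str, int]] = []  # haplotypes finished this block
            for group in groups:
                fb = f_of[group][idx]
                for h in range(n_of[group]):
                    if not done or rng.random() < cfg.fresh_template_prob:
                        out[group][h, idx] = rng.random(len(idx)) < fb
                    else:
                        pool = done if rng.random() < cfg.cross_copy_prob \
                            else ([d for d in done if d[0] == group] or done)
                        tg, th = pool[int(rng.integers(0, len(pool)))]
                        alle = out[tg][th, idx].copy()
                        flip = rng.random(len(idx)) < cfg.copy_mutation_rate
                        alle[flip] ^= 1
                        out[group][h, idx] = alle
                    done.append((group, h))
    return out


def simulate_admixed_haplotypes(source_alleles: dict[str, np.ndarray],
                                variants: pd.DataFrame, cfg: AdmixtureConfig,
                                chrom_lengths: dict[str, int],
                                rng: np.random.Generator,
                                sample_prefix: str = "TGT"):
    """Mosaic admixed haplotypes: Poisson tract breakpoints at rate
    g × recomb_rate per bp, tract ancestry from the admixture proportions,
    alleles copied from a random source haplotype of that ancestry."""
    n_hap = 2 * cfg.n_admixed
    chroms = variants["chrom"].to_numpy()
    pos0 = variants["pos"].to_numpy() - 1
    samples = [f"{sample_prefix}{i:02d}" for i in range(cfg.n_admixed)]
    groups = list(SOURCES)
    props = np.array([cfg.proportions[g] for g in groups])
    rate = cfg.generations * cfg.recomb_rate_per_bp

    H = np.zeros((n_hap, len(variants)), dtype=np.uint8)
    anc = np.zeros((n_hap, len(variants)), dtype=np.uint8)
    rows = []
    for h in range(n_hap):
        for chrom, length in chrom_lengths.items():
            cmask = np.nonzero(chroms == chrom)[0]
            cpos = pos0[cmask]
            start = 0
            while start < length:
                if rate > 0:
                    tract_len = max(1, int(rng.exponential(1.0 / rate)))
                else:
                    tract_len = length
                end = min(start + tract_len, length)
                a = int(rng.choice(3, p=props))
                src = source_alleles[groups[a]]
                t = int(rng.integers(0, src.shape[0]))
                lo, hi = np.searchsorted(cpos, [start, end])
                idx = cmask[lo:hi]
                H[h, idx] = src[t, idx]
                anc[h, idx] = a
                rows.append((h, samples[h // 2], chrom, start, end, groups[a]))
                start = end
    tracts = pd.DataFrame(
        rows, columns=["hap", "sample", "chrom", "start", "end", "ancestry"])
    truth = TruthTracks(tracts=tracts, ancestry_of_hap=anc, samples=samples)
    hap_panel = HaplotypePanel(variants.copy(), H,
                               [s for s in samples for _ in range(2)])
    return hap_panel, truth


def _splice_tracts(tracts: pd.DataFrame, hap: int, chrom: str,
                   a: int, b: int, ancestry: str) -> pd.DataFrame:
    """Replace the interval [a, b) of one haplotype's tract list."""
    keep = []
    for row in tracts.itertuples(index=False):
        if row.hap != hap or row.chrom != chrom or row.end <= a or row.start >= b:
            keep.append(tuple(row))
            continue
        if row.start < a:
            keep.append((row.hap, row.sample, row.chrom, row.start, a, row.ancestry))
        if row.end > b:
            keep.append((row.hap, row.sample, row.chrom, b, row.end, row.ancestry))
    sample = tracts.loc[tracts["hap"] == hap, "sample"].iloc[0]
    keep.append((hap, sample, chrom, a, b, ancestry))
    out = pd.DataFrame(keep, columns=tracts.columns)
    return out.sort_values(["hap", "chrom", "start"], kind="stable",
                           ignore_index=True)


def impose_sweep(hap_panel: HaplotypePanel, truth: TruthTracks,
                 source_alleles: dict[str, np.ndarray], sweep: SweepConfig,
                 chrom_lengths: dict[str, int], rng: np.random.Generator):
    """Copy-replace a donor haplotype into a fraction ``f_sweep`` of target
    haplotypes over exponentially distributed tract lengths around the core."""
    if sweep.chrom not in chrom_lengths:
        raise ValueError(f"sweep chromosome {sweep.chrom!r} not simulated")
    length = chrom_lengths[sweep.chrom]
    if not 1 <= sweep.core_pos <= length:
        raise ValueError("sweep core position outside chromosome")
    donor_src = source_alleles[sweep.donor]
    if donor_src.shape[0] < 1:
        raise ValueError("donor ancestry has no source haplotypes")
    n_hap = hap_panel.n_haplotypes
    n_carriers = int(round(sweep.f_sweep * n_hap))
    if n_carriers < 2:
        raise ValueError("f_sweep x n_haplotypes < 2: no detectable sweep")

    donor_hap = int(rng.integers(0, donor_src.shape[0]))
    carriers = np.sort(rng.choice(n_hap, size=n_carriers, replace=False))
    chroms = hap_panel.variants["chrom"].to_numpy()
    pos0 = hap_panel.variants["pos"].to_numpy() - 1
    cmask = np.nonzero(chroms == sweep.chrom)[0]
    cpos = pos0[cmask]
    core0 = sweep.core_pos - 1
    anc_code = SOURCES.index(sweep.donor)

    tracts = truth.tracts
    for h in carriers:
        if sweep.tract_decay_bp is None:
            a, b = 0, length
        else:
            half_l = sweep.core_min_bp + rng.exponential(sweep.tract_decay_bp)
            half_r = sweep.core_min_bp + rng.exponential(sweep.tract_decay_bp)
            a = max(0, core0 - int(half_l))
            b = min(length, core0 + 1 + int(half_r))
        lo, hi = np.searchsorted(cpos, [a, b])
        idx = cmask[lo:hi]
        hap_panel.alleles[h, idx] = donor_src[donor_hap, idx]
        truth.ancestry_of_hap[h, idx] = anc_code
        tracts = _splice_tracts(tracts, int(h), sweep.chrom, a, b, sweep.donor)
    truth.tracts = tracts
    truth.sweep = {"chrom": sweep.chrom, "core_pos": sweep.core_pos,
                   "donor": sweep.donor, "donor_hap": donor_hap,
                   "f_sweep": sweep.f_sweep,
                   "carriers": [int(h) for h in carriers]}
    return hap_panel, truth


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    combined: HaplotypePanel  # target + sources, grouped via SamplePanel
    target: HaplotypePanel
    truth: TruthTracks
    freqs: pd.DataFrame


def simulate_dataset(cfg: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Run the full generator: sources → admixture → optional sweep."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(seed)
    variants = draw_positions(cfg.chrom_lengths, cfg.snp_density, rng)
    freqs = simulate_source_frequencies(cfg.ancestry, variants, rng)
    src = simulate_source_haplotypes(freqs, variants, cfg.ancestry, cfg, rng)
    target, truth = simulate_admixed_haplotypes(
        src, variants, cfg.admixture, cfg.chrom_lengths, rng)
    if cfg.sweep is not None:
        target, truth = impose_sweep(target, truth, src, cfg.sweep,
                                     cfg.chrom_lengths, rng)

    rows = [(s, "TARGET", "TARGET") for s in truth.samples]
    sample_of_hap = list(target.sample_of_haplotype)
    mats = [target.alleles]
    for group in SOURCES:
        n_hap = cfg.ancestry.n_haplotypes[group]
        names = [f"{group}{i:02d}" for i in range(n_hap // 2)]
        rows += [(s, group, group) for s in names]
        sample_of_hap += [s for s in names for _ in range(2)]
        mats.append(src[group][: 2 * (n_hap // 2)])
    panel = SamplePanel(pd.DataFrame(rows, columns=["sample", "population", "group"]))
    combined = HaplotypePanel(variants.copy(), np.vstack(mats), sample_of_hap, panel)
    target = HaplotypePanel(variants.copy(), target.alleles,
                            list(target.sample_of_haplotype))
    return SimulatedDataset(cfg, seed, combined, target, truth, freqs)


def emit_dataset(ds: SimulatedDataset, out_dir) -> dict[str, Path]:
    """Write VCF + panel TSV + truth TSVs; deterministic given the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "panel": out / "panel.tsv",
        "tracts": out / "truth_tracts.tsv",
        "dosages": out / "truth_dosages.tsv",
        "sweep": out / "truth_sweep.json",
    }
    write_phased_vcf(paths["vcf"], ds.combined, ds.config.chrom_lengths)
    ds.combined.panel.write_tsv(paths["panel"])
    ds.truth.tracts.to_csv(paths["tracts"], sep="\t", index=False)

    d = ds.truth.dosages()  # (n_var, n_samples, 3)
    cols = {"chrom": ds.combined.variants["chrom"],
            "pos": ds.combined.variants["pos"]}
    for si, s in enumerate(ds.truth.samples):
        for ai, a in enumerate(SOURCES):
            cols[f"{s}:{a}"] = d[:, si, ai]
    pd.DataFrame(cols).to_csv(paths["dosages"], sep="\t", index=False,
                              float_format="%.6g")
    with open(paths["sweep"], "w") as fh:
        json.dump(ds.truth.sweep if ds.truth.sweep is not None
                  else {"sweep": None}, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
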