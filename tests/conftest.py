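import numpy as np
import pandas as pd
import pytest

from admixscan.ancestry import AncestryDosageTrack
from admixscan.panel import HaplotypePanel, make_variant_table
from admixscan.pipeline import scan_dataset
from admixscan.simulate import SimulationConfig, simulate_dataset


def make_hap_panel(alleles, pos=None, chrom="1", ancestral_is_alt=None,
                   samples=None):
    """Hand-crafted haplotype panel for unit tests."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_var = alleles.shape
    if pos is None:
        pos = np.arange(1, n_var + 1) * 1000
    variants = make_variant_table(chrom, pos,
                                  ancestral_is_alt=ancestral_is_alt)
    if samples is None:
        samples = [f"S{i}" for i in range(n_hap // 2)]
    sample_of_hap = [s for s in samples for _ in range(2)]
    return HaplotypePanel(variants, alleles, sample_of_hap[:n_hap])


@pytest.fixture(scope="session")
def sweep_ds():
    """Default study conditions: 2x25 Mb, IND-donor sweep at chr1:12.5 Mb."""
    return simulate_dataset(SimulationConfig(), seed=7)


@pytest.fixture(scope="session")
def sweep_track(sweep_ds):
    return AncestryDosageTrack(sweep_ds.combined.variants[["chrom", "pos"]],
                               sweep_ds.truth.samples, sweep_ds.truth.dosages())


@pytest.fixture(scope="session")
def sweep_scan(sweep_ds, sweep_track):
    return scan_dataset(sweep_ds.combined, sweep_ds.config.chrom_lengths,
                        sweep_track)


@pytest.fixture(scope="session")
def neutral_ds():
    return simulate_dataset(SimulationConfig(sweep=None), seed=8)


SWEEP_CORE0 = 12_500_000 - 1  # 0-based core position of the default sweep


def near_core(start, end, pad=500_000):
    """Does the window (or its +-1-window vicinity) contain the sweep core?"""
    return start - pad <= SWEEP_CORE0 < end + pad
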