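"""VCF and tabular ingestion/emission.

Reading goes through cyvcf2; writing emits plain-text VCF 4.2 with phased
``|``-separated genotypes so that a simulated dataset round-trips exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import (GenotypePanel, HaplotypePanel, SamplePanel,
                    make_variant_table)


class VcfFormatError(ValueError):
    pass


def read_phased_vcf(path, panel_path=None, require_phased: bool = True):
    """Read a biallelic-SNP VCF into haplotype + genotype panels.

    Multiallelic sites and indels are dropped. Every VCF sample must appear
    in the panel file when one is given.

    Returns
    -------
    (HaplotypePanel | None, GenotypePanel)
        The haplotype panel is None when ``require_phased`` is False and
        unphased genotypes are present.
    """
    panel = SamplePanel.read_tsv(panel_path) if panel_path is not None else None
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if panel is not None:
        missing = sorted(set(samples) - set(panel.samples))
        if missing:
            raise VcfFormatError(f"VCF samples absent from panel file: {missing}")

    chroms, poss, refs, alts, quals = [], [], [], [], []
    hap_cols, gt_cols = [], []
    any_unphased = False
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # multiallelic
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            continue  # indel / MNP
        arr = v.genotype.array()  # (n_samples, 3): a1, a2, phased
        a1, a2, phased = arr[:, 0], arr[:, 1], arr[:, 2]
        miss = (a1 < 0) | (a2 < 0)
        unphased_here = (~miss & (phased == 0)).any()
        if unphased_here:
            if require_phased:
                bad = samples[int(np.nonzero(~miss & (phased == 0))[0][0])]
                raise VcfFormatError(
                    f"unphased genotype for sample {bad} at {v.CHROM}:{v.POS}; "
                    "a phased haplotype panel was requested")
            any_unphased = True
        if miss.any() and require_phased:
            bad = samples[int(np.nonzero(miss)[0][0])]
            raise VcfFormatError(
                f"missing genotype for sample {bad} at {v.CHROM}:{v.POS}; "
                "haplotype panels must be complete")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        quals.append(v.QUAL if v.QUAL is not None else 0.0)
        hap_cols.append(np.stack([a1, a2], axis=1).ravel())
        g = np.where(miss, -1, np.clip(a1, 0, 1) + np.clip(a2, 0, 1))
        gt_cols.append(g.astype(np.int8))
    vcf.close()
    if not poss:
        raise VcfFormatError(f"no biallelic SNPs found in {path}")

    variants = make_variant_table(chroms, poss, refs, alts, quals)
    order = np.lexsort((variants["pos"].to_numpy(),
                        variants["chrom"].to_numpy()))
    # VCFs are normally coordinate-sorted already; enforce (chrom, pos) order
    variants = variants.iloc[order].reset_index(drop=True)
    gmat = np.stack(gt_cols, axis=1)[:, order]
    gpanel = GenotypePanel(variants, gmat, samples, panel)

    hpanel = None
    if not any_unphased:
        hmat = np.stack(hap_cols, axis=1)[:, order]
        sample_of_hap = [s for s in samples for _ in range(2)]
        hmat = hmat.reshape(len(samples), 2, -1)
        hmat = hmat.reshape(2 * len(samples), -1)
        hpanel = HaplotypePanel(variants, hmat.astype(np.uint8),
                                sample_of_hap, panel)
    return hpanel, gpanel


_VCF_HEADER = """##fileformat=VCFv4.2
##source=admixscan
{contigs}##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_phased_vcf(path, hap_panel: HaplotypePanel,
                     chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a HaplotypePanel as a phased plain-text VCF (deterministic)."""
    variants = hap_panel.variants
    samples = hap_panel.samples
    contigs = ""
    if chrom_lengths:
        contigs = "".join(f"##contig=<ID={c},length={l}>\n"
                          for c, l in chrom_lengths.items())
    n = len(samples)
    alleles = hap_panel.alleles.reshape(n, 2, -1)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, samples="\t".join(samples)))
        for j in range(len(variants)):
            row = variants.iloc[j]
            gts = "\t".join(f"{alleles[i, 0, j]}|{alleles[i, 1, j]}"
                            for i in range(n))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t"
                     f"{row.qual:g}\tPASS\t.\tGT\t{gts}\n")


def write_kept_variants(path, variants: pd.DataFrame) -> None:
    variants[["chrom", "pos", "ref", "alt"]].to_csv(path, sep="\t", index=False)


def write_relatedness_matrix(path, samples, pihat: np.ndarray) -> None:
    pd.DataFrame(pihat, index=samples, columns=samples).to_csv(path, sep="\t")


def write_bed(path, intervals: pd.DataFrame, extra_cols=()) -> None:
    """Write 0-based half-open intervals as BED (chrom, start, end [, extras])."""
    cols = ["chrom", "start", "end", *extra_cols]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)
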