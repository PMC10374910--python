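"""End-to-end orchestration: simulate → filter → scans → consensus → report.

The scan stages follow the study design: quality filters on the combined
panel, dataset-wide ancestral-allele assignment, a stringent LD pruning
(r² 0.4) feeding the EHH scans and a moderate one (r² 0.6) feeding ROH
detection, diversity/differentiation and the CLR scan on the full filtered
set, ancestry windows from the dosage track, and the consensus caller on
the 500-kb grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry as anc
from . import clr as clrmod
from . import consensus as cons
from . import diversity as divmod_
from . import ehh as ehhmod
from . import filters as filt
from . import roh as rohmod
from . import simulate as sim
from .io import read_phased_vcf, write_bed
from .panel import SOURCES, HaplotypePanel, build_window_grid

log = logging.getLogger("admixscan")


@dataclass
class ScanParams:
    maf_min: float = 0.1
    miss_max: float = 0.1
    hwe_p_min: float = 0.01
    qual_min: float = 100.0
    prune_r2_scan: float = 0.4
    prune_r2_structure: float = 0.6
    prune_window_snps: int = 20
    prune_step_snps: int = 4
    max_gap_bp: int = 500_000
    ehh_floor: float = 0.05
    p_threshold: float = 6.0
    min_outlier_snps: int = 5
    ehh_window_bp: int = 500_000
    fine_window_bp: int = 50_000
    pi_window_bp: int = 1_000_000
    fst_min_snps: int = 4
    top_pct: float = 1.0
    clr_grid_per_window: int = 10
    clr_flank_bp: int = 200_000
    roh: rohmod.RohParams = field(default_factory=rohmod.RohParams)
    island_threshold: float = 0.30
    ancestry_margin_sd: float = 2.0
    pi_reduction_pct: float = 10.0
    xpehh_framing: str = "site"


@dataclass
class ScanOutputs:
    params: ScanParams
    chrom_lengths: dict[str, int]
    scores: dict[str, pd.DataFrame]
    window_calls: dict[str, pd.DataFrame]
    clr: pd.DataFrame
    pi_fine: pd.DataFrame
    pi_coarse: pd.DataFrame
    fst: dict[str, pd.DataFrame]
    fst_tops: dict[str, pd.DataFrame]
    roh_segments: pd.DataFrame
    roh_islands: pd.DataFrame
    ancestry_windows: pd.DataFrame | None
    global_ancestry: pd.DataFrame | None
    candidates: pd.DataFrame
    filter_report: filt.FilterReport


ALL_STAGES = ("ehh", "clr", "diversity", "roh", "ancestry", "consensus")


def scan_dataset(combined: HaplotypePanel,
                 chrom_lengths: dict[str, int],
                 dosage_track: anc.AncestryDosageTrack | None = None,
                 params: ScanParams | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> ScanOutputs:
    """Run the scan stages on a combined panel with TARGET/AFT/EUT/IND groups.

    ``stages`` selects a subset of {ehh, clr, diversity, roh, ancestry,
    consensus}; variant filtering and ancestral-allele assignment always
    run first, and consensus combines whatever stages were computed.
    """
    params = params or ScanParams()
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    if combined.panel is None:
        raise ValueError("combined panel needs sample group annotations")

    log.info("filtering %d variants", combined.n_variants)
    geno = combined.to_genotypes()
    geno, report = filt.apply_variant_filters(
        geno, params.maf_min, params.miss_max, params.hwe_p_min,
        params.qual_min, hwe_panel=geno.subset_group("TARGET"))
    kept_keys = set(zip(geno.variants["chrom"], geno.variants["pos"]))
    kept = np.array([i for i, key in enumerate(
        zip(combined.variants["chrom"], combined.variants["pos"]))
        if key in kept_keys])
    hap = combined.take_variants(kept)
    geno = filt.assign_ancestral_alleles(geno)
    hap.variants["ancestral_is_alt"] = geno.variants["ancestral_is_alt"].to_numpy()
    if dosage_track is not None:
        dosage_track = dosage_track.take_variants(kept)
    log.info("%d variants pass filters", hap.n_variants)

    grid_ehh = build_window_grid(chrom_lengths, params.ehh_window_bp)
    grid_fine = build_window_grid(chrom_lengths, params.fine_window_bp)
    grid_pi = build_window_grid(chrom_lengths, params.pi_window_bp)

    if "consensus" in stages:
        stages = ALL_STAGES  # consensus consumes every stream

    scores: dict[str, pd.DataFrame] = {}
    calls: dict[str, pd.DataFrame] = {}
    if "ehh" in stages:
        # EHH scans on the stringently pruned set
        idx_scan = filt.ld_prune(geno, params.prune_window_snps,
                                 params.prune_step_snps, params.prune_r2_scan)
        hap_scan = hap.take_variants(idx_scan)
        log.info("EHH scans on %d pruned variants", hap_scan.n_variants)
        target = hap_scan.subset_group("TARGET")
        scores["iHS"] = ehhmod.ihs_scan(target, params.max_gap_bp,
                                        params.ehh_floor)
        ies_t = ehhmod.site_ies_table(target, params.max_gap_bp,
                                      params.ehh_floor)
        for group in SOURCES:
            ref = hap_scan.subset_group(group)
            ies_r = ehhmod.site_ies_table(ref, params.max_gap_bp,
                                          params.ehh_floor)
            scores[f"Rsb_vs_{group}"] = ehhmod.rsb_scan(
                target, ref, params.max_gap_bp, params.ehh_floor,
                ies_target=ies_t, ies_reference=ies_r)
            scores[f"XPEHH_vs_{group}"] = ehhmod.xpehh_scan(
                target, ref, params.max_gap_bp, params.ehh_floor,
                framing=params.xpehh_framing, ies_target=ies_t,
                ies_reference=ies_r)
        for name, tab in scores.items():
            calls[name] = ehhmod.classify_outlier_windows(
                tab, grid_ehh, params.p_threshold, params.min_outlier_snps)

    target_full = hap.subset_group("TARGET")
    clr_res = pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                    "clr", "argmax_pos", "alpha_hat"])
    if "clr" in stages:
        log.info("CLR scan")
        clr_res = clrmod.clr_scan(target_full, grid_ehh,
                                  params.clr_grid_per_window,
                                  params.clr_flank_bp)

    pi_fine = pd.DataFrame(columns=["chrom", "start", "end", "n_snps", "pi"])
    pi_coarse = pi_fine.copy()
    fst: dict[str, pd.DataFrame] = {}
    fst_tops: dict[str, pd.DataFrame] = {}
    if "diversity" in stages:
        log.info("pi / Fst windows")
        pi_fine = divmod_.windowed_pi(target_full, grid_fine)
        pi_coarse = divmod_.windowed_pi(target_full, grid_pi)
        for group in SOURCES:
            ref_full = hap.subset_group(group)
            f = divmod_.wc_fst_window(target_full, ref_full, grid_fine,
                                      params.fst_min_snps)
            fst[f"TARGET_vs_{group}"] = f
            fst_tops[f"TARGET_vs_{group}"] = divmod_.top_percentile_windows(
                f, "fst", params.top_pct, params.fst_min_snps)

    segments = pd.DataFrame(columns=["sample", "chrom", "start", "end",
                                     "n_snps", "length"])
    islands = pd.DataFrame(columns=["chrom", "start", "end", "fraction"])
    if "roh" in stages:
        # ROH on the moderately pruned target genotypes
        idx_roh = filt.ld_prune(geno, params.prune_window_snps,
                                params.prune_step_snps,
                                params.prune_r2_structure)
        geno_roh = geno.take_variants(idx_roh).subset_group("TARGET")
        log.info("ROH scan on %d pruned variants", geno_roh.n_variants)
        segments = rohmod.scan_roh_all(geno_roh, params.roh)
        if len(segments):
            islands = rohmod.roh_islands(segments, geno_roh.n_samples,
                                         params.island_threshold)

    ancestry_windows = None
    global_anc = None
    if "ancestry" in stages and dosage_track is not None:
        ancestry_windows = anc.ancestry_excess_windows(
            dosage_track, grid_ehh, params.top_pct, params.ancestry_margin_sd)
        global_anc, _ = anc.global_ancestry(dosage_track)

    candidates = pd.DataFrame(columns=[
        "chrom", "start", "end", "n_tests", "tests", "sign_positive",
        "ancestry_excess", "excess_ancestry", "top_fst", "pi_reduction",
        "clr_chrom_max", "roh_island", "relevant"])
    if "consensus" in stages:
        candidates = cons.call_consensus(
            calls, grid_ehh, ancestry_windows, fst_tops, pi_fine, clr_res,
            islands, pi_pct=params.pi_reduction_pct)

    return ScanOutputs(params, chrom_lengths, scores, calls, clr_res,
                       pi_fine, pi_coarse, fst, fst_tops, segments, islands,
                       ancestry_windows, global_anc, candidates, report)


def write_outputs(out: ScanOutputs, out_dir) -> None:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for name, tab in out.scores.items():
        tab.to_csv(d / f"scores_{name}.tsv", sep="\t", index=False,
                   float_format="%.6g")
    for name, tab in out.window_calls.items():
        tab.to_csv(d / f"windows_{name}.tsv", sep="\t", index=False,
                   float_format="%.6g")
        flagged = tab[tab["flagged"]]
        write_bed(d / f"flagged_{name}.bed", flagged)
    out.clr.to_csv(d / "clr_windows.tsv", sep="\t", index=False,
                   float_format="%.6g")
    if out.clr["clr"].notna().any():
        from .clr import chromosome_maxima
        write_bed(d / "clr_chrom_maxima.bed", chromosome_maxima(out.clr))
    if len(out.pi_fine) and out.pi_fine["n_snps"].gt(0).any():
        from .diversity import top_percentile_windows
        bottom = top_percentile_windows(out.pi_fine, "pi", side="low",
                                        min_snps=1)
        write_bed(d / "bottom_pi_50kb.bed", bottom)
    out.pi_fine.to_csv(d / "pi_50kb.tsv", sep="\t", index=False,
                       float_format="%.6g")
    out.pi_coarse.to_csv(d / "pi_1mb.tsv", sep="\t", index=False,
                         float_format="%.6g")
    for name, tab in out.fst.items():
        tab.to_csv(d / f"fst_{name}.tsv", sep="\t", index=False,
                   float_format="%.6g")
    for name, tab in out.fst_tops.items():
        write_bed(d / f"top_fst_{name}.bed", tab)
    out.roh_segments.to_csv(d / "roh_segments.tsv", sep="\t", index=False)
    out.roh_islands.to_csv(d / "roh_islands.tsv", sep="\t", index=False,
                           float_format="%.4g")
    if out.ancestry_windows is not None:
        out.ancestry_windows.to_csv(d / "ancestry_windows.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    if out.global_ancestry is not None:
        out.global_ancestry.to_csv(d / "global_ancestry.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    out.candidates.to_csv(d / "candidate_regions.tsv", sep="\t", index=False)
    with open(d / "report.txt", "w") as fh:
        fh.write(format_report(out))


def format_report(out: ScanOutputs) -> str:
    """Human-readable run report: candidates, diversity, global ancestry."""
    lines = ["admixscan run report", "=" * 40, ""]
    lines.append("Candidate regions (>= 2 EHH tests):")
    if len(out.candidates) == 0:
        lines.append("  none")
    else:
        for row in out.candidates.itertuples(index=False):
            status = "RELEVANT" if row.relevant else "candidate"
            lines.append(
                f"  {row.chrom}:{row.start}-{row.end} [{status}] "
                f"tests={row.tests} sign_positive={row.sign_positive} "
                f"ancestry_excess={row.excess_ancestry or '-'} "
                f"topFst={row.top_fst or '-'} pi_red={row.pi_reduction} "
                f"CLRmax={row.clr_chrom_max} ROHisl={row.roh_island}")
    lines.append("")
    n_rel = int(out.candidates["relevant"].sum()) if len(out.candidates) else 0
    lines.append(f"Relevant regions: {n_rel}")
    lines.append("")
    if len(out.pi_coarse):
        lines.append("Target diversity (1-Mb windows): median pi/bp = "
                     f"{out.pi_coarse['pi'].median():.3e}")
    else:
        lines.append("Target diversity: stage not run")
    if out.global_ancestry is not None:
        lines.append("")
        lines.append("Global ancestry per individual:")
        for row in out.global_ancestry.itertuples(index=False):
            lines.append(f"  {row.sample}: AFT={row.mean_AFT:.3f} "
                         f"EUT={row.mean_EUT:.3f} IND={row.mean_IND:.3f}")
    else:
        lines.append("")
        lines.append("Ancestry dosages unavailable: consensus downgraded to "
                     "two-test calls (no ancestry-excess requirement applied; "
                     "'relevant' requires ancestry evidence and is therefore "
                     "not assessable).")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# config-file driven entry points (used by the CLI)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def simulation_config_from_dict(cfg: dict) -> sim.SimulationConfig:
    known = {"chrom_lengths", "snp_density", "ld_block_bp",
             "copy_mutation_rate", "fresh_template_prob", "cross_copy_prob",
             "divergence", "n_source_haplotypes", "proportions",
             "generations", "recomb_rate_per_bp", "n_admixed", "sweep"}
    unknown = set(cfg) - known - {"seed", "out_dir"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    # the dataclass defaults ARE the study conditions; only override what
    # the config file provides
    ancestry = sim.AncestryModel()
    if "divergence" in cfg:
        ancestry.divergence = {str(k): float(v)
                               for k, v in cfg["divergence"].items()}
    if "n_source_haplotypes" in cfg:
        ancestry.n_haplotypes = {str(k): int(v)
                                 for k, v in cfg["n_source_haplotypes"].items()}
    admix = sim.AdmixtureConfig()
    if "proportions" in cfg:
        admix.proportions = {str(k): float(v)
                             for k, v in cfg["proportions"].items()}
    for key, cast in (("generations", int), ("recomb_rate_per_bp", float),
                      ("n_admixed", int)):
        if key in cfg:
            setattr(admix, key, cast(cfg[key]))
    out = sim.SimulationConfig(ancestry=ancestry, admixture=admix)
    if "chrom_lengths" in cfg:
        out.chrom_lengths = {str(k): int(v)
                             for k, v in cfg["chrom_lengths"].items()}
    for key, cast in (("snp_density", float), ("ld_block_bp", float),
                      ("copy_mutation_rate", float),
                      ("fresh_template_prob", float),
                      ("cross_copy_prob", float)):
        if key in cfg:
            setattr(out, key, cast(cfg[key]))
    if "sweep" in cfg:
        if not cfg["sweep"]:
            out.sweep = None
        else:
            s = cfg["sweep"]
            sweep = sim.SweepConfig()
            for key, cast in (("chrom", str), ("core_pos", int),
                              ("donor", str), ("f_sweep", float)):
                if key in s:
                    setattr(sweep, key, cast(s[key]))
            if "tract_decay_bp" in s:
                sweep.tract_decay_bp = (None if s["tract_decay_bp"] is None
                                        else float(s["tract_decay_bp"]))
            if "core_min_bp" in s:
                sweep.core_min_bp = float(s["core_min_bp"])
            sweep.__post_init__()
            out.sweep = sweep
    return out


def run_simulate(cfg: dict, out_dir, seed: int):
    """Simulate a dataset and emit VCF + panel + truth files."""
    sc = simulation_config_from_dict(cfg)
    ds = sim.simulate_dataset(sc, seed)
    paths = sim.emit_dataset(ds, out_dir)
    log.info("simulated dataset written to %s (seed %d)", out_dir, seed)
    return ds, paths


def run_scan(dataset_dir, out_dir, params: ScanParams | None = None,
             chrom_lengths: dict[str, int] | None = None,
             stages: tuple[str, ...] = ALL_STAGES) -> ScanOutputs:
    """Scan an emitted dataset directory end to end and write result files."""
    dataset_dir = Path(dataset_dir)
    hap, _ = read_phased_vcf(dataset_dir / "genotypes.vcf",
                             dataset_dir / "panel.tsv")
    if chrom_lengths is None:
        chrom_lengths = _lengths_from_vcf_header(dataset_dir / "genotypes.vcf")
    track = None
    dos_path = dataset_dir / "truth_dosages.tsv"
    if dos_path.exists():
        track = anc.load_dosages(dos_path, hap.variants, source_tag="truth")
    out = scan_dataset(hap, chrom_lengths, track, params, stages)
    write_outputs(out, out_dir)
    return out


def run_filter(vcf_path, panel_path, out_dir,
               params: ScanParams | None = None,
               relatedness: bool = False):
    """Apply the variant filters to a phased VCF; write the filtered VCF,
    the kept-variant list and (optionally) the PI_HAT relatedness matrix."""
    from .io import write_kept_variants, write_phased_vcf, \
        write_relatedness_matrix
    params = params or ScanParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hap, geno = read_phased_vcf(vcf_path, panel_path)
    hwe_panel = geno.subset_group("TARGET") if geno.panel is not None else geno
    geno_f, report = filt.apply_variant_filters(
        geno, params.maf_min, params.miss_max, params.hwe_p_min,
        params.qual_min, hwe_panel=hwe_panel)
    kept_keys = set(zip(geno_f.variants["chrom"], geno_f.variants["pos"]))
    kept = np.array([i for i, key in enumerate(
        zip(hap.variants["chrom"], hap.variants["pos"])) if key in kept_keys])
    write_phased_vcf(out_dir / "filtered.vcf", hap.take_variants(kept))
    write_kept_variants(out_dir / "kept_variants.tsv", geno_f.variants)
    if relatedness:
        kept_samples, matrix = filt.prune_related_samples(geno_f)
        write_relatedness_matrix(out_dir / "relatedness.tsv",
                                 geno_f.samples, matrix)
        (out_dir / "kept_samples.txt").write_text(
            "\n".join(kept_samples) + "\n")
    log.info("filtering: %d of %d variants kept", report.n_kept,
             report.n_input)
    return report


def _lengths_from_vcf_header(path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##contig"):
                inner = line.strip()[len("##contig=<"):-1]
                kv = dict(p.split("=", 1) for p in inner.split(","))
                lengths[kv["ID"]] = int(kv["length"])
            elif line.startswith("#CHROM"):
                break
    if not lengths:
        raise ValueError(f"no contig lengths in VCF header: {path}")
    return lengths
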