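# Methods

This note documents the statistics implemented in `admixscan`, the model
behind the synthetic data generator, the defaults and the reasoning behind
them, and what the test suite does and does not establish about behaviour
on real data.

## Setting

The package targets the analysis design used for recently admixed
populations: a target population (group `TARGET`) formed from three
diverged source ancestries (`AFT`, `EUT`, `IND`), phased biallelic SNP
genotypes, and the question of which genomic windows carry signatures of
recent positive selection in the target. Evidence is accumulated from
statistics with different sensitivities — haplotype homozygosity for
ongoing/recent sweeps, SFS distortion for completed sweeps, allele-frequency
differentiation, diversity reduction, runs of homozygosity, and local
ancestry excess — and combined by a consensus rule.

## Variant and sample preparation

Filters follow common WGS practice: minor allele frequency ≥ 0.1,
per-variant missingness ≤ 0.1, site quality ≥ 100, and an exact
Hardy–Weinberg test at p ≥ 0.01. The HWE test is the exact conditional
test (plain two-sided tail sum of configurations no more probable than the
observed one; no mid-p), chosen for reproducibility over power. By default
the pipeline evaluates HWE **within the target population**: pooling
diverged groups violates HWE by construction (Wahlund effect) and
preferentially removes exactly the differentiated sites the scans look
for. The test itself accepts any genotype panel, so a pooled or
per-population policy is one argument away.

LD pruning reimplements PLINK's `--indep-pairwise w s r²` greedy pass:
windows of `w` SNPs advancing by `s`, pruning one of any pair with
genotype-r² above the cut. Two presets are used: r² ≤ 0.6 feeding ROH
detection and r² ≤ 0.4 feeding the EHH scans. Tie-break: the variant with
the lower MAF is removed; at equal MAF, the later position — keeping the
more informative marker and making the output deterministic. Missing
genotypes are excluded pairwise.

Relatedness uses the method-of-moments IBD estimator (PLINK's PI_HAT =
P(IBD2) + ½P(IBD1)) with whole-panel allele frequencies, truncated to
[0, 1] and renormalized; pairs above PI_HAT 0.05 are greedily pruned.

Ancestral alleles are assigned as the dataset-wide majority allele; an
exact 50/50 tie resolves to the reference allele. This is error-prone (the
true ancestral state is unknown), which is why the CLR scan also offers a
folded-spectrum mode.

## EHH statistics

EHH at a flanking SNP is the probability that two random haplotypes of the
carrier class are identical over the interval from the focal SNP:
`Σ_c n_c(n_c−1) / (m(m−1))` over the cells of the haplotype partition. The
walk refines the partition SNP by SNP and stops at the chromosome end, at
an inter-SNP gap above 500 kb, or when EHH falls below a floor of 0.05
(the crossing point is kept and integrated; the floor bounds runtime and
follows common practice — the tools in this space use the same device).
Integration is trapezoidal over physical distance in bp; no genetic map is
assumed, matching SNP-only data.

- **iHS**: `ln(iHH_ancestral / iHH_derived)` per SNP, standardized to mean
  0 / sd 1 within derived-allele-frequency bins of width 0.05 (bins with
  < 10 SNPs merge rightward). The focal SNP's own allele is part of the
  defining haplotype string.
- **Rsb**: `ln(iES_target / iES_reference)` where iES integrates site-EHH
  (all haplotypes pooled, partition seeded by the focal alleles) normalized
  to 1 at the focal SNP.
- **XP-EHH** (default "site" framing): the same machinery without the focal
  normalization — the integral equals focal homozygosity × normalized iES,
  so the statistic weights sites by their focal homozygosity, the classic
  cross-population framing. Truncation is applied on the normalized scale
  in both statistics so the two share one walk. A "derived-allele" framing
  (iHH of derived carriers in both populations) is available as a switch.

Cross-population scores are standardized genome-wide by subtracting the
median (robust to the sweep's own outliers; mean-centering is available)
and dividing by the standard deviation. Scores map to two-sided
`-log10 p = -log10[1 − 2|Φ(x) − 0.5|]` under a standard Gaussian null,
computed via `log(sf)` for numerical stability; positive Rsb/XP-EHH means
longer haplotypes in the target, i.e. selection there.

A 500-kb window is *putatively selected* when ≥ 5 SNPs exceed
`-log10 p = 6` (clusters, not isolated outliers, are the signature of a
sweep). A relaxed replication preset (1-Mb sliding windows, 500-kb step,
threshold 4, one SNP) reproduces the looser criterion used in older chip
studies.

## CLR sweep scan

The background SFS is the genome-wide unfolded spectrum of the scanned
population (its own data, not a theoretical spectrum). Under a complete
hard sweep at distance *d*, a site escapes with probability
`p_e = 1 − exp(−αd)`; escaped sites follow the background, non-escaped
sites follow a star-like post-sweep spectrum with mass only on the extreme
classes: the highest derived class with probability `Σ_k p_k·k/n` (the
sweeping haplotype carried the derived allele) and the singleton class
otherwise. The per-grid-point statistic is
`Λ = 2[max_α Σ ln P_sweep(k_i|α,d_i) − Σ ln P_bg(k_i)]`, clamped at 0
(the neutral model is nested as α → ∞).

Numerics: 10 grid points per 500-kb window; sites within 200 kb of the
grid point enter the likelihood (desk-scale resolution/runtime trade-off);
α is maximized by golden-section search on ln α over [ln 10⁻⁸, ln 10⁻²]
per bp, a bracket covering sweep footprints from whole-chromosome to
sub-kb. Windows without a polymorphic site report a missing Λ — note that
a *fully fixed* sweep with a long shared core can render its own window
monomorphic.

## Diversity and differentiation

Per-site π is the unbiased mean pairwise difference `2k(n−k)/(n(n−1))`
computed from haplotype counts (phased data make the pairwise
interpretation exact); window π divides the site sum by the *covered*
window length, so the truncated terminal window is not biased. Fst is the
Weir–Cockerham (1984) variance-components estimator per site, combined per
window as a ratio of sums; windows need ≥ 4 SNPs and a positive
denominator to be valid. Top-percentile sets take the highest (or lowest)
1 % of valid windows; ties at the cut are all included rather than broken
arbitrarily.

## Runs of homozygosity

The detector mirrors PLINK `--homozyg` semantics with the standard
parameter set: 100-SNP sliding windows with ≤ 3 heterozygous and ≤ 5
missing calls; a SNP joins a run when ≥ 5 % of its overlapping windows are
homozygous (the scanning tool's documented default for the threshold the
parameter set leaves unstated); runs split at gaps > 1 Mb and must contain
≥ 100 homozygous SNPs at ≥ 1 SNP / 50 kb. Missing and heterozygous calls
never count toward the SNP-count or density tallies. Segment bounds are
the first/last SNP of the run as a 0-based half-open bp interval.

ROH islands are maximal intervals where the per-bp fraction of individuals
covered by a ROH reaches 30 %. The reported island fraction is the
*minimum* pointwise coverage across the island — the fraction guaranteed
to share the entire interval (whether published island fractions count
individuals or segments is ambiguous; per-individual per-bp coverage is the
interpretation implemented).

## Ancestry and consensus

Dosage tracks give, per SNP × individual, the probability of descent from
each ancestry; they are consumed as input (truth from the simulator, or an
external local-ancestry inference — a 0–2 diploid scale is rescaled on
load, row sums are validated, and variant order is aligned explicitly).
Ancestry-excess windows per ancestry are those in the genome-wide top 1 %
of window-mean dosage **or** strictly above the chromosome mean by 2
chromosome-level standard deviations of window means — "sudden increase"
is nowhere quantified in the source analyses, so both published anchors
(top-percentile membership and chromosome-relative excess) are honored,
either sufficing.

The consensus caller marks a window *relevant* when (1) ≥ 2 EHH-based
tests flag it (iHS counts as one eligible test), (2) the supporting
cross-population tests have positive median sign — a window supported only
by tests indicating selection in the reference is excluded — and (3) the
window or an immediately adjacent window shows an ancestry excess (the
vicinity rule reflects that ancestry peaks can sit just off the EHH
window). Top-1 % Fst, π below the chromosome 10th percentile,
chromosome-maximum CLR and ROH-island overlap are attached as flags but by
construction never gate relevance — removing any corroborative stream
changes flags, not the relevant set.

## Synthetic data generator

The generator produces the study conditions the tests run under:

| parameter | default | meaning |
|---|---|---|
| genome | 2 × 25 Mb, 1 SNP/kb | jittered-grid SNP positions |
| source divergence F | 0.1 per group | Balding–Nichols: group freq ~ Beta with mean p, var F·p(1−p); base p ~ U(0.05, 0.95) |
| LD blocks | 50 kb mean, exponential | shared block boundaries across groups (recombination structure is common) |
| template copying | fresh 0.15, cross-group 0.6, flip 0.005 | haplotypes copy earlier templates within blocks; cross-group copies model shared ancestral haplotypes |
| admixture | 29 % EUT / 35 % AFT / 36 % IND, g = 70, 1 cM/Mb | tract breakpoints Poisson(g·r) per bp, ancestry i.i.d. per tract, alleles copied from a random source haplotype |
| target size | 20 diploids (+ 3 × 10 source diploids) | |
| sweep | IND donor, f = 0.9, core chr1:12.5 Mb | carriers replaced by one donor haplotype over core ± (500 kb + Exp(1 Mb)) per side |

Two calibration points deserve comment. First, cross-population haplotype
*sharing* is essential, not cosmetic: if the source groups are simulated
with independent haplotype structure, ln(iES) is nearly uncorrelated
between target and reference and the Rsb/XP-EHH null variance makes any
realistic sweep undetectable — real diverged cattle populations share long
ancestral haplotypes, and the cross-copy probability encodes that.
Second, the sweep tract has a deterministic 500-kb shared core plus
exponential flanks: a hard sweep leaves essentially no surviving
recombinant immediately around the selected site, and with purely
exponential half-lengths the minimum shared segment over ~36 carriers
would be ~30 kb, scattering the EHH peak off the core window. Defaults are
chosen for signal detectability at desk scale rather than for demographic
realism, and 50 Mb of genome keeps the swept span a small fraction of the
null distribution used for standardization.

What the generator does **not** emulate: coalescent genealogies and
realistic allele-frequency spectra, genotyping error and missingness,
recombination-map heterogeneity beyond block structure, background
selection, and HMM-correlated ancestry tracts (tract ancestries are
independent draws). Passing tests therefore establish the *machinery* —
formulas, window rules, consensus logic, calibration of means and rates —
not performance guarantees on real WGS data.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on the
2 × 25 Mb default genome (≈ 50 000 SNPs, 100 haplotypes); replicate-based
checks use 20 seeded datasets in the test suite and 10 in the acceptance
script, sizes chosen so the whole suite completes in minutes on one CPU.
All randomness flows from one `numpy` Generator seeded per dataset;
identical seeds give byte-identical emitted files and scan outputs. The
scan itself is deterministic.

## Known limitations

- Majority-allele ancestral assignment misorients sites with derived
  frequency > 0.5; iHS and the unfolded SFS inherit that bias (the folded
  CLR mode is the mitigation).
- The CLR escape model treats whole sites, not lineages, as escaping —
  the standard desk approximation of the full sweep likelihood.
- PI_HAT assumes HWE-distributed genotypes; strong structure inflates it
  (hence relatedness is assessed within populations in practice).
- Fst and π windows use all filtered SNPs; the alternative of feeding the
  LD-pruned set is a one-line parameter change but slightly shifts
  percentile cuts.
- With ~40 windows per chromosome at 500 kb, percentile-based rules are
  coarse; real genomes provide the window counts the 1 % cuts assume.
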