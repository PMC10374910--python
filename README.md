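# admixscan

Multi-statistic selection-signature scans for admixed populations.

`admixscan` is a reusable implementation of the consensus workflow used to
find regions under recent selection in an admixed genome — the setting of,
for example, a Creole cattle population formed from African taurine (AFT),
European taurine (EUT) and indicine (IND) ancestries. No single scan is
trusted on its own: a region counts as a candidate only when several
statistics with different blind spots agree. The package provides:

- **Haplotype-homozygosity scans** — iHS within the target population, Rsb
  and XP-EHH against each ancestral reference, with the two-sided Gaussian
  transform `p = -log10[1 - 2|Φ(x) - 0.5|]`, a 500-kb maximum inter-SNP
  gap, and outlier-window calling (≥ 5 SNPs above `-log10 p = 6` per 500-kb
  window; a relaxed 1-Mb/`-log10 p = 4` replication preset exists).
- **SFS composite-likelihood sweep scan (CLR)** — a complete-sweep model in
  which a site at distance *d* from the sweep escapes with probability
  `1 - exp(-αd)`, tested against the genome-wide background SFS per 500-kb
  window.
- **Windowed diversity and differentiation** — haplotype-based nucleotide
  diversity π and Weir–Cockerham Fst in 50-kb windows (≥ 4 SNPs), with
  top-1 % window sets.
- **Runs of homozygosity** — PLINK-style sliding-window ROH detection
  (100-SNP windows, ≤ 3 het / ≤ 5 missing, 100-SNP minimum, 1 SNP / 50 kb
  density, 1-Mb gap) and ROH islands shared by ≥ 30 % of individuals.
- **Local-ancestry evidence** — per-SNP ancestry-dosage tracks (consumed as
  input; the simulator provides truth), global and per-chromosome ancestry
  summaries, and top-1 % / sudden-increase ancestry-excess windows.
- **Consensus calling** — a window is *relevant* when ≥ 2 EHH-based tests
  flag it with positive sign (longer haplotypes in the target) **and** it
  (or an adjacent window) shows an ancestry excess; top-Fst, low-π,
  chromosome-maximum CLR and ROH-island overlap are attached as
  corroborating flags.
- **A synthetic admixture generator** — phased haplotypes for three
  diverged source groups (Balding–Nichols divergence, block-wise LD with
  cross-population haplotype sharing), a three-way admixed target
  (defaults 29 % EUT / 35 % AFT / 36 % IND, 70 generations of admixture),
  and an optional planted hard sweep of an IND-donor haplotype — so the
  whole pipeline is testable end to end with known truth.

## Worked example

Simulate the default study conditions (2 × 25 Mb genome, 1 SNP/kb,
20 admixed diploids + 3 × 10 source diploids, hard sweep of an IND
haplotype at chr1:12.5 Mb reaching frequency 0.9) and scan it:

```sh
admixscan all --seed 2 --out run/
```

prints (abridged):

```
admixscan run report
========================================

Candidate regions (>= 2 EHH tests):
  1:12000000-12500000 [RELEVANT] tests=Rsb_vs_AFT,Rsb_vs_EUT,Rsb_vs_IND,XPEHH_vs_AFT,XPEHH_vs_EUT,XPEHH_vs_IND sign_positive=True ancestry_excess=IND topFst=TARGET_vs_AFT,TARGET_vs_EUT,TARGET_vs_IND pi_red=True CLRmax=False ROHisl=True
  1:12500000-13000000 [RELEVANT] tests=Rsb_vs_AFT,... CLRmax=True ROHisl=True
  ...

Relevant regions: 4

Target diversity (1-Mb windows): median pi/bp = 1.901e-04
```

The planted sweep at chr1:12.5 Mb is recovered as a block of relevant
windows: all six cross-population EHH tests flag it with positive sign, it
carries the top-1 % indicine ancestry, sits in the top-1 % Fst windows
against all three references, has reduced diversity, contains the
chromosome-maximum CLR, and overlaps a ROH island. A neutral genome
(`sweep: null` in the config) reports zero relevant regions.

Stage-wise subcommands (`simulate`, `filter`, `scan-ehh`, `scan-clr`,
`diversity`, `roh`, `ancestry`, `consensus`, `report`) expose the same
pipeline piecewise; `--config cfg.yaml` overrides any simulation parameter.
Real data enter as a phased VCF + sample panel TSV
(sample / population / group) and an optional ancestry-dosage TSV.

## Layout

| module | contents |
|---|---|
| `admixscan.panel` | haplotype/genotype panels, sample sheets, window grids |
| `admixscan.io` | VCF and TSV ingestion/emission |
| `admixscan.filters` | MAF/missingness/HWE/quality filters, LD pruning, PI_HAT relatedness, ancestral alleles |
| `admixscan.simulate` | synthetic admixture generator with truth tracts and planted sweeps |
| `admixscan.ehh` | EHH/EHHS decay, iHS, Rsb, XP-EHH, outlier windows |
| `admixscan.clr` | site frequency spectra and the CLR sweep scan |
| `admixscan.diversity` | windowed π and Weir–Cockerham Fst |
| `admixscan.roh` | ROH segments, summaries, islands |
| `admixscan.ancestry` | dosage tracks, global ancestry, excess windows |
| `admixscan.consensus` | the candidate-region caller |
| `admixscan.pipeline` / `admixscan.cli` | orchestration and command line |

See `docs/methods.md` for the statistical model behind each stage, the
defaults and their rationale, and known limitations.
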