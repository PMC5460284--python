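# Methods

## Scope and model

`amtpipe` implements the quantification and statistics layer of an
AMT-tag label-free proteomics study with a matched two-group bulk
transcriptome. The measurement model it assumes (and that the synthetic
generator emulates) is:

* Each peptide species has a fixed monoisotopic neutral mass and a fixed
  normalized elution time (NET ∈ [0, 1]). In each LC-MS run it produces a
  short train of co-eluting deisotoped ion features whose masses carry
  independent Gaussian relative errors (ppm scale) and whose elution
  position is the true NET plus Gaussian drift, discretized onto the
  run's integer scan axis.
* Peptide abundance is log-normal: a per-peptide log2 baseline plus a
  per-(peptide, run) Gaussian log2 noise term. Group effects are planted
  at the protein level (±`effect_size` log2 for a `de_fraction` of
  proteins, exactly 0 otherwise) and propagate to all of a protein's
  peptides. The expression matrix uses the same planted effects for the
  mapped genes plus independent draws for extra genes.
* A Bernoulli(`id_rate`) subset of peptide detections carries an MS/MS
  identification with a search score; a configurable fraction of scores
  falls below the database score filter so the filter is exercised.
  About 5% of peptides are shared between two proteins (non-proteotypic),
  exercising the protein-rollup rule.

## Stage-by-stage procedure

**UMC grouping.** Ions are sorted by neutral mass and chained while
adjacent sorted masses differ by ≤ `mass_tol_ppm` (default 10; ppm is
always `1e6·|m1−m2|/min(m1,m2)`). Because the gap predicate is monotone
along the sorted axis, this equals all-pairs single linkage. Chains are
then split where member scans (sorted) gap by more than `max_scan_gap`
(default 5). Charge states pool together since features arrive as
neutral masses. The UMC mass is the intensity-weighted member mean, the
intensity the member sum, the elution representative the median member
scan (robust to tailing). Partition and intensity conservation are exact
by construction and asserted in tests against a brute-force oracle.

**NET.** Raw NET min-max scales the median scan onto the run's observed
scan range. Cross-run alignment fits, per run, a least-squares line from
raw NET to a reference (the per-peptide median raw NET of identified
UMCs across runs) and applies it to all UMCs, clipped to [0, 1]. A run
with a single distinct scan is rejected as degenerate.

**AMT database and matching.** Identified UMCs with score ≥
`score_threshold` (default 3.0) aggregate per peptide sequence into
average mass and median NET. The score filter applies at build time, not
at match time (match inputs are unidentified). Matching accepts
candidates inside both tolerances (defaults ±10 ppm, ±0.02 NET — the
procedural value; the looser 0.025 sometimes quoted for the same step is
available through the config) and picks the minimizer of the normalized
squared distance `(Δppm/tol_m)² + (ΔNET/tol_t)²`. An exact distance tie
is deliberately left unassigned (conservative and reproducible). Within
a run each peptide keeps only its highest-intensity UMC; the rest are
flagged duplicates so the alignment table gets one intensity per
(peptide, run).

**Alignment, rescue, normalization.** The table's rows are the union of
assigned peptides over runs; consensus mass is the intensity-weighted
mean and consensus NET the median over contributing UMCs. Missing cells
are rescued from the pool of still-unassigned UMCs of that run within
±10 ppm and a tiered NET tolerance: 0.01 when another run of the same
mouse contains the peptide (technical replicate), 0.02 otherwise
(biological). Candidates are consumed greedily by ascending normalized
distance and each UMC fills at most one cell, so one stray feature can
never populate many rows. Cells that rescue cannot fill stay missing —
there is no imputation. Quantile normalization is missing-aware: each
column's quantile curve is interpolated onto a common grid, the
reference is the across-column mean curve, and each observed value maps
through its within-column quantile fraction `(rank−1)/(n_obs−1)` onto
the reference. With complete data this reduces exactly to the classical
mean-order-statistics construction; ranks are preserved; a column with
fewer than two observed values is an error.

**Integrative DE statistic.** On log2 values, per feature: pooled-
variance Student *T* (condition − control, df = n1+n2−2) and
log2-median-ratio (difference of group medians). A feature needs ≥ 2
observed values per group, otherwise it is excluded and reported.
Zero-pooled-variance features get t = 0 when means agree, else the
largest finite |t| in the matrix (flagged). The null is built by
sampling label permutations with replacement (seeded), recomputing both
statistics for every feature, and pooling across features and
permutations — pooling gives fine p-resolution even though a 3v3 design
has only 20 distinct splits. Empirical p's are two-tailed on |statistic|
with the add-one rule `p = (#{|null| ≥ |obs|}+1)/(pool+1)`, so p = 0 is
impossible. The two p's combine by signed Stouffer:
`z_i = sign(stat_i)·Φ⁻¹(1−p_i/2)`, `z = (z_T + z_ratio)/√2` — concordant
statistics reinforce, discordant cancel.

*Calibration of the overall p.* The two statistics are strongly
dependent (both measure the group shift; their correlation under a 3v3
normal null is ≈ 0.75), so the normal-theory p `2(1−Φ(|z|))` is markedly
anticonservative (≈ 14% of null features below 0.05). The package
therefore refers the combined z to its own permutation null — the same
marginal-p + Stouffer construction applied to every permuted statistic
pair — and uses that empirical two-tailed p as `p_overall`; the
closed-form value is reported alongside as `p_stouffer`. This restores
exact type-I calibration (measured 4.5% at the 5% level on 5,000 null
features) while keeping Stouffer's rule as the combination.

**Selection rules.** DEG: `p_overall < 0.05` and |log2-median-ratio| at
or above the 95th percentile of the signed permutation null of the
ratio — a data-dependent cutoff recomputed from the data at hand (it is
≈ 0.52 on the default synthetic study; reference mouse data of this
design put it near 0.42). DEpeptide: `p_overall < 0.05` and
|log2-median-ratio| ≥ 0.58 (1.5-fold). DEP: ≥ 2 distinct same-direction
proteotypic DEpeptides; proteins reaching 2 in both directions are
conflicts, reported but excluded. All thresholds are config knobs.

**Integration.** Overlaps are exact Venn-region counts over a shared
identifier namespace (gene ↔ protein mapping supplied as a two-column
table; unmapped identifiers dropped and counted). Protein abundance per
sample is log2 of the summed linear intensities of the protein's
proteotypic peptides, with technical replicates averaged per mouse;
per-gene mRNA–protein association is Spearman's rho over shared samples
(≥ 3 required; constant vectors excluded and counted). Term enrichment
is an upper-tail hypergeometric test against an explicitly supplied
background — never a whole-genome default — with BH q-values reported
alongside the raw p < 0.05 call. This replaces an external annotation
web service on purpose: the test is exact, offline and reproducible,
at the cost of not reproducing that service's EASE-score variant.

## Defaults and what they represent

| knob | default | meaning |
|---|---|---|
| `n_proteins`, `peptides_per_protein` | 200, 5–10 | desk-scale stand-in for a ~4,400-protein / ~50,000-peptide study |
| `n_bio_per_group`, `n_tech_per_bio` | 3, 1 | 3 vs 3 mice; technical triplicates available via config |
| `mass_error_ppm_sd` | 2 ppm | instrument relative mass error; sits well inside the 10 ppm window |
| `net_error_sd` | 0.005 | elution drift; well inside 0.01 / 0.02 NET tolerances |
| `detection_rate`, `id_rate` | 0.9, 0.6 | per-run peptide detection and MS/MS identification rates |
| `de_fraction`, `effect_size` | 0.1, 1.0 log2 | planted DE scale matching called fractions of ~7–10% in studies of this design |
| `intensity_noise_sd`, `expr_noise_sd` | 0.25 log2 | replicate-to-replicate abundance noise |
| `n_permutations` | 1,000 | permutation draws (with replacement) |

Problem sizes used by the test suite and acceptance script — 5,000
features × 1,000 permutations for the calibration and recovery
experiments, 150–200 proteins for the matching/recall and end-to-end
runs, 50 + 50 brute-force oracle fixtures — were chosen so the whole
default workflow completes in about a minute on one core.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the method assumes:
independent Gaussian mass/NET errors, log-normal intensities,
missingness that is completely at random, effects planted as clean
mean shifts shared by all of a protein's peptides. Real data violate
several of these: correlated mass drift within a run, intensity-
dependent missingness, interference and co-elution, peptide-specific
ionization efficiencies, and partial mRNA–protein concordance. Passing
tests therefore demonstrate that the implementation is correct and
calibrated under its stated model, not that the model captures every
property of a real instrument.

## Known limitations

* **Percentile fold-change cutoff under dense alternatives.** The DEG
  cutoff is a percentile of the permutation null of the ratio, and with
  3 samples per group the median is a majority statistic: every label
  permutation of a truly shifted feature still yields a ratio near the
  full effect. When ≥ ~5% of features carry effects comparable to the
  percentile's tail, the null pool is contaminated and the cutoff is
  dragged toward the planted effect, costing sensitivity; conversely the
  empirical FDR of the joint rule sits near its nominal level only
  because the p-gate is calibrated. The percentile is read from the
  signed null distribution (its literal definition); reading it from
  absolute values raises the cutoff by ~20% and costs ~15 points of
  sensitivity at the default study scale.
* The permutation space of a 3v3 design is tiny (20 splits); pooling
  across features provides resolution but makes feature p's dependent.
* AMT matching reports no false-match rate; the ambiguity rule only
  guards exact ties.
* Rescue is greedy-optimal per candidate distance, not a global optimal
  assignment.
* No empirical-Bayes variance moderation and no multiplicity correction
  on the overall p — selection thresholds the raw p by design, with BH
  q-values reported only in the enrichment output.
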