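# Methods

This note records the models, conventions and design choices behind
`rohscan`, at the level of detail a maintainer or reviewer needs to
reproduce or challenge them.

## 1. Genotype representation and quality control

Genotypes are a dense `samples × markers` int8 matrix with calls 0 (hom-A),
1 (het), 2 (hom-B), −1 (missing). Allele A of a marker is the first allele
listed for it (A1 in a .bim, first allele observed in a .ped). Hom/het
status — the only property downstream analyses use — is invariant to this
labelling. A consequence for the text dialect: .ped/.map stores no allele
order, so a write/read round trip reproduces genotypes exactly as allele
letters but may relabel which homozygote is call 0 vs 2 at markers whose
first non-missing genotype is hom-B. The binary dialect stores A1/A2 and
round-trips bit-exactly.

QC order and boundaries (all deliberate and fixed):

* samples with missing fraction **strictly above** 5% are removed first —
  sample filtering changes marker MAF denominators, so the order matters;
* markers with missing fraction strictly above 10% are then removed;
* markers with MAF **strictly below** 0.05 are removed (boundary values
  retained, following the "MAF > 0.05 kept" inequality direction); MAF is
  computed on retained samples, missing calls excluded;
* a marker failing both filters is counted under missingness.

The per-marker missing-rate reading of "genotype missing rate" (PLINK
`--geno` semantics) is assumed.

## 2. ROH detection

Six-parameter sliding-window scan (defaults for a ~700K bovine array):

| parameter | default | meaning |
|---|---|---|
| `window_snps` | 50 | window width in SNPs, slid one SNP at a time |
| `window_max_het` | 1 | max heterozygous calls per homozygous window |
| `window_max_missing` | 2 | max missing calls per homozygous window |
| `hit_threshold` | 0.05 | min fraction of covering windows that are homozygous for a SNP to be eligible |
| `min_snps` | 100 | min SNPs per emitted ROH |
| `min_length_kb` | 500 | min bp span per ROH |
| `max_density_kb_per_snp` | 50 | max mean spacing (span / SNP count) |
| `max_gap_kb` | 100 | max gap between consecutive member SNPs |
| `seg_max_het` | 1 | max het calls per emitted ROH |
| `seg_max_missing` | 2 | max missing calls per emitted ROH |

Procedure per sample × chromosome: (a) window het/missing counts by
convolution; a chromosome shorter than the window uses the single
full-chromosome window; per-SNP hit fractions use the realized number of
covering windows (no padding at chromosome ends); (b) SNPs with fraction ≥
threshold are eligible; (c) maximal eligible runs are split at oversized
gaps; (d) a candidate that satisfies every segment constraint is emitted
whole; otherwise its maximal constraint-satisfying sub-intervals are
emitted, made disjoint by a recursive rule — keep the longest (bp span,
ties to the leftmost), then re-enumerate within the uncovered flanks. The
recursion matters: a one-pass greedy would silently discard the passing
run beyond a second heterozygote. The het/missing caps are enforced at
both window and segment level — the conservative reading of "per ROH"
limits, matching the layered design of window-based callers.

Conventions: coordinates are 1-based inclusive; ROH length is
`end_bp − start_bp` (so length equals the difference of the printed
boundary columns in standard summary tables); size classes are half-open
with the upper class winning ties (exactly 1 Mb → Medium, exactly 5 Mb →
Large); the density check is mean spacing `length/n_snps ≤ 50 kb`.

**Relationship to exhaustive enumeration.** For parameter settings with
`hit_threshold × window_snps ≤ 1` and `min_snps ≥ window_snps` (e.g. the
scaled test setting: 5-SNP windows, 10-SNP minimum), the caller provably
equals a brute-force oracle that enumerates every contiguous interval
against the segment constraints and applies the same disjoint-selection
rule: any constraint-passing interval is fully eligible, so the two
enumeration strategies see the same maximal set. At full-scale defaults
(0.05 × 50 = 2.5, so an edge SNP needs ≥ 3 passing windows) window
eligibility may trim a few SNPs at run edges relative to the oracle —
never add any — which is why oracle equivalence is asserted under scaled
parameters and recovery under defaults is asserted with a one-window-span
boundary tolerance.

## 3. Inbreeding coefficients

`F_HOM = (O − E)/(N − E)` with `E = Σ 1 − 2 p_i (1 − p_i) · n_i/(n_i − 1)`
over the individual's non-missing markers (method-of-moments with the
small-sample correction; `n_i` = non-missing individuals at marker *i*).
The estimator family is pinned by the fact that raw homozygote proportions
cannot be negative while excess-homozygosity F can. Allele frequencies are
estimated in-sample from the QC'd panel. Markers that are monomorphic
in-sample or have `n_i < 2` are skipped (degenerate expectation) with a
warning.

`F_ROH` divides an individual's summed ROH length by the SNP-covered
autosomal length — per chromosome, last SNP bp − first SNP bp, summed.
SNP-span is the literal reading of "covered by SNPs"; assembly length
would give systematically smaller coefficients and is not what an
array-based study can observe. The denominator is an explicit argument, so
callers can substitute assembly lengths if desired.

## 4. Consensus regions

The population scan is defined on the per-SNP ROH-frequency track (number
of individuals with a ROH covering the SNP / n), not on pool-based
grouping of allelically matching segments: the frequency track is what
gets plotted and thresholded in practice, and pool-based grouping depends
on an allelic-match parameter that cannot be standardized. Regions are
maximal runs of consecutive SNPs with frequency **strictly** above the
threshold (default 10%), never spanning a chromosome break, bounded by the
first/last qualifying SNP. Interval annotation reports every
(region, annotation) pair with ≥ 1 shared bp (inclusive test:
`min(ends) ≥ max(starts)`); the reported overlap is the span
`min(ends) − max(starts)`, consistent with the `end − start` length
convention (a coincident annotation has overlap = region length; intervals
sharing exactly one bp are reported with span 0).

## 5. Region association

Merging uses the 1-based inclusive "share ≥ 1 bp" rule: `[100,200]` and
`[200,300]` merge; `[100,200]` and `[201,300]` do not. Coverage of a
region by a sample is summed intersection span / region span, in [0,1]
because within-sample segments never overlap. `carrier_frequency` is the
fraction of samples with ≥ 1 overlapping segment (the count/n convention
of published region tables), not mean coverage.

Association is the two-stage procedure: OLS-adjust the trait for farm
(categorical), age (numeric), gender and generation (categorical,
indicator contrasts; constant columns dropped as intercept-aliased;
rank-deficient designs raise with the aliased columns named), then simple
regression per region with t-based two-sided p on n − 2 df. By default the
coverage is **also residualized** on the same fixed effects before the
regression (Frisch–Waugh): the slope then equals the joint
covariates-plus-coverage GLM and is unbiased for the dosage effect,
whereas regressing residuals on raw coverage attenuates the slope by
roughly (covariate dimension)/(sample size) — enough to push a
beta-within-2-SE recovery rate from ~95% down to ~91% at n = 400 with five
covariate dimensions. Both routes are exposed
(`adjust_coverage=True/False`); the raw-coverage route is retained for
comparison with studies that adjusted only the phenotype. Samples with
missing phenotype or covariates are dropped per trait, not globally.
Monomorphic regions (zero coverage variance) are skipped with a logged
reason.

FDR: Benjamini–Hochberg step-up, and Storey q-values computed as
`π̂₀ ×` the BH values with π̂₀ from the smoother method (cubic spline of
π₀(λ) over λ = 0.05…0.95, evaluated at λ = 0.95, clipped to (0,1]; falls
back to 1 — i.e. BH — when too few p-values support the spline). q-values
are computed across regions within each trait. Significance conventions:
p < 0.01 "significant", q < 0.10 "suggestive".

## 6. Synthetic panels

The generator emulates a dense autosomal array: exponential inter-SNP
spacing (configurable mean, default 5 kb), per-marker allele frequencies
from a uniform or folded-beta distribution, Hardy–Weinberg background
genotypes, and autozygous tracts planted directly — hom calls with the
allele drawn by its frequency — at a Poisson per-genome rate with fixed or
exponential lengths. Within tracts, calls flip to het with a genotyping
error probability (default 1e-3; recovery experiments use 1e-4, the
concordance level of modern arrays); all calls go missing at a global
missing rate. Tracts within a genome keep ≥ 200 kb apart so each planted
tract represents a distinct autozygous run rather than an accidentally
split one. Island regions — shared tract locations carried with a
configured frequency — provide population structure for the consensus
scan; a causal region is an island whose coverage enters one trait with a
chosen slope. Phenotypes are fixed covariate effects (3-level farm,
uniform age 24–60 months, 2-level gender and generation) + dosage +
Gaussian noise, with every generative component stored in the truth table.
A single seed drives hierarchical generator streams (`SeedSequence.spawn`),
so panels are bitwise reproducible.

What the generator does **not** model: linkage disequilibrium and its
decay, realistic allele-frequency spectra under drift or selection, cattle
demography, chromosome-length heterogeneity, or array ascertainment.
Passing tests therefore demonstrate correctness of the detection and
inference machinery on panels with known truth — not that the pipeline's
population-level numbers on real cattle data would be reproduced.

## 7. Validation experiment sizes

Chosen as the package's own test conditions: oracle equivalence on 200
random 300-SNP panels (scaled parameters); tract recovery on 100 animals
(~85 two-Mb tracts) with recall evaluated over tracts whose realized calls
satisfy the per-ROH het/missing caps — a planted tract that genotyping
error endows with three missing calls is not one ROH by the definition
itself and is counted separately rather than against the caller; 100
HWE-only null panels (MAF uniform 0.3–0.5) for specificity; F_ROH recovery
at planted fractions {0, 0.05, 0.1, 0.2, 0.3} with 200 animals each on a
75 Mb genome; ≥ 2,000 null region×trait tests (island panels, multiple
independent phenotype draws) for type-I rate and KS uniformity; 100
replicates at n = 400, β = 5, σ = 1 for effect recovery. The analysis
drivers use a 200-animal, 240 Mb cohort (roughly a tenth of the cattle
autosomes at array density).

## 8. Known limitations

* Consensus regions approximate pool-based grouping by frequency
  thresholding; boundaries of published pool-based tables are not exactly
  recoverable.
* F_HOM uses the per-individual sum over that individual's non-missing
  markers, so individuals with different missing patterns have slightly
  different expectations — intended, but worth knowing when comparing
  across very incomplete samples.
* The window-eligibility trimming at full-scale parameters (≤ a few SNPs
  per run edge) is inherent to window-based calling and bounded by one
  window span in all recovery experiments.
* The sub-interval search within a failing candidate is quadratic in the
  candidate's SNP count; candidates that pass outright (the overwhelming
  majority) bypass it.
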