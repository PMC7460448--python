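# rohscan

Runs-of-homozygosity (ROH) analysis for dense SNP-array genotypes, built
around the workflow used in cattle genomics: detect ROH per animal with a
sliding-window scan, estimate genomic inbreeding two ways (F_HOM and
F_ROH), scan the population for consensus ROH regions (ROH islands), and
test nonredundant ROH regions for dosage association with quantitative
carcass and conformation traits.

## Who this is for

Livestock and population geneticists working with PLINK-format SNP-array
panels (e.g. a ~700K bovine array) who want a transparent, testable
re-implementation of the standard ROH pipeline — including a synthetic-data
generator with planted autozygous tracts, so every stage can be validated
end to end without access to proprietary genotypes.

## The statistics at the core

**ROH detection.** A window of 50 consecutive SNPs slides along each
autosome of each animal; a window is homozygous if it has ≤ 1 heterozygous
and ≤ 2 missing calls. A SNP is eligible when ≥ 5% of the windows covering
it are homozygous. Maximal eligible runs, split at inter-SNP gaps > 100 kb,
become ROH when they have ≥ 100 SNPs, span ≥ 500 kb, average ≤ 50 kb/SNP,
and themselves contain ≤ 1 het and ≤ 2 missing calls. ROH are classed as
Small (0.5–1 Mb), Medium (1–5 Mb) or Large (≥ 5 Mb).

**Inbreeding.** For animal *j* with non-missing markers *M_j*,

    F_HOM = (O_hom − E_hom) / (N − E_hom),
    E_hom = Σ_{i∈M_j} [1 − 2 p_i (1 − p_i) · n_i/(n_i − 1)]

(method-of-moments excess homozygosity; can be negative), and

    F_ROH = Σ length(ROH_j) / L_auto,

where `L_auto` is the SNP-covered autosomal length (per chromosome, last
SNP bp − first SNP bp, summed).

**Consensus regions.** The per-SNP ROH frequency is the fraction of animals
whose ROH cover the SNP; maximal runs of SNPs with frequency strictly
above 10% are reported as consensus regions and can be annotated against
QTL/gene interval files by ≥ 1 bp overlap.

**Region association.** All animals' ROH merge (≥ 1 bp overlap) into
nonredundant regions; per animal the dosage is the proportion of a region
covered by its ROH. Each trait is adjusted for farm, age, gender and
generation by OLS, the coverage is residualized on the same fixed effects
(Frisch–Waugh, so the slope equals the joint GLM's), and the regression of
residuals on residuals gives per-region slopes, *p*-values (t, n − 2 df),
and Storey or Benjamini–Hochberg *q*-values per trait.

## Worked example

The `analysis/` scripts run a complete scaled study on a simulated
Wagyu-like cohort (200 animals, 10 autosomes × 3,000 SNPs, planted
autozygous tracts, ten shared ROH islands, one causal body-height region):

```bash
python analysis/01_simulate_panel.py
python analysis/02_qc_and_detect.py
python analysis/03_inbreeding.py
python analysis/04_consensus_regions.py
python analysis/05_region_association.py
```

which prints (abridged):

```
panel: 200 animals x 30000 SNPs on 10 autosomes
detected 1256 ROH segments; mean 6.28 per animal, mean summed length 13.12 Mb
longest ROH: chr5 10.9 Mb with 1378 SNPs
F_HOM range: 0.007 .. 0.150
F_ROH range: 0.006 .. 0.144
F_HOM vs F_ROH: r = 0.960 (p = 1.16e-111, n = 200)
10 consensus regions exceed 10% ROH frequency (peak 0.55)
11 nonredundant ROH regions from 1256 segments
1 region x trait pairs at p < 0.01; 1 at q < 0.10
causal region check: chr3:1243494-23708277 x body_height beta = 13.05, p = 3.16e-11
```

The mean per-animal count and summed length summarize individual
autozygosity; the 0.96 correlation shows the two inbreeding estimators
agree on ranked inbreeding; the consensus scan recovers every planted
island; and the only region×trait pair passing p < 0.01 (and q < 0.10) is
the planted causal region for the trait it was planted on. Tables land
under `results/`.

A CLI mirrors the library for shell use:
`rohscan qc | detect | inbreeding | consensus | assoc | simulate --help`.

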