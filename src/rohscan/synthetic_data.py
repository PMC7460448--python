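"""Synthetic SNP-array panels with planted autozygous tracts.

The generator emulates a dense autosomal genotyping array for a livestock
population: marker positions with exponential inter-SNP spacing, background
genotypes in Hardy-Weinberg equilibrium at per-marker allele frequencies,
and — planted directly rather than via coalescent ancestry — autozygous
tracts within which an individual is homozygous (with a small genotyping
error rate converting single calls to heterozygotes).  Optional *island*
regions are shared tract locations carried by a configurable fraction of
individuals, which is what makes population-level consensus regions and a
polymorphic causal region possible.  Phenotypes are generated as fixed
covariate effects (farm, age, gender, generation) plus an optional
region-dosage effect on one trait plus Gaussian noise, with every
generative component recorded in a truth table.

Tracts are identity-by-descent by construction only in their homozygosity
structure; the generator does not model linkage disequilibrium, allele
frequency spectra under drift, or realistic chromosome lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, write_plink

#: The eight carcass/conformation traits simulated by default.
TRAITS = ["fat_coverage", "slaughter_weight", "backfat_thickness",
          "ribeye_area", "carcass_length", "body_height",
          "chest_circumference", "body_length"]


@dataclass(frozen=True)
class CausalRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    beta: float
    trait: str = "body_height"
    carrier_frequency: float = 0.3


@dataclass(frozen=True)
class IslandSpec:
    """A shared tract location carried by a fraction of individuals."""

    chromosome: int
    start_bp: int
    end_bp: int
    carrier_frequency: float


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulated study; ``seed`` determines everything."""

    n_samples: int = 50
    n_autosomes: int = 3
    snps_per_chromosome: int = 2000
    mean_spacing_bp: int = 5000
    maf_distribution: tuple = ("uniform", 0.1, 0.5)
    tract_rate_per_genome: float = 2.0
    tract_length_distribution: tuple = ("fixed", 2_000_000)
    #: planted tracts within one genome are kept at least this far apart so
    #: each represents a distinct autozygous run rather than a split one
    min_tract_separation_bp: int = 200_000
    het_error_rate: float = 0.001
    missing_rate: float = 0.001
    causal_region: Optional[CausalRegion] = None
    island_regions: tuple[IslandSpec, ...] = ()
    covariate_effects: dict = field(default_factory=lambda: {
        "farm": (0.0, 1.5, -1.0), "age": 0.05, "gender": 2.0, "generation": -1.0})
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("het_error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tract_rate_per_genome < 0:
            raise ValueError("tract_rate_per_genome must be >= 0")


@dataclass
class TruthTable:
    """Ground truth of one simulated panel."""

    tracts: pd.DataFrame          # sample_id, chromosome, start_bp, end_bp
    autozygosity: pd.Series       # per sample: planted bp / SNP-covered bp
    covered_length_bp: int
    components: Optional[pd.DataFrame] = None  # sample_id, trait, covariate_part, dosage_part, noise

    def tracts_of(self, sample_id: str) -> pd.DataFrame:
        return self.tracts[self.tracts["sample_id"] == sample_id]


def _draw_maf(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size)
    if kind == "beta":
        # fold onto (0, 0.5] so the value really is the *minor* frequency
        return np.minimum(rng.beta(dist[1], dist[2], size), 0.5).clip(1e-3, 0.5)
    raise ValueError(f"unknown maf_distribution {dist!r}")


def _draw_tract_length(dist: tuple, rng: np.random.Generator) -> int:
    kind = dist[0]
    if kind == "fixed":
        return int(dist[1])
    if kind == "exponential":
        return max(1, int(rng.exponential(dist[1])))
    raise ValueError(f"unknown tract_length_distribution {dist!r}")


def _overlaps(start: int, end: int, placed: list[tuple[int, int, int]],
              chrom: int, buffer_bp: int = 0) -> bool:
    return any(c == chrom and start <= e + buffer_bp and end >= s - buffer_bp
               for c, s, e in placed)


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, MarkerMap, TruthTable]:
    """Simulate a genotype panel with planted autozygous tracts.

    Marker positions are cumulative exponential spacings; background calls
    are Hardy-Weinberg draws at each marker's allele frequency; within a
    planted tract the call is homozygous for an allele drawn by its
    frequency, then flipped to heterozygous with probability
    ``het_error_rate``; every call is set missing with probability
    ``missing_rate``.  Fully reproducible from ``cfg.seed``.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_map, rng_geno, rng_tract, rng_err = [np.random.default_rng(s)
                                             for s in ss.spawn(4)]
    n, m_per, n_chrom = cfg.n_samples, cfg.snps_per_chromosome, cfg.n_autosomes

    # marker map
    chroms, positions = [], []
    for c in range(1, n_chrom + 1):
        spacing = np.maximum(1, rng_map.exponential(
            cfg.mean_spacing_bp, m_per).astype(np.int64))
        pos = np.cumsum(spacing)
        positions.append(pos)
        chroms.append(np.full(m_per, c, dtype=np.int64))
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions)
    m = len(pos_arr)
    ids = np.array([f"snp_{c}_{i}" for c, i in
                    zip(chrom_arr, np.concatenate([np.arange(m_per)] * n_chrom))],
                   dtype=object)
    alleles = np.tile(np.array([["A", "B"]], dtype=object), (m, 1))
    mm = MarkerMap(chrom_arr, pos_arr, ids, alleles)

    p = _draw_maf(cfg.maf_distribution, m, rng_geno)  # B-allele frequency
    calls = rng_geno.binomial(2, p, size=(n, m)).astype(np.int8)

    # chromosome spans for tract placement
    spans = {}
    for c in range(1, n_chrom + 1):
        sl = mm.chromosome_slice(c)
        spans[c] = (int(pos_arr[sl.start]), int(pos_arr[sl.stop - 1]))
    covered = mm.snp_covered_length_bp()
    chrom_lens = np.array([spans[c][1] - spans[c][0] for c in range(1, n_chrom + 1)],
                          dtype=float)
    chrom_weights = chrom_lens / chrom_lens.sum()

    samples = [f"animal_{i:04d}" for i in range(n)]
    tract_rows: list[dict] = []
    auto_frac = np.zeros(n)
    islands = list(cfg.island_regions)
    if cfg.causal_region is not None:
        cr = cfg.causal_region
        islands.append(IslandSpec(cr.chromosome, cr.start_bp, cr.end_bp,
                                  cr.carrier_frequency))
    for i in range(n):
        placed: list[tuple[int, int, int]] = []
        for isl in islands:
            lo, hi = spans[isl.chromosome]
            if isl.end_bp - isl.start_bp > hi - lo:
                raise ValueError("island tract longer than its chromosome span")
            if rng_tract.random() < isl.carrier_frequency and \
                    not _overlaps(isl.start_bp, isl.end_bp, placed, isl.chromosome,
                                  cfg.min_tract_separation_bp):
                placed.append((isl.chromosome, isl.start_bp, isl.end_bp))
        n_tracts = rng_tract.poisson(cfg.tract_rate_per_genome)
        for _ in range(n_tracts):
            length = _draw_tract_length(cfg.tract_length_distribution, rng_tract)
            for _attempt in range(50):
                c = int(rng_tract.choice(n_chrom, p=chrom_weights)) + 1
                lo, hi = spans[c]
                if length > hi - lo:
                    raise ValueError(
                        f"tract of {length} bp exceeds chromosome {c} span {hi - lo}")
                start = int(rng_tract.integers(lo, hi - length + 1))
                end = start + length
                if not _overlaps(start, end, placed, c, cfg.min_tract_separation_bp):
                    placed.append((c, start, end))
                    break
        for c, s, e in placed:
            tract_rows.append({"sample_id": samples[i], "chromosome": c,
                               "start_bp": s, "end_bp": e})
            sl = mm.chromosome_slice(c)
            seg_pos = pos_arr[sl]
            a = sl.start + int(np.searchsorted(seg_pos, s, side="left"))
            b = sl.start + int(np.searchsorted(seg_pos, e, side="right"))
            if b > a:
                hom_b = rng_geno.random(b - a) < p[a:b]
                calls[i, a:b] = np.where(hom_b, 2, 0).astype(np.int8)
        auto_frac[i] = sum(e - s for _, s, e in placed) / covered

    # genotyping error inside tracts / everywhere: het flips then missingness
    if cfg.het_error_rate > 0:
        sample_idx = {s: i for i, s in enumerate(samples)}
        tract_mask = np.zeros((n, m), dtype=bool)
        for row in tract_rows:
            i = sample_idx[row["sample_id"]]
            sl = mm.chromosome_slice(row["chromosome"])
            seg_pos = pos_arr[sl]
            a = sl.start + int(np.searchsorted(seg_pos, row["start_bp"], side="left"))
            b = sl.start + int(np.searchsorted(seg_pos, row["end_bp"], side="right"))
            tract_mask[i, a:b] = True
        flip = tract_mask & (rng_err.random((n, m)) < cfg.het_error_rate)
        calls[flip] = 1
    if cfg.missing_rate > 0:
        calls[rng_err.random((n, m)) < cfg.missing_rate] = MISSING

    tracts = pd.DataFrame(tract_rows, columns=["sample_id", "chromosome",
                                               "start_bp", "end_bp"])
    truth = TruthTable(tracts=tracts,
                       autozygosity=pd.Series(auto_frac, index=samples,
                                              name="autozygosity"),
                       covered_length_bp=covered)
    return GenotypeMatrix(samples, calls), mm, truth


def true_region_coverage(truth: TruthTable, chromosome: int,
                         start_bp: int, end_bp: int) -> pd.Series:
    """Per-sample proportion of a region's span covered by planted tracts."""
    span = end_bp - start_bp
    cov = pd.Series(0.0, index=truth.autozygosity.index)
    for r in truth.tracts.itertuples(index=False):
        if r.chromosome != chromosome:
            continue
        inter = min(r.end_bp, end_bp) - max(r.start_bp, start_bp)
        if inter > 0:
            cov[r.sample_id] += inter / span
    return cov.clip(upper=1.0)


def simulate_phenotypes(truth: TruthTable, cfg: SimConfig,
                        coverage: pd.Series | None = None) -> pd.DataFrame:
    """Phenotype/covariate table with known generative components.

    Each trait is covariate effects + (for the causal trait) beta times the
    causal region's coverage + N(0, noise_sd^2).  ``coverage`` defaults to
    the oracle coverage computed from the planted tracts.  All components
    are stored in ``truth.components``.
    """
    ss = np.random.SeedSequence((cfg.seed, 1))
    rng = np.random.default_rng(ss)
    samples = list(truth.autozygosity.index)
    n = len(samples)

    farm = rng.integers(0, 3, n)
    age = rng.uniform(24.0, 60.0, n)
    gender = rng.integers(0, 2, n)
    generation = rng.integers(0, 2, n)
    eff = cfg.covariate_effects
    covariate_part = (np.asarray(eff["farm"])[farm] + eff["age"] * age
                      + eff["gender"] * gender + eff["generation"] * generation)

    dosage = np.zeros(n)
    causal_trait = None
    if cfg.causal_region is not None:
        cr = cfg.causal_region
        causal_trait = cr.trait
        if coverage is None:
            coverage = true_region_coverage(truth, cr.chromosome, cr.start_bp, cr.end_bp)
        dosage = cr.beta * coverage.reindex(samples).fillna(0.0).to_numpy()

    table = pd.DataFrame({
        "sample_id": samples,
        "farm": [f"farm_{k}" for k in farm],
        "age": age,
        "gender": np.where(gender == 1, "male", "female"),
        "generation": [f"gen_{k}" for k in generation],
    })
    comp_rows = []
    for trait in TRAITS:
        noise = rng.normal(0.0, cfg.noise_sd, n)
        dose = dosage if trait == causal_trait else np.zeros(n)
        table[trait] = covariate_part + dose + noise
        comp_rows.append(pd.DataFrame({
            "sample_id": samples, "trait": trait,
            "covariate_part": covariate_part, "dosage_part": dose,
            "noise": noise}))
    truth.components = pd.concat(comp_rows, ignore_index=True)
    return table


def write_fixture(cfg: SimConfig, out_prefix: str | Path,
                  dialect: str = "binary") -> tuple[GenotypeMatrix, MarkerMap, TruthTable]:
    """Simulate a panel and write PLINK files plus pheno.tsv and truth.tsv."""
    out_prefix = Path(out_prefix)
    gm, mm, truth = simulate_panel(cfg)
    pheno = simulate_phenotypes(truth, cfg)
    write_plink(gm, mm, out_prefix, dialect=dialect)
    pheno.to_csv(out_prefix.with_suffix(".pheno.tsv"), sep="\t", index=False)
    truth.tracts.to_csv(out_prefix.with_suffix(".truth.tsv"), sep="\t", index=False)
    return gm, mm, truth
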