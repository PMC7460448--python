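"""Validation experiments: oracle equivalence, planted-truth recovery, calibration.

Everything here recomputes a quantity from scratch on simulated data, so the
same functions back the test suite, the acceptance script and the analysis
drivers.  ``brute_force_segments`` is an independent re-derivation of the
ROH definition by exhaustive interval enumeration — it never calls the
sliding-window code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, allele_frequencies
from .inbreeding_stats import correlate, f_hom, f_roh
from .region_association import (associate, adjust_phenotype, coverage_matrix,
                                 merge_regions, residualize_covariates,
                                 run_association)
from .roh_detection import (RohParams, RohSegment, call_segments, detect_roh,
                            select_disjoint)
from .synthetic_data import (TRAITS, CausalRegion, IslandSpec, SimConfig,
                             TruthTable, simulate_panel, simulate_phenotypes,
                             true_region_coverage)

#: Scaled-down window parameters used for exhaustive-oracle comparisons.
SCALED_PARAMS = RohParams(window_snps=5, window_max_het=1, window_max_missing=2,
                          hit_threshold=0.05, min_snps=10, min_length_kb=20.0,
                          max_density_kb_per_snp=50.0, max_gap_kb=100.0,
                          seg_max_het=1, seg_max_missing=2)


def brute_force_segments(calls: np.ndarray, positions: np.ndarray,
                         params: RohParams, sample_id: str = "",
                         chromosome: int = 1) -> list[RohSegment]:
    """ROH by exhaustive enumeration of every contiguous SNP interval.

    An interval passes when it satisfies every segment-level constraint
    (SNP count, bp span, mean spacing, het/missing caps, no internal gap
    above the cap); maximal passing intervals are found by direct
    enumeration and made disjoint by the same documented longest-first
    recursive rule as the caller.  O(n^2); intended for panels of a few
    hundred SNPs.
    """
    calls = np.asarray(calls)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(calls)
    if n == 0:
        return []
    chet = np.concatenate(([0], np.cumsum(calls == 1)))
    cmiss = np.concatenate(([0], np.cumsum(calls == MISSING)))
    gaps_bad = np.diff(positions) > params.max_gap_kb * 1000.0
    cbad = np.concatenate(([0], np.cumsum(gaps_bad)))
    min_len_bp = params.min_length_kb * 1000.0
    max_density_bp = params.max_density_kb_per_snp * 1000.0

    js = np.arange(n)

    def enumerate_maximal(lo: int, hi: int) -> list[tuple[int, int]]:
        maximal: list[tuple[int, int]] = []
        best_j = -1
        for i in range(lo, hi - params.min_snps + 2):
            jj = js[i + params.min_snps - 1:hi + 1]
            cnt = jj - i + 1
            length = positions[jj] - positions[i]
            ok = ((length >= min_len_bp)
                  & (length / cnt <= max_density_bp)
                  & (chet[jj + 1] - chet[i] <= params.seg_max_het)
                  & (cmiss[jj + 1] - cmiss[i] <= params.seg_max_missing)
                  & (cbad[jj] - cbad[i] == 0))
            if not ok.any():
                continue
            jmax = int(jj[np.nonzero(ok)[0][-1]])
            if jmax > best_j:
                maximal.append((i, jmax))
                best_j = jmax
        return maximal

    chosen = select_disjoint(enumerate_maximal, 0, n - 1, positions)
    return [RohSegment(sample_id, chromosome, int(positions[i]), int(positions[j]),
                       j - i + 1, int(chet[j + 1] - chet[i]),
                       int(cmiss[j + 1] - cmiss[i]))
            for i, j in chosen]


def _random_vector(rng: np.random.Generator, n_snps: int
                   ) -> tuple[np.ndarray, np.ndarray]:
    """A call vector with long quasi-homozygous stretches and noisy stretches."""
    spacing = np.maximum(1, rng.exponential(3000, n_snps).astype(np.int64))
    # occasionally inject an oversized gap to exercise the gap-split rule
    big = rng.random(n_snps) < 0.01
    spacing[big] += 150_000
    positions = np.cumsum(spacing)
    # piecewise het intensity: homozygous-ish blocks alternate with HWE blocks
    calls = np.empty(n_snps, dtype=np.int8)
    i = 0
    while i < n_snps:
        block = int(rng.integers(10, 80))
        hetp = rng.choice([0.01, 0.05, 0.45])
        j = min(n_snps, i + block)
        u = rng.random(j - i)
        block_calls = np.where(u < hetp, 1, np.where(rng.random(j - i) < 0.5, 0, 2))
        miss = rng.random(j - i) < 0.02
        block_calls[miss] = MISSING
        calls[i:j] = block_calls
        i = j
    return calls, positions


def oracle_agreement(seed: int, n_panels: int = 200, n_snps: int = 300) -> float:
    """Fraction of random panels on which the sliding-window caller's
    segment set exactly equals the brute-force oracle's (scaled parameters)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_panels):
        calls, positions = _random_vector(rng, n_snps)
        got = call_segments(calls, positions, SCALED_PARAMS)
        want = brute_force_segments(calls, positions, SCALED_PARAMS)
        agree += set(got) == set(want)
    return agree / n_panels


@dataclass
class RecoveryResult:
    n_tracts: int
    n_recovered: int
    recall: float
    max_boundary_error_bp: int
    window_span_bp: int
    #: planted tracts whose realized calls violate the ROH definition
    #: itself (> seg_max_het hets or > seg_max_missing missing calls) and
    #: which therefore cannot be one ROH under any definition-honoring caller
    n_definition_inconsistent: int = 0


def tract_recovery(seed: int, n_samples: int = 100,
                   params: RohParams | None = None) -> RecoveryResult:
    """Recall and boundary accuracy for planted tracts of 2x the minimum length.

    Every planted 2 Mb tract (>= 2x the 500 kb minimum, ~400 SNPs at 5 kb
    spacing) whose realized calls still satisfy the per-ROH het/missing caps
    should be recovered: the union of detected segments overlapping the
    tract must have both boundaries within one window span of the truth.
    Tracts that the simulated genotyping error itself breaks (e.g. three
    missing calls, where the ROH definition allows two) are counted
    separately — they are not one ROH by definition, so no caller honoring
    the definition can return them whole.  The genotyping-error rate
    emulates modern array concordance (~1e-4 miscalls per call).
    """
    params = params or RohParams()
    cfg = SimConfig(n_samples=n_samples, n_autosomes=5, snps_per_chromosome=2000,
                    mean_spacing_bp=5000, maf_distribution=("uniform", 0.3, 0.5),
                    tract_rate_per_genome=1.0,
                    tract_length_distribution=("fixed", 2_000_000),
                    het_error_rate=1e-4, missing_rate=0.001, seed=seed)
    gm, mm, truth = simulate_panel(cfg)
    segments = detect_roh(gm, mm, params)
    by_sample_chrom: dict[tuple[str, int], list[RohSegment]] = {}
    for s in segments:
        by_sample_chrom.setdefault((s.sample_id, s.chromosome), []).append(s)
    window_span_bp = params.window_snps * cfg.mean_spacing_bp
    sample_idx = {s: i for i, s in enumerate(gm.samples)}
    n_tracts = n_rec = n_broken = 0
    max_err = 0
    for t in truth.tracts.itertuples(index=False):
        sl = mm.chromosome_slice(int(t.chromosome))
        pos = mm.position_bp[sl]
        lo = sl.start + int(np.searchsorted(pos, t.start_bp, side="left"))
        hi = sl.start + int(np.searchsorted(pos, t.end_bp, side="right"))
        member = gm.calls[sample_idx[t.sample_id], lo:hi]
        if ((member == 1).sum() > params.seg_max_het
                or (member == MISSING).sum() > params.seg_max_missing):
            n_broken += 1
            continue
        n_tracts += 1
        hits = [s for s in by_sample_chrom.get((t.sample_id, t.chromosome), [])
                if min(s.end_bp, t.end_bp) > max(s.start_bp, t.start_bp)]
        if not hits:
            continue
        union_start = min(s.start_bp for s in hits)
        union_end = max(s.end_bp for s in hits)
        err = max(abs(union_start - t.start_bp), abs(union_end - t.end_bp))
        if err <= window_span_bp:
            n_rec += 1
            max_err = max(max_err, err)
    return RecoveryResult(n_tracts=n_tracts, n_recovered=n_rec,
                          recall=n_rec / n_tracts if n_tracts else float("nan"),
                          max_boundary_error_bp=max_err,
                          window_span_bp=window_span_bp,
                          n_definition_inconsistent=n_broken)


def null_panel_segments(seed: int, n_panels: int = 100, n_samples: int = 10,
                        params: RohParams | None = None) -> int:
    """Total segments called on HWE-only panels (MAF uniform on [0.3, 0.5]).

    With an expected heterozygosity around 0.42 a 100-SNP quasi-homozygous
    run essentially never arises, so the expectation is zero.
    """
    params = params or RohParams()
    total = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_panels):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = SimConfig(n_samples=n_samples, n_autosomes=1,
                        snps_per_chromosome=3000, mean_spacing_bp=2000,
                        maf_distribution=("uniform", 0.3, 0.5),
                        tract_rate_per_genome=0.0, het_error_rate=0.0,
                        missing_rate=0.0, seed=sub_seed)
        gm, mm, _ = simulate_panel(cfg)
        total += len(detect_roh(gm, mm, params))
    return total


@dataclass
class FrohRecoveryResult:
    levels: list[float]
    mean_froh: list[float]
    mean_planted: list[float]
    max_abs_error: float
    fhom_froh_r: float


def froh_recovery(seed: int, levels: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.3),
                  n_samples: int = 200) -> FrohRecoveryResult:
    """Mean F_ROH against the planted autozygosity fraction per level.

    For each target fraction g, a panel is simulated whose expected planted
    autozygosity is g (fixed 2 Mb tracts at a Poisson rate of
    g x genome / 2 Mb); F_ROH is computed from detected ROH and compared to
    g, and the F_HOM-F_ROH correlation is pooled over the inbred panels.
    """
    params = RohParams()
    genome_bp = 5 * 3000 * 5000  # autosomes x SNPs x mean spacing
    tract_bp = 2_000_000
    mean_froh, mean_planted = [], []
    fh_all, fr_all = [], []
    ss = np.random.SeedSequence(seed)
    for g, child in zip(levels, ss.spawn(len(levels))):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = SimConfig(n_samples=n_samples, n_autosomes=5,
                        snps_per_chromosome=3000, mean_spacing_bp=5000,
                        maf_distribution=("uniform", 0.3, 0.5),
                        tract_rate_per_genome=g * genome_bp / tract_bp,
                        tract_length_distribution=("fixed", tract_bp),
                        het_error_rate=0.001, missing_rate=0.001, seed=sub_seed)
        gm, mm, truth = simulate_panel(cfg)
        segments = detect_roh(gm, mm, params)
        covered = mm.snp_covered_length_bp()
        by_sample: dict[str, list[RohSegment]] = {s: [] for s in gm.samples}
        for s in segments:
            by_sample[s.sample_id].append(s)
        fr = np.array([f_roh(by_sample[s], covered) for s in gm.samples])
        p, n = allele_frequencies(gm)
        fh = np.array([f_hom(gm.calls[i], p, n)[0] for i in range(gm.n_samples)])
        mean_froh.append(float(fr.mean()))
        mean_planted.append(float(truth.autozygosity.mean()))
        if g > 0:
            fh_all.append(fh)
            fr_all.append(fr)
    r = correlate(np.concatenate(fh_all), np.concatenate(fr_all)).r
    max_err = max(abs(m - g) for m, g in zip(mean_froh, levels))
    return FrohRecoveryResult(levels=list(levels), mean_froh=mean_froh,
                              mean_planted=mean_planted,
                              max_abs_error=max_err, fhom_froh_r=r)


# ---------------------------------------------------------------------------
# association calibration


def _island_panel_config(seed: int, n_samples: int, beta: float = 0.0) -> SimConfig:
    """A panel with shared tract locations so merged regions are polymorphic."""
    islands = tuple(IslandSpec(chromosome=c, start_bp=s, end_bp=s + 2_000_000,
                               carrier_frequency=f)
                    for c, s, f in [(1, 1_000_000, 0.3), (1, 6_000_000, 0.15),
                                    (2, 2_000_000, 0.4), (2, 7_000_000, 0.2),
                                    (3, 3_000_000, 0.25), (3, 8_000_000, 0.35),
                                    (4, 1_500_000, 0.2), (4, 7_500_000, 0.3),
                                    (5, 2_500_000, 0.35), (5, 8_500_000, 0.15)])
    causal = CausalRegion(chromosome=1, start_bp=1_000_000, end_bp=3_000_000,
                          beta=beta, trait="body_height",
                          carrier_frequency=0.3) if beta else None
    return SimConfig(n_samples=n_samples, n_autosomes=5, snps_per_chromosome=2400,
                     mean_spacing_bp=5000, maf_distribution=("uniform", 0.3, 0.5),
                     tract_rate_per_genome=0.3,
                     tract_length_distribution=("fixed", 2_000_000),
                     het_error_rate=0.001, missing_rate=0.001,
                     causal_region=causal, island_regions=islands if not beta else (),
                     seed=seed)


@dataclass
class NullCalibrationResult:
    n_tests: int
    type1_rate_p01: float
    binomial_ci: tuple[float, float]
    ks_statistic: float
    ks_pvalue: float


def null_calibration(seed: int, n_panels: int = 6, n_pheno_draws: int = 6,
                     n_samples: int = 120) -> NullCalibrationResult:
    """Type-I error and p-value uniformity of the region association under the null.

    Panels carry island tracts but traits carry no dosage effect, so every
    region x trait test is null; the fraction of p < 0.01 is compared with
    its 95% binomial interval and pooled p-values with Uniform(0,1) by a
    Kolmogorov-Smirnov test.
    """
    pvals: list[np.ndarray] = []
    ss = np.random.SeedSequence(seed)
    for panel_child in ss.spawn(n_panels):
        panel_seed = int(panel_child.generate_state(1)[0] % (2**31))
        cfg = _island_panel_config(panel_seed, n_samples)
        gm, mm, truth = simulate_panel(cfg)
        segments = detect_roh(gm, mm)
        if not segments:
            continue
        regions = merge_regions(segments, n_samples=gm.n_samples)
        cov = coverage_matrix(regions, segments, gm.samples)
        for k in range(n_pheno_draws):
            pheno_cfg = replace(cfg, seed=panel_seed + 7919 * (k + 1))
            pheno = simulate_phenotypes(truth, pheno_cfg)
            res = run_association(cov, pheno, TRAITS, fdr_method="bh")
            pvals.append(res["p_value"].to_numpy())
    p = np.concatenate(pvals)
    rate = float((p < 0.01).mean())
    half = 1.96 * np.sqrt(0.01 * 0.99 / len(p))
    ks = stats.kstest(p, "uniform")
    return NullCalibrationResult(n_tests=len(p), type1_rate_p01=rate,
                                 binomial_ci=(0.01 - half, 0.01 + half),
                                 ks_statistic=float(ks.statistic),
                                 ks_pvalue=float(ks.pvalue))


def beta_recovery(seed: int, n_seeds: int = 100, n_samples: int = 400,
                  beta: float = 5.0, noise_sd: float = 1.0) -> float:
    """Fraction of replicates where the planted dosage effect is within 2 SE.

    Each replicate simulates a panel with a causal region, builds the
    oracle coverage of that region from the planted tracts, adjusts both
    the causal trait and the coverage for covariates (Frisch-Waugh) and
    regresses residuals on residuals.
    """
    hits = 0
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_seeds):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        causal = CausalRegion(chromosome=1, start_bp=1_000_000, end_bp=3_000_000,
                              beta=beta, trait="body_height", carrier_frequency=0.3)
        cfg = SimConfig(n_samples=n_samples, n_autosomes=1, snps_per_chromosome=400,
                        mean_spacing_bp=20_000, tract_rate_per_genome=0.0,
                        causal_region=causal, noise_sd=noise_sd, seed=sub_seed)
        _, _, truth = simulate_panel(cfg)
        pheno = simulate_phenotypes(truth, cfg)
        cov = true_region_coverage(truth, causal.chromosome,
                                   causal.start_bp, causal.end_bp)
        adjusted = adjust_phenotype(pheno, "body_height")
        x_res = residualize_covariates(pheno, cov).reindex(adjusted.index)
        x = x_res.to_numpy()
        if np.var(x) == 0:
            continue
        res = associate(x, adjusted.to_numpy())
        hits += abs(res.beta - beta) <= 2.0 * res.se
    return hits / n_seeds
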