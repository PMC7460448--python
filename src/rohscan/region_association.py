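"""ROH-region dosage association with quantitative traits.

Pipeline: (1) merge all individuals' ROH segments into nonredundant regions
(intervals sharing >= 1 bp aggregate into one region); (2) per individual
and region, the dosage variable is the proportion of the region's span
covered by that individual's ROH; (3) each trait is adjusted for fixed
effects (farm, age, gender, generation) by ordinary least squares and the
residuals are regressed on region coverage, one simple regression per
region x trait; (4) p-values are corrected per trait by the
Benjamini-Hochberg step-up or the Storey q-value.

By default the coverage variable is residualized on the same fixed effects
before the regression (the Frisch-Waugh route, whose slope equals the
covariate-plus-coverage joint model and is unbiased for the dosage
effect); ``adjust_coverage=False`` regresses the adjusted phenotype on raw
coverage, which attenuates the slope by roughly the covariate dimension
over the sample size.

Coordinates are 1-based inclusive: segments [100, 200] and [200, 300]
share bp 200 and merge; [100, 200] and [201, 300] do not.  Region length
and coverage use the ``end - start`` span convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .roh_detection import RohSegment

logger = logging.getLogger(__name__)

#: Covariate columns a phenotype table must carry.
COVARIATES = ["farm", "age", "gender", "generation"]
CATEGORICAL_COVARIATES = ["farm", "gender", "generation"]


@dataclass(frozen=True)
class RohRegion:
    """A nonredundant interval from merging overlapping segments."""

    chromosome: int
    start_bp: int
    end_bp: int
    n_segments: int
    carrier_frequency: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def merge_regions(segments: list[RohSegment], n_samples: int | None = None) -> list[RohRegion]:
    """Aggregate segments overlapping by >= 1 bp into disjoint sorted regions.

    ``carrier_frequency`` is the fraction of samples with at least one
    segment in the region; when ``n_samples`` is not given, the number of
    distinct sample ids among the input segments is used.
    """
    if not segments:
        return []
    if n_samples is None:
        n_samples = len({s.sample_id for s in segments})
    ordered = sorted(segments, key=lambda s: (s.chromosome, s.start_bp, s.end_bp))
    regions: list[RohRegion] = []
    cur = [ordered[0]]
    cur_end = ordered[0].end_bp

    def _close(members: list[RohSegment], end_bp: int) -> None:
        carriers = len({m.sample_id for m in members})
        regions.append(RohRegion(
            chromosome=members[0].chromosome,
            start_bp=members[0].start_bp, end_bp=end_bp,
            n_segments=len(members),
            carrier_frequency=carriers / n_samples))

    for seg in ordered[1:]:
        if seg.chromosome == cur[0].chromosome and seg.start_bp <= cur_end:
            cur.append(seg)
            cur_end = max(cur_end, seg.end_bp)
        else:
            _close(cur, cur_end)
            cur = [seg]
            cur_end = seg.end_bp
    _close(cur, cur_end)
    return regions


def coverage_matrix(regions: list[RohRegion], segments: list[RohSegment],
                    samples: list[str]) -> pd.DataFrame:
    """samples x regions proportion of each region's span covered by ROH.

    Entry (i, j) sums the bp intersection of sample i's segments with
    region j and divides by the region span; values lie in [0, 1] because
    a sample's segments never overlap.
    """
    idx = {s: i for i, s in enumerate(samples)}
    cov = np.zeros((len(samples), len(regions)))
    by_chrom: dict[int, list[tuple[int, RohRegion]]] = {}
    for j, r in enumerate(regions):
        by_chrom.setdefault(r.chromosome, []).append((j, r))
    for seg in segments:
        i = idx.get(seg.sample_id)
        if i is None:
            continue
        for j, r in by_chrom.get(seg.chromosome, ()):
            inter = min(seg.end_bp, r.end_bp) - max(seg.start_bp, r.start_bp)
            if inter > 0:
                cov[i, j] += inter / r.length_bp
    labels = [f"chr{r.chromosome}:{r.start_bp}-{r.end_bp}" for r in regions]
    return pd.DataFrame(cov, index=pd.Index(samples, name="sample_id"), columns=labels)


class RankDeficientDesignError(ValueError):
    pass


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + indicator-contrast design for the fixed effects."""
    X = pd.get_dummies(covariates,
                       columns=[c for c in CATEGORICAL_COVARIATES
                                if c in covariates.columns],
                       drop_first=True, dtype=float)
    # constant columns carry no information beyond the intercept
    X = X.loc[:, X.nunique() > 1]
    X = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        q, r = np.linalg.qr(X.to_numpy())
        aliased = [c for c, d in zip(X.columns, np.abs(np.diag(r)) < 1e-10) if d]
        raise RankDeficientDesignError(f"design matrix rank-deficient; aliased: {aliased}")
    return X


def adjust_phenotype(table: pd.DataFrame, trait: str) -> pd.Series:
    """OLS residuals of one trait on intercept + farm + age + gender + generation.

    Categorical covariates enter as indicator contrasts.  Rows with a
    missing trait value or any missing covariate are dropped (and logged);
    the returned Series is indexed by sample_id of the rows used.
    """
    if trait not in table.columns:
        raise KeyError(f"trait {trait!r} not in phenotype table")
    missing_cov = [c for c in COVARIATES if c not in table.columns]
    if missing_cov:
        raise KeyError(f"phenotype table lacks covariates: {missing_cov}")
    cols = [trait] + COVARIATES
    sub = table.set_index("sample_id")[cols] if "sample_id" in table.columns \
        else table[cols]
    used = sub.dropna()
    n_dropped = len(sub) - len(used)
    if n_dropped:
        logger.info("adjust_phenotype(%s): dropped %d sample(s) with missing data",
                    trait, n_dropped)
    X = _design_matrix(used[COVARIATES])
    if len(used) < X.shape[1] + 2:
        raise ValueError("too few samples for the covariate model")
    fit = sm.OLS(used[trait].astype(float), X).fit()
    return pd.Series(fit.resid, index=used.index, name=f"{trait}_adj")


def residualize_covariates(table: pd.DataFrame, values: pd.Series) -> pd.Series:
    """Residuals of an arbitrary per-sample vector on the fixed effects.

    Used to put the coverage variable on the same covariate-free footing as
    the adjusted phenotype (Frisch-Waugh).  The returned Series is indexed
    by the samples present in both inputs with complete covariates.
    """
    cov = (table.set_index("sample_id")[COVARIATES]
           if "sample_id" in table.columns else table[COVARIATES])
    cov = cov.dropna()
    common = cov.index.intersection(values.dropna().index)
    X = _design_matrix(cov.loc[common])
    y = values.loc[common].astype(float)
    beta, *_ = np.linalg.lstsq(X.to_numpy(), y.to_numpy(), rcond=None)
    return pd.Series(y.to_numpy() - X.to_numpy() @ beta, index=common,
                     name=values.name)


@dataclass
class AssociationResult:
    region: str
    trait: str
    beta: float
    se: float
    t_stat: float
    p_value: float
    n_used: int
    q_value: float = np.nan


def associate(coverage: np.ndarray, adjusted: np.ndarray,
              region: str = "", trait: str = "") -> AssociationResult:
    """Simple least-squares regression of an adjusted trait on region coverage.

    beta = cov(x, y)/var(x); two-sided p from the t distribution on n - 2
    degrees of freedom.
    """
    x = np.asarray(coverage, dtype=float)
    y = np.asarray(adjusted, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.var(x) == 0:
        raise ValueError("zero coverage variance (monomorphic region)")
    res = stats.linregress(x, y)
    t = res.slope / res.stderr if res.stderr > 0 else np.inf * np.sign(res.slope)
    return AssociationResult(region=region, trait=trait, beta=float(res.slope),
                             se=float(res.stderr), t_stat=float(t),
                             p_value=float(res.pvalue), n_used=len(x))


def storey_pi0(p: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    Fits a cubic spline to pi0(lambda) over a lambda grid and evaluates it
    at the largest lambda; the estimate is clipped to (0, 1].  Falls back
    to 1.0 when too few p-values are available for the spline.
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    if len(p) < 2 * len(lambdas):
        return 1.0
    pi0_l = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = CubicSpline(lambdas, pi0_l)
    pi0 = float(spline(lambdas[-1]))
    if not np.isfinite(pi0) or pi0 <= 0:
        return 1.0
    return min(pi0, 1.0)


def fdr(p_values: np.ndarray, method: str = "bh") -> np.ndarray:
    """q-values by Benjamini-Hochberg step-up or Storey's method.

    Storey's q-values equal pi0-hat times the BH step-up values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "storey"):
        raise ValueError("method must be 'bh' or 'storey'")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "storey":
        q = np.minimum(storey_pi0(p) * q, 1.0)
    return q


def run_association(coverage: pd.DataFrame, phenotypes: pd.DataFrame,
                    traits: list[str], alpha_p: float = 0.01,
                    alpha_q: float = 0.10, fdr_method: str = "storey",
                    adjust_coverage: bool = True) -> pd.DataFrame:
    """Full region x trait association grid.

    For each trait, the phenotype is covariate-adjusted, each region's
    coverage column is regressed on the residuals (per-trait sample
    dropping for missing phenotypes), and q-values are computed across
    regions within the trait.  With ``adjust_coverage`` (default) the
    coverage is residualized on the same fixed effects first, making the
    slope that of the joint covariate-plus-coverage model.  Monomorphic
    regions are skipped with a logged reason.
    """
    available = [c for c in phenotypes.columns
                 if c not in COVARIATES + ["sample_id"]]
    for t in traits:
        if t not in phenotypes.columns:
            raise KeyError(f"trait {t!r} not found; available traits: {available}")
    all_rows: list[pd.DataFrame] = []
    for trait in traits:
        adjusted = adjust_phenotype(phenotypes, trait)
        common = coverage.index.intersection(adjusted.index)
        y = adjusted.loc[common].to_numpy()
        if adjust_coverage:
            cov_used = coverage.loc[common].apply(
                lambda col: residualize_covariates(phenotypes, col))
        else:
            cov_used = coverage.loc[common]
        rows = []
        for region in coverage.columns:
            if np.var(coverage.loc[common, region].to_numpy()) == 0:
                logger.info("skipping %s x %s: zero coverage variance", region, trait)
                continue
            x = cov_used.loc[common, region].to_numpy()
            rows.append(associate(x, y, region=region, trait=trait).__dict__)
        if not rows:
            continue
        df = pd.DataFrame(rows)
        df["q_value"] = fdr(df["p_value"].to_numpy(), method=fdr_method)
        all_rows.append(df)
    if not all_rows:
        return pd.DataFrame(columns=["region", "trait", "beta", "se", "t_stat",
                                     "p_value", "n_used", "q_value",
                                     "significant_p", "suggestive_q"])
    out = pd.concat(all_rows, ignore_index=True)
    out["significant_p"] = out["p_value"] < alpha_p
    out["suggestive_q"] = out["q_value"] < alpha_q
    return out


def regions_to_frame(regions: list[RohRegion]) -> pd.DataFrame:
    rows = [{"chromosome": r.chromosome, "start_bp": r.start_bp,
             "end_bp": r.end_bp, "length_bp": r.length_bp,
             "n_segments": r.n_segments,
             "carrier_frequency": r.carrier_frequency} for r in regions]
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp",
                                       "length_bp", "n_segments", "carrier_frequency"])
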