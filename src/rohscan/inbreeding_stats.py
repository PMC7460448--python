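"""Per-individual genomic inbreeding: F_HOM and F_ROH.

F_HOM is the method-of-moments excess-homozygosity coefficient

    F_HOM = (O_hom - E_hom) / (N - E_hom)

where, over an individual's non-missing markers, O_hom counts observed
homozygous genotypes, N counts markers, and the Hardy-Weinberg expectation
carries the small-sample correction

    E_hom = sum_i [ 1 - 2 p_i (1 - p_i) * n_i / (n_i - 1) ]

with p_i the in-sample allele frequency and n_i the number of non-missing
individuals at marker i.  The estimator is negative for individuals more
heterozygous than expected.

F_ROH is the summed ROH length of an individual divided by the SNP-covered
autosomal length (per chromosome, last SNP bp minus first SNP bp, summed);
it lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeMatrix, MarkerMap, allele_frequencies
from .roh_detection import RohSegment

logger = logging.getLogger(__name__)


class DegenerateStatisticError(ValueError):
    """Raised when a statistic is undefined for the given input."""


@dataclass
class InbreedingResult:
    sample_id: str
    f_hom: float
    f_roh: float
    o_hom: int
    e_hom: float
    n_nonmissing: int


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int


def f_hom(sample_calls: np.ndarray, allele_freqs: np.ndarray,
          n_per_marker: np.ndarray) -> tuple[float, int, float, int]:
    """Excess-homozygosity F for one sample.

    Parameters
    ----------
    sample_calls : call vector in {0, 1, 2, MISSING}
    allele_freqs : per-marker B-allele frequency (in-sample estimate)
    n_per_marker : per-marker count of non-missing individuals

    Returns ``(f_hom, o_hom, e_hom, n_nonmissing)``.  Markers with fewer
    than two non-missing individuals, or with a monomorphic frequency, are
    skipped with a warning (their HW expectation is degenerate).
    """
    sample_calls = np.asarray(sample_calls)
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    n_per_marker = np.asarray(n_per_marker)
    nonmiss = sample_calls != MISSING
    usable = nonmiss & (n_per_marker >= 2) & (allele_freqs > 0) & (allele_freqs < 1)
    n_skipped = int(nonmiss.sum() - usable.sum())
    if n_skipped:
        logger.warning("f_hom: skipped %d marker(s) with degenerate frequency or n < 2",
                       n_skipped)
    n = int(usable.sum())
    o = int(np.isin(sample_calls[usable], (0, 2)).sum())
    p = allele_freqs[usable]
    ni = n_per_marker[usable].astype(float)
    e = float(np.sum(1.0 - 2.0 * p * (1.0 - p) * ni / (ni - 1.0)))
    if np.isclose(n, e):
        raise DegenerateStatisticError("F_HOM undefined: N equals E_hom")
    return (o - e) / (n - e), o, e, n


def f_roh(segments: list[RohSegment], covered_length_bp: int) -> float:
    """Summed ROH length over the SNP-covered autosomal length, for one sample."""
    if covered_length_bp <= 0:
        raise ValueError("covered_length_bp must be positive")
    by_chrom: dict[int, list[RohSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chromosome, []).append(s)
    total = 0
    for segs in by_chrom.values():
        segs = sorted(segs, key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp < a.end_bp:
                raise ValueError("overlapping segments within one sample")
        total += sum(s.length_bp for s in segs)
    return total / covered_length_bp


def correlate(f_hom_vec: np.ndarray, f_roh_vec: np.ndarray) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(f_hom_vec, dtype=float)
    y = np.asarray(f_roh_vec, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateStatisticError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), n=len(x))


def inbreeding_table(gm: GenotypeMatrix, mm: MarkerMap,
                     segments: list[RohSegment]) -> pd.DataFrame:
    """Per-sample F_HOM and F_ROH for a QC'd panel and its detected ROH."""
    p, n = allele_frequencies(gm)
    covered = mm.snp_covered_length_bp()
    by_sample: dict[str, list[RohSegment]] = {s: [] for s in gm.samples}
    for seg in segments:
        by_sample[seg.sample_id].append(seg)
    rows = []
    for idx, sid in enumerate(gm.samples):
        fh, o, e, nn = f_hom(gm.calls[idx], p, n)
        fr = f_roh(by_sample[sid], covered)
        rows.append({"sample_id": sid, "o_hom": o, "e_hom": e,
                     "n_nonmissing": nn, "f_hom": fh, "f_roh": fr})
    return pd.DataFrame(rows)
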