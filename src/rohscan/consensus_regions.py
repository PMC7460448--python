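"""Population ROH-frequency track, consensus regions and interval annotation.

The per-SNP ROH frequency is the fraction of individuals whose ROH cover
that SNP; consensus regions (ROH islands) are maximal runs of consecutive
SNPs whose frequency strictly exceeds a threshold (default 10%), bounded by
the first and last qualifying SNP.  Regions can be annotated against
BED-like interval sets (QTLs, genes) by >= 1 bp overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genotype_io import MarkerMap
from .roh_detection import RohSegment


@dataclass
class FrequencyTrack:
    """Per-SNP ROH frequency, aligned to a MarkerMap."""

    chromosome: np.ndarray
    position_bp: np.ndarray
    roh_frequency: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chromosome": self.chromosome,
                             "position_bp": self.position_bp,
                             "roh_frequency": self.roh_frequency})


@dataclass(frozen=True)
class ConsensusRegion:
    chromosome: int
    start_bp: int
    end_bp: int
    peak_frequency: float
    mean_frequency: float
    n_snps: int


@dataclass(frozen=True)
class IntervalAnnotation:
    """A labelled 1-based inclusive genomic interval (QTL or gene)."""

    chromosome: int
    start_bp: int
    end_bp: int
    label: str

    def __post_init__(self) -> None:
        if self.start_bp >= self.end_bp:
            raise ValueError("annotation requires start_bp < end_bp")


def snp_frequency(segments: list[RohSegment], mm: MarkerMap,
                  n_samples: int) -> FrequencyTrack:
    """Fraction of samples whose ROH cover each SNP.

    A sample's segments never overlap, so each segment contributes at most
    one distinct sample per SNP; counting covered SNPs per segment therefore
    counts distinct samples.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if len({s.sample_id for s in segments}) > n_samples:
        raise ValueError("segments reference more samples than n_samples")
    counts = np.zeros(len(mm), dtype=np.int64)
    chrom_set = set(int(c) for c in mm.chromosomes)
    for seg in segments:
        if seg.chromosome not in chrom_set:
            raise ValueError(f"segment on chromosome {seg.chromosome} absent from map")
        sl = mm.chromosome_slice(seg.chromosome)
        pos = mm.position_bp[sl]
        lo = int(np.searchsorted(pos, seg.start_bp, side="left"))
        hi = int(np.searchsorted(pos, seg.end_bp, side="right"))
        counts[sl.start + lo: sl.start + hi] += 1
    return FrequencyTrack(mm.chromosome.copy(), mm.position_bp.copy(),
                          counts / n_samples)


def extract_consensus(track: FrequencyTrack, threshold: float = 0.10) -> list[ConsensusRegion]:
    """Maximal runs of consecutive SNPs with frequency strictly above ``threshold``.

    Runs never span a chromosome boundary; region coordinates are the first
    and last qualifying SNP positions.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must lie in [0, 1)")
    above = track.roh_frequency > threshold
    regions: list[ConsensusRegion] = []
    n = len(above)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while (j + 1 < n and above[j + 1]
               and track.chromosome[j + 1] == track.chromosome[i]):
            j += 1
        freqs = track.roh_frequency[i:j + 1]
        regions.append(ConsensusRegion(
            chromosome=int(track.chromosome[i]),
            start_bp=int(track.position_bp[i]),
            end_bp=int(track.position_bp[j]),
            peak_frequency=float(freqs.max()),
            mean_frequency=float(freqs.mean()),
            n_snps=j - i + 1))
        i = j + 1
    return regions


def annotate(regions: list[ConsensusRegion],
             annotations: list[IntervalAnnotation]) -> pd.DataFrame:
    """All (region, annotation) pairs sharing >= 1 bp, with overlap span.

    Intervals are 1-based inclusive; two intervals overlap when
    ``min(ends) >= max(starts)``.  The reported ``overlap_bp`` is the span
    ``min(ends) - max(starts)``, matching the ``end - start`` length
    convention used for regions (a coincident annotation has overlap equal
    to the region length; intervals sharing a single bp have span 0 but are
    still reported).
    """
    trees: dict[int, IntervalTree] = {}
    for a in annotations:
        # IntervalTree is half-open; +1 so inclusive-touching intervals hit
        trees.setdefault(a.chromosome, IntervalTree()).addi(
            a.start_bp, a.end_bp + 1, a)
    rows = []
    for r in regions:
        tree = trees.get(r.chromosome)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(r.start_bp, r.end_bp + 1),
                          key=lambda h: (h.begin, h.end)):
            a = hit.data
            rows.append({
                "chromosome": r.chromosome,
                "region_start_bp": r.start_bp, "region_end_bp": r.end_bp,
                "annot_start_bp": a.start_bp, "annot_end_bp": a.end_bp,
                "label": a.label,
                "overlap_bp": min(r.end_bp, a.end_bp) - max(r.start_bp, a.start_bp),
            })
    cols = ["chromosome", "region_start_bp", "region_end_bp",
            "annot_start_bp", "annot_end_bp", "label", "overlap_bp"]
    return pd.DataFrame(rows, columns=cols)


def read_annotations(path: str | Path, coords: str = "bed") -> list[IntervalAnnotation]:
    """Read a 4-column interval file (chrom, start, end, label).

    ``coords='bed'`` treats start as 0-based half-open and converts to the
    internal 1-based inclusive convention; ``coords='one-based'`` takes the
    columns as-is.
    """
    if coords not in ("bed", "one-based"):
        raise ValueError("coords must be 'bed' or 'one-based'")
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "label"])
    out = []
    for r in df.itertuples(index=False):
        start = int(r.start) + 1 if coords == "bed" else int(r.start)
        end = int(r.end)
        out.append(IntervalAnnotation(int(r.chrom), start, end, str(r.label)))
    return out


def regions_to_frame(regions: list[ConsensusRegion]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in regions],
                        columns=["chromosome", "start_bp", "end_bp",
                                 "peak_frequency", "mean_frequency", "n_snps"])
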