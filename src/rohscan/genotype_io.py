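"""PLINK-format genotype I/O and SNP-array quality control.

Genotypes are held as a dense ``samples x markers`` int8 matrix with calls
coded 0 (homozygous for the A allele), 1 (heterozygous), 2 (homozygous for
the B allele) and ``MISSING`` (-1).  The A allele of a marker is the first
allele listed for it (first allele observed in a .ped file, the A1 column of
a .bim file); hom/het status — all that downstream ROH analysis uses — does
not depend on this labelling.

Both the PLINK 1 text dialect (.ped/.map) and the SNP-major binary dialect
(.bed/.bim/.fam, magic bytes ``6c 1b 01``) are supported.  Only autosomal
markers are retained on read: chromosome codes that are not positive
integers (X, Y, XY, MT, 0, contigs) are dropped with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call.
MISSING: int = -1

Dialect = Literal["text", "binary"]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit codes of the PLINK .bed format (SNP-major): 00 hom A1, 01 missing,
# 10 het, 11 hom A2.  Internal coding: A1 == allele A.
_BED_TO_CALL = np.array([0, MISSING, 1, 2], dtype=np.int8)
_CALL_TO_BED = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkParseError(ValueError):
    """A malformed line or structural inconsistency in a PLINK fileset."""


class EmptyPanelError(ValueError):
    """Raised when an operation would leave no samples or no markers."""


@dataclass
class MarkerMap:
    """Ordered autosomal marker coordinates.

    Attributes
    ----------
    chromosome : int array, autosome labels (1-based)
    position_bp : int array, 1-based physical coordinates
    marker_id : str array
    alleles : (n, 2) str array, the (A, B) allele labels per marker
    """

    chromosome: np.ndarray
    position_bp: np.ndarray
    marker_id: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=object)
        self.validate()

    def validate(self) -> None:
        if np.any(self.chromosome < 1):
            raise ValueError("non-positive chromosome label in MarkerMap")
        if np.any(self.position_bp < 1):
            raise ValueError("non-positive bp position in MarkerMap")
        order = np.lexsort((self.position_bp, self.chromosome))
        if not np.array_equal(order, np.arange(len(self))):
            raise ValueError("markers must be sorted by (chromosome, position)")
        key = self.chromosome.astype(np.int64) * (self.position_bp.max() + 1 if len(self) else 1) + self.position_bp
        if len(np.unique(key)) != len(self):
            raise ValueError("duplicate (chromosome, position) in MarkerMap")

    def __len__(self) -> int:
        return len(self.position_bp)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct autosome labels present, ascending."""
        return np.unique(self.chromosome)

    def chromosome_slice(self, chrom: int) -> slice:
        """Contiguous index slice of the markers on one chromosome."""
        lo = int(np.searchsorted(self.chromosome, chrom, side="left"))
        hi = int(np.searchsorted(self.chromosome, chrom, side="right"))
        return slice(lo, hi)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chromosome[idx], self.position_bp[idx],
                         self.marker_id[idx], self.alleles[idx])

    def snp_covered_length_bp(self) -> int:
        """Sum over autosomes of (last SNP bp - first SNP bp).

        This is the SNP-span denominator used for F_ROH.
        """
        total = 0
        for c in self.chromosomes:
            sl = self.chromosome_slice(int(c))
            total += int(self.position_bp[sl.stop - 1] - self.position_bp[sl.start])
        return total


@dataclass
class GenotypeMatrix:
    """samples x markers call matrix; entries in {0, 1, 2, MISSING}."""

    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.samples):
            raise ValueError("calls must be a 2-D samples x markers array")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]


@dataclass
class QcReport:
    """Counts removed/retained by :func:`qc_filter`."""

    n_samples_in: int
    n_markers_in: int
    n_samples_removed: int = 0
    n_markers_removed_missing: int = 0
    n_markers_removed_maf: int = 0

    @property
    def n_samples_retained(self) -> int:
        return self.n_samples_in - self.n_samples_removed

    @property
    def n_markers_retained(self) -> int:
        return self.n_markers_in - self.n_markers_removed_missing - self.n_markers_removed_maf

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame([self.__dict__ | {
            "n_samples_retained": self.n_samples_retained,
            "n_markers_retained": self.n_markers_retained,
        }]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# reading


def _autosome_mask(chrom_codes: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Boolean keep-mask over markers plus the parsed integer labels."""
    keep = np.zeros(len(chrom_codes), dtype=bool)
    labels = np.zeros(len(chrom_codes), dtype=np.int64)
    for i, code in enumerate(chrom_codes):
        try:
            v = int(code)
        except ValueError:
            continue
        if v >= 1:
            keep[i] = True
            labels[i] = v
    return keep, labels


def read_plink(prefix: str | Path, dialect: Dialect = "binary") -> tuple[GenotypeMatrix, MarkerMap]:
    """Read a PLINK fileset, keeping autosomal markers only.

    Markers are returned sorted by (chromosome, position).  Non-autosomal
    markers (chromosome codes X/Y/XY/MT/0 or other non-integers) are dropped
    and the count is logged.
    """
    prefix = Path(prefix)
    if dialect == "text":
        return _read_text(prefix)
    if dialect == "binary":
        return _read_binary(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def _finalize_map(chroms, poss, ids, alleles, calls) -> tuple[GenotypeMatrix, MarkerMap, np.ndarray]:
    keep, labels = _autosome_mask(chroms)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropped %d non-autosomal marker(s)", n_drop)
    labels = labels[keep]
    poss = np.asarray(poss, dtype=np.int64)[keep]
    ids = np.asarray(ids, dtype=object)[keep]
    alleles = np.asarray(alleles, dtype=object)[keep]
    calls = calls[:, keep]
    order = np.lexsort((poss, labels))
    mm = MarkerMap(labels[order], poss[order], ids[order], alleles[order])
    return calls[:, order], mm, order


def _read_text(prefix: Path) -> tuple[GenotypeMatrix, MarkerMap]:
    map_path = prefix.with_suffix(".map")
    ped_path = prefix.with_suffix(".ped")
    chroms, ids, poss = [], [], []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(f"{map_path}:{lineno}: expected 4 fields, got {len(parts)}")
            chroms.append(parts[0])
            ids.append(parts[1])
            try:
                poss.append(int(parts[3]))
            except ValueError as e:
                raise PlinkParseError(f"{map_path}:{lineno}: bad bp position {parts[3]!r}") from e
    n_markers = len(chroms)

    samples: list[str] = []
    rows: list[np.ndarray] = []
    # first observed allele per marker defines allele A; second defines B
    allele_a = np.full(n_markers, None, dtype=object)
    allele_b = np.full(n_markers, None, dtype=object)
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_markers:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_markers} fields, got {len(parts)}")
            samples.append(parts[1])
            row = np.empty(n_markers, dtype=np.int8)
            g = parts[6:]
            for j in range(n_markers):
                a1, a2 = g[2 * j], g[2 * j + 1]
                if a1 == "0" or a2 == "0":
                    row[j] = MISSING
                    continue
                code = 0
                for a in (a1, a2):
                    if allele_a[j] is None:
                        allele_a[j] = a
                    if a == allele_a[j]:
                        continue
                    if allele_b[j] is None:
                        allele_b[j] = a
                    if a == allele_b[j]:
                        code += 1
                    else:
                        raise PlinkParseError(
                            f"{ped_path}:{lineno}: marker {j} has >2 alleles")
                row[j] = code
            rows.append(row)
    calls = np.vstack(rows) if rows else np.empty((0, n_markers), dtype=np.int8)
    alleles = np.array([[a if a is not None else "A",
                         b if b is not None else "B"]
                        for a, b in zip(allele_a, allele_b)], dtype=object)
    if n_markers == 0:
        alleles = np.empty((0, 2), dtype=object)
    gm_calls, mm, _ = _finalize_map(chroms, poss, ids, alleles, calls)
    return GenotypeMatrix(samples, gm_calls), mm


def _read_binary(prefix: Path) -> tuple[GenotypeMatrix, MarkerMap]:
    bim = prefix.with_suffix(".bim")
    fam = prefix.with_suffix(".fam")
    bed = prefix.with_suffix(".bed")
    chroms, ids, poss, alleles = [], [], [], []
    with open(bim) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise PlinkParseError(f"{bim}:{lineno}: expected 6 fields, got {len(parts)}")
            chroms.append(parts[0])
            ids.append(parts[1])
            poss.append(int(parts[3]))
            alleles.append((parts[4], parts[5]))
    samples = []
    with open(fam) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 2:
                raise PlinkParseError(f"{fam}:{lineno}: expected >= 2 fields")
            samples.append(parts[1])
    n, m = len(samples), len(chroms)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkParseError(f"{bed}: bad magic bytes (not SNP-major PLINK .bed)")
    bpm = (n + 3) // 4  # bytes per marker
    if len(raw) != 3 + bpm * m:
        raise PlinkParseError(f"{bed}: size {len(raw)} inconsistent with {n} samples x {m} markers")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpm)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bpm * 4)[:, :n]
    calls = _BED_TO_CALL[codes].T.copy()  # samples x markers
    gm_calls, mm, _ = _finalize_map(chroms, poss, ids,
                                    np.array(alleles, dtype=object).reshape(m, 2), calls)
    return GenotypeMatrix(samples, gm_calls), mm


# ---------------------------------------------------------------------------
# writing


def write_plink(gm: GenotypeMatrix, mm: MarkerMap, prefix: str | Path,
                dialect: Dialect = "binary") -> None:
    """Write a panel as a PLINK fileset; ``read_plink`` inverts it exactly."""
    if gm.n_samples == 0:
        raise EmptyPanelError("refusing to write a panel with no samples")
    if gm.n_markers != len(mm):
        raise ValueError("matrix/map marker dimensions disagree")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "text":
        _write_text(gm, mm, prefix)
    elif dialect == "binary":
        _write_binary(gm, mm, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_text(gm: GenotypeMatrix, mm: MarkerMap, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for c, i, p in zip(mm.chromosome, mm.marker_id, mm.position_bp):
            fh.write(f"{c}\t{i}\t0\t{p}\n")
    geno_strings = {
        0: lambda a, b: f"{a} {a}",
        1: lambda a, b: f"{a} {b}",
        2: lambda a, b: f"{b} {b}",
        MISSING: lambda a, b: "0 0",
    }
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for s, row in zip(gm.samples, gm.calls):
            fields = [s, s, "0", "0", "0", "-9"]
            fields.extend(geno_strings[int(g)](a, b)
                          for g, (a, b) in zip(row, mm.alleles))
            fh.write(" ".join(fields) + "\n")


def _write_binary(gm: GenotypeMatrix, mm: MarkerMap, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for (c, i, p, (a, b)) in zip(mm.chromosome, mm.marker_id, mm.position_bp, mm.alleles):
            fh.write(f"{c}\t{i}\t0\t{p}\t{a}\t{b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in gm.samples:
            fh.write(f"{s} {s} 0 0 0 -9\n")
    n, m = gm.n_samples, gm.n_markers
    bpm = (n + 3) // 4
    # 2-bit codes: 0->00, 1->10, 2->11, MISSING->01
    codes = np.empty((m, n), dtype=np.uint8)
    calls_t = gm.calls.T
    codes[calls_t == 0] = 0b00
    codes[calls_t == 1] = 0b10
    codes[calls_t == 2] = 0b11
    codes[calls_t == MISSING] = 0b01
    padded = np.zeros((m, bpm * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# quality control


def allele_frequencies(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker B-allele frequency and non-missing sample count.

    Frequency is NaN for markers with no non-missing calls.
    """
    calls = gm.calls
    nonmiss = calls != MISSING
    n = nonmiss.sum(axis=0)
    b_dosage = np.where(nonmiss, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, b_dosage / (2.0 * n), np.nan)
    return p, n


def qc_filter(gm: GenotypeMatrix, mm: MarkerMap,
              max_sample_missing: float = 0.05,
              min_maf: float = 0.05,
              max_marker_missing: float = 0.10,
              ) -> tuple[GenotypeMatrix, MarkerMap, QcReport]:
    """Apply array QC: sample call-rate filter first, then marker filters.

    Samples with missing-call fraction strictly above ``max_sample_missing``
    are removed first; marker MAF and missingness are then computed on the
    retained samples (missing calls excluded).  Markers are removed when
    missing fraction is strictly above ``max_marker_missing`` or MAF is
    strictly below ``min_maf`` (boundary values are retained).  A marker
    failing both filters is counted under missingness.
    """
    for t in (max_sample_missing, min_maf, max_marker_missing):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    report = QcReport(n_samples_in=gm.n_samples, n_markers_in=gm.n_markers)

    miss = gm.calls == MISSING
    sample_missing_frac = miss.mean(axis=1) if gm.n_markers else np.zeros(gm.n_samples)
    keep_samples = sample_missing_frac <= max_sample_missing
    report.n_samples_removed = int((~keep_samples).sum())
    if not keep_samples.any():
        raise EmptyPanelError("sample missingness filter removed every sample")
    gm2 = GenotypeMatrix([s for s, k in zip(gm.samples, keep_samples) if k],
                         gm.calls[keep_samples])

    p, n = allele_frequencies(gm2)
    marker_missing_frac = (gm2.calls == MISSING).mean(axis=0)
    fail_missing = marker_missing_frac > max_marker_missing
    maf = np.minimum(p, 1.0 - p)
    fail_maf = ~fail_missing & (np.isnan(maf) | (maf < min_maf))
    keep_markers = ~(fail_missing | fail_maf)
    report.n_markers_removed_missing = int(fail_missing.sum())
    report.n_markers_removed_maf = int(fail_maf.sum())
    if not keep_markers.any():
        raise EmptyPanelError("marker filters removed every marker")
    gm3 = GenotypeMatrix(gm2.samples, gm2.calls[:, keep_markers])
    mm3 = mm.subset(keep_markers)
    return gm3, mm3, report
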