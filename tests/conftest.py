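import numpy as np
import pytest

from rohscan import GenotypeMatrix, MarkerMap, MISSING


@pytest.fixture
def tiny_panel():
    """3 samples x 5 markers, handmade, with one het and one missing call."""
    mm = MarkerMap(
        chromosome=[1, 1, 1, 2, 2],
        position_bp=[1000, 2000, 3500, 500, 1500],
        marker_id=[f"m{i}" for i in range(5)],
        alleles=np.array([["A", "G"], ["C", "T"], ["A", "C"],
                          ["G", "T"], ["A", "T"]], dtype=object),
    )
    calls = np.array([
        [0, 1, 2, 0, 0],
        [2, 0, 0, 1, MISSING],
        [0, 0, 1, 2, 2],
    ], dtype=np.int8)
    gm = GenotypeMatrix(["s1", "s2", "s3"], calls)
    return gm, mm


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_panel(rng, n_samples=10, n_markers=50, missing_rate=0.05, n_chrom=2):
    """Random valid panel for round-trip tests."""
    per = n_markers // n_chrom
    chrom = np.repeat(np.arange(1, n_chrom + 1), per)
    pos = np.concatenate([np.sort(rng.choice(np.arange(1, 10**6), per, replace=False))
                          for _ in range(n_chrom)])
    letters = np.array(list("ACGT"))
    alleles = np.empty((n_chrom * per, 2), dtype=object)
    for i in range(n_chrom * per):
        a, b = rng.choice(4, 2, replace=False)
        alleles[i] = [letters[a], letters[b]]
    mm = MarkerMap(chrom, pos, np.array([f"rs{i}" for i in range(n_chrom * per)],
                                        dtype=object), alleles)
    calls = rng.integers(0, 3, size=(n_samples, n_chrom * per)).astype(np.int8)
    calls[rng.random(calls.shape) < missing_rate] = MISSING
    gm = GenotypeMatrix([f"ind{i}" for i in range(n_samples)], calls)
    return gm, mm
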