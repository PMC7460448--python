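"""Sliding-window ROH caller: window fractions, segment calling, size classes."""

import numpy as np
import pytest

from rohscan import (MISSING, GenotypeMatrix, MarkerMap, RohParams, RohSegment,
                     SizeClass, call_segments, classify, detect_roh, summarize,
                     window_hit_fraction)
from rohscan.experiments import SCALED_PARAMS, brute_force_segments, _random_vector


class TestWindowHitFraction:
    def test_all_homozygous_gives_ones(self):
        frac = window_hit_fraction(np.zeros(200, dtype=np.int8), RohParams())
        assert np.all(frac == 1.0)

    def test_alternating_het_gives_zeros(self):
        calls = np.zeros(200, dtype=np.int8)
        calls[::2] = 1  # every 50-SNP window holds >= 25 hets
        frac = window_hit_fraction(calls, RohParams())
        assert np.all(frac == 0.0)

    def test_matches_exhaustive_enumeration(self):
        # 8 SNPs, window of 3, one het: check against direct window listing
        params = RohParams(window_snps=3, window_max_het=0)
        calls = np.zeros(8, dtype=np.int8)
        calls[4] = 1
        windows = [(j, j + 2) for j in range(6)]
        expected = []
        for i in range(8):
            containing = [(a, b) for a, b in windows if a <= i <= b]
            passing = [1 for a, b in containing if calls[a:b + 1].sum() == 0]
            expected.append(sum(passing) / len(containing))
        got = window_hit_fraction(calls, params)
        assert np.allclose(got, expected)

    def test_short_chromosome_uses_single_window(self):
        params = RohParams(window_snps=50)
        frac = window_hit_fraction(np.zeros(10, dtype=np.int8), params)
        assert frac.shape == (10,)
        assert np.all(frac == 1.0)

    def test_empty_vector(self):
        assert window_hit_fraction(np.array([], dtype=np.int8), RohParams()).size == 0


class TestCallSegments:
    def test_planted_run_is_single_segment(self):
        # 120 homozygous SNPs at 5 kb spacing (595 kb) amid dense heterozygosity
        rng = np.random.default_rng(5)
        n = 400
        calls = rng.integers(0, 2, n).astype(np.int8)  # ~50% het outside
        calls[calls == 1] = 1
        calls[140:260] = 0
        positions = np.arange(1, n + 1) * 5000
        segs = call_segments(calls, positions, RohParams(), "s", 1)
        assert len(segs) == 1
        (seg,) = segs
        assert seg.n_snps >= 100
        assert seg.n_het <= 1
        # covers the planted run, with boundary slack below one window span
        assert abs(seg.start_bp - positions[140]) <= 50 * 5000
        assert abs(seg.end_bp - positions[259]) <= 50 * 5000
        # at full-scale parameters window eligibility may trim a few edge
        # SNPs relative to the pure-constraint oracle, never add any
        (oracle_seg,) = brute_force_segments(calls, positions, RohParams(), "s", 1)
        assert oracle_seg.start_bp <= seg.start_bp <= seg.end_bp <= oracle_seg.end_bp

    def test_short_run_fails_min_snps(self):
        # 90 homozygous SNPs spanning > 500 kb: below the 100-SNP minimum
        calls = np.ones(300, dtype=np.int8)
        calls[100:190] = 0
        positions = np.arange(1, 301) * 7000  # 90 SNPs span 623 kb
        assert call_segments(calls, positions, RohParams()) == []

    def test_gap_splits_candidate(self):
        params = SCALED_PARAMS  # min 10 SNPs / 20 kb, gap cap 100 kb
        calls = np.zeros(40, dtype=np.int8)
        positions = np.arange(1, 41) * 4000
        positions[20:] += 150_000  # 150 kb gap between SNP 19 and 20
        segs = call_segments(calls, positions, params, "s", 1)
        assert len(segs) == 2
        assert set(segs) == set(brute_force_segments(calls, positions, params, "s", 1))

    def test_mismatched_lengths_raise(self):
        with pytest.raises(ValueError):
            call_segments(np.zeros(5, dtype=np.int8), np.arange(4), RohParams())

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(40):
            calls, positions = _random_vector(rng, 250)
            got = call_segments(calls, positions, SCALED_PARAMS)
            want = brute_force_segments(calls, positions, SCALED_PARAMS)
            assert set(got) == set(want)

    def test_monotone_in_stringency(self):
        rng = np.random.default_rng(17)
        base = SCALED_PARAMS
        from dataclasses import replace
        for _ in range(20):
            calls, positions = _random_vector(rng, 250)
            n0 = len(call_segments(calls, positions, base))
            for tighter in (replace(base, min_snps=base.min_snps + 5),
                            replace(base, min_length_kb=base.min_length_kb * 2),
                            replace(base, hit_threshold=min(1.0, base.hit_threshold * 8))):
                assert len(call_segments(calls, positions, tighter)) <= n0

    def test_segments_never_overlap_and_counts_consistent(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            calls, positions = _random_vector(rng, 250)
            segs = call_segments(calls, positions, SCALED_PARAMS)
            segs = sorted(segs, key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                assert a.end_bp < b.start_bp
            for s in segs:
                lo = np.searchsorted(positions, s.start_bp)
                hi = np.searchsorted(positions, s.end_bp, side="right")
                member = calls[lo:hi]
                assert hi - lo == s.n_snps
                assert (member == 1).sum() == s.n_het <= SCALED_PARAMS.seg_max_het
                assert (member == MISSING).sum() == s.n_missing


class TestDetectRoh:
    def _panel_with_tract(self, seed=11):
        rng = np.random.default_rng(seed)
        n_snps = 2000
        positions = np.arange(1, n_snps + 1) * 5000
        p = rng.uniform(0.3, 0.5, n_snps)
        calls = rng.binomial(2, p, size=(5, n_snps)).astype(np.int8)
        # plant a 2 Mb (400-SNP) tract in sample 2
        calls[2, 800:1200] = np.where(rng.random(400) < p[800:1200], 2, 0)
        mm = MarkerMap(np.ones(n_snps, dtype=int), positions,
                       np.array([f"m{i}" for i in range(n_snps)], dtype=object),
                       np.tile(np.array([["A", "B"]], dtype=object), (n_snps, 1)))
        gm = GenotypeMatrix([f"s{i}" for i in range(5)], calls)
        return gm, mm

    def test_only_tract_carrier_yields_segment(self):
        gm, mm = self._panel_with_tract()
        segs = detect_roh(gm, mm)
        assert {s.sample_id for s in segs} == {"s2"}
        tract_lo, tract_hi = 800 * 5000 + 5000, 1200 * 5000
        assert any(min(s.end_bp, tract_hi) > max(s.start_bp, tract_lo) for s in segs)

    def test_identical_samples_get_identical_segments(self):
        gm, mm = self._panel_with_tract()
        calls = np.vstack([gm.calls[2], gm.calls[2]])
        gm2 = GenotypeMatrix(["a", "b"], calls)
        segs = detect_roh(gm2, mm)
        a = [(s.chromosome, s.start_bp, s.end_bp) for s in segs if s.sample_id == "a"]
        b = [(s.chromosome, s.start_bp, s.end_bp) for s in segs if s.sample_id == "b"]
        assert a == b and len(a) >= 1


class TestClassify:
    @pytest.mark.parametrize("length_bp,expected", [
        (700_000, SizeClass.SMALL),
        (999_999, SizeClass.SMALL),
        (1_000_000, SizeClass.MEDIUM),   # boundary: upper class wins
        (4_999_999, SizeClass.MEDIUM),
        (5_000_000, SizeClass.LARGE),
        (48_600_000, SizeClass.LARGE),
    ])
    def test_boundaries(self, length_bp, expected):
        seg = RohSegment("s", 1, 1, 1 + length_bp, 200, 0, 0)
        assert classify(seg) == expected


class TestSummarize:
    def test_toy_means_match_hand_computation(self):
        segs = [
            RohSegment("a", 1, 1_000_000, 1_800_000, 160, 0, 0),
            RohSegment("a", 2, 1_000_000, 2_000_000, 200, 1, 0),
            RohSegment("b", 1, 5_000_000, 5_600_000, 120, 0, 1),
            RohSegment("b", 3, 1_000_000, 7_000_000, 1200, 0, 0),
        ]
        s = summarize(segs, n_samples=2)
        assert s.n_segments == 4
        assert s.mean_count_per_sample == pytest.approx(2.0)
        # total length 0.8 + 1.0 + 0.6 + 6.0 = 8.4 Mb over 2 samples
        assert s.mean_length_mb_per_sample == pytest.approx(4.2)
        per_class = dict(zip(s.per_class["size_class"], s.per_class["n_segments"]))
        assert per_class == {"Small": 2, "Medium": 1, "Large": 1}

    def test_sample_without_segments_counts_zero(self):
        s = summarize([], n_samples=1, sample_ids=["lonely"])
        assert s.n_segments == 0
        assert s.per_sample.loc[0, "n_segments"] == 0
        assert s.per_sample.loc[0, "total_length_bp"] == 0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            summarize([], n_samples=0)
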