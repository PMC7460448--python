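"""Region merging, coverage, phenotype adjustment, regression and FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rohscan import (RohSegment, adjust_phenotype, associate, coverage_matrix,
                     fdr, merge_regions, run_association)
from rohscan.region_association import RankDeficientDesignError


def seg(sample, chrom, start, end):
    return RohSegment(sample, chrom, start, end,
                      max(2, (end - start) // 1000), 0, 0)


class TestMergeRegions:
    def test_single_segment_identity(self):
        regions = merge_regions([seg("a", 1, 100, 200)], n_samples=1)
        assert len(regions) == 1
        assert (regions[0].start_bp, regions[0].end_bp) == (100, 200)
        assert regions[0].carrier_frequency == 1.0

    def test_shared_single_bp_merges(self):
        regions = merge_regions([seg("a", 1, 100, 200), seg("b", 1, 200, 300)],
                                n_samples=2)
        assert [(r.start_bp, r.end_bp) for r in regions] == [(100, 300)]
        assert regions[0].carrier_frequency == 1.0

    def test_abutting_without_shared_bp_stays_separate(self):
        regions = merge_regions([seg("a", 1, 100, 200), seg("b", 1, 201, 300)],
                                n_samples=2)
        assert len(regions) == 2

    def test_matches_sweep_line_oracle(self):
        rng = np.random.default_rng(7)
        segments = []
        for i in range(40):
            c = int(rng.integers(1, 4))
            a = int(rng.integers(1, 10**6))
            segments.append(seg(f"s{i % 7}", c, a, a + int(rng.integers(1000, 300_000))))
        regions = merge_regions(segments, n_samples=7)
        # independent sweep by bp events per chromosome
        expected = []
        for c in sorted({s.chromosome for s in segments}):
            ivs = sorted((s.start_bp, s.end_bp) for s in segments if s.chromosome == c)
            cur_s, cur_e = ivs[0]
            for a, b in ivs[1:]:
                if a <= cur_e:
                    cur_e = max(cur_e, b)
                else:
                    expected.append((c, cur_s, cur_e))
                    cur_s, cur_e = a, b
            expected.append((c, cur_s, cur_e))
        assert [(r.chromosome, r.start_bp, r.end_bp) for r in regions] == expected
        # every segment fully inside exactly one region
        for s in segments:
            inside = [r for r in regions if r.chromosome == s.chromosome
                      and r.start_bp <= s.start_bp and s.end_bp <= r.end_bp]
            assert len(inside) == 1

    def test_order_invariance(self):
        rng = np.random.default_rng(11)
        segments = [seg(f"s{i}", 1, int(a), int(a) + 5000)
                    for i, a in enumerate(rng.integers(1, 10**5, 20))]
        r1 = merge_regions(segments, n_samples=20)
        rng.shuffle(segments)
        r2 = merge_regions(segments, n_samples=20)
        assert [(r.start_bp, r.end_bp) for r in r1] == [(r.start_bp, r.end_bp) for r in r2]

    def test_carrier_frequency_is_distinct_sample_count(self):
        segments = [seg("a", 1, 100, 5000), seg("a", 1, 4000, 9000),
                    seg("b", 1, 200, 300)]
        (region,) = merge_regions(segments, n_samples=4)
        assert region.n_segments == 3
        assert region.carrier_frequency == pytest.approx(2 / 4)


class TestCoverageMatrix:
    def test_exact_and_zero_and_half(self):
        segments = [seg("a", 1, 1000, 9000), seg("b", 1, 1000, 5000)]
        regions = merge_regions(segments, n_samples=3)
        cov = coverage_matrix(regions, segments, ["a", "b", "c"])
        col = cov.iloc[:, 0]
        assert col["a"] == pytest.approx(1.0)
        assert col["b"] == pytest.approx(0.5)
        assert col["c"] == 0.0


class TestAdjustPhenotype:
    def _table(self, n=60, rng=None, noise=0.0):
        rng = rng or np.random.default_rng(0)
        farm = rng.choice(["f1", "f2", "f3"], n)
        age = rng.uniform(24, 60, n)
        gender = rng.choice(["m", "f"], n)
        gen = rng.choice(["g1", "g2"], n)
        effect = (pd.Series(farm).map({"f1": 0, "f2": 2.0, "f3": -1.0}).to_numpy()
                  + 0.1 * age + (gender == "m") * 1.5 + (gen == "g2") * -0.5)
        eps = rng.normal(0, noise, n) if noise else np.zeros(n)
        return pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                             "farm": farm, "age": age, "gender": gender,
                             "generation": gen, "trait": effect + eps}), eps

    def test_exact_linear_function_gives_zero_residuals(self):
        table, _ = self._table()
        resid = adjust_phenotype(table, "trait")
        assert np.allclose(resid.to_numpy(), 0.0, atol=1e-8)

    def test_constant_covariates_give_centered_trait(self):
        n = 20
        rng = np.random.default_rng(1)
        y = rng.normal(size=n)
        table = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                              "farm": "f1", "age": 30.0, "gender": "m",
                              "generation": "g1", "trait": y})
        resid = adjust_phenotype(table, "trait")
        assert np.allclose(resid.to_numpy(), y - y.mean(), atol=1e-10)

    def test_residuals_recover_injected_noise(self):
        table, eps = self._table(n=500, rng=np.random.default_rng(5), noise=1.0)
        resid = adjust_phenotype(table, "trait")
        r = np.corrcoef(resid.to_numpy(), eps)[0, 1]
        assert r > 0.99

    def test_missing_phenotypes_dropped(self):
        table, _ = self._table()
        table.loc[3, "trait"] = np.nan
        resid = adjust_phenotype(table, "trait")
        assert len(resid) == len(table) - 1
        assert "s3" not in resid.index

    def test_aliased_design_raises(self):
        table, _ = self._table()
        table["generation"] = table["gender"]  # perfectly aliased
        with pytest.raises(RankDeficientDesignError):
            adjust_phenotype(table, "trait")

    def test_unknown_trait_raises(self):
        table, _ = self._table()
        with pytest.raises(KeyError):
            adjust_phenotype(table, "slaughter_weight")


class TestAssociate:
    def test_exact_linear_relation(self):
        x = np.arange(10, dtype=float)
        res = associate(x, 2.0 * x)
        assert res.beta == pytest.approx(2.0)
        assert res.p_value < 1e-12

    def test_five_point_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.1, 3.9, 6.2, 8.1, 9.8])
        n = 5
        sxx = (x ** 2).sum() - x.sum() ** 2 / n
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        beta_hand = sxy / sxx
        resid = y - y.mean() - beta_hand * (x - x.mean())
        se_hand = np.sqrt((resid ** 2).sum() / (n - 2) / sxx)
        res = associate(x, y)
        assert res.beta == pytest.approx(beta_hand, abs=1e-10)
        assert res.se == pytest.approx(se_hand, abs=1e-10)

    def test_null_type_one_error(self):
        rng = np.random.default_rng(2)
        n_sig = 0
        n_sim = 1000
        for _ in range(n_sim):
            x = np.where(rng.random(50) < 0.3, rng.random(50), 0.0)
            y = rng.normal(size=50)
            n_sig += associate(x, y).p_value < 0.01
        # 95% binomial band around 0.01
        assert n_sig / n_sim <= 0.01 + 1.96 * np.sqrt(0.01 * 0.99 / n_sim)

    def test_constant_coverage_rejected(self):
        with pytest.raises(ValueError):
            associate(np.ones(10), np.arange(10.0))


class TestFdr:
    def test_all_ones(self):
        assert np.all(fdr(np.ones(5)) == 1.0)

    def test_single_p_equals_itself(self):
        assert fdr(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_worked_step_up_example(self):
        q = fdr(np.array([0.01, 0.02, 0.03, 0.5]), method="bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_storey_never_exceeds_bh(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 1, 150), rng.uniform(0, 0.01, 50)])
        q_bh = fdr(p, "bh")
        q_st = fdr(p, "storey")
        assert np.all(q_st <= q_bh + 1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_monotone_in_p_rank(self, pvals):
        p = np.array(pvals)
        q = fdr(p, "bh")
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr(np.array([0.5, 1.2]))


class TestRunAssociation:
    def test_single_region_single_trait_single_row(self):
        rng = np.random.default_rng(9)
        n = 40
        samples = [f"s{i}" for i in range(n)]
        cov = pd.DataFrame({"chr1:1-100": np.where(rng.random(n) < 0.4,
                                                   1.0, 0.0)},
                           index=pd.Index(samples, name="sample_id"))
        pheno = pd.DataFrame({"sample_id": samples,
                              "farm": rng.choice(["a", "b"], n),
                              "age": rng.uniform(20, 60, n),
                              "gender": rng.choice(["m", "f"], n),
                              "generation": rng.choice(["g1", "g2"], n),
                              "body_height": rng.normal(size=n)})
        res = run_association(cov, pheno, ["body_height"])
        assert len(res) == 1
        assert set(["beta", "p_value", "q_value"]).issubset(res.columns)

    def test_absent_trait_lists_available(self):
        pheno = pd.DataFrame({"sample_id": ["a"], "farm": ["f"], "age": [30],
                              "gender": ["m"], "generation": ["g"],
                              "body_height": [1.0]})
        cov = pd.DataFrame({"r": [0.5]}, index=pd.Index(["a"], name="sample_id"))
        with pytest.raises(KeyError, match="body_height"):
            run_association(cov, pheno, ["no_such_trait"])
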