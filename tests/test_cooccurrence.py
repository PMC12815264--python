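"""Presence calling, co-occurrence statistics, fraction classes, prevalence."""

from __future__ import annotations

from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hgtcooc.cooccurrence import (
    call_presence,
    classify_size_fraction,
    drop_empty_samples,
    feature_prevalence,
    filter_prevalence,
    hypergeom_cooccurrence,
    paired_feature_tests,
    paired_fraction_test,
    proportionality_rho,
    simple_overlap,
)
from hgtcooc.simulate import simulate_independent_presence


def _presence(mat, genomes=None, samples=None) -> pd.DataFrame:
    mat = np.asarray(mat, dtype=bool)
    return pd.DataFrame(
        mat,
        index=samples or [f"S{i}" for i in range(mat.shape[0])],
        columns=genomes or [f"G{j}" for j in range(mat.shape[1])],
    )


class TestCallPresence:
    def test_threshold_is_inclusive(self):
        breadth = pd.DataFrame({"G0": [0.30, 0.299, 0.0]})
        rpkm = pd.DataFrame({"G0": [2.0, 5.0, 1.0]})
        out = call_presence(breadth, rpkm)
        assert out.present["G0"].tolist() == [True, False, False]
        assert out.rpkm["G0"].tolist() == [2.0, 0.0, 0.0]
        assert rpkm["G0"].tolist() == [2.0, 5.0, 1.0]  # input untouched

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_presence(pd.DataFrame({"G0": [0.5]}), pd.DataFrame({"G1": [1.0]}))


class TestPrevalenceFilter:
    def test_boundary_at_min_samples(self):
        mat = np.zeros((12, 2), dtype=bool)
        mat[:10, 0] = True  # exactly 10
        mat[:9, 1] = True  # 9: dropped
        retained, _ = filter_prevalence(_presence(mat))
        assert retained == ["G0"]

    def test_matches_column_sum_oracle_and_idempotent(self):
        rng = np.random.default_rng(3)
        pres = _presence(rng.random((40, 30)) < rng.uniform(0.05, 0.6, 30))
        retained, empty = filter_prevalence(pres)
        oracle = sorted(c for c in pres.columns if pres[c].sum() >= 10)
        assert retained == oracle
        retained2, _ = filter_prevalence(pres[retained])
        assert retained2 == retained

    def test_empty_samples_flagged(self):
        mat = np.ones((3, 2), dtype=bool)
        mat[1] = False
        _, empty = filter_prevalence(_presence(mat))
        assert empty == ["S1"]


class TestHypergeom:
    def test_worked_example_small_table(self):
        # N=10, k_a=5, k_b=4, obs=4 -> p = C(5,4) C(5,0) / C(10,4) = 5/210
        mat = np.zeros((10, 2), dtype=bool)
        mat[:5, 0] = True
        mat[:4, 1] = True
        res = hypergeom_cooccurrence(_presence(mat)).iloc[0]
        assert res.expected == pytest.approx(2.0)
        assert res.ratio == pytest.approx(2.0)
        assert res.p == pytest.approx(5 / 210, abs=1e-12)

    def test_ubiquitous_genome_forced_overlap(self):
        mat = np.zeros((8, 2), dtype=bool)
        mat[:, 0] = True
        mat[:3, 1] = True
        res = hypergeom_cooccurrence(_presence(mat)).iloc[0]
        assert res.obs == res.k_b
        assert res.ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_overlap_never_significant(self):
        mat = np.zeros((10, 2), dtype=bool)
        mat[:4, 0] = True
        mat[4:8, 1] = True
        res = hypergeom_cooccurrence(_presence(mat)).iloc[0]
        assert res.obs == 0 and res.ratio == 0.0
        assert not res.significant

    def test_bh_q_monotone_and_at_least_p(self, cooc_results):
        df = cooc_results.sort_values("p")
        assert (df["q"].to_numpy() >= df["p"].to_numpy() - 1e-15).all()
        # same p => same q; q is a monotone transform of p
        assert (np.diff(df["q"].to_numpy()) >= -1e-12).all()

    def test_null_mid_p_uniform_and_exact_p_conservative(self):
        """With independent occupancy the exact upper-tail p is super-uniform
        (conservative) while the mid-p variant is near-uniform."""
        pres = simulate_independent_presence(200, 2000, occupancy=0.3, seed=0)
        pairs = [(f"G{2 * i:03d}", f"G{2 * i + 1:03d}") for i in range(1000)]
        exact = hypergeom_cooccurrence(pres, pairs=pairs)
        midp = hypergeom_cooccurrence(pres, pairs=pairs, midp=True)
        assert stats.kstest(midp["p"], "uniform").pvalue > 0.01
        for u in (0.05, 0.1, 0.25, 0.5):
            assert (exact["p"] <= u).mean() <= u + 0.02

    def test_permuted_margins_keep_mean_ratio_near_one(self):
        rng = np.random.default_rng(11)
        base = rng.random(200) < 0.4
        other = rng.random(200) < 0.35
        ratios = []
        for _ in range(200):
            perm = rng.permutation(200)
            mat = np.column_stack([base, other[perm]])
            res = hypergeom_cooccurrence(_presence(mat)).iloc[0]
            ratios.append(res.ratio)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)


class TestSimpleOverlap:
    def test_examples(self):
        mat = np.zeros((4, 2), dtype=bool)
        mat[[0, 1, 2], 0] = True
        mat[[1, 2, 3], 1] = True
        assert simple_overlap(_presence(mat), ("G0", "G1")) == pytest.approx(2 / 3)

    def test_subset_gives_one(self):
        mat = np.zeros((5, 2), dtype=bool)
        mat[[0, 1], 0] = True
        mat[[0, 1, 2, 3], 1] = True
        assert simple_overlap(_presence(mat), ("G0", "G1")) == 1.0

    def test_absent_genome_rejected(self):
        mat = np.zeros((4, 2), dtype=bool)
        mat[0, 0] = True
        with pytest.raises(ValueError, match="G1"):
            simple_overlap(_presence(mat), ("G0", "G1"))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    def test_equals_obs_over_min_margin(self, bits_a, bits_b):
        """The printed formula is literally obs/min(k_a, k_b)."""
        va = np.array([(bits_a >> i) & 1 for i in range(20)], dtype=bool)
        vb = np.array([(bits_b >> i) & 1 for i in range(20)], dtype=bool)
        if not va.any() or not vb.any():
            return
        pres = _presence(np.column_stack([va, vb]))
        expected = (va & vb).sum() / min(va.sum(), vb.sum())
        assert simple_overlap(pres, ("G0", "G1")) == pytest.approx(expected)


class TestProportionality:
    def test_scaled_copy_has_rho_one(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(1, 0.5, 50)
        rpkm = pd.DataFrame({"G0": x, "G1": 2 * x, "G2": rng.lognormal(1, 0.5, 50)})
        # without a pseudocount distortion: use a tiny one
        rho = proportionality_rho(rpkm, pseudocount=1e-9)
        assert rho.loc["G0", "G1"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(rho.to_numpy(), rho.to_numpy().T, equal_nan=True)

    def test_matches_direct_formula_on_toy_matrix(self):
        rpkm = pd.DataFrame(
            [[1.0, 2.0, 0.0, 4.0], [2.0, 1.0, 3.0, 0.0], [0.0, 5.0, 1.0, 1.0],
             [3.0, 0.0, 2.0, 2.0], [1.0, 1.0, 1.0, 1.0]],
            columns=list("ABCD"),
        )
        rho = proportionality_rho(rpkm, pseudocount=1.0)
        x = np.log(rpkm.to_numpy() + 1.0)
        clr = x - x.mean(axis=1, keepdims=True)
        # closure cancels inside clr: log(p) - mean log(p) == log(x) - mean log(x)
        for i, j in [(0, 1), (0, 3), (2, 3)]:
            vi, vj = clr[:, i], clr[:, j]
            expected = 1 - np.var(vi - vj, ddof=1) / (np.var(vi, ddof=1) + np.var(vj, ddof=1))
            assert rho.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_independent_columns_mean_near_zero(self):
        rng = np.random.default_rng(1)
        rpkm = pd.DataFrame(rng.lognormal(1, 0.8, (500, 40)))
        rho = proportionality_rho(rpkm, pseudocount=1.0)
        off = rho.to_numpy()[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_constant_column_undefined(self):
        rpkm = pd.DataFrame({"G0": [1.0, 1.0, 1.0], "G1": [1.0, 2.0, 3.0], "G2": [3.0, 1.0, 2.0]})
        rho = proportionality_rho(rpkm, pseudocount=1.0)
        # G0's clr is not constant (row closure varies), but a truly
        # zero-variance profile arises for identical rows
        flat = pd.DataFrame({"G0": [1.0, 1.0], "G1": [1.0, 1.0], "G2": [1.0, 1.0]})
        rho2 = proportionality_rho(flat, pseudocount=1.0)
        assert rho2.drop("G0").isna().all().all() or rho2.isna().any().any()


class TestFractionClass:
    def _inputs(self, labels, present_rows, rpkm_vals):
        samples = [f"S{i}" for i in range(len(labels))]
        pres = pd.DataFrame({"G0": present_rows}, index=samples)
        rpkm = pd.DataFrame({"G0": rpkm_vals}, index=samples)
        fr = pd.Series(labels, index=samples)
        return pres, rpkm, fr

    def test_clear_free_living_assignment(self):
        labels = ["free_living"] * 8 + ["combined_fl_pa"] * 2
        pres, rpkm, fr = self._inputs(labels, [True] * 10, [5.0] * 8 + [1.0] * 2)
        out = classify_size_fraction(pres, rpkm, fr)[0]
        assert out.fraction_class == "free_living"
        assert out.support == pytest.approx(0.8)

    def test_support_exactly_threshold_unclassified(self):
        labels = ["free_living"] * 6 + ["combined_fl_pa"] * 2
        pres, rpkm, fr = self._inputs(labels, [True] * 8, [5.0] * 6 + [1.0] * 2)
        out = classify_size_fraction(pres, rpkm, fr)[0]  # support = 0.75 strict
        assert out.fraction_class == "unclassified"

    def test_median_rpkm_must_be_highest(self):
        labels = ["free_living"] * 8 + ["combined_fl_pa"] * 2
        pres, rpkm, fr = self._inputs(labels, [True] * 10, [1.0] * 8 + [9.0] * 2)
        out = classify_size_fraction(pres, rpkm, fr)[0]
        assert out.fraction_class == "unclassified"

    def test_other_samples_count_in_denominator(self):
        labels = ["free_living"] * 6 + ["other"] * 4
        pres, rpkm, fr = self._inputs(labels, [True] * 10, [5.0] * 10)
        out = classify_size_fraction(pres, rpkm, fr)[0]
        assert out.support == pytest.approx(0.6)
        assert out.fraction_class == "unclassified"


class TestFeaturePrevalence:
    def test_simple_fraction(self):
        mat = np.ones((1, 10), dtype=bool)
        pres = _presence(mat)
        flags = {g: i < 3 for i, g in enumerate(pres.columns)}
        assert feature_prevalence(pres, flags).iloc[0] == pytest.approx(0.3)

    def test_no_flags_all_zero_and_empty_sample_missing(self):
        mat = np.ones((3, 4), dtype=bool)
        mat[1] = False
        pres = _presence(mat)
        out = feature_prevalence(pres, {g: False for g in pres.columns})
        assert out.iloc[0] == 0.0 and np.isnan(out.iloc[1])

    def test_matches_row_wise_oracle(self, dataset, presence_bundle):
        _, retained, present = presence_bundle
        carriers = dataset.truth.carriers()
        flags = {g: g in carriers for g in present.columns}
        out = feature_prevalence(present, flags)
        for s in present.index[:20]:
            row = present.loc[s]
            expected = sum(flags[g] for g in present.columns if row[g]) / row.sum()
            assert out[s] == pytest.approx(expected)


class TestPairedTest:
    def test_equal_series_fold_one_p_one(self):
        x = pd.Series(np.linspace(0.1, 0.5, 10))
        fold, p = paired_fraction_test(x, x.copy())
        assert fold == 1.0 and p == 1.0

    def test_doubled_series_exact_signed_rank(self):
        rng = np.random.default_rng(5)
        small = pd.Series(rng.uniform(0.05, 0.3, 20))
        fold, p = paired_fraction_test(small, 2 * small)
        assert fold == pytest.approx(2.0)
        # all 20 differences positive: exact two-sided p = 2 / 2^20
        assert p == pytest.approx(2 / 2**20, rel=1e-6)

    def test_planted_fold_significant_after_bh(self):
        from hgtcooc.simulate import simulate_paired_prevalence

        small, large = simulate_paired_prevalence(n_samples=43, fold=2.09, seed=1)
        null_small, null_large = simulate_paired_prevalence(n_samples=43, fold=1.0, seed=2)
        out = paired_feature_tests(
            {"hgt": (small, large), "null_feature": (null_small, null_large)}
        ).set_index("feature")
        assert out.loc["hgt", "q"] < 0.05
        assert out.loc["hgt", "fold_change"] == pytest.approx(2.09, rel=0.15)
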