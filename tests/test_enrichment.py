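import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spongemag.config import RunConfig
from spongemag.enrichment import (
    bh_adjust,
    child_seed,
    log10_ratio,
    normalize_counts,
    permutation_t_test,
    prevalence_filter,
    run_enrichment,
    stratified_enrichment,
)


def brute_force_welch_p(x, y):
    """Enumerate every label assignment and count |t*| >= |t_obs| directly."""

    def welch(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        se2 = a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)
        d = a.mean() - b.mean()
        if se2 == 0:
            return 0.0 if d == 0 else math.inf
        return abs(d / math.sqrt(se2))

    pooled = list(x) + list(y)
    t_obs = welch(x, y)
    hits = total = 0
    for combo in combinations(range(len(pooled)), len(x)):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if welch(xs, ys) >= t_obs - 1e-12:
            hits += 1
    return hits / total


class TestNormalize:
    def test_simple_division(self):
        m = pd.DataFrame({"K1": [2, 0]}, index=["a", "b"])
        out = normalize_counts(m, {"a": 1000, "b": 500})
        assert out.loc["a", "K1"] == pytest.approx(0.002)
        assert out.loc["b", "K1"] == 0.0

    def test_row_sum_identity(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.poisson(2, size=(5, 30)),
            index=[f"m{i}" for i in range(5)],
            columns=[f"K{j}" for j in range(30)],
        )
        totals = pd.Series(rng.integers(500, 5000, 5), index=m.index)
        out = normalize_counts(m, totals)
        np.testing.assert_allclose(
            out.sum(axis=1), m.sum(axis=1) / totals, rtol=1e-12
        )

    def test_nonpositive_total_names_mag(self):
        m = pd.DataFrame({"K1": [1]}, index=["bad"])
        with pytest.raises(ValueError, match="bad"):
            normalize_counts(m, {"bad": 0})


class TestPrevalenceFilter:
    def _mats(self, prev_f, prev_r, n=100):
        f = pd.DataFrame({"K": [1] * int(prev_f * n) + [0] * (n - int(prev_f * n))})
        r = pd.DataFrame({"K": [1] * int(prev_r * n) + [0] * (n - int(prev_r * n))})
        return f, r

    def test_low_in_both_removed(self):
        f, r = self._mats(0.05, 0.08)
        assert list(prevalence_filter(f, r)) == []

    def test_one_side_suffices(self):
        f, r = self._mats(0.05, 0.50)
        assert list(prevalence_filter(f, r)) == ["K"]

    def test_exact_threshold_retained(self):
        f, r = self._mats(0.10, 0.0)
        assert list(prevalence_filter(f, r)) == ["K"]


class TestPermutationTest:
    def test_no_signal_gives_one(self):
        assert permutation_t_test([3, 3, 3], [3, 3, 3]) == 1.0

    def test_constant_unequal_exhaustive(self):
        """Only the original split and its mirror give an infinite statistic."""
        assert permutation_t_test([0, 0, 0], [1, 1, 1]) == pytest.approx(2 / 20)

    def test_group_too_small_rejected(self):
        with pytest.raises(ValueError):
            permutation_t_test([1], [2, 3])

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_branch_equals_brute_force(self, seed):
        """Exhaustive enumeration matches an independent brute-force count on
        all instances with <= 10 labels."""
        rng = np.random.default_rng(seed)
        nx, ny = rng.integers(2, 6), rng.integers(2, 6)
        x = rng.poisson(2.0, nx).astype(float)
        y = rng.poisson(2.0, ny).astype(float)
        assert permutation_t_test(x, y) == pytest.approx(
            brute_force_welch_p(x, y)
        )

    def test_exact_branch_symmetric_in_groups(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 4), rng.normal(1, 1, 5)
        assert permutation_t_test(x, y) == pytest.approx(
            permutation_t_test(y, x)
        )

    def test_strong_planted_effect_significant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5.0, 1.0, 15)
        y = rng.normal(0.0, 1.0, 15)
        assert permutation_t_test(x, y, seed=1) < 0.01

    @pytest.mark.parametrize("seed", range(4))
    def test_monte_carlo_agrees_with_exact(self, seed):
        """MC p lies within 3 MC standard errors of the exact tail."""
        rng = np.random.default_rng(40 + seed)
        x = rng.normal(0.6, 1.0, 5)
        y = rng.normal(0.0, 1.0, 5)
        exact = permutation_t_test(x, y, n_iter=300)  # C(10,5)=252 -> exact
        n_iter = 10_000
        mc = permutation_t_test(x, y, n_iter=n_iter, seed=seed)
        se = math.sqrt(exact * (1 - exact) / n_iter) + 1 / n_iter
        assert abs(mc - exact) <= 3 * se + 1e-12

    def test_add_one_never_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 1, 20)
        y = rng.normal(0, 1, 20)
        p = permutation_t_test(x, y, n_iter=1000, seed=0)
        assert p == pytest.approx(1 / 1001)


class TestBH:
    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_value_capped(self):
        assert bh_adjust([0.5], m=10) == pytest.approx([1.0])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5), [1.0] * 5)

    def test_family_smaller_than_tests_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 0.2], m=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_vectors_vs_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, 20)
        m = 20 + int(rng.integers(0, 30))
        q = bh_adjust(p, m=m)
        # brute-force oracle: direct min-over-tail of the step-up formula
        order = np.argsort(p)
        expect = np.empty_like(p)
        for rank0, i in enumerate(order):
            tail = [
                min(1.0, m * p[j] / (r + 1))
                for r, j in enumerate(order)
                if r >= rank0
            ]
            expect[i] = min(tail)
        np.testing.assert_allclose(q, expect, rtol=1e-12)

    def test_matches_statsmodels_when_family_equals_tests(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.uniform(0.001, 1, 50)
        q = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, rtol=1e-10)

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestLog10Ratio:
    def test_fourfold(self):
        v, inf = log10_ratio(0.004, 0.001)
        assert v == pytest.approx(math.log10(4))
        assert not inf

    def test_depletion_negative(self):
        v, _ = log10_ratio(0.001, 0.004)
        assert v == pytest.approx(-math.log10(4))

    def test_zero_side_sentinel(self):
        v, inf = log10_ratio(0.0, 0.002)
        assert v == -math.inf and inf


class TestRunEnrichment:
    def test_planted_effects_recovered(self, small_cohort):
        d = small_cohort
        cfg = RunConfig(rng_seed=11, n_permutations=10_000)
        tbl = run_enrichment(
            d["focal_counts"],
            {m.mag_id: m.total_proteins for m in d["focal_mags"]},
            d["reference_counts"],
            {m.mag_id: m.total_proteins for m in d["reference_mags"]},
            cfg,
        )
        truth = d["truth"].set_index("feature_id")
        called = tbl[tbl["call"].isin(["enriched", "depleted"])]
        called = called.set_index("feature_id")
        # every strong planted effect is recovered in the right direction
        strong = truth[truth["fold_change"] >= 4.0]
        for f, row in strong.iterrows():
            assert f in called.index
            assert called.loc[f, "call"] == row["direction"]
        # no planted feature is ever called in the wrong direction
        for f in truth.index.intersection(called.index):
            assert called.loc[f, "call"] == truth.loc[f, "direction"]
        # and nulls stay quiet
        assert len(set(called.index) - set(truth.index)) <= 2

    def test_null_split_makes_no_calls(self, small_cohort):
        """Splitting one group at random should produce no calls."""
        d = small_cohort
        ref = d["reference_counts"]
        totals = {m.mag_id: m.total_proteins for m in d["reference_mags"]}
        half = len(ref) // 2
        cfg = RunConfig(rng_seed=1, n_permutations=2000)
        tbl = run_enrichment(ref.iloc[:half], totals, ref.iloc[half:], totals, cfg)
        assert (tbl["call"].isin(["enriched", "depleted"])).sum() == 0

    def test_filtered_features_never_called(self, small_cohort):
        d = small_cohort
        cfg = RunConfig(rng_seed=2, n_permutations=200)
        tbl = run_enrichment(
            d["focal_counts"],
            {m.mag_id: m.total_proteins for m in d["focal_mags"]},
            d["reference_counts"],
            {m.mag_id: m.total_proteins for m in d["reference_mags"]},
            cfg,
        )
        filtered = tbl[tbl["call"] == "filtered"]
        assert filtered["p_raw"].isna().all()
        assert filtered["p_adj"].isna().all()

    def test_child_seed_stable_and_order_free(self):
        assert child_seed(5, "K00010") == child_seed(5, "K00010")
        assert child_seed(5, "K00010") != child_seed(5, "K00011")
        assert 0 <= child_seed(5, "K00010") < 2**31


class TestStratified:
    def _meta(self, mags):
        return pd.DataFrame(
            {"phylum": [m.phylum for m in mags], "class_": [m.class_ for m in mags]},
            index=[m.mag_id for m in mags],
        )

    def test_min_mag_gate(self, small_cohort):
        d = small_cohort
        cfg = RunConfig(rng_seed=3, n_permutations=200, min_mags_per_category=10)
        results, skipped = stratified_enrichment(
            d["focal_counts"],
            {m.mag_id: m.total_proteins for m in d["focal_mags"]},
            self._meta(d["focal_mags"]),
            d["reference_counts"],
            {m.mag_id: m.total_proteins for m in d["reference_mags"]},
            self._meta(d["reference_mags"]),
            cfg,
        )
        focal_strata = self._meta(d["focal_mags"])
        ref_strata = self._meta(d["reference_mags"])

        def count(meta, taxon):
            s = meta["phylum"].where(
                meta["phylum"] != "Proteobacteria", meta["class_"]
            )
            return int((s == taxon).sum())

        for taxon in results:
            assert count(focal_strata, taxon) >= 10
            assert count(ref_strata, taxon) >= 10
        for taxon, reason in skipped:
            assert (
                count(focal_strata, taxon) < 10 or count(ref_strata, taxon) < 10
            )
            assert "MAG" in reason

    def test_proteobacteria_split_by_class(self, small_cohort):
        d = small_cohort
        cfg = RunConfig(rng_seed=3, n_permutations=200, min_mags_per_category=2)
        results, skipped = stratified_enrichment(
            d["focal_counts"],
            {m.mag_id: m.total_proteins for m in d["focal_mags"]},
            self._meta(d["focal_mags"]),
            d["reference_counts"],
            {m.mag_id: m.total_proteins for m in d["reference_mags"]},
            self._meta(d["reference_mags"]),
            cfg,
        )
        taxa = set(results) | {t for t, _ in skipped}
        assert "Proteobacteria" not in taxa
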