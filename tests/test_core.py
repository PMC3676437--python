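"""Unit and property tests for the frequency estimator, variance models and
the two-pool chi-square test."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolassoc import (
    PoolSpec,
    SiteCounts,
    VarianceModel,
    estimate_freq,
    site_test,
    run_site_tests,
    variance_full,
    variance_naive,
    variance_observed,
    variance_shares,
)

from _oracles import (
    mc_variance_se,
    one_stage_freqs,
    two_stage_freqs,
    gamma_weights,
    three_stage_freqs,
)


class TestEstimateFreq:
    @pytest.mark.parametrize(
        "alt,depth,expected",
        [(30, 100, 0.30), (0, 500, 0.0), (6000, 6000, 1.0)],
    )
    def test_direct_ratio(self, alt, depth, expected):
        assert estimate_freq(alt, depth) == expected

    def test_zero_depth_is_nan_not_error(self):
        assert np.isnan(estimate_freq(0, 0))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_freq(10, 5)


class TestVarianceFormulas:
    @pytest.mark.parametrize(
        "p,n,expected",
        [
            (0.5, 640, 3.90625e-4),
            (0.0, 640, 0.0),
            (0.1, 726, 0.09 / 726),
        ],
    )
    def test_naive_closed_form(self, p, n, expected):
        assert variance_naive(p, n) == pytest.approx(expected, rel=1e-12)

    def test_observed_closed_form(self):
        # 0.25 * (1/6000 + 1/640 - 1/3840000)
        assert variance_observed(0.5, 640, 6000) == pytest.approx(
            4.322265625e-4, rel=1e-9
        )

    def test_observed_infinite_depth_limit_is_naive(self):
        assert variance_observed(0.3, 640, 10**12) == pytest.approx(
            variance_naive(0.3, 640), rel=1e-6
        )

    def test_observed_infinite_pool_limit_is_read_sampling(self):
        assert variance_observed(0.3, 10**12, 500) == pytest.approx(
            0.3 * 0.7 / 500, rel=1e-6
        )

    def test_full_reduces_to_observed_at_k_zero(self):
        grid = [(0.05, 40, 50), (0.2, 640, 2000), (0.5, 640, 6000)]
        for p, n, r in grid:
            assert variance_full(p, n, r, 0.0) == variance_observed(p, n, r)

    def test_full_closed_form(self):
        # 0.25 * (1/6000 + 4.34/640 - 4.34/3840000)
        assert variance_full(0.5, 640, 6000, 3.34) == pytest.approx(
            1.7366966e-3, rel=1e-6
        )

    def test_full_infinite_depth_limit(self):
        k = 2.0
        assert variance_full(0.5, 640, 10**12, k) == pytest.approx(
            0.25 * (1 + k) / 640, rel=1e-6
        )

    def test_interaction_flag_drops_cross_term(self):
        p, n, r, k = 0.3, 640, 2000, 1.5
        with_term = variance_full(p, n, r, k, include_interaction=True)
        without = variance_full(p, n, r, k, include_interaction=False)
        assert without - with_term == pytest.approx(
            p * (1 - p) * (1 + k) / (n * r), rel=1e-9
        )

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            variance_full(0.5, 640, 6000, -0.1)

    @given(
        p=st.floats(0.01, 0.99),
        n_ind=st.integers(2, 2000),
        r=st.integers(1, 20000),
        k=st.floats(1e-6, 20),
    )
    @settings(derandomize=True, max_examples=150)
    def test_variance_nesting(self, p, n_ind, r, k):
        """naive <= observed <= full for any k > 0."""
        n = 2 * n_ind
        v1 = variance_naive(p, n)
        v2 = variance_observed(p, n, r)
        v3 = variance_full(p, n, r, k)
        assert v1 <= v2 * (1 + 1e-12)
        assert v2 <= v3 * (1 + 1e-12)

    @given(
        p1=st.floats(0.01, 0.99),
        p2=st.floats(0.01, 0.99),
        n_ind=st.integers(2, 2000),
        r=st.integers(2, 20000),
        k=st.floats(0, 20),
    )
    @settings(derandomize=True, max_examples=100)
    def test_inflation_constant_in_allele_frequency(self, p1, p2, n_ind, r, k):
        """full / observed is the same at any frequency."""
        n = 2 * n_ind
        r1 = variance_full(p1, n, r, k) / variance_observed(p1, n, r)
        r2 = variance_full(p2, n, r, k) / variance_observed(p2, n, r)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_shares_sum_to_one_and_interaction_negative(self):
        shares = variance_shares(640, 6000, 3.34)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-12)
        assert shares["interaction"] < 0


class TestMonteCarloOracle:
    """Spot checks of the closed forms against the staged-sampling oracle
    (the full grid runs in the acceptance suite)."""

    REPS = 100_000

    def test_naive_matches_chromosome_sampling(self):
        rng = np.random.default_rng(11)
        f = one_stage_freqs(0.2, 640, self.REPS, rng)
        assert abs(f.var(ddof=1) - variance_naive(0.2, 640)) <= 3 * mc_variance_se(f)

    def test_observed_matches_two_stage_sampling(self):
        rng = np.random.default_rng(12)
        phat = two_stage_freqs(0.5, 640, 2000, self.REPS, rng)
        expected = variance_observed(0.5, 640, 2000)
        assert abs(phat.var(ddof=1) - expected) <= 3 * mc_variance_se(phat)

    def test_full_matches_three_stage_sampling(self):
        rng = np.random.default_rng(13)
        weights, realized = gamma_weights(20, 3.0, rng)
        phat = three_stage_freqs(0.5, weights, 2000, self.REPS, rng)
        expected = variance_full(0.5, 40, 2000, realized)
        assert abs(phat.var(ddof=1) - expected) <= 3 * mc_variance_se(phat)


class TestSiteTest:
    def setup_method(self):
        self.case = PoolSpec(320)
        self.ctrl = PoolSpec(320)

    def _site(self, xc, rc, xt, rt):
        return SiteCounts("s", "chr1", 1, "A", "G", rc, xc, rt, xt)

    @pytest.mark.parametrize("model", ["naive", "observed", "full"])
    def test_identical_counts_give_zero_statistic(self, model):
        res = site_test(
            self._site(300, 1000, 300, 1000), self.case, self.ctrl, model=model, k=1.0
        )
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_statistic_invariant_under_allele_relabel(self):
        a = site_test(self._site(300, 1000, 200, 900), self.case, self.ctrl, k=2.0)
        b = site_test(self._site(700, 1000, 700, 900), self.case, self.ctrl, k=2.0)
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_zero_total_variance_flagged_untestable(self):
        res = site_test(self._site(0, 1000, 0, 900), self.case, self.ctrl, k=0.0)
        assert not res.testable
        assert np.isnan(res.statistic)

    def test_statistics_weakly_ordered_across_models(self):
        site = self._site(350, 1000, 250, 900)
        t1 = site_test(site, self.case, self.ctrl, model="naive").statistic
        t2 = site_test(site, self.case, self.ctrl, model="observed").statistic
        t3 = site_test(site, self.case, self.ctrl, model="full", k=2.0).statistic
        assert t1 >= t2 >= t3

    def test_p_value_monotone_decreasing_in_statistic(self):
        sites = [self._site(300 + d, 1000, 300, 1000) for d in (10, 40, 80)]
        res = [site_test(s, self.case, self.ctrl, model="observed") for s in sites]
        stats_ = [r.statistic for r in res]
        pvals = [r.p_value for r in res]
        assert stats_ == sorted(stats_)
        assert pvals == sorted(pvals, reverse=True)

    def test_components_reported_per_pool(self):
        res = site_test(
            self._site(300, 1000, 200, 900), self.case, self.ctrl, model="full", k=3.0
        )
        for pool in ("case", "ctrl"):
            assert sum(res.components[pool].values()) == pytest.approx(1.0, abs=1e-12)
            assert res.components[pool]["pooling"] > 0


class TestBatchRanking:
    def test_naive_and_full_top3_differ_on_heterogeneous_depths(self, ranking_sites):
        """With depths spanning 40-6000x, depth-blind ranking promotes
        low-depth extreme sites that the full model demotes."""
        case, ctrl = PoolSpec(320), PoolSpec(320)
        naive = run_site_tests(ranking_sites, case, ctrl, model=VarianceModel.NAIVE)
        full = run_site_tests(ranking_sites, case, ctrl, model=VarianceModel.FULL, k=3.0)
        top_naive = naive.sort_values("rank").head(3)["site_id"].tolist()
        top_full = full.sort_values("rank").head(3)["site_id"].tolist()
        assert top_naive != top_full
        assert set(top_naive).isdisjoint(set(top_full))

    def test_untestable_sites_unranked(self):
        sites = [
            SiteCounts("a", "c", 1, "A", "G", 100, 30, 100, 20),
            SiteCounts("b", "c", 2, "A", "G", 0, 0, 100, 20),
        ]
        df = run_site_tests(sites, PoolSpec(10), PoolSpec(10), model="observed")
        assert df.loc[df.site_id == "b", "rank"].item() == 0
        assert df.loc[df.site_id == "a", "rank"].item() == 1

    def test_rank_ties_broken_by_frequency_difference(self):
        # two sites with equal statistics by symmetry, third clearly weaker
        sites = [
            SiteCounts("x", "c", 1, "A", "G", 1000, 400, 1000, 300),
            SiteCounts("y", "c", 2, "A", "G", 1000, 600, 1000, 700),
            SiteCounts("z", "c", 3, "A", "G", 1000, 400, 1000, 390),
        ]
        df = run_site_tests(sites, PoolSpec(100), PoolSpec(100), model="observed")
        assert df.loc[df.site_id == "z", "rank"].item() == 3
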