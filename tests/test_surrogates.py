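"""Surrogate nulls, signed-rank test against 0.05, Holm correction."""

import itertools

import numpy as np
import pytest
from scipy import stats

from dyadte import (
    PlayerParams,
    holm_adjust,
    per_trial_significance,
    simulate_trial,
    surrogate_null,
    wilcoxon_vs_threshold,
)
from dyadte.preprocess import discard_initialization

from conftest import independent_pool


def coupled_pool(n_dyads, seed, duration=25.0):
    pool = []
    for s in range(n_dyads):
        leader = PlayerParams(coupling_in=0.3)
        follower = PlayerParams(coupling_in=2.0, initial_phase=1.0)
        trial = simulate_trial(
            leader, follower, seed=seed + s, duration=duration, pair_id=f"p{s}"
        )
        pool.append(discard_initialization(trial, 500))
    return pool


class TestSurrogateNull:
    def test_strong_coupling_beats_every_surrogate(self):
        """Observed TE above all nulls gives the add-one minimum p."""
        pool = coupled_pool(8, seed=0)
        res = surrogate_null(pool[0], pool, n_surrogates=100, seed=1)
        assert res.n_surrogates == 100
        assert np.all(res.null_te < res.observed_te)
        assert res.p_value == pytest.approx(1 / 101)

    def test_add_one_rule_with_single_surrogate(self):
        pool = independent_pool(4, seed=10)
        res = surrogate_null(pool[0], pool, n_surrogates=1, seed=0)
        expected = 1.0 if res.null_te[0] >= res.observed_te else 0.5
        assert res.p_value == expected

    def test_default_produces_1000_nulls(self):
        pool = coupled_pool(4, seed=20)
        res = surrogate_null(pool[0], pool, n_surrogates=1000, seed=2)
        assert res.n_surrogates == 1000
        assert np.isfinite(res.null_te).all()
        assert 0 < res.p_value <= 1

    def test_donor_pool_without_other_dyads_rejected(self):
        pool = coupled_pool(1, seed=30)
        with pytest.raises(ValueError, match="donor pool"):
            surrogate_null(pool[0], pool, n_surrogates=10, seed=0)

    def test_block_shuffle_scheme(self):
        pool = coupled_pool(2, seed=40, duration=35.0)
        res = surrogate_null(
            pool[0], pool, n_surrogates=50, seed=3, scheme="block_shuffle"
        )
        assert res.scheme == "block_shuffle"
        assert res.n_surrogates == 50
        # rotation destroys the phase-specific coupling
        assert np.median(res.null_te) < res.observed_te

    def test_deterministic_given_seed(self):
        pool = coupled_pool(4, seed=50)
        a = surrogate_null(pool[0], pool, n_surrogates=20, seed=7)
        b = surrogate_null(pool[0], pool, n_surrogates=20, seed=7)
        np.testing.assert_array_equal(a.null_te, b.null_te)
        assert a.p_value == b.p_value


class TestWilcoxon:
    def test_ten_identical_low_values_exact_p(self):
        """All values below threshold: W+ = 0, one-sided p = 1/1024."""
        p = wilcoxon_vs_threshold([0.001] * 10, 0.05)
        assert p == pytest.approx(1 / 1024)

    def test_symmetric_values_give_half(self):
        values = [0.05 - d for d in (0.01, 0.02, 0.03)] + [
            0.05 + d for d in (0.01, 0.02, 0.03)
        ]
        p = wilcoxon_vs_threshold(values, 0.05)
        assert 0.3 < p < 0.7

    def test_values_above_threshold_give_p_near_one(self):
        assert wilcoxon_vs_threshold([0.9] * 10, 0.05) > 0.99

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_p_matches_full_sign_enumeration(self, seed):
        """For n <= 12, compare with brute-force enumeration of all 2^n
        sign assignments on the observed (mid-)ranks."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        values = np.round(rng.uniform(0.0, 0.12, n), 3)
        values = values[values != 0.05]
        n = len(values)
        d = values - 0.05
        ranks = stats.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        count = sum(
            1
            for signs in itertools.product([0, 1], repeat=n)
            if np.sum(ranks * np.array(signs)) <= w_obs
        )
        expected = count / 2**n
        assert wilcoxon_vs_threshold(values, 0.05) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_in_clean_exact_regime(self):
        """No ties, n <= 25: agrees with scipy's exact signed-rank test."""
        rng = np.random.default_rng(3)
        values = rng.uniform(0.0, 0.2, 15)
        ours = wilcoxon_vs_threshold(values, 0.05)
        ref = stats.wilcoxon(values - 0.05, alternative="less", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_for_large_n(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.0, 0.09, 60)
        ours = wilcoxon_vs_threshold(values, 0.05)
        ref = stats.wilcoxon(
            values - 0.05, alternative="less", method="approx", correction=True
        ).pvalue
        assert ours == pytest.approx(ref, rel=0.05)

    def test_all_values_at_threshold_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            wilcoxon_vs_threshold([0.05] * 10, 0.05)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_vs_threshold([0.01, 0.02, 0.03], 0.05)


class TestHolm:
    def test_worked_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
        assert (adj <= 0.05).tolist() == [True, False, False]

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.2]), [0.2])

    def test_all_zero_stay_zero(self):
        np.testing.assert_allclose(holm_adjust([0.0, 0.0, 0.0]), [0.0, 0.0, 0.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_reference(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 12)
        ref = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_holm_rejects_at_least_as_much_as_bonferroni(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = rng.uniform(0, 0.2, 10)
        holm_rej = (holm_adjust(p) <= 0.05).sum()
        bonf_rej = (np.minimum(1, p * len(p)) <= 0.05).sum()
        assert holm_rej >= bonf_rej

    def test_adjusted_monotone_along_sorted_order(self):
        rng = np.random.default_rng(200)
        p = rng.uniform(0, 1, 20)
        adj = holm_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestPerTrialSignificance:
    def test_strongly_coupled_cohort_all_trials_significant(self):
        """Strong coupling: every pair's surrogate p is small in every
        trial, so each trial's Wilcoxon against 0.05 rejects after Holm."""
        rng = np.random.default_rng(0)
        p_by_trial = {t: rng.uniform(0.001, 0.02, 8) for t in range(1, 6)}
        sig = per_trial_significance(p_by_trial, alpha=0.05)
        assert all(s.significant for s in sig)
        assert [s.trial_index for s in sig] == [1, 2, 3, 4, 5]

    def test_null_pvalues_rarely_significant(self):
        rng = np.random.default_rng(1)
        flags = []
        for rep in range(20):
            p_by_trial = {t: rng.uniform(0, 1, 8) for t in range(1, 6)}
            sig = per_trial_significance(p_by_trial, alpha=0.05)
            flags.append(sum(s.significant for s in sig))
        assert np.mean([f <= 1 for f in flags]) >= 0.9

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(2)
        p_by_trial = {t: rng.uniform(0, 0.5, 6) for t in range(1, 8)}
        for s in per_trial_significance(p_by_trial):
            assert s.adjusted_p >= s.raw_p - 1e-15

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            per_trial_significance({})
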