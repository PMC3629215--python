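import math

import numpy as np
import pytest
from scipy.stats import kstest, multinomial

from neodemic.admixture import (
    LineagePmfCache,
    PosteriorSample,
    _pmf_matrix,
    _pmf_series,
    drift_lineage_pmf,
    drifted_sample_loglik,
    posterior_mode_hpd,
    run_admixture_mcmc,
)
from neodemic.io import HaplogroupCounts

from _oracles import (
    drifted_count_prob_enumeration,
    lineage_pmf_expm,
    lineage_pmf_wright_fisher,
)


class TestDriftLineagePmf:
    def test_no_time_no_coalescence(self):
        p = drift_lineage_pmf(5, 0.0)
        np.testing.assert_array_equal(p, [0, 0, 0, 0, 1])

    def test_pair_closed_form(self):
        p = drift_lineage_pmf(2, 0.5)
        assert p[0] == pytest.approx(1 - math.exp(-0.5), abs=1e-12)
        assert p[1] == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_long_time_single_founder(self):
        assert drift_lineage_pmf(4, 10.0)[0] > 0.999

    @pytest.mark.parametrize("n,t", [(3, 0.1), (5, 0.5), (8, 1.0), (20, 0.05)])
    def test_matches_matrix_exponential(self, n, t):
        np.testing.assert_allclose(drift_lineage_pmf(n, t),
                                   lineage_pmf_expm(n, t), atol=1e-10)

    @pytest.mark.parametrize("T", [10, 100])
    def test_matches_forward_wright_fisher(self, T):
        """Oracle: agreement with a haploid WF ancestry simulation."""
        N, n, reps = 200, 5, 100_000
        wf, se = lineage_pmf_wright_fisher(n, N, T, reps, seed=T)
        p = drift_lineage_pmf(n, T / N)
        # WF and coalescent differ O(1/N); allow 3 SE plus that bias scale
        np.testing.assert_array_less(np.abs(p - wf), 3 * se + 3.0 / N)

    def test_series_and_matrix_paths_agree(self):
        p_s = _pmf_series(12, 0.4)
        assert p_s is not None
        np.testing.assert_allclose(p_s, _pmf_matrix(12, 0.4), atol=1e-9)

    def test_stable_at_large_n(self):
        # the alternating series is hopeless here; the matrix route is not
        p = drift_lineage_pmf(1000, 0.02)
        assert np.all(p >= 0) and p.sum() == pytest.approx(1.0, abs=1e-9)
        assert 80 < np.argmax(p) + 1 < 110  # mass far from both ends

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            drift_lineage_pmf(0, 1.0)
        with pytest.raises(ValueError):
            drift_lineage_pmf(3, -0.1)

    def test_interpolating_cache_matches_exact(self):
        cache = LineagePmfCache(40)
        for t in (0.0123, 0.17, 1.9):
            exact = np.log(drift_lineage_pmf(40, t))
            approx = cache.logpmf(t)
            keep = exact > -25
            np.testing.assert_allclose(approx[keep], exact[keep],
                                       rtol=0, atol=5e-3)


class TestDriftedSampleLoglik:
    def test_zero_drift_is_multinomial(self):
        c = np.array([4, 2, 1])
        x = np.array([0.5, 0.3, 0.2])
        assert drifted_sample_loglik(c, x, 0.0) == pytest.approx(
            multinomial.logpmf(c, 7, x), abs=1e-10)

    def test_single_lineage_any_drift(self):
        x = np.array([0.25, 0.75])
        for t in (0.0, 0.3, 5.0):
            assert drifted_sample_loglik(np.array([0, 1]), x, t) == pytest.approx(
                math.log(0.75), abs=1e-12)

    def test_pair_same_type_two_term_sum(self):
        x = np.array([0.3, 0.7])
        for t in (0.2, 1.0, 8.0):
            expected = math.exp(-t) * 0.3**2 + (1 - math.exp(-t)) * 0.3
            assert drifted_sample_loglik(np.array([2, 0]), x, t) == pytest.approx(
                math.log(expected), abs=1e-10)
        # t -> infinity limit: single founder, log x_k
        assert drifted_sample_loglik(np.array([2, 0]), x, 50.0) == pytest.approx(
            math.log(0.3), abs=1e-4)

    @pytest.mark.parametrize("c", [[2, 1], [3, 1], [2, 2], [1, 1, 2], [0, 4]])
    @pytest.mark.parametrize("t", [0.05, 0.6, 3.0])
    def test_matches_brute_force_enumeration(self, c, t):
        """Oracle: exact agreement with exhaustive founder enumeration."""
        c = np.array(c)
        x = np.array([0.5, 0.3, 0.2])[: len(c)]
        x = x / x.sum()
        expected = drifted_count_prob_enumeration(c, x, t)
        assert drifted_sample_loglik(c, x, t) == pytest.approx(
            math.log(expected), abs=1e-9)

    def test_total_probability_sums_to_one(self):
        # all count vectors of n=3 over K=2 must sum to 1
        x = np.array([0.4, 0.6])
        total = sum(
            math.exp(drifted_sample_loglik(np.array([k, 3 - k]), x, 0.7))
            * 1.0
            for k in range(4)
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_unsupported_type_without_drift_impossible(self):
        x = np.array([1.0, 0.0])
        assert drifted_sample_loglik(np.array([1, 1]), x, 0.0) == -np.inf


def _synthetic_admixture(p1, t, seed, n=200, K=10):
    from neodemic.synth import simulate_admixture_counts

    table, truth = simulate_admixture_counts(p1, t, t, t, (n, n, n), K, seed)
    return table, truth


class TestAdmixtureMcmc:
    def test_identical_parents_leave_p1_uninformed(self):
        """With P1 = P2 frequency profiles the likelihood carries no
        information about p1, so its posterior stays ~ Uniform(0,1)."""
        rng = np.random.default_rng(3)
        c = rng.multinomial(300, [0.4, 0.3, 0.2, 0.1])
        data = HaplogroupCounts(["P1", "P2", "H"], list("abcd"),
                                np.vstack([c, c, c]))
        post = run_admixture_mcmc(data, seed=5, n_iter=6000, burn_in=1500, thin=3)
        assert abs(post["p1"].mean() - 0.5) < 0.05

    def test_h_identical_to_p2_pushes_p1_to_zero(self):
        """H sharing P2's profile, both far from P1, forces p1 towards 0."""
        c1 = np.array([240, 240, 10, 10])
        c2 = np.array([10, 10, 240, 240])
        data = HaplogroupCounts(["P1", "P2", "H"], list("abcd"),
                                np.vstack([c1, c2, c2]))
        post = run_admixture_mcmc(data, seed=2, n_iter=6000, burn_in=2000, thin=3)
        _, (lo, hi) = posterior_mode_hpd(post["p1"], level=0.9)
        assert hi < 0.3

    def test_parameter_recovery_at_high_p1(self):
        """Posterior modes track a strong Palaeolithic contribution; a
        single-locus mode is noisy, so check a small ensemble."""
        errors = []
        for seed in (100, 101, 102):
            table, truth = _synthetic_admixture(0.8, 0.05, seed=seed)
            post = run_admixture_mcmc(table, seed=seed, n_iter=6000,
                                      burn_in=2000, thin=3)
            mode, _ = posterior_mode_hpd(post["p1"])
            errors.append(abs(mode - truth["p1"]))
        assert np.median(errors) < 0.15
        assert sum(e < 0.15 for e in errors) >= 2

    def test_prior_only_chain_recovers_priors(self):
        """With the likelihood switched off the sampler must reproduce
        p1 ~ U(0,1) and log t ~ U(log bounds)."""
        data = HaplogroupCounts(["P1", "P2", "H"], list("ab"),
                                np.array([[5, 5], [5, 5], [5, 5]]))
        post = run_admixture_mcmc(data, seed=9, n_iter=40000, burn_in=2000,
                                  thin=4, likelihood_on=False)
        ks_p1 = kstest(post["p1"], "uniform").statistic
        logt = np.log(post["t1"])
        lo, hi = np.log(1e-3), np.log(10.0)
        ks_t = kstest((logt - lo) / (hi - lo), "uniform").statistic
        assert ks_p1 < 0.05 and ks_t < 0.05

    def test_posterior_invariant_under_column_relabeling(self, rng):
        """The likelihood is exactly invariant under jointly permuting
        count and frequency columns; with the (symmetric) flat Dirichlet
        prior this makes the p1 posterior invariant under relabeling."""
        for _ in range(10):
            K = int(rng.integers(2, 7))
            c = rng.multinomial(30, np.full(K, 1.0 / K))
            x = rng.dirichlet(np.ones(K))
            t = float(rng.uniform(0.01, 2.0))
            perm = rng.permutation(K)
            assert drifted_sample_loglik(c[perm], x[perm], t) == pytest.approx(
                drifted_sample_loglik(c, x, t), abs=1e-9)

    def test_k1_unidentifiable(self):
        data = HaplogroupCounts(["P1", "P2", "H"], ["only"],
                                np.array([[5], [5], [5]]))
        with pytest.raises(ValueError):
            run_admixture_mcmc(data, seed=0, n_iter=10, burn_in=0)


class TestPosteriorModeHpd:
    def test_degenerate_point_mass(self):
        mode, (lo, hi) = posterior_mode_hpd(np.full(500, 0.42))
        assert mode == lo == hi == 0.42

    def test_uniform_hpd_length(self, rng):
        draws = rng.uniform(size=100_000)
        _, (lo, hi) = posterior_mode_hpd(draws, level=0.9)
        assert hi - lo == pytest.approx(0.9, abs=0.02)

    def test_beta_boundary_mode(self, rng):
        draws = rng.beta(9, 1, size=50_000)
        mode, _ = posterior_mode_hpd(draws)
        assert mode > 0.95  # analytic mode at the upper boundary

    def test_empty_draws_error(self):
        with pytest.raises(ValueError):
            posterior_mode_hpd(np.array([]))
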