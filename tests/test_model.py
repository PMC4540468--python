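"""Exact-inference machinery: parameter translation, enumeration, posterior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit
from scipy.stats import norm, poisson

import sheetsampler as ss
from sheetsampler.model import EnumerationCapError

from conftest import make_random_model


class TestTranslateLikelihood:
    def test_bernoulli_frozen_values(self):
        V, V0, A, _ = ss.translate_likelihood(
            "bernoulli", np.array([[0.6]]), np.array([0.1]))
        assert V0[0] == pytest.approx(-2.1972246, abs=1e-6)
        assert V[0, 0] == pytest.approx(2.6026897, abs=1e-6)
        # A_ki = log[(1-pi0)/(1-pi)]
        assert A[0, 0] == pytest.approx(np.log(0.9 / 0.4), abs=1e-12)

    @pytest.mark.parametrize("family,val", [("bernoulli", 0.3),
                                            ("poisson", 2.5)])
    def test_edge_equal_to_default_is_null(self, family, val):
        V, _, A, _ = ss.translate_likelihood(
            family, np.array([[val]]), np.array([val]))
        assert V[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert A[0, 0] == pytest.approx(0.0, abs=1e-12)

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_bernoulli_round_trip(self, pi, pi0):
        V, V0, _, _ = ss.translate_likelihood(
            "bernoulli", np.array([[pi]]), np.array([pi0]))
        assert expit(V[0, 0] + V0[0]) == pytest.approx(pi, abs=1e-12)

    def test_poisson_matches_pmf_log_ratio(self):
        lam, lam0, y = 3.0, 1.2, 4
        V, V0, A, A0 = ss.translate_likelihood(
            "poisson", np.array([[lam]]), np.array([lam0]))
        got = V[0, 0] * y - A[0, 0]
        want = poisson.logpmf(y, lam) - poisson.logpmf(y, lam0)
        assert got == pytest.approx(want, abs=1e-10)

    def test_gaussian_matches_pdf_log_ratio(self):
        mu, mu0, s2, y = 1.5, -0.5, 0.7, 0.9
        V, V0, A, A0 = ss.translate_likelihood(
            "gaussian", np.array([[mu]]), np.array([mu0]), sigma2=s2)
        got = V[0, 0] * y - A[0, 0]
        want = (norm.logpdf(y, mu, np.sqrt(s2)) -
                norm.logpdf(y, mu0, np.sqrt(s2)))
        assert got == pytest.approx(want, abs=1e-10)

    def test_out_of_domain_parameter_names_offender(self):
        bad = np.array([[0.5, 1.5]])
        with pytest.raises(ValueError, match=r"k=0, i=1"):
            ss.translate_likelihood("bernoulli", bad, np.array([0.2, 0.2]))


class TestNetworkFromModel:
    def test_null_model_gives_zero_parameters(self):
        K, N = 3, 4
        model = ss.GenerativeModel(
            "bernoulli", np.full((K, N), 0.2), np.full(N, 0.2),
            np.zeros((K, K)), np.zeros((K, K)), np.zeros(K))
        p = ss.network_from_model(model)
        assert np.allclose(p.V, 0) and np.allclose(p.b, 0)

    def test_excitability_shift_by_normalizer(self):
        model = ss.GenerativeModel(
            "bernoulli", np.array([[0.6]]), np.array([0.1]),
            np.zeros((1, 1)), np.zeros((1, 1)), np.array([-1.0]))
        p = ss.network_from_model(model)
        assert p.b[0] == pytest.approx(-1.0 - 0.8109302, abs=1e-6)

    def test_asymmetric_coupling_rejected(self):
        W = np.zeros((2, 2))
        W[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            ss.GenerativeModel("bernoulli", np.full((2, 2), 0.3),
                               np.full(2, 0.3), W, np.zeros((2, 2)),
                               np.zeros(2))


class TestValidStates:
    def test_free_network_counts_all_states(self):
        assert ss.valid_states(np.zeros((3, 3), bool)).shape == (8, 3)

    def test_ring_of_columns_count(self):
        topo = ss.build_grid_sheet((6, 21), (3, 7), (6, 6), (0, 3))
        assert ss.valid_states(topo.inh_mask).shape[0] == 337

    def test_disjoint_population_count(self):
        topo = ss.build_population_topology(7, 3)
        assert ss.valid_states(topo.inh_mask).shape[0] == 4 ** 7

    def test_enumeration_cap(self):
        with pytest.raises(EnumerationCapError):
            ss.valid_states(np.zeros((25, 25), bool))

    @given(st.integers(0, 2 ** 20))
    @settings(deadline=None, max_examples=20)
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        K = 6
        mask = np.triu(rng.random((K, K)) < 0.4, k=1)
        mask = mask | mask.T
        states = ss.valid_states(mask)
        brute = [s for s in ss.enumerate_states(K)
                 if not np.any(np.outer(s, s) & mask)]
        assert np.array_equal(states, np.array(brute).reshape(-1, K))


class TestPriorAndPosterior:
    def test_flat_prior_is_uniform(self):
        model = ss.GenerativeModel("bernoulli", np.full((3, 1), 0.2),
                                   np.array([0.2]), np.zeros((3, 3)),
                                   np.zeros((3, 3)), np.zeros(3))
        table = ss.prior_table(model)
        assert np.allclose(table.probs, 1 / 8)

    def test_strong_inhibition_suppresses_coactivation(self):
        Winh = np.array([[0.0, -100.0], [-100.0, 0.0]])
        model = ss.GenerativeModel("bernoulli", np.full((2, 1), 0.2),
                                   np.array([0.2]), np.zeros((2, 2)), Winh,
                                   np.zeros(2))
        table = ss.prior_table(model)
        assert table.prob_of([1, 1]) < 1e-40

    def test_prior_matches_direct_summation(self, rng):
        model = make_random_model(rng, K=3, N=2)
        table = ss.prior_table(model)
        direct = np.array([np.exp(ss.prior_log_prob(s, model))
                           for s in table.states])
        assert np.allclose(table.probs, direct / direct.sum(), atol=1e-12)
        assert table.probs.sum() == pytest.approx(1.0, abs=1e-12)
        # marginals consistent with the state table
        assert np.allclose(table.marginals, table.probs @ table.states)

    def test_likelihood_log_prob_examples(self):
        model = ss.GenerativeModel("bernoulli", np.array([[0.6]]),
                                   np.array([0.1]), np.zeros((1, 1)),
                                   np.zeros((1, 1)), np.zeros(1))
        assert ss.likelihood_log_prob([1], [0], model) == 0.0
        got = ss.likelihood_log_prob([1], [1], model)
        assert got == pytest.approx(np.log(0.6 / 0.1), abs=1e-10)

    def test_full_bernoulli_pmf_normalizes(self, rng):
        model = make_random_model(rng, K=2, N=5, wta_pairs=(), exc_pairs=())
        V, V0, A_ki, A0 = ss.translate_likelihood(
            "bernoulli", model.params, model.defaults)
        A = A_ki.sum(axis=1)
        z = np.array([1, 0])
        total = 0.0
        for code in range(2 ** 5):
            y = np.array([(code >> i) & 1 for i in range(5)])
            logp = (z @ V @ y - z @ A) + (V0 @ y - A0.sum())
            total += np.exp(logp)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_no_input_posterior_equals_prior(self, rng):
        model = make_random_model(rng, K=3, N=0, wta_pairs=(), exc_pairs=())
        post = ss.exact_posterior(np.zeros(0), model)
        prior = ss.prior_table(model)
        assert np.allclose(post.probs, prior.probs, atol=1e-12)

    def test_symmetric_neurons_have_equal_marginals(self):
        pi = np.array([[0.6, 0.3], [0.6, 0.3]])
        model = ss.GenerativeModel(
            "bernoulli", pi, np.array([0.2, 0.2]), np.zeros((2, 2)),
            np.array([[0.0, -100.0], [-100.0, 0.0]]), np.zeros(2))
        post = ss.exact_posterior([1, 0], model)
        assert post.marginals[0] == pytest.approx(post.marginals[1], abs=1e-12)

    def test_posterior_matches_gibbs_oracle(self, rng):
        """Single-site Gibbs sampling converges to the enumerated posterior."""
        model = make_random_model(rng, K=3, N=4)
        params = ss.network_from_model(model)
        y = rng.integers(0, 2, 4)
        post = ss.exact_posterior(y, model)
        # independent Gibbs oracle on the conditional activation odds
        import math
        drive = (params.V @ y + params.b).tolist()
        W = params.W.tolist()
        z = [0, 0, 0]
        counts = {}
        u = np.random.default_rng(7).random((1_000_000, 3)).tolist()
        for row in u:
            for k in range(3):
                h = drive[k]
                for j in range(3):
                    if z[j]:
                        h += W[k][j]
                z[k] = 1 if row[k] < 1.0 / (1.0 + math.exp(-h)) else 0
            key = (z[0], z[1], z[2])
            counts[key] = counts.get(key, 0) + 1
        total = sum(counts.values())
        tv = 0.5 * sum(abs(counts.get(tuple(s), 0) / total - p)
                       for s, p in zip(post.states, post.probs))
        assert tv < 0.01


class TestConditionalLogOdds:
    def test_single_neuron_closed_form(self, rng):
        model = make_random_model(rng, K=1, N=3, wta_pairs=(), exc_pairs=())
        params = ss.network_from_model(model)
        y = np.array([1, 0, 1])
        got = ss.conditional_log_odds(0, [], y, params)
        assert got == pytest.approx(params.b[0] + params.V[0] @ y, abs=1e-12)

    def test_unconnected_neighbor_is_irrelevant(self, rng):
        model = make_random_model(rng, K=3, N=2, wta_pairs=((0, 1),),
                                  exc_pairs=())
        params = ss.network_from_model(model)
        y = np.array([1, 1])
        a = ss.conditional_log_odds(0, [0, 0], y, params)
        b = ss.conditional_log_odds(0, [0, 1], y, params)  # flip neuron 2
        assert a == pytest.approx(b, abs=1e-12)


class TestCalibration:
    def test_independent_closed_forms(self):
        Z = np.zeros((3, 3))
        bhat = ss.calibrate_prior_biases(Z, Z, [0.5, 0.5, 0.5])
        assert np.allclose(bhat, 0.0, atol=1e-5)
        bhat = ss.calibrate_prior_biases(Z, Z, [0.1, 0.1, 0.1])
        assert np.allclose(bhat, logit(0.1), atol=1e-4)

    def test_wta_round_trip(self):
        Winh = np.array([[0.0, -100.0], [-100.0, 0.0]])
        m = np.array([0.3, 0.3])
        bhat = ss.calibrate_prior_biases(np.zeros((2, 2)), Winh, m)
        model = ss.GenerativeModel("bernoulli", np.full((2, 1), 0.2),
                                   np.array([0.2]), np.zeros((2, 2)), Winh,
                                   bhat)
        assert np.allclose(ss.prior_table(model).marginals, m, atol=1e-6)

    def test_infeasible_targets_raise(self):
        with pytest.raises(ValueError):
            ss.calibrate_prior_biases(np.zeros((2, 2)), np.zeros((2, 2)),
                                      [0.0, 0.5])


class TestLogLikelihood:
    def test_prior_free_model_sums_channel_logpmf(self):
        model = ss.GenerativeModel("bernoulli", np.zeros((0, 2)),
                                   np.array([0.3, 0.6]), np.zeros((0, 0)),
                                   np.zeros((0, 0)), np.zeros(0))
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        got = ss.log_likelihood(Y, model)
        want = np.mean([np.log(0.3) + np.log(0.4), np.log(0.7) + np.log(0.6)])
        assert got == pytest.approx(want, abs=1e-12)

    def test_single_sample_matches_two_term_mixture(self):
        model = ss.GenerativeModel("bernoulli", np.array([[0.6]]),
                                   np.array([0.1]), np.zeros((1, 1)),
                                   np.zeros((1, 1)), np.array([0.4]))
        got = ss.log_likelihood(np.array([[1.0]]), model, bhat=model.bhat)
        p1 = expit(0.4)
        want = np.log((1 - p1) * 0.1 + p1 * 0.6)
        assert got == pytest.approx(want, abs=1e-10)

    def test_true_parameters_beat_perturbed(self, rng):
        """Gibbs inequality: the generating model maximizes the likelihood."""
        model = make_random_model(rng, K=2, N=4, wta_pairs=((0, 1),),
                                  exc_pairs=())
        # sample y from the model: z ~ prior, y ~ p(y|z)
        prior = ss.prior_table(model)
        S = 10_000
        zi = rng.choice(len(prior.states), size=S, p=prior.probs)
        Z = prior.states[zi].astype(float)
        P = np.tile(model.defaults, (S, 1))
        for s in range(S):
            for k in range(2):
                if Z[s, k]:
                    P[s] = model.params[k]
        Y = (rng.random((S, 4)) < P).astype(float)
        ll_true = ss.log_likelihood(Y, model, bhat=model.bhat)
        pert = ss.GenerativeModel(
            "bernoulli", np.clip(model.params + 0.15, 0.01, 0.99),
            model.defaults, model.Wexc_hat, model.Winh_hat, model.bhat)
        ll_pert = ss.log_likelihood(Y, pert, bhat=pert.bhat)
        assert ll_true > ll_pert

    def test_empty_samples_rejected(self, small_model):
        with pytest.raises(ValueError):
            ss.log_likelihood(np.zeros((0, 6)), small_model)


class TestReconstruction:
    def test_window_cases(self, rng):
        model = make_random_model(rng, K=2, N=3, wta_pairs=(), exc_pairs=())
        params = ss.network_from_model(model)
        pi0 = model.defaults
        z_off = np.zeros((10, 2))
        assert np.allclose(ss.reconstruct_input(z_off, params), pi0,
                           atol=1e-12)
        z_on = np.zeros((10, 2))
        z_on[:, 0] = 1
        assert np.allclose(ss.reconstruct_input(z_on, params),
                           model.params[0], atol=1e-12)
        z_half = np.zeros((10, 2))
        z_half[5:, 0] = 1
        assert np.allclose(ss.reconstruct_input(z_half, params),
                           (pi0 + model.params[0]) / 2, atol=1e-12)

    def test_empty_window_rejected(self, rng):
        model = make_random_model(rng, K=2, N=3)
        params = ss.network_from_model(model)
        with pytest.raises(ValueError):
            ss.reconstruct_input(np.zeros((0, 2)), params)
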