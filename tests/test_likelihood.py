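"""The marginalized zero-inflated N-mixture likelihood and its priors."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import beta as beta_dist
from scipy.stats import halfnorm, norm

import commnmix as cx
from commnmix.design import ABUNDANCE_COVS, DETECTION_COVS
from commnmix.likelihood import (choose_truncation, predictors,
                                 site_year_marginal_loglik)
from _oracles import (allzero_closed_form, enum_loglik,
                      plain_nmixture_loglik, random_small_instance)


class TestLinearPredictors:
    def test_abundance_identity_and_spots(self):
        assert cx.linear_abundance(0.0, [0.0], [0.0]) == 1.0
        assert np.isclose(cx.linear_abundance(np.log(2), [0.0], [0.0]), 2.0)
        # one-sd basal shift at the community-scale coefficient -0.23
        assert np.isclose(cx.linear_abundance(0.0, [-0.23], [1.0]),
                          np.exp(-0.23))

    def test_abundance_nonfinite_rejected(self):
        with pytest.raises(FloatingPointError):
            cx.linear_abundance(np.inf, [0.0], [1.0])

    def test_detection_identity_and_spots(self):
        assert cx.linear_detection(0.0, [0.0], [0.0]) == 0.5
        # reported community detection intercept -1.71 -> P_d ~ 0.15
        val = cx.linear_detection(-1.71, [0.0], [0.0])
        assert np.isclose(val, expit(-1.71))
        assert 0.14 < val < 0.16

    def test_detection_boundary_limit(self):
        assert cx.linear_detection(-800.0, [0.0], [0.0]) == 0.0


class TestCellLikelihood:
    def test_allzero_spot_value(self):
        got = site_year_marginal_loglik([0, 0, 0], 0.5, 1.0, 0.5)
        want = np.log(0.5 + 0.5 * np.exp(-0.875))
        assert abs(got - want) < 1e-10

    def test_structural_zero(self):
        assert site_year_marginal_loglik([0, 0, 0], 0.0, 2.0, 0.5) == 0.0
        assert site_year_marginal_loglik([1, 0, 0], 0.0, 2.0, 0.5) == -np.inf

    def test_allzero_closed_form_randomized(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            V = rng.integers(1, 5)
            psi = rng.uniform(0, 1)
            lam = rng.uniform(0.05, 8.0)
            phi = rng.uniform(0.01, 0.99, V)
            got = site_year_marginal_loglik(np.zeros(V, int), psi, lam, phi)
            assert abs(got - np.log(allzero_closed_form(psi, lam, phi))) < 1e-10

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            y, psi, lam, phi = random_small_instance(rng)
            K = choose_truncation(int(y.max()), lam, 1e-12, 400)
            got = site_year_marginal_loglik(y, psi, lam, phi, K=K)
            assert abs(got - enum_loglik(y, psi, lam, phi, K)) < 1e-10

    def test_psi_one_reduces_to_plain_nmixture(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            y, _, lam, phi = random_small_instance(rng)
            K = choose_truncation(int(y.max()), lam, 1e-12, 400)
            got = site_year_marginal_loglik(y, 1.0, lam, phi, K=K)
            assert abs(got - plain_nmixture_loglik(y, lam, phi, K)) < 1e-10

    def test_truncation_stability(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            y, psi, lam, phi = random_small_instance(rng)
            a = site_year_marginal_loglik(y, psi, lam, phi)  # adaptive rule
            b = site_year_marginal_loglik(y, psi, lam, phi, K=350, k_cap=400)
            assert abs(a - b) < 1e-8

    def test_visit_order_invariance(self):
        rng = np.random.default_rng(14)
        y = np.array([2, 0, 1])
        phi = np.array([0.3, 0.6, 0.1])
        base = site_year_marginal_loglik(y, 0.7, 2.0, phi)
        for _ in range(5):
            perm = rng.permutation(3)
            assert np.isclose(site_year_marginal_loglik(y[perm], 0.7, 2.0,
                                                        phi[perm]), base)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="truncation"):
            site_year_marginal_loglik([5, 0], 0.5, 1.0, 0.5, K=3)
        with pytest.raises(ValueError, match="negative"):
            site_year_marginal_loglik([-1, 0], 0.5, 1.0, 0.5)
        with pytest.raises(ValueError):
            site_year_marginal_loglik([0, 0], 1.5, 1.0, 0.5)


class TestVectorizedLikelihood:
    def test_matches_scalar_reference(self, tiny_dataset):
        data, params = tiny_dataset["data"], tiny_dataset["params"]
        lam, phi = predictors(data, params)
        lik = cx.MarginalLikelihood(data)
        cell = lik.cell_loglik(lam, phi, params.psi)
        for s in range(data.n_species):
            for c in range(data.n_cells):
                ref = site_year_marginal_loglik(data.y[s, c], params.psi[s],
                                                lam[s, c], phi[s, c])
                assert abs(cell[s, c] - ref) < 1e-7

    def test_total_additivity_single_cell(self, tiny_dataset):
        data, params = tiny_dataset["data"], tiny_dataset["params"]
        total = cx.total_loglik(data, params)
        lam, phi = predictors(data, params)
        lik = cx.MarginalLikelihood(data)
        assert np.isclose(total,
                          lik.cell_loglik(lam, phi, params.psi).sum())

    def test_empty_data_gives_zero(self):
        data = cx.ModelData(
            species=("A",), y=np.zeros((1, 0, 3), int),
            x=np.zeros((0, len(ABUNDANCE_COVS))),
            v=np.zeros((0, 3, len(DETECTION_COVS))),
            site_idx=np.zeros(0, int), site_ids=(),
            point_of_cell=np.array([]), year_of_cell=np.array([], int))
        params = cx.SpeciesParams(
            species=("A",), abundance_covs=ABUNDANCE_COVS,
            detection_covs=DETECTION_COVS, beta0=[0.5],
            beta=np.zeros((1, len(ABUNDANCE_COVS))), alpha0=[-1.0],
            alpha=np.zeros((1, len(DETECTION_COVS))), psi=[0.5],
            gamma=np.zeros(0))
        assert cx.total_loglik(data, params) == 0.0

    def test_true_params_beat_perturbed(self, tiny_design):
        """Likelihood consistency: the generating parameters outscore a
        heavily perturbed alternative in nearly all replicate datasets."""
        hyper = cx.default_hyperparams()
        wins = 0
        for rep in range(100):
            cov = cx.generate_covariates(tiny_design, rng_seed=100 + rep)
            params = cx.draw_species_params(hyper, tiny_design,
                                            rng_seed=200 + rep)
            ct = cx.simulate_counts(params, cov, tiny_design,
                                    rng_seed=300 + rep)
            data = cx.ModelData.from_tables(ct, cov)
            shifted = cx.SpeciesParams(
                species=params.species, abundance_covs=params.abundance_covs,
                detection_covs=params.detection_covs,
                beta0=params.beta0 + 2.0, beta=params.beta,
                alpha0=params.alpha0, alpha=params.alpha, psi=params.psi,
                gamma=params.gamma)
            if cx.total_loglik(data, params) > cx.total_loglik(data, shifted):
                wins += 1
        assert wins >= 95


class TestLogPrior:
    def _params_at(self, hyper, S=3):
        mu = np.r_[hyper.mu_beta0,
                   [hyper.mu_beta_cov[c] for c in ABUNDANCE_COVS],
                   hyper.mu_alpha0,
                   [hyper.mu_alpha_cov[c] for c in DETECTION_COVS]]
        P, Q = len(ABUNDANCE_COVS), len(DETECTION_COVS)
        return cx.SpeciesParams(
            species=tuple(f"s{i}" for i in range(S)),
            abundance_covs=ABUNDANCE_COVS, detection_covs=DETECTION_COVS,
            beta0=np.full(S, mu[0]), beta=np.tile(mu[1:1 + P], (S, 1)),
            alpha0=np.full(S, mu[1 + P]), alpha=np.tile(mu[2 + P:], (S, 1)),
            psi=np.full(S, 0.5), gamma=np.zeros(2))

    def test_closed_form_at_hyper_means(self):
        hyper = cx.default_hyperparams()
        spec = cx.ModelSpec()
        params = self._params_at(hyper)
        got = cx.log_prior(params, hyper, spec)
        mu = np.r_[hyper.mu_beta0,
                   [hyper.mu_beta_cov[c] for c in ABUNDANCE_COVS],
                   hyper.mu_alpha0,
                   [hyper.mu_alpha_cov[c] for c in DETECTION_COVS]]
        sd = np.r_[hyper.sigma_beta0,
                   [hyper.sigma_beta_cov[c] for c in ABUNDANCE_COVS],
                   hyper.sigma_alpha0,
                   [hyper.sigma_alpha_cov[c] for c in DETECTION_COVS]]
        want = (norm.logpdf(mu, 0, np.sqrt(1000)).sum()
                + halfnorm.logpdf(sd, scale=2.0).sum()
                + halfnorm.logpdf(hyper.sigma_site, scale=2.0)
                + 3 * norm.logpdf(mu, mu, sd).sum()
                + 3 * beta_dist.logpdf(0.5, 1, 1)
                + norm.logpdf(np.zeros(2), 0, hyper.sigma_site).sum())
        assert np.isclose(got, want)

    def test_nonpositive_scale_gives_neg_inf(self):
        from types import SimpleNamespace
        hyper = cx.default_hyperparams()
        bad = SimpleNamespace(**{
            "mu_beta0": 0.0, "sigma_beta0": -0.1,
            "mu_beta_cov": hyper.mu_beta_cov,
            "sigma_beta_cov": hyper.sigma_beta_cov,
            "mu_alpha0": 0.0, "sigma_alpha0": 1.0,
            "mu_alpha_cov": hyper.mu_alpha_cov,
            "sigma_alpha_cov": hyper.sigma_alpha_cov,
            "sigma_site": 1.0})
        assert cx.log_prior(self._params_at(hyper), bad) == -np.inf

    def test_species_term_additivity(self):
        hyper = cx.default_hyperparams()
        lp1 = cx.log_prior(self._params_at(hyper, S=1), hyper)
        lp2 = cx.log_prior(self._params_at(hyper, S=2), hyper)
        lp3 = cx.log_prior(self._params_at(hyper, S=3), hyper)
        # identical per-species values: each extra species adds the same term
        assert np.isclose(lp2 - lp1, lp3 - lp2)
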