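"""Synthetic point-count generator: regimes, hierarchy, and the observation
process."""

import numpy as np
import pandas as pd
import pytest

import commnmix as cx
from commnmix.design import ABUNDANCE_COVS, DETECTION_COVS, TruncNormSpec


def _degenerate_regime(mean_map):
    specs = {c: TruncNormSpec(m, 0.0, 0.0, 100.0) for c, m in mean_map.items()}
    specs["basal"] = TruncNormSpec(mean_map["basal"], 0.0, 0.0, 100.0)
    return cx.CovariateRegime(control=specs, treatment=specs)


class TestSurveyDesign:
    def test_paper_layout(self):
        d = cx.SurveyDesign()
        assert d.n_points == 150 and d.n_sites == 18
        assert d.n_surveys == 1800
        # balanced treatment split over near-equal site sizes
        assert d.treatment_of_point.sum() == 75
        assert sorted(d.site_sizes, reverse=True) == [9] * 6 + [8] * 12

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            cx.SurveyDesign(n_years=0)
        with pytest.raises(ValueError):
            cx.SurveyDesign(species=("XX",))  # not in suite map

    def test_points_per_site_constructor(self):
        d = cx.SurveyDesign.from_points_per_site(6, 5, n_years=2)
        assert d.n_points == 30 and d.n_surveys == 30 * 2 * 3


class TestGenerateCovariates:
    def test_degenerate_sd_gives_group_mean(self):
        design = cx.SurveyDesign(n_sites=4, n_points=20, n_years=1)
        means = {"grass": 10.0, "woody": 40.0, "vor2": 50.0, "basal": 20.0}
        cov = cx.generate_covariates(design, _degenerate_regime(means),
                                     rng_seed=0)
        for c, m in means.items():
            assert np.allclose(cov.points[c], m)

    def test_seed_determinism(self):
        design = cx.SurveyDesign(n_years=2)
        a = cx.generate_covariates(design, rng_seed=5, include_redundant=True)
        b = cx.generate_covariates(design, rng_seed=5, include_redundant=True)
        pd.testing.assert_frame_equal(a.points, b.points)
        pd.testing.assert_frame_equal(a.visits, b.visits)

    def test_infeasible_regime_names_covariate(self):
        bad = {c: TruncNormSpec(5, 1, 0, 100) for c in ("grass", "woody", "vor2")}
        bad["basal"] = TruncNormSpec(50.0, 1.0, 0.0, 30.0)  # mean above upper
        with pytest.raises(ValueError, match="basal"):
            cx.CovariateRegime(control=bad, treatment=bad)

    def test_control_basal_matches_regime_mean(self):
        # 75 control points x 4 years = 300 draws; sample mean within 3 SE
        cov = cx.generate_covariates(cx.SurveyDesign(), rng_seed=42)
        ctl = cov.points.loc[cov.points["treatment"] == 0, "basal"]
        assert len(ctl) == 300
        se = 9.83 / np.sqrt(len(ctl))
        assert abs(ctl.mean() - 28.89) < 3 * se

    def test_bounds_respected(self):
        cov = cx.generate_covariates(cx.SurveyDesign(), rng_seed=3,
                                     include_redundant=True)
        for c in ("grass", "woody", "vor2"):
            assert cov.points[c].between(0, 100).all()
        assert (cov.points["basal"] >= 0).all()
        assert cov.visits["date"].between(0, 86).all()
        assert cov.visits["wind"].between(0, 15).all()
        assert cov.visits["disturbance"].isin(range(5)).all()


class TestDrawSpeciesParams:
    def test_point_mass_hyperpriors(self, desk_design):
        h = cx.CommunityHyperparams(
            mu_beta0=1.0, sigma_beta0=0.0,
            mu_beta_cov={c: 0.5 for c in ABUNDANCE_COVS},
            sigma_beta_cov={c: 0.0 for c in ABUNDANCE_COVS},
            mu_alpha0=-1.0, sigma_alpha0=0.0,
            mu_alpha_cov={c: -0.2 for c in DETECTION_COVS},
            sigma_alpha_cov={c: 0.0 for c in DETECTION_COVS},
            psi=0.3, sigma_site=0.0)
        p = cx.draw_species_params(h, desk_design, rng_seed=1)
        assert np.allclose(p.beta0, 1.0) and np.allclose(p.beta, 0.5)
        assert np.allclose(p.alpha0, -1.0) and np.allclose(p.alpha, -0.2)
        assert np.allclose(p.gamma, 0.0) and np.allclose(p.psi, 0.3)

    def test_hyperdistribution_moments(self):
        # 10,000 species draws reproduce Normal(1, 0.5) within MC error
        design = cx.SurveyDesign(
            n_sites=2, n_points=2, n_years=1,
            species=tuple(f"s{i}" for i in range(10_000)),
            suite_map={f"s{i}": "Grassland" for i in range(10_000)})
        h = cx.default_hyperparams()
        h = cx.CommunityHyperparams(**{**_hyper_dict(h), "mu_beta0": 1.0,
                                       "sigma_beta0": 0.5})
        p = cx.draw_species_params(h, design, rng_seed=9)
        assert abs(p.beta0.mean() - 1.0) < 4 * 0.5 / 100
        assert abs(p.beta0.std(ddof=1) - 0.5) < 0.02


def _hyper_dict(h):
    return {"mu_beta0": h.mu_beta0, "sigma_beta0": h.sigma_beta0,
            "mu_beta_cov": h.mu_beta_cov, "sigma_beta_cov": h.sigma_beta_cov,
            "mu_alpha0": h.mu_alpha0, "sigma_alpha0": h.sigma_alpha0,
            "mu_alpha_cov": h.mu_alpha_cov,
            "sigma_alpha_cov": h.sigma_alpha_cov,
            "psi": h.psi, "sigma_site": h.sigma_site}


def _constant_params(design, beta0, alpha0, psi):
    S = design.n_species
    return cx.SpeciesParams(
        species=design.species, abundance_covs=ABUNDANCE_COVS,
        detection_covs=DETECTION_COVS,
        beta0=np.full(S, beta0), beta=np.zeros((S, len(ABUNDANCE_COVS))),
        alpha0=np.full(S, alpha0), alpha=np.zeros((S, len(DETECTION_COVS))),
        psi=np.full(S, psi), gamma=np.zeros(design.n_sites))


class TestSimulateCounts:
    def test_full_zero_inflation(self, tiny_design):
        cov = cx.generate_covariates(tiny_design, rng_seed=0)
        p = _constant_params(tiny_design, beta0=1.0, alpha0=0.0, psi=0.0)
        ct = cx.simulate_counts(p, cov, tiny_design, rng_seed=1)
        assert (ct.counts["count"] == 0).all()

    def test_perfect_detection_reveals_latent_abundance(self, tiny_design):
        cov = cx.generate_covariates(tiny_design, rng_seed=0)
        p = _constant_params(tiny_design, beta0=0.7, alpha0=0.0, psi=1.0)
        ct = cx.simulate_counts(p, cov, tiny_design, rng_seed=2,
                                phi_override=1.0)
        merged = ct.counts.merge(ct.latent, on=["species", "point", "year"])
        assert (merged["count"] == merged["M"]).all()

    def test_counts_bounded_by_latent_abundance(self, tiny_dataset):
        ct = tiny_dataset["counts"]
        m = (ct.counts.groupby(["species", "point", "year"])["count"].max()
             .reset_index().merge(ct.latent, on=["species", "point", "year"]))
        assert (m["count"] <= m["M"]).all()

    def test_poisson_thinning_identity(self):
        # psi=1, lam=2, phi=0.5: marginal visit counts are Poisson(1)
        design = cx.SurveyDesign(n_sites=2, n_points=2500, n_years=4,
                                 visits_per_year=3, species=("A",),
                                 suite_map={"A": "Grassland"})
        cov = cx.generate_covariates(design, rng_seed=4)
        p = _constant_params(design, beta0=np.log(2.0), alpha0=0.0, psi=1.0)
        ct = cx.simulate_counts(p, cov, design, rng_seed=5)
        assert len(ct.latent) == 10_000
        assert abs(ct.counts["count"].mean() - 1.0) < 0.05

    def test_seed_determinism(self, tiny_dataset):
        d = tiny_dataset
        again = cx.simulate_counts(d["params"], d["cov"], d["design"],
                                   rng_seed=13)
        pd.testing.assert_frame_equal(again.counts, d["counts"].counts)
        pd.testing.assert_frame_equal(again.latent, d["counts"].latent)
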