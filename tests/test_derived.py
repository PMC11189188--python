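"""Derived posterior quantities: P_d, zero-inflation, z-matrix, Jaccard,
suite summaries, and natural-scale effects."""

import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import binom, poisson

import commnmix as cx
from commnmix.derived import COMMUNITY, conditional_absence_prob
from commnmix.design import ABUNDANCE_COVS, DETECTION_COVS
from _oracles import jaccard_sets

SUITES = {"A": "Forested Upland", "B": "Scrub-Shrub", "C": "Grassland"}


def make_draws(values: dict, species=("A", "B", "C"), n=50):
    """PosteriorDraws with constant (or given) per-parameter values."""
    params = {}
    for name, v in values.items():
        arr = np.asarray(v, float)
        params[name] = arr if arr.ndim == 2 else np.full((2, n), float(v))
    return cx.PosteriorDraws(
        params=params,
        config=cx.McmcConfig(n_iterations=2, n_burnin=0, thin=1),
        meta={"species": list(species),
              "abundance_covs": list(ABUNDANCE_COVS),
              "detection_covs": list(DETECTION_COVS),
              "site_ids": ["s00"]})


class TestDetectionAndZeroInflation:
    def test_intercept_zero_gives_half(self):
        d = make_draws({f"alpha0[{s}]": 0.0 for s in "ABC"})
        out = cx.detection_summary(d, SUITES)
        assert np.allclose(out["mean"], 0.5)

    def test_reported_intercept_scale(self):
        d = make_draws({"alpha0[A]": -1.71}, species=("A",),)
        out = cx.detection_summary(d, {"A": "Grassland"})
        assert np.allclose(out["mean"], expit(-1.71), atol=1e-12)
        assert 0.14 < out["mean"].iloc[0] < 0.16

    def test_community_is_mean_of_species(self):
        rng = np.random.default_rng(0)
        vals = {f"alpha0[{s}]": rng.normal(-1, 0.5, (2, 50)) for s in "ABC"}
        d = make_draws(vals)
        out = cx.detection_summary(d, SUITES).set_index("label")
        per_draw = np.mean([expit(vals[f"alpha0[{s}]"]) for s in "ABC"],
                           axis=0)
        assert np.isclose(out.loc[COMMUNITY, "mean"], per_draw.mean())

    def test_zero_inflation_point_mass_and_uniform(self):
        d = make_draws({"psi[A]": 1.0}, species=("A",))
        out = cx.zero_inflation_summary(d, {"A": "Grassland"})
        assert np.allclose(out["mean"], 1.0)
        # one-species suite equals the species row
        assert out.set_index("level").loc["suite", "mean"] == 1.0
        rng = np.random.default_rng(1)
        d2 = make_draws({"psi[A]": rng.uniform(size=(2, 4000))},
                        species=("A",))
        out2 = cx.zero_inflation_summary(d2, {"A": "Grassland"})
        assert abs(out2["mean"].iloc[0] - 0.5) < 0.03

    def test_missing_suite_errors(self):
        d = make_draws({"alpha0[A]": 0.0}, species=("A",))
        with pytest.raises(ValueError, match="suite"):
            cx.detection_summary(d, {})


def _one_point_data(y, n_visits=3):
    y = np.asarray(y, int).reshape(1, 1, n_visits)
    return cx.ModelData(
        species=("A",), y=y, x=np.zeros((1, len(ABUNDANCE_COVS))),
        v=np.zeros((1, n_visits, len(DETECTION_COVS))),
        site_idx=np.zeros(1, int), site_ids=("s00",),
        point_of_cell=np.array(["p0"]), year_of_cell=np.array([1]))


def _const_param_draws(beta0, alpha0, psi, n=2000):
    vals = {"beta0[A]": beta0, "alpha0[A]": alpha0, "psi[A]": psi,
            "gamma[s00]": 0.0}
    for c in ABUNDANCE_COVS:
        vals[f"beta[A,{c}]"] = 0.0
    for c in DETECTION_COVS:
        vals[f"alpha[A,{c}]"] = 0.0
    return make_draws(vals, species=("A",), n=n)


class TestZMatrix:
    def test_observed_point_always_present(self):
        data = _one_point_data([0, 2, 0])
        draws = _const_param_draws(beta0=0.0, alpha0=0.0, psi=0.5, n=100)
        zm = cx.build_z_matrix(draws, data, rng_seed=0)
        assert (zm.z == 1).all()

    def test_structural_absence(self):
        data = _one_point_data([0, 0, 0])
        draws = _const_param_draws(beta0=1.0, alpha0=0.0, psi=1e-12, n=100)
        zm = cx.build_z_matrix(draws, data, rng_seed=0)
        assert (zm.z == 0).all()

    def test_conditional_matches_enumeration(self):
        """All-zero cell, psi=1, lam=5, phi=0.9 x 3 visits: the sampled
        presence rate matches the exact conditional, itself cross-checked
        against direct enumeration over M."""
        lam, phi, psi, V = 5.0, 0.9, 1.0, 3
        q = (1 - phi) ** V
        # enumeration: P(M=0 | all-zero) over M = 0..60
        m = np.arange(61)
        w = ((1 - psi) * (m == 0) + psi * poisson.pmf(m, lam)) \
            * binom.pmf(0, m, phi) ** V
        p0_enum = w[0] / w.sum()
        p0_closed = conditional_absence_prob(psi, lam, q)
        assert abs(p0_enum - p0_closed) < 1e-10

        data = _one_point_data([0, 0, 0])
        draws = _const_param_draws(beta0=np.log(lam),
                                   alpha0=np.log(phi / (1 - phi)), psi=psi,
                                   n=4000)
        zm = cx.build_z_matrix(draws, data, rng_seed=1, max_draws=8000)
        p_present = zm.z.mean()
        se = np.sqrt(p0_closed * (1 - p0_closed) / zm.z.shape[0])
        assert abs(p_present - (1 - p0_closed)) < 5 * se + 1e-4


class TestJaccard:
    def test_hand_examples(self):
        assert cx.jaccard([1, 1, 0], [1, 0, 1]) == pytest.approx(1 / 3)
        assert cx.jaccard([1, 0, 1], [1, 0, 1]) == 1.0
        assert cx.jaccard([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0
        assert np.isnan(cx.jaccard([0, 0], [0, 0]))

    def test_matches_set_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            zi = rng.integers(0, 2, 12)
            zj = rng.integers(0, 2, 12)
            want = jaccard_sets(zi, zj)
            got = cx.jaccard(zi, zj)
            assert (np.isnan(got) and np.isnan(want)) or got == want

    def test_posterior_pair_table(self):
        rng = np.random.default_rng(3)
        species = tuple(f"s{i:02d}" for i in range(12))
        z = (rng.random((40, 12, 30)) < 0.4).astype(np.int8)
        zm = cx.ZMatrix(z=z, species=species,
                        points=tuple(f"p{i}" for i in range(30)))
        out = cx.jaccard_posterior(zm)
        assert len(out) == 66  # 12 choose 2
        assert out["mean"].between(0, 1).all()
        assert (out["lower"] <= out["upper"]).all()

    def test_degenerate_draws(self):
        z = np.ones((5, 2, 4), dtype=np.int8)
        zm = cx.ZMatrix(z=z, species=("A", "B"), points=("p0", "p1", "p2", "p3"))
        out = cx.jaccard_posterior(zm)
        assert np.allclose(out[["mean", "lower", "upper"]], 1.0)


class TestSuiteSummary:
    def test_opposite_coefficients_cancel(self):
        vals = {}
        for sp, c in (("A", 0.8), ("B", -0.8)):
            vals[f"beta0[{sp}]"] = 0.0
            vals[f"alpha0[{sp}]"] = 0.0
            vals[f"psi[{sp}]"] = 0.5
            for cov in ABUNDANCE_COVS:
                vals[f"beta[{sp},{cov}]"] = c if cov == "basal" else 0.0
            for cov in DETECTION_COVS:
                vals[f"alpha[{sp},{cov}]"] = 0.0
        for h in ("mu_beta0", "mu_alpha0"):
            vals[h] = 0.0
        for cov in ABUNDANCE_COVS:
            vals[f"mu_beta[{cov}]"] = 0.0
        for cov in DETECTION_COVS:
            vals[f"mu_alpha[{cov}]"] = 0.0
        d = make_draws(vals, species=("A", "B"))
        out = cx.suite_summary(d, {"A": "Scrub-Shrub", "B": "Scrub-Shrub"})
        row = out[(out.group == "Scrub-Shrub") & (out.parameter == "basal")]
        assert np.isclose(row["mean"].iloc[0], 0.0)
        assert not row["significant"].iloc[0]

    def test_negative_basal_suite_flagged(self):
        rng = np.random.default_rng(4)
        vals = {"mu_beta0": 0.0, "mu_alpha0": 0.0}
        for cov in ABUNDANCE_COVS:
            vals[f"mu_beta[{cov}]"] = 0.0
        for cov in DETECTION_COVS:
            vals[f"mu_alpha[{cov}]"] = 0.0
        for sp in ("A", "B"):
            vals[f"beta0[{sp}]"] = 0.0
            vals[f"alpha0[{sp}]"] = 0.0
            vals[f"psi[{sp}]"] = 0.5
            for cov in ABUNDANCE_COVS:
                vals[f"beta[{sp},{cov}]"] = (
                    rng.normal(-0.3, 0.05, (2, 50)) if cov == "basal" else 0.0)
            for cov in DETECTION_COVS:
                vals[f"alpha[{sp},{cov}]"] = 0.0
        d = make_draws(vals, species=("A", "B"))
        out = cx.suite_summary(d, {"A": "Scrub-Shrub", "B": "Scrub-Shrub"})
        row = out[(out.group == "Scrub-Shrub") & (out.parameter == "basal")]
        assert row["significant"].iloc[0] and row["upper"].iloc[0] < 0


class TestRescaleEffect:
    def test_zero_effect_or_shift(self):
        lam = np.full(100, 2.0)
        assert cx.rescale_effect(np.zeros(100), 13.0, -26.0, lam)["mean"] == 0
        assert cx.rescale_effect(np.full(100, -0.23), 13.0, 0.0, lam)["mean"] == 0

    def test_basal_translation_arithmetic(self):
        # beta=-0.23 per sd, sd=13 m^2/ha, a 26 m^2/ha decrease from a
        # 2-bird baseline adds ~1.17 birds
        out = cx.rescale_effect(np.full(50, -0.23), 13.0, -26.0,
                                np.full(50, 2.0))
        assert np.isclose(out["mean"], 2.0 * (np.exp(0.46) - 1.0))

    def test_invalid_sd(self):
        with pytest.raises(ValueError):
            cx.rescale_effect(np.zeros(5), 0.0, 1.0, np.ones(5))
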