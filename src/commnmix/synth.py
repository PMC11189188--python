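"""Synthetic point-count data with the exact structure the model assumes.

The generator draws community hyperparameters -> species-level coefficients
-> latent inclusion/abundance -> binomially thinned visit counts, so every
downstream stage (standardization, screening, likelihood, MCMC, derived
quantities) can be exercised and validated without field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .design import (ABUNDANCE_COVS, DETECTION_COVS, CovariateRegime,
                     SurveyDesign, pine_barrens_regime)

__all__ = [
    "CommunityHyperparams", "SpeciesParams", "CovariateTable", "CountTable",
    "generate_covariates", "draw_species_params", "simulate_counts",
    "default_hyperparams",
]


@dataclass(frozen=True)
class CommunityHyperparams:
    """Community-level hyperdistribution for species coefficients.

    Species intercepts and slopes are exchangeable Normal draws around the
    community means; ``psi`` is the zero-inflation (inclusion) probability,
    either one value shared by all species or a per-species mapping;
    ``sigma_site`` scales the shared site random effect.
    """

    mu_beta0: float
    sigma_beta0: float
    mu_beta_cov: Mapping[str, float]
    sigma_beta_cov: Mapping[str, float]
    mu_alpha0: float
    sigma_alpha0: float
    mu_alpha_cov: Mapping[str, float]
    sigma_alpha_cov: Mapping[str, float]
    psi: float | Mapping[str, float] = 0.6
    sigma_site: float = 0.2

    def __post_init__(self) -> None:
        if set(self.mu_beta_cov) != set(self.sigma_beta_cov):
            raise ValueError("mu_beta_cov / sigma_beta_cov keys differ")
        if set(self.mu_alpha_cov) != set(self.sigma_alpha_cov):
            raise ValueError("mu_alpha_cov / sigma_alpha_cov keys differ")
        sigmas = ([self.sigma_beta0, self.sigma_alpha0, self.sigma_site]
                  + list(self.sigma_beta_cov.values())
                  + list(self.sigma_alpha_cov.values()))
        if any(s < 0 for s in sigmas):
            raise ValueError("all sigma hyperparameters must be >= 0")
        psis = (self.psi.values() if isinstance(self.psi, Mapping)
                else [self.psi])
        if any(not 0 <= p <= 1 for p in psis):
            raise ValueError("psi must lie in [0, 1]")

    def psi_for(self, species: str) -> float:
        if isinstance(self.psi, Mapping):
            return float(self.psi[species])
        return float(self.psi)


def default_hyperparams() -> CommunityHyperparams:
    """Moderate-effect community used throughout the synthetic study.

    Baseline abundance ~2 birds per plot (mu_beta0 = 0.7), per-visit
    detection ~0.18 (mu_alpha0 = -1.5), a clear negative basal-area effect
    (-0.4) among moderate vegetation effects, inclusion probability 0.6,
    and a small site random effect.
    """
    return CommunityHyperparams(
        mu_beta0=0.7, sigma_beta0=0.3,
        mu_beta_cov={"grass": 0.3, "woody": -0.2, "vor2": 0.2,
                     "basal": -0.4, "treatment": 0.4},
        sigma_beta_cov={c: 0.3 for c in ABUNDANCE_COVS},
        mu_alpha0=-1.5, sigma_alpha0=0.25,
        mu_alpha_cov={"date": 0.2, "date2": -0.15, "wind": -0.2,
                      "disturbance": -0.1},
        sigma_alpha_cov={c: 0.2 for c in DETECTION_COVS},
        psi=0.6, sigma_site=0.2,
    )


@dataclass
class SpeciesParams:
    """Realized species-level coefficients and site effects.

    Arrays are ordered by ``species`` / the covariate tuples; ``gamma`` is
    the site random effect shared by all species.
    """

    species: tuple[str, ...]
    abundance_covs: tuple[str, ...]
    detection_covs: tuple[str, ...]
    beta0: np.ndarray          # (S,)
    beta: np.ndarray           # (S, P)
    alpha0: np.ndarray         # (S,)
    alpha: np.ndarray          # (S, Q)
    psi: np.ndarray            # (S,)
    gamma: np.ndarray          # (T,)

    def __post_init__(self) -> None:
        S = len(self.species)
        for name in ("beta0", "beta", "alpha0", "alpha", "psi", "gamma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.beta0.shape != (S,) or self.alpha0.shape != (S,):
            raise ValueError("intercept arrays must have one entry per species")
        if self.beta.shape != (S, len(self.abundance_covs)):
            raise ValueError("beta shape does not conform to covariate set")
        if self.alpha.shape != (S, len(self.detection_covs)):
            raise ValueError("alpha shape does not conform to covariate set")
        if self.psi.shape != (S,) or np.any((self.psi < 0) | (self.psi > 1)):
            raise ValueError("psi must be per-species in [0, 1]")


def draw_species_params(hyper: CommunityHyperparams, design: SurveyDesign,
                        rng_seed: int) -> SpeciesParams:
    """Draw species coefficients from the community hyperdistributions and
    site effects from Normal(0, sigma_site^2)."""
    rng = np.random.default_rng(rng_seed)
    S = design.n_species
    P, Q = len(ABUNDANCE_COVS), len(DETECTION_COVS)
    beta0 = rng.normal(hyper.mu_beta0, hyper.sigma_beta0, S)
    beta = np.column_stack([
        rng.normal(hyper.mu_beta_cov[c], hyper.sigma_beta_cov[c], S)
        for c in ABUNDANCE_COVS])
    alpha0 = rng.normal(hyper.mu_alpha0, hyper.sigma_alpha0, S)
    alpha = np.column_stack([
        rng.normal(hyper.mu_alpha_cov[c], hyper.sigma_alpha_cov[c], S)
        for c in DETECTION_COVS])
    psi = np.array([hyper.psi_for(s) for s in design.species])
    gamma = rng.normal(0.0, hyper.sigma_site, design.n_sites)
    return SpeciesParams(species=design.species,
                         abundance_covs=ABUNDANCE_COVS,
                         detection_covs=DETECTION_COVS,
                         beta0=beta0, beta=np.atleast_2d(beta).reshape(S, P),
                         alpha0=alpha0, alpha=np.atleast_2d(alpha).reshape(S, Q),
                         psi=psi, gamma=gamma)


@dataclass
class CovariateTable:
    """Point x year vegetation covariates and visit-level detection covariates.

    ``scale`` holds (mean, sd) standardization constants per covariate once
    :func:`commnmix.prep.standardize_table` has been applied; standardized
    companions live in ``<name>_z`` columns.
    """

    points: pd.DataFrame
    visits: pd.DataFrame
    scale: dict[str, tuple[float, float]] = field(default_factory=dict)

    def copy(self) -> "CovariateTable":
        return CovariateTable(self.points.copy(), self.visits.copy(),
                              dict(self.scale))


@dataclass
class CountTable:
    """Observed visit counts, optionally with the simulated latent truth.

    ``counts`` is long format (species, site, point, year, visit, count);
    ``latent`` (simulation only) carries the inclusion indicator ``a`` and
    latent abundance ``M`` per species x point x year.
    """

    counts: pd.DataFrame
    latent: pd.DataFrame | None = None


def _draw_truncnorm(spec, size: int, rng: np.random.Generator) -> np.ndarray:
    if spec.sd == 0:
        return np.full(size, spec.mean)
    a = (spec.lower - spec.mean) / spec.sd
    b = (spec.upper - spec.mean) / spec.sd
    return truncnorm.rvs(a, b, loc=spec.mean, scale=spec.sd, size=size,
                         random_state=rng)


def _redundant_covariates(pts: pd.DataFrame, rng: np.random.Generator) -> None:
    """Append screened-out covariates with planted |r| > 0.7 partners.

    Groundcover percentages that mirror grass/woody, lower visual-obstruction
    strata tracking VOR2, and canopy closure tracking basal area.
    """
    def mix(base: pd.Series, rho: float, lo: float, hi: float,
            scale_to: tuple[float, float]) -> np.ndarray:
        z = (base - base.mean()) / base.std()
        noisy = rho * z + np.sqrt(1 - rho ** 2) * rng.standard_normal(len(z))
        out = scale_to[0] + scale_to[1] * noisy
        return np.clip(out, lo, hi)

    pts["forbs"] = mix(pts["grass"], 0.9, 0, 100, (12, 10))
    pts["bare"] = mix(pts["grass"], 0.85, 0, 100, (10, 8))
    pts["litter"] = mix(-pts["woody"], 0.9, 0, 100, (30, 15))
    pts["vor025"] = mix(pts["vor2"], 0.92, 0, 100, (55, 25))
    pts["vor1"] = mix(pts["vor2"], 0.9, 0, 100, (50, 25))
    pts["canopy"] = mix(pts["basal"], 0.92, 0, 100, (60, 25))


def generate_covariates(design: SurveyDesign,
                        regime: CovariateRegime | None = None,
                        rng_seed: int = 0,
                        include_redundant: bool = False) -> CovariateTable:
    """Draw point x year vegetation covariates from the per-group truncated
    normals and visit-level date/wind/disturbance covariates.

    Visit dates fall in consecutive thirds of the season window, mimicking
    the ~3-week revisit interval; wind is uniform below the surveyable
    ceiling and disturbance a uniform ordinal score.
    """
    regime = regime if regime is not None else pine_barrens_regime()
    rng = np.random.default_rng(rng_seed)
    treated = design.treatment_of_point
    site_idx = design.site_of_point
    n_rows = design.n_points * design.n_years

    pts = pd.DataFrame({
        "point": np.tile(design.point_ids, design.n_years),
        "site": np.tile(design.site_ids[site_idx], design.n_years),
        "year": np.repeat(np.arange(1, design.n_years + 1), design.n_points),
        "treatment": np.tile(treated.astype(int), design.n_years),
    })
    treated_rows = pts["treatment"].to_numpy(bool)
    for cov in regime.covariates:
        vals = np.empty(n_rows)
        for flag in (False, True):
            mask = treated_rows == flag
            vals[mask] = _draw_truncnorm(regime.group(flag)[cov],
                                         int(mask.sum()), rng)
        pts[cov] = vals
    if include_redundant:
        _redundant_covariates(pts, rng)

    V = design.visits_per_year
    n_visits = n_rows * V
    third = regime.season_length_days / V
    visit_no = np.tile(np.arange(1, V + 1), n_rows)
    vis = pd.DataFrame({
        "point": np.repeat(pts["point"].to_numpy(), V),
        "site": np.repeat(pts["site"].to_numpy(), V),
        "year": np.repeat(pts["year"].to_numpy(), V),
        "visit": visit_no,
        "date": (visit_no - 1) * third + rng.uniform(0, third, n_visits),
        "wind": rng.uniform(*regime.wind_range, n_visits),
        "disturbance": rng.integers(0, regime.disturbance_levels,
                                    n_visits).astype(float),
    })
    return CovariateTable(points=pts, visits=vis)


def _cell_tables(design: SurveyDesign) -> tuple[np.ndarray, np.ndarray]:
    """Point index and year per point x year cell, year-major to match
    generate_covariates row order."""
    point_idx = np.tile(np.arange(design.n_points), design.n_years)
    year = np.repeat(np.arange(1, design.n_years + 1), design.n_points)
    return point_idx, year


def simulate_counts(params: SpeciesParams, covariates: CovariateTable,
                    design: SurveyDesign, rng_seed: int = 0,
                    phi_override: float | None = None) -> CountTable:
    """Simulate the zero-inflated N-mixture observation process.

    Per species x point x year: a ~ Bernoulli(psi), M ~ Poisson(a * lambda)
    with log(lambda) = beta0 + beta . x + gamma_site; per visit
    y ~ Binomial(M, phi) with logit(phi) = alpha0 + alpha . v. Covariates
    are standardized (over the generated population) before entering the
    linear predictors. ``phi_override`` replaces the detection model with a
    fixed per-visit rate (e.g. 1.0 for perfect detection).
    """
    from .prep import standardize_table  # deferred: prep imports this module's types

    cov = covariates
    need = [c for c in params.abundance_covs if c != "treatment"] + \
           [c for c in params.detection_covs if c != "date2"]
    if not all(f"{c}_z" in cov.points.columns or f"{c}_z" in cov.visits.columns
               for c in need):
        cov = standardize_table(cov)

    S, T = len(params.species), design.n_sites
    V = design.visits_per_year
    point_idx, year = _cell_tables(design)
    C = len(point_idx)
    site_of_cell = design.site_of_point[point_idx]

    # abundance design matrix (C, P): standardized vegetation + raw 0/1 flag
    xcols = []
    for c in params.abundance_covs:
        col = "treatment" if c == "treatment" else f"{c}_z"
        xcols.append(cov.points[col].to_numpy(float))
    x = np.column_stack(xcols)

    eta = (params.beta0[:, None] + params.beta @ x.T
           + params.gamma[site_of_cell][None, :])
    if not np.all(np.isfinite(eta)):
        s, c = np.argwhere(~np.isfinite(eta))[0]
        raise FloatingPointError(
            f"non-finite abundance predictor for species "
            f"{params.species[s]} at point {design.point_ids[point_idx[c]]} "
            f"year {year[c]}")
    lam = np.exp(eta)

    if phi_override is None:
        vcols = []
        for c in params.detection_covs:
            if c == "date2":
                vcols.append(cov.visits["date_z"].to_numpy(float) ** 2)
            else:
                vcols.append(cov.visits[f"{c}_z"].to_numpy(float))
        v = np.column_stack(vcols)            # (C*V, Q)
        zeta = params.alpha0[:, None] + params.alpha @ v.T
        if not np.all(np.isfinite(zeta)):
            s, c = np.argwhere(~np.isfinite(zeta))[0]
            raise FloatingPointError(
                f"non-finite detection predictor for species "
                f"{params.species[s]} at visit row {c}")
        phi = expit(zeta).reshape(S, C, V)
    else:
        if not 0 <= phi_override <= 1:
            raise ValueError("phi_override must be in [0, 1]")
        phi = np.full((S, C, V), float(phi_override))

    rng = np.random.default_rng(rng_seed)
    a = rng.random((S, C)) < params.psi[:, None]
    M = rng.poisson(np.where(a, lam, 0.0))
    y = rng.binomial(M[:, :, None], phi)

    pid = design.point_ids[point_idx]
    sid = design.site_ids[site_of_cell]
    counts = pd.DataFrame({
        "species": np.repeat(params.species, C * V),
        "site": np.tile(np.repeat(sid, V), S),
        "point": np.tile(np.repeat(pid, V), S),
        "year": np.tile(np.repeat(year, V), S),
        "visit": np.tile(np.tile(np.arange(1, V + 1), C), S),
        "count": y.reshape(-1),
    })
    latent = pd.DataFrame({
        "species": np.repeat(params.species, C),
        "point": np.tile(pid, S),
        "year": np.tile(year, S),
        "a": a.astype(int).reshape(-1),
        "M": M.reshape(-1),
        "lambda": lam.reshape(-1),
    })
    return CountTable(counts=counts, latent=latent)
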