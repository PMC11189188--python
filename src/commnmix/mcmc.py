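"""Posterior sampling for the community N-mixture model.

The sampler is an adaptive Metropolis-within-Gibbs scheme on the exactly
marginalized likelihood: species coefficient blocks (abundance, detection),
zero-inflation probabilities, and site effects get random-walk proposals
accepted blockwise (species are conditionally independent given the
hyperparameters, and sites partition the cells, so whole batches are
proposed and accepted in one vectorized pass); community hyper-means are
conjugate Gibbs draws; hyper scales move on the log scale. Proposal scales
and block covariances adapt during burn-in only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .likelihood import MarginalLikelihood, ModelData, ModelSpec
from .synth import SpeciesParams

__all__ = ["McmcConfig", "PosteriorDraws", "run_mcmc", "gelman_rubin",
           "summarize"]

_ADAPT_EVERY = 50
_LOG_SQRT_2PI = 0.9189385332046727


def _norm_lp(x, mu, sd):
    """Normal log-density; manual because scipy call overhead dominates the
    sampler's many small-array prior evaluations."""
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - _LOG_SQRT_2PI


def _psi_logp(u, psi, prior):
    """Beta log-density (up to its constant) plus the logit-scale Jacobian
    psi(1-psi); used in Metropolis ratios only."""
    a, b = prior
    psi = np.clip(psi, 1e-12, 1 - 1e-12)
    return a * np.log(psi) + b * np.log1p(-psi)


@dataclass(frozen=True)
class McmcConfig:
    """Chain layout and iteration budget.

    The desk-scale default (3 chains x 4,000 iterations, half burn-in,
    thin 5) replaces the original 3 x 200,000 / 100,000 / thin-5 budget,
    which remains reachable through these fields.
    """

    n_chains: int = 3
    n_iterations: int = 4000
    n_burnin: int = 2000
    thin: int = 5
    seed: int = 0
    monitor: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("need 0 <= n_burnin < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin


@dataclass
class PosteriorDraws:
    """Retained draws, chain x iteration per parameter name."""

    params: dict[str, np.ndarray]
    config: McmcConfig
    meta: dict = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return list(self.params)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        return self.params[name]

    def pooled(self, name: str) -> np.ndarray:
        return self.params[name].reshape(-1)

    def array_for(self, names: Sequence[str]) -> np.ndarray:
        """Pooled draws stacked over parameters, shape (draws, len(names))."""
        return np.column_stack([self.pooled(n) for n in names])

    def to_frame(self) -> pd.DataFrame:
        """Long table (chain, iteration, parameter, value)."""
        nc, nd = self.n_chains, self.n_draws
        frames = []
        for name, arr in self.params.items():
            frames.append(pd.DataFrame({
                "chain": np.repeat(np.arange(nc), nd),
                "iteration": np.tile(np.arange(nd), nc),
                "parameter": name,
                "value": arr.reshape(-1),
            }))
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, config: McmcConfig | None = None,
                   meta: dict | None = None) -> "PosteriorDraws":
        params = {}
        for name, g in df.groupby("parameter", sort=False):
            piv = g.pivot(index="chain", columns="iteration", values="value")
            params[name] = piv.to_numpy()
        nc = next(iter(params.values())).shape[0]
        cfg = config or McmcConfig(n_chains=max(nc, 1), n_iterations=2,
                                   n_burnin=0, thin=1)
        return cls(params=params, config=cfg, meta=meta or {})


# ---------------------------------------------------------------------------
# adaptive proposal helpers


class _VectorBlocks:
    """Adaptive multivariate random-walk proposals for a batch of blocks."""

    def __init__(self, n_blocks: int, dim: int, init_scale: float = 0.1,
                 target: float = 0.25):
        self.dim = dim
        self.target = target
        self.scale = np.full(n_blocks, init_scale)
        self.chol = np.broadcast_to(np.eye(dim), (n_blocks, dim, dim)).copy()
        self.mean = np.zeros((n_blocks, dim))
        self.m2 = np.zeros((n_blocks, dim, dim))
        self.count = 0
        self._acc = np.zeros(n_blocks)
        self._n = 0
        self._using_emp = False

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        eps = rng.standard_normal(x.shape)
        return x + self.scale[:, None] * np.einsum("bij,bj->bi", self.chol, eps)

    def record(self, x: np.ndarray, accepted: np.ndarray) -> None:
        self.count += 1
        d = x - self.mean
        self.mean += d / self.count
        self.m2 += d[:, :, None] * (x - self.mean)[:, None, :]
        self._acc += accepted
        self._n += 1

    def adapt(self) -> None:
        if self._n == 0:
            return
        rate = self._acc / self._n
        self.scale *= np.exp(np.clip(rate - self.target, -0.5, 0.5))
        self._acc[:] = 0.0
        self._n = 0
        if self.count > 10 * self.dim:
            cov = self.m2 / (self.count - 1) + 1e-8 * np.eye(self.dim)
            try:
                chol = np.linalg.cholesky((2.38 ** 2 / self.dim) * cov)
            except np.linalg.LinAlgError:
                return
            self.chol = chol
            if not self._using_emp:
                # switching to the empirical covariance resets the residual
                # acceptance-rate multiplier
                self.scale[:] = 1.0
                self._using_emp = True


class _ScalarBatch:
    """Adaptive scalar random-walk proposals for a batch of parameters."""

    def __init__(self, n: int, init_scale: float = 0.2, target: float = 0.44):
        self.scale = np.full(n, init_scale)
        self.target = target
        self._acc = np.zeros(n)
        self._n = 0

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return x + self.scale * rng.standard_normal(x.shape)

    def record(self, accepted: np.ndarray) -> None:
        self._acc += accepted
        self._n += 1

    def adapt(self) -> None:
        if self._n == 0:
            return
        rate = self._acc / self._n
        self.scale *= np.exp(np.clip(rate - self.target, -0.5, 0.5))
        self._acc[:] = 0.0
        self._n = 0


# ---------------------------------------------------------------------------
# sampler


class _ChainState:
    """Mutable per-chain state with cached likelihood terms."""

    def __init__(self, data: ModelData, spec: ModelSpec,
                 lik: MarginalLikelihood, rng: np.random.Generator):
        S = data.n_species
        P = len(data.abundance_covs)
        Q = len(data.detection_covs)
        self.P, self.Q = P, Q
        self.D = 2 + P + Q
        self.i_b0 = 0
        self.sl_beta = slice(1, 1 + P)
        self.i_a0 = 1 + P
        self.sl_alpha = slice(2 + P, 2 + P + Q)
        self.sl_ab = slice(0, 1 + P)
        self.sl_det = slice(1 + P, 2 + P + Q)

        self.mu = 0.1 * rng.standard_normal(self.D)
        self.log_sigma = 0.1 * rng.standard_normal(self.D)
        self.log_sigma_site = 0.1 * rng.standard_normal()
        self.coefs = self.mu[None, :] + 0.1 * rng.standard_normal((S, self.D))
        if data.n_cells:
            p_obs = (~lik.allzero).mean(axis=1)
        else:
            p_obs = np.full(S, 0.5)
        self.u_psi = logit(np.clip(p_obs, 0.05, 0.95)) \
            + 0.2 * rng.standard_normal(S)
        self.gamma = 0.05 * rng.standard_normal(data.n_sites)

        # treatment/site ridge geometry, available when treatment is a model
        # term and constant within each site
        self.i_treat: int | None = None
        self.treated_sites: np.ndarray | None = None
        if "treatment" in data.abundance_covs and data.n_cells:
            j = data.abundance_covs.index("treatment")
            tcol = data.x[:, j]
            if np.isin(tcol, (0.0, 1.0)).all():
                tot = np.bincount(data.site_idx, weights=tcol,
                                  minlength=data.n_sites)
                n = np.bincount(data.site_idx, minlength=data.n_sites)
                frac = np.divide(tot, n, out=np.zeros_like(tot),
                                 where=n > 0)
                if np.all((frac == 0) | (frac == 1)):
                    self.i_treat = 1 + j
                    self.treated_sites = frac == 1
        self.slow_cols = tuple(c for c in (self.i_b0, self.i_treat, self.i_a0)
                               if c is not None)

        self.data, self.spec, self.lik = data, spec, lik
        self.refresh()

    # -- cached predictors -------------------------------------------------

    def lam_of(self, coefs: np.ndarray, gamma: np.ndarray) -> np.ndarray:
        eta = (coefs[:, [self.i_b0]] + coefs[:, self.sl_beta] @ self.data.x.T
               + gamma[self.data.site_idx][None, :])
        return np.exp(np.clip(eta, -700, 700))

    def phi_of(self, coefs: np.ndarray) -> np.ndarray:
        zeta = coefs[:, self.i_a0, None, None] + np.einsum(
            "sq,cvq->scv", coefs[:, self.sl_alpha], self.data.v)
        return expit(zeta)

    @property
    def psi(self) -> np.ndarray:
        return expit(self.u_psi)

    def refresh(self) -> None:
        self.lam = self.lam_of(self.coefs, self.gamma)
        self.phi = self.phi_of(self.coefs)
        self.det = self.lik.det_cache(self.phi)
        self.log_b1, self.cell = self.lik.loglik_cell(self.lam, self.det,
                                                      self.psi)

    def update_det_rows(self, det_p, acc: np.ndarray) -> None:
        self.det[0][acc] = det_p[0][acc]
        if len(self.lik.nz_s):
            mask = acc[self.lik.nz_s]
            self.det[2][mask] = det_p[2][mask]

    def finite(self) -> bool:
        return bool(np.all(np.isfinite(self.cell)))

    @property
    def sigma(self) -> np.ndarray:
        return np.exp(self.log_sigma)

    @property
    def sigma_site(self) -> float:
        return float(np.exp(self.log_sigma_site))


def _coef_block_update(st: _ChainState, sl: slice, adapter: _VectorBlocks,
                       rng: np.random.Generator, is_abundance: bool) -> None:
    coefs_prop = st.coefs.copy()
    coefs_prop[:, sl] = adapter.propose(st.coefs[:, sl], rng)
    if is_abundance:
        lam_p = st.lam_of(coefs_prop, st.gamma)
        log_b1_p, cell_p = st.lik.loglik_cell(lam_p, st.det, st.psi)
    else:
        phi_p = st.phi_of(coefs_prop)
        det_p = st.lik.det_cache(phi_p)
        log_b1_p, cell_p = st.lik.loglik_cell(st.lam, det_p, st.psi)

    mu, sd = st.mu[sl], st.sigma[sl]
    d_prior = (_norm_lp(coefs_prop[:, sl], mu, sd)
               - _norm_lp(st.coefs[:, sl], mu, sd)).sum(axis=1)
    d_ll = (cell_p - st.cell).sum(axis=1)
    acc = np.log(rng.random(len(d_ll))) < d_ll + d_prior
    if np.any(acc):
        st.coefs[acc, sl] = coefs_prop[acc, sl]
        if is_abundance:
            st.lam[acc] = lam_p[acc]
        else:
            st.phi[acc] = phi_p[acc]
            st.update_det_rows(det_p, acc)
        st.log_b1[acc] = log_b1_p[acc]
        st.cell[acc] = cell_p[acc]
    adapter.record(st.coefs[:, sl], acc)


def _intercept_update(st: _ChainState, adapter: _VectorBlocks,
                      rng: np.random.Generator) -> None:
    """Joint (beta0, alpha0, logit psi) proposal per species.

    Counts identify the product lambda * phi and the inclusion probability
    only jointly; the adapted covariance of this block learns the resulting
    posterior ridges that the separate abundance/detection blocks cannot
    travel along.
    """
    cur = np.column_stack((st.coefs[:, st.i_b0], st.coefs[:, st.i_a0],
                           st.u_psi))
    prop = adapter.propose(cur, rng)
    coefs_p = st.coefs.copy()
    coefs_p[:, st.i_b0] = prop[:, 0]
    coefs_p[:, st.i_a0] = prop[:, 1]
    u_p = prop[:, 2]
    psi_p = expit(u_p)
    lam_p = st.lam_of(coefs_p, st.gamma)
    phi_p = st.phi_of(coefs_p)
    det_p = st.lik.det_cache(phi_p)
    log_b1_p, cell_p = st.lik.loglik_cell(lam_p, det_p, psi_p)

    idx = [st.i_b0, st.i_a0]
    mu, sd = st.mu[idx], st.sigma[idx]
    d = ((cell_p - st.cell).sum(axis=1)
         + (_norm_lp(prop[:, :2], mu, sd)
            - _norm_lp(cur[:, :2], mu, sd)).sum(axis=1)
         + _psi_logp(u_p, psi_p, st.spec.psi_prior)
         - _psi_logp(st.u_psi, st.psi, st.spec.psi_prior))
    acc = np.log(rng.random(len(d))) < d
    if np.any(acc):
        st.coefs[acc, st.i_b0] = prop[acc, 0]
        st.coefs[acc, st.i_a0] = prop[acc, 1]
        st.u_psi[acc] = u_p[acc]
        st.lam[acc] = lam_p[acc]
        st.phi[acc] = phi_p[acc]
        st.update_det_rows(det_p, acc)
        st.log_b1[acc] = log_b1_p[acc]
        st.cell[acc] = cell_p[acc]
    adapter.record(np.column_stack((st.coefs[:, st.i_b0],
                                    st.coefs[:, st.i_a0], st.u_psi)), acc)


def _column_species_update(st: _ChainState, adapter: "_ColumnAdapter",
                           rng: np.random.Generator, it: int) -> None:
    """Rotating scalar random-walk on one coefficient column, accepted per
    species.

    One-dimensional proposals take much larger steps than the joint blocks,
    which keeps the species spread (and hence the hyper-sd) of weakly
    identified columns — treatment especially — moving.
    """
    d = (it + 7) % st.D   # offset so it pairs with a different hyper column
    # cap the step at the current hyper-sd so species values keep moving
    # (and the spread keeps re-aligning) deep in the sigma -> 0 funnel
    step = min(adapter.scales[d, 0], 2.5 * st.sigma[d])
    coefs_p = st.coefs.copy()
    coefs_p[:, d] = st.coefs[:, d] + step \
        * rng.standard_normal(st.coefs.shape[0])
    if d < 1 + st.P:
        lam_p = st.lam_of(coefs_p, st.gamma)
        det_p = None
        log_b1_p, cell_p = st.lik.loglik_cell(lam_p, st.det, st.psi)
    else:
        phi_p = st.phi_of(coefs_p)
        det_p = st.lik.det_cache(phi_p)
        log_b1_p, cell_p = st.lik.loglik_cell(st.lam, det_p, st.psi)
    mu, sd = st.mu[d], st.sigma[d]
    dlp = ((cell_p - st.cell).sum(axis=1)
           + _norm_lp(coefs_p[:, d], mu, sd)
           - _norm_lp(st.coefs[:, d], mu, sd))
    acc = np.log(rng.random(len(dlp))) < dlp
    if np.any(acc):
        st.coefs[acc, d] = coefs_p[acc, d]
        if det_p is None:
            st.lam[acc] = lam_p[acc]
        else:
            st.phi[acc] = phi_p[acc]
            st.update_det_rows(det_p, acc)
        st.log_b1[acc] = log_b1_p[acc]
        st.cell[acc] = cell_p[acc]
    adapter.record(d, float(acc.mean()))


def _psi_update(st: _ChainState, adapter: _ScalarBatch,
                rng: np.random.Generator) -> None:
    u_p = adapter.propose(st.u_psi, rng)
    psi_p = expit(u_p)
    cell_p = st.lik.assemble(st.log_b1, psi_p)
    d = ((cell_p - st.cell).sum(axis=1)
         + _psi_logp(u_p, psi_p, st.spec.psi_prior)
         - _psi_logp(st.u_psi, st.psi, st.spec.psi_prior))
    acc = np.log(rng.random(len(d))) < d
    st.u_psi[acc] = u_p[acc]
    st.cell[acc] = cell_p[acc]
    adapter.record(acc)


def _gamma_update(st: _ChainState, adapter: _ScalarBatch,
                  rng: np.random.Generator) -> None:
    if len(st.gamma) == 0 or st.data.n_cells == 0:
        return
    g_p = adapter.propose(st.gamma, rng)
    dg = g_p - st.gamma
    lam_p = st.lam * np.exp(dg[st.data.site_idx])[None, :]
    log_b1_p, cell_p = st.lik.loglik_cell(lam_p, st.det, st.psi)
    d_cells = (cell_p - st.cell).sum(axis=0)
    d_site = np.bincount(st.data.site_idx, weights=d_cells,
                         minlength=len(st.gamma))
    ss = st.sigma_site
    d_site += _norm_lp(g_p, 0.0, ss) - _norm_lp(st.gamma, 0.0, ss)
    acc = np.log(rng.random(len(d_site))) < d_site
    if np.any(acc):
        st.gamma[acc] = g_p[acc]
        cols = acc[st.data.site_idx]
        st.lam[:, cols] = lam_p[:, cols]
        st.log_b1[:, cols] = log_b1_p[:, cols]
        st.cell[:, cols] = cell_p[:, cols]
    adapter.record(acc)


def _translation_updates(st: _ChainState, adapter: _ScalarBatch,
                         rng: np.random.Generator) -> None:
    """Likelihood-invariant shifts along exact model ridges.

    Shifting every species intercept (and its hyper-mean) up while shifting
    every site effect down leaves all linear predictors unchanged, as does
    the analogous shift of the treatment coefficients against the treated
    sites' effects. Both moves are Metropolis steps on the prior alone and
    decorrelate the hyper-means from the site effects.
    """
    if st.data.n_cells == 0 or len(st.gamma) == 0:
        return
    ss = st.sigma_site
    prior_sd = 1.0 / np.sqrt(st.spec.prior_precision)
    deltas = adapter.propose(np.zeros(2), rng)
    acc = np.zeros(2)

    # global intercept vs all site effects
    d = deltas[0]
    g_p = st.gamma - d
    mu_p = st.mu[st.i_b0] + d
    dlp = (_norm_lp(g_p, 0.0, ss).sum() - _norm_lp(st.gamma, 0.0, ss).sum()
           + _norm_lp(mu_p, 0.0, prior_sd) - _norm_lp(st.mu[st.i_b0], 0.0, prior_sd))
    if np.log(rng.random()) < dlp:
        st.gamma = g_p
        st.mu[st.i_b0] = mu_p
        st.coefs[:, st.i_b0] += d
        acc[0] = 1

    # treatment coefficients vs treated sites' effects
    if st.i_treat is not None and st.treated_sites is not None:
        d = deltas[1]
        tmask = st.treated_sites
        g_p = st.gamma.copy()
        g_p[tmask] -= d
        mu_p = st.mu[st.i_treat] + d
        dlp = (_norm_lp(g_p[tmask], 0.0, ss).sum()
               - _norm_lp(st.gamma[tmask], 0.0, ss).sum()
               + _norm_lp(mu_p, 0.0, prior_sd)
               - _norm_lp(st.mu[st.i_treat], 0.0, prior_sd))
        if np.log(rng.random()) < dlp:
            st.gamma = g_p
            st.mu[st.i_treat] = mu_p
            st.coefs[:, st.i_treat] += d
            acc[1] = 1
    adapter.record(acc)


def _recenter_update(st: _ChainState, adapter: _VectorBlocks,
                     rng: np.random.Generator) -> None:
    """Joint shift of each hyper-mean together with all its species
    coefficients.

    Between-level mixing: the species-level prior terms are invariant under
    the shift, so the move travels the (vague) hyper-mean marginal at the
    pace of the likelihood, not of the much tighter species-level
    conditionals. The adapted covariance is learned from the hyper-mean
    trajectory itself.
    """
    d = adapter.propose(np.zeros((1, st.D)), rng)[0]
    coefs_p = st.coefs + d[None, :]
    mu_p = st.mu + d
    lam_p = st.lam_of(coefs_p, st.gamma)
    phi_p = st.phi_of(coefs_p)
    det_p = st.lik.det_cache(phi_p)
    log_b1_p, cell_p = st.lik.loglik_cell(lam_p, det_p, st.psi)
    prior_sd = 1.0 / np.sqrt(st.spec.prior_precision)
    dlp = (cell_p.sum() - st.cell.sum()
           + (_norm_lp(mu_p, 0.0, prior_sd)
              - _norm_lp(st.mu, 0.0, prior_sd)).sum())
    acc = np.log(rng.random()) < dlp
    if acc:
        st.coefs = coefs_p
        st.mu = mu_p
        st.lam = lam_p
        st.phi = phi_p
        st.det = det_p
        st.log_b1 = log_b1_p
        st.cell = cell_p
    adapter.record(st.mu[None, :], np.array([acc]))


class _ColumnAdapter:
    """Per-column (shift, log-scale) proposal widths for the rotating
    hyper-column move."""

    def __init__(self, n_cols: int, target: float = 0.3):
        self.scales = np.tile(np.array([0.2, 0.15]), (n_cols, 1))
        self.target = target
        self._acc = np.zeros(n_cols)
        self._n = np.zeros(n_cols)

    def record(self, d: int, accepted: bool) -> None:
        self._acc[d] += accepted
        self._n[d] += 1

    def adapt(self) -> None:
        seen = self._n > 0
        rate = np.divide(self._acc, np.maximum(self._n, 1.0))
        f = np.exp(np.clip(rate - self.target, -0.5, 0.5))
        self.scales[seen] *= f[seen, None]
        self._acc[:] = 0.0
        self._n[:] = 0.0


def _column_hyper_update(st: _ChainState, adapter: _ColumnAdapter,
                         rng: np.random.Generator, it: int) -> None:
    """Rotating joint (hyper-mean shift, spread scale) move on one
    coefficient column.

    Column d's species values move to mu + shift + c (coef - mu), the
    hyper-mean to mu + shift, and the hyper log-sd by log c. The
    species-level prior ratio cancels against the coordinate-change
    Jacobian, so the move travels the mean and spread of one column at the
    likelihood's pace — the axis along which hyper-parameters otherwise mix
    worst.
    """
    d = it % st.D
    shift = adapter.scales[d, 0] * rng.standard_normal()
    eps = adapter.scales[d, 1] * rng.standard_normal()
    c = np.exp(eps)
    coefs_p = st.coefs.copy()
    coefs_p[:, d] = st.mu[d] + shift + c * (st.coefs[:, d] - st.mu[d])
    mu_p = st.mu[d] + shift
    if d < 1 + st.P:
        lam_p = st.lam_of(coefs_p, st.gamma)
        det_p = None
        log_b1_p, cell_p = st.lik.loglik_cell(lam_p, st.det, st.psi)
    else:
        phi_p = st.phi_of(coefs_p)
        det_p = st.lik.det_cache(phi_p)
        log_b1_p, cell_p = st.lik.loglik_cell(st.lam, det_p, st.psi)
    sd = st.sigma[d]
    s2h = st.spec.hyper_sd_scale ** 2
    prior_sd = 1.0 / np.sqrt(st.spec.prior_precision)
    dlp = (cell_p.sum() - st.cell.sum()
           + _norm_lp(mu_p, 0.0, prior_sd) - _norm_lp(st.mu[d], 0.0, prior_sd)
           - 0.5 * ((c * sd) ** 2 - sd ** 2) / s2h + eps)
    acc = bool(np.log(rng.random()) < dlp)
    if acc:
        st.coefs = coefs_p
        st.mu[d] = mu_p
        st.log_sigma[d] += eps
        if det_p is None:
            st.lam = lam_p
        else:
            st.phi = phi_p
            st.det = det_p
        st.log_b1 = log_b1_p
        st.cell = cell_p
    adapter.record(d, acc)


def _ncp_sigma_slice(st: _ChainState, rng: np.random.Generator,
                     d: int) -> None:
    """Non-centered slice draw of one hyper log-sd.

    Holding the standardized residuals z = (coef - mu)/sigma fixed, the
    conditional density of log sigma is the likelihood at mu + sigma z times
    the half-Normal prior (the species-prior ratio cancels against the
    rescaling Jacobian). A slice draw from it can cross the whole sigma
    range in one update, which is what frees chains from the sigma -> 0
    funnel that random-walk scale moves escape only diffusively.
    """
    sigma_d = max(st.sigma[d], 1e-12)
    z = (st.coefs[:, d] - st.mu[d]) / sigma_d
    s2h = st.spec.hyper_sd_scale ** 2
    cache: dict[float, tuple] = {}

    def logp(ls):
        if ls in cache:
            return cache[ls][0]
        sd = np.exp(ls)
        coefs_p = st.coefs.copy()
        coefs_p[:, d] = st.mu[d] + sd * z
        if d < 1 + st.P:
            lam_p = st.lam_of(coefs_p, st.gamma)
            phi_p, det_p = st.phi, st.det
            log_b1_p, cell_p = st.lik.loglik_cell(lam_p, st.det, st.psi)
        else:
            lam_p = st.lam
            phi_p = st.phi_of(coefs_p)
            det_p = st.lik.det_cache(phi_p)
            log_b1_p, cell_p = st.lik.loglik_cell(st.lam, det_p, st.psi)
        val = cell_p.sum() - 0.5 * sd * sd / s2h + ls
        cache[ls] = (val, coefs_p, lam_p, phi_p, det_p, log_b1_p, cell_p)
        return val

    ls0 = st.log_sigma[d]
    ls_new = _slice_1d(logp, ls0, rng, w=1.5, max_steps=6)
    if ls_new != ls0 and ls_new in cache:
        _, coefs_p, lam_p, phi_p, det_p, log_b1_p, cell_p = cache[ls_new]
        st.log_sigma[d] = float(ls_new)
        st.coefs = coefs_p
        st.lam = lam_p
        st.phi = phi_p
        st.det = det_p
        st.log_b1 = log_b1_p
        st.cell = cell_p


def _mu_gibbs(st: _ChainState, rng: np.random.Generator) -> None:
    S = st.coefs.shape[0]
    var = st.sigma ** 2
    prec = st.spec.prior_precision + S / var
    mean = (st.coefs.sum(axis=0) / var) / prec
    st.mu = mean + rng.standard_normal(st.D) / np.sqrt(prec)


def _slice_1d(logp, x0, rng, w=1.0, max_steps=30):
    """Univariate slice sampler with stepping out (Neal 2003)."""
    ly = logp(x0) + np.log(rng.random())
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(max_steps):
        if logp(lo) < ly:
            break
        lo -= w
    for _ in range(max_steps):
        if logp(hi) < ly:
            break
        hi += w
    for _ in range(100):
        x = lo + (hi - lo) * rng.random()
        if logp(x) >= ly:
            return x
        if x < x0:
            lo = x
        else:
            hi = x
    return x0


def _slice_log_sd(ls0, n, sse, prior_scale_sq, rng):
    """Slice draw of a log-sd whose conditional depends only on the count
    and sum of squared residuals (pure-scalar target)."""
    import math

    def logp(ls):
        v = math.exp(2.0 * ls)
        return -n * ls - sse / (2.0 * v) - 0.5 * v / prior_scale_sq + ls

    return _slice_1d(logp, ls0, rng)


def _sigma_update(st: _ChainState, rng: np.random.Generator) -> None:
    """Slice-sample each hyper log-sd given its column of species
    coefficients."""
    sse = ((st.coefs - st.mu[None, :]) ** 2).sum(axis=0)
    S = st.coefs.shape[0]
    s2h = st.spec.hyper_sd_scale ** 2
    for d in range(st.D):
        st.log_sigma[d] = _slice_log_sd(st.log_sigma[d], S, float(sse[d]),
                                        s2h, rng)


def _sigma_site_update(st: _ChainState, rng: np.random.Generator) -> None:
    if len(st.gamma) == 0:
        sse = 0.0
    else:
        sse = float((st.gamma ** 2).sum())
    st.log_sigma_site = float(_slice_log_sd(
        st.log_sigma_site, len(st.gamma), sse,
        st.spec.site_sd_scale ** 2, rng))


def _param_names(data: ModelData) -> dict[str, list[str]]:
    hyper_mu = (["mu_beta0"] + [f"mu_beta[{c}]" for c in data.abundance_covs]
                + ["mu_alpha0"] + [f"mu_alpha[{c}]" for c in data.detection_covs])
    hyper_sd = [n.replace("mu_", "sigma_") for n in hyper_mu]
    coef = []
    for s in data.species:
        coef.append(f"beta0[{s}]")
        coef += [f"beta[{s},{c}]" for c in data.abundance_covs]
        coef.append(f"alpha0[{s}]")
        coef += [f"alpha[{s},{c}]" for c in data.detection_covs]
    return {
        "hyper_mu": hyper_mu,
        "hyper_sd": hyper_sd,
        "coef": coef,
        "psi": [f"psi[{s}]" for s in data.species],
        "gamma": [f"gamma[{s}]" for s in data.site_ids],
    }


def default_monitor(data: ModelData) -> tuple[str, ...]:
    """Community-level parameters whose convergence is checked by default."""
    names = _param_names(data)
    return tuple(names["hyper_mu"] + names["hyper_sd"] + ["sigma_site"])


def run_mcmc(data: ModelData, spec: ModelSpec = ModelSpec(),
             config: McmcConfig = McmcConfig(),
             max_init_retries: int = 10) -> PosteriorDraws:
    """Sample the posterior; fully reproducible under a fixed config seed."""
    lik = MarginalLikelihood(data, spec)
    names = _param_names(data)
    all_names = (names["hyper_mu"] + names["hyper_sd"] + ["sigma_site"]
                 + names["coef"] + names["psi"] + names["gamma"])
    n_keep = config.n_draws_per_chain
    store = {n: np.empty((config.n_chains, n_keep)) for n in all_names}

    S = data.n_species
    for chain in range(config.n_chains):
        rng = np.random.default_rng([int(config.seed), chain])
        st = None
        for _ in range(max_init_retries):
            st = _ChainState(data, spec, lik, rng)
            if st.finite():
                break
        else:
            raise RuntimeError("could not find a finite starting point; "
                               "check counts and covariates for anomalies")

        ab = _VectorBlocks(S, 1 + st.P)
        det = _VectorBlocks(S, 1 + st.Q)
        icpt = _VectorBlocks(S, 3, init_scale=0.15)
        psi_ad = _ScalarBatch(S)
        gam_ad = _ScalarBatch(data.n_sites, init_scale=0.1)
        trans_ad = _ScalarBatch(2, init_scale=0.3)
        rec_ad = _VectorBlocks(1, st.D, init_scale=0.1)
        col_ad = _ColumnAdapter(st.D)
        colsp_ad = _ColumnAdapter(st.D, target=0.44)

        kept = 0
        for it in range(config.n_iterations):
            # slope blocks alternate (slopes are well identified and mix
            # easily); the intercept ridge block runs every iteration
            if it % 2 == 0:
                _coef_block_update(st, st.sl_ab, ab, rng, is_abundance=True)
            else:
                _coef_block_update(st, st.sl_det, det, rng,
                                   is_abundance=False)
            _intercept_update(st, icpt, rng)
            _psi_update(st, psi_ad, rng)
            _gamma_update(st, gam_ad, rng)
            _translation_updates(st, trans_ad, rng)
            _recenter_update(st, rec_ad, rng)
            for j in range(2 * it, 2 * it + 2):
                _column_hyper_update(st, col_ad, rng, j)
                _column_species_update(st, colsp_ad, rng, j)
            if it % 2 == 0:
                # weighted rotation: the site-confounded treatment column
                # and the two ridge-bound intercepts funnel hardest, so
                # they get slice draws several times more often
                turn = it // 2
                if turn % 2 == 0:
                    d = st.slow_cols[(turn // 2) % len(st.slow_cols)]
                else:
                    d = (turn // 2) % st.D
                _ncp_sigma_slice(st, rng, d)
            _mu_gibbs(st, rng)
            if it % 2 == 0:
                _sigma_update(st, rng)
                _sigma_site_update(st, rng)

            burnin = it < config.n_burnin
            if burnin and (it + 1) % _ADAPT_EVERY == 0:
                for a in (ab, det, icpt, psi_ad, gam_ad, trans_ad, rec_ad,
                          col_ad, colsp_ad):
                    a.adapt()
            if not burnin and (it - config.n_burnin) % config.thin == 0 \
                    and kept < n_keep:
                row = np.concatenate((st.mu, np.exp(st.log_sigma),
                                      [st.sigma_site],
                                      st.coefs.reshape(-1), st.psi, st.gamma))
                for n, v in zip(all_names, row):
                    store[n][chain, kept] = v
                kept += 1

    meta = {
        "species": list(data.species),
        "abundance_covs": list(data.abundance_covs),
        "detection_covs": list(data.detection_covs),
        "site_ids": list(data.site_ids),
        "data_fingerprint": hashlib.sha256(
            np.ascontiguousarray(data.y).tobytes()).hexdigest()[:16],
        "seed": int(config.seed),
    }
    return PosteriorDraws(params=store, config=config, meta=meta)


# ---------------------------------------------------------------------------
# diagnostics and summaries


def gelman_rubin(draws: PosteriorDraws | Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Potential scale reduction factor per parameter.

    Classic between/within variance form: with m chains of length n,
    W = mean within-chain variance, B/n = variance of chain means, and
    R-hat = sqrt(((n-1)/n W + B/n) / W). Chains with zero within-chain
    variance everywhere are flagged degenerate rather than raising.
    """
    params = draws.params if isinstance(draws, PosteriorDraws) else dict(draws)
    rows = {}
    for name, arr in params.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValueError("gelman_rubin needs >= 2 chains per parameter")
        m, n = arr.shape
        if n < 10:
            raise ValueError("gelman_rubin needs >= 10 draws per chain")
        w = arr.var(axis=1, ddof=1).mean()
        b_over_n = arr.mean(axis=1).var(ddof=1)
        if w == 0:
            rows[name] = (np.nan, True)
            continue
        vhat = (n - 1) / n * w + b_over_n
        rows[name] = (float(np.sqrt(vhat / w)), False)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["rhat", "degenerate"])
    out.index.name = "parameter"
    return out


def summarize(draws: PosteriorDraws, names: Sequence[str] | None = None,
              ci: float = 0.95) -> pd.DataFrame:
    """Pooled-chain posterior mean, equal-tailed interval, significance flag
    (interval excludes 0), and R-hat per parameter."""
    names = list(names) if names is not None else draws.names
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rh = (gelman_rubin({n: draws.get(n) for n in names})
          if draws.n_chains >= 2 else None)
    rows = []
    for n in names:
        x = draws.pooled(n)
        lo, hi = np.quantile(x, [lo_q, hi_q])
        rows.append({
            "parameter": n, "mean": float(x.mean()),
            "lower": float(lo), "upper": float(hi),
            "significant": bool(lo > 0 or hi < 0),
            "rhat": float(rh.loc[n, "rhat"]) if rh is not None else np.nan,
        })
    return pd.DataFrame(rows).set_index("parameter")


def species_params_from_draw(draws: PosteriorDraws, idx: int) -> SpeciesParams:
    """Reconstruct a SpeciesParams object from one pooled draw index."""
    sp = draws.meta["species"]
    ac = tuple(draws.meta["abundance_covs"])
    dc = tuple(draws.meta["detection_covs"])
    sites = draws.meta["site_ids"]

    def v(name):
        return draws.pooled(name)[idx]

    return SpeciesParams(
        species=tuple(sp), abundance_covs=ac, detection_covs=dc,
        beta0=np.array([v(f"beta0[{s}]") for s in sp]),
        beta=np.array([[v(f"beta[{s},{c}]") for c in ac] for s in sp]),
        alpha0=np.array([v(f"alpha0[{s}]") for s in sp]),
        alpha=np.array([[v(f"alpha[{s},{c}]") for c in dc] for s in sp]),
        psi=np.array([v(f"psi[{s}]") for s in sp]),
        gamma=np.array([v(f"gamma[{t}]") for t in sites]),
    )
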