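"""Zero-inflated hierarchical community N-mixture likelihood and priors.

The observation model per species i, point j, year r is

    a_ijr ~ Bernoulli(psi_i)                      (inclusion / zero-inflation)
    M_ijr | a ~ Poisson(a_ijr * lambda_ijr)       (latent abundance)
    y_ijrv ~ Binomial(M_ijr, phi_ijrv)            (visit counts, v = 1..V)

with log(lambda) = beta0_i + beta_i . x_jr + gamma_site and
logit(phi) = alpha0_i + alpha_i . v_jrv. Both latent variables are
marginalized exactly: the Bernoulli by a two-term mixture and the Poisson by
a truncated sum over M with an adaptive tail rule, which leaves a smooth
likelihood in the continuous parameters that any sampler can use.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import binom, halfnorm, norm, poisson

from numba import njit

from .design import ABUNDANCE_COVS, DETECTION_COVS, DEFAULT_SUITE_MAP
from .synth import CountTable, CovariateTable, SpeciesParams

__all__ = [
    "ModelSpec", "ModelData", "MarginalLikelihood",
    "linear_abundance", "linear_detection", "choose_truncation",
    "site_year_marginal_loglik", "total_loglik", "log_prior", "predictors",
]

_PHI_EPS = 1e-12


@dataclass(frozen=True)
class ModelSpec:
    """Covariate sets, priors, and truncation rule for the community model.

    Fixed-effect hyper-means get vague Normal(0, precision 0.001) priors;
    hyper standard deviations and the site-effect scale get half-Normal
    priors (weakly informative; the source analysis left these unstated);
    zero-inflation probabilities get a Beta prior, flat by default.
    """

    abundance_covs: tuple[str, ...] = ABUNDANCE_COVS
    detection_covs: tuple[str, ...] = DETECTION_COVS
    prior_precision: float = 0.001
    hyper_sd_scale: float = 2.0
    site_sd_scale: float = 2.0
    psi_prior: tuple[float, float] = (1.0, 1.0)
    k_cap: int = 300
    tail_eps: float = 1e-8
    lam_cap: float | None = None
    suite_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SUITE_MAP))

    def __post_init__(self) -> None:
        if self.prior_precision <= 0:
            raise ValueError("prior_precision must be > 0")
        if self.hyper_sd_scale <= 0 or self.site_sd_scale <= 0:
            raise ValueError("prior scales must be > 0")
        if min(self.psi_prior) <= 0:
            raise ValueError("psi_prior parameters must be > 0")
        if self.k_cap < 1:
            raise ValueError("k_cap must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["abundance_covs"] = list(self.abundance_covs)
        d["detection_covs"] = list(self.detection_covs)
        d["psi_prior"] = list(self.psi_prior)
        d["suite_map"] = dict(self.suite_map)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        for k in ("abundance_covs", "detection_covs", "psi_prior"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# linear predictors


def linear_abundance(beta0: float, beta_cov: Sequence[float],
                     x: Sequence[float], gamma: float = 0.0) -> float:
    """Expected abundance lambda = exp(beta0 + beta . x + gamma)."""
    eta = float(beta0) + float(np.dot(beta_cov, x)) + float(gamma)
    lam = np.exp(eta)
    if not np.isfinite(lam):
        raise FloatingPointError(f"non-finite abundance (predictor {eta})")
    return float(lam)


def linear_detection(alpha0: float, alpha_cov: Sequence[float],
                     v: Sequence[float]) -> float:
    """Per-visit detection rate, inverse-logit of the linear predictor."""
    zeta = float(alpha0) + float(np.dot(alpha_cov, v))
    if not np.isfinite(zeta):
        raise FloatingPointError(f"non-finite detection predictor {zeta}")
    return float(expit(zeta))


# ---------------------------------------------------------------------------
# marginalized cell likelihood (reference scalar implementation)


def choose_truncation(ymax: int, lam: float, tail_eps: float = 1e-8,
                      k_cap: int = 300) -> int:
    """Smallest M-sum upper bound whose Poisson(lam) tail mass is below
    ``tail_eps``, at least the largest observed count, capped at ``k_cap``."""
    tail = int(poisson.isf(tail_eps, lam)) + 1
    return max(int(ymax), min(tail, k_cap))


def site_year_marginal_loglik(y: Sequence[int], psi: float, lam: float,
                              phi, K: int | None = None,
                              tail_eps: float = 1e-8,
                              k_cap: int = 300) -> float:
    """Log-likelihood of one species x point x year cell with the inclusion
    indicator and latent abundance summed out:

        log[(1 - psi) 1{all y = 0}
            + psi sum_{M >= max(y)}^{K} Pois(M; lam) prod_v Bin(y_v; M, phi_v)]
    """
    y = np.asarray(y, dtype=int)
    if np.any(y < 0):
        raise ValueError("negative counts are invalid")
    phi = np.broadcast_to(np.asarray(phi, dtype=float), y.shape)
    if not 0 <= psi <= 1:
        raise ValueError(f"psi must be in [0, 1], got {psi}")
    if not (np.isfinite(lam) and lam > 0):
        raise ValueError(f"lam must be positive and finite, got {lam}")
    ymax = int(y.max(initial=0))
    auto = K is None
    if auto:
        K = choose_truncation(ymax, lam, tail_eps, k_cap)
    if K < ymax:
        raise ValueError(f"truncation K={K} below max observed count {ymax}")

    def _chunk(lo, hi):
        m = np.arange(lo, hi + 1)
        logw = poisson.logpmf(m, lam)
        for yv, pv in zip(y, phi):
            logw = logw + binom.logpmf(yv, m, pv)
        return logsumexp(logw)

    log_b1 = _chunk(ymax, K)
    if auto:
        # extend until the log-likelihood itself has stabilized, so results
        # are insensitive (< 1e-10) to any further increase of K
        while K < k_cap:
            ext = _chunk(K + 1, min(K + 40, k_cap))
            new = np.logaddexp(log_b1, ext)
            K = min(K + 40, k_cap)
            if new - log_b1 < 1e-12:
                log_b1 = new
                break
            log_b1 = new

    allzero = ymax == 0
    if psi == 0:
        return 0.0 if allzero else -np.inf
    if psi == 1:
        return float(log_b1)
    branch0 = np.log1p(-psi) if allzero else -np.inf
    return float(np.logaddexp(branch0, np.log(psi) + log_b1))


# ---------------------------------------------------------------------------
# full-data containers and vectorized likelihood


@dataclass
class ModelData:
    """Count and design arrays in cell-major layout.

    Cells index point x year combinations; ``y`` is (S, C, V), ``x`` the
    abundance design matrix (C, P), ``v`` the visit design array (C, V, Q),
    and ``site_idx`` maps cells to site random effects.
    """

    species: tuple[str, ...]
    y: np.ndarray
    x: np.ndarray
    v: np.ndarray
    site_idx: np.ndarray
    site_ids: tuple[str, ...]
    point_of_cell: np.ndarray
    year_of_cell: np.ndarray
    abundance_covs: tuple[str, ...] = ABUNDANCE_COVS
    detection_covs: tuple[str, ...] = DETECTION_COVS
    scale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        S, C, V = self.y.shape
        if self.x.shape != (C, len(self.abundance_covs)):
            raise ValueError("x shape does not match cells x abundance covariates")
        if self.v.shape != (C, V, len(self.detection_covs)):
            raise ValueError("v shape does not match cells x visits x detection covariates")
        if self.site_idx.shape != (C,):
            raise ValueError("site_idx must have one entry per cell")
        if np.any(self.y < 0):
            raise ValueError("negative counts")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_cells(self) -> int:
        return self.y.shape[1]

    @property
    def n_visits(self) -> int:
        return self.y.shape[2]

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def points(self) -> np.ndarray:
        """Unique point ids, in first-appearance cell order."""
        return pd.unique(self.point_of_cell)

    @classmethod
    def from_tables(cls, counts: CountTable | pd.DataFrame,
                    covariates: CovariateTable,
                    abundance_covs: Sequence[str] = ABUNDANCE_COVS,
                    detection_covs: Sequence[str] = DETECTION_COVS,
                    species: Sequence[str] | None = None) -> "ModelData":
        from .prep import standardize_table

        cdf = counts.counts if isinstance(counts, CountTable) else counts
        cov = covariates
        need_z = [c for c in abundance_covs if c != "treatment"]
        if not all(f"{c}_z" in cov.points.columns for c in need_z):
            cov = standardize_table(cov)

        pts = cov.points.reset_index(drop=True)
        vis = cov.visits.reset_index(drop=True)
        cells = pts[["point", "year"]].copy()
        cells["_cell"] = np.arange(len(cells))

        if species is None:
            species = tuple(pd.unique(cdf["species"]))
        else:
            species = tuple(species)
        visits = np.sort(pd.unique(cdf["visit"]))
        V, C, S = len(visits), len(cells), len(species)

        merged = cdf.merge(cells, on=["point", "year"], how="left",
                           validate="many_to_one")
        if merged["_cell"].isna().any():
            bad = merged.loc[merged["_cell"].isna(), ["point", "year"]].iloc[0]
            raise ValueError(f"count row has no covariate record: "
                             f"point {bad['point']} year {bad['year']}")
        y = np.zeros((S, C, V), dtype=int)
        sidx = {s: i for i, s in enumerate(species)}
        vidx = {v: i for i, v in enumerate(visits)}
        rows = merged[merged["species"].isin(sidx)]
        y[[sidx[s] for s in rows["species"]],
          rows["_cell"].to_numpy(int),
          [vidx[v] for v in rows["visit"]]] = rows["count"].to_numpy(int)

        xcols = [pts["treatment"].to_numpy(float) if c == "treatment"
                 else pts[f"{c}_z"].to_numpy(float) for c in abundance_covs]
        x = np.column_stack(xcols)

        vm = vis.merge(cells, on=["point", "year"], how="left",
                       validate="many_to_one")
        if vm["_cell"].isna().any():
            raise ValueError("visit covariate row has no point x year record")
        varr = np.zeros((C, V, len(detection_covs)))
        ci = vm["_cell"].to_numpy(int)
        vi = np.array([vidx[v] for v in vm["visit"]])
        for q, c in enumerate(detection_covs):
            col = (vm["date_z"].to_numpy(float) ** 2 if c == "date2"
                   else vm[f"{c}_z"].to_numpy(float))
            varr[ci, vi, q] = col

        site_ids = tuple(pd.unique(pts["site"]))
        site_lookup = {s: i for i, s in enumerate(site_ids)}
        site_idx = np.array([site_lookup[s] for s in pts["site"]])

        return cls(species=species, y=y, x=x, v=varr, site_idx=site_idx,
                   site_ids=site_ids,
                   point_of_cell=pts["point"].to_numpy(),
                   year_of_cell=pts["year"].to_numpy(int),
                   abundance_covs=tuple(abundance_covs),
                   detection_covs=tuple(detection_covs),
                   scale=dict(cov.scale))


def predictors(data: ModelData, params: SpeciesParams) -> tuple[np.ndarray, np.ndarray]:
    """lambda (S, C) and phi (S, C, V) implied by species parameters."""
    eta = (params.beta0[:, None] + params.beta @ data.x.T
           + params.gamma[data.site_idx][None, :])
    lam = np.exp(np.clip(eta, -700, 700))
    zeta = params.alpha0[:, None, None] + np.einsum(
        "sq,cvq->scv", params.alpha, data.v)
    return lam, expit(zeta)


@njit(cache=True)
def _nz_grid_loglik(lam, a, t1, base, off, k_arr, cap, out):  # pragma: no cover
    """Per observed cell: log sum_{M} exp(base[M] + a*M) - lam + t1.

    ``base`` holds the count-dependent constants (binomial coefficients
    minus M!) flattened over cells; ``a = log(lam) + sum_v log(1-phi_v)``.
    Rates above the cell's truncation cap evaluate to -inf (rejection).
    """
    for n in range(lam.shape[0]):
        if lam[n] > cap[n]:
            out[n] = -np.inf
            continue
        o = off[n]
        an = a[n]
        wmax = -np.inf
        for m in range(k_arr[n] + 1):
            w = base[o + m] + an * m
            if w > wmax:
                wmax = w
        s = 0.0
        for m in range(k_arr[n] + 1):
            s += np.exp(base[o + m] + an * m - wmax)
        out[n] = t1[n] + wmax + np.log(s) - lam[n]


@njit(cache=True, fastmath=True)
def _det_terms(phi, grid_idx, y_nz, s2, t1):  # pragma: no cover
    """Detection-dependent constants in one pass: s2 = sum_v log(1-phi) per
    cell and t1 = sum_v y_v logit(phi_v) per observed cell."""
    S, C, V = phi.shape
    lo, hi = 1e-12, 1.0 - 1e-12
    for s in range(S):
        for c in range(C):
            acc = 0.0
            n = grid_idx[s, c]
            tt = 0.0
            for v in range(V):
                p = phi[s, c, v]
                if p < lo:
                    p = lo
                elif p > hi:
                    p = hi
                l1mp = np.log1p(-p)
                acc += l1mp
                if n >= 0 and y_nz[n, v] > 0.0:
                    tt += y_nz[n, v] * (np.log(p) - l1mp)
            s2[s, c] = acc
            if n >= 0:
                t1[n] = tt


@njit(cache=True, fastmath=True)
def _fused_cell_loglik(lam, s2, lp, l1mp, grid_idx, t1, base, off, k_arr,
                       ymax_nz, cap, log_b1, cell):  # pragma: no cover
    """One pass over all species x cells: inclusion-branch log-likelihood
    (closed form for all-zero cells, truncated grid otherwise) and the
    zero-inflation mixture, written into ``log_b1`` and ``cell``."""
    S, C = lam.shape
    for s in range(S):
        for c in range(C):
            n = grid_idx[s, c]
            if n < 0:
                b1 = -lam[s, c] * (1.0 - np.exp(s2[s, c]))
                log_b1[s, c] = b1
                x = l1mp[s]
                y = lp[s] + b1
                if x == -np.inf and y == -np.inf:
                    cell[s, c] = -np.inf
                elif x > y:
                    cell[s, c] = x + np.log1p(np.exp(y - x))
                else:
                    cell[s, c] = y + np.log1p(np.exp(x - y))
            else:
                if lam[s, c] > cap[n]:
                    log_b1[s, c] = -np.inf
                    cell[s, c] = -np.inf
                    continue
                o = off[n]
                a = np.log(lam[s, c]) + s2[s, c]
                wmax = -np.inf
                total = 0.0
                wprev = -np.inf
                # the summand is unimodal in M: once past the peak and 36
                # log-units below it, the remaining tail is negligible
                for m in range(ymax_nz[n], k_arr[n] + 1):
                    w = base[o + m] + a * m
                    if w <= wmax:
                        total += np.exp(w - wmax)
                        if w < wprev and w < wmax - 36.0:
                            break
                    else:
                        total = total * np.exp(wmax - w) + 1.0
                        wmax = w
                    wprev = w
                b1 = t1[n] + wmax + np.log(total) - lam[s, c]
                log_b1[s, c] = b1
                cell[s, c] = lp[s] + b1


def _max_lam_for_k(K: int, tail_eps: float) -> float:
    """Largest Poisson rate whose mass above K stays below ``tail_eps``."""
    lo, hi = 0.0, float(K) + 1.0
    while poisson.sf(K, hi) < tail_eps:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if poisson.sf(K, mid) < tail_eps:
            lo = mid
        else:
            hi = mid
    return lo


class MarginalLikelihood:
    """Vectorized marginal log-likelihood over all species x cell entries.

    All-zero cells (the bulk of a zero-inflated dataset) use the exact
    identity  sum_M Pois(M; lam) prod_v (1-phi_v)^M = exp(-lam (1 - q))
    with q = prod_v (1-phi_v), valid for any lambda. Cells with observed
    counts are grouped into buckets by their largest count; each bucket
    carries a truncated M-grid whose upper bound keeps the Poisson tail
    mass below ``tail_eps`` for rates up to a generous cap (proposals
    beyond the cap evaluate to -inf, i.e. are rejected).
    """

    #: cap on plausible lambda relative to a cell's largest count; generous
    #: enough for per-visit detection rates down to ~0.08
    _CAP_MULT = 12.0
    _CAP_MIN = 25.0

    def __init__(self, data: ModelData, spec: ModelSpec = ModelSpec()):
        self.data = data
        self.spec = spec
        y = data.y
        self.ymax = y.max(axis=2) if y.size else np.zeros(y.shape[:2], int)
        self.allzero = self.ymax == 0

        nz_s, nz_c = np.nonzero(~self.allzero)
        ymax_nz = self.ymax[nz_s, nz_c]
        # bucket observed cells by max count: (1,2], (2,4], (4,8], ...
        levels = np.ceil(np.log2(np.maximum(ymax_nz, 1))).astype(int) \
            if len(ymax_nz) else np.array([], int)
        order = np.argsort(levels, kind="stable")
        self.nz_s, self.nz_c = nz_s[order], nz_c[order]
        self.y_nz = y[self.nz_s, self.nz_c].astype(float)     # (N, V)
        levels = levels[order]

        # bucket truncation bounds, then merge buckets that end up with the
        # same grid size
        ks, caps = [], []
        for lev in np.unique(levels):
            yb_max = int(self.y_nz[levels == lev].max())
            cap = (spec.lam_cap if spec.lam_cap is not None
                   else max(self._CAP_MIN, self._CAP_MULT * yb_max))
            K = choose_truncation(yb_max, cap, spec.tail_eps, spec.k_cap)
            if K < yb_max:
                raise ValueError(f"k_cap {spec.k_cap} below max observed "
                                 f"count {yb_max}")
            # if the configured cap on K bites, shrink the rate cap to match
            ks.append(K)
            caps.append(min(cap, _max_lam_for_k(K, spec.tail_eps)))
        cell_k = np.zeros(len(levels), int)
        cell_cap = np.zeros(len(levels))
        for lev, K, cap in zip(np.unique(levels), ks, caps):
            cell_k[levels == lev] = K
            cell_cap[levels == lev] = cap

        # flat per-cell grids for the numba kernel
        self.K = int(cell_k.max(initial=0))
        N = len(levels)
        self.cell_k = cell_k.astype(np.int64)
        self.cell_cap = cell_cap
        self.offsets = np.zeros(N, dtype=np.int64)
        if N:
            self.offsets[1:] = np.cumsum(cell_k[:-1] + 1)
        self.base = np.empty(int((cell_k + 1).sum()), dtype=float)
        for n in range(N):
            K = int(cell_k[n])
            yb = self.y_nz[n]                                  # (V,)
            m = np.arange(K + 1, dtype=float)
            glm = gammaln(m + 1)
            diff = m[None, :] - yb[:, None]                    # (V, K+1)
            valid = diff >= 0
            logc = (glm[None, :]
                    - gammaln(np.where(valid, diff, 0) + 1.0)
                    - gammaln(yb + 1.0)[:, None])
            logcsum = np.where(valid, logc, -np.inf).sum(axis=0)
            self.base[self.offsets[n]:self.offsets[n] + K + 1] = logcsum - glm

        self.grid_idx = np.full(y.shape[:2], -1, dtype=np.int64)
        if N:
            self.grid_idx[self.nz_s, self.nz_c] = np.arange(N)
        self.ymax_nz = self.y_nz.max(axis=1).astype(np.int64) if N \
            else np.zeros(0, dtype=np.int64)

    def det_cache(self, phi: np.ndarray):
        """Detection-dependent terms reused while phi is unchanged."""
        S, C = phi.shape[:2]
        s2 = np.empty((S, C))
        t1 = np.empty(len(self.nz_s))
        _det_terms(np.ascontiguousarray(phi), self.grid_idx, self.y_nz,
                   s2, t1)
        return [s2, None, t1]

    def components_cached(self, lam: np.ndarray, cache) -> np.ndarray:
        """log of the inclusion branch, sum_M Pois * prod_v Binom, per cell."""
        s2, _, t1 = cache
        # exact all-zero identity, overwritten below for observed cells
        log_b1 = -lam * (1.0 - np.exp(s2))
        if len(self.nz_s) == 0:
            return log_b1
        lam_nz = np.ascontiguousarray(lam[self.nz_s, self.nz_c])
        a = np.log(lam_nz) + s2[self.nz_s, self.nz_c]
        out = np.empty(len(lam_nz))
        _nz_grid_loglik(lam_nz, a, t1, self.base, self.offsets,
                        self.cell_k, self.cell_cap, out)
        log_b1[self.nz_s, self.nz_c] = out
        return log_b1

    def components(self, lam: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return self.components_cached(lam, self.det_cache(phi))

    def loglik_cell(self, lam: np.ndarray, cache, psi: np.ndarray):
        """Fused fast path: (inclusion-branch log_b1, mixed cell loglik)."""
        psi = np.asarray(psi, dtype=float)
        with np.errstate(divide="ignore"):
            lp = np.log(psi)
            l1mp = np.log1p(-psi)
        log_b1 = np.empty_like(lam)
        cell = np.empty_like(lam)
        t1 = cache[2]
        _fused_cell_loglik(np.ascontiguousarray(lam),
                           np.ascontiguousarray(cache[0]), lp, l1mp,
                           self.grid_idx, t1, self.base, self.offsets,
                           self.cell_k, self.ymax_nz, self.cell_cap,
                           log_b1, cell)
        return log_b1, cell

    def assemble(self, log_b1: np.ndarray, psi: np.ndarray) -> np.ndarray:
        """Mix the inclusion branch with the structural-zero branch."""
        psi = np.asarray(psi, dtype=float)[:, None]
        with np.errstate(divide="ignore"):
            branch0 = np.where(self.allzero, np.log1p(-psi), -np.inf)
            return np.logaddexp(branch0, np.log(psi) + log_b1)

    def cell_loglik(self, lam: np.ndarray, phi: np.ndarray,
                    psi: np.ndarray) -> np.ndarray:
        return self.assemble(self.components(lam, phi), psi)

    def per_species(self, lam: np.ndarray, phi: np.ndarray,
                    psi: np.ndarray) -> np.ndarray:
        return self.cell_loglik(lam, phi, psi).sum(axis=1)


def total_loglik(data: ModelData, params: SpeciesParams,
                 spec: ModelSpec = ModelSpec()) -> float:
    """Sum of marginalized cell log-likelihoods over all species x cells."""
    if data.n_cells == 0:
        return 0.0
    lam, phi = predictors(data, params)
    lik = MarginalLikelihood(data, spec)
    total = lik.per_species(lam, phi, params.psi).sum()
    if np.isnan(total):
        bad = np.argwhere(np.isnan(lik.cell_loglik(lam, phi, params.psi)))
        s, c = bad[0]
        raise FloatingPointError(
            f"invalid likelihood for species {data.species[s]} at point "
            f"{data.point_of_cell[c]} year {data.year_of_cell[c]}")
    return float(total)


# ---------------------------------------------------------------------------
# priors


def log_prior(params: SpeciesParams, hyper, spec: ModelSpec = ModelSpec()) -> float:
    """Joint log-prior of the hierarchical parameter stack.

    Hyper-means: Normal(0, 1/prior_precision). Hyper-sds and the site
    scale: half-Normal. Species coefficients: Normal around their community
    means. psi: Beta. Site effects: Normal(0, sigma_site^2). Any
    non-positive scale where a positive one is required gives -inf.
    """
    mu_stack = np.concatenate((
        [hyper.mu_beta0], [hyper.mu_beta_cov[c] for c in params.abundance_covs],
        [hyper.mu_alpha0], [hyper.mu_alpha_cov[c] for c in params.detection_covs]))
    sd_stack = np.concatenate((
        [hyper.sigma_beta0], [hyper.sigma_beta_cov[c] for c in params.abundance_covs],
        [hyper.sigma_alpha0], [hyper.sigma_alpha_cov[c] for c in params.detection_covs]))
    if np.any(sd_stack <= 0) or hyper.sigma_site <= 0:
        return -np.inf

    prior_sd = 1.0 / np.sqrt(spec.prior_precision)
    lp = norm.logpdf(mu_stack, 0.0, prior_sd).sum()
    lp += halfnorm.logpdf(sd_stack, scale=spec.hyper_sd_scale).sum()
    lp += halfnorm.logpdf(hyper.sigma_site, scale=spec.site_sd_scale)

    coefs = np.column_stack((params.beta0, params.beta,
                             params.alpha0, params.alpha))   # (S, 2+P+Q)
    lp += norm.logpdf(coefs, mu_stack, sd_stack).sum()
    a, b = spec.psi_prior
    lp += beta_dist.logpdf(np.clip(params.psi, 1e-12, 1 - 1e-12), a, b).sum()
    lp += norm.logpdf(params.gamma, 0.0, hyper.sigma_site).sum()
    return float(lp)
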