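"""Derived posterior quantities: detection probability, zero-inflation,
presence/absence z-matrices, Jaccard co-occurrence with propagated
uncertainty, suite-level coefficient summaries, and natural-scale effect
translations."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .mcmc import PosteriorDraws

__all__ = [
    "detection_summary", "zero_inflation_summary", "ZMatrix",
    "build_z_matrix", "jaccard", "jaccard_posterior", "suite_summary",
    "rescale_effect",
]

COMMUNITY = "Community"


def _summary_rows(values: np.ndarray, labels: Sequence[str],
                  level: Sequence[str], ci: float = 0.95) -> pd.DataFrame:
    """Posterior mean + equal-tailed interval per column of (draws, k)."""
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    lo, hi = np.quantile(values, [lo_q, hi_q], axis=0)
    return pd.DataFrame({
        "label": list(labels), "level": list(level),
        "mean": values.mean(axis=0), "lower": lo, "upper": hi,
        "significant": (lo > 0) | (hi < 0),
    })


def _suite_groups(species: Sequence[str],
                  suite_map: Mapping[str, str]) -> dict[str, list[int]]:
    missing = [s for s in species if s not in suite_map]
    if missing:
        raise ValueError(f"species missing suite assignment: {missing}")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(species):
        groups.setdefault(suite_map[s], []).append(i)
    if any(len(ix) == 0 for ix in groups.values()):
        raise ValueError("empty suite")
    return groups


def _species_suite_community(per_species: np.ndarray, species: Sequence[str],
                             suite_map: Mapping[str, str]) -> pd.DataFrame:
    """Summarize a (draws, S) array at species, suite, and community level.

    Suite and community values are unweighted means over member species,
    taken per draw so the credible intervals propagate correctly.
    """
    groups = _suite_groups(species, suite_map)
    cols = [per_species]
    labels, levels = list(species), ["species"] * len(species)
    for suite, ix in groups.items():
        cols.append(per_species[:, ix].mean(axis=1, keepdims=True))
        labels.append(suite)
        levels.append("suite")
    cols.append(per_species.mean(axis=1, keepdims=True))
    labels.append(COMMUNITY)
    levels.append("community")
    return _summary_rows(np.hstack(cols), labels, levels)


def detection_summary(draws: PosteriorDraws,
                      suite_map: Mapping[str, str]) -> pd.DataFrame:
    """Detection probability P_d at mean covariate conditions.

    Detection covariates are centered, so the species intercept on the
    inverse-logit scale is the natural per-visit detection summary; suite
    and community rows are per-draw means over member species.
    """
    species = draws.meta["species"]
    alpha0 = draws.array_for([f"alpha0[{s}]" for s in species])
    return _species_suite_community(expit(alpha0), species, suite_map)


def zero_inflation_summary(draws: PosteriorDraws,
                           suite_map: Mapping[str, str]) -> pd.DataFrame:
    """Zero-inflation (inclusion) probability per species, suite, community."""
    species = draws.meta["species"]
    psi = draws.array_for([f"psi[{s}]" for s in species])
    return _species_suite_community(psi, species, suite_map)


# ---------------------------------------------------------------------------
# z-matrix and Jaccard


@dataclass
class ZMatrix:
    """Binary occupancy indicators per posterior draw.

    ``z`` has shape (draws, species, points); a species observed at a point
    (any positive count in any year/visit) is present in every draw.
    """

    z: np.ndarray
    species: tuple[str, ...]
    points: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.z.ndim != 3:
            raise ValueError("z must be (draws, species, points)")
        if not np.isin(self.z, (0, 1)).all():
            raise ValueError("z entries must be binary")


def conditional_absence_prob(psi, lam, q):
    """P(M = 0 | all visit counts zero) for one cell.

    With q = prod_v (1 - phi_v) the all-zero marginal is
    (1 - psi) + psi exp(-lam (1 - q)); the M = 0 share of it is
    (1 - psi) + psi exp(-lam).
    """
    num = (1 - psi) + psi * np.exp(-lam)
    den = (1 - psi) + psi * np.exp(-lam * (1 - q))
    return num / den


def build_z_matrix(draws: PosteriorDraws, data, rng_seed: int = 0,
                   max_draws: int = 250) -> ZMatrix:
    """Sample per-draw presence/absence from the latent-state conditionals.

    z = 1 at a point iff latent abundance is positive in at least one year
    there. Cells with observed counts force z = 1; all-zero cells draw
    absence from the exact conditional P(M = 0 | y = 0, params), multiplied
    across years.
    """
    from .mcmc import species_params_from_draw
    from .likelihood import predictors

    rng = np.random.default_rng(rng_seed)
    total = draws.n_chains * draws.n_draws
    if total > max_draws:
        use = np.linspace(0, total - 1, max_draws).astype(int)
    else:
        use = np.arange(total)

    points = tuple(pd.unique(data.point_of_cell))
    pt_index = {p: i for i, p in enumerate(points)}
    cell_pt = np.array([pt_index[p] for p in data.point_of_cell])
    S, C = data.n_species, data.n_cells
    observed = data.y.sum(axis=2) > 0                      # (S, C)

    # cell -> point aggregation as a one-hot indicator matrix
    ind = np.zeros((C, len(points)))
    ind[np.arange(C), cell_pt] = 1.0
    any_obs = (observed.astype(float) @ ind) > 0            # (S, points)

    z = np.zeros((len(use), S, len(points)), dtype=np.int8)
    for k, idx in enumerate(use):
        params = species_params_from_draw(draws, int(idx))
        lam, phi = predictors(data, params)
        q = np.prod(1 - phi, axis=2)
        p_abs = conditional_absence_prob(params.psi[:, None], lam, q)
        p_abs = np.where(observed, 0.0, p_abs)
        # absent at a point iff absent in every year there
        log_p_point = np.log(np.clip(p_abs, 1e-300, 1.0)) @ ind
        p_absent_point = np.where(any_obs, 0.0, np.exp(log_p_point))
        z[k] = (rng.random((S, len(points))) >= p_absent_point).astype(np.int8)
    return ZMatrix(z=z, species=tuple(data.species), points=points)


def jaccard(z_i: Sequence[int], z_j: Sequence[int]) -> float:
    """Jaccard co-occurrence J = |intersection| / |union| of occupied points.

    Returns NaN (flagged missing) when both species are absent everywhere,
    where the index is undefined.
    """
    zi = np.asarray(z_i)
    zj = np.asarray(z_j)
    if zi.shape != zj.shape:
        raise ValueError("z vectors must have equal length")
    if not (np.isin(zi, (0, 1)).all() and np.isin(zj, (0, 1)).all()):
        raise ValueError("z vectors must be binary")
    inter = int(np.sum((zi == 1) & (zj == 1)))
    union = int(np.sum((zi == 1) | (zj == 1)))
    if union == 0:
        return float("nan")
    return inter / union


def jaccard_posterior(zmat: ZMatrix, ci: float = 0.95) -> pd.DataFrame:
    """Per-pair posterior mean and CrI of J, computed per draw.

    Draws where a pair's union is empty are dropped from that pair's
    summary; ``n_dropped`` records how many.
    """
    z = zmat.z.astype(float)
    inter = np.einsum("dsp,dtp->dst", z, z)
    occ = z.sum(axis=2)
    union = occ[:, :, None] + occ[:, None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        j = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    rows = []
    S = len(zmat.species)
    for a in range(S):
        for b in range(a + 1, S):
            vals = j[:, a, b]
            ok = ~np.isnan(vals)
            if ok.sum() == 0:
                mean = lo = hi = np.nan
            else:
                mean = float(vals[ok].mean())
                lo, hi = np.quantile(vals[ok], [lo_q, hi_q])
            rows.append({
                "species_i": zmat.species[a], "species_j": zmat.species[b],
                "mean": mean, "lower": float(lo), "upper": float(hi),
                "n_dropped": int((~ok).sum()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# suite-level coefficients and natural-scale effects


def suite_summary(draws: PosteriorDraws,
                  suite_map: Mapping[str, str]) -> pd.DataFrame:
    """Suite- and community-level coefficient table.

    Suite coefficients are per-draw means of member species' coefficients
    (the community hyper-mean is reported from its own draws), summarized
    with 95% CrIs and the interval-excludes-zero significance flag.
    """
    species = draws.meta["species"]
    groups = _suite_groups(species, suite_map)
    rows = []
    coef_specs = ([("alpha0", "detection", "Intercept")]
                  + [(f"alpha[{{s}},{c}]", "detection", c)
                     for c in draws.meta["detection_covs"]]
                  + [("beta0", "abundance", "Intercept")]
                  + [(f"beta[{{s}},{c}]", "abundance", c)
                     for c in draws.meta["abundance_covs"]])
    for pattern, process, label in coef_specs:
        if pattern in ("alpha0", "beta0"):
            names = [f"{pattern}[{s}]" for s in species]
            hyper = f"mu_{pattern[:-1]}0"
        else:
            names = [pattern.format(s=s) for s in species]
            hyper = ("mu_" + pattern.split("[")[0]
                     + "[" + pattern.split(",")[1])
        per_sp = draws.array_for(names)
        blocks = {COMMUNITY: draws.pooled(hyper)}
        for suite, ix in groups.items():
            blocks[suite] = per_sp[:, ix].mean(axis=1)
        for group, vals in blocks.items():
            lo, hi = np.quantile(vals, [0.025, 0.975])
            rows.append({
                "process": process, "parameter": label, "group": group,
                "mean": float(vals.mean()), "lower": float(lo),
                "upper": float(hi), "significant": bool(lo > 0 or hi < 0),
            })
    return pd.DataFrame(rows)


def rescale_effect(beta_draws: np.ndarray, covariate_sd: float,
                   delta_raw: float, baseline_lambda_draws: np.ndarray) -> dict:
    """Expected abundance change for a raw-scale covariate shift.

    Per draw: delta_abundance = lambda_baseline * (exp(beta * delta_raw /
    covariate_sd) - 1), i.e. the change in expected birds per plot when the
    covariate moves by ``delta_raw`` in its field units.
    """
    if covariate_sd <= 0:
        raise ValueError("covariate_sd must be > 0")
    beta_draws = np.asarray(beta_draws, dtype=float)
    lam = np.broadcast_to(np.asarray(baseline_lambda_draws, dtype=float),
                          beta_draws.shape)
    delta = lam * (np.exp(beta_draws * delta_raw / covariate_sd) - 1.0)
    lo, hi = np.quantile(delta, [0.025, 0.975])
    return {"mean": float(delta.mean()), "lower": float(lo),
            "upper": float(hi), "draws": delta}
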