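"""Delimited-table I/O contracts and the pipeline configuration file."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .design import (PERCENT_COVS, CovariateRegime, SurveyDesign,
                     TruncNormSpec, pine_barrens_regime)
from .likelihood import ModelSpec
from .mcmc import McmcConfig, PosteriorDraws
from .synth import CommunityHyperparams, CountTable, CovariateTable

__all__ = ["read_counts", "write_counts", "read_covariates",
           "write_covariates", "read_suite_map", "write_draws", "read_draws",
           "PipelineConfig"]

COUNT_COLS = ["species", "site", "point", "year", "visit", "count"]
POINT_COLS = ["point", "site", "year", "treatment"]
VISIT_COLS = ["point", "site", "year", "visit", "date", "wind", "disturbance"]
REQUIRED_POINT_COVS = ["grass", "woody", "vor2", "basal"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns {missing}; "
                         f"required: {required}")


def read_counts(path) -> CountTable:
    """Read and validate a long-format survey count table."""
    df = pd.read_csv(path)
    _check_columns(df, COUNT_COLS, "count table")
    neg = df.index[df["count"] < 0]
    if len(neg):
        raise ValueError(f"negative count at row(s) {list(neg[:5])}")
    frac = df["count"] % 1 != 0
    if frac.any():
        raise ValueError(f"non-integer count at row(s) "
                         f"{list(df.index[frac][:5])}")
    key = ["species", "point", "year", "visit"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"duplicated survey row(s) at {list(df.index[dup][:5])}")
    df["count"] = df["count"].astype(int)
    return CountTable(counts=df)


def write_counts(counts: CountTable, path) -> None:
    counts.counts.to_csv(path, index=False)


def read_covariates(points_path, visits_path) -> CovariateTable:
    """Read and validate the point x year and visit covariate tables."""
    pts = pd.read_csv(points_path)
    _check_columns(pts, POINT_COLS + REQUIRED_POINT_COVS,
                   "point covariate table")
    for c in [c for c in pts.columns if c in PERCENT_COVS]:
        bad = pts.index[(pts[c] < 0) | (pts[c] > 100)]
        if len(bad):
            raise ValueError(f"{c} outside [0, 100] at row(s) {list(bad[:5])}")
    bad = pts.index[pts["basal"] < 0]
    if len(bad):
        raise ValueError(f"negative basal area at row(s) {list(bad[:5])}")
    vis = pd.read_csv(visits_path)
    _check_columns(vis, VISIT_COLS, "visit covariate table")
    return CovariateTable(points=pts, visits=vis)


def write_covariates(cov: CovariateTable, points_path, visits_path) -> None:
    cov.points.to_csv(points_path, index=False)
    cov.visits.to_csv(visits_path, index=False)


def read_suite_map(path) -> dict[str, str]:
    df = pd.read_csv(path)
    _check_columns(df, ["species", "suite"], "suite map")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in suite map")
    return dict(zip(df["species"], df["suite"]))


def write_draws(draws: PosteriorDraws, path) -> None:
    draws.to_frame().to_csv(path, index=False)


def read_draws(path, meta: dict | None = None) -> PosteriorDraws:
    return PosteriorDraws.from_frame(pd.read_csv(path), meta=meta)


# ---------------------------------------------------------------------------
# configuration


def _regime_to_dict(r: CovariateRegime) -> dict:
    def grp(g):
        return {c: [s.mean, s.sd, s.lower, s.upper] for c, s in g.items()}
    return {"control": grp(r.control), "treatment": grp(r.treatment),
            "season_length_days": r.season_length_days,
            "wind_range": list(r.wind_range),
            "disturbance_levels": r.disturbance_levels}


def _regime_from_dict(d: Mapping) -> CovariateRegime:
    def grp(g):
        return {c: TruncNormSpec(*vals) for c, vals in g.items()}
    return CovariateRegime(
        control=grp(d["control"]), treatment=grp(d["treatment"]),
        season_length_days=d.get("season_length_days", 86.0),
        wind_range=tuple(d.get("wind_range", (0.0, 15.0))),
        disturbance_levels=d.get("disturbance_levels", 5))


def _design_to_dict(ds: SurveyDesign) -> dict:
    return {"n_sites": ds.n_sites, "n_points": ds.n_points,
            "n_years": ds.n_years, "visits_per_year": ds.visits_per_year,
            "species": list(ds.species), "suite_map": dict(ds.suite_map),
            "site_sizes": list(ds.site_sizes),
            "treatment_sites": list(ds.treatment_sites)}


def _design_from_dict(d: Mapping) -> SurveyDesign:
    d = dict(d)
    for k in ("species", "site_sizes", "treatment_sites"):
        if k in d and d[k] is not None:
            d[k] = tuple(d[k])
    return SurveyDesign(**d)


def _hyper_to_dict(h: CommunityHyperparams) -> dict:
    return {"mu_beta0": h.mu_beta0, "sigma_beta0": h.sigma_beta0,
            "mu_beta_cov": dict(h.mu_beta_cov),
            "sigma_beta_cov": dict(h.sigma_beta_cov),
            "mu_alpha0": h.mu_alpha0, "sigma_alpha0": h.sigma_alpha0,
            "mu_alpha_cov": dict(h.mu_alpha_cov),
            "sigma_alpha_cov": dict(h.sigma_alpha_cov),
            "psi": dict(h.psi) if isinstance(h.psi, Mapping) else h.psi,
            "sigma_site": h.sigma_site}


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs: mode, design/regime/hyperparameters
    (simulation mode) or input paths (analysis mode), model spec, MCMC
    settings, and the global seed."""

    mode: str = "simulate"
    seed: int = 0
    design: SurveyDesign = field(default_factory=SurveyDesign)
    regime: CovariateRegime = field(default_factory=pine_barrens_regime)
    hyper: CommunityHyperparams | None = None
    spec: ModelSpec = field(default_factory=ModelSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    paths: dict = field(default_factory=dict)
    z_matrix_draws: int = 250

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError("mode must be 'simulate' or 'analyze'")
        if self.hyper is None:
            from .synth import default_hyperparams
            self.hyper = default_hyperparams()

    def validate(self) -> None:
        if self.mode == "analyze":
            required = ["counts", "covariates_points", "covariates_visits",
                        "suite_map"]
            missing = [k for k in required if k not in self.paths]
            if missing:
                raise ValueError(f"analysis mode requires paths for {missing}")
            absent = [k for k in required
                      if not Path(self.paths[k]).exists()]
            if absent:
                raise ValueError(
                    f"configured input files do not exist: "
                    f"{[self.paths[k] for k in absent]}")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode, "seed": self.seed,
            "design": _design_to_dict(self.design),
            "regime": _regime_to_dict(self.regime),
            "hyper": _hyper_to_dict(self.hyper),
            "spec": self.spec.to_dict(),
            "mcmc": {"n_chains": self.mcmc.n_chains,
                     "n_iterations": self.mcmc.n_iterations,
                     "n_burnin": self.mcmc.n_burnin,
                     "thin": self.mcmc.thin, "seed": self.mcmc.seed},
            "paths": dict(self.paths),
            "z_matrix_draws": self.z_matrix_draws,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "design" in d:
            d["design"] = _design_from_dict(d["design"])
        if "regime" in d:
            d["regime"] = _regime_from_dict(d["regime"])
        if "hyper" in d:
            d["hyper"] = CommunityHyperparams(**d["hyper"])
        if "spec" in d:
            d["spec"] = ModelSpec.from_dict(d["spec"])
        if "mcmc" in d:
            d["mcmc"] = McmcConfig(**d["mcmc"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
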