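"""Pre-modelling covariate steps: standardization, collinearity screening,
and treatment-vs-control group comparison."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import ABUNDANCE_COVS, DETECTION_COVS, REDUNDANT_COVS
from .synth import CovariateTable

__all__ = ["standardize", "back_transform", "standardize_table",
           "ScreenReport", "correlation_screen", "compare_groups",
           "DEFAULT_PRIORITY"]

#: Retention order for collinearity screening: basal area first (the routine
#: forest-management measurement), then the groundcover and midstory terms.
DEFAULT_PRIORITY = ("basal", "grass", "woody", "vor2", "forbs", "bare",
                    "litter", "vor025", "vor1", "canopy")


def standardize(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Center to mean 0 and scale to sample sd 1 (divisor n-1).

    Returns (standardized, mean, sd); the constants allow exact
    back-transformation. A constant input is rejected: it carries no
    information for the regression.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("standardize needs a 1-d sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("standardize requires finite values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("constant covariate (sd = 0) cannot be standardized")
    return (x - mean) / sd, mean, sd


def back_transform(z: Sequence[float], mean: float, sd: float) -> np.ndarray:
    return np.asarray(z, dtype=float) * sd + mean


def standardize_table(cov: CovariateTable,
                      point_covs: Sequence[str] | None = None,
                      visit_covs: Sequence[str] | None = None) -> CovariateTable:
    """Add ``<name>_z`` columns and store the standardization constants.

    The standardization population is all point x year rows (pooled across
    groups and years) for vegetation covariates and all visit rows for
    detection covariates, matching the single pooled design matrix the model
    uses. The binary treatment flag is left on its 0/1 scale.
    """
    out = cov.copy()
    if point_covs is None:
        point_covs = [c for c in ABUNDANCE_COVS + REDUNDANT_COVS
                      if c in out.points.columns and c != "treatment"]
    if visit_covs is None:
        visit_covs = [c for c in DETECTION_COVS
                      if c in out.visits.columns and c != "date2"]
    for c in point_covs:
        z, m, s = standardize(out.points[c].to_numpy())
        out.points[f"{c}_z"] = z
        out.scale[c] = (m, s)
    for c in visit_covs:
        z, m, s = standardize(out.visits[c].to_numpy())
        out.visits[f"{c}_z"] = z
        out.scale[c] = (m, s)
    return out


@dataclass
class ScreenReport:
    """Outcome of the greedy collinearity screen."""

    correlations: pd.DataFrame
    retained: list[str]
    excluded: dict[str, str] = field(default_factory=dict)  # cov -> partner
    threshold: float = 0.7

    def to_frame(self) -> pd.DataFrame:
        rows = [{"covariate": c, "status": "retained", "partner": "",
                 "abs_r": np.nan} for c in self.retained]
        rows += [{"covariate": c, "status": "excluded", "partner": p,
                  "abs_r": abs(self.correlations.loc[c, p])}
                 for c, p in self.excluded.items()]
        return pd.DataFrame(rows)


def correlation_screen(table: CovariateTable | pd.DataFrame,
                       threshold: float = 0.7,
                       priority: Sequence[str] = DEFAULT_PRIORITY) -> ScreenReport:
    """Greedy Pearson-correlation screen.

    Walking candidates in retention-priority order, a covariate is excluded
    as soon as its |r| with an already-retained covariate exceeds
    ``threshold``; the report names the partner that triggered each
    exclusion.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    df = table.points if isinstance(table, CovariateTable) else table
    candidates = [c for c in priority if c in df.columns]
    if not candidates:
        raise ValueError("no screening candidates present in the table")
    if len(df) < 3:
        raise ValueError("need >= 3 records to estimate correlations")
    corr = df[candidates].corr(method="pearson")
    retained: list[str] = []
    excluded: dict[str, str] = {}
    for c in candidates:
        partner = next((r for r in retained
                        if abs(corr.loc[c, r]) > threshold), None)
        if partner is None:
            retained.append(c)
        else:
            excluded[c] = partner
    return ScreenReport(correlations=corr, retained=retained,
                        excluded=excluded, threshold=threshold)


def compare_groups(values: Sequence[float], group: Sequence) -> dict:
    """Welch two-sample t-test between the two label groups.

    Returns t, degrees of freedom, two-sided p, per-group means, and the
    direction of difference (first-label group minus second).
    """
    x = np.asarray(values, dtype=float)
    g = np.asarray(group)
    labels = np.sort(pd.unique(g))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 group labels, got {len(labels)}")
    a, b = x[g == labels[0]], x[g == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 members")
    res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "labels": (labels[0], labels[1]),
        "direction": "greater" if a.mean() > b.mean()
                     else ("less" if a.mean() < b.mean() else "equal"),
    }
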