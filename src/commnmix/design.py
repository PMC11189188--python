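"""Survey design and covariate regimes for repeat-visit point-count studies.

The default objects emulate a Pine Barrens style forest-stewardship study:
18 sites (half actively managed "treatment", half unmanaged "control")
holding 150 point-count stations in total, each visited three times per
breeding season over four survey years, with a 12-species priority community
grouped into three habitat suites (Forested Upland, Scrub-Shrub, Grassland).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

FORESTED_UPLAND = "Forested Upland"
SCRUB_SHRUB = "Scrub-Shrub"
GRASSLAND = "Grassland"

#: BCR 30 priority upland species codes and their habitat suites.
DEFAULT_SUITE_MAP: Mapping[str, str] = {
    "BAOR": FORESTED_UPLAND,
    "BAWW": FORESTED_UPLAND,
    "GCFL": FORESTED_UPLAND,
    "NOFL": FORESTED_UPLAND,
    "SCTA": FORESTED_UPLAND,
    "WOTH": FORESTED_UPLAND,
    "BWWA": SCRUB_SHRUB,
    "BRTH": SCRUB_SHRUB,
    "EATO": SCRUB_SHRUB,
    "FISP": SCRUB_SHRUB,
    "PRAW": SCRUB_SHRUB,
    "EAKI": GRASSLAND,
}

DEFAULT_SPECIES = tuple(DEFAULT_SUITE_MAP)

#: Abundance (point-level) covariates entering log(lambda), in model order.
ABUNDANCE_COVS = ("grass", "woody", "vor2", "basal", "treatment")
#: Detection (visit-level) covariates entering logit(phi), in model order.
DETECTION_COVS = ("date", "date2", "wind", "disturbance")

#: Optional point-level covariates that are screened out by collinearity.
REDUNDANT_COVS = ("forbs", "bare", "litter", "vor025", "vor1", "canopy")

#: Percentage-scale covariates, bounded in [0, 100].
PERCENT_COVS = ("grass", "woody", "vor2", "forbs", "bare", "litter",
                "vor025", "vor1", "canopy")


def _near_equal_sizes(n_points: int, n_sites: int) -> tuple[int, ...]:
    base, extra = divmod(n_points, n_sites)
    return tuple([base + 1] * extra + [base] * (n_sites - extra))


def _balanced_treatment(site_sizes: Sequence[int]) -> tuple[int, ...]:
    """Greedily split sites into two groups with near-equal point totals.

    Returns the indices of the treatment sites. For the default layout
    (six 9-point and twelve 8-point sites) this yields a 75/75 point split.
    """
    order = sorted(range(len(site_sizes)), key=lambda i: -site_sizes[i])
    totals = [0, 0]
    counts = [0, 0]
    half = len(site_sizes) // 2
    groups: list[list[int]] = [[], []]
    for i in order:
        # prefer the lighter group, but never overfill a group's site quota
        g = 0 if (totals[0], counts[0]) <= (totals[1], counts[1]) else 1
        if counts[g] >= len(site_sizes) - half:
            g = 1 - g
        groups[g].append(i)
        totals[g] += site_sizes[i]
        counts[g] += 1
    return tuple(sorted(groups[0]))


@dataclass(frozen=True)
class SurveyDesign:
    """Dimensions and treatment layout of the sampling frame.

    Points are allocated to sites near-equally (sizes differ by at most one)
    unless ``site_sizes`` is given explicitly; sites are split into treatment
    and control groups balancing the point totals.
    """

    n_sites: int = 18
    n_points: int = 150
    n_years: int = 4
    visits_per_year: int = 3
    species: tuple[str, ...] = DEFAULT_SPECIES
    suite_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SUITE_MAP))
    site_sizes: tuple[int, ...] | None = None
    treatment_sites: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        for name, val in (("n_sites", self.n_sites), ("n_points", self.n_points),
                          ("n_years", self.n_years),
                          ("visits_per_year", self.visits_per_year)):
            if int(val) < 1:
                raise ValueError(f"{name} must be >= 1, got {val}")
        if self.n_points < self.n_sites:
            raise ValueError("need at least one point per site")
        if len(self.species) < 1:
            raise ValueError("need at least one species")
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species codes")
        missing = [s for s in self.species if s not in self.suite_map]
        if missing:
            raise ValueError(f"species missing from suite_map: {missing}")
        if self.site_sizes is None:
            object.__setattr__(self, "site_sizes",
                               _near_equal_sizes(self.n_points, self.n_sites))
        if len(self.site_sizes) != self.n_sites:
            raise ValueError("site_sizes length must equal n_sites")
        if sum(self.site_sizes) != self.n_points:
            raise ValueError("site_sizes must sum to n_points")
        if self.treatment_sites is None:
            object.__setattr__(self, "treatment_sites",
                               _balanced_treatment(self.site_sizes))
        bad = [t for t in self.treatment_sites if not 0 <= t < self.n_sites]
        if bad:
            raise ValueError(f"treatment site index out of range: {bad}")

    @classmethod
    def from_points_per_site(cls, n_sites: int, points_per_site: int,
                             **kwargs) -> "SurveyDesign":
        return cls(n_sites=n_sites, n_points=n_sites * points_per_site,
                   site_sizes=tuple([points_per_site] * n_sites), **kwargs)

    # -- derived layout ----------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_surveys(self) -> int:
        """Total point-count surveys: points x years x visits."""
        return self.n_points * self.n_years * self.visits_per_year

    @property
    def site_of_point(self) -> np.ndarray:
        """Site index for every point, shape (n_points,)."""
        return np.repeat(np.arange(self.n_sites), self.site_sizes)

    @property
    def treatment_of_site(self) -> np.ndarray:
        """Boolean treatment flag per site."""
        flags = np.zeros(self.n_sites, dtype=bool)
        flags[list(self.treatment_sites)] = True
        return flags

    @property
    def treatment_of_point(self) -> np.ndarray:
        return self.treatment_of_site[self.site_of_point]

    @property
    def point_ids(self) -> np.ndarray:
        return np.array([f"p{i:03d}" for i in range(self.n_points)])

    @property
    def site_ids(self) -> np.ndarray:
        return np.array([f"s{i:02d}" for i in range(self.n_sites)])

    def suites(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.species:
            if self.suite_map[s] not in seen:
                seen.append(self.suite_map[s])
        return tuple(seen)


@dataclass(frozen=True)
class TruncNormSpec:
    """Location/scale/bounds of a truncated-normal covariate draw."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} > upper {self.upper}")


@dataclass(frozen=True)
class CovariateRegime:
    """Treatment- and control-group vegetation regimes plus visit-covariate
    supports.

    Vegetation covariates are drawn from truncated normals whose location,
    scale, and bounds come from the per-group summary statistics; visit date
    is day-of-season within a ~86-day breeding window (16 May - 10 Aug),
    wind in km/h below the surveyable ceiling, and disturbance an ordinal
    0-4 ambient-noise score.
    """

    control: Mapping[str, TruncNormSpec]
    treatment: Mapping[str, TruncNormSpec]
    season_length_days: float = 86.0
    wind_range: tuple[float, float] = (0.0, 15.0)
    disturbance_levels: int = 5

    def __post_init__(self) -> None:
        if set(self.control) != set(self.treatment):
            raise ValueError("control and treatment must cover the same covariates")
        for group_name, group in (("control", self.control),
                                  ("treatment", self.treatment)):
            for cov, spec in group.items():
                if not spec.lower <= spec.mean <= spec.upper:
                    raise ValueError(
                        f"infeasible regime for {cov} ({group_name}): mean "
                        f"{spec.mean} outside [{spec.lower}, {spec.upper}]")
                if cov in PERCENT_COVS and not (0 <= spec.lower and spec.upper <= 100):
                    raise ValueError(f"{cov} bounds must lie in [0, 100]")
                if cov == "basal" and spec.lower < 0:
                    raise ValueError("basal must be >= 0")
        if self.season_length_days <= 0:
            raise ValueError("season_length_days must be positive")
        if self.wind_range[0] > self.wind_range[1]:
            raise ValueError("wind_range reversed")
        if self.disturbance_levels < 1:
            raise ValueError("disturbance_levels must be >= 1")

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.control)

    def group(self, treated: bool) -> Mapping[str, TruncNormSpec]:
        return self.treatment if treated else self.control


def pine_barrens_regime() -> CovariateRegime:
    """Default vegetation regimes for managed vs unmanaged pine forest.

    Treatment points (variable thinning/burning) have more grass, less woody
    groundcover, less 2-m visual obstruction, and much lower basal area than
    the dense unmanaged reference stands.
    """
    control = {
        "grass": TruncNormSpec(0.28, 1.64, 0.0, 15.0),
        "woody": TruncNormSpec(48.76, 40.48, 0.0, 100.0),
        "vor2": TruncNormSpec(47.66, 27.40, 0.0, 100.0),
        "basal": TruncNormSpec(28.89, 9.83, 3.44, 65.04),
    }
    treatment = {
        "grass": TruncNormSpec(12.69, 24.49, 0.0, 100.0),
        "woody": TruncNormSpec(32.55, 34.33, 0.0, 100.0),
        "vor2": TruncNormSpec(36.56, 32.67, 0.0, 100.0),
        "basal": TruncNormSpec(9.45, 8.04, 0.0, 34.05),
    }
    return CovariateRegime(control=control, treatment=treatment)
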