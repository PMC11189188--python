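import numpy as np
import pytest

import commnmix as cx

TINY_SUITES = {"A": "Forested Upland", "B": "Scrub-Shrub", "C": "Grassland"}


@pytest.fixture(scope="session")
def tiny_design():
    return cx.SurveyDesign(n_sites=2, n_points=10, n_years=1,
                           visits_per_year=3, species=("A", "B", "C"),
                           suite_map=TINY_SUITES)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design):
    cov = cx.generate_covariates(tiny_design, rng_seed=11)
    params = cx.draw_species_params(cx.default_hyperparams(), tiny_design,
                                    rng_seed=12)
    counts = cx.simulate_counts(params, cov, tiny_design, rng_seed=13)
    data = cx.ModelData.from_tables(counts, cov)
    return {"design": tiny_design, "cov": cov, "params": params,
            "counts": counts, "data": data}


@pytest.fixture(scope="session")
def desk_design():
    """One survey season of the full 18-site / 150-point / 12-species frame."""
    return cx.SurveyDesign(n_years=1)
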