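"""End-to-end orchestration: simulate (or load) -> prepare -> fit ->
summarize -> derive, with structured logging and a run manifest."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .derived import (build_z_matrix, detection_summary, jaccard_posterior,
                      suite_summary, zero_inflation_summary)
from .io import (PipelineConfig, read_counts, read_covariates, read_suite_map,
                 write_counts, write_covariates, write_draws)
from .likelihood import ModelData
from .mcmc import default_monitor, gelman_rubin, run_mcmc, summarize
from .prep import compare_groups, correlation_screen, standardize_table
from .synth import draw_species_params, generate_covariates, simulate_counts

log = logging.getLogger("commnmix")


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run every stage and write all outputs under ``out_dir``.

    Deterministic under the config seed; any stage failure aborts with the
    stage name in the log record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.validate()
    manifest: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                      "versions": {"commnmix": __version__,
                                   "numpy": np.__version__,
                                   "pandas": pd.__version__},
                      "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                res = fn()
            except Exception:
                log.exception("stage %s: failed", name)
                raise
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3)}
            log.info("stage %s: done (%.1fs)", name,
                     time.perf_counter() - t0)
            return res
        return deco

    suite_map = dict(config.design.suite_map)

    @stage("data")
    def _data():
        nonlocal suite_map
        if config.mode == "simulate":
            cov = generate_covariates(config.design, config.regime,
                                      rng_seed=config.seed,
                                      include_redundant=True)
            params = draw_species_params(config.hyper, config.design,
                                         rng_seed=config.seed + 1)
            counts = simulate_counts(params, cov, config.design,
                                     rng_seed=config.seed + 2)
            write_covariates(cov, out / "covariates_points.csv",
                             out / "covariates_visits.csv")
            write_counts(counts, out / "counts.csv")
            counts.latent.to_csv(out / "latent_truth.csv", index=False)
        else:
            counts = read_counts(config.paths["counts"])
            cov = read_covariates(config.paths["covariates_points"],
                                  config.paths["covariates_visits"])
            suite_map = read_suite_map(config.paths["suite_map"])
        missing = set(counts.counts["species"]) - set(suite_map)
        if missing:
            raise ValueError(f"species without suite assignment: "
                             f"{sorted(missing)}")
        return counts, cov

    counts, cov = _data

    @stage("prep")
    def _prep():
        cov_z = standardize_table(cov)
        screen = correlation_screen(cov_z)
        screen.to_frame().to_csv(out / "screen_report.csv", index=False)
        dropped = set(screen.excluded) & set(config.spec.abundance_covs)
        if dropped:
            log.warning("model covariates flagged by collinearity screen: %s",
                        sorted(dropped))
        tt = []
        for c in [c for c in config.spec.abundance_covs if c != "treatment"]:
            r = compare_groups(cov_z.points[c],
                               cov_z.points["treatment"].to_numpy())
            tt.append({"covariate": c, **{k: r[k] for k in
                                          ("t", "df", "p", "mean_a", "mean_b",
                                           "direction")}})
        pd.DataFrame(tt).to_csv(out / "group_comparison.csv", index=False)
        log.info("screen retained %s, excluded %s", screen.retained,
                 dict(screen.excluded))
        return cov_z

    cov_z = _prep

    @stage("fit")
    def _fit():
        data = ModelData.from_tables(counts, cov_z,
                                     config.spec.abundance_covs,
                                     config.spec.detection_covs)
        draws = run_mcmc(data, config.spec, config.mcmc)
        write_draws(draws, out / "draws.csv")
        monitor = config.mcmc.monitor or default_monitor(data)
        summ = summarize(draws)
        summ.to_csv(out / "summary.csv")
        rh = gelman_rubin({n: draws.get(n) for n in monitor}) \
            if config.mcmc.n_chains >= 2 else None
        if rh is not None:
            bad = rh[(rh["rhat"] >= 1.1) & ~rh["degenerate"]]
            manifest["max_monitored_rhat"] = float(np.nanmax(rh["rhat"]))
            if len(bad):
                log.warning("monitored parameters above Rhat 1.1: %s",
                            list(bad.index))
        return data, draws

    data, draws = _fit

    @stage("derive")
    def _derive():
        detection_summary(draws, suite_map).to_csv(out / "detection.csv",
                                                   index=False)
        zero_inflation_summary(draws, suite_map).to_csv(
            out / "zero_inflation.csv", index=False)
        suite_summary(draws, suite_map).to_csv(out / "suite_summary.csv",
                                               index=False)
        zmat = build_z_matrix(draws, data, rng_seed=config.seed + 3,
                              max_draws=config.z_matrix_draws)
        jaccard_posterior(zmat).to_csv(out / "jaccard.csv", index=False)

    _derive

    manifest["n_surveys"] = int(len(counts.counts) / max(data.n_species, 1))
    manifest["n_species"] = data.n_species
    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
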