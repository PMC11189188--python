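"""Pre-modelling covariate workflow on the simulated survey.

Standardizes every continuous covariate, screens collinearity at |r| > 0.7
(expecting the redundant groundcover/midstory/canopy measures to drop out),
and compares vegetation between treatment and control points with Welch
t-tests.
"""

from pathlib import Path

import pandas as pd

import commnmix as cx
from commnmix.io import read_covariates

SIM = Path("results/analysis/sim")
OUT = Path("results/analysis/prep")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cov = cx.standardize_table(read_covariates(SIM / "covariates_points.csv",
                                               SIM / "covariates_visits.csv"))
    report = cx.correlation_screen(cov)
    report.to_frame().to_csv(OUT / "screen_report.csv", index=False)
    print(f"retained covariates: {report.retained}")
    for c, partner in report.excluded.items():
        r = report.correlations.loc[c, partner]
        print(f"excluded {c}: |r| = {abs(r):.2f} with {partner}")

    rows = []
    for c in ("grass", "woody", "vor2", "basal"):
        r = cx.compare_groups(cov.points[c],
                              cov.points["treatment"].to_numpy())
        rows.append({"covariate": c, "t": r["t"], "df": r["df"], "p": r["p"],
                     "mean_control": r["mean_a"],
                     "mean_treatment": r["mean_b"]})
        print(f"{c}: control {r['mean_a']:.2f} vs treatment "
              f"{r['mean_b']:.2f} (t = {r['t']:.2f}, df = {r['df']:.0f}, "
              f"p = {r['p']:.2e})")
    pd.DataFrame(rows).to_csv(OUT / "group_comparison.csv", index=False)
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
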