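"""Racial/ethnic and income disparities in occupational exposure and health.

Fits the demographic spline curves for each indicator, tabulates the
worst-off (>= 95th percentile) tracts by demographic category, correlates
indicators with outcome prevalences, and fits the stratified Poisson
prevalence-ratio models (natural cubic spline, df=4, with and without SVI
adjustment) for the three exposure-outcome pairs.  Writes
results/disparities/* and prints the between-stratum prevalence ratios at
50% minority, which recover the planted ratio recorded in truth.json.
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from occindex import (correlate_indicators_outcomes, fit_demographic_spline,
                      fit_stratified_pr, worst_off_breakdown)
from occindex.io import read_bundle, read_indicators
from occindex.registry import CORE_PERCENTILE_COLUMNS, OUTCOME_EXPOSURE_PAIRS

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--bundle", type=Path, default=ROOT / "results" / "bundle")
    ap.add_argument("--indicators", type=Path,
                    default=ROOT / "results" / "indicators.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "disparities")
    args = ap.parse_args()

    bundle = read_bundle(args.bundle)
    ind = read_indicators(args.indicators)
    ctx = bundle.context
    args.out.mkdir(parents=True, exist_ok=True)

    curves = []
    for col in CORE_PERCENTILE_COLUMNS:
        for pred in ("pct_minority", "pct_low_income", "avg_of_both"):
            fit = fit_demographic_spline(ind, ctx, pred, col, df=4)
            curves.append(pd.DataFrame({"indicator": col, "predictor": pred,
                                        "grid": fit.grid, "fitted": fit.fitted}))
    pd.concat(curves).to_csv(args.out / "demographic_splines.csv", index=False)

    worst = worst_off_breakdown(ind, ctx, CORE_PERCENTILE_COLUMNS)
    worst.to_csv(args.out / "worst_off.csv", index=False)
    mino = worst[worst.demographic == "pct_minority"]
    print("worst-off (>=95th percentile) tracts in >75%-minority communities: "
          f"{mino.share_gt75.min() * 100:.1f}-{mino.share_gt75.max() * 100:.1f}% "
          "across indicators")
    print("  ... in <25%-minority communities: "
          f"{mino.share_lt25.min() * 100:.1f}-{mino.share_lt25.max() * 100:.1f}%")

    day_cols = [c for c in ind.columns if c.endswith("_days")] + ["noise_prevalence"]
    outcome_cols = [c for c in ctx.columns if c.startswith("prev_")]
    corr = correlate_indicators_outcomes(ind, ctx, day_cols, outcome_cols)
    corr.rename_axis("indicator").to_csv(args.out / "correlations.csv")
    print("indicator-outcome Pearson r range: "
          f"{corr.min().min():.2f} .. {corr.max().max():.2f}")

    planted = math.exp(bundle.truth["planted_log_pr"])
    rows = []
    for outcome, exposure in OUTCOME_EXPOSURE_PAIRS.items():
        for svi_adjust in (False, True):
            curve = fit_stratified_pr(ind, ctx, outcome, exposure, df=4,
                                      svi_adjust=svi_adjust, robust=True)
            est, lo, hi = curve.between_at(0.5)
            rows.append(pd.DataFrame({
                "outcome": outcome, "exposure": exposure,
                "adjustment": curve.adjustment, "pct_minority": curve.grid,
                "pr_high": curve.pr_high, "pr_low": curve.pr_low,
                "between_pr": curve.between_pr, "between_lo": curve.between_lo,
                "between_hi": curve.between_hi}))
            label = "SVI-adjusted" if svi_adjust else "unadjusted"
            print(f"{outcome} vs {exposure} ({label}): between-stratum PR at "
                  f"50% minority = {est:.3f} [{lo:.3f}, {hi:.3f}] "
                  f"(planted {planted:.2f})")
    pd.concat(rows).to_csv(args.out / "disparity_curves.csv", index=False)


if __name__ == "__main__":
    main()
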