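"""Demographic disparity analyses: exposure-demographic spline curves,
worst-off breakdowns, indicator-outcome correlations, and stratified Poisson
prevalence-ratio models.

The prevalence-ratio model treats each tract's outcome count
(prevalence x population, with a log-population offset) as Poisson and
regresses it on a natural cubic spline of the tract's % racial/ethnic
minority, separately within the high- and low-exposure stratum defined by a
median split of the paired occupational indicator.  The between-stratum
prevalence ratio at a given % minority is the ratio of the two modeled rates
there; with a log-linear planted stratum effect it estimates the planted
ratio at every grid point.  An optional linear SVI-percentile term adjusts
for social vulnerability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .splines import SplineBasis, SplineFit, fit_spline_ols

logger = logging.getLogger(__name__)

DEMOGRAPHICS = ("pct_minority", "pct_low_income", "avg_of_both")


def _demographic(context: pd.DataFrame, predictor: str) -> pd.Series:
    if predictor == "avg_of_both":
        return ((context["pct_minority"] + context["pct_low_income"]) / 2.0).rename("avg_of_both")
    if predictor not in ("pct_minority", "pct_low_income"):
        raise ValueError(f"predictor must be one of {DEMOGRAPHICS}")
    return context[predictor]


def fit_demographic_spline(indicators: pd.DataFrame, context: pd.DataFrame,
                           predictor: str, indicator_col: str,
                           df: int = 4, grid_n: int = 101) -> SplineFit:
    """Unadjusted spline regression of an indicator on a demographic fraction.

    No spatial terms or random effects enter the model: the curves describe
    marginal associations, not significance-tested effects.
    """
    x = _demographic(context, predictor).reindex(indicators.index)
    y = indicators[indicator_col]
    return fit_spline_ols(x, y, df=df, predictor=predictor,
                          response=indicator_col, grid_n=grid_n)


def worst_off_breakdown(indicators: pd.DataFrame, context: pd.DataFrame,
                        indicator_cols, exposure_quantile: float = 0.95,
                        demo_cuts=(0.25, 0.75),
                        demographics=DEMOGRAPHICS) -> pd.DataFrame:
    """Demographic composition of the worst-off (top-percentile) tracts.

    For each indicator, tracts at or above ``exposure_quantile`` of its
    percentile rank are cross-tabulated into demographic categories
    (<25%, 25-75%, >75% by default); shares sum to 1 within each row.
    """
    lo, hi = demo_cuts
    rows = []
    for col in indicator_cols:
        pct = indicators[col]
        worst = pct.index[pct >= exposure_quantile]
        if len(worst) == 0:
            raise ValueError(f"empty worst-off set for {col!r}")
        for demo in demographics:
            d = _demographic(context, demo).reindex(worst)
            d = d.dropna()
            rows.append({
                "indicator": col, "demographic": demo, "n_worst": len(d),
                f"share_lt{int(lo * 100)}": float((d < lo).mean()),
                f"share_{int(lo * 100)}_{int(hi * 100)}": float(((d >= lo) & (d <= hi)).mean()),
                f"share_gt{int(hi * 100)}": float((d > hi).mean()),
            })
    return pd.DataFrame(rows)


def correlate_indicators_outcomes(indicators: pd.DataFrame, context: pd.DataFrame,
                                  indicator_cols, outcome_cols) -> pd.DataFrame:
    """Pairwise Pearson correlations, indicators x outcome prevalences.

    Deletion is listwise per pair; a constant column yields a missing cell.
    """
    joined = indicators[list(indicator_cols)].join(
        context[list(outcome_cols)].reindex(indicators.index))
    if len(joined) < 3:
        raise ValueError("need at least 3 tracts")
    out = pd.DataFrame(index=list(indicator_cols), columns=list(outcome_cols), dtype=float)
    for a in indicator_cols:
        for b in outcome_cols:
            pair = joined[[a, b]].dropna()
            if len(pair) < 3 or pair[a].nunique() < 2 or pair[b].nunique() < 2:
                logger.warning("correlation %s~%s undefined (constant or too few)", a, b)
                continue
            out.loc[a, b] = float(np.corrcoef(pair[a], pair[b])[0, 1])
    return out


def median_split(values: pd.Series) -> pd.Series:
    """High/low exposure split at the 50th percentile; the exact-median tract
    goes to the low stratum (the high stratum is strictly above)."""
    v = values.dropna()
    med = float(np.median(v))
    return (values > med).where(values.notna())


@dataclass
class PrevalenceRatioCurve:
    """Within- and between-stratum prevalence-ratio curves over % minority."""

    outcome: str
    exposure: str
    grid: np.ndarray
    pr_high: np.ndarray        # within-stratum PR relative to the reference point
    pr_low: np.ndarray
    between_pr: np.ndarray     # modeled rate ratio high/low at each grid point
    between_lo: np.ndarray     # 95% CI
    between_hi: np.ndarray
    reference: float
    adjustment: str
    df: int
    n_high: int
    n_low: int
    fits: dict = field(default_factory=dict, repr=False)

    def between_at(self, m: float) -> tuple[float, float, float]:
        """Between-stratum PR and 95% CI at % minority ``m`` (fraction)."""
        est, lo, hi = _between_ratio(self.fits["high"], self.fits["low"], np.array([m]),
                                     self.fits["svi_value"])
        return float(est[0]), float(lo[0]), float(hi[0])


def _stratum_design(basis: SplineBasis, m: np.ndarray, svi_value):
    cols = [basis.transform(m)]
    if svi_value is not None:
        cols.append(np.full((len(m), 1), svi_value))
    return np.column_stack(cols)


def _log_rate(fit, m: np.ndarray, svi_value):
    X = _stratum_design(fit["basis"], m, svi_value)
    eta = X @ fit["result"].params
    var = np.einsum("ij,jk,ik->i", X, fit["result"].cov_params(), X)
    return eta, var


def _between_ratio(fit_high, fit_low, m: np.ndarray, svi_value):
    eta_h, var_h = _log_rate(fit_high, m, svi_value)
    eta_l, var_l = _log_rate(fit_low, m, svi_value)
    diff = eta_h - eta_l
    se = np.sqrt(var_h + var_l)  # independent strata
    zcrit = stats.norm.ppf(0.975)
    return np.exp(diff), np.exp(diff - zcrit * se), np.exp(diff + zcrit * se)


def _fit_one_stratum(m, counts, offset, svi, df, robust, label):
    basis = SplineBasis.fit(m, df)
    cols = [basis.transform(m)]
    if svi is not None:
        cols.append(np.asarray(svi, dtype=float)[:, None])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design in the {label} stratum")
    model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset)
    try:
        res = model.fit(cov_type="HC1") if robust else model.fit()
    except Exception as e:  # perfect separation / convergence failure
        raise ValueError(f"Poisson fit failed in the {label} stratum: {e}") from e
    return {"basis": basis, "result": res}


def fit_stratified_pr(indicators: pd.DataFrame, context: pd.DataFrame,
                      outcome: str, exposure_col: str, df: int = 4,
                      svi_adjust: bool = False, population: pd.Series | None = None,
                      reference: float = 0.0, grid_n: int = 101,
                      robust: bool = False) -> PrevalenceRatioCurve:
    """Stratified Poisson spline model of an outcome prevalence vs % minority.

    ``exposure_col`` names the indicator column whose median split defines
    the high/low strata.  ``population`` scales prevalences to pseudo-counts
    (defaults to the ``total_workers`` column); the point estimates are
    invariant to its overall scale.  ``robust`` requests HC1 sandwich
    standard errors, appropriate when outcome dispersion is not Poisson.
    """
    prev_col = f"prev_{outcome}"
    if prev_col not in context.columns:
        raise KeyError(f"context lacks {prev_col!r}")
    data = indicators[[exposure_col]].join(context[[prev_col, "pct_minority",
                                                    "svi_percentile"]].reindex(indicators.index))
    if population is None:
        if "total_workers" not in indicators.columns:
            raise ValueError("no population column; supply `population` explicitly")
        population = indicators["total_workers"]
    data["pop"] = population.reindex(data.index)
    data = data.dropna(subset=[exposure_col, prev_col, "pct_minority", "pop"])
    if svi_adjust:
        data = data.dropna(subset=["svi_percentile"])

    high = median_split(data[exposure_col]).astype(bool)
    fits = {}
    for label, mask in (("high", high), ("low", ~high)):
        sub = data[mask]
        if len(sub) < df + 2:
            raise ValueError(f"{label} stratum too small ({len(sub)} tracts)")
        fits[label] = _fit_one_stratum(
            m=sub["pct_minority"].to_numpy(),
            counts=(sub[prev_col] * sub["pop"]).to_numpy(),
            offset=np.log(sub["pop"].to_numpy()),
            svi=sub["svi_percentile"].to_numpy() if svi_adjust else None,
            df=df, robust=robust, label=label)

    svi_value = float(data["svi_percentile"].mean()) if svi_adjust else None
    fits["svi_value"] = svi_value
    grid = np.linspace(float(data["pct_minority"].min()),
                       float(data["pct_minority"].max()), grid_n)

    pr = {}
    for label in ("high", "low"):
        eta, _ = _log_rate(fits[label], grid, svi_value)
        eta_ref, _ = _log_rate(fits[label], np.array([reference]), svi_value)
        pr[label] = np.exp(eta - eta_ref[0])
    between, lo, hi = _between_ratio(fits["high"], fits["low"], grid, svi_value)

    return PrevalenceRatioCurve(
        outcome=outcome, exposure=exposure_col, grid=grid,
        pr_high=pr["high"], pr_low=pr["low"],
        between_pr=between, between_lo=lo, between_hi=hi,
        reference=reference, adjustment="svi" if svi_adjust else "none", df=df,
        n_high=int(high.sum()), n_low=int((~high).sum()), fits=fits)
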