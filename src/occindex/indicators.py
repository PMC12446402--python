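"""Employment-weighted occupational hazard indicators at the areal-unit (tract) level.

Each frequency indicator is the expected number of days per 250-day work-year
that a typical worker in a tract is exposed to a hazard.  It is built by
weighting each major occupational group's 0-100 frequency ("Context") score by
the group's share of tract employment:

    days(tract, hazard) = sum_g (workers_g / total) * score(g, hazard) / 100 * 250

The three chemical/physical indicators (pollutants, hazardous equipment,
hazardous conditions) are additionally averaged into a single
"hazardous workplace" indicator.  Percentile ranks of the indicators put them
on the same scale as the Social Vulnerability Index percentile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .registry import (
    CORE_PERCENTILE_COLUMNS,
    FREQUENCY_HAZARDS,
    HAZARDOUS_WORKPLACE_COMPONENTS,
    WORK_YEAR_DAYS,
)

logger = logging.getLogger(__name__)

_PCT_METHODS = ("hazen", "weibull", "inclusive")


def compute_frequency_indicator(
    employment: pd.DataFrame, scores: pd.DataFrame, hazard: str
) -> pd.Series:
    """Weighted days-per-work-year exposure indicator for one hazard.

    Parameters
    ----------
    employment
        Wide table, one row per tract, one integer column per occupational
        group (worker counts).
    scores
        One row per group, one column per hazard, values on the 0-100
        frequency scale.
    hazard
        Column of ``scores`` to use.

    Returns
    -------
    Series of day counts in [0, 250] indexed by tract id.  Tracts with zero
    workers are returned as missing (NaN), never as zero exposure.
    """
    if hazard not in scores.columns:
        raise KeyError(f"unknown hazard {hazard!r}; scores table has {list(scores.columns)}")
    employed = employment.columns[(employment.to_numpy() > 0).any(axis=0)]
    for g in employed:
        if g not in scores.index or pd.isna(scores.at[g, hazard]):
            raise ValueError(f"missing Context score for (group={g!r}, hazard={hazard!r})")
    svals = scores[hazard].reindex(employment.columns).to_numpy(dtype=float)
    if np.nanmin(svals[np.isin(employment.columns, employed)]) < 0 or np.nanmax(svals) > 100:
        raise ValueError(f"Context scores for {hazard!r} outside [0, 100]")
    svals = np.nan_to_num(svals)  # unemployed groups only
    counts = employment.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        days = (counts @ (svals / 100.0 * WORK_YEAR_DAYS)) / totals
    days = np.where(totals > 0, days, np.nan)
    return pd.Series(days, index=employment.index, name=f"{hazard}_days")


def days_to_percent(days):
    """Convert day counts to the fraction of the 250-day standard work-year.

    88 days -> 0.352, i.e. 35% of the year when rounded.
    """
    arr = np.asarray(days, dtype=float)
    if np.any((arr < 0) | (arr > WORK_YEAR_DAYS)):
        raise ValueError(f"days must lie in [0, {WORK_YEAR_DAYS:.0f}]")
    out = arr / WORK_YEAR_DAYS
    return out.item() if np.isscalar(days) or arr.ndim == 0 else out


def aggregate_hazardous_workplace(days: pd.DataFrame) -> pd.Series:
    """Mean of the pollutant, hazardous-equipment and hazardous-conditions day counts.

    ``days`` must contain the three component columns; a tract missing any
    component gets a missing aggregate.
    """
    missing = [c for c in HAZARDOUS_WORKPLACE_COMPONENTS if c not in days.columns]
    if missing:
        raise KeyError(f"missing component columns: {missing}")
    comp = days[list(HAZARDOUS_WORKPLACE_COMPONENTS)]
    return comp.mean(axis=1, skipna=False).rename("hazardous_workplace_days")


def percentile_rank(values, method: str = "hazen") -> pd.Series:
    """Rank-based percentile in [0, 1] with mean ranks for ties.

    ``hazen`` (default) maps rank r of n to (r - 0.5)/n, so an all-tied column
    sits at 0.5 and the percentiles are symmetric around the median;
    ``weibull`` uses r/(n + 1) and ``inclusive`` r/n.  Missing values
    propagate and are excluded from n.
    """
    if method not in _PCT_METHODS:
        raise ValueError(f"method must be one of {_PCT_METHODS}")
    s = pd.Series(values, dtype=float)
    n = int(s.notna().sum())
    if n == 0:
        raise ValueError("cannot rank an all-missing column")
    r = s.rank(method="average")
    if method == "hazen":
        return (r - 0.5) / n
    if method == "weibull":
        return r / (n + 1)
    return r / n


def combine_proximity_items(physical_proximity, face_to_face):
    """Single proximity score from the two 0-100 survey items.

    The physical-proximity construct combines how close a job places the
    worker to others and how often it requires face-to-face discussion; with
    no weighting stated for either item, the unweighted mean is used.
    """
    a = np.asarray(physical_proximity, dtype=float)
    b = np.asarray(face_to_face, dtype=float)
    for arr in (a, b):
        if np.any((arr < 0) | (arr > 100)):
            raise ValueError("proximity items must lie on the 0-100 scale")
    return (a + b) / 2.0


def filter_min_workers(employment: pd.DataFrame, threshold: int = 20) -> pd.DataFrame:
    """Retain tracts with total workers strictly above ``threshold``.

    Small tracts make the weighted indicators unstable, so they are excluded
    from percentile ranking and every downstream analysis.
    """
    totals = employment.sum(axis=1)
    kept = employment.loc[totals > threshold]
    n_dropped = len(employment) - len(kept)
    if n_dropped:
        logger.info("dropped %d tracts with <= %d workers", n_dropped, threshold)
    return kept


def build_indicator_set(
    employment: pd.DataFrame,
    scores: pd.DataFrame,
    jem: pd.DataFrame | None = None,
    noise_cfg=None,
    min_workers: int = 20,
    pct_method: str = "hazen",
) -> pd.DataFrame:
    """Full per-tract indicator table: day counts, noise prevalence, percentiles.

    Applies the minimum-worker filter, computes the five frequency indicators
    and the hazardous-workplace aggregate, runs the Monte Carlo noise
    estimator when a JEM is supplied, and appends percentile-rank columns
    (suffix ``_pct``) plus their four-indicator average
    ``avg_occupational_pct``.
    """
    emp = filter_min_workers(employment, min_workers)
    if emp.empty:
        raise ValueError("no tracts pass the minimum-worker filter")
    out = pd.DataFrame(index=emp.index)
    out["total_workers"] = emp.sum(axis=1).astype(int)
    for hazard in FREQUENCY_HAZARDS:
        out[f"{hazard}_days"] = compute_frequency_indicator(emp, scores, hazard)
    out["hazardous_workplace_days"] = aggregate_hazardous_workplace(out)

    if jem is not None:
        from .noise import NoiseMcConfig, simulate_overexposure

        cfg = noise_cfg if noise_cfg is not None else NoiseMcConfig()
        mc = simulate_overexposure(emp, jem, scores, cfg)
        out["noise_prevalence"] = mc["prevalence"]
        out["noise_mc_se"] = mc["mc_se"]

    pct_sources = {
        "pollutants_pct": "pollutants_days",
        "hazardous_equipment_pct": "hazardous_equipment_days",
        "hazardous_conditions_pct": "hazardous_conditions_days",
        "hazardous_workplace_pct": "hazardous_workplace_days",
        "physical_proximity_pct": "physical_proximity_days",
        "disease_infection_pct": "disease_infection_days",
        "noise_prevalence_pct": "noise_prevalence",
    }
    for pct_col, src in pct_sources.items():
        if src in out.columns:
            out[pct_col] = percentile_rank(out[src], method=pct_method)

    core = [c for c in CORE_PERCENTILE_COLUMNS if c in out.columns]
    if len(core) == len(CORE_PERCENTILE_COLUMNS):
        out["avg_occupational_pct"] = out[list(core)].mean(axis=1, skipna=False)
    return out
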