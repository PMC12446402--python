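"""Monte Carlo estimation of tract-level hazardous-noise overexposure prevalence.

A job exposure matrix (JEM) supplies each occupational group's mean and SD of
the 8-hour time-weighted average sound level (TWA-8h, dBA).  The 0-100 noise
frequency score supplies the fraction of work-days exposed.  Each Monte Carlo
iteration draws one TWA-8h level per worker from Normal(mean_g, sd_g) on the
dBA scale; under the ``energy_average`` adjustment the annualized level is

    L_adj = L + 10 * log10(f_g),   f_g = noise score / 100,

the energy average of an intermittent exposure over the work-year (f_g = 0
means never exposed).  A worker is overexposed when the (adjusted) level
meets the threshold (default 85 dBA, the NIOSH recommended exposure limit;
90 dBA, the OSHA permissible exposure limit, is a common alternative).
The tract prevalence is the mean overexposed fraction across iterations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

FREQ_ADJUSTMENTS = ("none", "energy_average")


@dataclass(frozen=True)
class NoiseMcConfig:
    """Monte Carlo settings for the overexposure estimator."""

    n_iterations: int = 100
    threshold_dBA: float = 85.0
    seed: int = 0
    frequency_adjustment: str = "energy_average"

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if not 70.0 <= self.threshold_dBA <= 120.0:
            raise ValueError(f"threshold_dBA must lie in [70, 120], got {self.threshold_dBA}")
        if self.frequency_adjustment not in FREQ_ADJUSTMENTS:
            raise ValueError(f"frequency_adjustment must be one of {FREQ_ADJUSTMENTS}")


def _tract_rng(seed: int, tract_id) -> np.random.Generator:
    # One stream per tract keyed by (seed, crc32(id)): results do not depend
    # on tract processing order.
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(str(tract_id).encode())])


def _validate_jem(jem: pd.DataFrame, groups) -> None:
    missing = [g for g in groups if g not in jem.index]
    if missing:
        raise ValueError(f"group {missing[0]!r} missing from the JEM")
    if (jem["sd_twa"] < 0).any():
        raise ValueError("sd_twa must be non-negative")
    bad = jem.loc[list(groups)]
    if ((bad["mean_twa"] < 40) | (bad["mean_twa"] > 140)).any():
        raise ValueError("mean_twa outside the plausible acoustic range [40, 140] dBA")


def _adjustments(scores: pd.Series, mode: str) -> np.ndarray:
    """Per-group dB offset; -inf marks groups never exposed (score 0)."""
    f = scores.to_numpy(dtype=float) / 100.0
    if np.any((f < 0) | (f > 1)):
        raise ValueError("noise frequency scores must lie in [0, 100]")
    if mode == "none":
        adj = np.zeros_like(f)
        adj[f == 0.0] = -np.inf
        return adj
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(f)


def simulate_overexposure(
    employment: pd.DataFrame,
    jem: pd.DataFrame,
    scores: pd.DataFrame,
    cfg: NoiseMcConfig = NoiseMcConfig(),
) -> pd.DataFrame:
    """Per-tract overexposure prevalence with its Monte Carlo standard error.

    Returns a DataFrame indexed by tract id with columns ``prevalence`` and
    ``mc_se`` (across-iteration SD / sqrt(n_iterations)).  Tracts with zero
    workers are missing.  Deterministic given ``cfg.seed``.
    """
    employed = employment.columns[(employment.to_numpy() > 0).any(axis=0)]
    _validate_jem(jem, employed)
    if "noise" not in scores.columns:
        raise KeyError("scores table lacks a 'noise' column")

    means = jem["mean_twa"].reindex(employment.columns).to_numpy(dtype=float)
    sds = jem["sd_twa"].reindex(employment.columns).to_numpy(dtype=float)
    adj = _adjustments(scores["noise"].reindex(employment.columns), cfg.frequency_adjustment)

    prev = np.full(len(employment), np.nan)
    se = np.full(len(employment), np.nan)
    counts = employment.to_numpy(dtype=int)
    for t, tract_id in enumerate(employment.index):
        row = counts[t]
        total = int(row.sum())
        if total == 0:
            continue
        rng = _tract_rng(cfg.seed, tract_id)
        active = np.nonzero(row)[0]
        flagged = np.zeros(cfg.n_iterations)
        for g in active:
            c = int(row[g])
            if np.isneginf(adj[g]):
                rng.standard_normal((cfg.n_iterations, c))  # keep stream alignment
                continue
            draws = means[g] + sds[g] * rng.standard_normal((cfg.n_iterations, c))
            flagged += (draws + adj[g] >= cfg.threshold_dBA).sum(axis=1)
        frac = flagged / total
        prev[t] = frac.mean()
        se[t] = 0.0 if cfg.n_iterations == 1 else frac.std(ddof=1) / np.sqrt(cfg.n_iterations)
    return pd.DataFrame({"prevalence": prev, "mc_se": se}, index=employment.index)


def expected_overexposure(
    employment: pd.DataFrame,
    jem: pd.DataFrame,
    scores: pd.DataFrame,
    cfg: NoiseMcConfig = NoiseMcConfig(),
) -> pd.Series:
    """Analytic expectation of the Monte Carlo prevalence (Normal tail mass).

    The simulation estimate converges to this quantity as iterations grow;
    it is used as an oracle in tests and to define planted truths.
    """
    from scipy.stats import norm

    employed = employment.columns[(employment.to_numpy() > 0).any(axis=0)]
    _validate_jem(jem, employed)
    means = jem["mean_twa"].reindex(employment.columns).to_numpy(dtype=float)
    sds = jem["sd_twa"].reindex(employment.columns).to_numpy(dtype=float)
    adj = _adjustments(scores["noise"].reindex(employment.columns), cfg.frequency_adjustment)

    shifted = means + adj  # -inf where never exposed
    p = np.zeros(len(means))
    pos = sds > 0
    p[pos] = norm.sf(cfg.threshold_dBA, loc=shifted[pos], scale=sds[pos])
    p[~pos] = (shifted[~pos] >= cfg.threshold_dBA).astype(float)
    counts = employment.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = (counts @ p) / totals
    return pd.Series(np.where(totals > 0, out, np.nan), index=employment.index, name="prevalence")


def aggregate_prevalence(
    prevalence: pd.Series, totals: pd.Series, mapping: pd.Series
) -> pd.Series:
    """Employment-weighted prevalence at a coarser areal level (county, state...).

    ``mapping`` assigns each tract to a region; every tract with a prevalence
    must be mapped.
    """
    idx = prevalence.dropna().index
    unmapped = idx.difference(mapping.dropna().index)
    if len(unmapped):
        raise ValueError(f"tract {unmapped[0]!r} has no region mapping")
    df = pd.DataFrame(
        {"p": prevalence.loc[idx], "w": totals.loc[idx], "region": mapping.loc[idx]}
    )
    grouped = df.groupby("region", sort=True)
    return grouped.apply(lambda d: np.average(d["p"], weights=d["w"]), include_groups=False).rename(
        "prevalence"
    )
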