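"""Synthetic tract-level study data with controllable spatial and planted structure.

The generator emulates the statistical regime of the national inputs the
pipeline is designed for — employment by major occupational group from a
census survey, 0-100 workplace-condition frequency scores, a noise job
exposure matrix, an SVI percentile, demographics and chronic-disease
prevalences — on a rectangular grid of square "tracts":

* occupational composition varies smoothly in space and mainly along one
  latent "industrialness" gradient whose group loadings are the same latent
  factor the hazard scores share (plus per-group smoothed-noise fields,
  mapped through a softmax), so every weighted indicator inherits positive
  spatial autocorrelation and the co-varying hazards move together;
* the four co-varying hazard scores (pollutants, equipment, conditions,
  noise) share a latent group factor with loading sqrt(hazard_corr); the
  disease/infection and physical-proximity scores get small controlled
  loadings on the composition-gradient direction (weak/negative and
  moderate/positive respectively), reproducing the observed ordering of
  indicator correlations;
* the SVI percentile is a noisy monotone transform of expected tract
  exposure with target correlation ``svi_exposure_corr``;
* outcome prevalences follow log(prev) = intercept + slope*(pct_minority-1/2)
  + planted_log_pr * 1[high-exposure stratum] + lognormal noise, where each
  outcome's stratum is the median split of its paired exposure indicator
  (the same rule the disparity model applies), so the planted contrast is
  recoverable by construction.

Everything is deterministic given the seed; ``truth`` carries the planted
parameters and stratum masks needed to verify downstream estimates.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit, softmax

from . import indicators as ind
from . import noise as noisemod
from .registry import HAZARDS, REGIONS, group_ids


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition knobs for the generator.

    spatial_range is the correlation length (grid cells) of every latent
    field; hazard_corr targets the pairwise correlation among the four
    co-varying hazard scores; planted_log_pr is the log prevalence ratio of
    the high-exposure stratum; mean_workers the expected workers per tract.
    """

    n_rows: int = 20
    n_cols: int = 20
    n_groups: int = 22
    seed: int = 0
    spatial_range: float = 3.0
    hazard_corr: float = 0.95
    svi_exposure_corr: float = 0.5
    planted_log_pr: float = math.log(1.2)
    mean_workers: float = 150.0
    outcome_noise_sd: float = 0.05

    def __post_init__(self):
        if self.n_rows * self.n_cols < 9:
            raise ValueError(f"n_rows*n_cols must be >= 9, got {self.n_rows * self.n_cols}")
        if self.n_groups < 2:
            raise ValueError(f"n_groups must be >= 2, got {self.n_groups}")
        if not 0.0 <= self.hazard_corr <= 1.0:
            raise ValueError(f"hazard_corr must lie in [0, 1], got {self.hazard_corr}")
        if not -1.0 <= self.svi_exposure_corr <= 1.0:
            raise ValueError(f"svi_exposure_corr must lie in [-1, 1], got {self.svi_exposure_corr}")
        if self.mean_workers <= 0:
            raise ValueError(f"mean_workers must be > 0, got {self.mean_workers}")
        if self.spatial_range <= 0:
            raise ValueError(f"spatial_range must be > 0, got {self.spatial_range}")
        if self.outcome_noise_sd < 0:
            raise ValueError(f"outcome_noise_sd must be >= 0, got {self.outcome_noise_sd}")


@dataclass
class SyntheticBundle:
    employment: pd.DataFrame   # tract x group worker counts
    scores: pd.DataFrame       # group x hazard, 0-100
    jem: pd.DataFrame          # group: mean_twa, sd_twa, n_measurements
    geometry: dict             # GeoJSON FeatureCollection of unit squares
    context: pd.DataFrame      # SVI, demographics, outcomes per tract
    truth: dict                # planted parameters and masks

    @property
    def tract_ids(self):
        return list(self.employment.index)


def _smooth_field(rng, shape, sigma):
    """Standardized latent field: white noise smoothed with a separable kernel."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (f - f.mean()) / f.std()


def _grid_geometry(n_rows, n_cols, ids):
    feats = []
    k = 0
    for r in range(n_rows):
        for c in range(n_cols):
            x, y = float(c), float(n_rows - 1 - r)
            ring = [[x, y], [x + 1, y], [x + 1, y + 1], [x, y + 1], [x, y]]
            feats.append({
                "type": "Feature",
                "properties": {"tract_id": ids[k]},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
            k += 1
    return {"type": "FeatureCollection", "features": feats}


def _regions_states(n_rows, n_cols):
    """Quadrants as census regions, each split in two 'states'."""
    region, state = [], []
    for r in range(n_rows):
        for c in range(n_cols):
            q = (0 if r < n_rows / 2 else 2) + (0 if c < n_cols / 2 else 1)
            reg = REGIONS[q]
            half = (c // max(1, n_cols // 4)) % 2  # split each quadrant into two blocks
            region.append(reg)
            state.append(f"{reg[:2].upper()}{half + 1}")
    return region, state


def _make_scores(rng, groups, rho, u, ghat):
    """Group x hazard Context scores.

    The four co-varying hazards load sqrt(rho) on the shared factor ``u``;
    the disease and proximity scores take small fixed loadings on ``ghat``,
    the composition-gradient direction in group space, which pins their
    tract-level correlations with the other indicators at weak-negative and
    moderate-positive values instead of leaving them to random alignment.
    """
    G = len(groups)
    cols = {}
    for h in ("pollutants", "hazardous_equipment", "hazardous_conditions", "noise"):
        eps = rng.standard_normal(G)
        cols[h] = 50.0 + 22.0 * (math.sqrt(rho) * u + math.sqrt(1.0 - rho) * eps)

    def controlled(center, scale, load):
        eps = rng.standard_normal(G)
        e = eps - (eps @ ghat) * ghat
        e = e / e.std()
        raw = load * ghat * math.sqrt(G) + math.sqrt(max(0.0, 1.0 - load * load)) * e
        return center + scale * raw

    cols["disease_infection"] = controlled(40.0, 18.0, -0.05)
    cols["physical_proximity"] = controlled(60.0, 15.0, 0.15)
    scores = pd.DataFrame(cols, index=pd.Index(groups, name="group_id"))
    return scores.clip(0.0, 100.0)[list(HAZARDS)]


def _make_jem(rng, scores):
    # TWA-8h means track the noise frequency score so intensity and
    # frequency rank groups consistently, as in an empirical JEM.
    noise_score = scores["noise"].to_numpy()
    mean_twa = np.clip(74.0 + 0.3 * (noise_score - 50.0), 45.0, 115.0)
    sd_twa = rng.uniform(8.0, 12.0, len(scores))
    n_meas = rng.integers(20, 500, len(scores))
    return pd.DataFrame({"mean_twa": mean_twa, "sd_twa": sd_twa, "n_measurements": n_meas},
                        index=scores.index)


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Generate one complete synthetic study dataset. Deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    R, C, G = cfg.n_rows, cfg.n_cols, cfg.n_groups
    n = R * C
    groups = group_ids(G)
    ids = [f"T{i:05d}" for i in range(n)]

    # occupational composition: a shared industrialness gradient with group
    # loadings u, plus per-group fields, through a softmax
    u = rng.standard_normal(G)
    base = rng.normal(0.0, 1.0, G)
    wbar = softmax(base)
    g = wbar * (u - wbar @ u)  # softmax gradient direction in group space
    ghat = g / np.linalg.norm(g)
    shared = _smooth_field(rng, (R, C), cfg.spatial_range).ravel()
    own = np.stack([_smooth_field(rng, (R, C), cfg.spatial_range).ravel()
                    for _ in range(G)], axis=1)
    logits = base[None, :] + 1.1 * u[None, :] * shared[:, None] + 0.5 * own
    mixing = softmax(logits, axis=1)

    totals = rng.poisson(cfg.mean_workers, n)
    counts = np.stack([rng.multinomial(totals[i], mixing[i]) for i in range(n)])
    employment = pd.DataFrame(counts, index=pd.Index(ids, name="tract_id"), columns=groups)

    scores = _make_scores(rng, groups, cfg.hazard_corr, u, ghat)
    jem = _make_jem(rng, scores)
    geometry = _grid_geometry(R, C, ids)

    # expected exposure (mixing-weighted mean of the four co-varying hazards)
    four = scores[["pollutants", "hazardous_equipment", "hazardous_conditions",
                   "noise"]].mean(axis=1).to_numpy()
    expected_exposure = mixing @ four
    ez = (expected_exposure - expected_exposure.mean()) / expected_exposure.std()

    # SVI: noisy monotone transform of exposure at the target correlation
    rs = cfg.svi_exposure_corr
    svi_latent = rs * ez + math.sqrt(max(0.0, 1.0 - rs * rs)) * rng.standard_normal(n)
    svi = ind.percentile_rank(pd.Series(svi_latent, index=ids))

    # demographics: smooth fields pushed through a logistic; % minority is
    # moderately coupled to the exposure gradient so highly exposed tracts
    # are enriched in minority communities
    zm = 0.45 * shared + 0.65 * _smooth_field(rng, (R, C), cfg.spatial_range).ravel() \
        + 0.6 * rng.standard_normal(n)
    pct_minority = expit(1.2 * zm - 0.1)
    zl = 0.6 * zm + 0.8 * _smooth_field(rng, (R, C), cfg.spatial_range).ravel() \
        + 0.4 * rng.standard_normal(n)
    pct_low_income = expit(0.9 * zl - 0.4)
    zd = _smooth_field(rng, (R, C), cfg.spatial_range).ravel() + 0.5 * rng.standard_normal(n)
    pop_density = np.exp(7.2 + 1.3 * zd)

    region, state = _regions_states(R, C)

    # planted strata: median split of each outcome's paired exposure,
    # computed with the same rules the analysis applies
    pollutant_days = ind.compute_frequency_indicator(employment, scores, "pollutants")
    disease_days = ind.compute_frequency_indicator(employment, scores, "disease_infection")
    exp_noise_prev = noisemod.expected_overexposure(employment, jem, scores)
    masks = {
        "asthma": (pollutant_days > pollutant_days.median()).to_numpy(),
        "high_blood_pressure": (disease_days > disease_days.median()).to_numpy(),
        "diabetes": (exp_noise_prev > exp_noise_prev.median()).to_numpy(),
    }

    bases = {"diabetes": 0.11, "asthma": 0.095, "high_blood_pressure": 0.30}
    slopes = {"diabetes": 0.5, "asthma": 0.4, "high_blood_pressure": 0.45}
    outcomes = {}
    for o in ("diabetes", "asthma", "high_blood_pressure"):
        log_prev = (math.log(bases[o]) + slopes[o] * (pct_minority - 0.5)
                    + cfg.planted_log_pr * masks[o]
                    + cfg.outcome_noise_sd * rng.standard_normal(n))
        outcomes[f"prev_{o}"] = np.clip(np.exp(log_prev), 1e-4, 0.95)

    context = pd.DataFrame({
        "svi_percentile": svi.to_numpy(),
        "pct_minority": pct_minority,
        "pct_low_income": pct_low_income,
        "pop_density": pop_density,
        "region": region,
        "state": state,
        **outcomes,
    }, index=pd.Index(ids, name="tract_id"))

    truth = {
        "config": asdict(cfg),
        "planted_log_pr": cfg.planted_log_pr,
        "planted_pr": math.exp(cfg.planted_log_pr),
        "high_exposure_masks": {o: m.astype(int).tolist() for o, m in masks.items()},
        "expected_exposure": expected_exposure.tolist(),
        "group_base_logits": base.tolist(),
        "outcome_bases": bases,
        "outcome_minority_slopes": slopes,
    }
    return SyntheticBundle(employment=employment, scores=scores, jem=jem,
                           geometry=geometry, context=context, truth=truth)


def fixture_small() -> SyntheticBundle:
    """Fixed 4-tract, 3-group bundle with hand-checkable round numbers.

    Tract T00000: 10 workers all in g03 (pollutants score 100) -> 250 days.
    Tract T00001: 5 in g01 (score 50) + 5 in g02 (score 0) -> 62.5 days.
    JEM rows are degenerate (sd 0), so overexposure prevalences are exact:
    g03's 95 dBA at full frequency exceeds an 85 dBA threshold -> 1.0.
    """
    groups = ["g01", "g02", "g03"]
    ids = ["T00000", "T00001", "T00002", "T00003"]
    employment = pd.DataFrame(
        [[0, 0, 10], [5, 5, 0], [20, 5, 0], [0, 40, 0]],
        index=pd.Index(ids, name="tract_id"), columns=groups)
    scores = pd.DataFrame({
        "pollutants": [50.0, 0.0, 100.0],
        "hazardous_equipment": [25.0, 0.0, 75.0],
        "hazardous_conditions": [25.0, 25.0, 50.0],
        "noise": [50.0, 0.0, 100.0],
        "disease_infection": [0.0, 75.0, 25.0],
        "physical_proximity": [75.0, 50.0, 25.0],
    }, index=pd.Index(groups, name="group_id"))[list(HAZARDS)]
    jem = pd.DataFrame({
        "mean_twa": [80.0, 70.0, 95.0],
        "sd_twa": [0.0, 0.0, 0.0],
        "n_measurements": [10, 10, 10],
    }, index=scores.index)
    geometry = _grid_geometry(2, 2, ids)
    context = pd.DataFrame({
        "svi_percentile": [0.125, 0.375, 0.625, 0.875],
        "pct_minority": [0.2, 0.4, 0.6, 0.8],
        "pct_low_income": [0.1, 0.3, 0.5, 0.7],
        "pop_density": [500.0, 5000.0, 15000.0, 800.0],
        "region": ["Midwest", "Midwest", "South", "South"],
        "state": ["MW1", "MW1", "SO1", "SO1"],
        "prev_diabetes": [0.10, 0.12, 0.14, 0.16],
        "prev_asthma": [0.08, 0.09, 0.10, 0.11],
        "prev_high_blood_pressure": [0.25, 0.30, 0.35, 0.40],
    }, index=pd.Index(ids, name="tract_id"))
    truth = {"planted_log_pr": 0.0, "planted_pr": 1.0, "fixture": True}
    return SyntheticBundle(employment=employment, scores=scores, jem=jem,
                           geometry=geometry, context=context, truth=truth)
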