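"""Where occupational exposure percentiles diverge from SVI percentiles.

The gap for a tract is the average percentile of the four occupational
indicators minus the tract's SVI percentile; positive values mark places
whose workplace hazards rank higher than their social vulnerability, i.e.
places a residence-only index under-counts.  Tracts whose absolute gap
reaches 0.25 are flagged as substantially discordant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import CORE_PERCENTILE_COLUMNS, DENSITY_BINS, DENSITY_LABELS
from .spatial import SpatialWeights, local_moran_bv
from .splines import SplineFit, fit_spline_ols


@dataclass
class GapResult:
    table: pd.DataFrame  # avg_occ_pct, svi_pct, gap, flagged
    flag_threshold: float
    n_flagged: int
    share_flagged: float
    n_excluded_missing_svi: int


def compute_gap(indicators: pd.DataFrame, context: pd.DataFrame,
                flag_threshold: float = 0.25, sided: str = "both") -> GapResult:
    """Per-tract occupational-minus-SVI percentile gap with a discordance flag.

    ``sided``: "both" flags |gap| >= threshold (over- and under-counting),
    "over" flags gap >= threshold only, "under" flags gap <= -threshold.
    Tracts with missing SVI are excluded and counted.
    """
    if sided not in ("both", "over", "under"):
        raise ValueError("sided must be 'both', 'over' or 'under'")
    avg = indicators["avg_occupational_pct"]
    svi = context["svi_percentile"].reindex(avg.index)
    ok = avg.notna() & svi.notna()
    n_excl = int((avg.notna() & svi.isna()).sum())
    gap = (avg[ok] - svi[ok]).rename("gap")
    if sided == "both":
        flagged = gap.abs() >= flag_threshold
    elif sided == "over":
        flagged = gap >= flag_threshold
    else:
        flagged = gap <= -flag_threshold
    table = pd.DataFrame({
        "avg_occ_pct": avg[ok],
        "svi_pct": svi[ok],
        "gap": gap,
        "flagged": flagged,
    })
    return GapResult(table=table, flag_threshold=flag_threshold,
                     n_flagged=int(flagged.sum()),
                     share_flagged=float(flagged.mean()) if len(gap) else float("nan"),
                     n_excluded_missing_svi=n_excl)


def summarize_gap(gap: GapResult, context: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of the gap by census region and by population-density class.

    Density classes (people per square mile): rural <1000, intermediate
    1000-10,000, dense urban >10,000.  Empty strata are absent from the
    output, not reported as zero.
    """
    g = gap.table["gap"]
    ctx = context.reindex(g.index)
    rows = []
    for kind, labels in (
        ("region", ctx["region"]),
        ("density", pd.cut(ctx["pop_density"], bins=list(DENSITY_BINS),
                           labels=list(DENSITY_LABELS), right=False)),
    ):
        for name, sub in g.groupby(labels, observed=True):
            if len(sub) == 0:
                continue
            rows.append({"stratum_type": kind, "stratum": str(name), "n": len(sub),
                         "mean": float(sub.mean()),
                         "sd": float(sub.std(ddof=1)) if len(sub) > 1 else 0.0})
    return pd.DataFrame(rows, columns=["stratum_type", "stratum", "n", "mean", "sd"])


def high_exposure_low_svi(indicators: pd.DataFrame, context: pd.DataFrame,
                          w: SpatialWeights, indicator_cols=CORE_PERCENTILE_COLUMNS,
                          alpha: float = 0.05, n_perm: int = 999, seed: int = 0) -> dict:
    """Bivariate-LISA HL clusters: high indicator surrounded by low SVI.

    Returns, per indicator percentile column, the HL tract set, its size and
    its share of analyzed tracts.
    """
    svi = context["svi_percentile"]
    out = {}
    for col in indicator_cols:
        lisa = local_moran_bv(indicators[col], svi.reindex(indicators.index), w,
                              n_perm=n_perm, alpha=alpha, seed=seed)
        tracts = lisa.cluster("HL")
        n = int(lisa.table["local_I"].notna().sum())
        out[col] = {"tracts": tracts, "count": len(tracts),
                    "share": len(tracts) / n if n else float("nan"), "lisa": lisa}
    return out


def spline_exposure_vs_svi(indicators: pd.DataFrame, context: pd.DataFrame,
                           indicator_col: str, df: int = 4, grid_n: int = 101) -> SplineFit:
    """Unadjusted natural-cubic-spline regression of SVI percentile on an
    indicator percentile; compare the fitted curve with the 1:1 line."""
    x = indicators[indicator_col]
    y = context["svi_percentile"].reindex(x.index)
    fit = fit_spline_ols(x, y, df=df, predictor=indicator_col,
                         response="svi_percentile", grid_n=grid_n)
    return fit
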