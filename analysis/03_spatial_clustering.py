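"""Spatial clustering of the occupational indicators.

Global univariate Moran's I (999 permutations) for the four headline
indicator percentiles, the bivariate Moran's I among them, the per-state
decomposition, and univariate LISA cluster counts.  Writes
results/spatial/*.csv.
"""

import argparse
import itertools
from pathlib import Path

import pandas as pd

from occindex import (SpatialWeights, bivariate_moran, global_moran, local_moran,
                      per_group_moran)
from occindex.io import read_bundle, read_indicators
from occindex.registry import CORE_PERCENTILE_COLUMNS

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--bundle", type=Path, default=ROOT / "results" / "bundle")
    ap.add_argument("--indicators", type=Path,
                    default=ROOT / "results" / "indicators.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "spatial")
    args = ap.parse_args()

    bundle = read_bundle(args.bundle)
    ind = read_indicators(args.indicators)
    w = SpatialWeights.from_geojson(bundle.geometry, scheme="queen")
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for col in CORE_PERCENTILE_COLUMNS:
        res = global_moran(ind[col], w, n_perm=999, seed=args.seed)
        rows.append({"variable": col, "I": res.I, "p_perm": res.p_perm, "n": res.n})
        print(f"global Moran's I [{col}] = {res.I:.3f} (p = {res.p_perm:.3f})")
    pd.DataFrame(rows).to_csv(args.out / "moran_global.csv", index=False)

    rows = []
    for a, b in itertools.combinations(CORE_PERCENTILE_COLUMNS, 2):
        res = bivariate_moran(ind[a], ind[b], w, n_perm=199, seed=args.seed)
        rows.append({"x": a, "y": b, "I": res.I, "p_perm": res.p_perm})
    bv = pd.DataFrame(rows)
    bv.to_csv(args.out / "moran_bivariate.csv", index=False)
    print(f"bivariate Moran's I range: {bv['I'].min():.3f} .. {bv['I'].max():.3f}")

    states = bundle.context["state"].reindex(ind.index)
    rows = []
    for col in CORE_PERCENTILE_COLUMNS:
        results, skipped = per_group_moran(ind[col], w, states, n_perm=199,
                                           seed=args.seed)
        rows += [{"variable": col, "state": s, "I": r.I, "p_perm": r.p_perm,
                  "n": r.n} for s, r in results.items()]
        for s, why in skipped.items():
            print(f"  skipped state {s} for {col}: {why}")
    per_state = pd.DataFrame(rows)
    per_state.to_csv(args.out / "moran_by_state.csv", index=False)
    strongest = per_state.loc[per_state["I"].idxmax()]
    print(f"strongest state-level clustering: {strongest.variable} in "
          f"{strongest.state} (I = {strongest.I:.3f})")

    frames = []
    for col in CORE_PERCENTILE_COLUMNS:
        lisa = local_moran(ind[col], w, n_perm=999, alpha=0.05, seed=args.seed)
        t = lisa.table.copy()
        t.insert(0, "variable", col)
        frames.append(t.reset_index())
        counts = t["quadrant"].value_counts()
        print(f"LISA [{col}]: HH={counts.get('HH', 0)} LL={counts.get('LL', 0)} "
              f"HL={counts.get('HL', 0)} LH={counts.get('LH', 0)}")
    pd.concat(frames).to_csv(args.out / "lisa.csv", index=False)


if __name__ == "__main__":
    main()
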