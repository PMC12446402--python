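"""Plain-text readers/writers for the pipeline's tables (CSV / GeoJSON / JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .registry import HAZARDS


def read_employment(path) -> pd.DataFrame:
    """Long employment.csv (tract_id, group_id, workers) -> wide tract x group."""
    long = pd.read_csv(path, dtype={"tract_id": str, "group_id": str})
    wide = long.pivot_table(index="tract_id", columns="group_id", values="workers",
                            aggfunc="sum", fill_value=0)
    return wide.astype(int)


def write_employment(employment: pd.DataFrame, path) -> None:
    long = (employment.rename_axis(index="tract_id", columns="group_id")
            .stack().rename("workers").reset_index())
    long.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    long = pd.read_csv(path, dtype={"group_id": str, "hazard_id": str})
    wide = long.pivot(index="group_id", columns="hazard_id", values="score")
    cols = [h for h in HAZARDS if h in wide.columns]
    return wide[cols]


def write_scores(scores: pd.DataFrame, path) -> None:
    long = (scores.rename_axis(index="group_id", columns="hazard_id")
            .stack().rename("score").reset_index())
    long.to_csv(path, index=False)


def read_jem(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"group_id": str}).set_index("group_id")


def write_jem(jem: pd.DataFrame, path) -> None:
    jem.rename_axis("group_id").to_csv(path)


def read_context(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tract_id": str}).set_index("tract_id")


def write_context(context: pd.DataFrame, path) -> None:
    context.rename_axis("tract_id").to_csv(path)


def read_geometry(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_geometry(geometry: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(geometry, fh, sort_keys=True, separators=(",", ":"))


def read_indicators(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"tract_id": str}).set_index("tract_id")


def write_indicators(indicators: pd.DataFrame, path) -> None:
    indicators.rename_axis("tract_id").to_csv(path)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_bundle(bundle, out_dir) -> None:
    """Write a synthetic bundle's six artifacts into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_employment(bundle.employment, out / "employment.csv")
    write_scores(bundle.scores, out / "scores.csv")
    write_jem(bundle.jem, out / "jem.csv")
    write_context(bundle.context, out / "context.csv")
    write_geometry(bundle.geometry, out / "geometry.geojson")
    write_json(bundle.truth, out / "truth.json")


def read_bundle(in_dir):
    from .synthetic import SyntheticBundle

    p = Path(in_dir)
    with open(p / "truth.json") as fh:
        truth = json.load(fh)
    return SyntheticBundle(
        employment=read_employment(p / "employment.csv"),
        scores=read_scores(p / "scores.csv"),
        jem=read_jem(p / "jem.csv"),
        geometry=read_geometry(p / "geometry.geojson"),
        context=read_context(p / "context.csv"),
        truth=truth,
    )
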