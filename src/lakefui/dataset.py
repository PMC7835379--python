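"""Published-dataset table layout.

Four CSV products: ``lake_info.csv`` (one row per lake), raw and filled
monthly tables (rows = lakes, columns = months), and ``yearly_FUI.csv``
(rows = lakes, columns = years).  Missing values serialize as empty fields;
rows are ordered by Lake_id.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LAKE_INFO_COLUMNS", "validate_lake_info", "write_dataset"]

LAKE_INFO_COLUMNS = [
    "Lake_id", "Lake_name", "Lon", "Lat", "Lake_area", "Freezing",
    "Country/Region", "Continent",
]


def validate_lake_info(lake_info: pd.DataFrame) -> pd.DataFrame:
    """Check/normalise the lake inventory schema.

    Optional descriptive columns are added empty when absent; unknown
    columns are an error.
    """
    missing = [c for c in ("Lake_id", "Lon", "Lat", "Lake_area", "Freezing")
               if c not in lake_info.columns]
    if missing:
        raise ValueError(f"lake_info missing required columns: {missing}")
    unknown = [c for c in lake_info.columns if c not in LAKE_INFO_COLUMNS]
    if unknown:
        raise ValueError(f"lake_info has unknown columns: {unknown}")
    out = lake_info.copy()
    for col in LAKE_INFO_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    return out[LAKE_INFO_COLUMNS].sort_values("Lake_id").reset_index(drop=True)


def _month_columns(table: dict[str, dict[tuple[int, int], float]]) -> list:
    keys = sorted({m for by_month in table.values() for m in by_month})
    return keys


def _monthly_frame(table: dict[str, dict[tuple[int, int], float]],
                   lake_ids: list[str]) -> pd.DataFrame:
    months = _month_columns(table)
    cols = [f"{y:04d}-{m:02d}" for y, m in months]
    data = {
        lid: [table.get(lid, {}).get(m, np.nan) for m in months]
        for lid in lake_ids
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    df.index.name = "Lake_id"
    return df.sort_index()


def write_dataset(
    outdir: str | Path,
    lake_info: pd.DataFrame,
    raw_monthly: dict[str, dict[tuple[int, int], float]],
    filled_monthly: dict[str, dict[tuple[int, int], float]],
    yearly: dict[str, dict[int, float]],
) -> dict[str, Path]:
    """Write the four CSV products; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    info = validate_lake_info(lake_info)
    lake_ids = list(info["Lake_id"])

    paths = {}
    paths["lake_info"] = outdir / "lake_info.csv"
    info.to_csv(paths["lake_info"], index=False)

    for name, table in (("raw_monthly_FUI", raw_monthly),
                        ("filled_monthly_FUI", filled_monthly)):
        df = _monthly_frame(table, lake_ids)
        paths[name] = outdir / f"{name}.csv"
        df.to_csv(paths[name], float_format="%.4f")

    years = sorted({y for by_year in yearly.values() for y in by_year})
    ydf = pd.DataFrame.from_dict(
        {lid: [yearly.get(lid, {}).get(y, np.nan) for y in years]
         for lid in lake_ids},
        orient="index", columns=[str(y) for y in years],
    )
    ydf.index.name = "Lake_id"
    paths["yearly_FUI"] = outdir / "yearly_FUI.csv"
    ydf.sort_index().to_csv(paths["yearly_FUI"], float_format="%.4f")
    return paths
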