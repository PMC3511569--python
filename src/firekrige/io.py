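"""CSV readers and writers for plot tables.

All coordinates are metres from the plot's southwest corner (0-based).
Observation files are long format (core_id, x_m, y_m, value); lipid files are
wide format (core_id, x_m, y_m, then one amount column per lipid, nmol).
Malformed rows are reported with their line numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kriging import SpatialObservations
from .plfa import lipid_columns, parse_lipid

__all__ = [
    "read_observations",
    "write_observations",
    "read_lipids",
    "write_lipids",
    "write_surface",
    "surface_to_ascii_grid",
]


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _check_core_ids(df: pd.DataFrame, path) -> None:
    dup = df["core_id"][df["core_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate core_id value(s) {dup}")


def _check_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        bad = out.index[vals.isna() & out[c].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad]  # +2: header line and 0-base
            raise ValueError(f"{path}: non-numeric value(s) in {c!r} at line(s) {lines}")
        out[c] = vals
    return out


def read_observations(
    path, value_col: str = "value", trend: str = "linear", plot_size: float | None = None
) -> SpatialObservations:
    """Read one spatial response variable from a long CSV
    (core_id, x_m, y_m, <value_col>)."""
    df = pd.read_csv(path, comment="#")
    _check_columns(df, ("core_id", "x_m", "y_m", value_col), path)
    _check_core_ids(df, path)
    df = _check_numeric(df, ["x_m", "y_m", value_col], path)
    if plot_size is not None:
        oob = df.index[
            (df["x_m"] < 0) | (df["y_m"] < 0)
            | (df["x_m"] > plot_size) | (df["y_m"] > plot_size)
        ]
        if len(oob):
            lines = [int(i) + 2 for i in oob]
            raise ValueError(f"{path}: coordinates outside [0, {plot_size}] at line(s) {lines}")
    df = df.dropna(subset=[value_col])
    return SpatialObservations(
        coords=df[["x_m", "y_m"]].to_numpy(float),
        y=df[value_col].to_numpy(float),
        trend=trend,
        core_id=df["core_id"].tolist(),
    )


def write_observations(obs: SpatialObservations, path, value_col: str = "value") -> None:
    ids = obs.core_id or [f"c{i:03d}" for i in range(obs.n)]
    pd.DataFrame(
        {
            "core_id": ids,
            "x_m": obs.coords[:, 0],
            "y_m": obs.coords[:, 1],
            value_col: obs.y,
        }
    ).to_csv(path, index=False)


def read_lipids(path) -> pd.DataFrame:
    """Read a wide per-core lipid amount table; validates core ids, numeric
    amounts, non-negativity and that every lipid column name parses."""
    df = pd.read_csv(path, comment="#")
    _check_columns(df, ("core_id", "x_m", "y_m"), path)
    _check_core_ids(df, path)
    cols = lipid_columns(df)
    if not cols:
        raise ValueError(f"{path}: no lipid columns found")
    for c in cols:
        parse_lipid(c)  # raises naming the offending column
    df = _check_numeric(df, ["x_m", "y_m", *cols], path)
    neg = [c for c in cols if (df[c].dropna() < 0).any()]
    if neg:
        raise ValueError(f"{path}: negative amounts in column(s) {neg}")
    return df


def write_lipids(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_surface(surface: pd.DataFrame, path) -> None:
    """Write a kriged surface (x_m, y_m, pred_mean, pred_sd) as CSV."""
    surface.to_csv(path, index=False)


def surface_to_ascii_grid(surface: pd.DataFrame, path, value: str = "pred_mean") -> None:
    """Export a regular kriged surface as an ESRI-style ASCII grid raster."""
    xs = np.sort(surface["x_m"].unique())
    ys = np.sort(surface["y_m"].unique())
    if xs.size > 1:
        steps = np.diff(xs)
        if not np.allclose(steps, steps[0]):
            raise ValueError("surface is not on a regular grid")
    cell = float(xs[1] - xs[0]) if xs.size > 1 else 1.0
    grid = (
        surface.pivot(index="y_m", columns="x_m", values=value)
        .sort_index(ascending=False)
        .to_numpy()
    )
    header = (
        f"ncols {xs.size}\nnrows {ys.size}\n"
        f"xllcorner {xs[0]}\nyllcorner {ys[0]}\n"
        f"cellsize {cell}\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.where(np.isfinite(grid), grid, -9999.0), fmt="%.6g")
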