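"""Readers and writers for the plain-text exchange formats.

Grids travel as ESRI ASCII rasters (optionally with a CSV legend
mapping integer codes to class names), tables as CSV, polygons as
GeoJSON.  Every reader validates its schema and reports the offending
column or cell.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape

__all__ = [
    "SchemaError",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_class_grid",
    "read_class_grid",
    "write_legend",
    "read_legend",
    "read_table",
    "read_geojson_polygons",
    "write_manifest",
]

_NODATA = -9999.0


class SchemaError(ValueError):
    """An input file violates its declared schema."""


def write_ascii_grid(path, values: np.ndarray, x0=0.0, y0=0.0, cell_size=1.0) -> None:
    """Write a float grid as an ESRI ASCII raster (NaN -> NODATA)."""
    values = np.asarray(values, dtype=float)
    out = np.where(np.isfinite(values), values, _NODATA)
    header = (
        f"ncols {values.shape[1]}\n"
        f"nrows {values.shape[0]}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0}\n"
        f"cellsize {cell_size}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in out:
            fh.write(" ".join(format(v, ".10g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII raster; NODATA becomes NaN.  Returns
    (array, header dict)."""
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise SchemaError(f"{path}: bad value on line {lineno}: {exc}")
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise SchemaError(f"{path}: missing header field {key!r}")
    arr = np.array(rows, dtype=float)
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise SchemaError(
            f"{path}: data shape {arr.shape} does not match header "
            f"({int(header['nrows'])}, {int(header['ncols'])})"
        )
    nodata = header.get("nodata_value", _NODATA)
    arr[arr == nodata] = np.nan
    return arr, header


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def write_class_grid(path, labels: np.ndarray, legend_path=None, **grid_kw) -> None:
    """Write a categorical grid as integer codes + CSV legend."""
    classes = sorted({v for v in labels.ravel() if v is not None}, key=str)
    code_of = {cls: i + 1 for i, cls in enumerate(classes)}
    coded = np.full(labels.shape, np.nan)
    for idx in np.ndindex(labels.shape):
        if labels[idx] is not None:
            coded[idx] = code_of[labels[idx]]
    write_ascii_grid(path, coded, **grid_kw)
    if legend_path is None:
        legend_path = Path(path).with_suffix(".legend.csv")
    write_legend(legend_path, {v: str(k) for k, v in code_of.items()})


def read_class_grid(path, legend_path=None) -> np.ndarray:
    if legend_path is None:
        legend_path = Path(path).with_suffix(".legend.csv")
    legend = read_legend(legend_path)
    coded, _ = read_ascii_grid(path)
    out = np.full(coded.shape, None, dtype=object)
    for idx in np.ndindex(coded.shape):
        v = coded[idx]
        if np.isfinite(v):
            code = int(v)
            if code not in legend:
                raise SchemaError(f"{path}: code {code} at cell {idx} not in legend")
            out[idx] = legend[code]
    return out


def write_legend(path, legend: dict[int, str]) -> None:
    pd.DataFrame(
        {"code": list(legend), "name": [legend[k] for k in legend]}
    ).to_csv(path, index=False)


def read_legend(path) -> dict[int, str]:
    df = read_table(path, required=("code", "name"))
    legend = dict(zip(df["code"].astype(int), df["name"].astype(str)))
    if len(legend) != len(df):
        raise SchemaError(f"{path}: duplicate legend codes")
    return legend


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def read_geojson_polygons(path) -> list:
    """Geometries of all features in a GeoJSON file."""
    with open(path) as fh:
        doc = json.load(fh)
    features = doc.get("features", [doc] if doc.get("type") == "Feature" else [])
    geoms = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry")
        if geom is None:
            raise SchemaError(f"{path}: feature {i} has no geometry")
        geoms.append(shapely_shape(geom))
    return geoms


def write_manifest(path, **entries) -> None:
    """Machine-readable run manifest (seed, versions, per-stage counts)."""
    import benthomap

    manifest = {"benthomap_version": benthomap.__version__, **entries}
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
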