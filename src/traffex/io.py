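"""File formats and configuration shared by all pipeline stages.

Interchange formats are deliberately plain: GeoJSON for the road network
(FeatureCollection of LineString features carrying a numeric ``aadt``
property), UTF-8 CSV with a header row and ISO-8601 dates for tabular data,
ESRI ASCII grid for the density raster, and YAML for the pipeline
configuration.  Every reader validates before anything downstream runs, and
errors name the offending feature or row.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exposure import DensityRaster, RasterSpec, RoadSegment

logger = logging.getLogger("traffex")

__all__ = [
    "ValidationError",
    "read_network",
    "write_network",
    "read_table",
    "write_table",
    "read_raster_ascii",
    "write_raster_ascii",
    "load_config",
    "write_rejects",
]

NODATA = -9999.0

SETTINGS = ("inpatient", "ed", "outpatient")

# column -> dtype kind per table; "date" parsed as ISO-8601 calendar date
SCHEMAS: dict[str, dict[str, str]] = {
    "persons": {
        "person_id": "str",
        "sex": "category:male|female",
        "age": "float",
        "x_m": "float",
        "y_m": "float",
        "block_group_id": "str",
        "poverty_index": "float",
        "person_years": "int",
    },
    "visits": {
        "person_id": "str",
        "date": "date",
        "setting": "category:" + "|".join(SETTINGS),
        "dx1": "str",
        "dx2": "str?",
        "dx3": "str?",
    },
    "blockgroups": {"block_group_id": "str", "poverty_index": "float"},
    "exposures": {
        "person_id": "str",
        "vkt_250": "float",
        "vkt_500": "float",
        "density": "float",
    },
    "outcomes": {
        "person_id": "str",
        "n_events": "int",
        "person_years": "int",
        "rate": "float",
        "any_event": "bool",
    },
    "events": {"person_id": "str", "date": "date", "kind": "str"},
}


class ValidationError(ValueError):
    """Input file violates its declared schema."""


# ---------------------------------------------------------------------------
# Road network GeoJSON
# ---------------------------------------------------------------------------

def read_network(path: str | Path) -> list[RoadSegment]:
    """Read a GeoJSON FeatureCollection of LineString roads.

    Every feature must carry a numeric non-negative ``aadt`` property;
    MultiLineString features are split into one segment per part (ids get a
    ``/<part>`` suffix).
    """
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    segments: list[RoadSegment] = []
    for i, feat in enumerate(gj.get("features", [])):
        fid = str(feat.get("id", feat.get("properties", {}).get("id", i)))
        props = feat.get("properties") or {}
        aadt = props.get("aadt")
        if not isinstance(aadt, (int, float)) or isinstance(aadt, bool) or aadt < 0:
            raise ValidationError(
                f"{path}: feature {fid}: missing or negative 'aadt' ({aadt!r})"
            )
        geom = feat.get("geometry") or {}
        gtype = geom.get("type")
        if gtype == "LineString":
            parts = [geom["coordinates"]]
        elif gtype == "MultiLineString":
            parts = geom["coordinates"]
        else:
            raise ValidationError(
                f"{path}: feature {fid}: geometry must be LineString, got {gtype}"
            )
        for p, coords in enumerate(parts):
            sid = fid if len(parts) == 1 else f"{fid}/{p}"
            segments.append(RoadSegment(sid, np.asarray(coords, float), float(aadt)))
    return segments


def write_network(segments: list[RoadSegment], path: str | Path) -> None:
    """Write road segments as a GeoJSON FeatureCollection of LineStrings."""
    feats = [
        {
            "type": "Feature",
            "id": seg.id,
            "properties": {"aadt": seg.aadt},
            "geometry": {
                "type": "LineString",
                "coordinates": [[round(x, 6), round(y, 6)] for x, y in seg.vertices],
            },
        }
        for seg in segments
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Tabular CSV
# ---------------------------------------------------------------------------

def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate one of the pipeline's CSV tables.

    ``kind`` selects the schema (persons, visits, blockgroups, exposures,
    outcomes, events).  Unknown columns are preserved but ignored; schema
    violations raise :class:`ValidationError` naming the row.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    schema = SCHEMAS[kind]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema if not schema[c].endswith("?") and c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame(index=df.index)
    for col, spec in schema.items():
        optional = spec.endswith("?")
        spec = spec.rstrip("?")
        if col not in df.columns:
            out[col] = ""
            continue
        raw = df[col]
        try:
            if spec == "str":
                out[col] = raw.astype(str)
            elif spec == "float":
                out[col] = pd.to_numeric(raw, errors="raise").astype(float)
            elif spec == "int":
                out[col] = pd.to_numeric(raw, errors="raise").astype(int)
            elif spec == "bool":
                ok = raw.isin(["True", "False", "true", "false", "0", "1"])
                if not ok.all():
                    bad = int(np.flatnonzero(~ok.to_numpy())[0])
                    raise ValidationError(
                        f"{path}: row {bad + 2}: invalid boolean {raw.iloc[bad]!r}"
                    )
                out[col] = raw.isin(["True", "true", "1"])
            elif spec == "date":
                out[col] = pd.to_datetime(raw, format="%Y-%m-%d", errors="raise")
            elif spec.startswith("category:"):
                allowed = spec.split(":", 1)[1].split("|")
                ok = raw.isin(allowed)
                if not ok.all():
                    bad = int(np.flatnonzero(~ok.to_numpy())[0])
                    raise ValidationError(
                        f"{path}: row {bad + 2}: column {col!r} value "
                        f"{raw.iloc[bad]!r} not in allowed values {allowed}"
                    )
                out[col] = raw.astype(str)
            else:  # pragma: no cover - schema author error
                raise ValueError(f"bad schema spec {spec!r}")
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"{path}: column {col!r}: {exc}") from exc
        if optional and col not in df.columns:
            out[col] = ""
    extra = [c for c in df.columns if c not in schema]
    for c in extra:
        out[c] = df[c]
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a pipeline table as UTF-8 CSV with ISO dates and '.' decimals."""
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False, float_format="%.10g")


def write_rejects(rejects: pd.DataFrame, out_dir: str | Path, name: str) -> None:
    """Record dropped records with reasons under ``<out_dir>/rejects/``."""
    if rejects is None or rejects.empty:
        return
    d = Path(out_dir) / "rejects"
    d.mkdir(parents=True, exist_ok=True)
    rejects.to_csv(d / f"{name}.csv", index=False)
    logger.warning("%d records rejected; see %s", len(rejects), d / f"{name}.csv")


# ---------------------------------------------------------------------------
# ESRI ASCII raster
# ---------------------------------------------------------------------------

def write_raster_ascii(raster: DensityRaster, path: str | Path) -> None:
    """Write a density raster as an ESRI ASCII grid (north-up row order).

    Values are written with 6 significant digits; NODATA_value is -9999 and
    never emitted for computed cells.
    """
    spec = raster.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.origin[0]:.6g}\n")
        fh.write(f"yllcorner {spec.origin[1]:.6g}\n")
        fh.write(f"cellsize {spec.cell_size:.6g}\n")
        fh.write(f"NODATA_value {NODATA:.0f}\n")
        for row in raster.values[::-1]:  # top (north) row first
            fh.write(" ".join(f"{v:.6g}" for v in row))
            fh.write("\n")


def read_raster_ascii(path: str | Path) -> DensityRaster:
    """Read an ESRI ASCII grid back into a density raster."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)[::-1]  # back to south-up storage
    spec = RasterSpec(
        origin=(header["xllcorner"], header["yllcorner"]),
        cell_size=header["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return DensityRaster(spec=spec, values=values)


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the YAML pipeline configuration as a nested dict.

    Sections (all optional): ``simulation`` (SimulationConfig fields),
    ``kernel`` (sigma, cutoff, discretization_step), ``exposure``
    (cell_size, radii), ``paths``, ``seed``, ``log_level``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: top-level config must be a mapping")
    return cfg
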