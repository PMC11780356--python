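"""File formats: cells/starters/brain-wide CSV, parcellation GeoJSON,
YAML configuration and the run manifest.

Every writer stamps a schema tag (a comment line for CSV, a property for
GeoJSON/JSON) and every reader rejects unknown schema versions. Tabular data
round-trips exactly.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, shape, mapping

from .errors import SchemaError
from .synthgen import CELL_COLUMNS, FlatmapParcellation, SynthConfig

SCHEMA_PREFIX = "# trioquant-schema: "
SCHEMAS = {"cells": 1, "starters": 1, "brainwide": 1, "sc_cells": 1,
           "landmarks": 1}

_NUMERIC = {
    "cells": ("x_um", "y_um", "section", "depth_um"),
    "starters": ("count",),
    "brainwide": ("count",),
    "sc_cells": ("ap_mm", "x_um", "y_um"),
    "landmarks": ("section_a", "xa", "ya", "section_b", "xb", "yb"),
}
_COLUMNS = {
    "cells": list(CELL_COLUMNS),
    "starters": ["nucleus", "count"],
    "brainwide": ["region", "count"],
    "sc_cells": ["ap_mm", "x_um", "y_um", "layer", "target"],
    "landmarks": ["pair_id", "section_a", "xa", "ya", "section_b", "xb", "yb", "kind"],
}


def _write_csv(df: pd.DataFrame, path, kind: str):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(f"{SCHEMA_PREFIX}{kind}/v{SCHEMAS[kind]}\n")
        df.to_csv(fh, index=False)


def _read_csv(path, kind: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if first.startswith(SCHEMA_PREFIX):
            tag = first[len(SCHEMA_PREFIX):].strip()
            expect = f"{kind}/v{SCHEMAS[kind]}"
            if tag != expect:
                raise SchemaError(f"{path}: schema {tag!r}, expected {expect!r}")
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    cols = _COLUMNS[kind]
    missing = [c for c in cols if c not in df.columns]
    dupes = df.columns[df.columns.duplicated()].tolist()
    if missing or dupes:
        raise SchemaError(
            f"{path}: missing columns {missing}, duplicate columns {dupes}"
        )
    for col in _NUMERIC[kind]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, after header
            raise SchemaError(f"{path}: malformed value in column {col!r} at "
                              f"data row {row}")
        df[col] = coerced
    return df[cols]


def write_cells(df: pd.DataFrame, path):
    _write_csv(df[list(CELL_COLUMNS)], path, "cells")


def read_cells(path) -> pd.DataFrame:
    df = _read_csv(path, "cells")
    df["section"] = df["section"].astype(int)
    for c in ("layer", "area"):
        df[c] = df[c].fillna("").astype(str)
    return df


def write_counts(counts: dict, path, kind: str):
    key = _COLUMNS[kind][0]
    df = pd.DataFrame({key: list(counts), "count": list(counts.values())})
    _write_csv(df, path, kind)


def read_counts(path, kind: str) -> dict:
    df = _read_csv(path, kind)
    key = _COLUMNS[kind][0]
    return dict(zip(df[key], df["count"].astype(int)))


def write_sc_cells(df: pd.DataFrame, path):
    _write_csv(df[_COLUMNS["sc_cells"]], path, "sc_cells")


def read_sc_cells(path) -> pd.DataFrame:
    return _read_csv(path, "sc_cells")


# ---------------------------------------------------------------------------
# Parcellation GeoJSON
# ---------------------------------------------------------------------------

def write_parcellation(parc: FlatmapParcellation, path):
    features = []
    for name, poly in parc.areas:
        features.append({
            "type": "Feature",
            "properties": {"name": name},
            "geometry": mapping(poly),
        })
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "schema": "trioquant-parcellation/v1",
            "animal_id": parc.animal_id,
            "units": "um",
            "convention": "x lateral, y anterior",
        },
        "features": features,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))


def read_parcellation(path) -> FlatmapParcellation:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: not a GeoJSON FeatureCollection")
    schema = doc.get("properties", {}).get("schema", "trioquant-parcellation/v1")
    if schema != "trioquant-parcellation/v1":
        raise SchemaError(f"{path}: unknown schema {schema!r}")
    areas = []
    for feat in doc["features"]:
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise SchemaError(
                f"{path}: non-polygon geometry for feature "
                f"{feat.get('properties', {}).get('name')!r}"
            )
        areas.append((feat["properties"]["name"], geom))
    parc = FlatmapParcellation(
        animal_id=doc.get("properties", {}).get("animal_id", ""), areas=areas)
    parc.validate()
    return parc


# ---------------------------------------------------------------------------
# Config and manifest
# ---------------------------------------------------------------------------

def read_config(path) -> SynthConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SynthConfig.from_dict(data)


def write_config(config: SynthConfig, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: SynthConfig) -> str:
    canon = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(manifest: dict, path):
    manifest = {"schema_version": "trioquant-manifest/v1", **manifest}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def read_manifest(path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != "trioquant-manifest/v1":
        raise SchemaError(f"{path}: unknown manifest schema")
    return doc
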