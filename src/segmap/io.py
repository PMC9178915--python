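"""CSV / GeoJSON / JSON readers and writers for the pipeline's artefacts.

All geometry is plain planar metres (no CRS); GeoJSON files carry the
street network as LineString features whose properties hold segment_id,
length and the covariate values, with the expected coefficient signs in
a top-level ``expected_signs`` member.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from segmap.synthetic import StreetNetwork, TruthSurface


# -- measurements ------------------------------------------------------------

def write_measurements_csv(records: pd.DataFrame, path) -> None:
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def read_measurements_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


# -- reference series --------------------------------------------------------

def write_reference_csv(reference: pd.DataFrame, path) -> None:
    write_measurements_csv(reference, path)


def read_reference_csv(path) -> pd.DataFrame:
    return read_measurements_csv(path)


# -- street network ----------------------------------------------------------

def write_network_geojson(network: StreetNetwork, path) -> None:
    features = []
    for _, row in network.segments.iterrows():
        sid = int(row["segment_id"])
        props = {"segment_id": sid, "length_m": float(row["length_m"])}
        props.update(
            {k: float(v) for k, v in network.covariates.loc[sid].items()}
        )
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(c) for c in row["geometry"].coords],
                },
                "properties": props,
            }
        )
    doc = {
        "type": "FeatureCollection",
        "expected_signs": network.expected_signs,
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_network_geojson(path) -> StreetNetwork:
    doc = json.loads(Path(path).read_text())
    ids, geoms, lengths, cov_rows = [], [], [], []
    for feat in doc["features"]:
        props = dict(feat["properties"])
        sid = props.pop("segment_id")
        lengths.append(props.pop("length_m"))
        ids.append(sid)
        geoms.append(LineString(feat["geometry"]["coordinates"]))
        cov_rows.append(props)
    segments = pd.DataFrame(
        {"segment_id": ids, "geometry": geoms, "length_m": lengths}
    )
    covariates = pd.DataFrame(cov_rows, index=pd.Index(ids, name="segment_id"))
    return StreetNetwork(segments, covariates, dict(doc.get("expected_signs", {})))


# -- truth (synthetic campaigns only) ---------------------------------------

def write_truth_csv(truth: TruthSurface, path) -> None:
    pd.DataFrame(
        {"segment_id": truth.c_true.index, "c_true": truth.c_true.to_numpy(),
         "u": truth.u.to_numpy()}
    ).to_csv(path, index=False)


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- maps and reports --------------------------------------------------------

def write_map_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_map_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_map_geojson(df: pd.DataFrame, network: StreetNetwork, path) -> None:
    """Join per-segment map values onto the network geometry."""
    vals = df.set_index("segment_id")
    features = []
    for _, row in network.segments.iterrows():
        sid = int(row["segment_id"])
        if sid not in vals.index:
            continue
        props = {"segment_id": sid}
        for k, v in vals.loc[sid].items():
            props[k] = None if (isinstance(v, float) and np.isnan(v)) else (
                v.item() if hasattr(v, "item") else v
            )
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(c) for c in row["geometry"].coords],
                },
                "properties": props,
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def _jsonify(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def write_report_json(report, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(report), indent=2))
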