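"""File formats: cell-field CSV + landmark JSON sidecar, config YAML, cohort CSV.

A cell field is serialized as a CSV with exactly the nucleus-table schema
(one nucleus per row) plus a ``<stem>.landmarks.json`` sidecar holding the
landmark polylines and provenance.  Round-trips are lossless (full float
precision, UTF-8, '.' decimal).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import GeneratorConfig
from .errors import LandmarkError, SchemaError
from .field import CellField, Landmarks, NUCLEUS_COLUMNS

__all__ = ["write_cellfield_csv", "read_cellfield_csv", "sidecar_path",
           "load_config", "save_config", "write_cohort_csv", "read_cohort_csv"]


def sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".landmarks.json")


def _poly_to_list(a):
    return None if a is None else np.asarray(a, dtype=float).tolist()


def _poly_from_list(v):
    return None if v is None else np.asarray(v, dtype=float)


def write_cellfield_csv(field: CellField, path) -> Path:
    """Write the nucleus table as CSV and landmarks/provenance as JSON."""
    path = Path(path)
    df = field.nuclei.loc[:, list(NUCLEUS_COLUMNS)].copy()
    df.to_csv(path, index=False, float_format="%.10g")
    lm = field.landmarks
    side = {
        "stage_h": field.stage_h,
        "seed": field.seed,
        "cell_diameter_um": field.cell_diameter_um,
        "body_anterior_offset_um": field.body_anterior_offset_um,
        "truth": _jsonable(field.truth),
        "landmarks": {
            "midline": _poly_to_list(lm.midline),
            "gz_midline": _poly_to_list(lm.gz_midline),
            "stripe_lines": {str(k): _poly_to_list(v)
                             for k, v in lm.stripe_lines.items()},
            "widthA_line": _poly_to_list(lm.widthA_line),
            "widthB_line": _poly_to_list(lm.widthB_line),
            "last_segment_line": _poly_to_list(lm.last_segment_line),
            "margin_left": _poly_to_list(lm.margin_left),
            "margin_right": _poly_to_list(lm.margin_right),
        },
    }
    sidecar_path(path).write_text(json.dumps(side, indent=1), encoding="utf-8")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def read_cellfield_csv(path) -> CellField:
    """Read a cell field written by :func:`write_cellfield_csv`.

    The CSV must carry exactly the nucleus-table schema; unknown or missing
    columns raise :class:`SchemaError` naming the columns.  A missing
    landmark sidecar raises :class:`LandmarkError`.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = list(df.columns)
    missing = [c for c in NUCLEUS_COLUMNS if c not in cols]
    unknown = [c for c in cols if c not in NUCLEUS_COLUMNS]
    if missing:
        raise SchemaError(f"missing column(s): {missing}")
    if unknown:
        raise SchemaError(f"unknown column(s): {unknown}")
    for c in ("x_um", "y_um"):
        if len(df) and not np.issubdtype(df[c].dtype, np.number):
            raise SchemaError(f"non-numeric coordinate column {c!r}")
    df = df.loc[:, list(NUCLEUS_COLUMNS)]
    df["stripe_id"] = pd.array(df["stripe_id"], dtype="Int64")
    for c in ("s_phase", "m_hoechst", "m_ph3"):
        df[c] = df[c].astype(bool) if len(df) else df[c].astype(bool)
    df["spindle_deg"] = df["spindle_deg"].astype(float)
    df["region"] = df["region"].astype(object) if len(df) else df["region"]

    sp = sidecar_path(path)
    if not sp.exists():
        raise LandmarkError(f"landmark sidecar not found: {sp}")
    side = json.loads(sp.read_text(encoding="utf-8"))
    lmd = side["landmarks"]
    lm = Landmarks(
        midline=_poly_from_list(lmd["midline"]),
        gz_midline=_poly_from_list(lmd["gz_midline"]),
        stripe_lines={int(k): _poly_from_list(v)
                      for k, v in lmd["stripe_lines"].items()},
        widthA_line=_poly_from_list(lmd["widthA_line"]),
        widthB_line=_poly_from_list(lmd["widthB_line"]),
        last_segment_line=_poly_from_list(lmd["last_segment_line"]),
        margin_left=_poly_from_list(lmd["margin_left"]),
        margin_right=_poly_from_list(lmd["margin_right"]),
    )
    truth = side.get("truth", {})
    for key, val in list(truth.items()):
        if key.endswith("_interval") or key == "span":
            truth[key] = tuple(val)
    return CellField(nuclei=df, landmarks=lm, stage_h=side["stage_h"],
                     seed=side["seed"],
                     cell_diameter_um=side["cell_diameter_um"],
                     body_anterior_offset_um=side["body_anterior_offset_um"],
                     truth=truth)


def load_config(path) -> GeneratorConfig:
    """Load a generator config from YAML (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return GeneratorConfig.from_dict(data)


def save_config(config: GeneratorConfig, path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False),
                    encoding="utf-8")
    return path


def write_cohort_csv(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False, float_format="%.10g")
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "en_stripes" not in df.columns or "stage_h" not in df.columns:
        raise SchemaError("cohort CSV needs 'stage_h' and 'en_stripes' columns")
    return df
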