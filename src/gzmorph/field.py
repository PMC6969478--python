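"""In-memory containers for a single larva's ventral cell field.

A :class:`CellField` is the digital stand-in for one stained, flat-mounted
larva: a nucleus table (one row per nucleus, with axial/mediolateral
coordinates in µm and per-nucleus cell-cycle labels) plus the landmark
polylines a morphometrician would trace (midline, En-stripe lines, the
growth-zone width lines, lateral margins).

Coordinate convention: x is the anterior–posterior (AP) axis in µm, 0 at the
anterior boundary of the first trunk segment and increasing posteriorly;
y is mediolateral with 0 on the midline.  The head lies anterior to x = 0
and carries no nuclei; its length is stored as ``body_anterior_offset_um``
and enters only the body-length measure.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = ["REGIONS", "NUCLEUS_COLUMNS", "Landmarks", "CellField",
           "translate_field"]

REGIONS = ("segmented", "growth_zone", "telson")

#: canonical nucleus-table schema (also the CSV schema)
NUCLEUS_COLUMNS = ("x_um", "y_um", "stripe_id", "region", "s_phase",
                   "m_hoechst", "m_ph3", "spindle_deg")


@dataclass
class Landmarks:
    """Measurement polylines, each an ``(n, 2)`` float array of (x, y) µm."""

    midline: np.ndarray
    gz_midline: np.ndarray
    #: En stripe index (1-based, anterior->posterior) -> transverse line
    stripe_lines: dict = dc_field(default_factory=dict)
    widthA_line: np.ndarray | None = None
    widthB_line: np.ndarray | None = None
    last_segment_line: np.ndarray | None = None
    margin_left: np.ndarray | None = None
    margin_right: np.ndarray | None = None

    def all_polylines(self):
        out = [("midline", self.midline), ("gz_midline", self.gz_midline)]
        out += [(f"stripe_{k}", v) for k, v in self.stripe_lines.items()]
        for name in ("widthA_line", "widthB_line", "last_segment_line",
                     "margin_left", "margin_right"):
            v = getattr(self, name)
            if v is not None:
                out.append((name, v))
        return out


@dataclass
class CellField:
    """One larva: nucleus table + landmarks + provenance."""

    nuclei: pd.DataFrame
    landmarks: Landmarks
    stage_h: float
    seed: int
    cell_diameter_um: float          # effective (per-larva scaled) spacing
    body_anterior_offset_um: float = 0.0
    truth: dict = dc_field(default_factory=dict)

    def region_nuclei(self, region: str) -> pd.DataFrame:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}")
        return self.nuclei[self.nuclei["region"] == region]

    @property
    def n_stripes(self) -> int:
        ids = self.nuclei["stripe_id"].dropna()
        return int(ids.nunique())

    def copy(self) -> "CellField":
        return CellField(
            nuclei=self.nuclei.copy(),
            landmarks=copy.deepcopy(self.landmarks),
            stage_h=self.stage_h,
            seed=self.seed,
            cell_diameter_um=self.cell_diameter_um,
            body_anterior_offset_um=self.body_anterior_offset_um,
            truth=copy.deepcopy(self.truth),
        )


def translate_field(field: CellField, dx: float = 0.0, dy: float = 0.0) -> CellField:
    """Return a copy of ``field`` with all coordinates shifted by (dx, dy)."""
    out = field.copy()
    out.nuclei["x_um"] = out.nuclei["x_um"] + dx
    out.nuclei["y_um"] = out.nuclei["y_um"] + dy
    shift = np.asarray([dx, dy], dtype=float)
    lm = out.landmarks
    lm.midline = lm.midline + shift
    lm.gz_midline = lm.gz_midline + shift
    lm.stripe_lines = {k: v + shift for k, v in lm.stripe_lines.items()}
    for name in ("widthA_line", "widthB_line", "last_segment_line",
                 "margin_left", "margin_right"):
        v = getattr(lm, name)
        if v is not None:
            setattr(lm, name, v + shift)
    for key, val in list(out.truth.items()):
        if key.endswith("_interval") or key == "span":
            out.truth[key] = (val[0] + dx, val[1] + dx)
        elif key.endswith("_x"):
            out.truth[key] = val + dx
    return out
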