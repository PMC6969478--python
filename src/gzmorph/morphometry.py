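"""Morphometric measures of a ventral cell field.

Implements the eight standard linear/area measures of staged branchiopod
larvae and their cell-count analogues:

1. body length (anterior head tip to the posterior end, along the midline),
2. growth-zone (GZ) length (just posterior to the last En stripe to the
   anterior edge of the telson, along the midline),
3. GZ width A (width of the newest En stripe),
4. GZ width B (width at the GZ/telson boundary),
5. ventral trunk area (anterior trunk boundary to the width-B line),
6. ventral area of the last added segment,
7. ventral GZ area (trapezoid between the width-A and width-B lines),
8. last segment length (midline distance between, but not including, the
   final two En stripes).

Linear measures are landmark-polyline arclengths; areas are shoelace areas
of margin-bounded polygons; cell counts are nucleus counts inside a corridor
around the same polylines.  µm internally, mm/mm² in records.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import shapely
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import LineString, Polygon

from .errors import GeometryError, LandmarkError
from .field import CellField

__all__ = ["MorphometricRecord", "polygon_area", "count_cells_along",
           "score_en_stripes", "measure_larva", "PCA_MEASURES"]

#: the eight measures used for cohort-level multivariate statistics
PCA_MEASURES = ("body_length_mm", "gz_length_mm", "gz_widthA_mm",
                "gz_widthB_mm", "trunk_area_mm2", "last_segment_area_mm2",
                "gz_area_mm2", "last_segment_length_mm")


@dataclass
class MorphometricRecord:
    en_stripes: int
    body_length_mm: float
    gz_length_mm: float
    gz_length_cells: int
    gz_widthA_mm: float
    gz_widthA_cells: int
    gz_widthB_mm: float
    gz_widthB_cells: int
    trunk_area_mm2: float
    last_segment_area_mm2: float | None
    gz_area_mm2: float
    last_segment_length_mm: float | None
    last_segment_length_cells: int | None
    mitoses_gz_hoechst: int
    mitoses_gz_ph3: int
    stage_h: float
    tagma: str | None = None

    def __post_init__(self):
        for name in ("body_length_mm", "gz_length_mm", "gz_widthA_mm",
                     "gz_widthB_mm", "trunk_area_mm2", "gz_area_mm2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.gz_area_mm2 > self.trunk_area_mm2 + 1e-12:
            raise ValueError("gz_area_mm2 cannot exceed trunk_area_mm2")
        if self.en_stripes < 0:
            raise ValueError("en_stripes must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def polygon_area(vertices) -> float:
    """Absolute (orientation-independent) shoelace area of a closed ring, µm².

    ``vertices``: sequence of >= 3 (x, y) pairs; the closing edge is implied.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
        raise GeometryError("polygon needs at least 3 (x, y) vertices")
    poly = Polygon(v)
    area = poly.area
    if area == 0.0 and LineString(v).length > 0:
        # collinear ring: degenerate but well-defined zero area
        return 0.0
    return float(area)


def count_cells_along(field: CellField, path, corridor_halfwidth: float | None = None) -> int:
    """Number of nuclei whose center lies within ``corridor_halfwidth`` µm
    of the polyline ``path``.

    The default corridor half-width is half the field's cell diameter, so a
    single lattice row/column is counted once.
    """
    if corridor_halfwidth is None:
        corridor_halfwidth = 0.5 * field.cell_diameter_um
    if corridor_halfwidth <= 0:
        raise GeometryError("corridor_halfwidth must be > 0")
    p = np.asarray(path, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise GeometryError("path must be a polyline with >= 2 vertices")
    line = LineString(p)
    if line.length == 0:
        raise GeometryError("path has zero length")
    pts = shapely.points(field.nuclei["x_um"].to_numpy(),
                         field.nuclei["y_um"].to_numpy())
    return int(np.count_nonzero(shapely.dwithin(pts, line, corridor_halfwidth)))


def score_en_stripes(field: CellField, gap_cells: float = 1.5) -> int:
    """Count En stripes that form a complete transverse line.

    A stripe is scored only if its labeled nuclei form a connected chain
    reaching from one lateral margin of the animal to the other; scattered
    En-positive cells are not scored.  Two nuclei are adjacent when the gap
    between their edges is at most ``gap_cells`` cell diameters, i.e. their
    centers are within ``(1 + gap_cells)`` diameters.
    """
    lm = field.landmarks
    if lm.margin_left is None or lm.margin_right is None:
        raise LandmarkError("field has no lateral-margin landmarks")
    d = field.cell_diameter_um
    link = (1.0 + gap_cells) * d
    edge_tol = 1.5 * d
    nuc = field.nuclei
    count = 0
    for k in sorted(nuc["stripe_id"].dropna().unique()):
        sel = nuc[nuc["stripe_id"] == k]
        xy = sel[["x_um", "y_um"]].to_numpy()
        if len(xy) == 0:
            continue
        x0 = float(np.median(xy[:, 0]))
        y_left = float(np.interp(x0, lm.margin_left[:, 0], lm.margin_left[:, 1]))
        y_right = float(np.interp(x0, lm.margin_right[:, 0], lm.margin_right[:, 1]))
        if len(xy) == 1:
            continue
        tree = cKDTree(xy)
        graph = tree.sparse_distance_matrix(tree, link, output_type="coo_matrix")
        n_comp, labels = connected_components(graph.tocsr(), directed=False)
        for c in range(n_comp):
            ys = xy[labels == c, 1]
            if ys.min() <= y_left + edge_tol and ys.max() >= y_right - edge_tol:
                count += 1
                break
    return count


def _arclength(poly: np.ndarray) -> float:
    return float(LineString(np.asarray(poly, dtype=float)).length)


def _margin_polygon(lm, x_min: float, x_max: float) -> np.ndarray:
    """Closed ring following the lateral margins between two axial positions."""
    left, right = lm.margin_left, lm.margin_right
    mask = (left[:, 0] >= x_min - 1e-9) & (left[:, 0] <= x_max + 1e-9)
    if mask.sum() < 2:
        return np.empty((0, 2))
    return np.vstack([right[mask], left[mask][::-1]])


def measure_larva(field: CellField,
                  corridor_halfwidth: float | None = None) -> MorphometricRecord:
    """Measure the full morphometric record of one field.

    Pure: repeated calls on the same field return identical records.
    """
    lm = field.landmarks
    for name in ("midline", "gz_midline", "widthA_line", "widthB_line",
                 "margin_left", "margin_right"):
        if getattr(lm, name) is None:
            raise LandmarkError(f"field lacks landmark {name!r}")
    d = field.cell_diameter_um
    hw = corridor_halfwidth if corridor_halfwidth is not None else 0.5 * d

    en = score_en_stripes(field)
    body_um = field.body_anterior_offset_um + _arclength(lm.midline)
    gz_len_um = _arclength(lm.gz_midline)
    wA_um = _arclength(lm.widthA_line)
    wB_um = _arclength(lm.widthB_line)

    xA = float(np.mean(lm.widthA_line[:, 0]))
    xB = float(np.mean(lm.widthB_line[:, 0]))
    trunk_ring = _margin_polygon(lm, lm.margin_left[0, 0], xB)
    gz_ring = _margin_polygon(lm, xA, xB)
    trunk_area = polygon_area(trunk_ring) if len(trunk_ring) >= 3 else 0.0
    gz_area = polygon_area(gz_ring) if len(gz_ring) >= 3 else 0.0

    gz_cells = count_cells_along(field, lm.gz_midline, hw) if gz_len_um > 0 else 0
    wA_cells = count_cells_along(field, lm.widthA_line, hw)
    wB_cells = count_cells_along(field, lm.widthB_line, hw)

    if en >= 2 and lm.last_segment_line is not None and \
            lm.last_segment_line[1, 0] > lm.last_segment_line[0, 0]:
        ls_len_um = _arclength(lm.last_segment_line)
        ls_cells = count_cells_along(field, lm.last_segment_line, hw)
        x_pen = float(np.mean(lm.stripe_lines[max(lm.stripe_lines) - 1][:, 0]))
        ls_ring = _margin_polygon(lm, x_pen + d, xA)
        ls_area = polygon_area(ls_ring) / 1e6 if len(ls_ring) >= 3 else 0.0
        ls_len_mm = ls_len_um / 1000.0
    else:
        # fewer than two stripes: last-segment measures are undefined
        ls_len_mm = ls_area = None
        ls_cells = None

    gz = field.region_nuclei("growth_zone")
    return MorphometricRecord(
        en_stripes=en,
        body_length_mm=body_um / 1000.0,
        gz_length_mm=gz_len_um / 1000.0,
        gz_length_cells=gz_cells,
        gz_widthA_mm=wA_um / 1000.0,
        gz_widthA_cells=wA_cells,
        gz_widthB_mm=wB_um / 1000.0,
        gz_widthB_cells=wB_cells,
        trunk_area_mm2=trunk_area / 1e6,
        last_segment_area_mm2=ls_area,
        gz_area_mm2=gz_area / 1e6,
        last_segment_length_mm=ls_len_mm,
        last_segment_length_cells=ls_cells,
        mitoses_gz_hoechst=int(gz["m_hoechst"].sum()),
        mitoses_gz_ph3=int(gz["m_ph3"].sum()),
        stage_h=field.stage_h,
    )


def records_to_frame(records) -> pd.DataFrame:
    """Stack MorphometricRecords into a DataFrame."""
    return pd.DataFrame([r.to_dict() for r in records])
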