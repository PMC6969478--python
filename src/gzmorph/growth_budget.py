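"""Cell-count growth budget of the posterior growth zone.

Bookkeeping that converts growth-zone and new-segment cell-field areas
(counted in cells) into the average number of divisions the initial
growth-zone pool must undergo to supply all new segmental tissue.

The growth-zone cell-field area is a trapezoid, length × mean of the two
widths; each newly added segment is a rectangle, length × width A.  Under
the default *depletion* lineage model all final segmental tissue descends
from the initial pool, which is itself consumed (the growth zone shrinks
away), so the required doublings are ``log2(total_new / g0)``.  The
alternative *persistence* model (the pool survives alongside its output)
gives ``log2(1 + total_new / g0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import DomainError

__all__ = ["DivisionBudget", "gz_cell_area", "segment_cell_area",
           "divisions_required", "area_bookkeeping", "percent_change",
           "round_about", "budget_from_cohort"]


def gz_cell_area(length_cells: float, widthA_cells: float,
                 widthB_cells: float) -> float:
    """Growth-zone cell-field area: length × (widthA + widthB) / 2."""
    if min(length_cells, widthA_cells, widthB_cells) < 0:
        raise DomainError("cell counts must be >= 0")
    return float(length_cells * (widthA_cells + widthB_cells) / 2.0)


def segment_cell_area(length_cells: float, widthA_cells: float) -> float:
    """New-segment cell-field area: last segment length × width A."""
    if min(length_cells, widthA_cells) < 0:
        raise DomainError("cell counts must be >= 0")
    return float(length_cells * widthA_cells)


def divisions_required(g0_cells: float, total_new_cells: float,
                       mode: str = "depletion") -> float:
    """Average doublings of the initial pool needed to produce the new tissue.

    ``mode="depletion"`` (default): the pool is consumed into the output,
    d = log2(total/g0), floored at 0.  ``mode="persistence"``: the pool
    remains, d = log2(1 + total/g0).
    """
    if g0_cells <= 0:
        raise DomainError("g0_cells must be > 0")
    if total_new_cells < 0:
        raise DomainError("total_new_cells must be >= 0")
    if mode == "depletion":
        return max(0.0, math.log2(total_new_cells / g0_cells)) \
            if total_new_cells > 0 else 0.0
    if mode == "persistence":
        return math.log2(1.0 + total_new_cells / g0_cells)
    raise DomainError(f"unknown mode {mode!r}")


def area_bookkeeping(gz_area0_mm2: float, per_stage_last_segment_areas_mm2):
    """(total area of all newly formed segments, growth zone share in %).

    The total sums each newest segment's ventral area measured at the stage
    it formed; the share is 100 × gz_area0 / total (NaN when the total is 0
    and the growth zone is not itself empty).
    """
    areas = np.asarray(list(per_stage_last_segment_areas_mm2), dtype=float)
    if gz_area0_mm2 < 0 or (areas < 0).any():
        raise DomainError("areas must be >= 0")
    total = float(areas.sum())
    if total == 0.0:
        fraction = 0.0 if gz_area0_mm2 == 0.0 else math.nan
    else:
        fraction = 100.0 * gz_area0_mm2 / total
    return total, fraction


def percent_change(v0: float, v1: float) -> float:
    """Percent change from ``v0`` to ``v1``: 100 × (v1 − v0) / v0."""
    if v0 <= 0:
        raise DomainError("v0 must be > 0")
    return 100.0 * (v1 - v0) / v0


def round_about(value: float, base: int = 10) -> float:
    """Round to the nearest ``base`` — the "about 140 %" reporting style."""
    return float(base * round(value / base))


@dataclass
class DivisionBudget:
    g0_cells: float
    segment_cells: list
    total_new_cells: float
    divisions_required: float
    divisions_required_persistence: float
    gz_area0_mm2: float | None = None
    total_segment_area_mm2: float | None = None
    gz_area_fraction_pct: float | None = None

    def __post_init__(self):
        if abs(self.total_new_cells - sum(self.segment_cells)) > 1e-9:
            raise ValueError("total_new_cells must equal sum(segment_cells)")

    def to_dict(self) -> dict:
        return asdict(self)


def budget_from_cohort(cohort: pd.DataFrame) -> DivisionBudget:
    """Build a division budget from a measured cohort table.

    The initial pool is the growth-zone cell-field area at the earliest
    stage (lowest stripe count); each later stripe count contributes one
    new segment, its cell-field area taken as the stage-mean last-segment
    length (cells) × stage-mean width A (cells).  Area bookkeeping uses the
    corresponding mm² measures.
    """
    required = {"en_stripes", "gz_length_cells", "gz_widthA_cells",
                "gz_widthB_cells", "last_segment_length_cells",
                "last_segment_area_mm2", "gz_area_mm2"}
    missing = required - set(cohort.columns)
    if missing:
        raise DomainError(f"cohort table lacks columns {sorted(missing)}")
    by = cohort.groupby("en_stripes")
    means = by[["gz_length_cells", "gz_widthA_cells", "gz_widthB_cells",
                "last_segment_length_cells", "last_segment_area_mm2",
                "gz_area_mm2"]].mean()
    first = means.index.min()
    g0 = gz_cell_area(means.loc[first, "gz_length_cells"],
                      means.loc[first, "gz_widthA_cells"],
                      means.loc[first, "gz_widthB_cells"])
    seg_cells, seg_areas = [], []
    for en in means.index:
        if en == first:
            continue
        seg_cells.append(segment_cell_area(
            means.loc[en, "last_segment_length_cells"],
            means.loc[en, "gz_widthA_cells"]))
        seg_areas.append(means.loc[en, "last_segment_area_mm2"])
    total = float(sum(seg_cells))
    total_area, fraction = area_bookkeeping(
        float(means.loc[first, "gz_area_mm2"]), seg_areas)
    return DivisionBudget(
        g0_cells=g0, segment_cells=seg_cells, total_new_cells=total,
        divisions_required=divisions_required(g0, total, "depletion"),
        divisions_required_persistence=divisions_required(g0, total,
                                                          "persistence"),
        gz_area0_mm2=float(means.loc[first, "gz_area_mm2"]),
        total_segment_area_mm2=total_area,
        gz_area_fraction_pct=fraction,
    )
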