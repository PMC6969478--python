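"""Mitosis, spindle orientation, and S-phase (EdU) domain statistics.

Mitosis is scored with two independent markers: nuclear morphology
("hoechst", late M phase) and phospho-histone H3 ("ph3", early M phase).
The two flags are scored independently — in this system they correlate
poorly within individuals because the marker windows barely overlap.

A 30-min EdU pulse labels every nucleus in S phase.  Along the posterior
trunk this produces three stable domains, detected here from a sliding-
window S-phase fraction profile: a *synchronous band* filling the newest
segment (fraction near 1), a *clear* anterior growth zone (near 0) and a
*scattered* posterior growth zone (intermediate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .errors import DomainError, GeometryError
from .field import CellField

__all__ = ["OrientationSummary", "EdUDomainProfile", "BandExclusion",
           "mitotic_index", "classify_orientation", "orientation_summary",
           "detect_edu_domains", "ph3_band_exclusion", "boundary_concordance"]

MARKER_COLUMNS = {"hoechst": "m_hoechst", "ph3": "m_ph3"}

SYNC_THRESHOLD = 0.8
CLEAR_THRESHOLD = 0.1


def mitotic_index(field: CellField, region: str, marker: str = "hoechst"):
    """(count, fraction) of ``region`` nuclei flagged mitotic by ``marker``.

    The fraction is NaN for an empty region (count 0).
    """
    if marker not in MARKER_COLUMNS:
        raise DomainError(f"marker must be one of {sorted(MARKER_COLUMNS)}")
    nuc = field.region_nuclei(region)
    count = int(nuc[MARKER_COLUMNS[marker]].sum())
    frac = count / len(nuc) if len(nuc) else math.nan
    return count, frac


def classify_orientation(angle_deg: float) -> str:
    """Classify a spindle angle to the AP axis: ``"AP"`` iff angle <= 45°.

    The tie at exactly 45° is assigned to AP by convention.
    """
    if not 0.0 <= angle_deg <= 90.0 or not math.isfinite(angle_deg):
        raise DomainError(f"spindle angle must be in [0, 90], got {angle_deg}")
    return "AP" if angle_deg <= 45.0 else "transverse"


@dataclass
class OrientationSummary:
    n_mitoses: int
    n_ap: int
    ap_fraction: float          # NaN when n_mitoses == 0
    by_region: dict = dc_field(default_factory=dict)


def orientation_summary(field: CellField) -> OrientationSummary:
    """Spindle-orientation summary over all mitotic nuclei, per region.

    A nucleus counts as mitotic if either marker flags it; every mitotic
    nucleus carries a spindle angle.
    """
    nuc = field.nuclei
    mit = nuc[nuc["m_hoechst"] | nuc["m_ph3"]]
    by_region = {}
    for region in ("growth_zone", "segmented"):
        sub = mit[mit["region"] == region]
        n = len(sub)
        n_ap = sum(classify_orientation(a) == "AP" for a in sub["spindle_deg"])
        by_region[region] = {"n_mitoses": n, "n_ap": n_ap,
                             "ap_fraction": n_ap / n if n else math.nan}
    n = len(mit)
    n_ap = sum(classify_orientation(a) == "AP" for a in mit["spindle_deg"])
    return OrientationSummary(n_mitoses=n, n_ap=n_ap,
                              ap_fraction=n_ap / n if n else math.nan,
                              by_region=by_region)


@dataclass
class EdUDomainProfile:
    window_um: float
    #: ordered (x_center, S-phase fraction) pairs
    profile: list
    #: ordered, contiguous (class, x_start, x_end) anterior -> posterior
    domains: list
    band_sync_fraction: float   # NaN if no synchronous band detected
    ph3_in_band: int
    span: tuple                 # profiled (x_start, x_end)

    def domain(self, cls: str):
        """First domain of class ``cls`` or None."""
        for c, a, b in self.domains:
            if c == cls:
                return (a, b)
        return None


def _classify_window(frac: float) -> str:
    if frac >= SYNC_THRESHOLD:
        return "synchronous_band"
    if frac <= CLEAR_THRESHOLD:
        return "clear"
    return "scattered"


def detect_edu_domains(field: CellField, window_um: float | None = None,
                       step_um: float | None = None,
                       min_domain_um: float | None = None) -> EdUDomainProfile:
    """Detect axial S-phase domains posterior to the penultimate En stripe.

    A sliding window of width ``window_um`` (default twice the cell
    diameter, step half a cell diameter) moves from the penultimate stripe
    to the growth-zone/telson boundary; each window is classified by its
    S-phase fraction (>= 0.8 synchronous band, <= 0.1 clear, otherwise
    scattered), adjacent same-class windows are merged, and domains shorter
    than ``min_domain_um`` (default one window width) are absorbed into
    their longer neighbor.  Invariant to uniform translation of the field.
    """
    d = field.cell_diameter_um
    window_um = 2.0 * d if window_um is None else float(window_um)
    step_um = d / 2.0 if step_um is None else float(step_um)
    min_domain_um = window_um if min_domain_um is None else float(min_domain_um)
    if window_um <= 0 or step_um <= 0:
        raise GeometryError("window_um and step_um must be > 0")

    lm = field.landmarks
    stripes = sorted(lm.stripe_lines)
    if len(stripes) < 2:
        raise DomainError("domain detection needs at least 2 En stripes")
    # span starts just posterior to the penultimate stripe row
    x_start = float(np.mean(lm.stripe_lines[stripes[-2]][:, 0])) + d / 2.0
    x_end = float(np.mean(lm.widthB_line[:, 0])) + d / 2.0
    if window_um > x_end - x_start:
        raise GeometryError("window larger than the profiled span")

    nuc = field.nuclei[field.nuclei["region"] != "telson"]
    x = nuc["x_um"].to_numpy()
    s = nuc["s_phase"].to_numpy()

    centers, fracs = [], []
    c = x_start + window_um / 2.0
    while c + window_um / 2.0 <= x_end + 1e-9:
        m = (x >= c - window_um / 2.0) & (x < c + window_um / 2.0)
        n = int(m.sum())
        fracs.append(float(s[m].sum() / n) if n else math.nan)
        centers.append(c)
        c += step_um
    centers = np.asarray(centers)
    fracs = np.asarray(fracs)
    # empty windows inherit the previous (then next) defined fraction
    if np.isnan(fracs).any():
        idx = np.arange(len(fracs))
        ok = ~np.isnan(fracs)
        if not ok.any():
            raise GeometryError("no nuclei in the profiled span")
        fracs = np.interp(idx, idx[ok], fracs[ok])

    classes = [_classify_window(f) for f in fracs]

    # run-length encode into contiguous domains with boundaries at window
    # mid-gaps
    def runs_to_domains(cls_seq):
        doms = []
        start = x_start
        for i in range(1, len(cls_seq) + 1):
            if i == len(cls_seq) or cls_seq[i] != cls_seq[i - 1]:
                end = x_end if i == len(cls_seq) else \
                    float((centers[i - 1] + centers[i]) / 2.0)
                doms.append([cls_seq[i - 1], start, end])
                start = end
        return doms

    domains = runs_to_domains(classes)
    # absorb sub-resolution domains into the longer neighbor
    changed = True
    while changed and len(domains) > 1:
        changed = False
        widths = [b - a for _, a, b in domains]
        i = int(np.argmin(widths))
        if widths[i] < min_domain_um:
            if i == 0:
                domains[1][1] = domains[0][1]
                del domains[0]
            elif i == len(domains) - 1:
                domains[-2][2] = domains[-1][2]
                del domains[-1]
            else:
                left_w = domains[i - 1][2] - domains[i - 1][1]
                right_w = domains[i + 1][2] - domains[i + 1][1]
                mid = (domains[i][1] + domains[i][2]) / 2.0
                if left_w >= right_w:
                    domains[i - 1][2] = domains[i][2]
                else:
                    domains[i + 1][1] = domains[i][1]
                del domains[i]
            # re-merge identical neighbors
            j = 0
            while j < len(domains) - 1:
                if domains[j][0] == domains[j + 1][0]:
                    domains[j][2] = domains[j + 1][2]
                    del domains[j + 1]
                else:
                    j += 1
            changed = True

    # refine each internal boundary to the half-level crossing of the
    # profile (a box window blurs a step edge symmetrically, so the edge
    # sits where the profile crosses the midpoint of the two domain levels)
    def _level(dom):
        m = (centers >= dom[1]) & (centers < dom[2])
        return float(np.mean(fracs[m])) if m.any() else math.nan

    for i in range(len(domains) - 1):
        b = domains[i][2]
        l1, l2 = _level(domains[i]), _level(domains[i + 1])
        if math.isnan(l1) or math.isnan(l2) or l1 == l2:
            continue
        thr = (l1 + l2) / 2.0
        m = (centers >= b - window_um) & (centers <= b + window_um)
        xs, fs = centers[m], fracs[m]
        best = None
        for k in range(len(xs) - 1):
            f0, f1 = fs[k], fs[k + 1]
            if (f0 - thr) * (f1 - thr) <= 0 and f0 != f1:
                xc = float(xs[k] + (thr - f0) / (f1 - f0) * (xs[k + 1] - xs[k]))
                if best is None or abs(xc - b) < abs(best - b):
                    best = xc
        if best is not None:
            nb = min(max(best, domains[i][1] + 1e-9),
                     domains[i + 1][2] - 1e-9)
            domains[i][2] = nb
            domains[i + 1][1] = nb

    domains = [(c, a, b) for c, a, b in domains]

    band = next(((a, b) for c, a, b in domains if c == "synchronous_band"), None)
    if band is not None:
        in_band = (x >= band[0]) & (x < band[1])
        n_band = int(in_band.sum())
        band_frac = float(s[in_band].sum() / n_band) if n_band else math.nan
        ph3_in_band = int(nuc["m_ph3"].to_numpy()[in_band].sum())
    else:
        band_frac = math.nan
        ph3_in_band = 0

    return EdUDomainProfile(window_um=window_um,
                            profile=list(zip(centers.tolist(), fracs.tolist())),
                            domains=domains,
                            band_sync_fraction=band_frac,
                            ph3_in_band=ph3_in_band,
                            span=(x_start, x_end))


@dataclass
class BandExclusion:
    observed: int
    expected: float
    ratio: float                # NaN when expected == 0


def ph3_band_exclusion(field: CellField,
                       profile: EdUDomainProfile) -> BandExclusion | None:
    """Observed vs. expected-under-uniformity pH3 counts in the synchronous band.

    The expectation distributes the span's total pH3 count proportionally to
    the band's share of nuclei.  Returns None (absent-flag) when the profile
    has no synchronous band.
    """
    band = profile.domain("synchronous_band")
    if band is None:
        return None
    nuc = field.nuclei[field.nuclei["region"] != "telson"]
    x = nuc["x_um"].to_numpy()
    span = (x >= profile.span[0]) & (x < profile.span[1])
    in_band = span & (x >= band[0]) & (x < band[1])
    total_ph3 = int(nuc["m_ph3"].to_numpy()[span].sum())
    share = in_band.sum() / span.sum() if span.sum() else math.nan
    expected = total_ph3 * share
    observed = int(nuc["m_ph3"].to_numpy()[in_band].sum())
    ratio = observed / expected if expected > 0 else math.nan
    return BandExclusion(observed=observed, expected=float(expected),
                         ratio=float(ratio))


#: named pairings of expression domains and S-phase domains
_CONCORDANCE_PAIRS = (
    ("WntA_vs_clear", "WntA", "clear"),
    ("Wnt4_vs_scattered", "Wnt4", "scattered"),
)


def boundary_concordance(profile: EdUDomainProfile,
                         expression_domains: dict) -> pd.DataFrame:
    """Signed offsets (µm) between expression and cell-cycle domain boundaries.

    ``expression_domains`` maps gene names to (x_start, x_end) intervals.
    Rows with a missing domain on either side carry a NaN offset
    (absent-flag).  Compared boundaries: anterior/posterior edges of
    *WntA* vs the clear domain and *Wnt4* vs the scattered domain, and the
    anterior borders of *cad* and *WntA* vs the posterior edge of the
    synchronous band.
    """
    for name, (a, b) in expression_domains.items():
        if b < a:
            raise DomainError(f"expression domain {name!r} is reversed")

    rows = []
    for pair, gene, cls in _CONCORDANCE_PAIRS:
        dom = profile.domain(cls)
        expr = expression_domains.get(gene)
        for side, j in (("anterior", 0), ("posterior", 1)):
            off = expr[j] - dom[j] if dom is not None and expr is not None \
                else math.nan
            rows.append({"pair": pair, "boundary": side, "offset_um": off})
    band = profile.domain("synchronous_band")
    for pair, gene in (("band_posterior_vs_cad_anterior", "cad"),
                       ("band_posterior_vs_WntA_anterior", "WntA")):
        expr = expression_domains.get(gene)
        off = expr[0] - band[1] if band is not None and expr is not None \
            else math.nan
        rows.append({"pair": pair, "boundary": "anterior", "offset_um": off})
    return pd.DataFrame(rows)
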