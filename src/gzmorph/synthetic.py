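"""Synthetic staged-larva generator.

Emulates the ventral epithelium of an anamorphically developing branchiopod
larva as a jittered, hexagonally offset nucleus lattice.  The generator is
the package's data source: every downstream measurement (morphometry,
mitosis/orientation statistics, S-phase domain detection, cohort statistics)
runs on fields it produces, so its defaults encode the study conditions
documented in :class:`~gzmorph.config.GeneratorConfig`.

Layout of a generated field, anterior to posterior along x:

* one block of rows per specified segment, the posterior-most row of each
  carrying that segment's En stripe label;
* the growth zone (GZ): unlabeled rows whose count shrinks as segments are
  added (plus a gain at the first molt), tapering in width from width A at
  the last stripe to width B at the telson boundary;
* the telson.

Cell-cycle labels are drawn per sub-region: the newest segment is the
synchronous S-phase band, the anterior GZ is S-phase-clear, the posterior GZ
has scattered S-phase nuclei; mitosis flags (nuclear-morphology and pH3,
independent markers) are drawn first at exactly the configured per-region
rates, and S-phase is then drawn among non-mitotic nuclei.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ._rng import derive_rng, derive_int
from .config import GeneratorConfig
from .errors import DomainError
from .field import CellField, Landmarks

__all__ = ["stage_clock", "generate_larva", "generate_cohort",
           "expression_truth", "TAGMA_ORDER"]

TAGMA_ORDER = ("thoracic_premolt", "thoracic_postmolt", "genital", "abdominal")


def stage_clock(t: float, config: GeneratorConfig | None = None) -> int:
    """Number of trunk En stripes at ``t`` hours post hatch (noise-free).

    Stripes accrue linearly, one per ``interval_h``, from ``initial_stripes``
    at hatch up to ``max_stripes``.
    """
    cfg = (config or GeneratorConfig()).validate()
    if t < 0:
        raise DomainError(f"hours post hatch must be >= 0, got {t}")
    return int(min(cfg.max_stripes,
                   cfg.initial_stripes + math.floor(t / cfg.interval_h)))


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    base = math.floor(x)
    return int(base + (rng.random() < (x - base)))


def _gz_length_cells(cfg: GeneratorConfig, added: int, molted: bool) -> float:
    if cfg.constant_gz_mode:
        return float(cfg.gz_length0_cells)
    length = cfg.gz_length0_cells - cfg.gz_shrink_per_segment * added
    if molted:
        length += cfg.molt_gz_gain_cells
    return max(length, 2.0)


def generate_larva(t: float, config: GeneratorConfig | None = None,
                   seed: int = 0) -> CellField:
    """Generate one larva fixed at ``t`` hours post hatch.

    Deterministic for fixed ``(t, config, seed)``.
    """
    cfg = (config or GeneratorConfig()).validate()
    if t < 0:
        raise DomainError(f"hours post hatch must be >= 0, got {t}")
    rng = derive_rng(seed, "larva")

    n_stripes = stage_clock(t, cfg)
    added = n_stripes - cfg.initial_stripes
    molted = t >= cfg.molt_time_h

    scale = float(np.clip(rng.normal(1.0, cfg.size_cv), 0.7, 1.3)) \
        if cfg.size_cv > 0 else 1.0
    d = cfg.cell_diameter_um * scale

    # ---- row plan: (subregion, stripe_id, n_cells) per lattice row --------
    seg_bases = []
    rows_plan: list[tuple[str, int | None, int]] = []
    for k in range(1, n_stripes + 1):
        if k <= cfg.initial_stripes:
            base = cfg.initial_seg_length_cells
        else:
            base = cfg.segment_base_length(k - cfg.initial_stripes)
        seg_bases.append(base)
        age = n_stripes - k
        m = min(cfg.seg_growth_cap, 1.0 + cfg.seg_growth_per_stage * age)
        n_rows = int(round(base * m)) + 1          # +1: the En stripe row
        n_cells = int(round(cfg.widthA_cells * m))
        sub = "band" if k == n_stripes else "seg"
        for r in range(n_rows):
            stripe = k if r == n_rows - 1 else None
            rows_plan.append((sub, stripe, n_cells))

    gz_len_c = _gz_length_cells(cfg, added, molted)
    g = max(2, _stochastic_round(gz_len_c, rng))
    wB = cfg.widthB_cells if cfg.constant_gz_mode else max(
        2.0, cfg.widthB_cells - cfg.gz_widthB_shrink_per_segment * added)
    wB_cells = int(round(wB))
    first_gz_row = len(rows_plan)
    n_clear = max(1, min(g - 1, int(round(cfg.gz_anterior_frac * g))))
    for i in range(g):
        n_cells = int(round(cfg.widthA_cells
                            + (wB_cells - cfg.widthA_cells) * (i + 1) / g))
        rows_plan.append(("gz_clear" if i < n_clear else "gz_scatter",
                          None, max(2, n_cells)))
    first_telson_row = len(rows_plan)
    for _ in range(cfg.telson_length_cells):
        rows_plan.append(("telson", None, wB_cells))

    # ---- lattice ----------------------------------------------------------
    xs, ys, subs, stripes = [], [], [], []
    row_x = np.arange(len(rows_plan), dtype=float) * d
    row_off = np.where(np.arange(len(rows_plan)) % 2 == 1, d / 4.0, -d / 4.0)
    row_halfwidth = np.empty(len(rows_plan))
    for j, (sub, stripe, n_cells) in enumerate(rows_plan):
        y = (np.arange(n_cells) - (n_cells - 1) / 2.0) * d + row_off[j]
        xs.append(np.full(n_cells, row_x[j]))
        ys.append(y)
        subs.append(np.full(n_cells, sub, dtype=object))
        stripes.append(np.full(n_cells, stripe if stripe is not None else -1))
        row_halfwidth[j] = (n_cells - 1) / 2.0 * d
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    sub = np.concatenate(subs)
    stripe_id = np.concatenate(stripes).astype(int)
    n = x.size
    jf = cfg.jitter_frac * d
    x = x + rng.uniform(-jf, jf, n)
    y = y + rng.uniform(-jf, jf, n)

    # ---- cell-cycle labels -------------------------------------------------
    p_mh = {"seg": cfg.seg_mitotic_fraction,
            "band": cfg.seg_mitotic_fraction * cfg.band_m_suppression,
            "gz_clear": cfg.mitotic_fraction,
            "gz_scatter": cfg.mitotic_fraction,
            "telson": cfg.telson_mitotic_fraction}
    p_mp = {k: min(1.0, v * cfg.ph3_ratio) for k, v in p_mh.items()}
    p_s = {"seg": cfg.seg_s_frac, "band": cfg.band_sync_frac,
           "gz_clear": cfg.edu_clear_frac, "gz_scatter": cfg.edu_scatter_frac,
           "telson": cfg.telson_s_frac}
    p_ap = {"seg": cfg.seg_ap_orientation_prob,
            "band": cfg.seg_ap_orientation_prob,
            "gz_clear": cfg.ap_orientation_prob,
            "gz_scatter": cfg.ap_orientation_prob,
            "telson": 0.5}

    def per_sub(mapping):
        return np.array([mapping[s] for s in sub])

    m_h = rng.random(n) < per_sub(p_mh)
    m_p = rng.random(n) < per_sub(p_mp)
    m_any = m_h | m_p
    s_phase = (rng.random(n) < per_sub(p_s)) & ~m_any
    # telson nuclei never belong to the synchronous band; S there is sparse
    is_ap = rng.random(n) < per_sub(p_ap)
    ang_ap = rng.uniform(0.0, 45.0, n)
    ang_tr = rng.uniform(45.0, 90.0, n)
    angle = np.where(is_ap, ang_ap, ang_tr)
    spindle = np.where(m_any, angle, np.nan)

    if cfg.band_lateral_spill_prob > 0 and n_stripes >= 2:
        # the band occasionally extends into the lateral edges of the
        # penultimate segment
        if rng.random() < cfg.band_lateral_spill_prob:
            penult_x = _stripe_row_x(rows_plan, row_x, n_stripes - 1)
            lateral = (np.abs(x - penult_x) < d / 2) & \
                (np.abs(y) > 0.6 * np.abs(y).max()) & ~m_any
            s_phase = s_phase | (lateral & (rng.random(n) < cfg.band_sync_frac))

    nuclei = pd.DataFrame({
        "x_um": x, "y_um": y,
        "stripe_id": pd.array(np.where(stripe_id > 0, stripe_id, None),
                              dtype="Int64"),
        "region": np.where(np.isin(sub, ["seg", "band"]), "segmented",
                           np.where(sub == "telson", "telson", "growth_zone")),
        "s_phase": s_phase, "m_hoechst": m_h, "m_ph3": m_p,
        "spindle_deg": spindle,
    })

    # ---- landmarks ---------------------------------------------------------
    def row_line(j: int) -> np.ndarray:
        h = row_halfwidth[j]
        return np.array([[row_x[j], row_off[j] - h], [row_x[j], row_off[j] + h]])

    stripe_rows = {s: j for j, (_, s, _) in enumerate(rows_plan)
                   if s is not None}
    last_gz_row = first_telson_row - 1
    last_row = len(rows_plan) - 1
    stripe_lines = {k: row_line(j) for k, j in stripe_rows.items()}
    last_stripe_row = stripe_rows[n_stripes]
    lm = Landmarks(
        midline=np.array([[0.0, 0.0], [row_x[last_row], 0.0]]),
        gz_midline=np.array([[row_x[first_gz_row], 0.0],
                             [row_x[last_gz_row], 0.0]]),
        stripe_lines=stripe_lines,
        widthA_line=stripe_lines[n_stripes],
        widthB_line=row_line(last_gz_row),
        margin_left=np.column_stack([row_x, row_off - row_halfwidth]),
        margin_right=np.column_stack([row_x, row_off + row_halfwidth]),
    )
    if n_stripes >= 2:
        penult_row = stripe_rows[n_stripes - 1]
        lm.last_segment_line = np.array(
            [[row_x[penult_row] + d, 0.0], [row_x[last_stripe_row] - d, 0.0]])

    band_a = row_x[stripe_rows[n_stripes - 1]] + d / 2 if n_stripes >= 2 else 0.0
    gz_a = row_x[last_stripe_row] + d / 2
    gz_p = row_x[last_gz_row] + d / 2
    split_x = gz_a + cfg.gz_anterior_frac * g * d
    truth = {
        "stripes": n_stripes, "added": added, "molted": molted,
        "scale": scale,
        "gz_length_cells": g, "gz_length_cells_continuous": gz_len_c,
        "widthA_cells": int(cfg.widthA_cells), "widthB_cells": wB_cells,
        "seg_base_cells": seg_bases, "newest_base_cells": seg_bases[-1],
        "band_interval": (band_a, gz_a),
        "clear_interval": (gz_a, split_x),
        "scatter_interval": (split_x, gz_p),
        "telson_interval": (gz_p, row_x[last_row] + d / 2),
        "span": (row_x[stripe_rows[n_stripes - 1]] + d / 2 if n_stripes >= 2
                 else row_x[last_stripe_row] + d / 2, gz_p),
    }
    return CellField(nuclei=nuclei, landmarks=lm, stage_h=float(t),
                     seed=int(seed), cell_diameter_um=d,
                     body_anterior_offset_um=cfg.head_length_um * scale,
                     truth=truth)


def _stripe_row_x(rows_plan, row_x, k):
    for j, (_, s, _) in enumerate(rows_plan):
        if s == k:
            return row_x[j]
    raise KeyError(k)


def expression_truth(field: CellField) -> dict:
    """Ground-truth posterior gene-expression intervals for a generated field.

    *WntA* spans the anterior (S-phase-clear) growth zone, *Wnt4* the
    posterior (scattered) growth zone, *cad* the whole growth zone up to the
    telson, *Wnt6* the telson.  Returned as ``name -> (x_start, x_end)`` µm.
    """
    t = field.truth
    required = ("clear_interval", "scatter_interval", "telson_interval")
    if not all(k in t for k in required):
        raise KeyError("field carries no generator truth intervals")
    return {
        "WntA": tuple(t["clear_interval"]),
        "Wnt4": tuple(t["scatter_interval"]),
        "cad": (t["clear_interval"][0], t["scatter_interval"][1]),
        "Wnt6": tuple(t["telson_interval"]),
    }


def generate_cohort(config: GeneratorConfig | None = None,
                    n_per_timepoint: int = 25,
                    timepoints=tuple(range(19)),
                    seed: int = 0,
                    measure: bool = True) -> pd.DataFrame:
    """Generate a staged cohort table, one row per larva.

    Each larva gets a segmentation-cycle phase (uniform on
    ``[0, phase_jitter_frac * interval_h)``), a hatch-time jitter (uniform on
    ``±hatch_jitter_min/2``) and a stripe-count observation noise (uniform on
    ``{-k..k}``).  With ``measure=True`` a full cell field is generated and
    measured for every larva (columns of
    :class:`~gzmorph.morphometry.MorphometricRecord` are appended);
    with ``measure=False`` only staging columns are produced.

    Reproducible under ``(config, seed)``.
    """
    from .cohort_stats import assign_tagma
    from .morphometry import measure_larva

    cfg = (config or GeneratorConfig()).validate()
    timepoints = list(timepoints)
    if not timepoints:
        raise DomainError("timepoints must be non-empty")
    if n_per_timepoint < 1:
        raise DomainError("n_per_timepoint must be >= 1")
    rng = derive_rng(seed, "cohort")

    rows = []
    idx = 0
    for tp in timepoints:
        if tp < 0:
            raise DomainError("timepoints must be >= 0")
        m = n_per_timepoint
        phase = rng.uniform(0.0, cfg.phase_jitter_frac * cfg.interval_h, m) \
            if cfg.phase_jitter_frac > 0 else np.zeros(m)
        jit_h = cfg.hatch_jitter_min / 60.0
        jitter = rng.uniform(-jit_h / 2, jit_h / 2, m) if jit_h > 0 else np.zeros(m)
        k = cfg.stage_noise_stripes
        noise = rng.integers(-k, k + 1, m) if k > 0 else np.zeros(m, dtype=int)
        t_dev = np.clip(tp + phase + jitter, 0.0, None)
        for i in range(m):
            en_true = stage_clock(float(t_dev[i]), cfg)
            en_obs = max(0, en_true + int(noise[i]))
            row = {"larva_id": f"t{tp}_n{i}", "stage_h": float(tp),
                   "t_dev_h": float(t_dev[i]), "en_stripes": en_obs,
                   "tagma": assign_tagma(en_obs)}
            if measure:
                fld = generate_larva(float(t_dev[i]), cfg,
                                     seed=derive_int(seed, "cohort_field", idx))
                rec = measure_larva(fld)
                rd = rec.to_dict()
                rd.pop("en_stripes", None)
                rd.pop("stage_h", None)
                rd.pop("tagma", None)
                row.update(rd)
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)
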