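"""End-to-end analysis pipeline and report assembly.

``run_pipeline`` chains simulate -> measure -> cell dynamics -> growth
budget -> cohort statistics on a synthetic cohort and assembles an
:class:`AnalysisReport`: the segment-addition rate fit, per-stage
morphometric summaries, the division budget, S-phase domain and orientation
summaries, PCA/group-separation statistics and provenance.  Deterministic
for a fixed (config, seed); the JSON serialization is byte-identical across
runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import derive_int
from .cell_dynamics import (detect_edu_domains, mitotic_index,
                            orientation_summary, ph3_band_exclusion)
from .cohort_stats import (OUT_OF_RANGE, pca_morphometrics,
                           regress_pc1_on_group, segment_addition_rate,
                           tagma_group_compare, tagma_separation)
from .config import GeneratorConfig
from .growth_budget import budget_from_cohort
from .synthetic import generate_cohort, generate_larva

logger = logging.getLogger("gzmorph")

__all__ = ["AnalysisReport", "run_pipeline"]

SUMMARY_MEASURES = ("body_length_mm", "gz_length_mm", "gz_length_cells",
                    "gz_widthA_mm", "gz_widthB_mm", "trunk_area_mm2",
                    "last_segment_area_mm2", "gz_area_mm2",
                    "last_segment_length_mm", "mitoses_gz_hoechst",
                    "mitoses_gz_ph3")


@dataclass
class AnalysisReport:
    provenance: dict
    rate_fit: dict
    per_stage: list
    budget: dict
    edu: dict
    orientation: dict
    statistics: dict
    flags: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"provenance": self.provenance, "rate_fit": self.rate_fit,
                "per_stage": self.per_stage, "budget": self.budget,
                "edu": self.edu, "orientation": self.orientation,
                "statistics": self.statistics, "flags": self.flags}

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _config_hash(cfg: GeneratorConfig) -> str:
    canon = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def _nan_to_none(x):
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


def run_pipeline(config: GeneratorConfig | None = None, seed: int = 0,
                 n_per_timepoint: int = 25, timepoints=tuple(range(19)),
                 n_permutations: int = 999,
                 out_dir=None) -> AnalysisReport:
    """Run the full synthetic analysis and assemble a report.

    With ``out_dir``, writes ``report.json``, ``cohort.csv`` and
    ``per_stage.csv`` there.
    """
    cfg = (config or GeneratorConfig()).validate()
    logger.info("pipeline: generating cohort (%d larvae/timepoint, %d timepoints)",
                n_per_timepoint, len(list(timepoints)))
    cohort = generate_cohort(cfg, n_per_timepoint, timepoints, seed=seed,
                             measure=True)

    rate = segment_addition_rate(cohort).to_dict()

    per_stage = []
    for tp, sub in cohort.groupby("stage_h"):
        entry = {"stage_h": float(tp), "n": int(len(sub)),
                 "en_mean": float(sub["en_stripes"].mean())}
        for m in SUMMARY_MEASURES:
            vals = sub[m].dropna()
            entry[m] = {"mean": _nan_to_none(float(vals.mean())),
                        "sd": _nan_to_none(float(vals.std(ddof=1))),
                        "n": int(len(vals))}
        per_stage.append(entry)

    budget = budget_from_cohort(cohort).to_dict()

    # cell dynamics on dedicated early-stage larvae (one per hour, 0-4 h,
    # several replicates), regenerated from derived seeds
    edu_entries = []
    band_fracs, excl_ratios = [], []
    for t in range(0, 5):
        fld = generate_larva(float(t) + 0.05, cfg,
                             seed=derive_int(seed, "edu", t))
        prof = detect_edu_domains(fld)
        excl = ph3_band_exclusion(fld, prof)
        if not math.isnan(prof.band_sync_fraction):
            band_fracs.append(prof.band_sync_fraction)
        if excl is not None and not math.isnan(excl.ratio):
            excl_ratios.append(excl.ratio)
        edu_entries.append({
            "stage_h": float(t),
            "domain_order": [c for c, _, _ in prof.domains],
            "band_sync_fraction": _nan_to_none(prof.band_sync_fraction),
            "ph3_in_band": prof.ph3_in_band,
        })
    edu = {"per_larva": edu_entries,
           "mean_band_sync_fraction": _nan_to_none(
               float(np.mean(band_fracs)) if band_fracs else math.nan),
           "mean_ph3_band_ratio": _nan_to_none(
               float(np.mean(excl_ratios)) if excl_ratios else math.nan)}

    n_mit = n_ap = 0
    ch = cp = n_gz = 0
    for i in range(10):
        fld = generate_larva(2.05, cfg, seed=derive_int(seed, "orientation", i))
        osum = orientation_summary(fld)
        n_mit += osum.by_region["growth_zone"]["n_mitoses"]
        n_ap += osum.by_region["growth_zone"]["n_ap"]
        c, _ = mitotic_index(fld, "growth_zone", "hoechst")
        p, _ = mitotic_index(fld, "growth_zone", "ph3")
        ch += c
        cp += p
        n_gz += len(fld.region_nuclei("growth_zone"))
    orientation = {
        "gz_n_mitoses": int(n_mit), "gz_n_ap": int(n_ap),
        "gz_ap_fraction": _nan_to_none(n_ap / n_mit if n_mit else math.nan),
        "gz_hoechst_fraction": _nan_to_none(ch / n_gz if n_gz else math.nan),
        "ph3_hoechst_ratio": _nan_to_none(cp / ch if ch else math.nan),
    }

    in_range = cohort[cohort["tagma"] != OUT_OF_RANGE]
    n_excluded = len(cohort) - len(in_range)
    if n_excluded:
        logger.warning("excluding %d larvae with out-of-range stripe counts "
                       "from tagma statistics", n_excluded)
    pca = pca_morphometrics(in_range)
    labels = in_range.dropna(
        subset=[c for c in pca.loadings.index])["tagma"].to_numpy()
    stat, p_sep = tagma_separation(pca.scores, labels,
                                   n_permutations=n_permutations, seed=seed)
    adj_r2, p_reg = regress_pc1_on_group(pca.scores[:, 0], labels)
    tukey = tagma_group_compare(in_range, "gz_length_mm")
    statistics = {
        "pca_variance_fractions": [float(v) for v in pca.variance_fractions],
        "pc1_fraction": float(pca.variance_fractions[0]),
        "tagma_separation": {"pseudo_F": stat, "p": p_sep,
                             "n_permutations": n_permutations},
        "pc1_on_tagma": {"adj_r2": adj_r2, "p": p_reg},
        "tukey_gz_length": tukey.to_dict(orient="records"),
        "n_excluded_out_of_range": int(n_excluded),
    }

    # growth-zone trend flag: z-score of the per-stage mean GZ-length slope
    means = cohort.groupby("stage_h")["gz_length_mm"].mean().reset_index()
    fit = segment_addition_rate(means, time_col="stage_h",
                                count_col="gz_length_mm")
    gz_slope_z = fit.slope / fit.slope_se if fit.slope_se > 0 else 0.0
    flags = {"gz_length_nondecreasing": bool(gz_slope_z > -3.0),
             "gz_length_slope_mm_per_h": fit.slope,
             "constant_gz_mode": bool(cfg.constant_gz_mode)}

    report = AnalysisReport(
        provenance={"package": "gzmorph", "version": __version__,
                    "seed": int(seed), "config_hash": _config_hash(cfg),
                    "config": cfg.to_dict(),
                    "n_per_timepoint": int(n_per_timepoint),
                    "timepoints": [float(t) for t in timepoints]},
        rate_fit=rate, per_stage=per_stage, budget=budget, edu=edu,
        orientation=orientation, statistics=statistics, flags=flags)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json(), encoding="utf-8")
        cohort.to_csv(out / "cohort.csv", index=False, float_format="%.10g")
        pd.json_normalize(per_stage).to_csv(out / "per_stage.csv", index=False,
                                            float_format="%.10g")
    return report
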