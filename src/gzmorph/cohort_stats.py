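"""Cohort-level staging statistics.

Covers the segment-addition rate (OLS of stripe count on hours post hatch),
tagma assignment from stripe count, PCA of the eight standardized
morphometric measures, a permutation test of tagma separation in PC space
(a distribution-free stand-in for a parametric MANOVA), PC1-on-group
regression, and Tukey-HSD pairwise tagma comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import derive_rng
from .errors import (DegenerateColumnError, DegenerateFitError, DomainError,
                     GroupingError)
from .morphometry import PCA_MEASURES

__all__ = ["RateFit", "PCAResult", "assign_tagma", "segment_addition_rate",
           "pca_morphometrics", "tagma_separation", "regress_pc1_on_group",
           "tagma_group_compare", "TAGMA_LEVELS", "TAGMA_CODES"]

#: stripe-count ranges defining the four axial groups
TAGMA_LEVELS = {
    "thoracic_premolt": range(3, 7),     # En stripes 3-6
    "thoracic_postmolt": range(7, 12),   # 7-11
    "genital": range(12, 14),            # 12-13
    "abdominal": range(14, 18),          # 14-17
}
TAGMA_CODES = {name: i + 1 for i, name in enumerate(TAGMA_LEVELS)}
OUT_OF_RANGE = "out_of_range"


def assign_tagma(en_stripes: int) -> str:
    """Tagma label for a stripe count; ``"out_of_range"`` outside 3-17."""
    for name, rng in TAGMA_LEVELS.items():
        if en_stripes in rng:
            return name
    return OUT_OF_RANGE


@dataclass
class RateFit:
    slope: float        # segments / h
    intercept: float    # segments at t = 0
    slope_se: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def segment_addition_rate(table: pd.DataFrame,
                          time_col: str = "stage_h",
                          count_col: str = "en_stripes") -> RateFit:
    """OLS fit of stripe count on hours post hatch, by the normal equations."""
    t = np.asarray(table[time_col], dtype=float)
    y = np.asarray(table[count_col], dtype=float)
    n = t.size
    if len(np.unique(t)) < 3:
        raise DegenerateFitError("need >= 3 distinct timepoints")
    sxx = float(np.sum((t - t.mean()) ** 2))
    sxy = float(np.sum((t - t.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * t.mean())
    resid = y - (intercept + slope * t)
    rss = float(np.sum(resid ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    slope_se = math.sqrt(rss / (n - 2) / sxx) if n > 2 else math.nan
    r2 = 1.0 - rss / tss if tss > 0 else math.nan
    return RateFit(slope=slope, intercept=intercept, slope_se=slope_se,
                   r2=r2, n=int(n))


@dataclass
class PCAResult:
    variance_fractions: np.ndarray      # length-8, sums to 1
    loadings: pd.DataFrame              # measures x components
    scores: np.ndarray                  # n x 8

    def to_dict(self) -> dict:
        return {"variance_fractions": self.variance_fractions.tolist(),
                "loadings": self.loadings.to_dict(orient="list")}


def pca_morphometrics(records: pd.DataFrame,
                      measures=PCA_MEASURES) -> PCAResult:
    """PCA of the standardized morphometric measures.

    Columns are standardized to zero mean/unit variance and the correlation
    matrix is eigendecomposed; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    X = records.loc[:, list(measures)].dropna()
    if len(X) < 9:
        raise DegenerateFitError("need >= 9 complete records for PCA")
    arr = X.to_numpy(dtype=float)
    sd = arr.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise DegenerateColumnError(measures[j])
    Z = (arr - arr.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (len(Z) - 1)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] = -evecs[:, j]
    fractions = evals / evals.sum()
    loadings = pd.DataFrame(evecs, index=list(measures),
                            columns=[f"PC{i+1}" for i in range(len(measures))])
    scores = Z @ evecs
    return PCAResult(variance_fractions=fractions, loadings=loadings,
                     scores=scores)


def _pseudo_f(scores: np.ndarray, codes: np.ndarray) -> float:
    """Between/within multivariate dispersion ratio (one-way pseudo-F)."""
    n = len(codes)
    groups = np.unique(codes)
    g = len(groups)
    grand = scores.mean(axis=0)
    ssb = 0.0
    ssw = 0.0
    for c in groups:
        sub = scores[codes == c]
        mean = sub.mean(axis=0)
        ssb += len(sub) * float(np.sum((mean - grand) ** 2))
        ssw += float(np.sum((sub - mean) ** 2))
    if ssw == 0.0:
        return math.inf if ssb > 0 else 0.0
    return (ssb / (g - 1)) / (ssw / (n - g))


def tagma_separation(scores, labels, n_permutations: int = 999,
                     seed: int = 0, n_components: int = 3):
    """Permutation test of group separation in PC1–PC3 space.

    Statistic: one-way multivariate pseudo-F (between-group over
    within-group dispersion).  p = (1 + #{perm >= observed}) /
    (1 + n_permutations).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    scores = scores[:, :n_components]
    labels = np.asarray(labels)
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise GroupingError("need >= 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise GroupingError("every group needs >= 2 rows")
    obs = _pseudo_f(scores, codes)
    rng = derive_rng(seed, "tagma_separation")
    n_ge = 0
    perm = codes.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        if _pseudo_f(scores, perm) >= obs:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return float(obs), float(p)


def regress_pc1_on_group(pc1, group):
    """(adjusted R², p) of an OLS of PC1 on an integer-coded group.

    Tagma labels are coded thoracic_premolt=1 ... abdominal=4; numeric
    groups (e.g. stripe counts) are used as is.
    """
    pc1 = np.asarray(pc1, dtype=float)
    group = np.asarray(group)
    if group.dtype.kind in "OUS":
        bad = [g for g in np.unique(group) if g not in TAGMA_CODES]
        if bad:
            raise DomainError(f"unknown tagma labels: {bad}")
        x = np.asarray([TAGMA_CODES[g] for g in group], dtype=float)
    else:
        x = group.astype(float)
    n = len(x)
    if n < 3:
        raise DegenerateFitError("need >= 3 rows")
    if len(np.unique(x)) < 2:
        raise DegenerateFitError("group has a single level")
    res = stats.linregress(x, pc1)
    r2 = res.rvalue ** 2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(adj), float(res.pvalue)


def tagma_group_compare(records: pd.DataFrame, measure: str,
                        group_col: str = "tagma") -> pd.DataFrame:
    """All pairwise group mean differences with Tukey-HSD adjusted p-values.

    Rows with an out-of-range tagma are excluded with a warning.
    """
    df = records[[group_col, measure]].dropna()
    excluded = int((df[group_col] == OUT_OF_RANGE).sum())
    if excluded:
        warnings.warn(f"excluding {excluded} out-of-range records from "
                      f"{measure} comparison", stacklevel=2)
        df = df[df[group_col] != OUT_OF_RANGE]
    groups = [g for g in TAGMA_LEVELS if g in set(df[group_col])]
    if len(groups) < 2:
        raise GroupingError("need >= 2 groups")
    samples = [df.loc[df[group_col] == g, measure].to_numpy(dtype=float)
               for g in groups]
    if min(len(s) for s in samples) < 2:
        raise GroupingError("every group needs >= 2 rows")
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rows.append({
                "group_a": groups[i], "group_b": groups[j],
                "mean_difference": float(samples[i].mean() - samples[j].mean()),
                "p_adjusted": float(res.pvalue[i, j]),
            })
    return pd.DataFrame(rows)
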