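"""Statistical core for pixel-level lipidomics.

Implements the analysis chain used for every biological question:
balanced pixel sampling per group, 50% presence/missingness filters,
95%-confidence-ellipse outlier removal in PC1-PC2, k-nearest-neighbour
imputation, pareto scaling, PCA, per-section median aggregation, rank
tests, and Benjamini-Hochberg FDR correction.

Two significance modes exist because pixel counts and replicate counts
differ by orders of magnitude: ``pixel_rank_sum`` (Mann-Whitney U across
pixels) is the default for feature screening, while per-section medians
(n = biological replicates) feed the trend summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.impute import KNNImputer
from statsmodels.stats.multitest import multipletests

from .core import FeatureMatrix

logger = logging.getLogger(__name__)


@dataclass
class StatsParams:
    """Defaults follow the study workflow: 200 pixels per tissue type,
    50% presence and missingness filters, 95% confidence ellipse,
    k = 5 imputation."""

    n_per_group: int = 200
    group_presence_frac: float = 0.5
    pixel_missing_frac: float = 0.5
    ellipse_conf: float = 0.95
    knn_k: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.group_presence_frac, self.pixel_missing_frac):
            if not 0 < frac < 1:
                raise ValueError("filter fractions must be in (0, 1)")
        if not 0 < self.ellipse_conf < 1:
            raise ValueError("ellipse_conf must be in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


@dataclass
class PcaResult:
    scores: np.ndarray         # pixels x components
    loadings: np.ndarray       # features x components, orthonormal columns
    var_explained: np.ndarray  # fraction of total variance per component


def balanced_sample(
    fm: FeatureMatrix,
    group_col: str = "region_label",
    n_per_group: int = 200,
    seed: int = 0,
) -> FeatureMatrix:
    """Sample ``n_per_group`` pixels uniformly without replacement from
    each group; smaller groups are taken whole with a warning."""
    if group_col not in fm.pixel_meta.columns:
        raise ValueError(f"grouping column {group_col!r} absent from pixel metadata")
    rng = np.random.default_rng(seed)
    groups = fm.pixel_meta[group_col]
    keep_idx: List[np.ndarray] = []
    for label in sorted(groups.dropna().unique()):
        idx = np.flatnonzero((groups == label).to_numpy())
        if idx.size == 0:
            raise ValueError(f"group {label!r} is empty")
        if idx.size < n_per_group:
            logger.warning(
                "group %r has only %d pixels (< %d); keeping all",
                label, idx.size, n_per_group,
            )
            keep_idx.append(idx)
        else:
            keep_idx.append(np.sort(rng.choice(idx, size=n_per_group, replace=False)))
    return fm.select_pixels(np.concatenate(keep_idx))


def group_filters(
    fm: FeatureMatrix,
    group_col: str = "region_label",
    group_presence_frac: float = 0.5,
    pixel_missing_frac: float = 0.5,
) -> FeatureMatrix:
    """The 50% pixel/missing-value filters, applied features-first.

    A feature is kept if observed in at least ``group_presence_frac`` of
    the pixels of *some* group (so tissue-specific lipids survive); then
    pixels missing more than ``pixel_missing_frac`` of the retained
    features are dropped.
    """
    groups = fm.pixel_meta[group_col]
    observed = fm.observed
    keep_feature = np.zeros(fm.n_features, dtype=bool)
    for label in groups.dropna().unique():
        mask = (groups == label).to_numpy()
        frac = observed[mask].mean(axis=0)
        keep_feature |= frac >= group_presence_frac
    if not keep_feature.any():
        raise ValueError("all features removed by the group presence filter")
    out = fm.select_features(keep_feature)
    missing_frac = 1.0 - out.observed.mean(axis=1)
    return out.select_pixels(missing_frac <= pixel_missing_frac)


def knn_impute(values: np.ndarray, k: int = 5) -> np.ndarray:
    """Complete a pixels x features matrix by k-nearest-neighbour
    imputation.

    Distances are Euclidean over mutually observed features, rescaled by
    the total feature count so pixels with different observation overlap
    are comparable; a missing entry becomes the mean of the k nearest
    pixels that observed that feature (all eligible ones if fewer than
    k exist).
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).all(axis=1).any():
        raise ValueError("every pixel must observe at least one feature")
    col_all_missing = np.isnan(values).all(axis=0)
    if col_all_missing.any():
        raise ValueError(
            f"features observed in zero pixels: {np.flatnonzero(col_all_missing)}"
        )
    if not np.isnan(values).any():
        return values.copy()
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    return imputer.fit_transform(values)


def pareto_scale(matrix: np.ndarray) -> np.ndarray:
    """Mean-center each feature and divide by the square root of its
    sample standard deviation; constant features become zero columns."""
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1) if matrix.shape[0] > 1 else np.zeros(matrix.shape[1])
    centered = matrix - mean
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = centered / np.sqrt(sd)
    scaled[:, sd == 0] = 0.0
    return scaled


def pca(matrix: np.ndarray, n_components: int) -> PcaResult:
    """PCA by singular value decomposition of a centered/scaled matrix.

    Sign convention: in each loading vector the element of largest
    absolute value is positive, so results are platform-reproducible.
    """
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min{(n, p)}")
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    total = (s**2).sum()
    var_explained = (s**2) / total if total > 0 else np.zeros_like(s)
    loadings = vt.T[:, :n_components]
    scores = u[:, :n_components] * s[:n_components]
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    return PcaResult(scores * flip, loadings * flip, var_explained[:n_components])


def ellipse_outlier_filter(
    fm: FeatureMatrix,
    group_col: str = "region_label",
    conf: float = 0.95,
    knn_k: int = 5,
) -> FeatureMatrix:
    """Remove, per group, pixels outside the ``conf`` confidence ellipse
    of the group's PC1-PC2 scores.

    Each group is imputed, pareto-scaled and decomposed independently;
    squared Mahalanobis distance under the 2x2 score covariance is
    compared with the chi-square quantile at ``conf`` with 2 degrees of
    freedom (5.991 at 0.95).
    """
    groups = fm.pixel_meta[group_col]
    threshold = sp_stats.chi2.ppf(conf, df=2)
    keep = np.ones(fm.n_pixels, dtype=bool)
    for label in groups.dropna().unique():
        idx = np.flatnonzero((groups == label).to_numpy())
        if idx.size < 3:
            warnings.warn(f"group {label!r} has <3 pixels; skipping ellipse filter")
            continue
        sub = fm.values[idx]
        complete = knn_impute(sub, k=min(knn_k, idx.size - 1))
        scaled = pareto_scale(complete)
        res = pca(scaled, n_components=min(2, min(scaled.shape)))
        scores = res.scores
        if scores.shape[1] < 2:
            scores = np.column_stack([scores, np.zeros(len(scores))])
        cov = np.cov(scores.T)
        try:
            cov_inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            warnings.warn(f"singular score covariance for group {label!r}; skipped")
            continue
        centered = scores - scores.mean(axis=0)
        d2 = np.einsum("ij,jk,ik->i", centered, cov_inv, centered)
        keep[idx[d2 > threshold]] = False
    return fm.select_pixels(keep)


def median_by_section(
    fm: FeatureMatrix, region_label: str = "eggs"
) -> pd.DataFrame:
    """Per-section, per-feature median over a region's observed pixel
    values (rows = biological replicates).

    Sections with no pixels of the region are excluded with a warning;
    a feature observed nowhere in a section stays missing.
    """
    mask = (fm.pixel_meta["region_label"] == region_label).to_numpy()
    if not mask.any():
        raise ValueError(f"no pixels labeled {region_label!r}")
    sub = fm.select_pixels(mask)
    rows = {}
    meta_rows = {}
    for sid, grp in sub.pixel_meta.groupby("section_id", sort=True):
        idx = grp.index.to_numpy()
        if idx.size == 0:
            warnings.warn(f"section {sid!r} has no {region_label!r} pixels; excluded")
            continue
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
            med = np.nanmedian(sub.values[idx], axis=0)
        rows[sid] = med
        meta_rows[sid] = {
            "time_point_h": grp["time_point_h"].iloc[0],
            "treatment": grp["treatment"].iloc[0],
        }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=list(fm.feature_mz))
    table.index.name = "section_id"
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    return table.join(meta)


def rank_test(
    a: Sequence[float], b: Sequence[float], mode: str = "pixel_rank_sum"
) -> Tuple[float, float]:
    """Two-sided nonparametric comparison of two samples.

    ``pixel_rank_sum``: Mann-Whitney U, exact when min(n) <= 8 and the
    data are tie-free, tie-corrected normal approximation otherwise.
    ``paired_signed_rank``: Wilcoxon signed-rank on paired differences.
    Returns (statistic, two-sided p).  All-tied inputs yield p = 1 with
    a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "pixel_rank_sum":
        if np.unique(np.concatenate([a, b])).size == 1:
            warnings.warn("all values tied across both groups; p = 1")
            return float(a.size * b.size / 2), 1.0
        pooled = np.concatenate([a, b])
        has_ties = np.unique(pooled).size < pooled.size
        method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
        res = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    if mode == "paired_signed_rank":
        if a.size != b.size:
            raise ValueError("paired mode requires equal-length samples")
        diff = a - b
        if np.all(diff == 0):
            warnings.warn("all paired differences are zero; p = 1")
            return 0.0, 1.0
        res = sp_stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown rank test mode {mode!r}")


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1,
    order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_features(
    fm: FeatureMatrix,
    contrast_col: str = "treatment",
    group_a: str = "control",
    group_b: str = "BPA",
    mode: str = "pixel_rank_sum",
    min_n: int = 3,
) -> pd.DataFrame:
    """Per-feature rank test between two pixel groups with BH-FDR.

    ``direction`` is the sign of (group_b - group_a) median difference,
    computed over observed values.  Features with fewer than ``min_n``
    observed values in either group are skipped.
    """
    labels = fm.pixel_meta[contrast_col]
    idx_a = np.flatnonzero((labels == group_a).to_numpy())
    idx_b = np.flatnonzero((labels == group_b).to_numpy())
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"empty contrast group under {contrast_col!r}")
    rows = []
    for j, mz in enumerate(fm.feature_mz):
        va = fm.values[idx_a, j]
        vb = fm.values[idx_b, j]
        va = va[~np.isnan(va)]
        vb = vb[~np.isnan(vb)]
        if va.size < min_n or vb.size < min_n:
            continue
        stat, p = rank_test(va, vb, mode=mode)
        direction = float(np.sign(np.median(vb) - np.median(va)))
        rows.append({"feature_mz": mz, "statistic": stat, "p_value": p,
                     "direction": direction})
    table = pd.DataFrame(rows, columns=["feature_mz", "statistic", "p_value",
                                        "direction"])
    if len(table):
        table["fdr_adjusted_p"] = bh_fdr(table["p_value"].to_numpy())
    else:
        table["fdr_adjusted_p"] = pd.Series(dtype=float)
    return table
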