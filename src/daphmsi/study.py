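"""Study-level assembly and calibration QC.

Per-section feature matrices are merged across the study with a looser
ppm tolerance (default 35 ppm, accommodating multi-day m/z drift),
background ions shared with blank DESI slides are removed, and the two
calibration QC computations are provided: rhodamine 6G drift monitoring
and polyalanine-based mass recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import monoisotopic_mass
from .core import FeatureMatrix, MZ_MAX, MZ_MIN
from .preprocess import _gap_clusters

#: Theoretical rhodamine 6G cation m/z, computed from C28H31N2O3+ by
#: summing neutral-atom masses (no electron-mass correction) — the
#: convention that reproduces the value printed on instrument QC sheets.
RHODAMINE_6G_FORMULA = "C28H31N2O3"
RHODAMINE_6G_MZ = monoisotopic_mass(RHODAMINE_6G_FORMULA)

# Polyalanine [M+H]+ series building blocks, Da.
ALANINE_RESIDUE_MASS = 71.03711
WATER_MASS = 18.010565
PROTON_MASS = 1.007276


@dataclass
class StudyMatrix(FeatureMatrix):
    """A FeatureMatrix whose pixels span all study sections.

    ``provenance`` maps each study-level feature index to the
    ``(section_index, section_feature_index)`` pairs it merged.
    """

    provenance: Optional[Dict[int, List[Tuple[int, int]]]] = None


def align_study(
    matrices: Sequence[FeatureMatrix], tol_ppm: float = 35.0
) -> StudyMatrix:
    """Merge per-section feature matrices into one study matrix.

    Section-level consensus centroids are clustered with the same
    single-linkage gap rule used within sections; cluster centroids are
    weighted by each feature's total intensity.  Pixel rows are carried
    over unchanged; a section that contributed no feature to a cluster
    has missing values there for all its pixels.
    """
    if not matrices:
        raise ValueError("no feature matrices to align")

    mz_parts, w_parts, src = [], [], []
    for m_idx, fm in enumerate(matrices):
        mz_parts.append(fm.feature_mz)
        totals = np.nansum(np.where(fm.observed, fm.values, 0.0), axis=0)
        w_parts.append(totals)
        src.extend((m_idx, f_idx) for f_idx in range(fm.n_features))
    mz = np.concatenate(mz_parts)
    weights = np.concatenate(w_parts)
    src = np.asarray(src, dtype=np.intp)

    order = np.argsort(mz, kind="stable")
    mz, weights, src = mz[order], weights[order], src[order]
    cluster = _gap_clusters(mz, tol_ppm)
    n_clusters = int(cluster[-1]) + 1 if cluster.size else 0

    wsum = np.bincount(cluster, weights=weights, minlength=n_clusters)
    consensus = np.bincount(cluster, weights=weights * mz, minlength=n_clusters)
    counts = np.bincount(cluster, minlength=n_clusters)
    plain = np.bincount(cluster, weights=mz, minlength=n_clusters) / counts
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(wsum > 0, consensus / np.where(wsum == 0, 1, wsum), plain)

    offsets = np.cumsum([0] + [fm.n_pixels for fm in matrices])
    n_pixels = offsets[-1]
    values = np.full((n_pixels, n_clusters), np.nan)
    provenance: Dict[int, List[Tuple[int, int]]] = {c: [] for c in range(n_clusters)}
    for c, (m_idx, f_idx) in zip(cluster, src):
        fm = matrices[m_idx]
        sl = slice(offsets[m_idx], offsets[m_idx + 1])
        col = fm.values[:, f_idx]
        # If two features of one section fall in the same study cluster
        # (possible with a looser study tolerance), keep the larger value.
        existing = values[sl, c]
        merged = np.where(
            np.isnan(existing), col,
            np.where(np.isnan(col), existing, np.maximum(existing, col)),
        )
        values[sl, c] = merged
        provenance[int(c)].append((int(m_idx), int(f_idx)))

    meta = pd.concat([fm.pixel_meta for fm in matrices], ignore_index=True)
    return StudyMatrix(
        feature_mz=consensus, values=values, pixel_meta=meta,
        tol_ppm=tol_ppm, provenance=provenance,
    )


def remove_background(
    study: FeatureMatrix,
    blank: FeatureMatrix,
    fold: float = 10.0,
    tol_ppm: float = 35.0,
    missing_as_zero: bool = True,
) -> FeatureMatrix:
    """Remove background ions shared with blank DESI slides.

    A study feature matched (within ``tol_ppm``) to a blank feature is
    removed iff the median tissue-pixel intensity is below ``fold``
    times the median blank-pixel intensity.  Missing values enter the
    medians as 0 by default (a feature absent from most pixels has a low
    median, correctly biasing toward removal); ``missing_as_zero=False``
    computes medians over observed values only.  Unmatched features are
    always kept.
    """
    if blank.n_pixels == 0:
        raise ValueError("blank matrix has no pixels")

    def _median(fm: FeatureMatrix) -> np.ndarray:
        if missing_as_zero:
            return np.median(np.where(fm.observed, fm.values, 0.0), axis=0)
        with np.errstate(all="ignore"):
            return np.nanmedian(fm.values, axis=0)

    m_tissue = _median(study)
    m_blank = _median(blank)

    keep = np.ones(study.n_features, dtype=bool)
    for j, mz in enumerate(study.feature_mz):
        diffs = np.abs(blank.feature_mz - mz)
        i = int(np.argmin(diffs)) if blank.n_features else -1
        if i >= 0 and diffs[i] <= tol_ppm * min(mz, blank.feature_mz[i]) * 1e-6:
            if m_tissue[j] < fold * m_blank[i]:
                keep[j] = False
    out = study.select_features(keep)
    return out


def monitor_drift(
    observed_mz: float,
    theoretical_mz: float = RHODAMINE_6G_MZ,
    limit_ppm: float = 25.0,
) -> Tuple[float, bool]:
    """ppm error of a calibrant measurement and whether it exceeds the
    recalibration limit."""
    if observed_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be positive")
    ppm = (observed_mz - theoretical_mz) / theoretical_mz * 1e6
    return ppm, abs(ppm) > limit_ppm


def polyalanine_series(n_min: int, n_max: int) -> List[float]:
    """Theoretical [M+H]+ m/z of polyalanine oligomers with ``n``
    residues, restricted to the acquisition range [50, 1000] Da."""
    if not (2 <= n_min <= n_max):
        raise ValueError("require 2 <= n_min <= n_max")
    series = [
        n * ALANINE_RESIDUE_MASS + WATER_MASS + PROTON_MASS
        for n in range(n_min, n_max + 1)
    ]
    return [mz for mz in series if MZ_MIN <= mz <= MZ_MAX]


@dataclass
class CalibrationModel:
    """ppm-error model fitted to calibrant measurements.

    ``constant_ppm``: error = c0.  ``linear_in_mz``: error = c0 + c1 * m/z.
    Applying the model multiplies every m/z by (1 - predicted_ppm * 1e-6).
    """

    kind: str
    coefficients: np.ndarray
    fit_residual_ppm: float

    def predict_ppm(self, mz) -> np.ndarray:
        mz = np.asarray(mz, dtype=float)
        if self.kind == "constant_ppm":
            return np.full_like(mz, self.coefficients[0])
        return self.coefficients[0] + self.coefficients[1] * mz

    def correct(self, mz) -> np.ndarray:
        return np.asarray(mz, dtype=float) * (1.0 - self.predict_ppm(mz) * 1e-6)


def fit_recalibration(
    observed: Sequence[float],
    theoretical: Sequence[float],
    kind: str = "constant_ppm",
) -> CalibrationModel:
    """Least-squares fit of ppm error against m/z over matched calibrant
    pairs (constant needs >=1 pair, linear >=2 with distinct m/z)."""
    observed = np.asarray(observed, dtype=float)
    theoretical = np.asarray(theoretical, dtype=float)
    if observed.shape != theoretical.shape or observed.size == 0:
        raise ValueError("observed and theoretical must be equal-length, non-empty")
    ppm = (observed - theoretical) / theoretical * 1e6
    if kind == "constant_ppm":
        coef = np.array([ppm.mean()])
    elif kind == "linear_in_mz":
        if observed.size < 2 or np.ptp(theoretical) == 0:
            raise ValueError("linear recalibration needs >=2 distinct calibrant m/z")
        design = np.column_stack([np.ones_like(theoretical), theoretical])
        coef, *_ = np.linalg.lstsq(design, ppm, rcond=None)
    else:
        raise ValueError(f"unknown calibration kind {kind!r}")
    model = CalibrationModel(kind, coef, 0.0)
    corrected = model.correct(observed)
    residual = (corrected - theoretical) / theoretical * 1e6
    model.fit_residual_ppm = float(np.sqrt(np.mean(residual**2)))
    return model


def apply_recalibration(model: CalibrationModel, fm: FeatureMatrix) -> FeatureMatrix:
    """Correct a feature matrix's m/z axis with a fitted drift model."""
    out = fm.copy()
    out.feature_mz = model.correct(fm.feature_mz)
    return out
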