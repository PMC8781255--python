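"""Per-section spectral cleanup.

The fixed processing order mirrors the study workflow:

1. SNR filter — drop peaks with intensity / noise < ``snr_min``, where
   noise is the median absolute deviation (MAD) of the pixel's peak
   intensities.
2. ppm alignment — pool peaks across the section's pixels and cut
   clusters wherever the gap between consecutive pooled m/z exceeds the
   tolerance (single-linkage gap rule, default 25 ppm).
3. Pixel-frequency filter — drop features detected in fewer than 5% of
   the section's pixels.
4. RMS normalization — divide each pixel's observed intensities by the
   root of their mean square.

Each stage appends a record to an audit log so the order and per-stage
peak/feature counts are verifiable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (EmptySpectrumError, FeatureMatrix, PixelCoord,
                   PIXEL_META_COLUMNS, Section, Spectrum)


@dataclass
class PreprocessParams:
    """Knobs for per-section cleanup.

    snr_min : minimum signal-to-noise ratio (noise = scaled MAD).
    intra_tol_ppm : within-section alignment tolerance, ppm.
    min_pixel_frac : minimum fraction of pixels a feature must appear in.
    mad_scale : multiplier on the raw MAD; 1.0 means the plain MAD with
        no Gaussian consistency factor.
    """

    snr_min: float = 3.0
    intra_tol_ppm: float = 25.0
    min_pixel_frac: float = 0.05
    mad_scale: float = 1.0
    weighted_consensus: bool = True

    def __post_init__(self) -> None:
        if self.snr_min <= 0:
            raise ValueError("snr_min must be > 0")
        if not 0 < self.min_pixel_frac < 1:
            raise ValueError("min_pixel_frac must be in (0, 1)")
        if self.intra_tol_ppm <= 0:
            raise ValueError("intra_tol_ppm must be > 0")


@dataclass
class AuditRecord:
    stage: str
    detail: dict


AuditLog = List[AuditRecord]


def estimate_noise(spectrum: Spectrum, mad_scale: float = 1.0) -> float:
    """Noise level of one pixel: scaled median absolute deviation of its
    peak intensities."""
    if spectrum.is_empty:
        raise EmptySpectrumError("cannot estimate noise of an empty spectrum")
    med = np.median(spectrum.intensity)
    return float(mad_scale * np.median(np.abs(spectrum.intensity - med)))


def snr_filter(spectrum: Spectrum, params: PreprocessParams) -> Spectrum:
    """Keep peaks with intensity / noise >= ``snr_min``.

    A zero noise level (constant or single-peak spectrum) leaves the
    spectrum untouched: SNR is undefined, and annihilating a pixel on
    that basis would be arbitrary.
    """
    noise = estimate_noise(spectrum, params.mad_scale)
    if noise == 0:
        return spectrum
    keep = spectrum.intensity / noise >= params.snr_min
    return Spectrum(spectrum.mz[keep], spectrum.intensity[keep])


def _gap_clusters(sorted_mz: np.ndarray, tol_ppm: float) -> np.ndarray:
    """Cluster ids for sorted m/z under the single-linkage gap rule:
    cut wherever consecutive values are more than tol_ppm (of the lower
    value) apart."""
    if sorted_mz.size == 0:
        return np.empty(0, dtype=np.intp)
    gaps = np.diff(sorted_mz) > tol_ppm * sorted_mz[:-1] * 1e-6
    return np.concatenate([[0], np.cumsum(gaps)])


def align_section(
    spectra: Sequence[Tuple[PixelCoord, Spectrum]],
    tol_ppm: float = 25.0,
    weighted: bool = True,
    pixel_meta: Optional[pd.DataFrame] = None,
    min_pixel_count: int = 0,
) -> FeatureMatrix:
    """Align peaks across a section's pixels into consensus features.

    All peaks are pooled and sorted; clusters are cut at gaps larger
    than the ppm tolerance.  The consensus m/z of a cluster is the
    intensity-weighted mean of its member peaks (plain mean with
    ``weighted=False``).  When a pixel contributes more than one peak to
    a cluster the most intense is kept (ties broken toward lower m/z).

    ``min_pixel_count`` drops clusters detected in fewer pixels *before*
    the dense matrix is materialized — the same rule as
    :func:`pixel_frequency_filter`, applied early so that dense noise
    floors (one random peak per pixel per ~0.01 Da) do not blow up
    memory.  The default keeps every cluster.
    """
    spectra = [(c, s) for c, s in spectra]
    if not spectra or all(s.is_empty for _, s in spectra):
        raise EmptySpectrumError("no non-empty spectra to align")

    mz_parts, int_parts, pix_parts = [], [], []
    for pix_idx, (coord, spec) in enumerate(spectra):
        mz_parts.append(spec.mz)
        int_parts.append(spec.intensity)
        pix_parts.append(np.full(len(spec), pix_idx, dtype=np.intp))
    mz = np.concatenate(mz_parts)
    inten = np.concatenate(int_parts)
    pixel = np.concatenate(pix_parts)

    order = np.argsort(mz, kind="stable")
    mz, inten, pixel = mz[order], inten[order], pixel[order]
    cluster = _gap_clusters(mz, tol_ppm)
    n_clusters = int(cluster[-1]) + 1

    if min_pixel_count > 0:
        pair_ids = np.unique(cluster * np.int64(len(spectra)) + pixel)
        pix_counts = np.bincount((pair_ids // len(spectra)).astype(np.intp),
                                 minlength=n_clusters)
        keep_cluster = pix_counts >= min_pixel_count
        peak_keep = keep_cluster[cluster]
        remap = np.cumsum(keep_cluster) - 1
        mz, inten = mz[peak_keep], inten[peak_keep]
        pixel = pixel[peak_keep]
        cluster = remap[cluster[peak_keep]]
        n_clusters = int(keep_cluster.sum())
        if n_clusters == 0:
            raise EmptySpectrumError(
                "no cluster satisfies the minimum pixel count"
            )

    weights = inten if weighted else np.ones_like(inten)
    wsum = np.bincount(cluster, weights=weights, minlength=n_clusters)
    # Zero-intensity clusters fall back to the plain mean.
    zero = wsum == 0
    if np.any(zero):
        counts = np.bincount(cluster, minlength=n_clusters)
        plain = np.bincount(cluster, weights=mz, minlength=n_clusters) / counts
    consensus = np.bincount(cluster, weights=weights * mz, minlength=n_clusters)
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = consensus / wsum
    if np.any(zero):
        consensus[zero] = plain[zero]

    # Per (cluster, pixel): keep the most intense peak, tie -> lower m/z.
    # Sort so the winner comes first within each (cluster, pixel) run; the
    # pool is already ascending in m/z, so a stable sort on (-intensity)
    # within groups keeps the lower-m/z peak first among ties.
    sel = np.lexsort((-inten, pixel, cluster))
    c_s, p_s, i_s = cluster[sel], pixel[sel], inten[sel]
    first = np.ones(sel.size, dtype=bool)
    first[1:] = (c_s[1:] != c_s[:-1]) | (p_s[1:] != p_s[:-1])

    n_pixels = len(spectra)
    values = np.full((n_pixels, n_clusters), np.nan)
    values[p_s[first], c_s[first]] = i_s[first]

    if pixel_meta is None:
        pixel_meta = pd.DataFrame(
            {
                "section_id": "",
                "x": [c[0] for c, _ in spectra],
                "y": [c[1] for c, _ in spectra],
                "time_point_h": None,
                "treatment": None,
            }
        )
    # Guard against zero-intensity observations breaking the >0 invariant.
    values[values == 0] = np.nan
    return FeatureMatrix(consensus, values, pixel_meta, tol_ppm=tol_ppm)


def pixel_frequency_filter(fm: FeatureMatrix, min_frac: float = 0.05) -> FeatureMatrix:
    """Drop features detected in fewer than ``ceil(min_frac * n_pixels)``
    pixels ("present in less than 5% of pixels")."""
    threshold = math.ceil(min_frac * fm.n_pixels)
    counts = fm.observed.sum(axis=0)
    return fm.select_features(counts >= threshold)


def rms_normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each pixel's observed intensities by their root-mean-square.

    Missing entries stay missing; afterwards every pixel has RMS 1 over
    its observed features.
    """
    observed = fm.observed
    n_obs = observed.sum(axis=1)
    if np.any(n_obs == 0):
        bad = fm.pixel_meta.index[n_obs == 0].tolist()
        raise ValueError(f"pixels with no observed features: {bad}")
    sq = np.where(observed, fm.values, 0.0) ** 2
    rms = np.sqrt(sq.sum(axis=1) / n_obs)
    out = fm.copy()
    out.values = out.values / rms[:, None]
    return out


def preprocess_section(
    section: Section,
    params: Optional[PreprocessParams] = None,
    audit: Optional[AuditLog] = None,
) -> FeatureMatrix:
    """Run the full fixed-order per-section cleanup:
    SNR filter -> ppm alignment -> pixel-frequency filter -> RMS
    normalization.  Appends one audit record per stage."""
    params = params or PreprocessParams()
    if audit is None:
        audit = []

    items = list(section.items())
    n_peaks_in = sum(len(s) for _, s in items)
    filtered = []
    for coord, spec in items:
        if spec.is_empty:
            continue
        kept = snr_filter(spec, params)
        filtered.append((coord, kept))
    n_peaks_snr = sum(len(s) for _, s in filtered)
    audit.append(AuditRecord("snr_filter", {
        "section_id": section.section_id,
        "peaks_in": n_peaks_in, "peaks_out": n_peaks_snr,
        "snr_min": params.snr_min,
    }))

    meta = pd.DataFrame(
        {
            "section_id": section.section_id,
            "x": [c[0] for c, _ in filtered],
            "y": [c[1] for c, _ in filtered],
            "time_point_h": section.time_point_h,
            "treatment": section.treatment,
        }
    )
    # Early cluster pruning at the same threshold the pixel filter will
    # apply keeps the dense matrix small in the presence of noise floors.
    early_min = math.ceil(params.min_pixel_frac * len(filtered))
    fm = align_section(filtered, tol_ppm=params.intra_tol_ppm,
                       weighted=params.weighted_consensus, pixel_meta=meta,
                       min_pixel_count=early_min)
    audit.append(AuditRecord("align_section", {
        "section_id": section.section_id,
        "tol_ppm": params.intra_tol_ppm, "n_features": fm.n_features,
    }))

    fm = pixel_frequency_filter(fm, params.min_pixel_frac)
    audit.append(AuditRecord("pixel_frequency_filter", {
        "section_id": section.section_id,
        "min_pixel_frac": params.min_pixel_frac, "n_features": fm.n_features,
    }))

    # Drop pixels that lost every peak (possible for sparse off-tissue
    # pixels after the frequency filter) rather than failing RMS.
    has_obs = fm.observed.any(axis=1)
    if not has_obs.all():
        fm = fm.select_pixels(has_obs)
    fm = rms_normalize(fm)
    audit.append(AuditRecord("rms_normalize", {
        "section_id": section.section_id, "n_pixels": fm.n_pixels,
    }))
    return fm


def audit_table(audit: AuditLog) -> pd.DataFrame:
    """Flatten an audit log into a QC table (one row per stage)."""
    return pd.DataFrame(
        [{"stage": rec.stage, **rec.detail} for rec in audit]
    )
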