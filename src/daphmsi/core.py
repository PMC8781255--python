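"""Core data model for DESI mass-spectrometry-imaging datasets.

An MSI dataset is a grid of pixels, each carrying one centroided mass
spectrum.  Downstream processing converts collections of spectra into a
pixels x features intensity matrix with explicit missing values (a peak
that was not detected in a pixel is *missing*, never zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Acquisition m/z range of the study (positive-ion DESI).
MZ_MIN = 50.0
MZ_MAX = 1000.0

#: Default pixel size in micrometres.
DEFAULT_PIXEL_SIZE_UM = 35.0

#: Valid sampling time points, hours after the sixth brood.
TIME_POINTS_H = (8, 24, 48, 72)

#: Treatment arms.
TREATMENTS = ("control", "BPA")

PixelCoord = Tuple[int, int]  # (x, y), both 1-based per imzML convention


class EmptySpectrumError(ValueError):
    """Raised when an operation requires a non-empty spectrum."""


@dataclass(frozen=True)
class Spectrum:
    """One pixel's centroided peak list.

    Parameters
    ----------
    mz
        Peak m/z values in Da, strictly increasing, within [50, 1000].
    intensity
        Non-negative ion counts, same length as ``mz``.
    """

    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        intensity = np.asarray(self.intensity, dtype=np.float64)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", intensity)
        if mz.ndim != 1 or intensity.ndim != 1:
            raise ValueError("mz and intensity must be 1-d arrays")
        if mz.shape != intensity.shape:
            raise ValueError(
                f"mz and intensity lengths differ: {mz.size} vs {intensity.size}"
            )
        if mz.size:
            if np.isnan(mz).any() or np.isnan(intensity).any():
                raise ValueError("NaN values are not permitted in a spectrum")
            if np.any(np.diff(mz) <= 0):
                raise ValueError("mz values must be strictly increasing")
            if mz[0] < MZ_MIN or mz[-1] > MZ_MAX:
                raise ValueError(
                    f"m/z outside acquisition range [{MZ_MIN}, {MZ_MAX}]: "
                    f"[{mz[0]}, {mz[-1]}]"
                )
            if np.any(intensity < 0):
                raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def is_empty(self) -> bool:
        return self.mz.size == 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensity, other.intensity
        )


def empty_spectrum() -> Spectrum:
    return Spectrum(np.empty(0), np.empty(0))


@dataclass
class Section:
    """A tissue section (or blank slide): a pixel grid of spectra plus
    study metadata.

    ``grid_shape`` is (n_rows, n_cols); pixel coordinates are 1-based
    imzML (x = column, y = row).  Study metadata (time point, treatment,
    acquisition order) comes from the sidecar manifest, never from the
    imzML file itself.
    """

    section_id: str
    spectra: Dict[PixelCoord, Spectrum]
    grid_shape: Tuple[int, int]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    subject_id: Optional[str] = None
    time_point_h: Optional[int] = None
    treatment: Optional[str] = None
    acquisition_index: int = 0
    is_blank: bool = False

    def __post_init__(self) -> None:
        n_rows, n_cols = self.grid_shape
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for (x, y) in self.spectra:
            if not (1 <= x <= n_cols and 1 <= y <= n_rows):
                raise ValueError(
                    f"pixel ({x}, {y}) outside grid of shape {self.grid_shape} "
                    f"in section {self.section_id!r}"
                )
        if self.is_blank:
            if self.time_point_h is not None or self.treatment is not None:
                raise ValueError("blank sections carry no time point or treatment")
        else:
            if self.time_point_h is not None and self.time_point_h not in TIME_POINTS_H:
                raise ValueError(
                    f"time_point_h must be one of {TIME_POINTS_H}, got {self.time_point_h}"
                )
            if self.treatment is not None and self.treatment not in TREATMENTS:
                raise ValueError(
                    f"treatment must be one of {TREATMENTS}, got {self.treatment!r}"
                )
        if self.acquisition_index < 0:
            raise ValueError("acquisition_index must be >= 0")

    @property
    def n_pixels(self) -> int:
        return len(self.spectra)

    def items(self) -> Iterator[Tuple[PixelCoord, Spectrum]]:
        # Deterministic raster order: row-major (y, then x).
        for coord in sorted(self.spectra, key=lambda c: (c[1], c[0])):
            yield coord, self.spectra[coord]


#: Columns every FeatureMatrix pixel-metadata table carries.
PIXEL_META_COLUMNS = ("section_id", "x", "y", "time_point_h", "treatment")


@dataclass
class FeatureMatrix:
    """Pixels x consensus-m/z-features intensity matrix.

    Missing values are ``NaN`` (a feature not detected in a pixel);
    observed values are strictly positive.  ``pixel_meta`` is a
    DataFrame aligned row-wise with ``values`` and always contains the
    columns in :data:`PIXEL_META_COLUMNS`; a ``region_label`` column is
    added by ROI annotation.
    """

    feature_mz: np.ndarray
    values: np.ndarray
    pixel_meta: pd.DataFrame
    tol_ppm: Optional[float] = None

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-d (pixels x features)")
        if self.values.shape != (len(self.pixel_meta), self.feature_mz.size):
            raise ValueError(
                f"shape mismatch: values {self.values.shape}, "
                f"{len(self.pixel_meta)} pixels, {self.feature_mz.size} features"
            )
        if self.feature_mz.size > 1 and np.any(np.diff(self.feature_mz) <= 0):
            raise ValueError("feature_mz must be strictly increasing")
        observed = ~np.isnan(self.values)
        if np.any(self.values[observed] <= 0):
            raise ValueError(
                "observed intensities must be > 0 (absent peaks are missing, not 0)"
            )
        self.pixel_meta = self.pixel_meta.reset_index(drop=True)

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) entries."""
        return ~np.isnan(self.values)

    def select_pixels(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return FeatureMatrix(
            feature_mz=self.feature_mz.copy(),
            values=self.values[idx],
            pixel_meta=self.pixel_meta.iloc[idx].reset_index(drop=True),
            tol_ppm=self.tol_ppm,
        )

    def select_features(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return FeatureMatrix(
            feature_mz=self.feature_mz[idx],
            values=self.values[:, idx],
            pixel_meta=self.pixel_meta.copy(),
            tol_ppm=self.tol_ppm,
        )

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            feature_mz=self.feature_mz.copy(),
            values=self.values.copy(),
            pixel_meta=self.pixel_meta.copy(),
            tol_ppm=self.tol_ppm,
        )


def ppm_gap(mz_low: float, tol_ppm: float) -> float:
    """Absolute Da gap corresponding to ``tol_ppm`` at ``mz_low``."""
    return tol_ppm * mz_low * 1e-6
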