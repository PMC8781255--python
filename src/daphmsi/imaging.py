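"""Ion-image rendering.

An ion image maps one target m/z across a section's pixel grid: each
pixel shows the summed intensity of the features lying within a ppm
tolerance of the target.  Missing observations and off-tissue pixels
render as zero (detection dropout), and a series of images can share a
common intensity scale so temporal/exposure comparisons are visually
honest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .core import FeatureMatrix


@dataclass
class IonImage:
    grid: np.ndarray          # n_rows x n_cols intensities, >= 0
    target_mz: float
    tol_ppm: float
    scale_max: float          # intensity mapped to the top of the colormap

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(self.grid < 0):
            raise ValueError("ion image intensities must be non-negative")
        if self.scale_max < self.grid.max(initial=0.0):
            raise ValueError("scale_max must be >= the image maximum")


def ion_image(
    fm: FeatureMatrix,
    section_id: str,
    target_mz: float,
    tol_ppm: float = 35.0,
    grid_shape: Optional[tuple] = None,
) -> IonImage:
    """Render one section's distribution of a target m/z.

    Pixels absent from ``fm`` (dropped background) or with no matching
    observation are zero.  If no feature matches anywhere, an empty
    image is returned with a warning.
    """
    mask = (fm.pixel_meta["section_id"] == section_id).to_numpy()
    if not mask.any():
        raise ValueError(f"section {section_id!r} not present in the matrix")
    sub = fm.select_pixels(mask)
    matched = np.abs(sub.feature_mz - target_mz) <= tol_ppm * target_mz * 1e-6
    if grid_shape is None:
        n_rows = int(sub.pixel_meta["y"].max())
        n_cols = int(sub.pixel_meta["x"].max())
    else:
        n_rows, n_cols = grid_shape
    grid = np.zeros((n_rows, n_cols))
    if not matched.any():
        warnings.warn(
            f"no feature within {tol_ppm} ppm of m/z {target_mz} — empty image"
        )
    else:
        vals = np.where(sub.observed[:, matched], sub.values[:, matched], 0.0)
        totals = vals.sum(axis=1)
        xs = sub.pixel_meta["x"].to_numpy(dtype=int) - 1
        ys = sub.pixel_meta["y"].to_numpy(dtype=int) - 1
        grid[ys, xs] = totals
    return IonImage(grid, float(target_mz), float(tol_ppm),
                    scale_max=float(grid.max(initial=0.0)))


def common_scale(images: Sequence[IonImage]) -> List[IonImage]:
    """Put a series of ion images on one intensity scale (the global
    maximum); pixel values are untouched."""
    if not images:
        return []
    global_max = max(img.grid.max(initial=0.0) for img in images)
    return [replace(img, scale_max=global_max) for img in images]


def render(image: IonImage, path, colormap: str = "viridis") -> None:
    """Write an ion image as a PNG with a linear intensity-to-color map
    over [0, scale_max].  Output bytes are deterministic for a fixed
    input."""
    cmap = colormaps[colormap]
    denom = image.scale_max if image.scale_max > 0 else 1.0
    normed = np.clip(image.grid / denom, 0.0, 1.0)
    rgba = (cmap(normed) * 255).round().astype(np.uint8)
    Image.fromarray(rgba, mode="RGBA").save(path, format="PNG")


def grid_table(image: IonImage) -> np.ndarray:
    """The raw intensity grid (for delimited-text export)."""
    return image.grid.copy()
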