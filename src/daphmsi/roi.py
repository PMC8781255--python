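"""Region-of-interest definitions and pixel annotation.

ROIs are declarative config objects (ellipses or polygons in pixel
coordinates) rather than interactive selections, so the same schema can
be emitted by the synthetic generator and consumed here.  Labels follow
the anatomy of an adult female daphnid: the whole-body ``tissue``
outline, with ``appendages``, ``eye``, ``gut`` and the dorsal
``brood_chamber`` nested inside it, and ``eggs`` nested inside the
brood chamber (the two-stage brood-chamber-then-eggs annotation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Point, Polygon

from .core import FeatureMatrix, PixelCoord

ROI_LABELS = ("tissue", "appendages", "eggs", "eye", "gut", "brood_chamber")


class RoiConfigError(ValueError):
    """Inconsistent ROI configuration (duplicate labels, orphan parents,
    overlapping sibling regions...)."""


@dataclass
class ROI:
    """One region of interest.

    ``shape`` is ``"ellipse"`` (center_xy, semi_axes, rotation_rad) or
    ``"polygon"`` (vertices, a list of (x, y)).  ``parent`` names the
    enclosing ROI; a child is only evaluated inside its parent.
    Pixel-containment is boundary-inclusive.
    """

    label: str
    shape: str
    center_xy: Optional[Tuple[float, float]] = None
    semi_axes: Optional[Tuple[float, float]] = None
    rotation_rad: float = 0.0
    vertices: Optional[List[Tuple[float, float]]] = None
    parent: Optional[str] = None

    def __post_init__(self) -> None:
        if self.shape == "ellipse":
            if self.center_xy is None or self.semi_axes is None:
                raise RoiConfigError(f"ellipse ROI {self.label!r} needs center and axes")
            if min(self.semi_axes) <= 0:
                raise RoiConfigError(f"ellipse ROI {self.label!r} has non-positive axes")
        elif self.shape == "polygon":
            if not self.vertices or len(self.vertices) < 3:
                raise RoiConfigError(f"polygon ROI {self.label!r} needs >=3 vertices")
            poly = Polygon(self.vertices)
            if not poly.is_valid:
                raise RoiConfigError(f"polygon ROI {self.label!r} is self-intersecting")
        else:
            raise RoiConfigError(f"unknown ROI shape {self.shape!r}")

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive interior test for one pixel center."""
        if self.shape == "ellipse":
            cx, cy = self.center_xy
            a, b = self.semi_axes
            dx, dy = x - cx, y - cy
            if self.rotation_rad:
                c, s = math.cos(-self.rotation_rad), math.sin(-self.rotation_rad)
                dx, dy = dx * c - dy * s, dx * s + dy * c
            return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0 + 1e-12
        return Polygon(self.vertices).covers(Point(x, y))


def pixels_in_roi(grid_shape: Tuple[int, int], roi: ROI) -> Set[PixelCoord]:
    """All 1-based pixel coordinates whose centers fall inside the ROI.

    An ROI entirely off-grid yields an empty set with a warning.
    """
    n_rows, n_cols = grid_shape
    pixels = {
        (x, y)
        for y in range(1, n_rows + 1)
        for x in range(1, n_cols + 1)
        if roi.contains(x, y)
    }
    if not pixels:
        warnings.warn(f"ROI {roi.label!r} covers no pixel of grid {grid_shape}")
    return pixels


def _depth(roi: ROI, by_label: Dict[str, ROI]) -> int:
    depth, cur = 0, roi
    seen = set()
    while cur.parent is not None:
        if cur.parent in seen or cur.parent not in by_label:
            raise RoiConfigError(
                f"ROI {roi.label!r} has missing or cyclic parent {cur.parent!r}"
            )
        seen.add(cur.parent)
        cur = by_label[cur.parent]
        depth += 1
    return depth


def annotate_pixels(fm: FeatureMatrix, rois: Sequence[ROI]) -> FeatureMatrix:
    """Label each pixel with the most specific (deepest-nested) ROI
    containing it.

    A child ROI only claims pixels that also lie inside its parent.  Two
    same-depth sibling ROIs claiming one pixel is a config error, unless
    they are parts of one multi-part region (same label before an
    optional ``:part`` suffix, e.g. ``eggs:1`` ... ``eggs:6`` — the
    recorded label is the base name).  When a ``tissue`` ROI is
    supplied, pixels contained in no ROI are dropped (background
    removal); otherwise they are retained unlabeled.
    """
    by_label: Dict[str, ROI] = {}
    for roi in rois:
        if roi.label in by_label:
            raise RoiConfigError(f"duplicate ROI label {roi.label!r}")
        by_label[roi.label] = roi
    depths = {roi.label: _depth(roi, by_label) for roi in rois}

    def chain_contains(roi: ROI, x: float, y: float) -> bool:
        cur: Optional[ROI] = roi
        while cur is not None:
            if not cur.contains(x, y):
                return False
            cur = by_label[cur.parent] if cur.parent else None
        return True

    def base(label: str) -> str:
        return label.split(":", 1)[0]

    labels: List[Optional[str]] = []
    for x, y in zip(fm.pixel_meta["x"].to_numpy(), fm.pixel_meta["y"].to_numpy()):
        best: Optional[ROI] = None
        for roi in rois:
            if not chain_contains(roi, x, y):
                continue
            if best is None or depths[roi.label] > depths[best.label]:
                best = roi
            elif (depths[roi.label] == depths[best.label] and roi is not best
                  and base(roi.label) != base(best.label)):
                raise RoiConfigError(
                    f"pixel ({x}, {y}) lies in overlapping same-depth ROIs "
                    f"{best.label!r} and {roi.label!r}; resolve in config"
                )
        labels.append(base(best.label) if best is not None else None)

    out = fm.copy()
    out.pixel_meta["region_label"] = labels
    if any(base(lbl) == "tissue" for lbl in by_label):
        out = out.select_pixels(np.array([lbl is not None for lbl in labels]))
    return out


# ---------------------------------------------------------------------------
# Config round-trip

def roi_to_dict(roi: ROI) -> dict:
    d: dict = {"label": roi.label, "shape": roi.shape}
    if roi.shape == "ellipse":
        d["center_xy"] = [float(v) for v in roi.center_xy]
        d["semi_axes"] = [float(v) for v in roi.semi_axes]
        if roi.rotation_rad:
            d["rotation_rad"] = float(roi.rotation_rad)
    else:
        d["vertices"] = [[float(a), float(b)] for a, b in roi.vertices]
    if roi.parent:
        d["parent"] = roi.parent
    return d


def roi_from_dict(d: dict) -> ROI:
    return ROI(
        label=d["label"],
        shape=d["shape"],
        center_xy=tuple(d["center_xy"]) if "center_xy" in d else None,
        semi_axes=tuple(d["semi_axes"]) if "semi_axes" in d else None,
        rotation_rad=float(d.get("rotation_rad", 0.0)),
        vertices=[tuple(v) for v in d["vertices"]] if "vertices" in d else None,
        parent=d.get("parent"),
    )


def write_roi_config(rois_by_section: Dict[str, Sequence[ROI]], path) -> None:
    doc = {sid: [roi_to_dict(r) for r in rois] for sid, rois in rois_by_section.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_roi_config(path) -> Dict[str, List[ROI]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {sid: [roi_from_dict(d) for d in items] for sid, items in doc.items()}
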