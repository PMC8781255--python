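"""End-to-end, config-driven orchestration of the DESI-MSI workflow.

Stage order: read imzML -> per-section cleanup (SNR, 25 ppm alignment,
5% pixel filter, RMS normalization) -> per-section mass recalibration
from the calibrant QC log (when provided) -> 35 ppm study alignment ->
blank background removal -> ROI annotation -> mode-specific statistics
-> MS1 lipid annotation -> ion images.  All randomness flows from one
root seed; a run log and machine-readable summary are written.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (LipidRecord, annotate_features, annotations_table,
                       default_library, read_library)
from .core import FeatureMatrix
from .imaging import common_scale, ion_image, render
from .imzml import load_section, read_manifest
from .preprocess import PreprocessParams, audit_table, preprocess_section
from .roi import read_roi_config, annotate_pixels
from .stats import (StatsParams, balanced_sample, ellipse_outlier_filter,
                    group_filters, knn_impute, median_by_section, pareto_scale,
                    pca, test_features)
from .study import (align_study, apply_recalibration, fit_recalibration,
                    remove_background)

logger = logging.getLogger(__name__)

ANALYSIS_MODES = ("tissue_types", "egg_timecourse", "exposure_contrast")
TISSUE_TYPE_LABELS = ("appendages", "eggs", "eye", "gut")


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    manifest: str
    roi_config: str
    out_dir: str
    mode: str = "tissue_types"
    library: Optional[str] = None
    calibrant_qc: Optional[str] = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    stats: StatsParams = field(default_factory=StatsParams)
    study_tol_ppm: float = 35.0
    blank_fold: float = 10.0
    annotate_tol_ppm: float = 25.0
    image_tol_ppm: float = 35.0
    contrast_time_h: int = 48
    seed: int = 0
    write_images: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ANALYSIS_MODES:
            raise ValueError(f"mode must be one of {ANALYSIS_MODES}")


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


@_stage("read")
def _read_sections(config: PipelineConfig):
    base = Path(config.manifest).parent
    entries = read_manifest(config.manifest)
    sections, blanks = [], []
    for entry in entries:
        sec = load_section(entry, base_dir=base)
        (blanks if sec.is_blank else sections).append(sec)
    if not sections:
        raise ValueError("manifest lists no tissue sections")
    return sections, blanks


@_stage("preprocess")
def _preprocess_all(sections, params, audit):
    return [preprocess_section(sec, params, audit) for sec in sections]


@_stage("recalibrate")
def _recalibrate(matrices, sections, qc_path):
    qc = pd.read_csv(qc_path)
    out = []
    events = []
    for fm, sec in zip(matrices, sections):
        rows = qc[qc["section_id"] == sec.section_id]
        if rows.empty:
            out.append(fm)
            continue
        model = fit_recalibration(rows["observed_mz"].to_numpy(),
                                  rows["theoretical_mz"].to_numpy(),
                                  kind="constant_ppm")
        out.append(apply_recalibration(model, fm))
        events.append({"section_id": sec.section_id,
                       "ppm_correction": float(model.coefficients[0]),
                       "fit_residual_ppm": model.fit_residual_ppm})
    return out, pd.DataFrame(events)


@_stage("roi_annotation")
def _annotate_regions(study_fm: FeatureMatrix, rois_by_section) -> FeatureMatrix:
    pieces = []
    for sid, grp in study_fm.pixel_meta.groupby("section_id", sort=False):
        sub = study_fm.select_pixels(grp.index.to_numpy())
        rois = rois_by_section.get(sid)
        if rois is None:
            raise ValueError(f"no ROI config for section {sid!r}")
        pieces.append(annotate_pixels(sub, rois))
    meta = pd.concat([p.pixel_meta for p in pieces], ignore_index=True)
    values = np.vstack([p.values for p in pieces])
    return FeatureMatrix(study_fm.feature_mz, values, meta,
                         tol_ppm=study_fm.tol_ppm)


def run(config: PipelineConfig) -> dict:
    """Execute the configured workflow and write all outputs under
    ``config.out_dir``.  Returns the machine-readable summary dict."""
    t0 = time.time()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    audit = []
    summary: dict = {"version": __version__, "mode": config.mode,
                     "seed": config.seed, "stages": {}}

    sections, blanks = _read_sections(config)
    summary["stages"]["read"] = {
        "n_sections": len(sections), "n_blanks": len(blanks),
        "n_pixels": sum(s.n_pixels for s in sections),
    }

    matrices = _preprocess_all(sections, config.preprocess, audit)
    blank_matrices = _preprocess_all(blanks, config.preprocess, audit) if blanks else []
    summary["stages"]["preprocess"] = {
        "features_per_section": [fm.n_features for fm in matrices],
    }

    if config.calibrant_qc:
        matrices, recal_events = _recalibrate(matrices, sections,
                                              config.calibrant_qc)
        if blank_matrices:
            blank_matrices, _ = _recalibrate(blank_matrices, blanks,
                                             config.calibrant_qc)
        recal_events.to_csv(out_dir / "recalibration_log.csv", index=False)
        summary["stages"]["recalibrate"] = {
            "n_sections_corrected": int(len(recal_events)),
        }

    try:
        study = align_study(matrices, tol_ppm=config.study_tol_ppm)
    except Exception as exc:
        raise PipelineError(f"stage 'align_study' failed: {exc}") from exc
    summary["stages"]["align_study"] = {"n_features": study.n_features}

    if blank_matrices:
        blank = align_study(blank_matrices, tol_ppm=config.study_tol_ppm)
        n_before = study.n_features
        study = remove_background(study, blank, fold=config.blank_fold,
                                  tol_ppm=config.study_tol_ppm)
        summary["stages"]["remove_background"] = {
            "n_features_before": n_before, "n_features_after": study.n_features,
        }

    rois_by_section = read_roi_config(config.roi_config)
    study = _annotate_regions(study, rois_by_section)
    summary["stages"]["roi_annotation"] = {
        "n_tissue_pixels": study.n_pixels,
        "pixels_per_region": study.pixel_meta["region_label"]
        .value_counts().to_dict(),
    }

    # --- mode-specific statistics ---------------------------------------
    sp = config.stats
    if config.mode == "tissue_types":
        mask = study.pixel_meta["region_label"].isin(TISSUE_TYPE_LABELS).to_numpy()
        fm = study.select_pixels(mask)
        fm = balanced_sample(fm, "region_label", sp.n_per_group, seed=config.seed)
        n_balanced = fm.n_pixels
        fm = group_filters(fm, "region_label", sp.group_presence_frac,
                           sp.pixel_missing_frac)
        fm = ellipse_outlier_filter(fm, "region_label", sp.ellipse_conf, sp.knn_k)
        complete = knn_impute(fm.values, k=sp.knn_k)
        scaled = pareto_scale(complete)
        res = pca(scaled, n_components=min(5, min(scaled.shape)))
        scores = pd.DataFrame(res.scores,
                              columns=[f"PC{i+1}" for i in range(res.scores.shape[1])])
        scores.insert(0, "region_label", fm.pixel_meta["region_label"].to_numpy())
        scores.insert(0, "section_id", fm.pixel_meta["section_id"].to_numpy())
        scores.to_csv(out_dir / "pca_scores.csv", index=False)
        loadings = pd.DataFrame(res.loadings, index=fm.feature_mz,
                                columns=[f"PC{i+1}" for i in range(res.loadings.shape[1])])
        loadings.index.name = "feature_mz"
        loadings.to_csv(out_dir / "pca_loadings.csv")
        pd.DataFrame({"component": [f"PC{i+1}" for i in range(len(res.var_explained))],
                      "var_explained": res.var_explained}).to_csv(
            out_dir / "pca_variance.csv", index=False)
        summary["stages"]["tissue_types"] = {
            "n_balanced": n_balanced,
            "n_pixels": fm.n_pixels, "n_features": fm.n_features,
            "var_explained_pc1_pc2": float(res.var_explained[:2].sum()),
        }
        final_fm = fm
    elif config.mode == "egg_timecourse":
        mask = (study.pixel_meta["region_label"] == "eggs").to_numpy()
        fm = study.select_pixels(mask)
        fm = group_filters(fm, "time_point_h", sp.group_presence_frac,
                           sp.pixel_missing_frac)
        medians = median_by_section(fm, "eggs")
        medians.to_csv(out_dir / "egg_medians_by_section.csv")
        summary["stages"]["egg_timecourse"] = {
            "n_sections": int(len(medians)), "n_features": fm.n_features,
        }
        final_fm = fm
    else:  # exposure_contrast
        mask = ((study.pixel_meta["region_label"] == "eggs")
                & (study.pixel_meta["time_point_h"] == config.contrast_time_h)
                ).to_numpy()
        fm = study.select_pixels(mask)
        fm = group_filters(fm, "treatment", sp.group_presence_frac,
                           sp.pixel_missing_frac)
        tests = test_features(fm, "treatment", "control", "BPA",
                              mode="pixel_rank_sum")
        tests.to_csv(out_dir / "feature_tests.csv", index=False)
        summary["stages"]["exposure_contrast"] = {
            "n_pixels": fm.n_pixels, "n_features": fm.n_features,
            "n_significant_fdr05": int((tests["fdr_adjusted_p"] < 0.05).sum()),
        }
        final_fm = fm

    # --- MS1 annotation ---------------------------------------------------
    library = read_library(config.library) if config.library else default_library()
    hits = annotate_features(final_fm.feature_mz, library,
                             tol_ppm=config.annotate_tol_ppm)
    ann = annotations_table(hits)
    ann.to_csv(out_dir / "annotations.csv", index=False)
    summary["stages"]["annotate"] = {
        "n_features": final_fm.n_features,
        "n_annotated": int(sum(bool(h) for h in hits)),
    }

    # --- ion images -------------------------------------------------------
    if config.write_images:
        best = ann[ann["is_best"]]
        img_dir = out_dir / "ion_images"
        img_dir.mkdir(exist_ok=True)
        section_ids = study.pixel_meta["section_id"].unique()[:2]
        n_images = 0
        for _, row in best.drop_duplicates("lipid").head(4).iterrows():
            images = [
                ion_image(study, sid, row["feature_mz"],
                          tol_ppm=config.image_tol_ppm)
                for sid in section_ids
            ]
            for sid, img in zip(section_ids, common_scale(images)):
                render(img, img_dir / f"{row['lipid'].replace(':', '-')}_{sid}.png")
                n_images += 1
        summary["stages"]["ion_images"] = {"n_images": n_images}

    audit_table(audit).to_csv(out_dir / "qc_audit.csv", index=False)
    # The summary is deterministic for a fixed seed; wall time goes to
    # the log only.
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1f s", time.time() - t0)
    return summary
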