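"""Shared fixtures: one default synthetic study (and one null study) is
simulated per session and pushed through the pipeline once; the heavier
end-to-end assertions all read from these."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from daphmsi.pipeline import PipelineConfig, run
from daphmsi.preprocess import PreprocessParams, preprocess_section
from daphmsi.synthetic import default_spec, null_spec, simulate_study

STUDY_SEED = 1
NULL_SEED = 2


@pytest.fixture(scope="session")
def default_bundle():
    """The default 24-section + 2-blank synthetic study, in memory."""
    return simulate_study(default_spec(0), seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, default_bundle):
    """The default study written to disk (imzML + manifest + configs)."""
    from daphmsi.synthetic import write_study

    path = tmp_path_factory.mktemp("study_default")
    write_study(default_bundle, path)
    return path


@pytest.fixture(scope="session")
def pipeline_outputs(tmp_path_factory, study_dir):
    """All three analysis modes run on the default study; returns
    {mode: (out_dir, summary)}."""
    out = {}
    for mode in ("tissue_types", "egg_timecourse", "exposure_contrast"):
        out_dir = tmp_path_factory.mktemp(f"out_{mode}")
        cfg = PipelineConfig(
            manifest=str(study_dir / "manifest.yaml"),
            roi_config=str(study_dir / "rois.yaml"),
            calibrant_qc=str(study_dir / "calibrant_qc.csv"),
            out_dir=str(out_dir),
            mode=mode,
            seed=STUDY_SEED,
            write_images=(mode == "tissue_types"),
        )
        out[mode] = (out_dir, run(cfg))
    return out


@pytest.fixture(scope="session")
def null_outputs(tmp_path_factory):
    """Null study (all effects disabled) through the exposure contrast."""
    study = tmp_path_factory.mktemp("study_null")
    bundle = simulate_study(null_spec(0), seed=NULL_SEED, outdir=study)
    out_dir = tmp_path_factory.mktemp("out_null")
    cfg = PipelineConfig(
        manifest=str(study / "manifest.yaml"),
        roi_config=str(study / "rois.yaml"),
        calibrant_qc=str(study / "calibrant_qc.csv"),
        out_dir=str(out_dir),
        mode="exposure_contrast",
        seed=NULL_SEED,
        write_images=False,
    )
    summary = run(cfg)
    return bundle, out_dir, summary


@pytest.fixture(scope="session")
def section_matrices(default_bundle):
    """Per-section preprocessed feature matrices of the default study
    (no recalibration), for drift-recovery checks."""
    params = PreprocessParams()
    return [
        (sec, default_bundle.truths[sec.section_id],
         preprocess_section(sec, params))
        for sec in default_bundle.sections
    ]
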