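"""Synthetic whole-body *Daphnia magna* DESI-MSI study generator.

The phantom emulates the structure the real study's analyses rely on:

* 24 whole-body sections (2 treatments x 4 time points x 3 replicates)
  plus 2 blank slides, block-randomized over acquisition order;
* anatomical regions (body outline, eye, gut, appendages, dorsal brood
  chamber containing egg discs) with region-specific phosphatidylcholine
  and triacylglyceride abundances (PCs accumulate in eggs and eye, TGs
  in appendages and eggs);
* an egg-development time trend (PC rising toward 72 h, TG falling as
  yolk lipid is consumed) and a 48 h BPA perturbation (egg/storage PC
  down, TG up) that reverts by 72 h;
* multiplicative log-normal intensity noise, ppm-scale m/z jitter, a
  monotone per-acquisition m/z drift, intense background ions shared
  with the blanks, a low-intensity noise-peak floor, and an intensity
  detection threshold that produces missing values mechanistically.

Every quantity the recovery tests need is exported as ground truth.
Effect sizes and geometry are generator conventions (the source study
reports no numeric effect sizes); they are sized for desk-scale power
and all config-exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotate import LipidRecord, adduct_mz, default_library
from .core import Section, Spectrum, TIME_POINTS_H, DEFAULT_PIXEL_SIZE_UM
from .imzml import write_imzml, write_manifest
from .roi import ROI, write_roi_config
from .study import RHODAMINE_6G_MZ

REGION_LABELS = ("tissue", "appendages", "eggs", "eye", "gut", "brood_chamber")


@dataclass
class NoiseModel:
    """Acquisition noise parameters.

    sigma_log_intensity : sd of the natural-log multiplicative intensity
        noise (0.3 = roughly +-35% per peak).
    sigma_ppm : per-peak m/z jitter, ppm.
    drift_ppm_per_section : monotone m/z drift added per acquisition.
    detection_threshold : intensity below which a peak is not reported
        (the missingness mechanism).
    noise_peaks_per_pixel : mean count of low-intensity chemical-noise
        peaks per pixel (Poisson), which set the per-pixel MAD floor.
    """

    sigma_log_intensity: float = 0.3
    sigma_ppm: float = 5.0
    drift_ppm_per_section: float = 2.0
    detection_threshold: float = 50.0
    noise_peaks_per_pixel: float = 40.0
    noise_peak_mean: float = 80.0
    noise_peak_sd: float = 25.0
    calibrant_sigma_ppm: float = 0.5


@dataclass
class PhantomSpec:
    """Full parameterization of the synthetic study."""

    grid_shape: Tuple[int, int]                 # (n_rows, n_cols)
    pixel_size_um: float
    regions: Dict[str, List[ROI]]               # label -> ROI parts
    panel: List[Tuple[LipidRecord, str]]        # (lipid, emission adduct)
    abundance: pd.DataFrame                     # region x lipid base intensity
    temporal_multipliers: Dict[str, Dict[int, float]]   # class -> time -> factor
    treatment_effects: Dict[Tuple[int, str, str], float]  # (time, region, class)
    noise: NoiseModel
    background_ions: List[Tuple[float, float]]  # (m/z, base intensity)
    n_replicates: int = 3
    seed: int = 0

    def emission_mz(self) -> Dict[str, float]:
        """Emitted (theoretical adduct) m/z per panel lipid name."""
        return {
            lipid.name: adduct_mz(lipid.monoisotopic_mass, adduct)
            for lipid, adduct in self.panel
        }

    def validate(self) -> None:
        mzs = np.sort(np.array(list(self.emission_mz().values())))
        if mzs.size > 1:
            gaps_ppm = np.diff(mzs) / mzs[:-1] * 1e6
            if gaps_ppm.min() <= 100:
                raise ValueError(
                    f"panel emission m/z separation {gaps_ppm.min():.1f} ppm <= 100"
                )
        if (self.abundance.to_numpy() <= 0).any():
            raise ValueError("all base abundances must be > 0")
        for factors in self.temporal_multipliers.values():
            if any(f <= 0 for f in factors.values()):
                raise ValueError("temporal multipliers must be > 0")
        if any(f <= 0 for f in self.treatment_effects.values()):
            raise ValueError("treatment effect factors must be > 0")
        for label in self.regions:
            if label not in REGION_LABELS:
                raise ValueError(f"unknown region label {label!r}")


def _ellipse(label, cx, cy, a, b, parent=None, part=None) -> ROI:
    name = label if part is None else f"{label}:{part}"
    return ROI(label=name, shape="ellipse", center_xy=(cx, cy),
               semi_axes=(a, b), parent=parent)


def default_spec(seed: int = 0) -> PhantomSpec:
    """The default phantom: an adult female daphnid, ~290 tissue pixels
    per 80 x 50 section, with the four study-reported lipids plus filler
    panel and six plasticizer/solvent-like background ions."""
    # Geometry in (x=col, y=row) pixel coordinates of an 80-wide,
    # 50-tall grid; the animal faces left, brood chamber dorsal-right.
    regions: Dict[str, List[ROI]] = {
        "tissue": [_ellipse("tissue", 40, 25, 13, 7)],
        "eye": [_ellipse("eye", 29.5, 24, 2.0, 2.0, parent="tissue")],
        "gut": [_ellipse("gut", 41, 26, 7, 1.3, parent="tissue")],
        "appendages": [_ellipse("appendages", 33, 29.5, 4.5, 2.2, parent="tissue")],
        "brood_chamber": [_ellipse("brood_chamber", 44, 21, 4.8, 2.6,
                                   parent="tissue")],
        "eggs": [
            _ellipse("eggs", 41.5, 20, 1.1, 1.1, parent="brood_chamber", part=1),
            _ellipse("eggs", 44.0, 20, 1.1, 1.1, parent="brood_chamber", part=2),
            _ellipse("eggs", 46.5, 20, 1.1, 1.1, parent="brood_chamber", part=3),
            _ellipse("eggs", 42.5, 22, 1.1, 1.1, parent="brood_chamber", part=4),
            _ellipse("eggs", 45.0, 22, 1.1, 1.1, parent="brood_chamber", part=5),
            _ellipse("eggs", 47.5, 22, 1.1, 1.1, parent="brood_chamber", part=6),
        ],
    }

    library = default_library()
    panel = [
        (lipid, "[M+Na]+" if lipid.lipid_class == "PC" else "[M+K]+")
        for lipid in library
    ]

    # Region x class base intensities: PCs accumulate in eggs and eye,
    # TGs in appendages and eggs (storage lipid).
    class_base = {
        "PC": {"eggs": 2000.0, "eye": 1800.0, "gut": 400.0,
               "appendages": 300.0, "brood_chamber": 700.0, "tissue": 500.0},
        "TG": {"eggs": 2000.0, "eye": 300.0, "gut": 500.0,
               "appendages": 2500.0, "brood_chamber": 700.0, "tissue": 600.0},
    }
    rng = np.random.default_rng(seed)
    names = [lipid.name for lipid, _ in panel]
    # Per-lipid abundance scale and a mild region-specific fingerprint so
    # regions differ beyond the two class axes.
    lipid_scale = {n: s for n, s in zip(names, rng.uniform(0.6, 1.3, len(names)))}
    abundance = pd.DataFrame(index=list(REGION_LABELS), columns=names, dtype=float)
    for lipid, _ in panel:
        for region in REGION_LABELS:
            fingerprint = rng.uniform(0.8, 1.25)
            abundance.loc[region, lipid.name] = (
                class_base[lipid.lipid_class][region]
                * lipid_scale[lipid.name] * fingerprint
            )

    temporal = {
        "PC": {8: 1.0, 24: 1.0, 48: 1.1, 72: 1.8},
        "TG": {8: 1.0, 24: 0.85, 48: 0.70, 72: 0.55},
    }
    effects = {
        (48, "eggs", "PC"): 0.6,
        (48, "eggs", "TG"): 1.5,
        (48, "appendages", "PC"): 0.6,
        (48, "appendages", "TG"): 1.5,
    }
    background = [
        (104.1070, 6000.0),   # choline fragment
        (184.0733, 8000.0),   # phosphocholine headgroup
        (391.2843, 5000.0),   # phthalate plasticizer [M+H]+
        (413.2662, 4500.0),   # phthalate plasticizer [M+Na]+
        (553.4594, 3500.0),   # solvent cluster
        (615.4956, 3000.0),   # solvent cluster
    ]
    spec = PhantomSpec(
        grid_shape=(50, 80),
        pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
        regions=regions,
        panel=panel,
        abundance=abundance,
        temporal_multipliers=temporal,
        treatment_effects=effects,
        noise=NoiseModel(),
        background_ions=background,
        seed=seed,
    )
    spec.validate()
    return spec


def null_spec(seed: int = 0) -> PhantomSpec:
    """The default phantom with every temporal and treatment factor set
    to 1 (for false-positive-rate checks)."""
    spec = default_spec(seed)
    spec.temporal_multipliers = {
        cls: {t: 1.0 for t in TIME_POINTS_H} for cls in spec.temporal_multipliers
    }
    spec.treatment_effects = {}
    return spec


def region_label_grid(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth region label per grid pixel ('' = off-tissue).

    Computed directly from the ellipse quadratic forms with the same
    nesting precedence the ROI annotator uses (deepest label wins),
    independent of the annotation code path.
    """
    n_rows, n_cols = spec.grid_shape
    xs = np.arange(1, n_cols + 1)[None, :]
    ys = np.arange(1, n_rows + 1)[:, None]

    def mask_of(parts: List[ROI]) -> np.ndarray:
        m = np.zeros((n_rows, n_cols), dtype=bool)
        for roi in parts:
            cx, cy = roi.center_xy
            a, b = roi.semi_axes
            m |= ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0 + 1e-12
        return m

    body = mask_of(spec.regions["tissue"])
    labels = np.where(body, "tissue", "").astype(object)
    depth1 = ["eye", "gut", "appendages", "brood_chamber"]
    for label in depth1:
        if label in spec.regions:
            labels[mask_of(spec.regions[label]) & body] = label
    if "eggs" in spec.regions and "brood_chamber" in spec.regions:
        chamber = mask_of(spec.regions["brood_chamber"]) & body
        labels[mask_of(spec.regions["eggs"]) & chamber] = "eggs"
    return labels


@dataclass
class SectionTruth:
    """Everything the recovery tests need about one simulated section."""

    section_id: str
    label_grid: np.ndarray                   # region label per pixel ('' = off)
    true_intensity: Dict[str, np.ndarray]    # lipid -> grid of true intensity
    emission_mz: Dict[str, float]
    drift_ppm: float
    applied_effects: Dict[str, float]        # lipid -> treatment factor (eggs)


def _true_intensity_grids(
    spec: PhantomSpec, label_grid: np.ndarray,
    time_point_h: int, treatment: str,
) -> Tuple[Dict[str, np.ndarray], Dict[str, float]]:
    grids: Dict[str, np.ndarray] = {}
    applied: Dict[str, float] = {}
    for lipid, _ in spec.panel:
        grid = np.zeros(spec.grid_shape)
        cls = lipid.lipid_class
        for region in REGION_LABELS:
            mask = label_grid == region
            if not mask.any():
                continue
            value = float(spec.abundance.loc[region, lipid.name])
            if region == "eggs" and cls in spec.temporal_multipliers:
                value *= spec.temporal_multipliers[cls][time_point_h]
            if treatment == "BPA":
                value *= spec.treatment_effects.get((time_point_h, region, cls), 1.0)
            grid[mask] = value
        applied[lipid.name] = (
            spec.treatment_effects.get((time_point_h, "eggs", cls), 1.0)
            if treatment == "BPA" else 1.0
        )
        grids[lipid.name] = grid
    return grids, applied


def simulate_section(
    spec: PhantomSpec,
    time_point_h: int,
    treatment: str,
    replicate: int,
    acquisition_index: int,
    seed: int,
) -> Tuple[Section, SectionTruth]:
    """Simulate one whole-body section (deterministic for a fixed seed)."""
    if time_point_h not in TIME_POINTS_H:
        raise ValueError(f"time_point_h must be one of {TIME_POINTS_H}")
    if treatment not in ("control", "BPA"):
        raise ValueError(f"unknown treatment {treatment!r}")
    section_id = f"{treatment}_{time_point_h:02d}h_r{replicate}"
    rng = np.random.default_rng(seed)
    label_grid = region_label_grid(spec)
    drift = spec.noise.drift_ppm_per_section * acquisition_index
    grids, applied = _true_intensity_grids(spec, label_grid, time_point_h, treatment)
    emission = spec.emission_mz()

    spectra = _assemble_spectra(spec, rng, label_grid, grids, emission, drift)
    section = Section(
        section_id=section_id,
        spectra=spectra,
        grid_shape=spec.grid_shape,
        pixel_size_um=spec.pixel_size_um,
        subject_id=f"daphnid_{treatment}_{time_point_h}_{replicate}",
        time_point_h=time_point_h,
        treatment=treatment,
        acquisition_index=acquisition_index,
        is_blank=False,
    )
    truth = SectionTruth(section_id, label_grid, grids, emission, drift, applied)
    return section, truth


def simulate_blank(
    spec: PhantomSpec, seed: int, acquisition_index: int = 0,
    blank_id: str = "blank",
) -> Section:
    """A blank DESI slide: background ions and noise peaks only."""
    rng = np.random.default_rng(seed)
    n_rows, n_cols = spec.grid_shape
    empty_labels = np.full(spec.grid_shape, "", dtype=object)
    drift = spec.noise.drift_ppm_per_section * acquisition_index
    spectra = _assemble_spectra(spec, rng, empty_labels, {}, {}, drift)
    return Section(
        section_id=blank_id,
        spectra=spectra,
        grid_shape=spec.grid_shape,
        pixel_size_um=spec.pixel_size_um,
        subject_id=None,
        acquisition_index=acquisition_index,
        is_blank=True,
    )


def _assemble_spectra(
    spec: PhantomSpec,
    rng: np.random.Generator,
    label_grid: np.ndarray,
    true_grids: Dict[str, np.ndarray],
    emission: Dict[str, float],
    drift_ppm: float,
) -> Dict[Tuple[int, int], Spectrum]:
    noise = spec.noise
    n_rows, n_cols = spec.grid_shape
    n_pixels = n_rows * n_cols

    # Chemical-noise floor: many small peaks per pixel.  Noise m/z are
    # kept >100 ppm away from every panel emission m/z: blanks stay
    # panel-free by construction, and drifted panel peaks (up to ~50 ppm
    # over the study) never chain one-sidedly into adjacent noise, which
    # would bias consensus centroids.
    counts = rng.poisson(noise.noise_peaks_per_pixel, n_pixels)
    total = int(counts.sum())
    noise_mz = rng.uniform(60.0, 990.0, total)
    panel_mz_all = np.array(sorted(spec.emission_mz().values()))
    if panel_mz_all.size:
        nearest = panel_mz_all[
            np.clip(np.searchsorted(panel_mz_all, noise_mz), 0, panel_mz_all.size - 1)
        ]
        lower = panel_mz_all[
            np.clip(np.searchsorted(panel_mz_all, noise_mz) - 1, 0, panel_mz_all.size - 1)
        ]
        dist = np.minimum(np.abs(noise_mz - nearest), np.abs(noise_mz - lower))
        clash = dist <= 100.0 * noise_mz * 1e-6
        noise_mz[clash] += 0.3  # push clashing noise peaks out of the window
    noise_int = np.abs(rng.normal(noise.noise_peak_mean, noise.noise_peak_sd, total))
    noise_split = np.cumsum(counts)[:-1]
    noise_mz_per_pixel = np.split(noise_mz, noise_split)
    noise_int_per_pixel = np.split(noise_int, noise_split)

    # Background ions in every pixel (and in blanks).
    bg_mz = np.array([mz for mz, _ in spec.background_ions])
    bg_base = np.array([i for _, i in spec.background_ions])
    bg_jitter = rng.normal(0.0, noise.sigma_ppm, (n_pixels, bg_mz.size))
    bg_obs_mz = bg_mz[None, :] * (1.0 + (drift_ppm + bg_jitter) * 1e-6)
    bg_obs_int = bg_base[None, :] * rng.lognormal(
        0.0, noise.sigma_log_intensity, (n_pixels, bg_mz.size)
    )

    # Panel lipids in tissue pixels.
    lipid_names = list(true_grids)
    if lipid_names:
        flat_true = np.stack(
            [true_grids[name].ravel() for name in lipid_names], axis=1
        )  # n_pixels x n_lipids
        em = np.array([emission[name] for name in lipid_names])
        panel_jitter = rng.normal(0.0, noise.sigma_ppm, flat_true.shape)
        panel_mz = em[None, :] * (1.0 + (drift_ppm + panel_jitter) * 1e-6)
        panel_int = flat_true * rng.lognormal(
            0.0, noise.sigma_log_intensity, flat_true.shape
        )
        panel_int[flat_true == 0] = 0.0

    spectra: Dict[Tuple[int, int], Spectrum] = {}
    threshold = noise.detection_threshold
    for p in range(n_pixels):
        y, x = divmod(p, n_cols)
        mz_parts = [noise_mz_per_pixel[p], bg_obs_mz[p]]
        int_parts = [noise_int_per_pixel[p], bg_obs_int[p]]
        if lipid_names:
            present = panel_int[p] > 0
            if present.any():
                mz_parts.append(panel_mz[p][present])
                int_parts.append(panel_int[p][present])
        mz_all = np.concatenate(mz_parts)
        int_all = np.concatenate(int_parts)
        keep = int_all >= threshold
        mz_all, int_all = mz_all[keep], int_all[keep]
        order = np.argsort(mz_all)
        mz_all, int_all = mz_all[order], int_all[order]
        if mz_all.size > 1:  # drop exact duplicates (measure-zero but possible)
            distinct = np.concatenate([[True], np.diff(mz_all) > 0])
            mz_all, int_all = mz_all[distinct], int_all[distinct]
        np.clip(mz_all, 50.0, 1000.0, out=mz_all)
        spectra[(x + 1, y + 1)] = Spectrum(mz_all, int_all)
    return spectra


@dataclass
class StudyBundle:
    """A complete simulated study, in memory."""

    spec: PhantomSpec
    sections: List[Section]
    blanks: List[Section]
    truths: Dict[str, SectionTruth]
    manifest: List[dict]
    rois_by_section: Dict[str, List[ROI]]
    calibrant_qc: pd.DataFrame


def simulate_study(spec: PhantomSpec, seed: int, outdir=None) -> StudyBundle:
    """Simulate the full 2 x 4 x 3 study plus two blank slides.

    Acquisition order is block-randomized: one block per (time point,
    replicate) pair, each containing both treatments in shuffled order,
    so treatments are balanced over the monotone m/z drift.  Blanks are
    acquired first and last.  If ``outdir`` is given, imzML files, the
    manifest, ROI configs, the calibrant QC log and ground-truth tables
    are written so the pipeline can run with no other input.
    """
    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.spawn(len(TIME_POINTS_H) * 2 * spec.n_replicates + 2))

    blocks = [(t, r) for t in TIME_POINTS_H for r in range(1, spec.n_replicates + 1)]
    rng.shuffle(blocks)
    order: List[Tuple[int, str, int, int]] = []
    acq = 1
    for t, r in blocks:
        pair = ["control", "BPA"]
        rng.shuffle(pair)
        for treatment in pair:
            order.append((t, treatment, r, acq))
            acq += 1

    sections, truths = [], {}
    for t, treatment, r, a in order:
        child = np.random.default_rng(next(child_seeds))
        sec, truth = simulate_section(
            spec, t, treatment, r, acquisition_index=a,
            seed=int(child.integers(2**31 - 1)),
        )
        sections.append(sec)
        truths[sec.section_id] = truth
    blanks = []
    for blank_id, a in [("blank_start", 0), ("blank_end", acq)]:
        child = np.random.default_rng(next(child_seeds))
        blanks.append(simulate_blank(
            spec, seed=int(child.integers(2**31 - 1)),
            acquisition_index=a, blank_id=blank_id,
        ))

    manifest = []
    for sec in blanks[:1] + sections + blanks[1:]:
        manifest.append({
            "section_id": sec.section_id,
            "file": f"{sec.section_id}.imzML",
            "subject_id": sec.subject_id,
            "time_point_h": sec.time_point_h,
            "treatment": sec.treatment,
            "acquisition_index": sec.acquisition_index,
            "is_blank": sec.is_blank,
        })

    all_rois = default_roi_list(spec)
    rois_by_section = {sec.section_id: list(all_rois) for sec in sections}

    qc_rng = np.random.default_rng(ss.spawn(1)[0])
    qc_rows = []
    for sec in blanks[:1] + sections + blanks[1:]:
        drift = spec.noise.drift_ppm_per_section * sec.acquisition_index
        observed = RHODAMINE_6G_MZ * (
            1.0 + (drift + qc_rng.normal(0.0, spec.noise.calibrant_sigma_ppm)) * 1e-6
        )
        qc_rows.append({
            "section_id": sec.section_id,
            "acquisition_index": sec.acquisition_index,
            "calibrant": "rhodamine_6G",
            "observed_mz": observed,
            "theoretical_mz": RHODAMINE_6G_MZ,
        })
    calibrant_qc = pd.DataFrame(qc_rows)

    bundle = StudyBundle(spec, sections, blanks, truths, manifest,
                         rois_by_section, calibrant_qc)
    if outdir is not None:
        write_study(bundle, outdir)
    return bundle


def default_roi_list(spec: PhantomSpec) -> List[ROI]:
    """The phantom's region geometry as a flat ROI list (the same schema
    the annotator consumes)."""
    out: List[ROI] = []
    for label in REGION_LABELS:
        out.extend(spec.regions.get(label, []))
    return out


def write_study(bundle: StudyBundle, outdir) -> None:
    """Write imzML files, manifest, ROI config, calibrant QC log and
    ground-truth tables under ``outdir``."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sec in bundle.blanks[:1] + bundle.sections + bundle.blanks[1:]:
        write_imzml(sec, outdir / f"{sec.section_id}.imzML")
    write_manifest(bundle.manifest, outdir / "manifest.yaml")
    write_roi_config(bundle.rois_by_section, outdir / "rois.yaml")
    bundle.calibrant_qc.to_csv(outdir / "calibrant_qc.csv", index=False)

    mask_rows = []
    for sid, truth in bundle.truths.items():
        n_rows, n_cols = truth.label_grid.shape
        for y in range(n_rows):
            for x in range(n_cols):
                label = truth.label_grid[y, x]
                if label:
                    mask_rows.append({"section_id": sid, "x": x + 1, "y": y + 1,
                                      "region_label": label})
    pd.DataFrame(mask_rows).to_csv(outdir / "truth_region_masks.csv", index=False)

    effect_rows = []
    for sid, truth in bundle.truths.items():
        for lipid, factor in truth.applied_effects.items():
            effect_rows.append({
                "section_id": sid, "lipid": lipid,
                "egg_treatment_factor": factor,
                "drift_ppm": truth.drift_ppm,
                "emission_mz": truth.emission_mz[lipid],
            })
    pd.DataFrame(effect_rows).to_csv(outdir / "truth_effects.csv", index=False)
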