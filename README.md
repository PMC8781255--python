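# daphmsi

Processing and statistics for desorption-electrospray-ionization mass-
spectrometry imaging (DESI-MSI) of whole-body *Daphnia magna* sections —
spatial lipidomics for ecotoxicology. The package covers the full chain
from imzML pixel spectra to per-region lipid statistics, and ships a
synthetic-study generator so every stage can be exercised and validated
without the (very large) raw imaging data.

**Who it is for.** Analysts working with centroided MSI data of small
aquatic model organisms who need a reproducible, scriptable version of the
common DESI workflow: QC/recalibration, per-section spectral cleanup,
study-level feature alignment, blank-slide background removal, anatomical
ROI annotation, and pixel-level multivariate/univariate statistics with
MS1 lipid annotation.

## The workflow

Per section (fixed order):

1. **SNR filter** — noise per pixel is the median absolute deviation (MAD)
   of its peak intensities; peaks with intensity/noise < 3 are removed.
2. **25 ppm alignment** — pooled peaks are clustered by a single-linkage
   gap rule (cut where the gap between consecutive m/z exceeds
   `tol · m/z · 10⁻⁶`); consensus m/z is the intensity-weighted mean.
3. **5% pixel filter** — features detected in fewer than 5% of the
   section's pixels are removed.
4. **RMS normalization** — each pixel's observed intensities are divided
   by √(mean of squares).

Across the study: per-section mass recalibration from recorded rhodamine
6G calibrant measurements (theoretical m/z 443.2335 from C28H31N2O3+),
35 ppm study alignment, removal of features whose tissue median is <10×
their blank-slide median, and nested-ROI pixel annotation (body →
eye/gut/appendages/brood chamber → eggs).

Statistics follow the study design: balanced sampling (200 pixels per
tissue type), 50% presence/missingness filters, 95% confidence-ellipse
outlier removal in PC1–PC2 (χ², 2 df), KNN imputation (k = 5), pareto
scaling, PCA, per-section medians for trend analysis, Mann–Whitney /
Wilcoxon rank tests with Benjamini–Hochberg FDR, and MS1 annotation of
features against a lipid library within 25 ppm over the four common
positive adducts ([M+H]+, [M+Na]+, [M+K]+, [M+NH4]+).

## Worked example

Simulate the default synthetic study (24 whole-body sections: 2
treatments × 4 time points × 3 replicates, plus 2 blank slides) and run
the 48 h exposure contrast:

```sh
daphmsi simulate --out study --seed 1
daphmsi run --manifest study/manifest.yaml --rois study/rois.yaml \
    --calibrant-qc study/calibrant_qc.csv --mode exposure_contrast \
    --out results --seed 1
```

This prints per-stage counts, e.g.:

```
  read: {'n_sections': 24, 'n_blanks': 2, 'n_pixels': 96000}
  recalibrate: {'n_sections_corrected': 24}
  align_study: {'n_features': 27}
  remove_background: {'n_features_before': 27, 'n_features_after': 21}
  roi_annotation: {'n_tissue_pixels': 6744, 'pixels_per_region': {...}}
  exposure_contrast: {'n_pixels': 104, 'n_features': 20, 'n_significant_fdr05': 20}
  annotate: {'n_features': 20, 'n_annotated': 20}
```

Reading: 96,000 pixel spectra were reduced to a study matrix of 27
consensus features; the six blank-shared background ions were removed;
6,744 pixels fell inside the animal outlines; and in 48 h eggs all 20
panel lipids differ between control and BPA-exposed animals at FDR < 0.05.
`results/feature_tests.csv` holds per-feature statistics with a
`direction` column (sign of the exposed − control median difference:
negative for every phosphatidylcholine, positive for every
triacylglyceride, matching the injected perturbation), and
`results/annotations.csv` maps each feature m/z to its best library hit,
e.g. PC(32:0) [M+Na]+ within ~1 ppm of m/z 756.55.

The `tissue_types` mode writes PCA scores/loadings/variance tables
instead (`pca_scores.csv` separates appendages, eggs, eye and gut
pixels), and `egg_timecourse` writes per-section egg medians across
8–72 h. Library code is available for the same steps
(`daphmsi.preprocess`, `daphmsi.study`, `daphmsi.stats`, ...); see
`docs/methods.md` for the models and conventions.

## Acceptance script

`scripts/acceptance.py` re-runs the package's main computation from
scratch: it recomputes the calibrant and lipid-mass checks, simulates the
default synthetic study, and executes the pipeline end to end in two
analysis modes, printing the headline numbers to stderr.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
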