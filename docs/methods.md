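# Methods

`daphmsi` implements a desorption-electrospray-ionization mass-spectrometry-
imaging (DESI-MSI) processing and statistics workflow for whole-body spatial
lipidomics of *Daphnia magna*, together with a synthetic-study generator that
makes every stage testable at desk scale. This note documents the models,
conventions, numerical choices, and the limits of what a green test
establishes.

## Data model

A **Spectrum** is a centroided peak list (strictly increasing m/z in the
acquisition window 50–1000 Da, non-negative intensities). A **Section** is a
grid of spectra with 1-based imzML pixel coordinates (x = column, y = row;
internal image arrays are row-major `(row=y, col=x)`), a 35 µm pixel size by
default, and study metadata (time point ∈ {8, 24, 48, 72} h, treatment ∈
{control, BPA}, acquisition order) carried in a sidecar YAML manifest —
imzML has no standard slot for it. A **FeatureMatrix** is pixels × consensus
m/z features; a peak not detected in a pixel is *missing* (`NaN`), never
zero, and observed values are strictly positive. Profile-mode imzML is
rejected by default: every downstream rule (SNR, ppm alignment) is
peak-based.

imzML I/O is implemented in-package (processed-mode writer, processed- and
continuous-mode reader; 64-bit m/z, 32-bit intensities, uncompressed
external binary). Round-trip identity holds to ≤1e-6 Da in m/z and ≤1e-4
relative in intensity.

## Per-section cleanup (fixed order)

1. **SNR filter.** Noise per pixel = median absolute deviation (MAD) of the
   pixel's peak intensities; peaks with intensity/noise < 3 are dropped.
   The plain MAD is used (`mad_scale = 1.0`, no 1.4826 Gaussian consistency
   factor) since only "MAD" is specified by the source workflow; the factor
   is a parameter. Noise = 0 (constant or single-peak spectrum) keeps all
   peaks — SNR is undefined there and annihilating a pixel on that basis
   would be arbitrary.
2. **25 ppm alignment.** All peaks of a section are pooled and sorted;
   clusters are cut wherever the gap between consecutive m/z exceeds
   `tol × lower m/z × 1e-6` (single-linkage gap rule). On a sorted pool this
   is provably identical to transitively merging every pair within
   tolerance, which is the brute-force oracle the tests compare against.
   Consensus m/z is the intensity-weighted mean of cluster members (bright
   peaks are better mass estimates; plain mean by flag). A pixel
   contributing several peaks to one cluster keeps its most intense (tie →
   lower m/z). Clusters can be pruned early at the pixel-frequency
   threshold so that dense chemical-noise floors (one random peak per
   ~0.01 Da per pixel) never materialize as a huge dense matrix; the result
   is identical to filtering afterwards.
3. **5% pixel filter.** Features detected in fewer than
   `ceil(0.05 × n_pixels)` pixels are removed — the boundary is strict
   ("less than 5%"), so 5 of 100 survives and 4 of 100 does not.
4. **RMS normalization.** Each pixel's observed intensities are divided by
   the root mean square over its *observed* features; missing entries stay
   missing and are never zero-filled before normalization.

An audit log records the stage order and per-stage counts; tests assert the
order is exactly SNR → align → pixel filter → RMS.

## Study assembly and calibration QC

Section matrices are merged with the same gap rule at 35 ppm (cluster
weights = total feature intensity). Background removal compares, for every
study feature matched within 35 ppm to a blank-slide feature, the median
tissue-pixel intensity against 10× the median blank intensity; the feature
is removed iff below. Missing values enter the median as 0 by default (a
feature absent from most pixels has a low median, correctly biasing toward
removal); median-over-observed is available by flag. Unmatched features are
always kept, and both blank slides are pooled.

Drift monitoring uses the rhodamine 6G cation: its theoretical m/z is
computed from C28H31N2O3+ by summing neutral-atom masses *without*
electron-mass correction, which reproduces the printed calibrant constant
443.2335 (with electron correction it would be 443.2329). Recalibration
fits ppm error against m/z over matched calibrant pairs (constant or linear
model) and corrects by `m/z × (1 − predicted_ppm × 1e-6)`; the polyalanine
[M+H]+ ladder (n × 71.03711 + 18.010565 + 1.007276, restricted to 50–1000
Da) provides multi-point calibrants for the linear model.

The pipeline applies a per-section *constant* recalibration from the
recorded rhodamine measurements before study alignment. This is a design
choice this package makes deliberately: the default synthetic drift
(2 ppm per acquisition over 26 acquisitions) accumulates to ~50 ppm, and
without recalibration study-level consensus centroids would sit near the
25 ppm annotation tolerance. The real study handled this operationally by
recalibrating the instrument whenever the calibrant error exceeded 25 ppm;
here the same math is applied to the recorded data instead.

## ROI annotation

ROIs are declarative config objects (ellipses or simple polygons in pixel
coordinates) rather than interactive selections, so the generator can
export its geometry in the same schema the annotator consumes. Containment
is boundary-inclusive (ellipse: quadratic form ≤ 1; polygon: point-covered
test on a non-self-intersecting polygon). Pixels take the label of the
deepest nested ROI containing them, children count only inside their parent
(the two-stage brood-chamber → eggs annotation), and same-depth overlap
between different regions is a configuration error, not a silent tie-break.
A region may consist of several parts (`eggs:1` … `eggs:6` share the base
label `eggs`). When a `tissue` ROI is present, pixels outside every ROI are
dropped (background removal).

## Statistics

The analysis chain is: balanced sampling (200 pixels per tissue type,
seeded, without replacement; smaller groups are taken whole with a logged
warning) → 50% filters (feature kept if observed in ≥50% of the pixels of
*some* group, so tissue-specific lipids survive; then pixels missing >50%
of retained features are dropped — features first) → 95% confidence-ellipse
outlier removal (per group: impute, pareto-scale, PCA, squared Mahalanobis
distance of PC1–PC2 scores against the chi-square quantile with 2 df,
5.991 at 0.95) → KNN imputation (k = 5; nan-Euclidean distances over
mutually observed features rescaled by total feature count, mean of the k
nearest donors; scikit-learn's `KNNImputer` implements exactly this
convention and is used behind the module surface) → pareto scaling
((x − mean)/√sd, constant features → zero columns) → PCA by SVD with a
fixed sign convention (the largest-|loading| element of each component is
positive) for cross-platform reproducibility.

Significance testing runs in two modes. The source workflow names a
signed-rank test but reports FDR p-values (~1e-22) that are impossible at
n = 3 replicates per group; the default mode therefore tests at pixel level
with a Mann–Whitney rank-sum test (exact for min(n) ≤ 8 and tie-free data,
tie-corrected normal approximation otherwise), while per-section medians
(n = biological replicates) drive the trend summaries. A paired signed-rank
mode is exposed for matched designs. Multiple testing uses
Benjamini–Hochberg step-up (statsmodels behind the surface; an enumeration
oracle in the tests).

## The synthetic world

The generator's defaults are the stated study design: 2 treatments ×
4 time points × 3 replicates = 24 sections plus 2 blanks, 80 × 50 pixel
grids at 35 µm, block-randomized acquisition (each block holds both
treatments, so treatment is balanced over the monotone drift), blanks first
and last. The phantom daphnid occupies ~280 pixels per section (~6,700
tissue pixels study-wide) with eye, gut, appendage, brood-chamber and six
egg regions.

The lipid panel is 10 PCs + 10 TGs, including the four lipids reported in
the source study's figures — PC(32:0), PC(34:3), TG(48:5), TG(50:6) — each
emitted as one adduct (PC → [M+Na]+, TG → [M+K]+, matching the printed m/z
values) with pairwise emission separation > 100 ppm so alignment can never
merge distinct lipids. Abundances follow class × region bases (PC high in
eggs/eye, TG high in appendages/eggs), a per-lipid scale, and a mild
per-(region, lipid) fingerprint so regions are separable beyond the two
class axes. Egg-development multipliers are PC [1.0, 1.0, 1.1, 1.8] and TG
[1.0, 0.85, 0.70, 0.55] across 8/24/48/72 h; 48 h BPA multiplies egg and
appendage (storage-site) PC by 0.6 and TG by 1.5, reverting by 72 h. These
effect sizes are invented — the source study reports none numerically —
and are sized for desk-scale power at ~50–100 egg pixels per arm; all are
config-exposed and none were tuned against test outcomes.

Noise: multiplicative log-normal intensity noise (σ = 0.3 on the natural
log), 5 ppm per-peak m/z jitter, 2 ppm per-acquisition monotone drift, six
intense background ions (choline/phosphocholine fragments, plasticizers,
solvent clusters) present everywhere including blanks, a Poisson(40)
floor of low-intensity noise peaks per pixel (which is what gives the MAD
a realistic noise estimate to latch onto), and an intensity detection
threshold of 50 counts that produces missingness mechanistically rather
than by MCAR masking. Noise peaks are kept > 100 ppm away from panel m/z:
blanks are panel-free by construction, and drifted panel peaks (up to
~50 ppm late in the acquisition order) can never chain one-sidedly into
adjacent noise, which would bias consensus centroids and the recovered
drift slope.

What the phantom does *not* emulate: peak-shape and centroiding artifacts,
isotope envelopes, ion suppression and matrix effects, section-level random
intensity effects (pixels are independent given the design, which is why
pixel-level tests are exactly calibrated here but would be anti-conservative
on real data with between-animal variance), spatial autocorrelation within
regions, and tissue-boundary partial-volume pixels. A green recovery test
therefore establishes algorithmic correctness of the chain, not field
performance on real tissue.

## Numerical conventions

- Monoisotopic masses use most-abundant-isotope values to ≥6 decimals;
  adduct cations ([M+H]+ 1.007276, [M+Na]+ 22.989221, [M+K]+ 38.963158,
  [M+NH4]+ 18.033826) include the electron-mass correction. The rhodamine
  calibrant constant deliberately does not (see above); both conventions
  are available by flag.
- MS1 annotation searches all four positive adducts within 25 ppm and
  reports every hit sorted by |ppm|, flagging the best; which adduct the
  original authors assigned is unknowable from the printed values, so the
  minimum-|ppm| assignment is the operationalization.
- Ion images sum matched features within tolerance per pixel; missing and
  dropped pixels render as 0 (detection dropout), and common-scale series
  share the global maximum without touching pixel values. PNG rendering is
  byte-deterministic.
- All stochastic steps (sampling, simulation) take explicit seeds; the
  study generator derives per-section seeds from one root seed via
  `SeedSequence.spawn`. Pipeline summaries contain no wall-clock values,
  so rerunning with one seed reproduces outputs byte-for-byte.

## Known limitations

- The imzML reader targets well-formed imzML 1.1; vendor-converter dialect
  quirks are untested (no such files can ship here) beyond a hand-built
  fixture with inline cvParams.
- Blank matching reuses the 35 ppm study tolerance; the source workflow
  does not state a blank-matching tolerance.
- The 50% filters are interpreted as per-group presence then per-pixel
  missingness, in that order; the confidence ellipse uses PC1–PC2 only.
  Both are documented interpretations of ambiguous wording, exposed as
  parameters.
- Pixel-level rank tests treat pixels as independent; see the synthetic-
  world caveats above.
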