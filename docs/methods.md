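# Methods

`cytoscreen` re-creates, in software, an automated Raman cytology
workstation: a motorised bright-field microscope that finds cell nuclei on
a slide, a confocal Raman spectrometer that records one spectrum per
nucleus, a spectral pre-processing chain, and a chemometric classification
layer. Every stage can run against a simulated instrument with known
ground truth, so the whole workflow is testable on a desk.

## Nucleus localisation by the bright-spot (micro-lens) effect

An unstained epithelial cell is a phase object: almost invisible in a
focused bright-field image. With spatially coherent illumination (condenser
aperture closed to a minimum), the optical thickness of the nucleus focuses
the light into a bright spot in a plane displaced from focus — about 14 µm
for round, thick ThinPrep-prepared cells and about 50 µm for flat adherent
cells. The spot marks the nucleus position accurately enough to aim a
laser with a 2–3 µm sampling volume.

The package does not model this diffractively. The phantom renders each
nucleus as an isotropic Gaussian spot (default amplitude 150 counts over a
100-count background, radius σ = 2.5 µm) whose amplitude follows a Gaussian
axial envelope `exp(−(z−z_spot)²/2ζ²)` with ζ = 5 µm, plus a faint edge
ring near focus whose contrast vanishes exactly at focus and decays over
~10 µm of defocus. These constants were chosen so that noise-free contrast
profiles are well formed (a single interior maximum at the bright-spot
plane, a minimum at focus); the real paper reports no quantitative spot
statistics, so they are free parameters of the benchmark, with the spot
signal-to-noise ratio configurable down to ~3.

### Autofocus

Image contrast is measured as variance over mean, σ²/µ, of pixel
intensities (population σ). The alternative reading (σ/µ)² differs only by
a monotone transform of the same profile shape at fixed mean; σ²/µ is the
default and the choice is recorded per run. The bright-spot plane is the
interior global maximum of the contrast profile; the focal plane is the
interior local minimum nearest it, ties broken toward z = 0, boundary
extrema rejected. The default scan spans −20…+20 µm in 2 µm steps
(ThinPrep preset; the adherent preset scans to +60 µm). Ending the scan
near the bright-spot plane matters: beyond it the profile decays to a flat
noise floor where any wiggle is formally a local minimum.

### Stitching, detection, routing

Tiles are stitched translation-only: nominal offsets come from commanded
stage positions, then each adjacent pair is refined on its overlap strip.
The refinement is gated by the phase-correlation peak ratio (≥ 3, else the
nominal offset is kept — the fallback path, not an error) and localised by
direct normalised cross-correlation over a ±6 px window with parabolic
sub-pixel interpolation; spectral phase methods mislocalise on smooth,
band-limited content such as diffuse spots. Overlaps blend by feathered
average.

Candidates are local maxima of the Gaussian-smoothed mosaic (σ = 4 px)
above `background + 0.25·(max − background)` with background the smoothed
median, at least 8 px apart, plateaus reduced to centroids. A significance
floor (dynamic range ≤ 6 robust σ of the smoothed mosaic → no candidates)
keeps an empty field from sprouting noise detections. The most isolated
candidates are kept (clustered cells risk double targeting), mapped to
stage coordinates by a least-squares affine fit on tile-centre
correspondences, translated by the measured laser offset, and ordered by a
greedy nearest-neighbour route to minimise stage travel.

The simulated stage quantises commanded positions to 0.1 µm and adds
Gaussian repeatability jitter (σ = half the 0.25 µm repeatability spec).

## Spectral model

Spectra live on a 1024-sample linear axis over −34…2517 cm⁻¹. A raw cell
spectrum is modelled in electrons as

    t · (cr·R_class + cb·Glass + baseline + dark)

followed by Poisson shot noise, Gaussian read noise (4 e⁻), unit gain, and
occasional cosmic-ray spikes. `R_class` is a sum of Gaussian bands
(widths 4–10 cm⁻¹) at the common cellular Raman positions; amplitudes give
strong bands of ~2000 electrons at the default 10 s acquisition, typical of
nucleus spectra on a 532 nm system. The two default classes differ only at
789, 1003 and 1490 cm⁻¹, where the high-grade class is 15% stronger. Glass
is a set of broad humps strongest near 1050–1150 cm⁻¹; the baseline is a
random low-order Legendre polynomial; dark current is 0.0512 e⁻/s/sample.
The weights `cr` and `cb` vary log-normally between spectra (σ = 0.15 and
0.20) to emulate focus and morphology variation. Cosmic rays arrive at
0.02 events/s, 1–3 channels wide, each channel 20–200× the local noise σ;
ground-truth spike channels are recorded for oracle tests.

What the generator does **not** emulate: physical (pseudo-Voigt) line
shapes, wavenumber-axis nonlinearity and calibration drift, detector etaloning,
within-nucleus heterogeneity, autofluorescence photobleaching dynamics, and
between-batch culture variation. Passing tests therefore demonstrate that
the *algorithms* behave as specified under controlled, realistic noise —
not that real cell lines separate with any particular accuracy.

## Pre-processing chain

Order: cosmic-ray removal → reference construction → EMSC → Savitzky–Golay
→ fingerprint crop (600–1800 cm⁻¹, closed interval) → quality cull. Each
class cohort (one cell line, one slide series) is treated as its own
dataset for cosmic-ray matching, as it would be on the instrument.

### Cosmic-ray removal by matched-spectrum substitution

Cosmic rays are narrow positive spikes; with thousands of similar cell
spectra in a run, the cleanest repair is to substitute values from closely
matching spectra rather than acquire everything twice. The detection
reference for each spectrum is built in three steps:

1. **Shortlist** the 40 most correlated other spectra, with correlation
   computed on a median-filtered proxy — a shared-coincidence spike would
   otherwise make two spectra correlate best of all.
2. **Fit** each candidate to the target: least squares over a scale factor,
   a cohort-median column (absorbs band-height mismatch for spectra with
   extreme cell weight), and a 5th-order Legendre baseline (absorbs smooth
   background mismatch). Fits are initialised on despiked versions —
   otherwise a gross spike makes it cheaper for least squares to drop the
   match than to absorb the outlier — and refitted once with residuals
   beyond 25×MAD masked.
3. **Consensus**: the 7 candidates with the smallest upper-order residual
   statistic form a channel-wise median model (immune to any single
   match's own spikes). Detection uses Savitzky–Golay-denoised match
   columns so the reference adds no per-channel noise of its own;
   replacement values come from the raw-match fits.

A channel is flagged when its (one-sided, positive) residual exceeds
`k_sigma = 8` times a per-channel σ that combines a rolling 25-channel MAD,
a fitted CCD noise law (σ² = a + b·counts, recovered from the residuals by
intensity-binned robust regression — no camera calibration assumed), and a
shrunk (×0.6) consensus-disagreement term that widens the threshold
exactly where the reference model is unreliable. Contiguous runs wider
than `max_width = 3` channels are not cosmic-ray-like and are unflagged.
Two passes are run and flags accumulate; unflagged channels are never
altered, and the operation is idempotent on clean data. With only two
spectra the procedure degenerates gracefully to an exact twin fit.

### EMSC

Each raw spectrum is decomposed by ordinary least squares as
`X0 ≈ cr·R + cb·B + Σ_{m=0..N} cm·Pm` with `R` the cell reference, `B` the
substrate (glass) reference, and `Pm` a Legendre basis on the axis rescaled
to [−1, 1] (an orthogonal basis keeps the design well conditioned; the
reported `cm` are in that basis). N = 5 by default: a high-order polynomial
does not overfit in EMSC because the reference carries the sharp structure.
The corrected spectrum is `X = (X0 − cb·B − Σ cm·Pm)/cr` — background
removed and intensity normalised to the reference scale; `cb ≡ 0` when no
substrate is supplied (flat-background CaF₂ case). Degenerate fits
(cr ≤ 1e−6) and ill-conditioned designs (condition number > 1e10, e.g. a
substrate collinear with the reference) raise typed errors naming the
offending component.

The cell reference is the unsmoothed mean of the 50 highest-quality spectra
of a clean reference dataset; quality is ranked by Pearson correlation
against the channel-wise median spectrum (robust to spikes; a
signal-to-noise ranking is available by option). The substrate reference
is the mean glass spectrum smoothed with Savitzky–Golay order 3, window 9.

### Denoising and quality culling

Denoising is Savitzky–Golay order 3, window 7; edges are handled by
fitting the polynomial on the truncated end window. Quality culling
removes spectra whose Pearson correlation with the (fingerprint-cropped)
cell reference is below 0.99, boundary retained; it runs after EMSC and
denoising on the fingerprint region, since corrected spectra approximate
the reference by construction and the correlation then measures residual
noise and model failure.

## Chemometrics

Eleven reducer/classifier configurations are evaluated:
PCA(3 components, mean-centred, unscaled) × {LDA, QDA, kNN};
MR(10 wavelengths) × {LDA, QDA, kNN, RF, SVM}; and RF, SVM, PLS on all
wavelengths. Hyperparameters are fixed, not tuned: kNN k = 5 (Euclidean on
the reduced features); random forest 500 trees with mtry = ⌊√p⌋; SVM with a
Gaussian kernel whose bandwidth is the 0.1/0.9-quantile midrange of
pairwise squared distances on a 100-point subsample (seeded); PLS with 15
latent variables, used as a classifier by regressing a ±1 class code and
thresholding at 0.

The marginal-relevance score of a wavelength is the ratio of between-class
to within-class sum of squares, each wavelength independent; neighbouring
wavelengths share scores, so selection takes the best-scoring channel from
each of 10 contiguous equal-width regions (one per region by default,
count configurable; ties to the lowest index).

Cross-validation is stratified 10-fold: within each class a seeded
permutation is dealt round-robin, so per-fold class counts differ by at
most one. Reducers are fitted on each training split only; the same folds
serve every configuration. Metrics (accuracy, sensitivity, specificity;
positive class = high grade by convention) are pooled over folds
(micro-average), with per-fold accuracies also reported for box plots. A
fold where QDA meets a degenerate covariance is recorded and excluded for
that configuration, never silently.

## Numerical and design choices

- All generators and the instrument are pure functions of parameters and a
  seed; a single master seed fans out to fixed per-module streams.
- CSV is the canonical spectra format (wide layout, `wavenumber_cm1`
  first column; long layout accepted), with labels/metadata in a JSON
  sidecar; floats are written with 17 significant digits and parsed
  round-trip, so write→read is exact.
- Axes are stored ascending regardless of source order; the fingerprint
  crop is defined by wavenumber bounds (closed interval), not sample
  counts, because a pixel→wavenumber map is instrument-specific.
- The acquisition loop aborts with the diagnostic contrast profile when
  autofocus fails; stage-limit violations skip the offending target and are
  logged; every spectrum in a run is traceable to a stage coordinate and
  target index through the manifest.
- Problem sizes used by the test suite and the acceptance script — 300
  spectra per class for the classification screen, 100 spectra for
  cosmic-ray oracles, 40-nucleus slides for targeting, 10 phantoms per
  preset for autofocus — are chosen so each property is measured with
  comfortable statistical margin on a single CPU.

## Known limitations

- Bright-spot rendering is phenomenological; conclusions about real
  optical contrast budgets cannot be drawn from it.
- The classifier layer currently handles two classes (the study design);
  MR and stratification already accept more.
- The quality-cull retention on synthetic data is near 1 at default noise,
  unlike the ~50% typical of real instruments — the generator omits the
  slow drifts and failed acquisitions that dominate real culling.
- Cosmic-ray detection assumes ≥ 2 spectra per cohort; a median-filter
  fallback for single spectra is exposed through configuration as an
  explicit error path, not a silent default.
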