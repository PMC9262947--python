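# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `minwaves`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Scope and data model

The package analyses three observables of a cell-free Min/FtsZ patterning
assay:

* calibrated fluorescence movies (`ImageStack`: T×H×W intensities, pixel
  size in µm, frame interval in s) of membrane surface waves;
* tidy expression-kinetics tables (protein, replicate, time in min,
  concentration in µM);
* light/heavy LC-MS peptide peak-area tables (protein, peptide, role,
  areas, biological/technical replicate).

Every physical quantity carries its unit in the field or column name
(`…_um`, `…_s`, `…_uM`, `…_um_per_s`); calibration is never silently
defaulted — reading a TIFF without a YAML sidecar or explicit overrides is
an error.

## Traveling-wave metrics (Sobel + Hough on kymographs)

A kymograph is built along a straight line (user-supplied direction, or the
orientation of the dominant non-DC peak of the time-averaged 2D power
spectrum), sampling at ~1 px steps with bilinear interpolation and averaging
over a 3-px band perpendicular to the line. Rows are space, columns are
time; a wave traveling along the line appears as parallel diagonal stripes.

Wavefront detection:

1. Gaussian pre-smoothing. The scale adapts to the data: one tenth of the
   dominant spatial period (from the kymograph's own 1D spectrum, clamped to
   [1, 8] px) and one tenth of the dominant temporal period (clamped to
   [1, 4] px). A fixed scale cannot serve both a 30-µm and a 113-µm wave at
   the same noise level: the spatial gradient amplitude of a sinusoid falls
   as 1/λ, so long waves need proportionally stronger noise suppression.
2. Sobel derivative **along the space axis** (signed, rising edges only).
   Using the gradient magnitude instead would mark both the rising and the
   falling edge of every period — two line families spaced λ/2 — and halve
   the measured wavelength for symmetric profiles.
3. Otsu binarization of the derivative, intersected with a non-maximum
   suppression along the space axis (only local maxima of the derivative
   survive, as in Canny's thinning). This localizes each wavefront to a
   1-px ridge; skeletonizing the thick Otsu band instead follows the band's
   medial axis, which is *not* parallel to the stripe near the image
   corners and biases the slope.
4. Linear Hough transform on the ridge map (1° angle and 1 px distance
   resolution), peaks above 0.3× the accumulator maximum with non-maximum
   suppression (≥5° in angle, ≥9 px in distance), then retention of the
   largest family of lines within ±5° of the modal angle.
5. Per-line refinement: total-least-squares refit on the ridge pixels
   within 2 px of each Hough line (excluding columns within two temporal
   smoothing lengths of the record boundary, where reflective smoothing
   bends edges). The 1° Hough quantization alone limits velocity to ~5–8%
   per degree at typical stripe slopes; refinement removes that floor.

Velocity is the median absolute stripe slope (rows/column) × dx/dt.
Wavelength is the median spacing of distance-consecutive lines measured
**along the space axis at fixed time** (the reading that yields a physical
wavelength independent of wave speed; perpendicular spacing is available via
`spacing_mode="perpendicular"`). Lines parallel to the space axis flag a
static pattern with undefined velocity. Medians are used throughout for
outlier robustness.

An independent brute-force estimator (`fft_wave_estimate`: Hann-windowed,
8× zero-padded 2D FFT, strongest peak at nonzero spatial frequency,
parabolic sub-bin interpolation) serves as a cross-check; on noiseless
fields the two routes agree within 5% (tested), and the Hough route recovers
ground truth with ≤5% error noiseless and ~0.1–0.2% median error over the
full test grid (λ ∈ {30, 76, 113} µm × v ∈ {0.25, 0.5, 0.71} µm/s × noise
∈ {0, 0.1, 0.3}·amplitude × 3 seeds).

Rim (perimeter) kymographs sample a droplet circle at equal ~1-px arc steps,
averaged radially over the rim width but inset ~1 px from the rim borders
(pixels straddling the annulus edge mix in background and imprint a
common-mode arc pattern on both channels). Their space axis is periodic;
smoothing, differentiation and ridge suppression then use circular boundary
handling.

## Standing-wave period (per-pixel autocorrelation)

Each pixel's time series is demeaned and its normalized autocorrelation
computed by FFT over lags 1..T/2 with the **unbiased** (per-overlap)
normalization — the biased estimator's linear taper tilts the peak toward
shorter lags and would shift even a pure cosine off its true period. The
pixel's period is the first local maximum after the first zero crossing
whose value exceeds max(0.2, 3/√T); the 3/√T significance guard is needed
because a white-noise autocorrelation estimate has standard deviation
~1/√T, and a fixed 0.2 threshold would qualify pure noise on short records.
Pixels additionally need temporal variance ≥ 10% of the stack's median
variance. The reported period is the median over qualifying pixels (integer
lags; no sub-lag interpolation, so a pure cosine with an on-grid period is
recovered exactly and off-grid periods are exact to one frame interval).
A field with no qualifying pixel raises "no oscillation detected".

## Antiphase metrics

Pearson r is computed over all paired kymograph entries. The phase shift is
the lag of the column-wise spatial cross-correlation (circular for periodic
rim kymographs; windowed to ±1 wavelength otherwise), expressed as a
fraction of the wavelength in [0, 1). Classification: antiphase if
r < −0.3 and the shift is within 0.15 of 0.5; in phase if r > 0.3 and the
circular shift distance from 0 is below 0.15; otherwise indeterminate. The
wavelength normalizer defaults to the FFT estimate of the first channel, so
the antiphase call does not depend on the Hough stage.

## Expression kinetics

The sigmoid y(t) = k' + k·tⁿ/(tⁿ + Kⁿ) is evaluated in the numerically
stable form k' + k/(1 + (K/t)ⁿ), which saturates cleanly for extreme n.
Derived quantities: expression lifespan T_plateau = 2K/n + K and apparent
translation rate v = k·n/(4K), which equals the analytic slope dy/dt at
t = K (identity-tested to 1e-6 on 1000 random parameter draws).

Fitting is per biological replicate: trust-region least squares with
initialization k' = min(y), k = max(y) − min(y), K = earliest time the curve
exceeds half-rise (midpoint fallback), n = 2; bounds k' ∈ [0, max y],
k ∈ (0, 2·max y], K ∈ (0, 2·max t], n ∈ (0.2, 12]; tolerance 1e-8, ≤500
evaluations. Constant or monotonically decreasing data are rejected as
outside the model domain; non-converged fits are flagged and excluded from
aggregation (mean ± sample SD across replicates). Noiseless curves are
recovered to better than 1e-4 relative. At 0.1 µM noise on 9 timepoints
over 360 min, the median error over 50 seeds is ~3–4% for the yield k and
~7–9% for K, but ~15–20% for the steepness exponent n (and hence for
v = kn/4K per single replicate): n is intrinsically weakly identified at
that signal-to-noise and sampling density. This is an information limit of
the design, not of the fitter — replicate aggregation at the default
13-timepoint sampling brings the aggregate rate and lifespan within the
replicate SD of truth (tested).

Welch's two-tailed unequal-variance t test (with Welch–Satterthwaite
degrees of freedom) supports condition comparisons at α = 0.05; it is
cross-checked against an independent reference implementation in the tests.

## QconCAT quantification

Light/heavy area ratios are computed per peptide and technical replicate.
The QconCAT concentration in each run is ribo_conc / mean(ratio of the two
ribosomal reference peptides); each target protein's concentration is the
ratio of its most C-terminal peptide × the run's QconCAT concentration.
Technical replicates are averaged within each biological replicate, then
reported as mean ± SD over biological replicates. The second peptide of
proteins that have one is reported as a QC column, never averaged in. The
ribosomal core-protein concentration is a required, system-specific input
with deliberately no default. Zero light areas quantify as 0 µM and are
flagged below-detection rather than dropped. The pipeline is exactly
scale-invariant in the peak areas and linear in the target signal (tested),
and inverts the synthetic generator exactly at zero noise.

## Synthetic generators (ground truth)

All generators are phenomenological phase models, not reaction–diffusion
simulations: wavelength, velocity, period and phase relations are inputs.

* Traveling waves: intensity = baseline + amplitude·profile(2π(s − vt)/λ)
  with s the coordinate along the propagation direction (planar) or an
  Archimedean spiral phase kr − ωt + azimuth (spiral). Profiles: sinusoid
  (default) or an asymmetric sawtooth with a sharp trailing edge emulating
  abrupt detachment. The optional second channel is π-shifted with its
  bright band broadened by a width factor ≥ 1 (raised-cosine power), and
  reduces exactly to an anticorrelated cosine at factor 1.
* Standing waves: baseline + amplitude·cos(2πs/λ)·cos(2πt/T).
* Droplet rims: intensity confined to a hard annulus, two raised-cosine⁴
  arc patches π apart rotating at angular speed v/r.
* Kinetics: sigmoid evaluation plus Gaussian noise truncated at zero. The
  default parameters are obtained by inverting three per-protein
  observables — 3-h concentration (1.5/4.2/3.2 µM), translation rate
  (0.018/0.043/0.027 µM/min) and lifespan (119/144/250 min) — through the
  derived-quantity formulas with y(180 min) matched by root-finding; the
  3-h value cannot be equated with the asymptotic yield k for a protein
  whose lifespan extends past 180 min.
* Peptide tables: light/heavy ratio = concentration/qconcat ×
  mean-one lognormal noise of chosen CV; the panel has two peptides each
  for FtsA and MinD, one for MinE, two ribosomal references. The ribosome
  reference concentration defaults to 1.0 µM *in the generator only*, as a
  synthetic-world convention.
* Noise: additive Gaussian truncated at zero (default) or Poisson; a
  camera model (photon transfer curve, read noise) is not attempted.

All randomness flows from a single integer seed per generator call;
identical seeds give bit-identical outputs (tested).

What the generators do **not** emulate: photobleaching, stage drift, the
optical PSF, spatially inhomogeneous illumination, wave defects and
dislocations, spiral-core meandering, chromatographic interference or
missing peptides. Passing the closed-loop tests therefore demonstrates the
correctness and calibration of the analysis chain, not its robustness to
every artifact of real microscopy or LC-MS data.

## Study-scale conditions used in tests and acceptance runs

Traveling-wave runs use 320×320 px fields at 1.0 µm/px, 60 frames at
2 s/frame — ≥2.8 wavelengths of a 113-µm wave in frame and ≥2 wavefront
lines in every grid condition. Standing-wave runs use 128 frames at
3 s/frame (≥3.6 periods of a 105-s oscillation). Droplet tests use a 10-µm
radius rim sampled over ≥3 patch revolutions. Kinetics uses 13 timepoints
over 360 min, 3 replicates, 0.1 µM noise; quantification 3×3 replicates at
5–10% CV. These sizes were chosen once as realistic desk-scale equivalents
of the assay and are not tuned per test.

## Known limitations

* Wavelengths approaching the field size leave ≤2–3 wavefront lines; under
  heavy noise (0.3×amplitude) the 113-µm condition occasionally loses a
  line and degrades, which the grid medians absorb but single fields would
  not.
* The wavefront detector assumes an essentially linear (constant-velocity)
  stripe pattern within the record; accelerating waves violate the Hough
  model.
* The direction estimator returns an orientation in [0°, 180°); propagation
  sign along that orientation is taken from the stripe slope, not the
  spectrum.
* Fitted steepness exponents n from single noisy replicates are broad (see
  above); downstream inference should use replicate aggregates.
* The antiphase phase-shift fraction needs a wavelength estimate; for
  patterns without a measurable wavelength it is undefined.
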