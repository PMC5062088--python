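# Methods

This note documents the models, conventions and numerical choices behind
`echoqdi`, and what its synthetic phantoms do and do not establish about
clinical data.

## Geometry and units

Axis 0 of every array is the scan line (lateral), axis 1 the axial sample.
Depth of sample *k* is `z = k·c/(2 fs)` (round-trip time of flight); with the
defaults (c = 1540 m/s, fs = 12 MHz) the axial pitch is 0.0642 mm. The
lateral pitch defaults to 0.47 mm per line — the transducer's line spacing
is not part of the acquisition metadata we model, so a 60 mm aperture over
128 lines is assumed; it is a plain config field and can be overridden.
Frequencies are MHz, depths cm, attenuation dB·cm⁻¹·MHz⁻¹ (1 Np = 8.686 dB).
Pixel ranges are half-open `[start, stop)`.

## Transmit pulse

The pulse is a Gaussian-modulated sinusoid at `f_o` = 3.5 MHz whose *power*
spectrum is Gaussian with variance σ² (MHz²). σ² is derived from the stated
1 mm pulse length: a spatial FWHM of 1 mm at c = 1540 m/s is 0.649 µs of
envelope FWHM, giving σ² = (√ln2 / (π·FWHM_t))² ≈ 0.167 MHz². The transducer
band (2–5 MHz at −6 dB) and the 1 mm pulse length are not mutually
consistent for a Gaussian pulse; the pulse length is taken as authoritative
because the attenuation math depends on σ², and the same σ² is used in both
the simulator and the slope-to-β conversion. Configurations whose
`f_o + 3σ` exceeds Nyquist are rejected.

## Phantom simulator

Each scan line is an independent 1-D Poisson process of point scatterers in
depth. The density is specified per resolution cell, whose axial extent is
taken as `pulse_length/2` — the standard pulse-echo axial resolution, and
consistent with the 0.6 mm axial resolution quoted for a 1 mm pulse — so a
density of ρ per cell is `2ρ/pulse_length` scatterers per mm of depth.
Reflectivities are Normal(μ, σ_a²); scatterers deposit at the nearest axial
sample and the train is convolved with the pulse. Attenuation is applied by
depth-segmented spectral filtering (64-sample Hann segments, 50% overlap-add,
zero-padded to 128 points), multiplying each segment spectrum by the
round-trip amplitude factor `exp(−β_np·f·2z)` at the segment's center depth.
This realizes the classical downshift `f_c(z) = f_o − 4σ²β_np z` without
per-scatterer FFTs. All randomness flows through one seeded generator per
frame.

Severity presets (density/cell, reflectivity mean, relative reflectivity
spread, β in dB·cm⁻¹·MHz⁻¹):

| class  | density | μ   | σ_a/μ | β    |
|--------|---------|-----|-------|------|
| normal | 12      | 1.0 | 0.8   | 0.55 |
| mild   | 16      | 1.5 | 0.5   | 0.80 |
| severe | 20      | 2.0 | 0.3   | 1.10 |

β values bracket the range reported for normal through severely fatty livers
in the clinical attenuation literature (≈0.5–1.2 dB/cm/MHz). Fatty
infiltration is modelled as denser *and more uniform* scattering — numerous
similar-sized lipid droplets — which is what drives the envelope SNR upward
with severity in this generator. The generator has no coherent or periodic
scatterer component, so it cannot produce strongly post-Rayleigh envelopes
(SNR well above 1.91); class SNR differences here come from speckle
development degree, not from the droplet clustering that likely operates in
vivo. The default (non-preset) phantom uses σ_a/μ = 0.2, a mild reflectivity
variability typical of homogeneous tissue mimics.

Lateral beam coupling is ignored (each line independent), as are elevational
effects, diffraction, and nonlinear propagation. Envelope statistics,
spectral estimates and attenuation slopes are therefore somewhat cleaner
than clinical data; passing tests demonstrate correctness of the estimators
under the stated physics, not robustness to beam or motion artifacts.

## B-mode

Envelope via the analytic signal per line; B-mode as
`gray = round(255·(dB+40)/40)` with `dB = 20log₁₀(R/max R)` clipped to
[−40, 0]. Rounding is half-up, which fixes gray-level parity for the GLCM
regression tests. Normalization is per-frame maximum (no gain compensation),
which makes B-mode invariant to global echogenicity scale; `log_compress`
accepts an explicit `reference` to emulate a fixed-gain system when absolute
brightness matters (used in tests that compare phantoms of different
echogenicity).

## Texture features

Full 256-level symmetric GLCMs at d = 1 and four directions; features use
the 1-based Haralick convention (gray g housed at index g+1), so SA of a
black image is 2, not 0. SV is centered on SA (variance of the i+j
distribution); this is the variance-of-sum variant of the two found in the
literature. Sliding-window maps (3 × 3 mm², step 1 px, window rounded to the
nearest odd pixel count per axis) are computed exactly via integral images:
AC, SA, SV are first and second moments of the pairwise products and sums,
so no per-window GLCM is needed. Feature values per pixel are the mean over
the four directional matrices.

The LDA-texture index is the projection onto the leading generalized
eigenvector of between- vs within-class scatter, unit-norm, oriented so
class-mean indices increase with severity, and offset so the pooled mean
index is zero. The absolute scale of the published index (≈2.7–3.0, with
tertile cutoffs 2.72/2.93) is set by the original fitted weights and is not
recoverable; only ordering and separation are meaningful here, which is all
the downstream tertile coding consumes. A ridge of 1e-6·trace is added when
the within-class scatter is singular.

## Envelope SNR

`SNR = mean/population-sd` of envelope samples; the population (not sample)
standard deviation is used so the sliding map matches the scalar estimator
bit-for-bit — at ≥100 samples per window the difference is <1%. Windows with
numerically zero variance are masked invalid. The Rayleigh boundary is
quoted as 1.91 (analytic value 1.9131); the colormap shades pre-Rayleigh
blue, a ±0.005 band white, post-Rayleigh red. Because window samples are
correlated over the pulse length, the windowed estimator carries a small
(+0.5% or so) upward bias relative to i.i.d. sampling; it is well inside the
tolerances used.

## Attenuation

Block power spectra average one Hann-windowed periodogram per scan line of
the block, zero-padded to 256 bins (a 3 mm window is 47 samples — too short
for 32-sample 50%-overlap Welch segmentation to add anything; `nperseg`
exposes axial sub-segmentation for longer blocks, and `nfft` grows
automatically if a segment exceeds it). The center frequency is the midpoint
of the two half-maximum crossings, linearly interpolated between bins; when
several disjoint above-half regions exist the peak's region is used and a
warning issued. CFDS is `f_o − f_c` in MHz (a normalized variant
`(f_o−f_c)/f_o` is available behind a flag).

The attenuation estimate regresses CFDS on depth (cm) by ordinary least
squares and converts `β_np = slope/(4σ²)`. Single-line FWHM-midpoint
estimates on speckle are noisy, so `cfds_slope` can average the CFDS profile
over ±`lateral_halfwidth` neighbor lines before fitting;
`estimate_attenuation` defaults to ±32 lines (a ≈3 cm homogeneous strip) and
a 2–7 cm depth range. With those defaults the class presets are recovered
essentially unbiased (within ~1% in the mean over 20 replicates, per-frame
SD ≈ 0.05–0.06 dB/cm/MHz) and the three severity presets order correctly in
every replicate observed. Diffraction correction is deliberately omitted, so
the slope is treated as constant over the fitted range.

## QDI scoring

Tertile cutoffs are the empirical 33.33rd/66.67th percentiles (linear
interpolation between order statistics), fitted on training records only;
cutoffs shift by O(1/n) across quantile definitions, hence the definition is
pinned. Boundary values belong to the lower tertile (`value ≤ t1 → 0`); a
`boundary="right"` flag switches to strict-left comparisons since tie
handling at cutoffs is a convention. Codes 0/1/2 per feature sum to the 0–6
QDI, which is monotone in every feature by construction.

## Cohort simulation and evaluation

Feature-level cohorts draw per-class trivariate normals with the published
marginal moments and an exchangeable inter-feature correlation ρ
(default 0.3; the source reports marginals only, so ρ is a free parameter —
the scoring-stage acceptance band is a property band, not a reproduction).
Default class sizes are the training split 126/100/88 (test 35/27/18). AUC
is Mann–Whitney with half-credit ties and a seeded percentile bootstrap CI
(2000 resamples) — chosen over DeLong for simplicity at these cohort sizes.
Odds ratios come from a Newton-fitted multinomial logit (tolerance 1e-8)
with mild disease as reference; complete separation is flagged and the
coefficient capped at ±15. The trend test is a linear regression of the
feature on class rank; group comparisons use pairwise Welch t-tests with
Bonferroni correction rather than Tukey–Kramer.

## Pipeline problem sizes

The end-to-end phantom pipeline defaults to 10 frames per class, 8 cm depth,
128 lines — enough for all three features to separate the presets with trend
p ≪ 0.05 while a full cohort runs in well under a minute per ten frames. The
per-frame SNR feature averages the whole valid SNR map within a 2–7 cm depth
band rather than the 1 × 1 cm ROI: the phantoms are laterally homogeneous,
so the ROI restriction (kept for texture, where it mirrors the clinical
protocol) would only add sampling noise. Top-level seeds expand into
per-frame seeds via a `SeedSequence`, making reports byte-identical across
runs with the same config.

## Known limitations

* The LDA-texture index scale (and therefore the published cutoff values) is
  not comparable to the original instrument's.
* Under per-frame max normalization, class separation of the texture
  features in phantoms is driven largely by attenuation-induced ROI
  brightness differences rather than by intrinsic texture — the discriminant
  orientation makes the index rise with severity either way, but raw
  AC/SA/SV directions need not match clinical behavior.
* Envelope SNR above the Rayleigh value is out of the simulator's reach (no
  coherent component); clinical severe NAFLD reportedly reaches ≈2.05.
* CFDS-slope units of the source distributions (0.87–1.00) do not match the
  MHz/cm slopes this pulse produces (~0.04–0.09); only proportionality to β
  is contractual, and the feature-level cohort simulator uses the published
  numbers directly.
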