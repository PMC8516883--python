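# Methods

This note documents the models, conventions and numerical choices behind
`roipower`, in the spirit of the model documentation that packages like
`mne` or `statsmodels` ship: what each stage computes, what the synthetic
cohorts emulate (and what they do not), and where the design was genuinely
open.

## Scientific setting

Resting-state EEG in dementia shows characteristic *spectral slowing*:
power shifts from fast (α, β, γ) toward slow (δ, θ) rhythms. Studies of
genotype effects on this phenomenon compare two groups of subjects —
carriers of risk vs protective variants — on two source-level statistics:

* **Relative power (RP)** per frequency band and cortical region of
  interest (ROI), and
* **Spatial entropy (SE)** of the distribution of RP values across ROIs,
  a scalar per band quantifying how heterogeneously band power is laid
  out over the cortex.

Group contrasts use nonparametric tests because RP and SE distributions
fail normality/homoscedasticity checks in practice. The package
reimplements this chain end to end and pairs it with a synthetic cohort
generator so that every stage can be validated against ground truth
without patient data.

## Preprocessing

The sensor-space chain, in fixed order: (i) per-channel mean removal,
(ii) 50 Hz notch, (iii) 1–70 Hz bandpass, (iv) an optional
artifact-removal hook, (v) segmentation into non-overlapping 5 s epochs,
(vi) deterministic artifact rejection. Common average re-referencing is
applied after the filters (clinical systems typically record
average-referenced; synthetic recordings are not, so the pipeline enforces
the reference itself — the inverse kernel additionally centers its input,
making the result insensitive to this choice).

* **Bandpass**: Hamming-window FIR, transition width ≈ 1 Hz (≈ 1651 taps
  at 500 Hz), applied forward-backward. Because the taps are symmetric,
  the two passes are implemented as a single FFT convolution with
  `taps ∗ taps`; edges are odd-reflection padded. All attenuation
  contracts (≥ 40 dB by 0.5·lo and 1.25·hi, ≤ 1 dB ripple in-band) refer
  to this net zero-phase response.
* **Notch**: second-order IIR (quality 30), forward-backward. The net
  response at 50 Hz is numerically −∞ dB; at ±5 Hz it is ≈ −0.25 dB.
  The filter family for the notch was an open choice; a narrow IIR was
  picked because an FIR of comparable selectivity would be impractically
  long, and the committed behaviour is the dB contract, not the topology.
* **Artifact hook**: manual ICA-component selection is rater-dependent and
  irreproducible, so step (iv) is a pluggable callable defaulting to the
  identity.
* **Epoch rejection** replaces visual rejection with two deterministic
  rules: any channel peak-to-peak above 150 µV, or any channel whose
  within-epoch SD exceeds the mean + 4 SD of that channel's across-epoch
  SD distribution. Both thresholds are configurable. If every epoch of a
  subject is rejected the stage warns and the pipeline excludes the
  subject with a logged message, never silently.

## Source localization

A standardized minimum-norm (sLORETA-style) inverse with identity noise
covariance. With lead field `K` and average-reference centering operator
`H = I − 11ᵀ/n`:

    W = (HK)ᵀ (H K Kᵀ H + αH)⁺ H,      ĵ = W d,
    power_i = ĵ_i² / (W K)_ii

The resolution-diagonal standardization gives **zero localization error**
for noiseless point sources: with `P = (HK)⁺(HK)` a symmetric projection,
Cauchy–Schwarz gives `P_ij² ≤ P_ii P_jj`, so the standardized power is
maximized exactly at the true source. This is tested exhaustively on toy
models. Numerical conventions: pseudoinverse cutoff 1e−10 of the largest
singular value (the centered Gram matrix is rank n−1 by construction);
default α = 1e−8 · trace(HKKᵀH)/n (near-noiseless; raise it for noisy
data); resolution diagonal floored at 1e−12 of its mean.

The toy forward model is a random gain matrix with unit-norm columns over
sources placed in a unit sphere, partitioned as evenly as possible over
the atlas (68 cortical parcel names of the standard gyrus-based atlas ship
as a text resource). It preserves the algebraic structure the inverse
needs and nothing anatomical.

**ROI aggregation.** Whether ROI time series are the mean of member-source
time series or of member-source power was an open choice; the default is
the arithmetic mean of time series (no sign flipping), with
`aggregate="power"` (mean standardized-power time series) available.
Note that in strongly underdetermined toy settings signed averaging can
cancel within an ROI; the power aggregate is the one that provably tracks
a single active source's ROI.

## Relative power

Welch PSD per epoch and ROI — 1 s Hamming segments, 50 % overlap — gives
1 Hz resolution, aligning bins with the integer band edges. The PSD is
restricted to 1–70 Hz and normalized to unit mass; band RP is the sum of
normalized PSD over bins with `lo ≤ f < hi` (γ closed at 70 Hz). The
half-open convention makes the five bands a partition, so ΣRP = 1 holds
identically; a 13 Hz tone counts as β, not α. Per-subject values are the
unweighted mean of per-epoch RP. A per-whole-signal periodogram is
available as a config option.

Two systematic effects of the 1 Hz binning are worth knowing: a flat
spectrum yields the *discrete* ratios (3, 4, 5, 17, 41)/70 rather than the
continuous bandwidth ratios (3, 4, 5, 17, 40)/69 (differences ≤ 0.006),
and a band-limited component loses ≈ 10 % of its mass to neighbouring
bins via the FIR transition band and window leakage. Tests and the
acceptance checks account for both at their stated tolerances.

## Spatial entropy

Per epoch and band, the 68 ROI RP values are histogrammed with
Freedman–Diaconis binning (`h = 2·IQR·n^(−1/3)`, IQR by linear
interpolation of order statistics, equal-width bins spanning [min, max],
last bin right-closed, degenerate inputs → one bin) and scored with
normalized Shannon entropy

    SE = −(1/log N) Σ p_n log p_n ∈ [0, 1],    0·log 0 := 0,

natural log (the ratio is base-invariant), SE := 0 when N = 1. The sign
convention is the standard Shannon one — the quantity is non-negative and
0 for a perfectly homogeneous (single-bin) spatial distribution. Subject
values are epoch averages.

**A caution on interpreting the dispersion knob.** Because FD binning is
affine-equivariant, SE measures the *shape* of the spatial distribution,
not its scale. With any amount of estimation noise the RP values across
ROIs form a near-Gaussian histogram whose normalized entropy is already
high (≈ 0.9); increasing the generator's log-normal ROI dispersion skews
that distribution and therefore *lowers* SE (e.g. γ-band seed-averaged SE
falls from ≈ 0.90 at zero heterogeneity to ≈ 0.5 at σ = 1.0). SE = 0 is
attained only at exact homogeneity. The property tests assert this actual
behaviour; any expectation that SE grows monotonically with a smooth
dispersion knob does not survive contact with the estimator.

## Group statistics

* **Mann–Whitney U**, two-sided, reporting U of the first-listed (risk)
  group; the exact null distribution is used when n1+n2 ≤ 20 and the
  pooled sample is tie-free, otherwise the normal approximation with tie
  and continuity corrections. The reporting convention is configurable
  (`statistic_of="min"`) since published U values rarely disambiguate it.
* **FDR**: Benjamini–Hochberg step-up, one family per band across the 68
  ROIs (the per-ROI analysis is corrected within each band; global
  per-band and SE tests are single tests and are not corrected).
* **Pearson χ²** without continuity correction for demographic matching
  tables.
* **Exploratory checks**: one-sample KS against the fitted normal and
  Levene across groups, advisory only — the pipeline always proceeds
  nonparametrically.
* The global per-band test operates on subject-level ROI-averaged RP
  (whether to pool ROI values instead was open; ROI means are the
  committed default).

## Synthetic cohorts

Per subject, each source's signal is Σ_b amp(b, ROI, subject) · x_b(t) +
noise_amplitude · p(t), where x_b is white Gaussian noise band-limited
with the same FIR designs the analysis chain uses (applied single-pass —
phase is irrelevant for stationary noise) and normalized to unit sample
RMS, and p(t) is 1/f-shaped ("pink") noise supported on 1–70 Hz,
synthesized spectrally. Amplitudes factor into four knobs:

    amp = base_b · effect_b(group) · LogNormal(σ_subject) · LogNormal(σ_ROI)

Sensor data are `lead_field @ sources`; a ROI-level bypass (member sources
summed per ROI) lets the spectral/entropy/statistics stages run against
ground truth without the inverse stage. Unit-RMS normalization makes the
band variance fractions exactly `amp²/Σamp²` in the noiseless case, and
the squared effect multiplier is exactly the group power ratio — the two
oracles the generator tests rest on.

Defaults define the study conditions: groups of 18 (risk) and 35
(protective) subjects, 300 s at 500 Hz, band RMS amplitudes
δ 2.0, θ 1.5, α 2.0, β 1.0, γ 0.8 µV, ROI heterogeneity σ = 0.3,
between-subject dispersion σ = 0.15, background RMS 1.0 µV. The
amplitudes give a resting-EEG-like profile (slow-band dominance, β ≈ 8 %
relative power); the between-subject dispersion term reflects the large
inter-individual band-power variability of real EEG and is what keeps the
analysis honest: RP sums to one, so a β-only group effect mechanically
shifts every other band's RP, and only genuine between-subject variance
keeps those coupled shifts statistically invisible, as they are in
practice. With these conditions a β amplitude factor of 0.8 (power
× 0.64) is detected by the global β test in well over 80 % of cohorts
while the other bands reject near the nominal 5 %.

What the generator does **not** emulate: volume conduction with realistic
geometry, 1/f slope variation, oscillatory peak shifts, non-stationarity,
eye-blink/muscle artifacts (only a crude additive Gaussian transient is
provided to exercise epoch rejection), and any real genotype biology.
Passing tests therefore validate the *pipeline machinery and its
statistical calibration*, not claims about real EEG.

Synthetic metadata (sex, severity stage, age, MMSE) is sampled to mirror
the demographic composition of the published cohort tables, so the
demographic χ² and severity-stratified summaries have realistic inputs.

## Calibration problem sizes

The type-I/power simulations (`roipower.calibration`) run scaled-down
cohorts chosen to keep a full calibration affordable on one CPU: ROI
bypass, one 5 s epoch per subject at 200 Hz, 16 ROIs for the 500-cohort
null run and 68 ROIs for the 50-cohort effect run. Between-subject
dispersion dominates the test's operating characteristics, so epoch count
and sampling rate reductions leave the rejection rates essentially
unchanged; the null rate is reported pooled over the five per-band tests
(2500 tests) for a tight estimate.

## Known limitations

* The ROI "mean of time series" default can cancel signal within an ROI
  under highly underdetermined toy models; use `aggregate="power"` when
  single-source localization within ROIs matters.
* EDF files are read (via mne) but cohorts are written as plain ASCII/CSV
  matrices only.
* The FD + Shannon SE estimator inherits histogram-estimator bias at
  n = 68; values are comparable across groups computed with the same
  pipeline, not absolute entropies.
* The exact U distribution is only used for n1+n2 ≤ 20 without ties;
  published studies at these sample sizes (53 subjects) always take the
  corrected normal approximation, as this package does.
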