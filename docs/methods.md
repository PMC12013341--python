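# Methods

This note documents the models, parameter choices and numerical decisions
behind musemind, and what the synthetic-data tests do and do not establish
about real recordings.

## HRV from 1 Hz heart-rate samples

The input is a wearable's app export: one heart-rate value (BPM) per
second, with occasional dropped samples. Each sample is converted to an RR
interval by RR = 60000/HR (ms) and treated as one tachogram point. This is
a deliberate simplification — the device averages beats within the second
rather than reporting individual beat times — and it is the procedure the
pipeline is specified to follow; metrics are therefore comparable across
windows and participants but are not beat-exact HRV.

*Gap handling.* Participants with ≥ 20% missing samples are excluded (the
rule is "less than 20% may be interpolated", so exactly 20% excludes).
Interior gaps are filled by linear interpolation between the nearest
present neighbours; leading/trailing gaps take the nearest present value.
Filled samples are flagged so downstream consumers can trace provenance.

*Time domain.* SDNN uses the sample standard deviation (N−1); RMSSD
averages the N−1 squared successive differences. Windows with fewer than
two intervals return NaN rather than raising.

*Frequency domain.* The cumulative-time axis is built from the intervals
themselves (t_k = Σ RR_i / 1000). The tachogram is resampled at 4 Hz by
cubic spline, mean-removed, and a Welch PSD is taken (Hann taper, segment
length min(window, 256 s), 50% overlap). Band powers are trapezoid
integrals over the standard bands: VLF 0.0033–0.04 Hz, LF 0.04–0.15 Hz,
HF 0.15–0.40 Hz; these edges follow the cardiology task-force convention
since the analysis this package mirrors prints none. LF/HF is the ratio
(NaN when HF is zero). On a pure sinusoidal tachogram the band integral
reproduces the closed form a²/2 within a few percent (the remainder is
spectral leakage and interpolation error); tests allow 10%.

*Windows.* Metrics are computed for the 4-min baseline, each 5-min
sub-window of each 15-min section, whole sections, and a 1-min series for
line plots. VLF on windows shorter than 5 min is computed but flagged
`vlf_reliable=False`: the band's longest period (303 s) exceeds the window,
so those values are descriptive only. One further documentation note: the
LF/HF ratio is sometimes expanded inconsistently in reports of this
analysis ("very low-frequency to very high-frequency"); this package
implements the standard definition, LF power over HF power.

## EEG chain

Designed for 5-channel (AF3, AF4, T7, T8, Pz), 128 Hz consumer headsets.
Stage order is fixed: screen → slew limit → IQM reference → band-pass →
ICA → PSD → band powers → normalization. Each stage is a pure function of
the recording; the pipeline echoes every parameter into the run manifest.

*Missing-data screen.* Recordings with ≥ 50% samples flagged missing are
excluded (inclusive at the boundary).

*Slew-rate limiting.* y[n] = y[n−1] + clip(x[n]−y[n−1], ±limit). The
acquisition convention states the limiter as a "30 Hz" threshold; a
frequency alone does not determine a per-sample step limit, so the limiter
is parameterized in μV/sample with a default calibrated so a full-band
30 Hz sinusoid at a 100 μV reference amplitude passes unmodified:
limit = 2·100·sin(π·30/fs) ≈ 134 μV at fs = 128. The parameter is
configurable; the mapping is documented rather than asserted as unique.
The recurrence is idempotent, which the tests exploit.

*Interquartile-mean reference.* Per sample, channels are sorted and the
mean of the values strictly inside the outer quartiles (middle 3 of 5) is
subtracted from every channel. This keeps a single wild channel from
dragging the reference, unlike a plain average reference, and is
idempotent. Requires ≥ 4 channels.

*Band-pass.* 0.5–45 Hz windowed-sinc FIR (Hamming, ~0.5 Hz transition,
845 taps at 128 Hz), applied by centred convolution with reflection
padding — symmetric FIR, so exactly zero phase in a single pass. DC is
nulled by construction; 50 Hz mains residue is > 50 dB down. For signals
shorter than the nominal filter the tap count shrinks (widening the
transition band); tests use ≥ 30 s signals.

*ICA ocular cleaning.* PCA retains components explaining 99% of variance
(minimum 2), FastICA unmixes them (deterministic seed, components
implicitly ordered by the PCA variance they span). No dedicated EOG
electrodes exist on these headsets, so AF3/AF4 serve as proxies: each
component is scored by its absolute Pearson correlation with each proxy
(max over proxies) and scores are z-scored across components — a 3.5
starting threshold is only meaningful on a z scale. The threshold steps
down by 0.1 from 3.5 until ≥ 2 components exceed it; if it would cross the
floor (1.0), the two highest raw scorers are flagged instead, since blinks
and lateral eye movements are both expected. Flagged components are zeroed
and the mixture re-synthesized. With only five channels the z-spread is
bounded (max ≈ (k−1)/√k), so the floor/fallback path is common; this is by
design — at least two components are always removed. ICA is fitted on the
whole recording, not per section, so the same unmixing applies to baseline
and conditions.

*Spectral estimation.* Welch PSD with a Hann taper, 512-sample (4 s)
window and 128-sample step (0.25 Hz resolution, μV²/Hz). Per band (delta
0.5–4, theta 4–8, alpha 8–12, beta 13–27, gamma 28–40 Hz) both the mean
in-band PSD and the trapezoid band integral are reported; normalization
uses the mean ("average PSD"). Spectrograms for visualization use a
1028-sample STFT with 128-sample overlap.

*Normalization.* ratio = mean condition PSD / mean baseline PSD, per
participant × channel × band. Zero or near-zero baselines yield NaN and
are excluded from group averages. Normalization is per-channel (group
figures are per-electrode); pooling channels first is possible by
averaging the band table before the ratio, but is not the default.

## Psychometrics

Shortened instruments: SUDS 5 items (1–7), PSS 5 items (0–4), SMS 6 items
(1–5), ASC 9 items (slider stored as 0–100, the visual-analog convention),
SCS 4 items (1–6). Totals are plain sums; change = post − pre. Which items
of the shortened forms were reverse-keyed is not documented, so the default
applies none — raw sums then mirror the reported directions of change. A
switch (`scale_definitions(reverse_coded=True)`) enables the standard
sets: PSS item 5 (the positively-worded "able to control irritations") and
all four SCS items (all negatively worded). Under the default, higher SCS
totals mean *more endorsement of disconnection items*; under the reverse
convention they mean more connectedness. Neither is asserted as the
original scoring; analyses should state which they used. Cronbach's alpha
is k/(k−1)·(1 − Σ item var / var of totals), undefined (NaN) for zero
total variance; missing or out-of-range items raise rather than impute.

## Statistics

*RM-ANOVA.* Classical univariate within-subject decomposition, one- and
two-way, one observation per cell. Greenhouse–Geisser epsilon is computed
per effect from orthonormal effect contrasts K applied to the
within-subject covariance Σ: ε = tr(M)²/(df·tr(M²)) with M = KΣKᵀ,
clipped to [1/df, 1] (equivalent to the double-centering formulation for
one-way designs). Corrected p-values use ε-scaled numerator and
denominator df. The implementation reproduces R `car::Anova` (type-3
within design) to ≥ 5 decimals on frozen test data; note that a popular
Python package disagrees on the two-way interaction epsilon and itself
warns about that case. A caveat worth knowing: ε-shrunk df raise the
p-value only when F is in the rejection regime (roughly F > 1); for tiny F
the "corrected" p can be marginally smaller. The correction is calibrated
for its purpose — controlling type-I error, confirmed at 0.05 ± 0.02 by
simulation — not for order-preservation everywhere.

*Design table.* The study layout mixes a once-measured 4-min baseline with
per-window section values; the design table repeats the baseline value
across time bins so it appears as one Session level per window, mirroring
the three-bars-per-window reporting convention. This is a reporting
convention, not a claim that the baseline was measured repeatedly.

*Tukey.* Studentized-range q per pair with MS_error and df from the
one-way RM decomposition; for two levels q = t√2 of the paired t.

*Friedman.* scipy's tie-corrected statistic over complete blocks; fully
tied data (no rank information) returns χ² = 0, p = 1 instead of dividing
by zero.

*Wilcoxon.* Reports the signed statistic W = Σ(positive ranks) −
Σ(negative ranks) — the sign convention of common graphing software —
with zero differences dropped; p-values are exact for n ≤ 25 without
ties, otherwise normal with continuity correction.

*Levene.* Brown–Forsythe variant (absolute deviations from group
medians), robust to non-normality.

*Power.* Two-sided one-sample/paired t: noncentrality d·√n, df = n−1,
power = P(|T′| > t_crit). At n = 22, α = 0.05, d = 0.8 this gives 0.9469.

No multiple-testing correction is applied across scales or metrics beyond
Tukey within an ANOVA family; consumers should correct externally if their
inference requires it.

## Synthetic cohort generator

The generator exists so every stage has a computable ground truth.

*Heart rate.* RR(t) = mean_rr + a_lf·sin(2πf_lf t) + a_hf·sin(2πf_hf t) +
σ·ε(t), sampled at 1 Hz and exported as HR = 60000/RR. Defaults (800 ms
mean, 25 ms at 0.1 Hz, 15 ms at 0.25 Hz, 5 ms noise, 5% missing) put the
oscillations at canonical LF and respiratory-HF frequencies with resting
adult magnitudes. Missing samples are an exact count at uniform positions,
encoded as explicit markers (blank cells in the export) so the 20% rule is
computable. A parameter-validity invariant keeps RR strictly positive.

*EEG.* Per channel, one sinusoid per band at the band centre (random
phase, configurable amplitude, true power a²/2), plus 1/f-shaped Gaussian
noise (spectral shaping of white noise, exponent 1, RMS-normalized), plus
— on the frontal channels — a Poisson train of raised-cosine blink
deflections (0.4 s support, 12/min, 80 μV by default) and optional
hard-saturated segments flagged missing. The blink kernel is band-limited
and sign-consistent, which is what the ICA stage needs; it is not a
morphologically faithful blink.

*Surveys.* Integer item responses drawn around a per-scale mean with a
configurable post-shift, clipped to the printed ranges.

*What passing tests show — and don't.* The generator produces stationary
sinusoids over stationary noise; real tachograms and EEG are nonstationary,
have correlated artifacts (motion, electrode pops), real blink morphology,
and no known ground truth. Tests on this cohort establish that the
implementation computes its definitions correctly and recovers planted
structure under realistic magnitudes — not that the pipeline's choices are
optimal for any particular headset. Sections in tests are often shortened
(1–2 min) to keep suites fast; the windowing logic is size-agnostic and
the acceptance checks that need full-length sessions (slope recovery) use
the standard 4-min/15-min layout.

## Degenerate inputs and numerical floors

Too-short metric windows return NaN markers; too-short PSD sections raise;
zero-variance inputs to alpha, regression, or Wilcoxon return undefined
markers rather than crashing; rank-deficient ICA input raises a
`DecompositionError` with the participant named. Baseline-normalization
denominators below 1e−12 μV²/Hz are treated as zero. All simulation
randomness flows from explicit integer seeds; reruns are byte-identical.

## Known limitations

- RR intervals derive from 1 Hz averaged heart rate, not beat detections;
  ectopic-beat handling and nonlinear indices (SD1/SD2, entropy) are out
  of scope.
- VLF on 1- and 5-min windows is below the band's resolvable period and is
  flagged accordingly.
- With five channels, ICA can remove at most a five-source mixture; the
  always-two-components rule can discard neural signal on blink-free data
  (bounded in tests: < 10% total variance on the constructed cohort).
- The baseline-repeated design table inflates the apparent number of
  baseline measurements; treat the Session × Time ANOVA as the reporting
  convention it mirrors.
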