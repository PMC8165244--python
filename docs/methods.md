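# Methods

## Overview

`facepulse` implements a non-contact autonomic nervous system (ANS) analysis
chain: per-frame ROI-mean RGB traces of facial skin are decomposed into
hemoglobin, melanin and shading components; the pulsatile hemoglobin series
yields beat-to-beat (RR) intervals; 20 heart-rate-variability (HRV) and
hemoglobin indices are computed per analyzed segment; change-from-baseline
features feed a PCA + gradient-boosting classifier under repeated
leave-one-out cross-validation, for both ASD-vs-TD group classification and
within-group four-emotion classification. Because no recordings ship with
the package, a synthetic cohort generator provides ground-truth inputs for
every stage.

## Forward model (synthetic cohort)

**Beat trains.** Beats follow an integral pulse frequency modulation (IPFM)
model: a beat fires each time `∫ m(t)/T0 dt` crosses an integer, with
`m(t) = 1 + A_LF sin(2π f_LF t + φ_LF) + A_HF sin(2π f_HF t + φ_HF)`.
This is the standard forward model when the analysis targets are spectral
band summaries of the RR tachogram: `A_LF`/`A_HF` directly control
low-frequency (0.04–0.15 Hz) and high-frequency (0.15–0.4 Hz) RR power,
i.e. the sympathovagal quantities the indices estimate. The admissibility
constraint `A_LF + A_HF < 1` keeps the instantaneous rate positive. The
integral is evaluated in closed form on a 5 ms grid and inverted by linear
interpolation; beat-time error is far below 0.1 ms. Long-run mean RR equals
`1000·T0` ms by construction (verified to 1% at 300 s).

**Skin color.** Log optical density per frame is
`BASE + shade(t)·(1,1,1)/√3 + hb(t)·u_hb + mel(t)·u_mel + ε`, and
RGB = `exp(−density)`. Each beat deposits a raised-cosine hemoglobin pulse
of width 0.35 s — matching the smooth pulsatile waveform the analysis must
invert; the exact shape is immaterial to peak timing. The hemoglobin
direction `u_hb ∝ (0.15, 0.75, 0.64)` reflects hemoglobin's strong green
and blue absorption and weak red absorption, which makes the pulsatile
density vector dominantly chromatic: only a small part of it is removed by
the shading projection. The default pulse amplitude (0.11 density units)
puts the chroma-plane pulse SD near 0.017, so at the default sensor noise
(0.003 per channel) hemoglobin recovery is noise-limited around |r| ≈ 0.98
and at 0.005 around 0.95. Shading is a slow sinusoid (0.05–0.15 Hz) on the
achromatic axis; melanin drifts at 0.01 Hz along a broadband direction.
These amplitudes are larger relative to real facial recordings (where
pulse modulations are a few tenths of a percent), which keeps validation
focused on the inversion chain rather than on extreme-SNR detection; the
generator therefore does not emulate motion artifacts, ROI tracking error,
or illumination steps, and passing tests say nothing about those failure
modes on real video.

**Cohorts.** 21 TD + 17 ASD participants by default. Baseline IPFM
parameters are drawn per participant (`T0 ~ N(0.85, 0.08)` s clipped to a
physiological range, `A_LF ~ N(0.08, 0.02)`, `A_HF ~ N(0.10, 0.03)`,
modulation frequencies uniform inside their bands). Each of six clips
(defaults: happy 270 s, fear 150 s, sad 240 s, neutral 120 s, line drawing
180 s, machine 120 s — all inside the 1.5–4.5 min stimulus range) is
preceded by a 30 s baseline; clip-segment parameters equal baseline
parameters plus a configurable per-group, per-clip additive shift on
`(T0, A_LF, A_HF)`. Only analyzed segments are materialized (no inter-trial
screens or rest blocks). Everything is reproducible from one master seed
(byte-identical CSV output).

## Chromophore separation

Densities are `−log(RGB)`. Shading is removed first by projecting each
frame onto the achromatic axis; the residual lives in a fixed orthonormal
basis of the plane orthogonal to `(1,1,1)`. This reduces a 3-source
problem to a well-posed 2-source one and makes the hemoglobin estimate
invariant to uniform illumination scaling (tested). The 2-D residual is
unmixed with deflation-mode FastICA (tolerance 1e-6, max 500 iterations,
fixed seed — the determinism contract). The hemoglobin component is the
one with the larger power fraction in the cardiac band 0.7–3.0 Hz; its
sign is set so pulsatile peaks are positive (skewness of the band-passed
series ≥ 0). If neither component reaches a 5% cardiac-band fraction the
result carries a low-quality flag.

## Pulse extraction

The hemoglobin series is band-passed 0.7–3.0 Hz (42–180 bpm; 4th-order
Butterworth applied forward-backward for zero phase). Peak detection uses
`find_peaks` with a refractory separation of `max(0.35 s, 0.6/f₀)`, where
`f₀` is the cardiac-band periodogram peak of the filtered series. The
adaptive term suppresses second-harmonic double detections at slow heart
rates (a raised-cosine train band-passed to 3 Hz retains its second
harmonic, which at 60 bpm otherwise produces mid-interval peaks that pass
a fixed 0.35 s refractory). Peaks must reach 25% of the median peak
prominence; retained peak times are refined by parabolic interpolation
over the three surrounding samples. At 30 fps the frame quantization is
33 ms, which would dominate RMSSD/pNN50/SD1 without sub-frame refinement;
with it, noiseless RR error is below 1 ms and ~4 ms at default noise.

RR intervals are screened twice: a physiological range rule (333–1500 ms)
and a local-median rule (reject intervals deviating more than 25% from the
median of up to 5 range-surviving neighbors per side). The 10-point window
matters: split-beat artifacts arrive in runs, and a narrower median is
itself corrupted by the run, cascading rejections onto genuine neighbors.
Segments keeping fewer than 10 intervals are flagged unusable and their
features masked (never silently zeroed).

## HRV indices

Twenty indices per segment, computed from kept intervals only:

- **Spectral (1–10).** The RR tachogram is cubic-spline interpolated at
  the kept end-beat times, resampled at 4 Hz and mean-detrended. The FFT
  spectrum is a Welch estimate (Hann window, `min(span, 64 s)` segments,
  50% overlap); the AR spectrum uses Burg coefficients of order 16 (the
  common default in HRV software). The Burg density is evaluated on a
  dense grid (16384-point rFFT grid): near-deterministic tachograms place
  AR poles close to the unit circle, and the resulting sub-mHz peaks are
  not integrable on a Welch-resolution grid. Band powers are trapezoidal
  integrals with interpolated band-edge points so VLF (0–0.04 Hz), LF
  (0.04–0.15 Hz) and HF (0.15–0.4 Hz) tile total power (capped at 0.4 Hz)
  exactly; consequently normalized LF and HF (denominator total − VLF)
  sum to one. Indices: LF/HF, normalized LF/HF, relative LF/HF — each per
  method.
- **Time domain (11–14).** Mean RR; mean HR as the mean of per-interval
  instantaneous rates (Kubios convention, not 60000/meanRR); RMSSD; pNN50
  as a fraction, with successive differences taken over adjacent kept
  pairs only.
- **Geometric (15–16).** Histogram with 1/128 s bins aligned to zero.
  Triangular index = total count / modal bin count (the canonical form;
  the "area/height" phrasing differs only by a bin-width factor). TINN is
  the base width `M − N` of the least-squares triangle with apex fixed at
  the modal bin, `N` and `M` searched on the bin grid; a single occupied
  bin degenerates to tri = 1, TINN = one bin width.
- **Poincaré (17–19).** Population-variance convention:
  `SD1² = var(ΔRR)/2`, `SD2² = 2·var(RR) − SD1²`, ratio SD1/SD2 (NaN
  with a flag for constant series). Under this convention
  `SD1 = RMSSD/√2` exactly when the differences sum to zero.
- **Hemoglobin (20).** Mean of the hemoglobin series over the segment.

Spectral estimation requires at least 20 s of tachogram span. A 30 s
baseline can only produce ~24–29 s of beat-to-beat span (less after edge
artifact losses), so a higher floor would reject the very baselines the
design prescribes; the floor exists only to refuse nonsensical spectra.
Any segment under 60 s of span carries a `short_segment` quality flag,
because the LF band is barely resolved there — baselines are analyzed
with the same machinery regardless, mirroring the study design, and this
is a known limitation of 30 s baselines rather than of the implementation.

## Features and classification

Features are `index(clip) − index(baseline)` per clip, 20 × 6 = 120 per
participant. Standardization (z-scores) and PCA are fitted inside each
training fold by default; held-out rows are transformed with training
statistics only, and masked features impute to the training mean (0 after
standardization). Fitting on all rows before cross-validation is available
behind a flag for comparison with the optimistic variant. PCA loadings are
sign-fixed (largest-magnitude element positive) for reproducibility.

The classifier is gradient boosting (100 trees, depth 3, learning rate
0.1, all features per split, row subsampling 0.9 so the repetition seed
matters; xgboost backend). Training folds receive balanced class weights:
leave-one-out tilts every training fold against the held-out class, and an
interpolating booster converts that tilt into a systematic below-chance
bias on uninformative features. Group classification is leave-one-
participant-out over 38 participants, repeated 20 times with consecutive
seeds; outputs are the per-participant ASD probability per repetition,
row-mean probabilities, thresholded counts (ties at 0.5 classify as ASD,
the positive class), accuracy/sensitivity/specificity/precision/F1 per
repetition with mean and SD, a PC-count sweep (1–10; ties broken toward
fewer PCs), and mean per-PC gain importance. Emotion classification is
leave-one-datum-out over the 4 × n per-clip delta vectors of one group
(happy, fear, neutral, sad), also repeated 20 times; confusion matrices
(rows true, columns predicted) are averaged entrywise, hit rates are
diagonal over row sum, and pairwise cosine similarity between the rows'
predicted-class distributions summarizes how distinguishable two induced
states are.

## Statistics

Pooled-variance (Student) two-sample t tests, from raw samples or summary
statistics (df = n1 + n2 − 2); Pearson chi-squared on 2×2 counts without
continuity correction (df = 1); Mann-Whitney U with midrank ties (exact
null when both n ≤ 8 and untied); Spearman rank correlations between mean
ASD probability and each of the seven questionnaire scales, Bonferroni
corrected within each cohort subset's family of seven; a two-tailed
one-sample t of repeated-LOOCV accuracies against chance (0.5) — a
zero-variance sample exactly at chance returns t = 0 rather than an error.

## Validation strategy and problem sizes

Unit oracles are hand-computed or brute-force values (RMSSD/pNN50/Poincaré
arithmetic, analytic band integrals, the Burg estimate against a known
AR(2) process, Mann-Whitney against the pairwise count). Pipeline-level
validation uses the generator's ground truth: noiseless end-to-end
hemoglobin recovery (|r| ≥ 0.95) and RR recovery (mean error ≤ 10 ms);
monotone recovery of a generated LF/HF grid {0.5, 1, 2, 4} on 5-minute
segments; null-cohort calibration (20 zero-effect cohorts of 38, each with
20-repetition LOOCV, accuracy within [0.35, 0.65] for ≥ 18 of 20 master
seeds); and planted-effect recovery (ΔA_LF = +0.15 on three clips,
accuracy ≥ 0.9) through the complete rendered pipeline at full study
scale. Cohort-level checks use ground-truth beat trains where rendering
adds only runtime, and the full rendered chain where the inversion is the
thing under test. The complete synthetic pipeline at study scale runs in
well under a minute per cohort on one CPU; the 20-cohort calibration loop
takes a few minutes.

## Known limitations

- LOOCV accuracy at n = 38 has cohort-level dispersion well beyond the
  binomial approximation (fold predictions are correlated); single-cohort
  accuracies should be read with ±0.1 uncertainty.
- The generator's noise model is white and per-channel; real recordings
  add motion, tracking and illumination artifacts that this package does
  not attempt to model or reject beyond the RR screening rules.
- 30 s baselines yield marginal LF resolution; the `short_segment` flag
  marks every affected index vector but does not alter the values.
- AR band powers of nearly noise-free tachograms depend on the evaluation
  grid; the dense-grid choice makes them stable but they remain less
  robust than the Welch estimates for tonal inputs.
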