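# Methods

## Scope and data model

`nirsretest` analyses test–retest continuous-wave fNIRS studies: raw
dual-wavelength intensities are preprocessed to oxy-/deoxy-hemoglobin
concentration changes, each channel of each session is classified as
activated or not by a short-channel-regressed, AR-prewhitened robust
GLM, and session-to-session reproducibility is quantified by the size
index R_q, the Dice-type overlap index R_o, channel activation
frequencies, and a regression of the variability complement
v_q = 1 − mean(R_q) on systemic-physiology covariates.

The probe model is a 2-D scalp-plane abstraction: 14 sources and 32
detectors forming 64 long channels at 3 cm and 4 short channels at
0.8 cm, split symmetrically over the hemispheres. Per hemisphere the
long-channel optodes sit on a triangular lattice of 3 cm pitch; the
source subset was chosen (by exhaustive search, then frozen) so that
exactly 32 source–detector pairs at 3 cm exist over 14 detectors. A
`compact` preset (24 long + 2 short channels) serves simulation studies
where runtime matters more than montage fidelity.

## Synthetic studies

The generator works at the hemoglobin level and maps to intensities
through the same decadic Beer–Lambert relation the analysis inverts
(shared extinction table, Gratzer/Kollias-compiled values at 760/850 nm;
DPF 6; I(t) = I0·10^(−ΔOD)). Components:

- **Evoked response** — a single-gamma HRF (unit peak at 6 s, nominal
  width 5.2 s) convolved with the stimulus boxcar; peak amplitudes
  +0.8 µM HbO / −0.3 µM HbR at the activation focus, attenuated by a
  Gaussian kernel (scale 1 cm) of the distance between the channel
  midpoint and the focus. The kernel is a one-parameter stand-in for a
  photon-transport sensitivity profile, which is out of scope. Long
  channels only. A lognormal session-level gain (sd 0.3 in the log)
  models day-to-day neurovascular variability.
- **Superficial physiology** — cardiac (at the session heart rate),
  respiration (0.25 Hz), Mayer waves (0.1 Hz) and slow drifts, shared
  by all channels including the shorts, with per-channel gain (sd 0.2)
  and phase jitter so short-channel regression is useful but not
  perfect — as in real data.
- **Cortical background hemodynamics** — per-channel AR(1) noise
  (0.3 µM HbO, correlation time 3 s, HbR coupled at −0.4 plus an
  independent 0.1 µM part). This is the component short channels cannot
  remove; it sets realistic detection power. Without it, synthetic
  activation is detected with t ≈ 25 everywhere and reproducibility
  saturates at 1.
- **Artifacts and noise** — motion spikes (Poisson 0.5/min, 10× OD sd,
  0.2–0.5 s) and persistent baseline shifts (probability 0.2/session),
  plus multiplicative white intensity noise (sd 0.005).
- **Placement error** — each session displaces the whole probe by an
  isotropic 2-D Gaussian vector: scale 0.3 cm for guided placement
  (consistent with 6 mm guidance spheres) and 1.5 cm for the standard
  tape-measure procedure. The standard scale is a modelling choice; no
  measured value exists for it. Displacement is the only difference
  between the two conditions.
- **Physiology readings** — heart rate and mean arterial pressure per
  session (mean of simulated pre/post readings), with time-of-day
  variation set to twice the day-to-day variation at a fixed time,
  mirroring the circadian structure of the emulated protocol.

The default design is 30 blocks of 2 s stimulation with rest uniform in
[10, 20] s at 8.9 Hz. What the generator does **not** emulate: real
optical coupling spectra, heterogeneous DPF, anatomical variability,
task-correlated systemic responses, or non-stationary artifact
statistics. Passing tests therefore demonstrate internal consistency
and statistical calibration of the pipeline, not performance on any
particular instrument's data.

## Preprocessing

Fixed stage order: SNR pruning → optical density → spline motion
correction → wavelet motion correction → Beer–Lambert inversion →
bandpass; every processed recording carries a log of stages and
parameters.

- **Pruning**: SNR = mean/SD (population SD) of raw intensity over the
  whole recording, per wavelength; a channel is removed iff SNR < 8 at
  either wavelength (strict inequality; exactly 8 is kept).
- **OD**: ΔOD = −log10(I/mean(I)). The mean-intensity reference means
  recovered concentrations are relative to their recording mean; all
  downstream statistics are invariant to that offset, and amplitude
  comparisons are made after baseline correction.
- **Spline correction** (MARA-style): motion samples are flagged when
  the 1 s windowed peak-to-peak exceeds 13.5× a robust point-noise
  scale (MAD of first differences / √2) or 0.2 OD; flagged segments are
  replaced by their residual around a smoothing spline (GCV-selected
  penalty), and every following segment is re-levelled by a constant to
  restore continuity — this is what removes persistent baseline shifts,
  and it only translates clean segments, never reshapes them.
- **Wavelet correction**: db2 DWT; per detail level, coefficients
  outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] are zeroed. The decomposition
  depth is capped so the approximation band below ~0.03 Hz is never
  thresholded, protecting slow hemodynamics.
- **MBLL**: per-sample 2×2 solve with d the geometric separation (cm)
  and DPF 6 at both wavelengths; concentrations in µM.
- **Bandpass**: 3rd-order Butterworth, 0.005–0.5 Hz, applied
  forward-backward (zero phase). Attenuation at the cardiac 1.1 Hz and
  at DC exceeds 20 dB; mid-band gain is within 1 dB of unity.

## GLM and activation

Design matrix: task regressor (boxcar ∗ unit-peak gamma HRF), the
nearest short channel's same-chromophore series (mean-centred,
unit-SD), and Legendre drift terms of order 0–3. Nearest = Euclidean
distance between channel midpoints, ties to the lowest index.

The solver iterates: AR(p) estimation on current residuals
(Levinson–Durbin, AIC order selection up to 4 s of lags) → whitening of
y and X by the AR polynomial → bisquare IRLS (tuning 4.685, MAD scale,
Huber "H1" sandwich covariance) → repeat until the coefficient vector
changes by < 1e−2 relative (max 10 outer iterations). p-values are
two-sided t with dof = n − columns. A channel is **activated** iff
p_HbO < 0.05, p_HbR < 0.05, β_HbO > 0 and β_HbR < 0; the two-sided
p-values plus sign constraints implement the one-sided scientific
hypothesis. Pruned channels score 0.

**Decimation before fitting.** Band-limited series are decimated so the
new Nyquist sits at ~1.5× the upper band edge (8.9 Hz → ~1.48 Hz after
the 0.005–0.5 Hz bandpass; the lowpass leg doubles as the anti-alias
filter). An AR model cannot whiten a process whose spectrum is empty
over half the band: fitting at the raw rate inflated null t-statistics
by a factor ~2.3 even for bandpassed white noise, while after
decimation the empirical null rejection rate matches α. This is a
calibration requirement of prewhitened inference, not a tuning knob.

Group-level coefficients are inverse-variance weighted means per
channel and chromophore, β_g = Σ(β_i/SE_i²)/Σ(1/SE_i²) with
SE_g = (Σ1/SE_i²)^(−1/2), and group activation uses the same
dual-chromophore rule.

## Reproducibility statistics

For sessions i, j with activated-channel counts A_i, A_j and common
count A_overlap (restricted to an ROI: whole probe, hemisphere, or the
navigated channel list):

    R_q = 1 − |A_i − A_j| / (A_i + A_j)
    R_o = 2·A_overlap / (A_i + A_j)

with R_q = R_o = 0 when A_i + A_j = 0 (consistent with reporting 0.00
for subjects without any activation). Subject-level values are means
(and SEs) over all C(n,2) session pairs; medians across subjects
summarize a condition, with the even-n median defined as the midpoint
of the two central order statistics. ΔHR and ΔMAP per condition are
100·(max − min)/mean over the session values (session value = mean of
pre/post readings).

The variability regression fits v_q = α + βΔHR + γΔMAP by OLS with the
covariates as fractions (percent/100). On the bundled reference table
(10 whole-probe subject×condition rows) this convention reproduces the
published coefficients and their standard errors to rounding precision,
which resolves the scale ambiguity in the source report; the percent
convention is also available and differs only by 100× on the slopes.

## Registration

Rigid (rotation + translation, no scale) landmark alignment by the SVD
(Kabsch) solution with determinant correction to exclude reflections;
requires ≥ 3 non-collinear named pairs, reports the fiducial
registration error (RMS residual). A 6 mm guidance-sphere check flags
whether an optode was repositioned onto its saved location.

## Problem sizes of the shipped experiments

The validation runners default to sizes that complete in a few minutes
on one core, and all sizes are arguments:

- null calibration: ≥ 500 channel-sessions from 10-block sessions on
  the compact probe;
- AR-IRLS recovery: 200 replicates of n = 2000, AR(1) φ = 0.8;
- placement contrast: 10 seed sets × (guided + standard) studies of
  5 subjects × 3 sessions, compact probe, 30-block sessions — the
  emulated study's block count, at which per-channel detection power is
  realistic.

## Known limitations

- The scalp plane is flat; no curvature or 3-D optode geometry in the
  simulator (the registration module is 3-D but independent).
- DPF is a single constant; partial-pathlength effects are not modelled,
  so absolute µM amplitudes are nominal.
- The GLM fits HbO and HbR separately (whether the emulated analysis
  fitted them jointly is not stated in its report).
- Wavelet thresholding assumes artifacts are sparse in the detail
  coefficients; dense continuous motion would require different tools.
- The AR model is estimated per channel per iteration; no spatial
  pooling of noise structure.
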