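# Methods

## Problem and model

Electrooculography (EOG) measures the standing corneo-retinal potential
through skin electrodes; within roughly ±35° of horizontal gaze the induced
voltage is linear in eye rotation,

    E(t) = Ee(t) + φ + Ω,        Ee(t) = K · θ(t),

where `Ee` is the corneo-retinal potential, `K` the per-participant
calibration factor (µV per degree of visual angle, textbook value ≈ 16),
`φ` collects artifacts (blinks, facial EMG) and `Ω` additive noise. The
package denoises `E` with Kalman filters whose prediction step comes from a
discrete state-space model of `Ee`:

    x_k = A x_{k−1} + w_k,  w ~ N(0, Q);     z_k = H x_k + v_k,  v ~ N(0, R)

Four estimators are provided. **BM** (Brownian motion) models the potential
as a random walk (n = 1, A = [1]). **CVM** (constant velocity) carries the
potential and its rate (A = [[1, dt], [0, 1]]); it is motivated by the
saccadic main sequence: peak velocity saturates with amplitude,
V_p = a1·(1 − e^(−θ/a2)), and V_p·D = θ, so large saccades look like
constant-rate segments to the filter. **CAM** (constant acceleration) adds
the second rate (n = 3). **LR** (linear reciprocal) is a 4th-order
companion-form model of the agonist–antagonist extraocular-muscle pair; its
constants C0..C3 derive from muscle physiology and must be supplied by the
caller — the continuous companion matrix is discretized by zero-order hold
(matrix exponential). All filters run "free" (no input term): saccades are
triggered by cues the electrode does not observe.

The filter is the classic predict/correct recursion; the covariance update
uses the (I − KH)P form by default with a Joseph-form option. The start is
diffuse: x̂₀ = [first sample, 0, …], P₀ = 10³·R·I, so the first correction
locks onto the data. NaN samples are rejected, not imputed.

## Choosing Q and R

R is the measurement-noise variance. The pipeline estimates it from the
calibration block with a robust high-frequency statistic: the
median-absolute first difference of each detrended calibration trace gives
σ (differences are dominated by sensor noise because saccadic transitions
are sparse), and R is the squared mean σ across trials.

Q trades responsiveness against smoothing and must be selected per signal
scale — a single dimensionless constant cannot serve both a µV-scale and a
mV-scale recording. With the default `white_noise` structure
(Q = q·G·Gᵀ, G the discrete integrator column), q is the variance of the
white acceleration (CVM, (µV/s²)²) or jerk (CAM/LR, (µV/s³)²) driving the
chain. Defaults were fixed once at the knee of that trade-off for
microvolt-scale EOG at 250 Hz: q = 3·10⁸ (CVM), 3·10¹⁰ (CAM/LR), and 50
µV²/step for BM. Below the knee the filter lags the ~50–100 ms saccadic
transition and peak velocity collapses; above it measurement noise passes
through. For reference, saccadic peak accelerations at 16 µV/deg reach
~3·10⁵ µV/s², so the CVM default corresponds to a 1-σ process acceleration
of ~6% of that peak. A `diagonal` structure (Q = q·I) is available for
running literal scalar-Q configurations. Note that with `diagonal` Q at
250 Hz all kinematic models nearly collapse onto BM behavior (A is close to
identity, so the potential channel dominates); the structured form is what
differentiates the estimators.

## Baseline bandpass chain

The comparison baseline is the conventional EOG pipeline: 251-tap
windowed-sinc (Hamming) FIR bandpass 0.5–35 Hz, linear drift removal, a
second-order IIR 60 Hz notch (quality factor 30), and Savitzky–Golay
smoothing with polynomial order 5 and frame length 111. FIR and notch are
applied forward–backward by default so that no group delay corrupts the
latency estimates (a single-pass mode exists behind `zero_phase=False`).
Note the Savitzky–Golay frame of 111 samples at 250 Hz implies a ≈4 Hz
effective cutoff: the chain is intentionally aggressive and visibly
flattens saccadic slopes — that distortion is precisely what the
model-based filters are compared against.

## Preprocessing and calibration

Drift removal is anchored on home-fixation evidence: the polynomial (order
1 by default) is fitted only on the start→cue window and the trailing
200 ms of the trial — samples where the eye is known to fixate the home
position — and subtracted across the whole trial. Fitting across the
saccade itself would absorb part of the step into the trend; the anchored
fit rectifies drift without touching the excursion and simultaneously
normalizes the baseline to zero. Trials without a cue marker fall back to a
plain per-segment polynomial fit between markers.

Calibration offers two routes. `fit_calibration` implements the peak-average
scheme: per target, all local maxima above min + 0.8·(max − min) of the
(orientation-corrected) trace are pooled across that target's trials and
averaged; ordinary least squares of peak average versus target angle gives
K and an intercept. The full pipeline instead calibrates through
`fit_calibration_from_features`, which measures each calibration trial with
the *same* baseline-referenced changepoint-peak statistic used later for
feature extraction; any bias common to both (residual drift, filter
overshoot, noise-peak elevation) then cancels in the µV→degree ratio.
Quartiles for the 1.5·IQR outlier fences use linear interpolation between
order statistics (the "type 7" convention).

## Feature extraction

The cue→end window of each calibrated trial is segmented by exactly two
mean-shift change points, found by exact minimization of the within-segment
sum of squared deviations over all break pairs (prefix sums, O(n²) pairs;
ties broken toward the largest offset then the largest onset). On a
step–hold–return trial the two breaks bracket the excursion: outbound
saccade plus fixation plateau. Amplitude is the average of local maxima in
that segment (magnitude trace, sign restored; every local maximum counts by
default, mirroring the calibration statistic), referenced to the median of
the 50 ms before the transition start. Peak velocity is the maximum
absolute central-difference derivative inside the segment. Because the
mean-shift break lands near the middle of the transition, the onset used
for latency is refined by walking backward until the absolute velocity
drops below max(2% of the window's peak velocity, 5 °/s); latency is that
refined onset time minus the cue time.

## Synthetic trials

Each generated trial plays out one cue-directed saccade: 1 s pre-cue
fixation, a latency drawn from N(180 ms, 30 ms), the outbound saccade, a
fixation of 1 ± 0.2 s (uniform jitter), a "ping" cue, a return saccade, and
0.5 s of trailing fixation, at 250 Hz. Saccade kinematics follow the main
sequence with a1 = 500 °/s and a2 = 15° (literature-typical constants); the
velocity profile is a raised-cosine pulse. A raised cosine of peak V_p and
length T displaces V_p·T/2, so the pulse length is set to 2D with
D = θ/V_p: the peak velocity is exactly V_p, the displacement exactly θ,
and D is the constant-velocity-equivalent duration. The eye lands at
gain·θ_target with gain ~ N(1, 0.1) (saccadic endpoint variability), which
gives the reference channel itself a realistic error floor against the
physical target.

The measured EOG is K_true·angle (K_true = 16 µV/deg) plus: Gaussian sensor
noise planted by default at a 6 dB clean-power/noise-power ratio per trial;
baseline drift (white noise through a single-pole 0.1 Hz low-pass, 50 µV
RMS); 5 µV of 60 Hz line interference; and raised-cosine blink bumps
(rate 0.1/trial, 400 µV, 200 ms) annotated with their intervals. A
low-noise (0.05° RMS) copy of the angle serves as the video-tracker
reference. All randomness flows from one seed.

What the generator does *not* emulate: EMG/EEG-like colored noise bursts,
electrode impedance drift across a session, illumination-dependent changes
of the corneo-retinal potential, overshoot/glissades in the saccade
trajectory, and vertical-channel crosstalk. Passing tests therefore show
that the pipeline recovers parameters under stationary additive
interference with main-sequence kinematics, not that it handles every
failure mode of real recordings.

## Study sizes and numerical choices

The comparison studies use 50 seeds × 12 experimental trials (plus a 20-trial
calibration block) per method — enough that the between-method differences
in mean absolute amplitude error exceed their standard errors. Monte-Carlo
recovery checks (calibration at 2% noise, main sequence at σ = 20 °/s with
100 saccades) also use 50 seeds. Covariances are re-symmetrized after every
update; the changepoint tie tolerance is 1e-9 relative; the main-sequence
fit starts from a1 = max(V_p), a2 = median(|θ|) with positive bounds. The
kernel density of normalized errors uses Silverman's bandwidth on a grid
spanning the data ± 3 bandwidths; both fractional and percent scalings are
available. The SNR follows the power-ratio form
10·log₁₀(Σf²/Σ(raw−f)²); a literal unsquared variant exists behind a flag.

## Known limitations

The LR model ships without default physiological constants — users must
supply C0..C3. The two-change-point segmentation assumes one excursion per
trial window; double saccades or mid-trial blinks can displace the breaks
(blink-corrupted trials are expected to be caught by the IQR outlier fence
on the error distributions). Q defaults are tuned for microvolt-scale
recordings at 250 Hz and should be re-selected (same knee procedure) for
other hardware scales. Smoothing (RTS) and adaptive Q/R estimation are out
of scope.
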