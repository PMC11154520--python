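# saccadekf

Model-based Kalman denoising of electrooculography (EOG) saccade signals,
with saccade parameter extraction and a ground-truthed synthetic trial
generator.

EOG tracks eye rotation through the standing corneo-retinal potential:
within ±35° of horizontal gaze the electrode voltage is linear in angle,
`Ee(t) = K·θ(t)` with `K` ≈ 16 µV per degree. Raw recordings are corrupted
by sensor noise, baseline drift, mains interference and blink artifacts, and
conventional bandpass filtering distorts exactly the quantities saccade
research cares about — amplitude, peak velocity, latency. This package
implements the alternative: fuse the raw signal with a kinematic model of
the potential through a Kalman filter,

    x_k = A x_{k−1} + w_k,  w ~ N(0, Q)
    z_k = H x_k + v_k,      v ~ N(0, R)

where the central estimator is the **constant-velocity model** (CVM,
`A = [[1, dt], [0, 1]]`), motivated by the saccadic main sequence
`V_p = a1·(1 − e^(−θ/a2))`, `V_p · D = θ`: for larger saccades the
potential changes at a nearly constant rate. Brownian-motion (BM),
constant-acceleration (CAM) and 4th-order agonist–antagonist muscle-model
(LR) estimators plus the conventional bandpass/notch/Savitzky–Golay chain
(BP) are provided for comparison. Downstream the package segments trials by
exact two-change-point detection, calibrates microvolts to degrees from
target-directed calibration blocks, extracts amplitude/peak-velocity/
latency, and evaluates everything against ground truth (errors, SNR,
normalized-error distributions, Pearson correlations, main-sequence fits).

It is written for oculomotor and biosignal researchers who want a tested,
scriptable EOG denoising pipeline — and for anyone who needs a saccade-aware
Kalman filter with an honest evaluation harness.

## Worked example

Simulate a session (3 calibration trials per target at −22°, −11°, +11°,
+22°, then 8 cued experimental trials, all at a planted 6 dB input SNR with
drift, 60 Hz interference and occasional blinks), then run the full CVM
pipeline:

```bash
saccadekf simulate --n 8 --n-cal 3 --seed 7 -o demo_session/
saccadekf run --model cvm --session demo_session/ -o demo_out/
```

which prints (abridged):

```
INFO saccadekf.pipeline stage=filter model=cvm q=3e+08 r=6558.7 fs=250
INFO saccadekf.pipeline stage=calibrate K=16.7175 intercept=1.50125 r2=0.9868
model: cvm
calibration K (uV/deg): 16.7175
trials: 8
mean |theta - theta_true| (deg): 2.9285
normalized error mean: 0.0799
normalized error variance: 0.0357
```

The session was generated with a true sensitivity of 16 µV/deg; the
pipeline recovers `K = 16.72` from the noisy calibration block, and the
mean absolute amplitude error of 2.93° against the physical target angles
includes the simulated eye's own endpoint scatter (the saccades land at
gain·target with gain SD 0.1, so even a perfect sensor would not score 0).
`demo_out/` also contains `features.csv` (per-trial `theta_deg`,
`vpeak_dps`, `latency_s`), `errors.csv` and `calibration.json`.

The same comparison from Python:

```python
from saccadekf.study import compare_filters
df = compare_filters(models=("cvm", "bp"), n_seeds=3, n_exp_trials=8, base_seed=7)
print(df.groupby("model")[["mean_abs_error_deg", "vp_rel_error"]].mean().round(3))
#        mean_abs_error_deg  vp_rel_error
# model
# bp                  4.082         0.261
# cvm                 3.543         0.196
```

The constant-velocity filter both recovers amplitudes better and preserves
peak velocity better than the bandpass chain, whose 0.5–35 Hz FIR plus
frame-111 Savitzky–Golay smoothing flattens the saccadic slope.

Other subcommands: `saccadekf filter` (denoise a single `time,value` CSV
with any of bp/bm/cvm/cam/lr), `saccadekf features` (extract parameters
from one trial), `saccadekf evaluate` (feature correlations against a
reference tracker). All accept `--config file.yaml`; see
`saccadekf.config.RunConfig` for the schema. `docs/methods.md` documents the
models, the Q/R selection rule, the synthetic study conditions and known
limitations.

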