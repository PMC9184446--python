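# emdtcn

Respiratory-motion forecasting for latency compensation in tumor-tracking
radiotherapy.

A treatment machine that chases a moving thoracic or abdominal tumor lags
the measured marker position by its mechanical and computational delay —
roughly 100-500 ms depending on the system.  Over half a second a breathing
chest marker moves several millimetres, so the beam must be aimed at where
the target *will be*, not where it was observed.  `emdtcn` implements a
forecasting pipeline for a 1-D marker-position trace sampled at 26 Hz:

1. **Artifact correction** — a bagging ensemble of regression trees flags
   dense disturbance segments (coughs, speech) and replaces them by cubic
   interpolation, leaving everything else bit-identical;
2. **Empirical mode decomposition (EMD)** — the nonstationary trace is
   adaptively split into intrinsic mode functions (IMFs) ordered from high
   to low frequency plus a trend residual; the two noise-dominated
   high-frequency IMFs are dropped and the rest (plus the residual,
   zero-padded to a uniform width) become the network's feature channels;
3. **Forecasting network** — three parallel convolution channels with
   kernels 3×1, 5×3, 7×5 (16 filters each) and squeeze-and-excitation
   channel attention feed a dilated causal temporal convolutional network
   (TCN: 32 filters, kernel 3, dilations 1…32, one residual-block stack),
   then a dense head predicts the position `t_i` samples ahead
   (`latency = 1000·t_i/fs` ms; at 26 Hz, t_i = 3, 5, 10, 13 ≈ 115, 192,
   385, 500 ms).

The causal convolution is `(F_d * X)(x_t) = Σ_k f_k · x_{t−(K−k)d}`: the
output at time *t* never depends on samples after *t* (checked bit-exactly
in the tests).  Training minimizes MSE (Adam, lr 0.001, batch 128) and
restores the epoch with the best validation MAE; evaluation reports MAE,
RMSE and R² against a chronological 6:2:2 train/validation/test split.
Data windows are built so that every feature index strictly precedes its
target index, and targets always come from the raw corrected series, never
from IMFs.

The network runs on a small reverse-mode autodiff engine written on numpy
(`emdtcn.autodiff`), so the package has no deep-learning-framework
dependency.  A synthetic generator (`emdtcn.synth`) produces quasi-periodic
breathing records — jittered 4-s cycles, amplitude and baseline drift,
observation noise, optional cough-like bursts with ground-truth intervals —
so the entire pipeline is testable without any external data.

## Worked example

```python
from emdtcn import SyntheticConfig, generate_trajectory, TrainConfig, run_pipeline
from emdtcn.pipeline import PreprocessConfig

traj = generate_trajectory(SyntheticConfig(duration_samples=4000, seed=1))
out = run_pipeline(
    traj, input_len=100, lead=10,             # forecast 385 ms ahead
    pre_cfg=PreprocessConfig(detect=False),   # record is artifact-free
    train_cfg=TrainConfig(epochs=20, seed=1),
)
m, b = out.metrics["test"], out.baseline["test"]
print(f"test MAE  {m.mae:.3f} mm  RMSE {m.rmse:.3f} mm  R2 {m.r2:.3f}")
print(f"persistence baseline MAE {b.mae:.3f} mm")
```

```
test MAE  1.379 mm  RMSE 1.780 mm  R2 0.908
persistence baseline MAE 3.444 mm
```

The forecaster reduces the 385-ms-ahead error more than twofold relative to
simply holding the last observed position; R² ≈ 0.91 means the prediction
tracks most of the breathing excursion on held-out data.  (A 20-epoch run
on a 2.6-minute record; longer records and training tighten these numbers.)

The same pipeline is scriptable from the shell:

```bash
emdtcn --seed 1 simulate signal.csv          # synthetic record + sidecar
emdtcn decompose signal.csv imfs.csv         # EMD to CSV, logs recon error
emdtcn --seed 1 train --out-dir run          # end-to-end fit, JSON results
emdtcn --seed 1 grid --leads 3,5,10,13       # resumable experiment grid
```

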