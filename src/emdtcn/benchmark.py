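"""The package's reference benchmark: scaled study conditions that exercise
the full pipeline on one synthetic breathing record.

Problem sizes (10,000-sample trajectory, stride-2 windows, 12 training
epochs with best-validation restore, X_i = 100) are chosen so the complete
benchmark — three forecaster trainings at leads {3, 10, 13} plus a
deliberately mis-configured high-learning-rate run — finishes in minutes on
a single CPU while preserving the qualitative outcomes of the full
protocol: the trained forecaster beats the persistence baseline, forecast
error grows with the lead, and Adam at lr = 0.1 fails to converge.
docs/methods.md discusses the scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emd import emd_decompose, reconstruct
from .errors import DivergenceError
from .model import causal_conv
from .pipeline import PreprocessConfig, run_pipeline
from .preprocess import correct_outliers, detect_outliers, latency_ms
from .synth import ArtifactSpec, SyntheticConfig, generate_trajectory, inject_artifacts
from .traineval import TrainConfig

__all__ = [
    "BENCH_DURATION",
    "BENCH_EPOCHS",
    "BENCH_INPUT_LEN",
    "BENCH_STRIDE",
    "emd_reconstruction_error",
    "conv_oracle_error",
    "outlier_recovery",
    "end_to_end",
    "lr_sanity",
]

BENCH_DURATION = 10_000   # samples (~6.4 min of breathing at 26 Hz)
BENCH_EPOCHS = 12
BENCH_INPUT_LEN = 100
BENCH_STRIDE = 2          # halves the step count per epoch; windows still
                          # overlap heavily, so little information is lost


def emd_reconstruction_error(n_trajectories: int = 100, length: int = 600,
                             seed: int = 0) -> float:
    """Worst relative L-inf reconstruction error of EMD over seeded
    synthetic trajectories."""
    worst = 0.0
    for k in range(n_trajectories):
        cfg = SyntheticConfig(duration_samples=length, seed=seed * 1009 + k)
        traj = generate_trajectory(cfg)
        stack = emd_decompose(traj)
        err = np.max(np.abs(reconstruct(stack) - traj.values))
        worst = max(worst, err / np.max(np.abs(traj.values)))
    return float(worst)


def _brute_force_causal(x: np.ndarray, taps: np.ndarray, d: int) -> np.ndarray:
    K = len(taps)
    out = np.zeros(len(x))
    for t in range(len(x)):
        for k in range(1, K + 1):
            src = t - (K - k) * d
            if src >= 0:
                out[t] += taps[k - 1] * x[src]
    return out


def conv_oracle_error(n_instances: int = 50, seed: int = 0) -> float:
    """Max relative error of the causal/dilated convolution against a
    double-loop evaluation on random instances."""
    rng = np.random.default_rng([seed % 2**31, 0xC0])
    worst = 0.0
    for _ in range(n_instances):
        n = int(rng.integers(16, 80))
        K = int(rng.integers(1, 8))
        d = int(rng.integers(1, 9))
        x = rng.standard_normal(n)
        taps = rng.standard_normal(K)
        got = causal_conv(x, taps, dilation=d)
        want = _brute_force_causal(x, taps, d)
        scale = max(np.max(np.abs(want)), 1e-12)
        worst = max(worst, float(np.max(np.abs(got - want)) / scale))
    return worst


@dataclass
class OutlierRecovery:
    rmse_corrupted: float      # corrupted vs clean inside the burst
    rmse_corrected: float      # corrected vs clean inside the burst
    outside_changed: int       # samples changed outside flagged intervals
    n_burst_samples: int


def outlier_recovery(seed: int = 0, duration: int = 10_000) -> OutlierRecovery:
    """Inject one disturbance burst, detect and correct it, and compare
    errors against the clean ground truth inside the burst."""
    clean = generate_trajectory(SyntheticConfig(duration_samples=duration, seed=seed))
    corrupted, truth = inject_artifacts(clean, ArtifactSpec(n_bursts=1, seed=seed))
    report = detect_outliers(corrupted, seed=seed)
    fixed = correct_outliers(report)

    bad = np.zeros(len(clean), dtype=bool)
    for s, e in truth:
        bad[s:e] = True
    flag = np.zeros(len(clean), dtype=bool)
    for s, e in report.flagged_intervals:
        flag[s:e] = True
    rmse = lambda a, b: float(np.sqrt(np.mean((a - b) ** 2)))
    return OutlierRecovery(
        rmse_corrupted=rmse(corrupted.values[bad], clean.values[bad]),
        rmse_corrected=rmse(fixed.values[bad], clean.values[bad]),
        outside_changed=int(np.sum(fixed.values[~flag] != corrupted.values[~flag])),
        n_burst_samples=int(bad.sum()),
    )


@dataclass
class EndToEnd:
    test_mae: dict            # lead -> model test MAE (mm)
    baseline_mae: dict        # lead -> persistence test MAE (mm)
    test_rmse: dict
    test_r2: dict
    latency: dict             # lead -> ms
    n_test_windows: int


def end_to_end(seed: int = 0, leads: tuple[int, ...] = (3, 10, 13),
               epochs: int = BENCH_EPOCHS,
               duration: int = BENCH_DURATION) -> EndToEnd:
    """Train the forecaster per lead on one record and evaluate against the
    persistence baseline on the chronological test partition."""
    traj = generate_trajectory(SyntheticConfig(duration_samples=duration, seed=seed))
    out: EndToEnd = EndToEnd({}, {}, {}, {}, {}, 0)
    for lead in leads:
        res = run_pipeline(
            traj,
            input_len=BENCH_INPUT_LEN,
            lead=lead,
            pre_cfg=PreprocessConfig(detect=False, stride=BENCH_STRIDE),
            train_cfg=TrainConfig(epochs=epochs, seed=seed),
            seed=seed,
        )
        out.test_mae[lead] = res.metrics["test"].mae
        out.test_rmse[lead] = res.metrics["test"].rmse
        out.test_r2[lead] = res.metrics["test"].r2
        out.baseline_mae[lead] = res.baseline["test"].mae
        out.latency[lead] = latency_ms(lead, traj.fs)
        out.n_test_windows = res.metrics["test"].n
    return out


def lr_sanity(seed: int = 0, lr: float = 0.1, epochs: int = 6,
              duration: int = BENCH_DURATION) -> dict:
    """Train with a deliberately excessive learning rate; report either the
    NaN abort or the (negative) test R-squared."""
    traj = generate_trajectory(SyntheticConfig(duration_samples=duration, seed=seed))
    try:
        res = run_pipeline(
            traj,
            input_len=BENCH_INPUT_LEN,
            lead=10,
            pre_cfg=PreprocessConfig(detect=False, stride=BENCH_STRIDE),
            train_cfg=TrainConfig(epochs=epochs, lr=lr, seed=seed),
            seed=seed,
        )
    except DivergenceError as exc:
        return {"diverged": True, "test_r2": None, "detail": str(exc)}
    return {"diverged": False, "test_r2": res.metrics["test"].r2}
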