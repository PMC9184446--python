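"""Synthetic quasi-periodic breathing trajectories with injected artifacts.

The generator emulates chest-marker motion recorded by an optical tracker:
a quasi-periodic waveform (cycle length ~3-5 s) whose amplitude and baseline
drift slowly, whose cycle length jitters from breath to breath, observed
with additive noise.  Sparse high-amplitude bursts (cough/speech-like
disturbances) can be injected on top, with the corrupted intervals returned
as ground truth for the outlier-detection stage.

The waveform for one cycle is ``A * sign(sin phi) * |sin phi|**p``: the
shaping exponent ``p >= 1`` flattens the exhale plateau the way real
breathing traces do, and ``p = 1`` recovers a pure sinusoid.  Phase accrues
per cycle (a renewal process with jittered period) so the number of breaths
in a record is controllable; because the waveform is zero at every cycle
boundary, switching amplitude per cycle keeps the trace continuous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .trajectory import Trajectory

__all__ = [
    "SyntheticConfig",
    "ArtifactSpec",
    "generate_trajectory",
    "inject_artifacts",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the breathing-signal generator.

    Defaults mimic a ~6.4-minute chest-marker record: 10,000 samples at
    26 Hz, 4-s breathing cycles of ~10 mm peak amplitude with mild
    cycle-to-cycle variability and 0.2 mm observation noise (typical of
    optical marker tracking).
    """

    duration_samples: int = 10_000
    fs: float = 26.0
    base_period_s: float = 4.0
    amplitude_mm: float = 10.0
    amplitude_drift_sd: float = 0.3      # mm random-walk step per cycle
    period_jitter_sd: float = 0.15       # s per cycle
    baseline_drift_sd: float = 0.002     # mm random-walk step per sample
    noise_sd: float = 0.2                # mm additive observation noise
    waveform_exponent: float = 1.6       # >=1, sharpens the exhale plateau
    seed: int = 0

    def validate(self) -> None:
        if self.duration_samples <= 0:
            raise ConfigurationError("duration_samples must be positive")
        if self.fs <= 0 or self.base_period_s <= 0:
            raise ConfigurationError("fs and base_period_s must be positive")
        if self.amplitude_mm < 0:
            raise ConfigurationError("amplitude_mm must be >= 0")
        for name in ("amplitude_drift_sd", "period_jitter_sd",
                     "baseline_drift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.waveform_exponent < 1:
            raise ConfigurationError("waveform_exponent must be >= 1")


@dataclass(frozen=True)
class ArtifactSpec:
    """Sparse high-amplitude disturbance bursts (cough/speech class)."""

    n_bursts: int = 3
    burst_len_samples: tuple[int, int] = (30, 80)   # inclusive range
    burst_amplitude_mm: float = 5.0
    seed: int = 0

    def validate(self, traj_len: int) -> None:
        lo, hi = self.burst_len_samples
        if self.n_bursts < 0:
            raise ConfigurationError("n_bursts must be >= 0")
        if not (1 <= lo <= hi):
            raise ConfigurationError("burst_len_samples must satisfy 1 <= lo <= hi")
        if hi > traj_len:
            raise ConfigurationError(
                f"burst length {hi} exceeds trajectory length {traj_len}"
            )
        if self.n_bursts * hi > traj_len:
            raise ConfigurationError(
                "bursts cannot fit disjointly inside the trajectory"
            )


def generate_trajectory(cfg: SyntheticConfig) -> Trajectory:
    """Generate one synthetic breathing trajectory.

    Deterministic under ``(cfg, cfg.seed)``; with all stochastic terms set
    to zero and ``waveform_exponent = 1`` the output is a pure sinusoid of
    period ``base_period_s``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.duration_samples
    total_s = n / cfg.fs

    # renewal process over breathing cycles
    n_cycles = max(4, int(np.ceil(total_s / cfg.base_period_s)) + 4)
    periods = cfg.base_period_s + cfg.period_jitter_sd * rng.standard_normal(n_cycles)
    periods = np.clip(periods, 0.5 * cfg.base_period_s, 2.0 * cfg.base_period_s)
    while periods.sum() < total_s:
        extra = cfg.base_period_s + cfg.period_jitter_sd * rng.standard_normal(8)
        extra = np.clip(extra, 0.5 * cfg.base_period_s, 2.0 * cfg.base_period_s)
        periods = np.concatenate([periods, extra])
    starts = np.concatenate([[0.0], np.cumsum(periods)])

    amp_walk = cfg.amplitude_mm + np.cumsum(
        cfg.amplitude_drift_sd * rng.standard_normal(len(periods))
    )
    amp_walk = np.clip(amp_walk, 0.1 * cfg.amplitude_mm, None)

    t = np.arange(n) / cfg.fs
    cycle = np.searchsorted(starts, t, side="right") - 1
    phase = 2.0 * np.pi * (t - starts[cycle]) / periods[cycle]
    s = np.sin(phase)
    wave = np.sign(s) * np.abs(s) ** cfg.waveform_exponent
    x = amp_walk[cycle] * wave

    x = x + np.cumsum(cfg.baseline_drift_sd * rng.standard_normal(n))
    x = x + cfg.noise_sd * rng.standard_normal(n)
    return Trajectory(x, fs=cfg.fs, id=f"synth-seed{cfg.seed}")


def _raised_cosine(length: int) -> np.ndarray:
    tau = np.arange(length) / max(length - 1, 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * tau))


def inject_artifacts(
    traj: Trajectory, spec: ArtifactSpec
) -> tuple[Trajectory, list[tuple[int, int]]]:
    """Add smooth transient bumps to a trajectory.

    Returns the corrupted copy and the ground-truth list of ``[start, end)``
    index intervals.  Samples outside the intervals are bit-identical to the
    input; bursts are disjoint and lie fully inside the trajectory.
    """
    spec.validate(len(traj))
    rng = np.random.default_rng(spec.seed)
    values = traj.values.copy()
    intervals: list[tuple[int, int]] = []

    lo, hi = spec.burst_len_samples
    for _ in range(spec.n_bursts):
        length = int(rng.integers(lo, hi + 1))
        for _attempt in range(10_000):
            start = int(rng.integers(0, len(traj) - length + 1))
            end = start + length
            if all(end <= s or start >= e for s, e in intervals):
                break
        else:  # pragma: no cover - guarded by validate()
            raise ConfigurationError("could not place disjoint bursts")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        scale = spec.burst_amplitude_mm * (0.8 + 0.4 * rng.random())
        values[start:end] += sign * scale * _raised_cosine(length)
        intervals.append((start, end))

    intervals.sort()
    return traj.copy(values=values, id=traj.id + "+artifacts"), intervals
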