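"""Artifact handling, chronological splitting, and supervised windowing.

Recording sessions last minutes, so coughs, sneezes or speech corrupt short
dense segments of the marker trace.  A bagging ensemble of regression trees
predicts each sample from its recent past; samples whose robustly
standardized prediction residual stays large over a short run are flagged
and replaced by cubic interpolation from the flanking clean samples —
everything else is left bit-identical.

The cleaned series is split chronologically 6:2:2 into train/validation/
test, and each partition is cut into sliding (feature-window, future-target)
pairs: the window covers ``X_i`` consecutive rows of the IMF feature matrix
and the target is the *raw* (corrected) marker position ``t_i`` samples
after the window's last sample, so no feature index ever reaches the target
index.  At 26 Hz a lead of ``t_i`` samples bridges ``1000 * t_i / fs`` ms of
system latency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.ensemble import BaggingRegressor
from sklearn.tree import DecisionTreeRegressor

from .emd import FeatureMatrix
from .errors import ConfigurationError, ContractError, InputTooShortError
from .trajectory import Trajectory

__all__ = [
    "OutlierReport",
    "SplitSpec",
    "WindowSpec",
    "WindowedDataset",
    "ColumnScaler",
    "save_windowed",
    "load_windowed",
    "detect_outliers",
    "correct_outliers",
    "split_622",
    "make_windows",
    "latency_ms",
]


@dataclass
class OutlierReport:
    """Outcome of artifact detection on one trajectory."""

    flagged_intervals: list[tuple[int, int]]  # sorted, disjoint [start, end)
    score_trace: np.ndarray                   # per-sample robust z of |residual|
    source: Trajectory


@dataclass(frozen=True)
class SplitSpec:
    """Chronological train/validation/test index ranges, 6:2:2."""

    train_range: tuple[int, int]
    valid_range: tuple[int, int]
    test_range: tuple[int, int]

    def as_dict(self) -> dict[str, tuple[int, int]]:
        return {
            "train": self.train_range,
            "valid": self.valid_range,
            "test": self.test_range,
        }


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the supervised windows.

    ``input_len`` feature rows per window, target ``lead`` samples after the
    window end, windows advancing by ``stride``.
    """

    input_len: int
    lead: int
    stride: int = 1
    fs: float = 26.0

    def __post_init__(self):
        if self.input_len < 1 or self.lead < 1 or self.stride < 1:
            raise ConfigurationError(
                "input_len, lead and stride must all be >= 1"
            )
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")

    @property
    def latency_ms(self) -> float:
        return latency_ms(self.lead, self.fs)


@dataclass
class WindowedDataset:
    """Aligned (feature-window, future-target) pairs for one partition."""

    features: np.ndarray     # (n_windows, input_len, width)
    targets: np.ndarray      # (n_windows,) raw positions in mm
    end_indices: np.ndarray  # source index of each window's last sample
    spec: WindowSpec

    def __len__(self) -> int:
        return self.targets.size

    @property
    def last_observed(self) -> np.ndarray:
        """Raw-signal value at each window's last sample (used by the
        persistence baseline); populated by :func:`make_windows`."""
        return self._last_observed

    _last_observed: np.ndarray = None  # type: ignore[assignment]


def latency_ms(t_i: int, fs: float) -> float:
    """Milliseconds of system delay bridged by a lead of ``t_i`` samples."""
    if fs <= 0:
        raise ConfigurationError("fs must be positive")
    return 1000.0 * t_i / fs


def split_622(length: int) -> SplitSpec:
    """Chronological 6:2:2 partition of ``[0, length)``."""
    if length < 10:
        raise InputTooShortError(f"need >= 10 samples to split, got {length}")
    # round-half-away-from-zero on the 0.6 / 0.2 boundaries
    n_train = int(np.floor(0.6 * length + 0.5))
    n_valid = int(np.floor(0.2 * length + 0.5))
    n_valid = min(n_valid, length - n_train - 1)
    return SplitSpec(
        train_range=(0, n_train),
        valid_range=(n_train, n_train + n_valid),
        test_range=(n_train + n_valid, length),
    )


def detect_outliers(
    traj: Trajectory,
    n_estimators: int = 25,
    window_m: int = 12,
    threshold_k: float = 6.0,
    seed: int = 0,
    min_run: int = 5,
    gap: int = 40,
    spacing: int = 4,
    dilate: int = 20,
    max_depth: int = 10,
) -> OutlierReport:
    """Flag artifact segments with a bagging ensemble of regression trees.

    Each tree predicts ``x[t]`` from ``window_m`` flanking samples on *each*
    side, offset at least ``gap`` samples away (roughly the half-length of a
    disturbance), so an artifact cannot hide inside its own prediction
    context; for a quasi-periodic signal the symmetric flank sums
    ``(x[t-d] + x[t+d])/2``, also supplied as features, are nearly
    proportional to ``x[t]``, which suits axis-aligned tree splits.  A
    disturbance therefore leaves a sustained prediction residual while the
    clean signal is interpolated accurately.

    Residuals are standardized by median/MAD; scores above ``threshold_k``
    sustained over at least ``min_run`` samples are flagged, each run
    dilated by ``dilate`` samples to catch the disturbance's low-amplitude
    tails, and runs closer than ``gap`` merged.  Deterministic under
    ``seed``.
    """
    if n_estimators < 1 or window_m < 2 or min_run < 1:
        raise ConfigurationError("n_estimators, window_m, min_run must be valid")
    if threshold_k <= 0:
        raise ConfigurationError("threshold_k must be positive")
    x = traj.values
    n = len(x)
    span = gap + (window_m - 1) * spacing
    if n < 3 * window_m or n <= 2 * span + 1:
        raise InputTooShortError(
            f"trajectory of {n} samples is too short for the detector "
            f"(needs > {2 * span + 1})"
        )
    deltas = gap + spacing * np.arange(window_m)
    t_idx = np.arange(span, n - span)
    left = x[t_idx[:, None] - deltas[None, :]]
    right = x[t_idx[:, None] + deltas[None, :]]
    X = np.hstack([0.5 * (left + right), 0.5 * (left - right), left, right])
    y = x[t_idx]
    model = BaggingRegressor(
        estimator=DecisionTreeRegressor(max_depth=max_depth, random_state=0),
        n_estimators=n_estimators,
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    model.fit(X, y)
    resid = np.abs(y - model.predict(X))

    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    denom = 1.4826 * mad if mad > 0 else max(float(np.std(resid)), 1e-12)
    score = np.zeros(n)
    score[t_idx] = (resid - med) / denom

    flagged = score > threshold_k
    intervals: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if flagged[i]:
            j = i
            while j < n and flagged[j]:
                j += 1
            if j - i >= min_run:
                intervals.append((max(0, i - dilate), min(n, j + dilate)))
            i = j
        else:
            i += 1
    # merge flagged runs separated by short clean gaps: one physical
    # disturbance often surfaces as several dense runs
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return OutlierReport(flagged_intervals=merged, score_trace=score, source=traj)


def correct_outliers(report: OutlierReport, n_support: int = 8) -> Trajectory:
    """Replace flagged samples by cubic interpolation across each interval.

    ``n_support`` clean samples on each side anchor the spline.  Intervals
    touching the series boundary fall back to nearest-clean-value fill.
    Unflagged samples are returned bit-identical.
    """
    x = report.source.values.copy()
    n = x.size
    bad = np.zeros(n, dtype=bool)
    for s, e in report.flagged_intervals:
        if not (0 <= s < e <= n):
            raise ContractError(f"interval ({s},{e}) out of bounds")
        bad[s:e] = True
    for s, e in report.flagged_intervals:
        left = np.arange(max(0, s - 3 * n_support), s)
        left = left[~bad[left]][-n_support:]
        right = np.arange(e, min(n, e + 3 * n_support))
        right = right[~bad[right]][:n_support]
        if len(left) < 2 or len(right) < 2:
            fill_value = x[left[-1]] if len(left) else x[right[0]]
            x[s:e] = fill_value
            continue
        support = np.concatenate([left, right])
        spline = CubicSpline(support, x[support])
        x[s:e] = spline(np.arange(s, e))
    return report.source.copy(values=x, id=report.source.id + "+corrected")


def make_windows(
    features: FeatureMatrix,
    raw: Trajectory,
    spec: WindowSpec,
    partition: tuple[int, int],
) -> WindowedDataset:
    """Cut one partition into supervised (window, target) pairs.

    Windows never straddle the partition boundary and every target index
    stays inside it; targets come from the raw (corrected) series, not from
    the IMF columns.
    """
    if features.time_len != len(raw):
        raise ContractError("feature matrix and raw series length mismatch")
    start, end = partition
    if not (0 <= start < end <= len(raw)):
        raise ContractError(f"partition {partition} out of bounds")
    X_i, t_i, stride = spec.input_len, spec.lead, spec.stride
    length = end - start
    n_windows = (length - X_i - t_i) // stride + 1
    if length < X_i + t_i or n_windows < 1:
        warnings.warn(
            f"partition of {length} samples too short for X_i={X_i}, "
            f"t_i={t_i}; returning empty dataset",
            stacklevel=2,
        )
        empty = WindowedDataset(
            features=np.empty((0, X_i, features.width)),
            targets=np.empty(0),
            end_indices=np.empty(0, dtype=np.intp),
            spec=spec,
        )
        empty._last_observed = np.empty(0)
        return empty

    ends = start + X_i - 1 + stride * np.arange(n_windows)
    wins = np.stack(
        [features.columns[e - X_i + 1 : e + 1] for e in ends], axis=0
    )
    ds = WindowedDataset(
        features=wins,
        targets=raw.values[ends + t_i],
        end_indices=ends,
        spec=spec,
    )
    ds._last_observed = raw.values[ends]
    return ds


def save_windowed(ds: WindowedDataset, path: str | Path,
                  scaler: "ColumnScaler | None" = None,
                  partition: str = "") -> None:
    """Persist a windowed dataset as compressed arrays plus a JSON sidecar
    recording the window geometry (and optionally the scaler)."""
    import json

    path = Path(path)
    np.savez_compressed(
        path,
        features=ds.features,
        targets=ds.targets,
        end_indices=ds.end_indices,
        last_observed=ds.last_observed,
    )
    sidecar = {
        "input_len": ds.spec.input_len,
        "lead": ds.spec.lead,
        "stride": ds.spec.stride,
        "fs": ds.spec.fs,
        "partition": partition,
        "scaler": scaler.to_dict() if scaler is not None else None,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_windowed(path: str | Path) -> tuple[WindowedDataset, dict]:
    """Load a dataset written by :func:`save_windowed`; returns the dataset
    and the sidecar metadata."""
    import json

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    meta = json.loads(path.with_suffix(".json").read_text())
    arrs = np.load(path)
    spec = WindowSpec(
        input_len=int(meta["input_len"]),
        lead=int(meta["lead"]),
        stride=int(meta["stride"]),
        fs=float(meta["fs"]),
    )
    ds = WindowedDataset(
        features=arrs["features"],
        targets=arrs["targets"],
        end_indices=arrs["end_indices"],
        spec=spec,
    )
    ds._last_observed = arrs["last_observed"]
    return ds, meta


class ColumnScaler:
    """Per-column affine standardization fitted on training rows only.

    Zero-variance columns (e.g. zero-padded IMF columns) get scale 1 and are
    only mean-shifted, so identically-zero padding stays identically zero.
    """

    def __init__(self):
        self.mean_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, train_rows: np.ndarray) -> "ColumnScaler":
        self.mean_ = train_rows.mean(axis=0)
        sd = train_rows.std(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, rows: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ContractError("scaler not fitted")
        return (rows - self.mean_) / self.scale_

    def inverse_transform(self, rows: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ContractError("scaler not fitted")
        return rows * self.scale_ + self.mean_

    def to_dict(self) -> dict:
        return {"mean": self.mean_.tolist(), "scale": self.scale_.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnScaler":
        sc = cls()
        sc.mean_ = np.asarray(d["mean"], dtype=np.float64)
        sc.scale_ = np.asarray(d["scale"], dtype=np.float64)
        return sc
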