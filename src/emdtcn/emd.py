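"""Empirical mode decomposition of breathing trajectories.

EMD adaptively splits a nonstationary signal into intrinsic mode functions
(IMFs) ordered from high to low frequency, plus a monotone-trend residual.
One *sifting* step subtracts the mean of the cubic-spline envelopes through
the local maxima and minima; sifting repeats until the normalized squared
difference between consecutive candidates (the SD criterion) falls below a
threshold, conventionally 0.2-0.3.  The extracted IMF is removed and the
procedure recurses on the remainder until it has too few extrema to
envelope, leaving the residual trend.

The decomposition is exactly additive by construction:
``sum(imfs) + residual == signal``.

Downstream, the first ``n_drop`` high-frequency IMFs (dominated by
observation noise) are discarded, the residual is appended as the last
feature column, and stacks from different records are zero-padded on the
right to a uniform width so one network can consume them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import (
    ConfigurationError,
    ContractError,
    DegenerateInputError,
    NotSiftableError,
)
from .trajectory import Trajectory

__all__ = [
    "SiftState",
    "IMFStack",
    "FeatureMatrix",
    "find_extrema",
    "envelope_mean",
    "sift_once",
    "sd_criterion",
    "emd_decompose",
    "reconstruct",
    "filter_imfs",
    "pad_imfs",
    "zero_crossings",
    "count_extrema",
    "save_imf_csv",
    "load_imf_csv",
]

#: default SD stopping threshold (conservative end of the 0.2-0.3 range)
DEFAULT_SD_THRESHOLD = 0.2
#: safety caps against non-termination on pathological input
DEFAULT_MAX_SIFT_ITERS = 50
DEFAULT_MAX_IMFS = 16


@dataclass
class SiftState:
    """Intermediate quantities of one sifting step."""

    candidate: np.ndarray
    mean_envelope: np.ndarray
    upper_envelope: np.ndarray
    lower_envelope: np.ndarray
    iteration: int = 0


@dataclass
class IMFStack:
    """Ordered IMFs plus the final residual for one trajectory."""

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_id: str = ""

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def validate(self, source: np.ndarray | None = None, rtol: float = 1e-8) -> None:
        n = self.residual.size
        for j, imf in enumerate(self.imfs):
            if imf.size != n:
                raise ContractError(
                    f"imf {j} length {imf.size} != residual length {n}"
                )
        if source is not None:
            recon = reconstruct(self)
            scale = max(np.max(np.abs(source)), 1e-30)
            err = np.max(np.abs(recon - source)) / scale
            if err > rtol:
                raise ContractError(
                    f"reconstruction error {err:.3g} exceeds rtol {rtol:.3g}"
                )


@dataclass
class FeatureMatrix:
    """Time x width matrix of retained (and zero-padded) IMF columns.

    The residual occupies the last non-padded column; padded columns are
    identically zero.
    """

    columns: np.ndarray  # shape (time_len, width)

    @property
    def width(self) -> int:
        return self.columns.shape[1]

    @property
    def time_len(self) -> int:
        return self.columns.shape[0]


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Strict interior local maxima and minima; plateaus contribute their
    midpoint index.  Returns two strictly increasing index arrays."""
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 3:
        raise ContractError("find_extrema needs length >= 3")

    # compress equal-value runs so a plateau is one node
    change = np.flatnonzero(np.diff(x) != 0.0)
    run_starts = np.concatenate([[0], change + 1])
    run_ends = np.concatenate([change, [x.size - 1]])  # inclusive
    vals = x[run_starts]

    maxima, minima = [], []
    for j in range(1, len(vals) - 1):
        mid = (run_starts[j] + run_ends[j]) // 2
        if vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            maxima.append(mid)
        elif vals[j] < vals[j - 1] and vals[j] < vals[j + 1]:
            minima.append(mid)
    return np.asarray(maxima, dtype=np.intp), np.asarray(minima, dtype=np.intp)


def _mirrored_spline(idx: np.ndarray, vals: np.ndarray, n: int) -> np.ndarray:
    """Cubic spline through (idx, vals), mirror-extending the two nearest
    extrema beyond each end to suppress envelope splay."""
    left_i = np.array([-idx[1], -idx[0]])
    left_v = np.array([vals[1], vals[0]])
    right_i = np.array([2 * (n - 1) - idx[-1], 2 * (n - 1) - idx[-2]])
    right_v = np.array([vals[-1], vals[-2]])
    xi = np.concatenate([left_i, idx, right_i])
    yi = np.concatenate([left_v, vals, right_v])
    # mirrored nodes can coincide with originals when idx[0] == 0 etc.
    xi, keep = np.unique(xi, return_index=True)
    yi = yi[keep]
    spline = CubicSpline(xi, yi)
    return spline(np.arange(n))


def envelope_mean(
    signal: np.ndarray, extrema: tuple[np.ndarray, np.ndarray]
) -> SiftState:
    """Upper/lower cubic-spline envelopes through the extrema and their
    pointwise mean.  Raises :class:`NotSiftableError` with fewer than two
    extrema of either kind."""
    x = np.asarray(signal, dtype=np.float64)
    maxima, minima = extrema
    if len(maxima) < 2 or len(minima) < 2:
        raise NotSiftableError(
            f"need >= 2 maxima and >= 2 minima, got {len(maxima)}/{len(minima)}"
        )
    upper = _mirrored_spline(maxima, x[maxima], x.size)
    lower = _mirrored_spline(minima, x[minima], x.size)
    mean = 0.5 * (upper + lower)
    return SiftState(
        candidate=x - mean,
        mean_envelope=mean,
        upper_envelope=upper,
        lower_envelope=lower,
    )


def sift_once(signal: np.ndarray) -> np.ndarray:
    """One sifting step: subtract the envelope mean from the signal."""
    state = envelope_mean(signal, find_extrema(signal))
    return state.candidate


def sd_criterion(h_prev: np.ndarray, h_curr: np.ndarray) -> float:
    """Normalized squared difference between consecutive sifting candidates:
    ``SD = sum((h_prev - h_curr)**2) / sum(h_prev**2)``."""
    h_prev = np.asarray(h_prev, dtype=np.float64)
    h_curr = np.asarray(h_curr, dtype=np.float64)
    if h_prev.shape != h_curr.shape:
        raise ContractError("sd_criterion: shape mismatch")
    denom = float(np.sum(h_prev**2))
    if denom == 0.0:
        raise DegenerateInputError("sd_criterion: zero-energy h_prev")
    return float(np.sum((h_prev - h_curr) ** 2) / denom)


def _is_mode_function(h: np.ndarray) -> bool:
    """Zero-crossing and extrema counts differ by at most one."""
    maxima, minima = find_extrema(h)
    return abs(zero_crossings(h) - (len(maxima) + len(minima))) <= 1


def _extract_imf(
    signal: np.ndarray, sd_threshold: float, max_sift_iters: int
) -> np.ndarray:
    h = sift_once(signal)  # may raise NotSiftableError on the first pass
    for _ in range(max_sift_iters - 1):
        try:
            h_new = sift_once(h)
        except NotSiftableError:
            break
        try:
            sd = sd_criterion(h, h_new)
        except DegenerateInputError:
            h = h_new
            break
        h = h_new
        if sd < sd_threshold and _is_mode_function(h):
            break
    return h


def emd_decompose(
    traj: Trajectory | np.ndarray,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    max_imfs: int = DEFAULT_MAX_IMFS,
    max_sift_iters: int = DEFAULT_MAX_SIFT_ITERS,
) -> IMFStack:
    """Full EMD of a trajectory.

    Decomposition stops when the remainder has fewer than two maxima or two
    minima (it then carries only the central trend), or when ``max_imfs`` is
    reached.  The returned stack reconstructs the input exactly.
    """
    if sd_threshold <= 0:
        raise ConfigurationError("sd_threshold must be positive")
    if max_imfs < 1 or max_sift_iters < 1:
        raise ConfigurationError("max_imfs and max_sift_iters must be >= 1")
    if isinstance(traj, Trajectory):
        x, source_id = traj.values, traj.id
    else:
        x, source_id = np.asarray(traj, dtype=np.float64), ""

    residual = x.astype(np.float64).copy()
    imfs: list[np.ndarray] = []
    for _ in range(max_imfs):
        maxima, minima = (
            find_extrema(residual) if residual.size >= 3 else (np.array([]), np.array([]))
        )
        if len(maxima) < 2 or len(minima) < 2:
            break
        imf = _extract_imf(residual, sd_threshold, max_sift_iters)
        if not np.any(imf):
            break
        imfs.append(imf)
        residual = residual - imf
    stack = IMFStack(imfs=imfs, residual=residual, source_id=source_id)
    stack.validate(source=x)
    return stack


def reconstruct(stack: IMFStack) -> np.ndarray:
    """Element-wise sum of all IMFs and the residual."""
    stack.validate()
    out = stack.residual.copy()
    for imf in stack.imfs:
        out += imf
    return out


def filter_imfs(stack: IMFStack, n_drop: int = 2) -> FeatureMatrix:
    """Drop the first ``n_drop`` high-frequency IMFs and append the residual
    as the last column.  A stack with <= ``n_drop`` IMFs keeps only the
    residual."""
    if n_drop < 0:
        raise ConfigurationError("n_drop must be >= 0")
    kept = stack.imfs[n_drop:]
    cols = kept + [stack.residual]
    return FeatureMatrix(columns=np.column_stack(cols))


def pad_imfs(
    matrices: list[FeatureMatrix], target_width: int
) -> list[FeatureMatrix]:
    """Right-pad every matrix with zero columns to a uniform width."""
    widest = max(m.width for m in matrices)
    if target_width < widest:
        raise ConfigurationError(
            f"target_width {target_width} < widest matrix {widest}"
        )
    out = []
    for m in matrices:
        if m.width == target_width:
            out.append(FeatureMatrix(columns=m.columns.copy()))
        else:
            pad = np.zeros((m.time_len, target_width - m.width))
            out.append(FeatureMatrix(columns=np.hstack([m.columns, pad])))
    return out


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros."""
    s = np.sign(np.asarray(x, dtype=np.float64))
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def count_extrema(x: np.ndarray) -> int:
    maxima, minima = find_extrema(x)
    return len(maxima) + len(minima)


def save_imf_csv(stack: IMFStack, path: str | Path) -> None:
    """Serialize a stack as CSV with columns ``imf_1..imf_n,residual``."""
    cols = {f"imf_{j + 1}": imf for j, imf in enumerate(stack.imfs)}
    cols["residual"] = stack.residual
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def load_imf_csv(
    path: str | Path, source: np.ndarray | None = None
) -> IMFStack:
    """Load a stack; when ``source`` is given the reconstruction invariant
    is re-validated on read."""
    df = pd.read_csv(path)
    if "residual" not in df.columns:
        raise ContractError(f"{path}: missing 'residual' column")
    imf_names = [c for c in df.columns if c.startswith("imf_")]
    imf_names.sort(key=lambda c: int(c.split("_")[1]))
    stack = IMFStack(
        imfs=[df[c].to_numpy() for c in imf_names],
        residual=df["residual"].to_numpy(),
        source_id=Path(path).stem,
    )
    stack.validate(source=source)
    return stack
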