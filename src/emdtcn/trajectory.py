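"""1-D marker-position trajectory container and its on-disk formats.

A trajectory is a uniformly sampled series of marker positions in mm.  Two
plain-text dialects are supported: a two-column CSV ``index,position_mm`` and
a headerless one-value-per-line signal dump.  Both round-trip at 12
significant digits.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = ["Trajectory", "read_signal", "write_signal"]


class Trajectory:
    """Uniformly sampled 1-D marker displacement.

    Parameters
    ----------
    values
        Positions in mm; must be finite and at least 4 samples long
        (the minimum for a cubic-spline envelope).
    fs
        Sampling rate in samples/second.
    id
        Free-text provenance label.
    """

    def __init__(self, values, fs: float = 26.0, id: str = "trajectory"):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 1:
            raise ContractError("trajectory values must be 1-D")
        if values.size < 4:
            raise ContractError(
                f"trajectory needs >= 4 samples, got {values.size}"
            )
        if not np.all(np.isfinite(values)):
            raise ContractError("trajectory values must all be finite")
        if not fs > 0:
            raise ContractError(f"sampling rate must be positive, got {fs}")
        self.values = values
        self.fs = float(fs)
        self.id = str(id)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def copy(self, values: np.ndarray | None = None, id: str | None = None) -> "Trajectory":
        return Trajectory(
            self.values.copy() if values is None else values,
            fs=self.fs,
            id=self.id if id is None else id,
        )


def write_signal(traj: Trajectory, path: str | Path, header: bool = True) -> None:
    """Write a trajectory to CSV (``index,position_mm``) or, with
    ``header=False``, to a headerless single-column text file."""
    path = Path(path)
    if header:
        df = pd.DataFrame(
            {"index": np.arange(len(traj)), "position_mm": traj.values}
        )
        df.to_csv(path, index=False, float_format="%.12g")
    else:
        np.savetxt(path, traj.values, fmt="%.12g")


def read_signal(path: str | Path, fs: float = 26.0, id: str | None = None) -> Trajectory:
    """Read either signal dialect, auto-detected by header sniffing."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first == "":
        raise ContractError(f"{path}: empty signal file")
    label = id if id is not None else path.stem
    if any(c.isalpha() for c in first.replace("e", "").replace("E", "")):
        # header present -> CSV dialect
        df = pd.read_csv(path)
        if "position_mm" not in df.columns:
            raise ContractError(
                f"{path}: CSV signal must have a 'position_mm' column"
            )
        return Trajectory(df["position_mm"].to_numpy(), fs=fs, id=label)
    data = np.loadtxt(path, ndmin=2)
    # single column -> the signal; two columns -> (index, position)
    values = data[:, -1]
    return Trajectory(values, fs=fs, id=label)
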