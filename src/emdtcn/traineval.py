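"""Training loop, regression metrics, persistence baseline, experiment grid.

Training minimizes mean squared error with mini-batch gradient descent
(default: Adam, learning rate 0.001, batch 128, 100 epochs).  The epoch
with the best validation MAE is restored before test evaluation.  All
randomness (parameter init, shuffling, dropout) derives from one seed, so
a run is exactly repeatable.

Evaluation reports the mean absolute error and root mean squared error in
mm and the coefficient of determination
``R^2 = 1 - sum (y - y*)^2 / sum (y - ybar)^2`` (undefined, reported as
missing, when the true series is constant).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ContractError, DivergenceError
from .model import ModelConfig, SEnetTCN, build_model
from .preprocess import WindowedDataset, latency_ms

__all__ = [
    "TrainConfig",
    "Metrics",
    "ExperimentResult",
    "evaluate",
    "train",
    "persistence_baseline",
    "run_experiment_grid",
]

_OPTIMIZERS = ("sgd", "adam", "adagrad", "adadelta", "rmsprop")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol."""

    epochs: int = 100
    batch_size: int = 128
    optimizer: str = "adam"
    lr: float = 0.001
    seed: int = 0
    early_stop: int | None = None  # patience on validation MAE, in epochs

    def validate(self) -> None:
        if self.lr <= 0:
            raise ConfigurationError("lr must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if self.optimizer not in _OPTIMIZERS:
            raise ConfigurationError(
                f"optimizer {self.optimizer!r} not in {_OPTIMIZERS}"
            )
        if self.early_stop is not None and self.early_stop < 1:
            raise ConfigurationError("early_stop patience must be >= 1")


@dataclass(frozen=True)
class Metrics:
    """MAE/RMSE in mm and R-squared (None when undefined)."""

    mae: float
    rmse: float
    r2: float | None
    n: int

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2, "n": self.n}


def evaluate(y_true, y_pred) -> Metrics:
    """Closed-form regression metrics of predicted vs actual positions."""
    y = np.asarray(y_true, dtype=np.float64)
    p = np.asarray(y_pred, dtype=np.float64)
    if y.shape != p.shape or y.ndim != 1 or y.size == 0:
        raise ContractError("evaluate expects equal-length nonempty 1-D arrays")
    err = y - p
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0.0 else float(1.0 - np.sum(err**2) / ss_tot)
    return Metrics(mae=mae, rmse=rmse, r2=r2, n=y.size)


def persistence_baseline(dataset: WindowedDataset) -> np.ndarray:
    """Zero-order hold: predict the last observed raw value of each window."""
    if len(dataset) == 0:
        raise ContractError("persistence_baseline needs a nonempty dataset")
    return dataset.last_observed.copy()


class _Optimizer:
    """The five supported first-order update rules on one parameter list."""

    def __init__(self, params: list[Tensor], name: str, lr: float):
        self.params = params
        self.name = name
        self.lr = lr
        self.t = 0
        self.state = [
            {"m": np.zeros_like(p.data), "v": np.zeros_like(p.data),
             "u": np.zeros_like(p.data)}
            for p in params
        ]

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        for p, st in zip(self.params, self.state):
            g = p.grad
            if g is None:
                continue
            if self.name == "sgd":
                p.data -= lr * g
            elif self.name == "adam":
                b1, b2, eps = 0.9, 0.999, 1e-8
                st["m"] = b1 * st["m"] + (1 - b1) * g
                st["v"] = b2 * st["v"] + (1 - b2) * g**2
                mhat = st["m"] / (1 - b1**self.t)
                vhat = st["v"] / (1 - b2**self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + eps)
            elif self.name == "adagrad":
                st["v"] += g**2
                p.data -= lr * g / (np.sqrt(st["v"]) + 1e-10)
            elif self.name == "adadelta":
                rho, eps = 0.95, 1e-6
                st["v"] = rho * st["v"] + (1 - rho) * g**2
                upd = np.sqrt(st["u"] + eps) / np.sqrt(st["v"] + eps) * g
                st["u"] = rho * st["u"] + (1 - rho) * upd**2
                p.data -= lr * upd
            elif self.name == "rmsprop":
                rho, eps = 0.9, 1e-8
                st["v"] = rho * st["v"] + (1 - rho) * g**2
                p.data -= lr * g / (np.sqrt(st["v"]) + eps)


def train(
    model: SEnetTCN,
    train_ds: WindowedDataset,
    valid_ds: WindowedDataset,
    cfg: TrainConfig,
    verbose: bool = False,
) -> dict:
    """Fit the model with MSE loss; returns the per-epoch history.

    The weights from the epoch with the lowest validation MAE are restored
    into ``model`` at the end.  A non-finite training loss aborts with a
    :class:`DivergenceError` naming the optimizer and learning rate.
    """
    cfg.validate()
    if len(train_ds) == 0 or len(valid_ds) == 0:
        raise ContractError("train and valid datasets must be nonempty")
    rng = np.random.default_rng([int(cfg.seed) % 2**31, 0x7EA1])
    opt = _Optimizer(model.parameters, cfg.optimizer, cfg.lr)

    Xtr, ytr = train_ds.features, train_ds.targets
    history = {"train_loss": [], "valid_mae": [], "epoch_s": []}
    best = {"mae": np.inf, "state": model.state_dict(), "epoch": -1}
    since_best = 0

    for epoch in range(cfg.epochs):
        tic = time.perf_counter()
        model.training = True
        order = rng.permutation(len(train_ds))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            model.zero_grad()
            pred = model.forward(Xtr[idx])
            loss = ad.mean_all(ad.square(pred - Tensor(ytr[idx][:, None])))
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"training loss became non-finite at epoch {epoch} "
                    f"(optimizer={cfg.optimizer}, lr={cfg.lr})",
                    optimizer=cfg.optimizer,
                    lr=cfg.lr,
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.training = False

        val_pred = model.predict(valid_ds.features)
        val_mae = float(np.mean(np.abs(val_pred - valid_ds.targets)))
        history["train_loss"].append(float(np.mean(losses)))
        history["valid_mae"].append(val_mae)
        history["epoch_s"].append(time.perf_counter() - tic)
        if verbose:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}: loss {np.mean(losses):.5f} "
                f"valid MAE {val_mae:.5f} mm"
            )

        if val_mae < best["mae"]:
            best = {"mae": val_mae, "state": model.state_dict(), "epoch": epoch}
            since_best = 0
        else:
            since_best += 1
            if cfg.early_stop is not None and since_best >= cfg.early_stop:
                break

    model.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    return history


@dataclass
class ExperimentResult:
    """One cell of the experiment grid, serializable as JSON."""

    input_len: int
    lead: int
    latency_ms: float
    fs: float
    model_config: dict
    train_config: dict
    metrics: dict            # partition name -> Metrics dict
    history: dict
    seed: int
    config_hash: str = ""

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentResult":
        res = cls(**d)
        expect = latency_ms(res.lead, res.fs)
        if abs(res.latency_ms - expect) > 1e-9:
            raise ContractError(
                f"latency_ms {res.latency_ms} inconsistent with "
                f"lead {res.lead} at fs {res.fs}"
            )
        return res


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]


def run_experiment_grid(
    datasets_for,
    input_lens: list[int],
    leads: list[int],
    optimizers: list[str] | None = None,
    lrs: list[float] | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    fs: float = 26.0,
    out_dir: str | Path | None = None,
    seed: int = 0,
    input_width: int | None = None,
) -> list[ExperimentResult]:
    """Train/evaluate one model per grid cell.

    ``datasets_for(input_len, lead)`` must return a dict with keys
    ``train``/``valid``/``test`` of :class:`WindowedDataset`.  Results are
    written incrementally to ``out_dir`` keyed by a config hash, so a rerun
    skips completed cells; an individual failure is recorded and the grid
    continues.
    """
    if not input_lens or not leads:
        raise ConfigurationError("grid must be nonempty")
    optimizers = optimizers or [None]
    lrs = lrs or [None]
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    results: list[ExperimentResult] = []
    for X_i in input_lens:
        for t_i in leads:
            for opt_name in optimizers:
                for lr in lrs:
                    tc = TrainConfig(
                        epochs=train_cfg.epochs,
                        batch_size=train_cfg.batch_size,
                        optimizer=opt_name or train_cfg.optimizer,
                        lr=lr if lr is not None else train_cfg.lr,
                        seed=seed,
                        early_stop=train_cfg.early_stop,
                    )
                    payload = {
                        "input_len": X_i,
                        "lead": t_i,
                        "model": model_cfg.to_dict(),
                        "train": asdict(tc),
                    }
                    h = _config_hash(payload)
                    cell_path = (
                        out_dir / f"result_{h}.json" if out_dir is not None else None
                    )
                    if cell_path is not None and cell_path.exists():
                        results.append(
                            ExperimentResult.from_dict(
                                json.loads(cell_path.read_text())
                            )
                        )
                        continue
                    try:
                        res = _run_cell(
                            datasets_for, X_i, t_i, model_cfg, tc, fs, seed,
                            input_width,
                        )
                        res.config_hash = h
                    except (DivergenceError, ContractError) as exc:
                        res = ExperimentResult(
                            input_len=X_i,
                            lead=t_i,
                            latency_ms=latency_ms(t_i, fs),
                            fs=fs,
                            model_config=model_cfg.to_dict(),
                            train_config=asdict(tc),
                            metrics={"error": str(exc)},
                            history={},
                            seed=seed,
                            config_hash=h,
                        )
                    results.append(res)
                    if cell_path is not None:
                        cell_path.write_text(json.dumps(res.as_dict(), indent=1))
    return results


def _run_cell(datasets_for, X_i, t_i, model_cfg, tc, fs, seed, input_width):
    ds = datasets_for(X_i, t_i)
    width = input_width or ds["train"].features.shape[2]
    model = build_model(model_cfg, X_i, width, seed=seed)
    history = train(model, ds["train"], ds["valid"], tc)
    metrics = {}
    for part in ("train", "valid", "test"):
        pred = model.predict(ds[part].features)
        metrics[part] = evaluate(ds[part].targets, pred).as_dict()
    return ExperimentResult(
        input_len=X_i,
        lead=t_i,
        latency_ms=latency_ms(t_i, fs),
        fs=fs,
        model_config=model_cfg.to_dict(),
        train_config=asdict(tc),
        metrics=metrics,
        history={k: v for k, v in history.items()},
        seed=seed,
    )


def grid_summary_csv(results: list[ExperimentResult], path: str | Path) -> None:
    """Write the grid in the tabular layout input_length,latency_ms,mae_mm,
    rmse_mm,r2 (test partition)."""
    import pandas as pd

    rows = []
    for r in results:
        m = r.metrics.get("test", {})
        rows.append(
            {
                "input_length": r.input_len,
                "latency_ms": r.latency_ms,
                "mae_mm": m.get("mae"),
                "rmse_mm": m.get("rmse"),
                "r2": m.get("r2"),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
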