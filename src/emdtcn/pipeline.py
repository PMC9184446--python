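"""End-to-end orchestration: trajectory -> clean -> IMF features -> windows
-> trained forecaster -> metrics.

The full trajectory is decomposed once before splitting and windowing,
with the 6:2:2 chronological partition applied afterwards.  This offline
protocol lets IMF rows of past windows reflect future samples; the
supervision targets, however, are always drawn from the raw corrected
series, never from IMFs (docs/methods.md discusses the trade-off).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import emd as emd_mod
from .emd import FeatureMatrix, emd_decompose, filter_imfs, pad_imfs
from .errors import ConfigurationError
from .model import ModelConfig, SEnetTCN, build_model
from .preprocess import (
    ColumnScaler,
    SplitSpec,
    WindowSpec,
    WindowedDataset,
    correct_outliers,
    detect_outliers,
    make_windows,
    split_622,
)
from .traineval import Metrics, TrainConfig, evaluate, persistence_baseline, train
from .trajectory import Trajectory

__all__ = ["PreprocessConfig", "EmdConfig", "PreparedData", "prepare",
           "supervised_datasets", "run_pipeline", "PipelineOutcome"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Outlier handling and windowing options."""

    n_estimators: int = 25
    window_m: int = 12          # flank samples per side for the detector
    threshold_k: float = 6.0
    stride: int = 1
    normalize: bool = True
    detect: bool = True

    def validate(self) -> None:
        if self.n_estimators < 1 or self.window_m < 1 or self.stride < 1:
            raise ConfigurationError("preprocess counts must be >= 1")
        if self.threshold_k <= 0:
            raise ConfigurationError("threshold_k must be positive")


@dataclass(frozen=True)
class EmdConfig:
    """Decomposition and IMF-filtering options."""

    sd_threshold: float = emd_mod.DEFAULT_SD_THRESHOLD
    n_drop: int = 2
    target_width: int = 10
    max_imfs: int = emd_mod.DEFAULT_MAX_IMFS
    max_sift_iters: int = emd_mod.DEFAULT_MAX_SIFT_ITERS
    enabled: bool = True        # False -> raw-signal (no-EMD) variant

    def validate(self) -> None:
        if self.sd_threshold <= 0:
            raise ConfigurationError("sd_threshold must be positive")
        if self.n_drop < 0 or self.target_width < 1:
            raise ConfigurationError("n_drop >= 0 and target_width >= 1 required")


@dataclass
class PreparedData:
    """Cleaned trajectory plus its (scaled) feature matrix and split."""

    raw: Trajectory               # outlier-corrected series (targets come from here)
    features: FeatureMatrix       # scaled IMF columns (or the raw signal column)
    split: SplitSpec
    scaler: ColumnScaler | None
    flagged_intervals: list[tuple[int, int]]
    n_imfs: int


def prepare(
    traj: Trajectory,
    emd_cfg: EmdConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    seed: int = 0,
) -> PreparedData:
    """Clean a trajectory, decompose it, and scale the feature columns.

    The scaler is fitted on training-partition rows only.
    """
    emd_cfg = emd_cfg or EmdConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    emd_cfg.validate()
    pre_cfg.validate()

    flagged: list[tuple[int, int]] = []
    clean = traj
    if pre_cfg.detect:
        report = detect_outliers(
            traj,
            n_estimators=pre_cfg.n_estimators,
            window_m=pre_cfg.window_m,
            threshold_k=pre_cfg.threshold_k,
            seed=seed,
        )
        flagged = report.flagged_intervals
        if flagged:
            clean = correct_outliers(report)

    if emd_cfg.enabled:
        stack = emd_decompose(
            clean,
            sd_threshold=emd_cfg.sd_threshold,
            max_imfs=emd_cfg.max_imfs,
            max_sift_iters=emd_cfg.max_sift_iters,
        )
        fm = filter_imfs(stack, n_drop=emd_cfg.n_drop)
        fm = pad_imfs([fm], emd_cfg.target_width)[0]
        n_imfs = stack.n_imfs
    else:
        fm = FeatureMatrix(columns=clean.values[:, None].copy())
        n_imfs = 0

    split = split_622(len(clean))
    scaler = None
    cols = fm.columns
    if pre_cfg.normalize:
        scaler = ColumnScaler().fit(cols[slice(*split.train_range)])
        cols = scaler.transform(cols)
    return PreparedData(
        raw=clean,
        features=FeatureMatrix(columns=cols),
        split=split,
        scaler=scaler,
        flagged_intervals=flagged,
        n_imfs=n_imfs,
    )


def supervised_datasets(
    prep: PreparedData, input_len: int, lead: int, stride: int = 1
) -> dict[str, WindowedDataset]:
    """Windowed train/valid/test datasets from prepared features."""
    spec = WindowSpec(input_len=input_len, lead=lead, stride=stride, fs=prep.raw.fs)
    return {
        name: make_windows(prep.features, prep.raw, spec, rng)
        for name, rng in prep.split.as_dict().items()
    }


@dataclass
class PipelineOutcome:
    """Everything the end-to-end run produced."""

    model: SEnetTCN
    history: dict
    metrics: dict[str, Metrics]
    baseline: dict[str, Metrics]
    datasets: dict[str, WindowedDataset]
    prep: PreparedData


def run_pipeline(
    traj: Trajectory,
    input_len: int = 100,
    lead: int = 10,
    emd_cfg: EmdConfig | None = None,
    pre_cfg: PreprocessConfig | None = None,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> PipelineOutcome:
    """Train and evaluate the forecaster on one trajectory."""
    emd_cfg = emd_cfg or EmdConfig()
    model_cfg = model_cfg or ModelConfig()
    pre_cfg = pre_cfg or PreprocessConfig()
    train_cfg = train_cfg or TrainConfig(seed=seed)
    if not model_cfg.use_emd_features:
        emd_cfg = EmdConfig(
            sd_threshold=emd_cfg.sd_threshold,
            n_drop=emd_cfg.n_drop,
            target_width=1,
            max_imfs=emd_cfg.max_imfs,
            max_sift_iters=emd_cfg.max_sift_iters,
            enabled=False,
        )

    prep = prepare(traj, emd_cfg=emd_cfg, pre_cfg=pre_cfg, seed=seed)
    datasets = supervised_datasets(prep, input_len, lead, stride=pre_cfg.stride)
    model = build_model(model_cfg, input_len, prep.features.width, seed=seed)
    history = train(model, datasets["train"], datasets["valid"], train_cfg)

    metrics, baseline = {}, {}
    for part, ds in datasets.items():
        metrics[part] = evaluate(ds.targets, model.predict(ds.features))
        baseline[part] = evaluate(ds.targets, persistence_baseline(ds))
    return PipelineOutcome(
        model=model,
        history=history,
        metrics=metrics,
        baseline=baseline,
        datasets=datasets,
        prep=prep,
    )
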