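"""The forecasting network: multi-scale SE-attention CNN front-end plus a
dilated causal temporal convolutional network (TCN).

Input is a window of the IMF feature matrix, shape ``(batch, X_i, W)``:
``X_i`` consecutive samples by ``W`` IMF columns.  Three parallel channels
convolve it with kernels of different time/IMF extent (default 3x1, 5x3,
7x5; 16 filters each) so small kernels catch instantaneous changes while
large ones track local trend.  A squeeze-and-excitation (SE) gate after
each channel reweights the 16 feature maps, then ReLU and 2x2 max pooling.
The three channels are concatenated and the pooled (time x imf x filter)
block is reshaped into a 1-D sequence over the pooled time axis, which a
TCN (two dilated causal convolutions per residual block, weight
normalization, ReLU, dropout; dilations growing as powers of two) maps to
an equal-length sequence.  A flatten plus a dense layer emits the single
predicted position in mm.

Causal convolution follows ``(F_d * X)(x_t) = sum_k f_k x_{t-(K-k)d}``: the
last tap reads the current sample, so no output ever depends on the future.
With ``d = 1`` this is ordinary causal convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .errors import ConfigurationError, ContractError

__all__ = ["ModelConfig", "causal_conv", "receptive_field", "SEnetTCN", "build_model"]


def causal_conv(x, taps, dilation: int = 1) -> np.ndarray:
    """Causal (optionally dilated) convolution of a 1-D sequence.

    ``out[t] = sum_{k=1..K} f_k * x[t - (K - k) * d]`` with zero for
    negative indices; the output has the input's length and ``out[t]``
    depends only on ``x[<= t]``.
    """
    x = np.asarray(x, dtype=np.float64)
    taps = np.asarray(taps, dtype=np.float64)
    if x.ndim != 1 or taps.ndim != 1 or taps.size < 1:
        raise ContractError("causal_conv expects 1-D x and taps")
    d = int(dilation)
    if d < 1:
        raise ConfigurationError("dilation must be >= 1")
    K = taps.size
    out = np.zeros_like(x)
    for k in range(K):  # tap k (0-based) reads lag (K-1-k)*d
        lag = (K - 1 - k) * d
        if lag == 0:
            out += taps[k] * x
        else:
            out[lag:] += taps[k] * x[:-lag]
    return out


def dilated_conv(x, taps, dilation: int) -> np.ndarray:
    """Alias of :func:`causal_conv` with an explicit dilation factor."""
    return causal_conv(x, taps, dilation)


def receptive_field(kernel: int, dilations: list[int], convs_per_block: int = 2) -> int:
    """Span of past inputs influencing one output of the TCN stack."""
    return 1 + convs_per_block * (kernel - 1) * sum(dilations)


@dataclass
class ModelConfig:
    """Architecture hyperparameters of the forecasting network."""

    scale_kernels: list[tuple[int, int]] = field(
        default_factory=lambda: [(3, 1), (5, 3), (7, 5)]
    )
    conv_filters: int = 16
    conv_stride: int = 1
    convs_per_channel: int = 1
    se_reduction: int = 4
    pool: tuple[int, int] = (2, 2)
    tcn_filters: int = 32
    tcn_kernel: int = 3
    tcn_dilations: list[int] = field(default_factory=lambda: [1, 2, 4, 8, 16, 32])
    tcn_stacks: int = 1
    dropout: float = 0.2
    activation: str = "relu"
    use_emd_features: bool = True

    def validate(self, input_len: int | None = None) -> None:
        if not self.scale_kernels:
            raise ConfigurationError("scale_kernels must be nonempty")
        for kt, kw in self.scale_kernels:
            if kt < 1 or kw < 1 or kt % 2 == 0 or kw % 2 == 0:
                raise ConfigurationError(
                    f"kernel ({kt},{kw}) must be odd and positive"
                )
            if input_len is not None and kt > input_len:
                raise ConfigurationError(
                    f"kernel time extent {kt} exceeds input length {input_len}"
                )
        for d in self.tcn_dilations:
            if d < 1 or (d & (d - 1)) != 0:
                raise ConfigurationError(
                    f"dilation {d} is not a positive power of 2"
                )
        if self.conv_stride != 1:
            raise ConfigurationError("only stride 1 is supported")
        if not (0 <= self.dropout < 1):
            raise ConfigurationError("dropout must be in [0, 1)")
        if self.se_reduction < 1 or self.conv_filters < 1 or self.tcn_filters < 1:
            raise ConfigurationError("filter/reduction counts must be >= 1")
        if self.tcn_stacks < 1 or self.tcn_kernel < 1 or self.convs_per_channel < 1:
            raise ConfigurationError("tcn_stacks/tcn_kernel must be >= 1")
        if self.activation != "relu":
            raise ConfigurationError("only relu activation is supported")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale_kernels"] = [list(k) for k in self.scale_kernels]
        d["pool"] = list(self.pool)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "scale_kernels" in d:
            d["scale_kernels"] = [tuple(k) for k in d["scale_kernels"]]
        if "pool" in d:
            d["pool"] = tuple(d["pool"])
        return cls(**d)


class _Param:
    """Named parameter registry entry."""

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.tensor = Tensor(value, requires_grad=True)


class _Layers:
    """Flat parameter store shared by all layers of one network."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.params: list[_Param] = []

    def add(self, name: str, value: np.ndarray) -> Tensor:
        p = _Param(name, value)
        self.params.append(p)
        return p.tensor

    def glorot(self, name: str, shape: tuple[int, ...], fan_in: int, fan_out: int) -> Tensor:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return self.add(name, self.rng.uniform(-lim, lim, size=shape))


class SEnetTCN:
    """Callable predictor mapping ``(batch, X_i, W)`` windows to ``(batch, 1)``
    positions.  Build with :func:`build_model`."""

    def __init__(self, cfg: ModelConfig, input_len: int, input_width: int, seed: int = 0):
        cfg.validate(input_len=input_len)
        max_kt = max(kt for kt, _ in cfg.scale_kernels)
        if input_len < 2 * max_kt:
            raise ConfigurationError(
                f"input_len {input_len} must be >= twice the largest kernel "
                f"time extent ({max_kt}) to survive pooling"
            )
        if input_width < 1:
            raise ConfigurationError("input_width must be >= 1")
        self.cfg = cfg
        self.input_len = input_len
        self.input_width = input_width
        self.seed = int(seed)
        self.training = False
        self._rng = np.random.default_rng([self.seed, 0xD0])
        store = _Layers(np.random.default_rng([self.seed, 0x1]))

        ph, pw_cfg = cfg.pool
        # a width-1 input (raw-signal variant) cannot be pooled across IMFs
        pw = pw_cfg if input_width >= pw_cfg else 1
        self._pool = (ph, pw)
        self.time_pooled = input_len // ph
        self.width_pooled = input_width // pw
        if self.time_pooled < 1 or self.width_pooled < 1:
            raise ConfigurationError("input too small for the pooling window")

        F = cfg.conv_filters
        self._front = []
        for ci, (kt, kw) in enumerate(cfg.scale_kernels):
            convs = []
            for li in range(cfg.convs_per_channel):
                cin = 1 if li == 0 else F
                w = store.glorot(
                    f"front{ci}.conv{li}.w", (F, cin, kt, kw),
                    fan_in=cin * kt * kw, fan_out=F * kt * kw,
                )
                b = store.add(f"front{ci}.conv{li}.b", np.zeros(F))
                convs.append((w, b))
            hidden = max(F // cfg.se_reduction, 1)
            se_w1 = store.glorot(f"front{ci}.se.w1", (F, hidden), F, hidden)
            se_b1 = store.add(f"front{ci}.se.b1", np.zeros(hidden))
            se_w2 = store.glorot(f"front{ci}.se.w2", (hidden, F), hidden, F)
            se_b2 = store.add(f"front{ci}.se.b2", np.zeros(F))
            self._front.append((convs, (se_w1, se_b1, se_w2, se_b2)))

        self.bridge_channels = len(cfg.scale_kernels) * F * self.width_pooled
        self._blocks = []
        cin = self.bridge_channels
        K = cfg.tcn_kernel
        for si in range(cfg.tcn_stacks):
            for d in cfg.tcn_dilations:
                blk = {}
                for li in range(2):
                    c_in = cin if li == 0 else cfg.tcn_filters
                    v = store.glorot(
                        f"tcn{si}.d{d}.conv{li}.v", (cfg.tcn_filters, c_in, K),
                        fan_in=c_in * K, fan_out=cfg.tcn_filters * K,
                    )
                    gain = store.add(
                        f"tcn{si}.d{d}.conv{li}.g",
                        np.sqrt((v.data**2).sum(axis=(1, 2))),
                    )
                    bias = store.add(f"tcn{si}.d{d}.conv{li}.b", np.zeros(cfg.tcn_filters))
                    blk[f"conv{li}"] = (v, gain, bias)
                if cin != cfg.tcn_filters:
                    blk["skip"] = (
                        store.glorot(
                            f"tcn{si}.d{d}.skip.w", (cfg.tcn_filters, cin, 1),
                            fan_in=cin, fan_out=cfg.tcn_filters,
                        ),
                        store.add(f"tcn{si}.d{d}.skip.b", np.zeros(cfg.tcn_filters)),
                    )
                blk["dilation"] = d
                self._blocks.append(blk)
                cin = cfg.tcn_filters

        flat = cfg.tcn_filters * self.time_pooled
        self._head_w = store.glorot("head.w", (flat, 1), flat, 1)
        self._head_b = store.add("head.b", np.zeros(1))
        self._store = store

    # -- building blocks ------------------------------------------------
    def _se_block(self, fmap: Tensor, weights) -> Tensor:
        """Squeeze-and-excitation: GAP -> bottleneck -> sigmoid gates in
        (0,1) -> per-channel rescale."""
        w1, b1, w2, b2 = weights
        B, C = fmap.shape[0], fmap.shape[1]
        squeeze = ad.reshape(ad.mean_axes(fmap, (2, 3), keepdims=False), (B, C))
        z = ad.relu(ad.matmul(squeeze, w1) + b1)
        gates = ad.sigmoid(ad.matmul(z, w2) + b2)
        return fmap * ad.reshape(gates, (B, C, 1, 1))

    def _normed_weight(self, v: Tensor, gain: Tensor) -> Tensor:
        """Weight normalization: w = g * v / ||v|| per output channel."""
        norm = ad.sqrt(ad.sum_axes(ad.square(v), (1, 2), keepdims=True) + 1e-12)
        return v * ad.reshape(gain, (gain.shape[0], 1, 1)) / norm

    def _residual_block(self, x: Tensor, blk: dict) -> Tensor:
        d = blk["dilation"]
        h = x
        for li in range(2):
            v, gain, bias = blk[f"conv{li}"]
            h = ad.causal_conv1d(h, self._normed_weight(v, gain), bias, dilation=d)
            h = ad.relu(h)
            if self.training and self.cfg.dropout > 0:
                h = ad.dropout(h, self.cfg.dropout, self._rng)
        if "skip" in blk:
            sw, sb = blk["skip"]
            skip = ad.causal_conv1d(x, sw, sb, dilation=1)
        else:
            skip = x
        return ad.relu(h + skip)

    # -- forward --------------------------------------------------------
    def forward(self, windows: np.ndarray | Tensor) -> Tensor:
        x = windows if isinstance(windows, Tensor) else Tensor(windows)
        if x.ndim != 3 or x.shape[1] != self.input_len or x.shape[2] != self.input_width:
            raise ContractError(
                f"expected (batch, {self.input_len}, {self.input_width}), "
                f"got {x.shape}"
            )
        B = x.shape[0]
        img = ad.reshape(x, (B, 1, self.input_len, self.input_width))

        channels = []
        for convs, se_weights in self._front:
            h = img
            for w, b in convs:
                h = ad.conv2d_same(h, w, b)
            h = self._se_block(h, se_weights)
            h = ad.relu(h)
            h = ad.maxpool2d(h, self._pool)
            channels.append(h)
        merged = ad.concat(channels, axis=1)  # (B, 3F, T', W')

        # bridge: fold channel and IMF axes into TCN channels, time last
        seq = ad.reshape(
            ad.transpose(merged, (0, 1, 3, 2)),
            (B, self.bridge_channels, self.time_pooled),
        )
        for blk in self._blocks:
            seq = self._residual_block(seq, blk)

        flat = ad.reshape(seq, (B, self.cfg.tcn_filters * self.time_pooled))
        return ad.matmul(flat, self._head_w) + self._head_b

    def predict(self, windows: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Dropout-free deterministic inference; one scalar per window."""
        was_training = self.training
        self.training = False
        try:
            outs = [
                self.forward(windows[i : i + batch_size]).data[:, 0]
                for i in range(0, len(windows), batch_size)
            ]
        finally:
            self.training = was_training
        return np.concatenate(outs) if outs else np.empty(0)

    __call__ = forward

    # -- parameter access ----------------------------------------------
    @property
    def parameters(self) -> list[Tensor]:
        return [p.tensor for p in self._store.params]

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.zero_grad()

    def n_parameters(self) -> int:
        return int(sum(p.tensor.data.size for p in self._store.params))

    def summary(self) -> dict:
        return {
            "config": self.cfg.to_dict(),
            "input_len": self.input_len,
            "input_width": self.input_width,
            "n_parameters": self.n_parameters(),
            "layers": [
                {"name": p.name, "shape": list(p.tensor.shape)}
                for p in self._store.params
            ],
        }

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.tensor.data.copy() for p in self._store.params}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self._store.params:
            if p.name not in state:
                raise ContractError(f"missing parameter {p.name}")
            val = np.asarray(state[p.name])
            if val.shape != p.tensor.shape:
                raise ContractError(
                    f"shape mismatch for {p.name}: {val.shape} vs {p.tensor.shape}"
                )
            p.tensor.data = val.astype(p.tensor.data.dtype).copy()


def build_model(
    cfg: ModelConfig, input_len: int, input_width: int, seed: int = 0
) -> SEnetTCN:
    """Validate the configuration and construct the predictor.

    Shape incompatibilities raise :class:`ConfigurationError` here, never at
    call time.  Identical ``(cfg, input_len, input_width, seed)`` yield
    identical initial parameters.
    """
    return SEnetTCN(cfg, input_len, input_width, seed=seed)
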