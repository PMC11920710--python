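"""Point-cloud U-Net regressing per-point TAWSS from ordered coordinates.

The network consumes a canonically ordered cloud of ``points`` 3D
coordinates, lifts each point to ``channels`` features with two shared
per-point layers, reshapes the ordered sequence to a rows x cols grid, and
applies a U-Net: per level two 3x3 convolutions then 2x2 max pooling, a
stack of bottleneck convolutions at the coarsest resolution, and a decoder
of 2x2 stride-2 transposed convolutions with skip concatenations.  Batch
normalization sits after each convolution and before its ReLU, except on
the 1x1 output layer.  Targets are min-max normalized by the dataset-global
TAWSS extremes; training uses Adam, MSE loss, and a staircase exponential
learning-rate decay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    BatchNorm,
    Conv3x3,
    ConvTranspose2x2,
    Dense,
    Layer,
    MaxPool2x2,
    Param,
    ReLU,
)
from .geometry import SurfacePointCloud
from .ordering import Ordering, from_grid

__all__ = [
    "UNetConfig",
    "TrainedModel",
    "TrainingData",
    "build_unet",
    "train",
    "predict",
    "save_model",
    "load_model",
]


class NetworkConfigError(ValueError):
    pass


@dataclass(frozen=True)
class UNetConfig:
    """Architecture and training hyperparameters."""

    points: int = 4096
    in_channels: int = 3
    grid_rows: int = 64
    grid_cols: int = 64
    channels: int = 8
    stem_width: int = 8
    levels: int = 4
    convs_per_level: int = 2
    bottleneck_convs: int = 4
    skip_connections: bool = True
    batch_norm: bool = True
    lr0: float = 1e-3
    decay_every_steps: int = 2000
    decay_rate: float = 0.9
    batch_size: int = 16
    epochs: int = 200
    patience: int = 20
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols != self.points:
            raise NetworkConfigError(
                f"grid {self.grid_rows}x{self.grid_cols} != points {self.points}"
            )
        if self.levels < 1:
            raise NetworkConfigError("need at least one pooling level")
        if (
            self.grid_rows % 2**self.levels != 0
            or self.grid_cols % 2**self.levels != 0
        ):
            raise NetworkConfigError(
                f"grid {self.grid_rows}x{self.grid_cols} not divisible by 2^{self.levels}"
            )
        if self.loss != "mse":
            raise NetworkConfigError(f"unsupported loss {self.loss!r}")


def _conv_block(c_in: int, c_out: int, cfg: UNetConfig, rng) -> list[Layer]:
    block: list[Layer] = [Conv3x3(c_in, c_out, rng)]
    if cfg.batch_norm:
        block.append(BatchNorm(c_out))
    block.append(ReLU())
    return block


def _run(layers: list[Layer], x: np.ndarray, train: bool) -> np.ndarray:
    for lyr in layers:
        x = lyr.forward(x, train)
    return x


def _back(layers: list[Layer], d: np.ndarray) -> np.ndarray:
    for lyr in reversed(layers):
        d = lyr.backward(d)
    return d


class UNet:
    """The bare network: layer storage plus forward/backward passes."""

    def __init__(self, cfg: UNetConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c = cfg.channels
        self.stem: list[Layer] = [Dense(cfg.in_channels, cfg.stem_width, rng)]
        if cfg.batch_norm:
            self.stem.append(BatchNorm(cfg.stem_width))
        self.stem.append(ReLU())
        self.stem.append(Dense(cfg.stem_width, c, rng))
        if cfg.batch_norm:
            self.stem.append(BatchNorm(c))
        self.stem.append(ReLU())

        def conv_stack(n: int) -> list[Layer]:
            layers: list[Layer] = []
            for _ in range(n):
                layers += _conv_block(c, c, cfg, rng)
            return layers

        self.enc_blocks = [conv_stack(cfg.convs_per_level) for _ in range(cfg.levels + 1)]
        self.pools = [MaxPool2x2() for _ in range(cfg.levels)]
        self.bottleneck = conv_stack(cfg.bottleneck_convs)
        self.ups: list[list[Layer]] = []
        self.dec_blocks: list[list[Layer]] = []
        for _ in range(cfg.levels):
            up: list[Layer] = [ConvTranspose2x2(c, c, rng)]
            if cfg.batch_norm:
                up.append(BatchNorm(c))
            up.append(ReLU())
            self.ups.append(up)
            dec_in = 2 * c if cfg.skip_connections else c
            dec: list[Layer] = _conv_block(dec_in, c, cfg, rng)
            for _ in range(cfg.convs_per_level - 1):
                dec += _conv_block(c, c, cfg, rng)
            self.dec_blocks.append(dec)
        self.head = Dense(c, 1, rng)  # 1x1 output convolution, no norm/activation

        self.encoder_sizes: list[int] = []
        self._skips: list[np.ndarray] | None = None

    # -- plumbing ---------------------------------------------------------
    def _all_layer_lists(self) -> list[list[Layer]]:
        return (
            [self.stem]
            + self.enc_blocks
            + [self.bottleneck]
            + self.ups
            + self.dec_blocks
            + [[self.head]]
        )

    def params(self) -> list[Param]:
        out: list[Param] = []
        for group in self._all_layer_lists():
            for lyr in group:
                out.extend(lyr.params())
        return out

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    # -- passes -----------------------------------------------------------
    def forward(self, points: np.ndarray, train: bool = False) -> np.ndarray:
        """(B, points, 3) ordered coordinates -> (B, points, 1) normalized TAWSS."""
        cfg = self.cfg
        b, n, cin = points.shape
        if n != cfg.points or cin != cfg.in_channels:
            raise NetworkConfigError(
                f"input shaped ({n}, {cin}), expected ({cfg.points}, {cfg.in_channels})"
            )
        from ._nn import DTYPE

        x = _run(self.stem, points.reshape(b * n, cin).astype(DTYPE), train)
        x = x.reshape(b, cfg.grid_rows, cfg.grid_cols, cfg.channels)
        self.encoder_sizes = [x.shape[1]]
        skips = []
        for lvl in range(cfg.levels):
            x = _run(self.enc_blocks[lvl], x, train)
            skips.append(x)
            x = self.pools[lvl].forward(x, train)
            self.encoder_sizes.append(x.shape[1])
        x = _run(self.enc_blocks[cfg.levels], x, train)
        x = _run(self.bottleneck, x, train)
        for lvl in range(cfg.levels):
            x = _run(self.ups[lvl], x, train)
            if cfg.skip_connections:
                x = np.concatenate([x, skips[cfg.levels - 1 - lvl]], axis=-1)
            x = _run(self.dec_blocks[lvl], x, train)
        y = self.head.forward(x.reshape(b * n, cfg.channels), train)
        return y.reshape(b, n, 1)

    def backward(self, dout: np.ndarray) -> None:
        cfg = self.cfg
        b = dout.shape[0]
        from ._nn import DTYPE

        d = self.head.backward(dout.reshape(b * cfg.points, 1).astype(DTYPE))
        d = d.reshape(b, cfg.grid_rows, cfg.grid_cols, cfg.channels)
        dskips: list[np.ndarray | None] = [None] * cfg.levels
        for lvl in reversed(range(cfg.levels)):
            d = _back(self.dec_blocks[lvl], d)
            if cfg.skip_connections:
                d, dskip = np.split(d, 2, axis=-1)
                dskips[cfg.levels - 1 - lvl] = dskip
            d = _back(self.ups[lvl], d)
        d = _back(self.bottleneck, d)
        d = _back(self.enc_blocks[cfg.levels], d)
        for lvl in reversed(range(cfg.levels)):
            d = self.pools[lvl].backward(d)
            if cfg.skip_connections and dskips[lvl] is not None:
                d = d + dskips[lvl]
            d = _back(self.enc_blocks[lvl], d)
        _back(self.stem, d.reshape(b * cfg.points, cfg.channels))


@dataclass
class TrainedModel:
    """Network plus everything needed to reproduce its predictions."""

    net: UNet
    config: UNetConfig
    tawss_global_max: float | None = None
    tawss_global_min: float | None = None
    history: dict[str, list[float]] = field(default_factory=lambda: {"train_mse": [], "val_name": []})

    @property
    def parameter_count(self) -> int:
        return self.net.parameter_count

    def normalize(self, y: np.ndarray) -> np.ndarray:
        rng_ = self.tawss_global_max - self.tawss_global_min
        return (y - self.tawss_global_min) / rng_

    def denormalize(self, y: np.ndarray) -> np.ndarray:
        rng_ = self.tawss_global_max - self.tawss_global_min
        return y * rng_ + self.tawss_global_min


def build_unet(cfg: UNetConfig) -> TrainedModel:
    """Instantiate an untrained model from a configuration."""
    return TrainedModel(net=UNet(cfg), config=cfg)


@dataclass
class TrainingData:
    """In-memory dataset: ordered aligned coordinates and TAWSS labels."""

    train_x: np.ndarray  # (M, points, 3)
    train_y: np.ndarray  # (M, points)
    val_x: np.ndarray
    val_y: np.ndarray
    tawss_global_max: float = 1.0
    tawss_global_min: float = 0.0


def recalibrate_batchnorm(model: TrainedModel, x: np.ndarray, batch_size: int) -> None:
    """Replace BN running statistics by their averages over ``x``.

    Running averages collected with momentum during training lag the final
    weights; one sweep over the training inputs re-estimates the inference
    statistics for the weights actually kept.
    """
    bns = [
        lyr
        for group in model.net._all_layer_lists()
        for lyr in group
        if isinstance(lyr, BatchNorm)
    ]
    if not bns or len(x) == 0:
        return
    means: list[list[np.ndarray]] = [[] for _ in bns]
    varis: list[list[np.ndarray]] = [[] for _ in bns]
    saved = [(b.running_mean.copy(), b.running_var.copy(), b.momentum) for b in bns]
    for b in bns:
        b.momentum = 0.0  # running <- current batch statistics exactly
    try:
        for s in range(0, len(x), batch_size):
            model.net.forward(x[s : s + batch_size], train=True)
            for i, b in enumerate(bns):
                means[i].append(b.running_mean.copy())
                varis[i].append(b.running_var.copy())
    finally:
        for b, (rm, rv, mom) in zip(bns, saved):
            b.running_mean[...] = rm
            b.running_var[...] = rv
            b.momentum = mom
    for i, b in enumerate(bns):
        b.running_mean[...] = np.mean(means[i], axis=0)
        b.running_var[...] = np.mean(varis[i], axis=0)


def _batched_forward(model: TrainedModel, x: np.ndarray, batch_size: int) -> np.ndarray:
    outs = []
    for s in range(0, len(x), batch_size):
        outs.append(model.net.forward(x[s : s + batch_size], train=False))
    return np.concatenate(outs, axis=0)


def _val_name(model: TrainedModel, x: np.ndarray, y: np.ndarray, batch_size: int) -> float:
    from .metrics import name_metric

    pred = model.denormalize(_batched_forward(model, x, batch_size)[..., 0])
    scores = [
        name_metric(y[i], pred[i], model.tawss_global_max, model.tawss_global_min)
        for i in range(len(x))
    ]
    return float(np.mean(scores))


def train(
    model: TrainedModel,
    data: TrainingData,
    epochs: int | None = None,
    batch_size: int | None = None,
    target_train_mse: float | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the model by MSE on min-max-normalized TAWSS targets.

    Early-stops on validation NAME with the configured patience (skipped when
    there is no validation set); restores the best validation weights.
    ``target_train_mse`` optionally stops once the normalized training MSE
    drops below the given value (used by overfitting smoke checks).
    """
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    batch_size = cfg.batch_size if batch_size is None else batch_size
    model.tawss_global_max = float(data.tawss_global_max)
    model.tawss_global_min = float(data.tawss_global_min)

    ty = model.normalize(data.train_y)
    opt = Adam(
        model.net.params(),
        lr0=cfg.lr0,
        decay_rate=cfg.decay_rate,
        decay_every=cfg.decay_every_steps,
    )
    rng = np.random.default_rng(cfg.seed + 1)
    n_train = len(data.train_x)
    best_name, best_state, since_best = np.inf, None, 0
    has_val = len(data.val_x) > 0

    for epoch in range(epochs):
        order = rng.permutation(n_train)
        losses = []
        for s in range(0, n_train, batch_size):
            idx = order[s : s + batch_size]
            xb, yb = data.train_x[idx], ty[idx]
            pred = model.net.forward(xb, train=True)
            resid = pred[..., 0] - yb
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {s // batch_size}, lr {opt.lr:g}"
                )
            losses.append(loss)
            opt.zero_grad()
            model.net.backward((2.0 * resid / resid.size)[..., None])
            opt.step()
        train_mse = float(np.mean(losses))
        model.history["train_mse"].append(train_mse)
        if has_val:
            vname = _val_name(model, data.val_x, data.val_y, batch_size)
            model.history["val_name"].append(vname)
            if vname < best_name - 1e-12:
                best_name, since_best = vname, 0
                best_state = [p.value.copy() for p in model.net.params()]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        if verbose:
            msg = f"epoch {epoch}: train mse {train_mse:.3e}"
            if has_val:
                msg += f", val NAME {model.history['val_name'][-1]:.3f}%"
            print(msg)
        if target_train_mse is not None and train_mse < target_train_mse:
            break

    if best_state is not None:
        for p, v in zip(model.net.params(), best_state):
            p.value[...] = v
    recalibrate_batchnorm(model, data.train_x, batch_size)
    return model


def predict(
    model: TrainedModel, cloud: SurfacePointCloud, ordering: Ordering
) -> np.ndarray:
    """Per-point TAWSS prediction (Pa) in the cloud's original point order.

    Coordinates are expressed in the ordering's canonical frame, permuted,
    passed through the network, de-normalized, clipped to the dataset-global
    TAWSS range, and un-permuted back to input order.
    """
    cfg = model.config
    if cloud.n_points != cfg.points:
        raise NetworkConfigError(
            f"cloud has {cloud.n_points} points, model expects {cfg.points}"
        )
    x = ordering.aligned(cloud.coords)[ordering.permutation][None]
    y = model.net.forward(x, train=False)[0]  # (points, 1)
    y = model.denormalize(y)
    y = np.clip(y, model.tawss_global_min, model.tawss_global_max)
    grid = y.reshape(cfg.grid_rows, cfg.grid_cols, 1)
    from .ordering import OrderedGrid

    return from_grid(OrderedGrid(tensor=grid), ordering)[:, 0]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """One-file checkpoint: weights, BN statistics, config, normalization."""
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.net.params()):
        arrays[f"param_{i}"] = p.value
    bn_idx = 0
    for group in model.net._all_layer_lists():
        for lyr in group:
            if isinstance(lyr, BatchNorm):
                arrays[f"bn_{bn_idx}_mean"] = lyr.running_mean
                arrays[f"bn_{bn_idx}_var"] = lyr.running_var
                bn_idx += 1
    meta = {
        "config": asdict(model.config),
        "tawss_global_max": model.tawss_global_max,
        "tawss_global_min": model.tawss_global_min,
        "history": model.history,
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        cfg = UNetConfig(**meta["config"])
        model = build_unet(cfg)
        for i, p in enumerate(model.net.params()):
            p.value[...] = z[f"param_{i}"]
        bn_idx = 0
        for group in model.net._all_layer_lists():
            for lyr in group:
                if isinstance(lyr, BatchNorm):
                    lyr.running_mean[...] = z[f"bn_{bn_idx}_mean"]
                    lyr.running_var[...] = z[f"bn_{bn_idx}_var"]
                    bn_idx += 1
        model.tawss_global_max = meta["tawss_global_max"]
        model.tawss_global_min = meta["tawss_global_min"]
        model.history = meta["history"]
    return model
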