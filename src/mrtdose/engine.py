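"""3D U-Net dose engine: normalization, training and prediction.

Two independent models are trained, one for the peak channel and one for
the valley channel, each mapping the (96, 16, 16) phantom density matrix to
the energy deposition per macrovoxel.  Inputs and targets are affinely
mapped to [0, 1] with the minimum and maximum of the *training* partition
(validation/test data may fall outside [0, 1] and are never clipped).
Training minimizes the mean absolute error (MAE) with Adam and stops early
when the validation MAE has not improved for a configurable number of
epochs; the weights of the best validation epoch are kept.

Architecture (choices fixed here, see docs/methods.md): a compression path
of stride-2 convolutions (one per level), a bottleneck convolution, and a
decompression path of nearest-neighbour 2x upsampling followed by two
convolutions per level, with skip concatenations joining the input of each
compression level to its mirror (the full-resolution skip is the density
input itself).  All convolutions use 3x3x3 kernels, ReLU activations and a
constant number of filters; the output layer is a linear 1x1x1 convolution.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .dosesim import DoseGrid
from .nn import Adam, Conv3d, Upsample3d, mae_loss


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite (e.g. learning rate too large)."""


@dataclass
class NormalizationSpec:
    """Frozen affine [0,1] mapping fitted on the training partition only."""

    input_min: float
    input_max: float
    target_min: float
    target_max: float

    def __post_init__(self) -> None:
        if not (self.input_max > self.input_min and self.target_max > self.target_min):
            raise ValueError("degenerate normalization: max must exceed min")


@dataclass
class UNetConfig:
    """Dose-engine hyperparameters."""

    n_filters: int = 16
    batch_size: int = 8
    learning_rate: float = 1e-3
    levels: int = 2
    patience: int = 30
    max_epochs: int = 60
    # cosine decay of the learning rate from `learning_rate` down to
    # `learning_rate * lr_min_fraction` over max_epochs; 1.0 = constant
    lr_min_fraction: float = 0.05
    # Adam second-moment decay; smaller values adapt faster in short runs
    adam_beta2: float = 0.999
    # per-step exponential moving average of the weights (Polyak averaging);
    # validation and the returned model use the averaged weights. 0 disables.
    weight_ema: float = 0.998

    def __post_init__(self) -> None:
        if self.n_filters < 1 or self.batch_size < 1 or self.patience < 1:
            raise ValueError("n_filters, batch_size and patience must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if not 0 < self.lr_min_fraction <= 1.0:
            raise ValueError("lr_min_fraction must be in (0, 1]")
        if not 0 <= self.weight_ema < 1.0:
            raise ValueError("weight_ema must be in [0, 1)")


@dataclass
class TrainingHistory:
    """Per-epoch training/validation MAE and the best validation epoch."""

    train_mae: list[float] = field(default_factory=list)
    val_mae: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_mae(self) -> float:
        return self.val_mae[self.best_epoch]


def fit_normalization(train_inputs: np.ndarray, train_targets: np.ndarray) -> NormalizationSpec:
    """Compute the training-set min/max for inputs (density) and targets."""
    train_inputs = np.asarray(train_inputs)
    train_targets = np.asarray(train_targets)
    if train_inputs.size == 0 or train_targets.size == 0:
        raise ValueError("training partition is empty")
    return NormalizationSpec(
        input_min=float(train_inputs.min()),
        input_max=float(train_inputs.max()),
        target_min=float(train_targets.min()),
        target_max=float(train_targets.max()),
    )


def normalize_input(x: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    return (np.asarray(x, dtype=np.float32) - spec.input_min) / (spec.input_max - spec.input_min)


def normalize_target(y: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    return (np.asarray(y, dtype=np.float32) - spec.target_min) / (spec.target_max - spec.target_min)


def denormalize_target(y01: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    return np.asarray(y01, dtype=float) * (spec.target_max - spec.target_min) + spec.target_min


class UNet3D:
    """The numpy 3D U-Net (see module docstring for the architecture)."""

    def __init__(self, cfg: UNetConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        f = cfg.n_filters
        # compression: one strided conv per level; skip l is the *input* of
        # down[l], so the full-resolution skip is the 1-channel density input
        self.down = [
            Conv3d(1 if l == 0 else f, f, rng, stride=2, dtype=dtype)
            for l in range(cfg.levels)
        ]
        self.bottleneck = Conv3d(f, f, rng, dtype=dtype)
        self.up = []
        for j in range(cfg.levels):
            skip_ch = 1 if j == cfg.levels - 1 else f
            self.up.append(
                (Upsample3d(), Conv3d(f + skip_ch, f, rng, dtype=dtype), Conv3d(f, f, rng, dtype=dtype))
            )
        self.head = Conv3d(f, 1, rng, kernel=1, relu=False, dtype=dtype)

    # -- plumbing --------------------------------------------------------
    def _layers(self):
        yield from self.down
        yield self.bottleneck
        for up, c1, c2 in self.up:
            yield c1
            yield c2
        yield self.head

    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.params)
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend(layer.grads)
        return out

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w

    # -- forward/backward ------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[-1] != 1:
            raise ValueError("input must have shape (N, D, H, W, 1)")
        for dim in x.shape[1:4]:
            if dim % (2**self.cfg.levels) != 0:
                raise ValueError(
                    f"spatial dims {x.shape[2:]} not divisible by 2^levels={2**self.cfg.levels}"
                )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._check_shape(x)
        cur = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for conv in self.down:
            skips.append(cur)
            cur = conv.forward(cur, train)
        cur = self.bottleneck.forward(cur, train)
        for (up, c1, c2), skip in zip(self.up, reversed(skips)):
            cur = up.forward(cur, train)
            cur = np.concatenate([cur, skip], axis=-1)
            cur = c1.forward(cur, train)
            cur = c2.forward(cur, train)
        return self.head.forward(cur, train)

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients (the input gradient is not needed)."""
        f = self.cfg.n_filters
        cur = self.head.backward(np.ascontiguousarray(dy, dtype=self.dtype))
        skip_grads = []
        for up, c1, c2 in reversed(self.up):
            cur = c1.backward(c2.backward(cur))
            skip_grads.append(cur[..., f:])
            cur = up.backward(cur[..., :f])
        cur = self.bottleneck.backward(cur)
        # skip_grads[k] is the gradient w.r.t. skips[k] (the input of down[k])
        for l in range(self.cfg.levels - 1, 0, -1):
            cur = self.down[l].backward(cur) + skip_grads[l]
        self.down[0].backward(cur, need_dx=False)


def build_model(cfg: UNetConfig, seed: int = 0, input_shape=(96, 16, 16), dtype=np.float32) -> UNet3D:
    """Construct a U-Net and validate it against the input shape."""
    for dim in input_shape:
        if dim % (2**cfg.levels) != 0:
            raise ValueError(
                f"input shape {input_shape} is not divisible by 2^levels={2**cfg.levels}; "
                "reduce `levels`"
            )
    return UNet3D(cfg, seed=seed, dtype=dtype)


def train_model(
    model: UNet3D,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    cfg: UNetConfig | None = None,
    seed: int = 0,
    verbose: bool = False,
) -> tuple[UNet3D, TrainingHistory]:
    """Adam/MAE training with early stopping on the validation MAE.

    ``train_data`` and ``val_data`` are (inputs, targets) pairs of shape
    (N, D, H, W, 1) on the normalized scale.  One seed governs batch
    shuffling (weight initialization is seeded in ``build_model``).
    Returns the model restored to its best validation epoch.
    """
    cfg = cfg or model.cfg
    xtr, ytr = (np.asarray(a, dtype=model.dtype) for a in train_data)
    xval, yval = (np.asarray(a, dtype=model.dtype) for a in val_data)
    if len(xtr) == 0 or len(xval) == 0:
        raise ValueError("training and validation partitions must be non-empty")
    rng = np.random.default_rng(seed)
    opt = Adam(model.params, lr=cfg.learning_rate, beta2=cfg.adam_beta2)
    history = TrainingHistory()
    best_weights = model.get_weights()
    best_val = np.inf
    since_best = 0
    # Polyak-averaged shadow weights (zero-initialized with bias correction);
    # damp the step-to-step wander of the sign-gradient (MAE) updates.
    # Validation is scored on the average.
    ema = [np.zeros_like(p) for p in model.params] if cfg.weight_ema > 0 else None
    ema_steps = 0  # decay ramps up from ~0 so short runs track the raw weights

    for epoch in range(cfg.max_epochs):
        if cfg.lr_min_fraction < 1.0 and cfg.max_epochs > 1:
            lo = cfg.learning_rate * cfg.lr_min_fraction
            cos = 0.5 * (1 + np.cos(np.pi * epoch / (cfg.max_epochs - 1)))
            opt.lr = lo + (cfg.learning_rate - lo) * cos
        order = rng.permutation(len(xtr))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = model.forward(xtr[idx], train=True)
            loss, dy = mae_loss(pred, ytr[idx])
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or increase the batch size"
                )
            model.backward(dy)
            opt.step(model.grads)
            if ema is not None:
                beta = min(cfg.weight_ema, (1.0 + ema_steps) / (10.0 + ema_steps))
                ema_steps += 1
                for avg, p in zip(ema, model.params):
                    avg += (1.0 - beta) * (p - avg)
            epoch_losses.append(loss)
        if ema is not None:
            raw = model.get_weights()
            model.set_weights(ema)
        else:
            raw = None
        val_mae = evaluate_mae(model, xval, yval, cfg.batch_size)
        if not np.isfinite(val_mae):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")
        history.train_mae.append(float(np.mean(epoch_losses)))
        history.val_mae.append(val_mae)
        if verbose:
            print(f"epoch {epoch:3d}  train MAE {history.train_mae[-1]:.5f}  val MAE {val_mae:.5f}")
        if val_mae < best_val:
            best_val = val_mae
            history.best_epoch = epoch
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
        if ema is not None:
            model.set_weights(raw)
    model.set_weights(best_weights)
    return model, history


def evaluate_mae(model: UNet3D, x: np.ndarray, y: np.ndarray, batch_size: int = 8) -> float:
    """MAE of the model over a dataset (normalized scale), batched."""
    total = 0.0
    for start in range(0, len(x), batch_size):
        xb = x[start : start + batch_size]
        pred = model.forward(xb, train=False)
        total += float(np.abs(pred - y[start : start + batch_size]).sum())
    return total / y.size


def grid_search(
    configs: list[UNetConfig],
    train_data,
    val_data,
    seed: int = 0,
    train_fn=None,
):
    """Train every config and select the one with minimal validation MAE.

    Diverged runs are recorded (``converged=False``) and never selected.
    ``train_fn(cfg, train_data, val_data, seed)`` may be injected; it must
    return a (model, TrainingHistory) pair.  Returns (best config, table)
    where the table is a pandas DataFrame with one row per config.
    """
    import pandas as pd

    if not configs:
        raise ValueError("grid_search needs at least one config")

    def default_train(cfg, train_data, val_data, seed):
        model = build_model(cfg, seed=seed, input_shape=np.shape(train_data[0])[1:4])
        return train_model(model, train_data, val_data, cfg, seed=seed)

    train_fn = train_fn or default_train
    rows = []
    results = []
    for i, cfg in enumerate(configs):
        try:
            model, history = train_fn(cfg, train_data, val_data, seed)
            rows.append({**asdict(cfg), "val_mae": history.best_val_mae,
                         "best_epoch": history.best_epoch, "converged": True})
            results.append((model, history))
        except TrainingDiverged:
            rows.append({**asdict(cfg), "val_mae": np.nan, "best_epoch": -1,
                         "converged": False})
            results.append(None)
    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise TrainingDiverged("all hyperparameter configurations diverged")
    best_idx = int(table.loc[table["converged"], "val_mae"].idxmin())
    return configs[best_idx], table


def predict(
    model: UNet3D,
    density: np.ndarray,
    spec: NormalizationSpec,
    channel: str = "peak",
) -> DoseGrid:
    """Predict one noiseless dose grid from a (D, H, W) density matrix.

    The normalized prediction is mapped back to energy units with the
    training NormalizationSpec and floored at zero (energy deposition is
    non-negative); the fraction of floored voxels is available on the
    returned grid's ``.floored_fraction``.
    """
    density = np.asarray(density, dtype=float)
    if density.ndim != 3:
        raise ValueError("density must be a 3D lattice")
    x = normalize_input(density, spec)[None, ..., None]
    y01 = model.forward(x, train=False)[0, ..., 0]
    y = denormalize_target(y01, spec)
    floored = float((y < 0).mean())
    grid = DoseGrid(channel=channel, values=np.maximum(y, 0.0))
    grid.floored_fraction = floored
    return grid


# -- persistence ---------------------------------------------------------

def save_engine(path: str, model: UNet3D, spec: NormalizationSpec, channel: str) -> None:
    """Persist model weights, config and normalization spec together."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    meta = {"config": asdict(model.cfg), "normalization": asdict(spec), "channel": channel}
    arrays = {f"param_{i}": p for i, p in enumerate(model.params)}
    np.savez(path, meta=json.dumps(meta, sort_keys=True), **arrays)


def load_engine(path: str) -> tuple[UNet3D, NormalizationSpec, str]:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = UNet3D(UNetConfig(**meta["config"]))
        weights = [data[f"param_{i}"] for i in range(len(model.params))]
    model.set_weights(weights)
    return model, NormalizationSpec(**meta["normalization"]), meta["channel"]
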