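"""Survpatch: the parameter-budgeted convolutional patch regressor.

Survpatch maps a single S x S x 3 normalized tile to a predicted survival
time in days.  It is deliberately tiny: four [3x3 conv -> ReLU -> 2x2
max-pool] blocks with channel widths (8, 16, 24, 32), global average
pooling, one 32->16 dense layer, and a 16->1 linear output.  Global
average pooling makes the trainable-parameter count independent of the
input size, so the same architecture stays under the 33,000-parameter
budget at the scientific 512-pixel tile size and at the small tile sizes
used for testing.

Training uses Adam with mean absolute error loss on labels in raw days.
The learning rate at epoch e is ``initial_lr * lr_decay_per_epoch ** e``.
The output bias is initialized to the mean training label, so an
untrained-but-initialized model is the constant mean predictor and
gradient descent only has to learn deviations around it — with an
absolute-error loss the per-step parameter movement is on the order of
the learning rate, which would never bridge a several-hundred-day offset
from a zero start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from survbira._nn import (
    Adam,
    Conv3x3,
    Dense,
    GlobalAvgPool,
    MaxPool2x2,
    ReLU,
    Sequential,
    mae_loss,
)
from survbira.tiling import PatchRecord, augment_patch


@dataclass
class SurvpatchConfig:
    """Training recipe and architecture budget for the patch regressor."""

    epochs: int = 50
    initial_lr: float = 0.001
    lr_decay_per_epoch: float = 0.9
    batch_size: int = 32
    param_budget: int = 33_000
    seed: int = 0
    augment: bool = True
    conv_channels: tuple[int, ...] = (8, 16, 24, 32)
    dense_width: int = 16

    #: Fixed by design: linear output activation, mean absolute error loss.
    loss: str = field(default="mae", init=False)
    output_activation: str = field(default="linear", init=False)

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.lr_decay_per_epoch <= 1.0:
            raise ValueError("lr_decay_per_epoch must be in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class PatchRegressor:
    """A built (possibly trained) Survpatch model.

    Attributes
    ----------
    net : the underlying layer stack.
    n_params : trainable parameter count (checked against the budget).
    architecture : short human-readable descriptor.
    patch_size : tile side length the model was built for.
    """

    def __init__(self, config: SurvpatchConfig, patch_size: int) -> None:
        if patch_size < 32:
            raise ValueError(f"patch_size must be >= 32, got {patch_size}")
        self.config = config
        self.patch_size = patch_size
        rng = np.random.default_rng(config.seed)
        layers = []
        c_prev = 3
        for c in config.conv_channels:
            layers += [Conv3x3(c_prev, c, rng), ReLU(), MaxPool2x2()]
            c_prev = c
        layers += [
            GlobalAvgPool(),
            Dense(c_prev, config.dense_width, rng),
            ReLU(),
            Dense(config.dense_width, 1, rng),
        ]
        self.net = Sequential(layers)
        self.n_params = self.net.n_params()
        self.architecture = (
            "conv3x3 " + "-".join(map(str, config.conv_channels))
            + f" | GAP | dense {config.dense_width} | linear 1"
        )
        if self.n_params > config.param_budget:
            raise ValueError(
                f"architecture has {self.n_params} trainable parameters, "
                f"exceeding the budget of {config.param_budget}"
            )
        self.trained = False

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Predict survival days for a (N, S, S, 3) array of [0,1] tiles."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.patch_size or x.shape[3] != 3:
            raise ValueError(
                f"expected tiles of shape ({self.patch_size}, {self.patch_size}, 3), "
                f"got {x.shape[1:]}"
            )
        out = np.empty(len(x), dtype=np.float64)
        for i in range(0, len(x), batch_size):
            out[i : i + batch_size] = self.net.forward(x[i : i + batch_size])[:, 0]
        return out

    def save(self, path: str | Path) -> None:
        weights = self.net.get_weights()
        np.savez(
            path,
            patch_size=self.patch_size,
            seed=self.config.seed,
            conv_channels=np.array(self.config.conv_channels),
            dense_width=self.config.dense_width,
            trained=self.trained,
            **{f"w{i}": w for i, w in enumerate(weights)},
        )

    @classmethod
    def load(cls, path: str | Path) -> "PatchRegressor":
        data = np.load(path)
        config = SurvpatchConfig(
            seed=int(data["seed"]),
            conv_channels=tuple(int(c) for c in data["conv_channels"]),
            dense_width=int(data["dense_width"]),
        )
        model = cls(config, patch_size=int(data["patch_size"]))
        n = len(model.net.params)
        model.net.set_weights([data[f"w{i}"] for i in range(n)])
        model.trained = bool(data["trained"])
        return model


def build_survpatch(config: SurvpatchConfig, patch_size: int) -> PatchRegressor:
    """Build an untrained Survpatch model for the given tile size.

    Raises if the configured channel widths exceed the parameter budget.
    Weight initialization is seeded: the same config yields bit-identical
    initial weights.
    """
    return PatchRegressor(config, patch_size)


def _patch_array(patches: list[PatchRecord]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(p.pixels, dtype=np.float32) for p in patches])
    y = np.array([p.label_days for p in patches], dtype=np.float64)
    return x, y


def train_survpatch(
    model: PatchRegressor,
    patches: list[PatchRecord],
    config: SurvpatchConfig | None = None,
) -> tuple[PatchRegressor, list[dict]]:
    """Train the patch regressor with Adam and mean absolute error loss.

    Runs exactly ``config.epochs`` epochs; the learning rate at epoch e is
    ``initial_lr * lr_decay_per_epoch ** e``.  Patches are shuffled each
    epoch with the config seed; augmentation (random contrast / gamma /
    brightness) is applied on the fly when enabled.  Returns the model and
    a history of ``{"epoch", "lr", "loss"}`` dicts, one per epoch.
    """
    config = config or model.config
    if not patches:
        raise ValueError("cannot train on an empty patch list")
    x, y = _patch_array(patches)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("all patch labels must be finite positive survival days")
    if x.min() < 0 or x.max() > 1:
        raise ValueError("patches must be normalized to [0, 1] before training")

    # Start from the constant mean predictor (see module docstring).
    model.net.layers[-1].params[1][...] = np.float32(y.mean())

    optimizer = Adam(model.net.params, lr=config.initial_lr)
    rng = np.random.default_rng(config.seed)
    n = len(x)
    history: list[dict] = []
    for epoch in range(config.epochs):
        lr = config.initial_lr * config.lr_decay_per_epoch**epoch
        optimizer.lr = lr
        order = rng.permutation(n)
        losses: list[float] = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = x[idx]
            if config.augment:
                xb = np.stack(
                    [augment_patch(tile, rng).astype(np.float32) for tile in xb]
                )
            pred = model.net.forward(xb, train=True)
            loss, grad = mae_loss(pred, y[idx, None].astype(np.float32))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "check input scaling and learning rate"
                )
            model.net.backward(grad)
            optimizer.step(model.net.grads)
            losses.append(loss)
        history.append({"epoch": epoch, "lr": lr, "loss": float(np.mean(losses))})
    model.trained = True
    return model, history


def predict_patches(
    model: PatchRegressor, patches: list[PatchRecord]
) -> list[tuple[str, float]]:
    """Predict survival days for each patch; order matches the input.

    Returns ``(slide_id, predicted_days)`` pairs so callers can group the
    per-patch outputs by slide.
    """
    if not patches:
        return []
    x, _ = _patch_array(patches)
    preds = model.predict(x)
    return [(p.slide_id, float(v)) for p, v in zip(patches, preds)]
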