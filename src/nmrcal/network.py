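"""A compact 1-D convolutional network mapping a normalized spectrum to component areas.

Architecture: a single *locally connected* 1-D convolutional layer (no weight
sharing across positions — each window position owns its own kernel and bias)
with ELU activation, flattened into a fully connected output layer with ReLU
activation, one node per component. With kernel size 9, stride 9, 4 filters and
4 outputs on a 1692-point spectrum this has 10,532 trainable parameters:

    P = floor((L - kernel) / stride) + 1          output positions
    params = P*F*(kernel+1)  +  (P*F*K + K)       conv + dense head

Training minimizes mean squared error with Adam, a stepped learning-rate
schedule, and additive white Gaussian noise (AWGN) injected freshly into each
training batch as regularization — never at evaluation time. Inputs and labels
are min-max normalized to [0, 1] by their training maxima; predictions are
back-transformed by the stored label scale.

The whole network is implemented directly in NumPy (forward, backward, Adam):
at this size that is fast on a single CPU core and exactly reproducible from
one integer seed, which controls weight init, the train/validation split, batch
shuffling and the AWGN stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .augment import LabeledDataset

__all__ = [
    "AnnConfig",
    "TrainedModel",
    "TrainingHistory",
    "parameter_count",
    "build_model",
    "normalize",
    "split",
    "train",
    "fit_dataset",
    "predict",
    "mse_eval",
]


@dataclass(frozen=True)
class AnnConfig:
    """Hyperparameters of the compact CNN.

    ``lr_schedule`` maps epoch boundaries to learning rates: the rate of the
    last boundary not exceeding the current epoch applies. The default steps
    1e-4 -> 3e-5 -> 1e-5 at epochs 170 and 240 (a third announced step at 310
    repeats 1e-5 and is a no-op). ``conv_type`` may be ``"locally_connected"``
    (default) or ``"shared"`` for an ordinary weight-sharing convolution.
    """

    input_length: int = 1692
    output_nodes: int = 4
    kernel_size: int = 9
    strides: int = 9
    n_filters: int = 4
    conv_type: str = "locally_connected"
    batch_size: int = 1024
    awgn_std: float = 0.04
    lr_schedule: tuple[tuple[int, float], ...] = ((0, 1e-4), (170, 3e-5), (240, 1e-5), (310, 1e-5))
    epochs: int = 400
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    split_ratio: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_size > self.input_length:
            raise ValueError("kernel_size must be <= input_length")
        if self.conv_type not in ("locally_connected", "shared"):
            raise ValueError(f"unknown conv_type {self.conv_type!r}")
        if self.strides < 1 or self.kernel_size < 1 or self.n_filters < 1:
            raise ValueError("kernel_size, strides, n_filters must be >= 1")
        if any(lr <= 0 for _, lr in self.lr_schedule):
            raise ValueError("learning rates must be > 0")

    @property
    def n_positions(self) -> int:
        """P = floor((L - kernel) / stride) + 1."""
        return (self.input_length - self.kernel_size) // self.strides + 1

    def lr_at(self, epoch: int) -> float:
        lr = self.lr_schedule[0][1]
        for start, rate in sorted(self.lr_schedule):
            if epoch >= start:
                lr = rate
        return lr


def parameter_count(config: AnnConfig) -> int:
    """Closed-form trainable parameter count for the configured architecture."""
    p, f, k = config.n_positions, config.n_filters, config.output_nodes
    dense = p * f * k + k
    if config.conv_type == "locally_connected":
        conv = p * f * (config.kernel_size + 1)
    else:  # shared weights: one kernel + bias per filter
        conv = f * (config.kernel_size + 1)
    return conv + dense


@dataclass
class TrainingHistory:
    """Per-epoch training record: losses on normalized data, learning rate,
    and (optionally) the MSE against an experimental reference set in a.u."""

    epoch: list[int] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    ref_mse: list[float] = field(default_factory=list)


@dataclass
class TrainedModel:
    """CNN weights plus the normalization scalars needed at prediction time.

    ``x_scale`` = max of the training spectra, ``y_scale`` = max of the
    training labels; raw spectra are divided by ``x_scale`` before the forward
    pass and outputs multiplied by ``y_scale`` after it.
    """

    config: AnnConfig
    weights: dict[str, np.ndarray]
    x_scale: float = 1.0
    y_scale: float = 1.0

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights.values()))

    # ---- forward pass -----------------------------------------------------

    def _patches(self, x: np.ndarray) -> np.ndarray:
        c = self.config
        win = np.lib.stride_tricks.sliding_window_view(x, c.kernel_size, axis=1)
        return win[:, :: c.strides, :][:, : c.n_positions, :]  # (B, P, k)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, L) normalized. Returns (B, K) outputs, optionally the cache
        of intermediates for backprop."""
        c = self.config
        w = self.weights
        patches = self._patches(x)
        if c.conv_type == "locally_connected":
            # batched matmul over positions: (P,B,k) @ (P,k,F) -> (P,B,F)
            z1 = (patches.transpose(1, 0, 2) @ w["W1"]).transpose(1, 0, 2) + w["b1"]
        else:
            z1 = patches @ w["W1"] + w["b1"]
        a1 = np.where(z1 > 0, z1, np.expm1(z1))  # ELU
        a1f = a1.reshape(x.shape[0], -1)
        z2 = a1f @ w["W2"] + w["b2"]
        y = np.maximum(z2, 0.0)  # ReLU
        if want_cache:
            return y, (patches, z1, a1f, z2)
        return y

    def backward(self, cache, dly: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. all weights; ``dly`` = dLoss/dy, (B, K)."""
        c = self.config
        w = self.weights
        patches, z1, a1f, z2 = cache
        dz2 = dly * (z2 > 0)
        grads = {
            "W2": a1f.T @ dz2,
            "b2": dz2.sum(axis=0),
        }
        da1 = (dz2 @ w["W2"].T).reshape(z1.shape)
        dz1 = da1 * np.where(z1 > 0, 1.0, np.exp(z1))  # ELU'
        if c.conv_type == "locally_connected":
            grads["W1"] = patches.transpose(1, 2, 0) @ dz1.transpose(1, 0, 2)
            grads["b1"] = dz1.sum(axis=0)
        else:
            k = c.kernel_size
            grads["W1"] = patches.reshape(-1, k).T @ dz1.reshape(-1, c.n_filters)
            grads["b1"] = dz1.sum(axis=(0, 1))
        return grads


def build_model(config: AnnConfig) -> TrainedModel:
    """Construct an untrained model with Glorot-uniform weights drawn from
    ``config.seed``."""
    c = config
    rng = np.random.default_rng(c.seed)
    p, k, f, kk = c.n_positions, c.kernel_size, c.n_filters, c.output_nodes

    def glorot(shape, fan_in, fan_out):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, shape)

    if c.conv_type == "locally_connected":
        w1 = glorot((p, k, f), k, f)
        b1 = np.zeros((p, f))
    else:
        w1 = glorot((k, f), k, f)
        b1 = np.zeros(f)
    w2 = glorot((p * f, kk), p * f, kk)
    b2 = np.zeros(kk)
    model = TrainedModel(config=c, weights={"W1": w1, "b1": b1, "W2": w2, "b2": b2})
    assert model.n_parameters == parameter_count(c)
    return model


# ---------------------------------------------------------------------------
# data plumbing


def normalize(dataset: LabeledDataset) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Min-max normalize spectra and labels to [0, 1] by their global maxima.

    Returns ``(X', A', x_scale, y_scale)`` with ``X' = X / max(X)`` and
    ``A' = A / max(A)``; the scales are stored on the trained model so that
    measured spectra can be normalized identically at prediction time and
    predictions back-transformed to a.u.
    """
    x_scale = float(dataset.spectra.max())
    y_scale = float(dataset.labels.max())
    if x_scale <= 0 or y_scale <= 0:
        raise ValueError("dataset maxima must be positive to normalize")
    return dataset.spectra / x_scale, dataset.labels / y_scale, x_scale, y_scale


def split(
    dataset: LabeledDataset, ratio: float = 0.95, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded random split into disjoint train/validation subsets (default 95:5)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = dataset.n_spectra
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * ratio))
    tr, va = np.sort(perm[:n_train]), np.sort(perm[n_train:])

    def take(idx: np.ndarray) -> LabeledDataset:
        return LabeledDataset(
            spectra=dataset.spectra[idx],
            labels=dataset.labels[idx],
            params_log=dataset.params_log.iloc[idx].reset_index(drop=True),
            grid=dataset.grid,
            component_names=list(dataset.component_names),
            seed=dataset.seed,
            meta=dict(dataset.meta),
        )

    return take(tr), take(va)


# ---------------------------------------------------------------------------
# training


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(
    model: TrainedModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    reference: tuple[np.ndarray, np.ndarray] | None = None,
    epochs: int | None = None,
    verbose: bool = False,
) -> tuple[TrainedModel, TrainingHistory]:
    """Train with Adam on MSE loss, per-batch AWGN, and the stepped LR schedule.

    ``x_train``/``y_train`` are *normalized* arrays (see :func:`normalize`);
    set ``model.x_scale``/``model.y_scale`` before calling (or use
    :func:`fit_dataset` which wires everything). ``reference`` is an optional
    ``(spectra_au, areas_au)`` pair of *measured* data evaluated after every
    epoch: spectra are scaled by ``x_scale``, predictions back-transformed by
    ``y_scale`` and scored as MSE in a.u. — the second validation track.
    """
    c = model.config
    n_epochs = epochs if epochs is not None else c.epochs
    rng = np.random.default_rng(c.seed + 1)  # distinct from init stream
    n = x_train.shape[0]
    hist = TrainingHistory()
    w = model.weights
    mom = {k: np.zeros_like(v) for k, v in w.items()}
    vel = {k: np.zeros_like(v) for k, v in w.items()}
    t = 0

    for epoch in range(n_epochs):
        lr = c.lr_at(epoch)
        perm = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, c.batch_size):
            idx = perm[start : start + c.batch_size]
            xb = x_train[idx]
            if c.awgn_std > 0:
                xb = xb + rng.normal(0.0, c.awgn_std, xb.shape)
            yb = y_train[idx]
            pred, cache = model.forward(xb, want_cache=True)
            loss = _mse(pred, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; "
                    "inspect input scaling and learning rate"
                )
            batch_losses.append(loss)
            dly = 2.0 * (pred - yb) / pred.size
            grads = model.backward(cache, dly)
            t += 1
            for key in w:
                mom[key] = c.adam_beta1 * mom[key] + (1 - c.adam_beta1) * grads[key]
                vel[key] = c.adam_beta2 * vel[key] + (1 - c.adam_beta2) * grads[key] ** 2
                mhat = mom[key] / (1 - c.adam_beta1**t)
                vhat = vel[key] / (1 - c.adam_beta2**t)
                w[key] -= lr * mhat / (np.sqrt(vhat) + c.adam_eps)

        hist.epoch.append(epoch)
        hist.lr.append(lr)
        hist.train_loss.append(float(np.mean(batch_losses)))
        if x_val is not None:
            hist.val_loss.append(_mse(model.forward(x_val), y_val))
        if reference is not None:
            ref_x, ref_y = reference
            pred_au = predict(model, ref_x)
            hist.ref_mse.append(_mse(pred_au, ref_y))
        if verbose:
            msg = f"epoch {epoch:3d}  lr {lr:.1e}  train {hist.train_loss[-1]:.3e}"
            if hist.val_loss:
                msg += f"  val {hist.val_loss[-1]:.3e}"
            if hist.ref_mse:
                msg += f"  ref_mse {hist.ref_mse[-1]:.3e}"
            print(msg)
    return model, hist


def fit_dataset(
    dataset: LabeledDataset,
    config: AnnConfig | None = None,
    reference: tuple[np.ndarray, np.ndarray] | None = None,
    epochs: int | None = None,
    verbose: bool = False,
) -> tuple[TrainedModel, TrainingHistory]:
    """End-to-end convenience: normalize, split, build, train.

    The config's ``input_length``/``output_nodes`` are adapted to the dataset.
    """
    config = config or AnnConfig()
    config = replace(
        config,
        input_length=dataset.spectra.shape[1],
        output_nodes=dataset.labels.shape[1],
    )
    xn, yn, x_scale, y_scale = normalize(dataset)
    rng_split_seed = config.seed
    n = xn.shape[0]
    rng = np.random.default_rng(rng_split_seed)
    perm = rng.permutation(n)
    n_train = int(round(n * config.split_ratio))
    tr, va = perm[:n_train], perm[n_train:]
    model = build_model(config)
    model.x_scale, model.y_scale = x_scale, y_scale
    return train(
        model, xn[tr], yn[tr], xn[va], yn[va],
        reference=reference, epochs=epochs, verbose=verbose,
    )


def predict(model: TrainedModel, spectra: np.ndarray) -> np.ndarray:
    """Predict component areas (a.u.) from raw spectra on the training grid.

    Accepts a single spectrum ``(L,)`` or a batch ``(n, L)``; outputs are
    non-negative by construction (ReLU head). Deterministic: no noise is
    applied at prediction time.
    """
    x = np.asarray(spectra, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.config.input_length:
        raise ValueError(
            f"spectrum length {x.shape[1]} does not match the model input "
            f"length {model.config.input_length}"
        )
    out = model.forward(x / model.x_scale) * model.y_scale
    return out[0] if single else out


def mse_eval(pred: np.ndarray, ref: np.ndarray) -> tuple[float, np.ndarray]:
    """Overall and per-component mean squared error between predicted and
    reference areas of equal shape ``(n, K)``."""
    pred = np.asarray(pred, float)
    ref = np.asarray(ref, float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {ref.shape}")
    sq = (pred - ref) ** 2
    return float(sq.mean()), sq.mean(axis=0)
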