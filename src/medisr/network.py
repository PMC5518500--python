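"""Hybrid super-resolution network: fixed bicubic layer + trainable convs.

Architecture (single luminance channel, intensities in [0, 1]):

    Y  = template_upscale(lr)                # fixed integer-template layer
    F2 = relu(W2 * Y  + B2)                  # patch extraction, f2 x f2, n2 filters
    F3 = relu(W3 * F2 + B3)                  # nonlinear mapping, 1 x 1, n3 filters
    F4 = W4 * F3 + B4                        # linear reconstruction, f3 x f3

The first layer is a constant — its weights are the exact integer
bicubic templates and never receive gradient — while {W2, B2, W3, B3,
W4, B4} are trained by minimising the mean squared error to the
ground-truth patch with plain stochastic gradient descent and
backpropagation.  Convolutions use "same" zero padding so every feature
map keeps the upscaled spatial size.

All convolution arithmetic is vectorised through sliding windows and
einsum; the backward pass is hand-derived and validated against central
finite differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataprep import TrainingPair
from .templates import TemplateBank, build_template_bank
from .upscale import upscale4

PARAM_NAMES = ("W2", "B2", "W3", "B3", "W4", "B4")


@dataclass(frozen=True)
class LayerSpec:
    filter_size: int
    n_filters: int
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.filter_size % 2 == 0 or self.filter_size < 1 or self.filter_size > 9:
            raise ValueError(f"filter size must be odd in 1..9, got {self.filter_size}")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class TrainState:
    """Bookkeeping for one training run."""

    epoch: int = 0
    learning_rate: float = 0.03
    batch_size: int = 10
    loss_history: List[float] = field(default_factory=list)
    rng_seed: int = 0


def _conv_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'same' zero-padded cross-correlation.

    x: (N, C, H, W); w: (K, C, f, f); b: (K,) -> (N, K, H, W)
    """
    f = w.shape[-1]
    pad = f // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (f, f), axis=(2, 3))  # (N, C, H, W, f, f)
    return np.einsum("nchwij,kcij->nkhw", win, w, optimize=True) + b[None, :, None, None]


def _conv_backward(
    x: np.ndarray, w: np.ndarray, dy: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of _conv_same w.r.t. x, w, b given upstream dy."""
    f = w.shape[-1]
    pad = f // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (f, f), axis=(2, 3))
    dw = np.einsum("nchwij,nkhw->kcij", win, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    # dx: full correlation of dy with the flipped kernel.
    dyp = np.pad(dy, ((0, 0), (0, 0), (f - 1, f - 1), (f - 1, f - 1)))
    dwin = sliding_window_view(dyp, (f, f), axis=(2, 3))  # (N, K, H + 2pad, W + 2pad, f, f)
    wf = w[:, :, ::-1, ::-1]
    dxp = np.einsum("nkhwij,kcij->nchw", dwin, wf, optimize=True)
    h, wd = x.shape[2], x.shape[3]
    return dxp[:, :, pad : pad + h, pad : pad + wd], dw, db


class HybridNetwork:
    """Fixed template layer plus three trainable convolutional stages.

    Parameters
    ----------
    f2, n2 : patch-extraction filter size and count (default 9, 64)
    n3 : nonlinear-mapping width, always 1x1 filters (default 32)
    f3 : reconstruction filter size (default 5)
    init : {"identity", "gaussian"}
        "identity" threads a pass-through path (centre-one stencils on
        one filter chain) plus small Gaussian perturbations, so the
        untrained network starts at the bicubic baseline; "gaussian"
        draws all weights from N(0, init_std^2).
    """

    def __init__(
        self,
        bank: TemplateBank | None = None,
        f2: int = 9,
        n2: int = 64,
        n3: int = 32,
        f3: int = 5,
        seed: int = 0,
        init: str = "identity",
        init_std: float = 1e-3,
        border: str = "replicate",
    ) -> None:
        self.bank = bank if bank is not None else build_template_bank()
        self.layer_specs = (
            LayerSpec(f2, n2, "relu"),
            LayerSpec(1, n3, "relu"),
            LayerSpec(f3, 1, "linear"),
        )
        self.border = border
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.params: Dict[str, np.ndarray] = {
            "W2": rng.normal(0.0, init_std, (n2, 1, f2, f2)),
            "B2": np.zeros(n2),
            "W3": rng.normal(0.0, init_std, (n3, n2, 1, 1)),
            "B3": np.zeros(n3),
            "W4": rng.normal(0.0, init_std, (1, n3, f3, f3)),
            "B4": np.zeros(1),
        }
        if init == "identity":
            self.params["W2"][0, 0, f2 // 2, f2 // 2] += 1.0
            self.params["W3"][0, 0, 0, 0] += 1.0
            self.params["W4"][0, 0, f3 // 2, f3 // 2] += 1.0
        elif init != "gaussian":
            raise ValueError(f"unknown init {init!r}")

    # ----------------------------------------------------------- forward
    def template_layer(self, lr_image: np.ndarray) -> np.ndarray:
        """The fixed layer: x4 bicubic upscale via the integer templates.

        Uses the centre-aligned subcell assignment so the upscaled grid
        registers with area-averaged ground truth (the two conventions
        differ by an exact 2-HR-pixel translation; the stencils are
        identical).
        """
        return upscale4(
            np.asarray(lr_image, dtype=np.float64), self.bank, border=self.border,
            clamp=False, grid="centered",
        )

    def _check_shapes(self) -> None:
        (s2, s3, s4) = self.layer_specs
        expect = {
            "W2": (s2.n_filters, 1, s2.filter_size, s2.filter_size),
            "W3": (s3.n_filters, s2.n_filters, 1, 1),
            "W4": (1, s3.n_filters, s4.filter_size, s4.filter_size),
        }
        for name, shape in expect.items():
            if self.params[name].shape != shape:
                raise ValueError(f"{name} has shape {self.params[name].shape}, expected {shape}")

    def forward_batch(self, y: np.ndarray, cache: bool = False):
        """Run layers 2-4 on upscaled inputs y of shape (N, H, W)."""
        self._check_shapes()
        p = self.params
        y = y[:, None]  # (N, 1, H, W)
        z2 = _conv_same(y, p["W2"], p["B2"])
        a2 = np.maximum(z2, 0.0)
        z3 = _conv_same(a2, p["W3"], p["B3"])
        a3 = np.maximum(z3, 0.0)
        out = _conv_same(a3, p["W4"], p["B4"])[:, 0]
        if cache:
            return out, {"y": y, "z2": z2, "a2": a2, "z3": z3, "a3": a3}
        return out

    def forward(self, lr_image: np.ndarray) -> np.ndarray:
        """Super-resolve one LR image (unit-interval intensities)."""
        y = self.template_layer(lr_image)
        return self.forward_batch(y[None])[0]

    # ---------------------------------------------------------- training
    def loss_and_grads(self, y: np.ndarray, x: np.ndarray):
        """MSE loss over a batch and gradients for all trainable tensors.

        y: (N, H, W) template-layer outputs; x: (N, H, W) ground truth.
        The loss is the mean over samples and pixels of the squared
        residual.
        """
        p = self.params
        out, c = self.forward_batch(y, cache=True)
        resid = out - x
        with np.errstate(over="ignore", invalid="ignore"):
            loss = float(np.mean(resid**2))
        dout = (2.0 / resid.size) * resid[:, None]
        da3, dW4, dB4 = _conv_backward(c["a3"], p["W4"], dout)
        dz3 = da3 * (c["z3"] > 0)
        da2, dW3, dB3 = _conv_backward(c["a2"], p["W3"], dz3)
        dz2 = da2 * (c["z2"] > 0)
        _, dW2, dB2 = _conv_backward(c["y"], p["W2"], dz2)
        grads = {"W2": dW2, "B2": dB2, "W3": dW3, "B3": dB3, "W4": dW4, "B4": dB4}
        return loss, grads

    def train(
        self,
        pairs: Sequence[TrainingPair],
        epochs: int = 100,
        learning_rate: float = 0.03,
        batch_size: int = 10,
        seed: int = 0,
        momentum: float = 0.0,
        scale: float = 255.0,
        callback=None,
    ) -> TrainState:
        """Fit {W2..B4} by mini-batch SGD on MSE; the template layer is frozen.

        Intensities are normalised by ``scale`` (255 for 8-bit pairs).
        Training is fully reproducible from ``seed`` (shuffling and any
        weight noise derive from it).  Divergence (non-finite loss)
        aborts with a diagnostic.
        """
        if not pairs:
            raise ValueError("training requires at least one pair")
        y = np.stack([self.template_layer(p.lr / scale) for p in pairs])
        x = np.stack([np.asarray(p.hr, dtype=np.float64) / scale for p in pairs])
        if y.shape != x.shape:
            raise ValueError(f"upscaled LR shape {y.shape} != HR shape {x.shape}")
        n = len(pairs)
        state = TrainState(learning_rate=learning_rate, batch_size=batch_size, rng_seed=seed)
        rng = np.random.default_rng(seed)
        velocity = {k: np.zeros_like(v) for k, v in self.params.items()}
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                loss, grads = self.loss_and_grads(y[idx], x[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch}: loss = {loss}; "
                        "reduce the learning rate"
                    )
                epoch_loss += loss * len(idx)
                for k, g in grads.items():
                    if momentum > 0:
                        velocity[k] = momentum * velocity[k] - learning_rate * g
                        self.params[k] = self.params[k] + velocity[k]
                    else:
                        self.params[k] = self.params[k] - learning_rate * g
            state.epoch = epoch + 1
            state.loss_history.append(epoch_loss / n)
            if callback is not None:
                callback(state)
        return state


def mse_loss(predicted: np.ndarray, ground_truth: np.ndarray) -> float:
    """Mean squared error between two equal-shape images or stacks."""
    predicted = np.asarray(predicted, dtype=np.float64)
    ground_truth = np.asarray(ground_truth, dtype=np.float64)
    if predicted.shape != ground_truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {ground_truth.shape}")
    return float(np.mean((predicted - ground_truth) ** 2))
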