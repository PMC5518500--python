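"""Model/Results front end for the hybrid super-resolver.

`SuperResolutionModel` holds the training data and architecture;
``fit()`` runs SGD and returns a `SuperResolutionResults` carrying the
fitted parameters, the loss trajectory and diagnostics, with
``predict`` for super-resolving new images, ``summary()`` for a fitted
report and HDF5 round-tripping.
"""

from __future__ import annotations

import json
from typing import Dict, List, Sequence

import h5py
import numpy as np

from .dataprep import TrainingPair, build_training_set
from .metrics import psnr
from .network import PARAM_NAMES, HybridNetwork, TrainState
from .upscale import upscale4


class SuperResolutionModel:
    """x4 single-image super-resolution fitted to (LR, HR) pairs.

    Parameters
    ----------
    pairs : sequence of TrainingPair
        LR patches one quarter the side length of their HR ground truth.
    f2, n2, n3, f3 : architecture of the trainable stages.
    scale : intensity normalisation (255 for 8-bit data).
    seed : seeds weight initialisation.
    """

    def __init__(
        self,
        pairs: Sequence[TrainingPair],
        f2: int = 9,
        n2: int = 64,
        n3: int = 32,
        f3: int = 5,
        init: str = "identity",
        border: str = "replicate",
        scale: float = 255.0,
        seed: int = 0,
    ) -> None:
        if not pairs:
            raise ValueError("SuperResolutionModel needs at least one training pair")
        self.pairs = list(pairs)
        self.scale = scale
        self.network = HybridNetwork(
            f2=f2, n2=n2, n3=n3, f3=f3, seed=seed, init=init, border=border
        )

    @classmethod
    def from_corpus(
        cls,
        images: Sequence[np.ndarray],
        n_patches: int,
        patch_size: int = 128,
        factor: int = 4,
        seed: int = 0,
        **kwargs,
    ) -> "SuperResolutionModel":
        """Build the model straight from a corpus of HR images."""
        pairs = build_training_set(images, count=n_patches, size=patch_size, factor=factor, seed=seed)
        return cls(pairs, seed=seed, **kwargs)

    def fit(
        self,
        epochs: int = 100,
        learning_rate: float = 0.03,
        batch_size: int = 10,
        seed: int = 0,
        momentum: float = 0.0,
    ) -> "SuperResolutionResults":
        state = self.network.train(
            self.pairs,
            epochs=epochs,
            learning_rate=learning_rate,
            batch_size=batch_size,
            seed=seed,
            momentum=momentum,
            scale=self.scale,
        )
        return SuperResolutionResults(self, state)


class SuperResolutionResults:
    """Fitted parameters, loss history and prediction for the hybrid net."""

    def __init__(self, model: SuperResolutionModel, train_state: TrainState) -> None:
        self.model = model
        self.train_state = train_state
        self.params: Dict[str, np.ndarray] = {k: v.copy() for k, v in model.network.params.items()}

    @property
    def loss_history(self) -> List[float]:
        return list(self.train_state.loss_history)

    @property
    def final_loss(self) -> float:
        return self.train_state.loss_history[-1]

    def predict(self, lr_image: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Super-resolve an LR image; returns intensities on the data scale."""
        lr = np.asarray(lr_image, dtype=np.float64) / self.model.scale
        out = self.model.network.forward(lr) * self.model.scale
        if clamp:
            out = np.clip(out, 0.0, self.model.scale)
        return out

    def baseline(self, lr_image: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Template-layer-only (bicubic) upscale on the data scale."""
        lr = np.asarray(lr_image, dtype=np.float64) / self.model.scale
        out = upscale4(
            lr, self.model.network.bank, border=self.model.network.border,
            clamp=False, grid="centered",
        )
        out = out * self.model.scale
        if clamp:
            out = np.clip(out, 0.0, self.model.scale)
        return out

    def training_psnr(self) -> float:
        """Mean PSNR of the fitted network over the training pairs."""
        vals = []
        for p in self.model.pairs:
            pred = self.predict(p.lr)
            vals.append(psnr(p.hr, pred).psnr_db)
        return float(np.mean(vals))

    def summary(self) -> str:
        net = self.model.network
        s2, s3, s4 = net.layer_specs
        hist = self.train_state.loss_history
        lines = [
            "          Hybrid Super-Resolution Results",
            "=" * 56,
            f"{'Training pairs:':<28}{len(self.model.pairs)}",
            f"{'Upscale factor:':<28}4 (fixed bicubic template layer)",
            f"{'Layer 2 (patch extract):':<28}{s2.filter_size}x{s2.filter_size}, {s2.n_filters} filters, relu",
            f"{'Layer 3 (nonlinear map):':<28}1x1, {s3.n_filters} filters, relu",
            f"{'Layer 4 (reconstruction):':<28}{s4.filter_size}x{s4.filter_size}, linear",
            f"{'Trainable parameters:':<28}{sum(v.size for v in self.params.values())}",
            f"{'Epochs:':<28}{self.train_state.epoch}",
            f"{'Learning rate:':<28}{self.train_state.learning_rate}",
            f"{'Batch size:':<28}{self.train_state.batch_size}",
            f"{'Initial loss (MSE):':<28}{hist[0]:.6g}" if hist else "",
            f"{'Final loss (MSE):':<28}{hist[-1]:.6g}" if hist else "",
            f"{'Training PSNR (dB):':<28}{self.training_psnr():.2f}",
            "=" * 56,
        ]
        return "\n".join(line for line in lines if line)

    # -------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Serialise weights, layer specs, seed and loss history to HDF5."""
        net = self.model.network
        with h5py.File(path, "w") as f:
            for name in PARAM_NAMES:
                f.create_dataset(name, data=self.params[name])
            f.attrs["layer_specs"] = json.dumps(
                [
                    {"filter_size": s.filter_size, "n_filters": s.n_filters, "activation": s.activation}
                    for s in net.layer_specs
                ]
            )
            f.attrs["scale"] = self.model.scale
            f.attrs["border"] = net.border
            f.attrs["seed"] = self.train_state.rng_seed
            f.create_dataset("loss_history", data=np.asarray(self.train_state.loss_history))


def load_network(path) -> HybridNetwork:
    """Rebuild a HybridNetwork (with trained weights) from an HDF5 file."""
    with h5py.File(path, "r") as f:
        specs = json.loads(f.attrs["layer_specs"])
        net = HybridNetwork(
            f2=specs[0]["filter_size"],
            n2=specs[0]["n_filters"],
            n3=specs[1]["n_filters"],
            f3=specs[2]["filter_size"],
            border=str(f.attrs.get("border", "replicate")),
            init="gaussian",
            init_std=0.0,
        )
        for name in PARAM_NAMES:
            net.params[name] = np.asarray(f[name])
    net._check_shapes()
    return net
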