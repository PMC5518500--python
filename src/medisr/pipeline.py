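"""End-to-end orchestration: prepare -> select -> train -> super-resolve -> evaluate.

A `PipelineConfig` fully determines a run: paths, seeds, architecture,
training hyperparameters and selection thresholds.  Every run report
embeds the resolved config and a content hash of it, so artifacts on
disk are traceable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import dataprep, fixtures, metrics, sift
from .io import read_image, write_image
from .model import SuperResolutionModel

log = logging.getLogger("medisr")


@dataclass
class PipelineConfig:
    # data
    corpus_dir: Optional[str] = None  # pool of candidate HR images
    reference_dir: Optional[str] = None  # small target-domain reference set
    out_dir: str = "medisr_run"
    n_fixture_images: int = 8  # used when corpus_dir is None (synthetic corpus)
    fixture_size: int = 96
    # patching
    n_patches: int = 50
    patch_size: int = 32
    factor: int = 4
    # selection
    use_selection: bool = True
    crop_size: int = 64
    crop_stride: int = 32
    match_ratio_test: float = 0.8
    # architecture
    f2: int = 9
    n2: int = 64
    n3: int = 32
    f3: int = 5
    border: str = "replicate"
    # training
    epochs: int = 100
    learning_rate: float = 0.03
    batch_size: int = 10
    seed: int = 0
    # evaluation
    n_eval_images: int = 4
    eval_size: int = 64

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _load_dir(path: str) -> List[np.ndarray]:
    files = sorted(
        p for p in Path(path).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise FileNotFoundError(f"no PNG/TIFF images in {path}")
    return [read_image(p) for p in files]


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute the full flow and return a JSON-serialisable run report.

    Stages: (1) corpus assembly (synthetic fixtures when no corpus dir
    is given), (2) SIFT-based selection of candidate subregions against
    the references, (3) paired training-set construction, (4) SGD
    training of the hybrid network, (5) held-out evaluation: ground
    truth -> x4 scale-down -> network -> PSNR against ground truth.
    Any stage failure raises with a stage-tagged message.
    """
    report: Dict = {"config": json.loads(config.to_json()), "config_hash": config.content_hash()}
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "corpus"
    try:
        if config.corpus_dir:
            corpus = _load_dir(config.corpus_dir)
        else:
            specs = fixtures.default_corpus_specs(
                config.n_fixture_images, base_seed=config.seed, height=config.fixture_size,
                width=config.fixture_size,
            )
            corpus = [fixtures.generate(s) for s in specs]
        if config.reference_dir:
            references = _load_dir(config.reference_dir)
        else:
            ref_specs = fixtures.default_corpus_specs(
                2, base_seed=config.seed + 1000, height=config.fixture_size, width=config.fixture_size
            )
            references = [fixtures.generate(s) for s in ref_specs]
        report["corpus"] = {"n_images": len(corpus), "n_references": len(references)}

        stage = "selection"
        if config.use_selection:
            ref_sets = [
                sift.extract_features(img, image_id=f"ref{i}") for i, img in enumerate(references)
            ]
            selected: List[np.ndarray] = []
            decisions = []
            for i, img in enumerate(corpus):
                for tid, box, crop in sift.tile_candidates(
                    img, f"img{i}", size=config.crop_size, stride=config.crop_stride
                ):
                    cand = sift.extract_features(crop, image_id=tid)
                    dec = sift.select_candidates(
                        [cand], ref_sets, sift.SelectionConfig(match_ratio_test=config.match_ratio_test)
                    )[0]
                    decisions.append(
                        {"id": tid, "box": list(box), "D": dec.D, "eta": dec.eta, "admitted": dec.admitted}
                    )
                    if dec.admitted:
                        selected.append(crop)
            # references always belong to the training corpus
            train_images = references + selected
            report["selection"] = {
                "n_candidates": len(decisions),
                "n_admitted": sum(d["admitted"] for d in decisions),
                "decisions": decisions,
            }
        else:
            train_images = references + corpus
            report["selection"] = {"skipped": True}
        log.info("selection done: %d training images", len(train_images))

        stage = "data_prep"
        train_images = [img for img in train_images if min(img.shape) >= config.patch_size]
        if not train_images:
            raise ValueError("no training image is large enough for the patch size")
        pairs = dataprep.build_training_set(
            train_images, count=config.n_patches, size=config.patch_size,
            factor=config.factor, seed=config.seed,
        )
        report["data_prep"] = {"n_pairs": len(pairs), "patch_size": config.patch_size}

        stage = "training"
        model = SuperResolutionModel(
            pairs, f2=config.f2, n2=config.n2, n3=config.n3, f3=config.f3,
            border=config.border, seed=config.seed,
        )
        results = model.fit(
            epochs=config.epochs, learning_rate=config.learning_rate,
            batch_size=config.batch_size, seed=config.seed,
        )
        model_path = out_dir / "model.h5"
        results.save(model_path)
        report["training"] = {
            "epochs": config.epochs,
            "initial_loss": results.loss_history[0],
            "final_loss": results.final_loss,
            "model_path": str(model_path),
        }

        stage = "evaluation"
        eval_specs = fixtures.default_corpus_specs(
            config.n_eval_images, base_seed=config.seed + 5000,
            height=config.eval_size, width=config.eval_size,
        )
        rows = []
        for i, spec in enumerate(eval_specs):
            gt = fixtures.generate(spec).astype(np.float64)
            lr = dataprep.scale_down(gt, factor=config.factor)
            sr = results.predict(lr)
            base = results.baseline(lr)
            rows.append(
                {
                    "image": f"eval{i}_{spec.kind}",
                    "psnr_network": metrics.psnr(gt, sr).psnr_db,
                    "psnr_bicubic": metrics.psnr(gt, base).psnr_db,
                }
            )
            write_image(out_dir / f"eval{i}_sr.png", sr)
        report["evaluation"] = {"images": rows}
    except Exception as exc:  # noqa: BLE001 - re-tag with the failing stage
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
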