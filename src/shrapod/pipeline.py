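"""End-to-end pipeline: synth → anchors → train → predict → evaluate → triage.

Every stage draws its randomness from a named substream of one global
seed, so a rerun with the same configuration reproduces the same
artifacts.  The output directory receives the dataset (PNG + COCO
JSON), the model checkpoint, training curves, the evaluation report,
the triage report, and a manifest listing every artifact with its
SHA-256 hash.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .boxes import CLASSES
from .evaluation import evaluate_dataset
from .io import (boxes_to_csv, save_png, sha256_file, write_coco,
                 write_detections)
from .model import (ArchSpec, TrainConfig, build_model, estimate_anchors,
                    predict_batch, save_model, train)
from .synth import PhantomConfig, generate_phantom, split_dataset
from .triage import (DEFAULT_MULTIPLIERS, gate, reference_diameter,
                     triage_image)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("shrapod")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig.desk)
    arch: ArchSpec = field(default_factory=ArchSpec.desk)
    train: TrainConfig = field(default_factory=TrainConfig.desk)
    n_images: int = 200
    fractions: tuple[float, float, float] = (0.75, 0.10, 0.15)
    iou_min: float = 0.5
    conf_threshold: float = 0.5
    nms_iou: float = 0.5
    multipliers: tuple[float, ...] = DEFAULT_MULTIPLIERS
    run_triage: bool = True
    #: Override of the coarse/fine anchor partition (None: larger half
    #: coarse); small frames profit from weighting the fine head.
    anchor_n_coarse: int | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.arch.input_size != self.phantom.image_size:
            raise ValueError("arch input size must match phantom image size")
        if self.n_images < 3:
            raise ValueError("need at least 3 images")

    def substream(self, name: str) -> int:
        """Derived deterministic per-stage seed (below 2^31)."""
        import zlib

        h = np.random.SeedSequence(
            [self.seed, zlib.crc32(name.encode())]).generate_state(1)[0]
        return int(h % (2 ** 31))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run all stages; returns a dict of result objects and paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    results: dict = {"out_dir": out}
    stage = "init"
    try:
        # ---- synth ----------------------------------------------------------
        stage = "synth"
        pcfg = config.phantom.with_(rng_seed=config.substream("synth"))
        images = [generate_phantom(pcfg, i) for i in range(config.n_images)]
        n_boxes = sum(len(im.boxes) for im in images)
        log.info("synth: %d images, %d boxes", len(images), n_boxes)
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        names = []
        for i, im in enumerate(images):
            name = f"{i:06d}.png"
            save_png(im.pixels, img_dir / name)
            names.append(name)
        ann_path = out / "annotations.json"
        write_coco(images, ann_path, names)
        boxes_to_csv([im.boxes for im in images], out / "annotations.csv")
        artifacts += [ann_path, out / "annotations.csv"]

        # ---- split + anchors ------------------------------------------------
        stage = "split"
        tr, va, te = split_dataset(images, config.fractions,
                                   seed=config.substream("split"))
        log.info("split: %d train / %d val / %d test", len(tr), len(va), len(te))

        stage = "anchors"
        train_boxes = [b for im in tr for b in im.boxes]
        k = min(config.train.n_anchors,
                len({(b.w, b.h) for b in train_boxes}))
        anchors = estimate_anchors(train_boxes, k=k,
                                   seed=config.substream("anchors"),
                                   n_coarse=(min(config.anchor_n_coarse, k - 1)
                                             if config.anchor_n_coarse else None))

        # ---- train ----------------------------------------------------------
        stage = "train"
        model = build_model(config.arch, anchors,
                            seed=config.substream("model"))
        tcfg = TrainConfig(**{**asdict(config.train),
                              "seed": config.substream("train")})
        model, history = train(model, tr, va, tcfg)
        ckpt = out / "model.npz"
        save_model(model, ckpt)
        import yaml

        (out / "arch.yaml").write_text(yaml.safe_dump({
            "arch": asdict(config.arch),
            "anchors": [list(a) for a in anchors.anchors],
            "n_coarse": anchors.n_coarse,
        }))
        history.to_csv(out / "training_curves.csv", index=False)
        artifacts += [ckpt, out / "arch.yaml", out / "training_curves.csv"]
        results.update(model=model, history=history, anchors=anchors)

        # ---- predict --------------------------------------------------------
        stage = "predict"
        test_dets = predict_batch(model, [im.pixels for im in te],
                                  config.conf_threshold, config.nms_iou)
        det_path = out / "detections.json"
        write_detections(test_dets, det_path)
        artifacts.append(det_path)
        log.info("predict: %d detections on %d test images",
                 sum(map(len, test_dets)), len(te))

        # ---- evaluate -------------------------------------------------------
        stage = "evaluate"
        truths = [im.boxes for im in te]
        table, summaries, curves = evaluate_dataset(
            test_dets, truths, CLASSES, config.iou_min)
        table.to_csv(out / "evaluation.csv")
        (out / "evaluation.json").write_text(
            table.to_json(orient="columns", indent=1))
        for cls, c in curves.items():
            c.to_frame().to_csv(out / f"pr_curve_{cls}.csv", index=False)
            artifacts.append(out / f"pr_curve_{cls}.csv")
        artifacts += [out / "evaluation.csv", out / "evaluation.json"]
        results.update(evaluation=table, summaries=summaries,
                       test_detections=test_dets, test_images=te)

        # ---- triage ---------------------------------------------------------
        if config.run_triage:
            stage = "triage"
            records = []
            for i, dets in enumerate(test_dets):
                rec = triage_image(dets, image_id=i)
                if rec is not None:
                    records.append(rec)
            ref = reference_diameter(
                [b for im in te for b in im.boxes if b.label == "artery"])
            summary = gate(records, ref, config.multipliers)
            log.info("triage: %d/%d test images kept (all four classes)",
                     len(records), len(te))
            rows = [{"image_id": r.image_id, "d_vein": r.d_vein,
                     "d_artery": r.d_artery, "d_nerve": r.d_nerve,
                     "d_min": r.d_min, "closest": r.closest,
                     **{f"flag_{m}x": v for m, v in r.flags.items()}}
                    for r in records]
            pd.DataFrame(rows).to_csv(out / "triage_records.csv", index=False)
            (out / "triage_summary.json").write_text(json.dumps({
                "n_images": summary.n_images,
                "mean_d_min": summary.mean_d_min,
                "reference_diameter": summary.reference_diameter,
                "feature_stats": summary.feature_stats,
                "closest_frequency_pct": summary.closest_frequency,
                "flagged_pct": {str(m): v for m, v in summary.flagged_pct.items()},
            }, indent=1))
            artifacts += [out / "triage_records.csv", out / "triage_summary.json"]
            results.update(triage_records=records, triage_summary=summary)

        # ---- manifest -------------------------------------------------------
        stage = "manifest"
        cfg_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
        lines = [f"config_sha256 {__import__('hashlib').sha256(cfg_json.encode()).hexdigest()}",
                 f"seed {config.seed}"]
        for p in artifacts:
            lines.append(f"{sha256_file(p)}  {p.relative_to(out)}")
        (out / "manifest.txt").write_text("\n".join(lines) + "\n")
        return results
    except Exception as exc:  # noqa: BLE001 - annotate stage then re-raise
        log.error("pipeline failed in stage %r; removing partial artifacts",
                  stage)
        for p in artifacts:
            Path(p).unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
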