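"""End-to-end orchestration: phantom data -> two translation models ->
quality-driven checkpoint selection -> conversion -> separability test.

Two models are trained from the same originals (macular_cube -> seven_lines
and the reverse).  Checkpoints of the model generating the clean preset are
ranked by mean quality score and the lowest-scoring epoch is selected; for
the model generating the noisy preset the highest-scoring epoch is selected.
Every stage is seeded from the master seed and writes its artefacts under the
output root; a run-level JSON manifest records stages, inputs, outputs and
seeds (timings are stored separately so that manifests of identical runs are
byte-identical).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import phantom as ph
from .cutgan import CUTModel, TrainingConfig
from . import quality as q
from .separability import (ClassifierConfig, PresetClassifier, SplitSpec,
                           synthetic_separability_test)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


@dataclass(frozen=True)
class PipelineConfig:
    out_root: Path
    seed: int = 0
    n_per_preset: int = 100
    image_size: int = 64
    cube_to_seven: TrainingConfig = field(default_factory=TrainingConfig.desk)
    seven_to_cube: TrainingConfig = field(default_factory=TrainingConfig.desk)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    n_probe_images: int = 8
    metrics: tuple[str, ...] = ("brisque",)

    @classmethod
    def desk(cls, out_root: Path, seed: int = 0, n_per_preset: int = 100,
             epochs: int = 12) -> "PipelineConfig":
        return cls(out_root=Path(out_root), seed=seed,
                   n_per_preset=n_per_preset, image_size=64,
                   cube_to_seven=TrainingConfig.desk(seed=seed + 1,
                                                     epochs=epochs),
                   seven_to_cube=TrainingConfig.desk(seed=seed + 2,
                                                     epochs=epochs),
                   classifier=ClassifierConfig(seed=seed + 3))

    @classmethod
    def full(cls, out_root: Path, seed: int = 0,
             n_per_preset: int = 517) -> "PipelineConfig":
        """Published-scale hyperparameters (multi-day on CPU)."""
        return cls(out_root=Path(out_root), seed=seed,
                   n_per_preset=n_per_preset, image_size=256,
                   cube_to_seven=TrainingConfig(seed=seed + 1),
                   seven_to_cube=TrainingConfig(seed=seed + 2),
                   classifier=ClassifierConfig(seed=seed + 3))


def run_pipeline(config: PipelineConfig, verbose: bool = False) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    root = Path(config.out_root)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": []}
    timings: dict[str, float] = {}

    def stage(name, fn, inputs, outputs):
        t0 = time.perf_counter()
        if verbose:
            print(f"[octpt:{name}] seed={config.seed} starting")
        try:
            result = fn()
        except Exception as exc:  # partial outputs are retained on disk
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        timings[name] = time.perf_counter() - t0
        manifest["stages"].append({"stage": name, "inputs": inputs,
                                   "outputs": outputs, "seed": config.seed})
        return result

    # 1. phantom dataset -----------------------------------------------------
    data_dir = root / "phantom"
    stage("phantom",
          lambda: ph.generate_dataset(data_dir, config.n_per_preset,
                                      seed=config.seed,
                                      height=config.image_size,
                                      width=config.image_size),
          inputs=[], outputs=[str(data_dir / "manifest.csv")])
    rows = ph.load_manifest(data_dir / "manifest.csv")
    images = {name: [ph.load_image(data_dir / r["path"], r["preset"])
                     for r in rows if r["preset"] == name]
              for name in ("macular_cube", "seven_lines")}

    # 2-3. train both directions ----------------------------------------------
    results = {}
    for name, src, tgt, cfg in (
            ("train_cube_to_seven", "macular_cube", "seven_lines",
             config.cube_to_seven),
            ("train_seven_to_cube", "seven_lines", "macular_cube",
             config.seven_to_cube)):
        tdir = root / name
        results[name] = stage(
            name,
            lambda src=src, tgt=tgt, cfg=cfg, tdir=tdir: CUTModel(
                images[src], images[tgt], cfg).fit(out_dir=tdir,
                                                   verbose=verbose),
            inputs=[str(data_dir / "manifest.csv")],
            outputs=[str(tdir / "loss_trace.csv")])

    # 4. checkpoint quality evaluation and selection ---------------------------
    qdir = root / "quality"
    qdir.mkdir(exist_ok=True)

    def quality_stage():
        scorer = q.train_synthetic_scorer(seed=config.seed + 11,
                                          size=max(64, config.image_size))
        score_fn = lambda img: q.brisque_score(img, scorer)
        chosen = {}
        for name, res, mode in (
                ("cube_to_seven", results["train_cube_to_seven"], "lowest"),
                ("seven_to_cube", results["train_seven_to_cube"], "highest")):
            probe = images[res.model.source_preset][:config.n_probe_images]
            table = q.evaluate_checkpoints(
                res.checkpoints, probe, score_fn,
                convert=lambda ckpt, img, res=res: res.convert(
                    img, epoch=ckpt.epoch))
            table.to_csv(qdir / f"scores_{name}.csv", index=False)
            chosen[name] = q.select_checkpoint(table, mode)
        with open(qdir / "selected.json", "w") as fh:
            json.dump(chosen, fh, indent=1)
        return chosen

    chosen = stage("quality", quality_stage,
                   inputs=[str(root / "train_cube_to_seven"),
                           str(root / "train_seven_to_cube")],
                   outputs=[str(qdir / "selected.json")])

    # 5. convert every original with the selected checkpoints ------------------
    conv_dir = root / "converted"
    conv_dir.mkdir(exist_ok=True)

    def convert_stage():
        out_rows = []
        for name, res in (("cube_to_seven", results["train_cube_to_seven"]),
                          ("seven_to_cube", results["train_seven_to_cube"])):
            converted = res.convert_many(images[res.model.source_preset],
                                         epoch=chosen[name])
            for i, img in enumerate(converted):
                fname = f"synthetic_{img.preset}_{i:04d}.png"
                ph.save_image(img, conv_dir / fname)
                out_rows.append({"path": fname, "preset": img.preset,
                                 "provenance": "synthetic",
                                 "seed": config.seed})
        with open(conv_dir / "manifest.json", "w") as fh:
            json.dump(out_rows, fh, indent=1)
        return out_rows

    stage("convert", convert_stage,
          inputs=[str(qdir / "selected.json")],
          outputs=[str(conv_dir / "manifest.json")])

    # 6. separability ---------------------------------------------------------
    sep_dir = root / "separability"
    sep_dir.mkdir(exist_ok=True)

    def separability_stage():
        originals = images["macular_cube"] + images["seven_lines"]
        clf = PresetClassifier(originals, config=config.classifier).fit(
            split_spec=SplitSpec(seed=config.seed + 17))
        clf.curves.to_csv(sep_dir / "training_curves.csv", index=False)
        reports = {"original_test_accuracy": clf.evaluate_split("test"),
                   "best_epoch": clf.best_epoch}
        conv_rows = json.load(open(conv_dir / "manifest.json"))
        for target in ("seven_lines", "macular_cube"):
            synth = [ph.load_image(conv_dir / r["path"], r["preset"],
                                   "synthetic")
                     for r in conv_rows if r["preset"] == target]
            rep = synthetic_separability_test(clf, synth, target)
            reports[f"synthetic_{target}"] = {
                "accuracy": rep.accuracy, "counts": rep.counts,
                "n": rep.n, "note": rep.note}
        with open(sep_dir / "report.json", "w") as fh:
            json.dump(reports, fh, indent=1)
        return reports

    sep_report = stage("separability", separability_stage,
                       inputs=[str(conv_dir / "manifest.json"),
                               str(data_dir / "manifest.csv")],
                       outputs=[str(sep_dir / "report.json")])

    manifest["selected_checkpoints"] = chosen
    manifest["separability"] = sep_report
    with open(root / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    with open(root / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=1)
    return manifest
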