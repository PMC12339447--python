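"""End-to-end experiment recipes at desk scale.

One call wires the pipeline simulate → split → fuse → pre-train →
supervised transfer → cross-evaluate for the five study arms:

* ``full``            — fused-source pre-training, per-source supervised
                        training, 3×3 cross-evaluation matrix.
* ``no_ssl``          — identical, but the classifier encoder is randomly
                        initialized (no pre-trained weights).
* ``no_fusion``       — pre-training runs per source on that source alone;
                        each classifier uses its own source's weights.
* ``unseen_pretrain`` — pre-training sees only the designated source(s);
                        the other sources appear solely as held-out tests.
* ``half_data``       — supervised training manifests subsampled to a
                        fraction (default 50%), stratified per class.

Every run writes its config snapshot, manifests, per-epoch logs and the
final report into the output directory; a failed run leaves its partial
artifacts under ``<out>.incomplete`` so they are never mistaken for
results.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .manifest import (DatasetManifest, FusionResult, fuse_for_pretraining,
                       map_labels_binary, split_random_stratified, write_fusion)
from .mae import preset, save_checkpoint
from .training import (ClassifierHeadSpec, PretrainConfig,
                       SupervisedConfig, build_classifier, pretrain,
                       train_classifier)
from .evaluation import EvalReport, cross_evaluate

EXPERIMENTS = ("full", "no_ssl", "no_fusion", "unseen_pretrain", "half_data")

__all__ = ["ExperimentConfig", "run_experiment", "simulate_sources",
           "prepare_fusion", "subsample_train", "EXPERIMENTS"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment run."""

    out_dir: str
    seed: int = 0
    experiment: str = "full"
    model_preset: str = "swinv2-tiny"
    mask_ratio: float = 0.7
    n_sources: int = 3
    subjects_per_source: int = 45               # ≈150 train scans per source
    scans_per_subject: int = 4
    image_size: tuple[int, int] = (64, 64)
    split_ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    pretrain_sources: tuple[str, ...] = ()      # unseen_pretrain arm
    train_fraction: float = 0.5                 # half_data arm
    head_dims: tuple[int, int] = (64, 32)
    pretrain: PretrainConfig = field(default_factory=lambda: PretrainConfig(
        epochs=3, batch_size=32))
    supervised: SupervisedConfig = field(
        default_factory=lambda: SupervisedConfig(
            epochs=30, early_stop_patience=10, augmentations=(),
            batch_size=32, lr=3e-3))

    def __post_init__(self):
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if not (0.0 < self.train_fraction <= 1.0):
            raise ValueError("train_fraction must lie in (0, 1]")


def simulate_sources(cfg: ExperimentConfig):
    """Generate the multi-source study data (pre-training class mix)."""
    domains = synth.default_domains(cfg.image_size)[:cfg.n_sources]
    store: dict[str, np.ndarray] = {}
    manifests: dict[str, DatasetManifest] = {}
    for k, domain in enumerate(domains):
        images, rows = synth.generate_source(
            domain, cfg.subjects_per_source, cfg.scans_per_subject,
            synth.PRETRAIN_MIX, rng_seed=cfg.seed * 1000 + k)
        store.update(images)
        manifest = DatasetManifest(rows, provenance=f"simulated:{domain.source_id}")
        manifests[domain.source_id] = split_random_stratified(
            manifest, cfg.split_ratios, rng_seed=cfg.seed * 1000 + 500 + k)
    return store, manifests


def prepare_fusion(manifests: dict[str, DatasetManifest],
                   sources: tuple[str, ...], seed: int) -> FusionResult:
    chosen = [manifests[s] for s in sources]
    return fuse_for_pretraining(chosen, rng_seed=seed)


def subsample_train(manifest: DatasetManifest, fraction: float,
                    rng_seed: int) -> DatasetManifest:
    """Stratified subsampling of the train split; val/test untouched."""
    df = manifest.records.copy()
    rng = np.random.default_rng(rng_seed)
    keep = pd.Series(True, index=df.index)
    train_df = df[df.split == "train"]
    for label in sorted(train_df.class_label.unique()):
        idx = train_df.index[train_df.class_label == label].to_numpy()
        n_keep = max(1, int(round(fraction * len(idx))))
        dropped = rng.permutation(idx)[n_keep:]
        keep.loc[dropped] = False
    return DatasetManifest(df[keep],
                           provenance=f"{manifest.provenance}|frac{fraction}")


def _binary_split(manifest: DatasetManifest, split: str) -> DatasetManifest:
    return map_labels_binary(manifest).subset(split)


def run_experiment(cfg: ExperimentConfig) -> EvalReport:
    """Execute one experiment arm; returns the cross-evaluation report."""
    out_dir = Path(cfg.out_dir)
    staging = Path(str(out_dir) + ".incomplete")
    if staging.exists():
        shutil.rmtree(staging)
    staging.mkdir(parents=True)
    try:
        report = _run(cfg, staging)
    except Exception:
        # leave partial artifacts quarantined under *.incomplete
        raise
    if out_dir.exists():
        shutil.rmtree(out_dir)
    staging.rename(out_dir)
    return report


def _run(cfg: ExperimentConfig, out_dir: Path) -> EvalReport:
    snapshot = asdict(cfg)
    (out_dir / "config.json").write_text(json.dumps(snapshot, indent=1,
                                                    default=list))
    store, manifests = simulate_sources(cfg)
    sources = tuple(manifests)
    for s, m in manifests.items():
        m.to_csv(out_dir / "manifests" / f"{s}.csv")

    mae_cfg = preset(cfg.model_preset, mask_ratio=cfg.mask_ratio)
    head = ClassifierHeadSpec(cfg.head_dims)

    # ---- pre-training arms ------------------------------------------------
    checkpoints: dict[str, object] = {}
    if cfg.experiment == "no_ssl":
        pass                                     # no pre-trained weights
    elif cfg.experiment == "no_fusion":
        for s in sources:
            fusion = prepare_fusion(manifests, (s,), cfg.seed)
            result = pretrain(fusion, mae_cfg, cfg.pretrain, store)
            result.write_log(out_dir / "logs" / f"pretrain_{s}.csv")
            save_checkpoint(result.model, out_dir / "ckpt" / f"mae_{s}",
                            {"sources": [s], "seed": cfg.seed})
            checkpoints[s] = result.model
    else:
        if cfg.experiment == "unseen_pretrain":
            pre_sources = cfg.pretrain_sources or (sources[0],)
        else:
            pre_sources = sources
        fusion = prepare_fusion(manifests, pre_sources, cfg.seed)
        write_fusion(fusion, out_dir / "manifests")
        result = pretrain(fusion, mae_cfg, cfg.pretrain, store)
        result.write_log(out_dir / "logs" / "pretrain.csv")
        save_checkpoint(result.model, out_dir / "ckpt" / "mae",
                        {"sources": list(pre_sources), "seed": cfg.seed})
        for s in sources:
            checkpoints[s] = result.model

    # ---- supervised arms --------------------------------------------------
    train_sources = sources
    if cfg.experiment == "unseen_pretrain":
        train_sources = cfg.pretrain_sources or (sources[0],)

    tests = {s: _binary_split(manifests[s], "test") for s in sources}
    report = EvalReport()
    for s in train_sources:
        sup_manifest = manifests[s]
        if cfg.experiment == "half_data":
            stable = sum(ord(c) for c in s)     # hash() is salted per run
            sup_manifest = subsample_train(sup_manifest, cfg.train_fraction,
                                           cfg.seed * 31 + stable)
        train_m = _binary_split(sup_manifest, "train")
        val_m = _binary_split(sup_manifest, "val")
        clf = build_classifier(checkpoints.get(s), head=head, freeze=True,
                               config=mae_cfg, rng_seed=cfg.seed)
        sup = train_classifier(clf, train_m, val_m, cfg.supervised, store)
        sup.write_log(out_dir / "logs" / f"supervised_{s}.csv")
        train_ids = train_m.image_ids | val_m.image_ids
        row = cross_evaluate(sup.classifier, tests, store, s,
                             train_ids=train_ids)
        for te, rec in row.cells[s].items():
            report.add(s, te, rec)
    report.to_json(out_dir / "report.json")
    return report
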