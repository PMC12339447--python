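"""Dataset manifests: label mapping, train/val/test splitting and
multi-source fusion for label-free pre-training.

A manifest is a table of B-scan records (image path, source, subject,
class, split).  Fusion concatenates and shuffles the train and validation
splits of several sources into a single pre-training pool while each
source's test split is held out untouched — test isolation is enforced
structurally (disjointness by image id is checked, and violations raise).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SPLITS = ("train", "val", "test", "unassigned")

COLUMNS = ["image_path", "source_id", "subject_id", "class_label", "split"]


@dataclass
class DatasetManifest:
    """An ordered set of image records with provenance.

    ``records`` carries the manifest columns plus a derived unique
    ``image_id`` (the path stem).  Subject integrity is enforced: a subject
    with any record in ``test`` must have all records in ``test``.
    """

    records: pd.DataFrame
    provenance: str = ""

    def __post_init__(self):
        df = self.records.copy().reset_index(drop=True)
        if "image_id" not in df.columns:
            df["image_id"] = [Path(p).stem for p in df["image_path"]]
        df["split"] = df["split"].fillna("").replace("", "unassigned")
        bad = set(df["split"]) - set(SPLITS)
        if bad:
            raise ValueError(f"invalid split values: {sorted(bad)}")
        if df["image_id"].duplicated().any():
            dupes = df.loc[df.image_id.duplicated(), "image_id"].head().tolist()
            raise ValueError(f"duplicate image_id: {dupes}")
        self.records = df
        self._check_subject_integrity()

    def _check_subject_integrity(self) -> None:
        df = self.records
        with_subject = df[df.subject_id.astype(str) != ""]
        for subject, group in with_subject.groupby("subject_id"):
            splits = set(group["split"])
            if "test" in splits and splits != {"test"}:
                raise ValueError(
                    f"subject {subject!r} straddles test and non-test splits")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def image_ids(self) -> set[str]:
        return set(self.records.image_id)

    def subset(self, split: str) -> "DatasetManifest":
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return DatasetManifest(self.records[self.records.split == split],
                               provenance=f"{self.provenance}|subset:{split}")

    def class_counts(self) -> dict[str, int]:
        return self.records.class_label.value_counts().to_dict()

    # ----------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        out = self.records[COLUMNS].copy()
        out["split"] = out["split"].replace("unassigned", "")
        out.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, provenance: str | None = None
                 ) -> "DatasetManifest":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
        return cls(df, provenance=provenance or f"csv:{path}")


@dataclass
class FusionResult:
    """Fused pre-training pools plus per-source held-out test sets."""

    fused_train: DatasetManifest
    fused_val: DatasetManifest
    held_out_tests: dict[str, DatasetManifest]

    def __post_init__(self):
        train_ids = self.fused_train.image_ids
        for source, test in self.held_out_tests.items():
            overlap = train_ids & test.image_ids
            if overlap:
                raise ValueError(
                    f"test isolation violated for {source}: {sorted(overlap)[:5]}")


# --------------------------------------------------------------- operations
def map_labels_binary(manifest: DatasetManifest,
                      drusen_to_amd: bool = True) -> DatasetManifest:
    """Reduce a manifest to the binary NORMAL/AMD task.

    Drusen is the early-AMD signature, so ``drusen_to_amd`` relabels
    DRUSEN records as AMD before filtering; every record that is not
    NORMAL or AMD afterwards is removed.  The input is left unmodified.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    df = manifest.records.copy()
    if drusen_to_amd:
        df.loc[df.class_label.str.upper() == "DRUSEN", "class_label"] = "AMD"
    df = df[df.class_label.isin(["NORMAL", "AMD"])]
    if df.empty:
        raise ValueError("empty after filtering to NORMAL/AMD")
    return DatasetManifest(df, provenance=f"{manifest.provenance}|binary")


def split_random_stratified(manifest: DatasetManifest,
                            ratios: tuple[float, float, float],
                            rng_seed: int) -> DatasetManifest:
    """Assign train/val/test per class by the given ratios.

    Counts use largest-remainder rounding with the remainder going to
    train; assignment within a class is a seeded shuffle, so the result is
    deterministic per seed.  When records carry subject ids the subject is
    the sampling unit (all of a subject's scans move together, preserving
    subject integrity); otherwise records are assigned individually.
    """
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios):
        raise ValueError("all three ratios must be positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    df = manifest.records.copy()
    grouped = (df.subject_id.astype(str) != "").all()
    if grouped:
        units = df.groupby("subject_id").class_label.first()
        unit_class = units.to_dict()
        unit_index = {u: df.index[df.subject_id == u].to_numpy()
                      for u in units.index}
    else:
        unit_class = dict(zip(df.index, df.class_label))
        unit_index = {i: np.array([i]) for i in df.index}
    by_class: dict[str, list] = {}
    for unit, label in unit_class.items():
        by_class.setdefault(label, []).append(unit)
    small = {lab: len(u) for lab, u in by_class.items() if len(u) < 3}
    if small:
        raise ValueError(
            f"classes with < 3 {'subjects' if grouped else 'records'} "
            f"cannot populate all splits: {small}")
    rng = np.random.default_rng(rng_seed)
    split_col = pd.Series("unassigned", index=df.index)
    for label in sorted(by_class):
        units_of = sorted(by_class[label])
        order = rng.permutation(len(units_of))
        units_of = [units_of[i] for i in order]
        n = len(units_of)
        quotas = [n * r for r in ratios]
        n_val, n_test = int(np.floor(quotas[1])), int(np.floor(quotas[2]))
        n_val, n_test = max(n_val, 1), max(n_test, 1)
        n_train = n - n_val - n_test          # remainder goes to train
        for pos, unit in enumerate(units_of):
            split = ("train" if pos < n_train
                     else "val" if pos < n_train + n_val else "test")
            split_col.loc[unit_index[unit]] = split
    df["split"] = split_col
    return DatasetManifest(
        df, provenance=f"{manifest.provenance}|stratified:{ratios}:seed{rng_seed}")


def split_by_subject(manifest: DatasetManifest, n_train_subjects: int,
                     n_val_subjects: int, n_test_subjects: int
                     ) -> DatasetManifest:
    """Assign splits at subject granularity, per class.

    Subjects are ordered lexicographically by subject_id within each class;
    the first ``n_train_subjects`` go to train, then val, then test.  The
    three counts must sum to the number of subjects of every class.
    """
    if min(n_train_subjects, n_val_subjects, n_test_subjects) <= 0:
        raise ValueError("each split needs at least one subject")
    df = manifest.records.copy()
    if (df.subject_id.astype(str) == "").any():
        raise ValueError("subject-wise split requires subject_id on every record")
    split_col = pd.Series("unassigned", index=df.index)
    want = n_train_subjects + n_val_subjects + n_test_subjects
    for label in sorted(df.class_label.unique()):
        subjects = sorted(df.loc[df.class_label == label, "subject_id"].unique())
        if len(subjects) != want:
            raise ValueError(
                f"class {label!r} has {len(subjects)} subjects, "
                f"expected {want}")
        assignment = (["train"] * n_train_subjects + ["val"] * n_val_subjects
                      + ["test"] * n_test_subjects)
        mapping = dict(zip(subjects, assignment))
        mask = df.class_label == label
        split_col.loc[mask] = df.loc[mask, "subject_id"].map(mapping)
    df["split"] = split_col
    return DatasetManifest(
        df, provenance=f"{manifest.provenance}|by_subject:"
                       f"({n_train_subjects},{n_val_subjects},{n_test_subjects})")


def fuse_for_pretraining(manifests: list[DatasetManifest],
                         rng_seed: int) -> FusionResult:
    """Combine several sources' train/val splits into shuffled pools.

    All class labels are retained — pre-training is label-free and benefits
    from the full morphology spectrum.  Test splits are returned per source
    and never enter the pools.
    """
    if not manifests:
        raise ValueError("no manifests to fuse")
    all_ids: set[str] = set()
    for m in manifests:
        if (m.records.split == "unassigned").any():
            raise ValueError("fusion requires fully assigned splits")
        overlap = all_ids & m.image_ids
        if overlap:
            raise ValueError(
                f"duplicate image_id across sources: {sorted(overlap)[:5]}")
        all_ids |= m.image_ids
    rng = np.random.default_rng(rng_seed)

    def pool(split: str) -> DatasetManifest:
        parts = [m.records[m.records.split == split] for m in manifests]
        df = pd.concat(parts, ignore_index=True)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        return DatasetManifest(df, provenance=f"fused:{split}:seed{rng_seed}")

    tests = {}
    for m in manifests:
        test_df = m.records[m.records.split == "test"]
        for source, group in test_df.groupby("source_id"):
            if source in tests:
                raise ValueError(f"source {source!r} appears in two manifests")
            tests[source] = DatasetManifest(
                group, provenance=f"test:{source}")
    return FusionResult(pool("train"), pool("val"), tests)


def dedup_exact(manifest: DatasetManifest, root: str | Path) -> DatasetManifest:
    """Drop records whose image files are byte-identical (keep first seen)."""
    root = Path(root)
    seen: dict[str, str] = {}
    keep = []
    for _, row in manifest.records.iterrows():
        digest = hashlib.sha256((root / row.image_path).read_bytes()).hexdigest()
        if digest not in seen:
            seen[digest] = row.image_id
            keep.append(True)
        else:
            keep.append(False)
    df = manifest.records[np.asarray(keep)]
    return DatasetManifest(df, provenance=f"{manifest.provenance}|dedup_exact")


def write_fusion(fusion: FusionResult, out_dir: str | Path) -> dict[str, Path]:
    """Write fused_train.csv, fused_val.csv and per-source test CSVs."""
    out_dir = Path(out_dir)
    paths = {
        "fused_train": fusion.fused_train.to_csv(out_dir / "fused_train.csv"),
        "fused_val": fusion.fused_val.to_csv(out_dir / "fused_val.csv"),
    }
    for source, test in fusion.held_out_tests.items():
        paths[f"test_{source}"] = test.to_csv(out_dir / f"test_{source}.csv")
    return paths
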