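"""Label mapping, splitting and fusion contracts."""

import numpy as np
import pandas as pd
import pytest

from retmae.manifest import (DatasetManifest, dedup_exact,
                             fuse_for_pretraining, map_labels_binary,
                             split_by_subject, split_random_stratified)

from conftest import manifest_from_labels


# ------------------------------------------------------------ label mapping
def test_drusen_relabeled_and_other_classes_removed():
    m = manifest_from_labels(["NORMAL"] * 5 + ["DRUSEN"] * 2 + ["DME"])
    out = map_labels_binary(m, drusen_to_amd=True)
    assert out.class_counts() == {"NORMAL": 5, "AMD": 2}
    # original untouched
    assert m.class_counts()["DRUSEN"] == 2


def test_binary_input_passes_through():
    m = manifest_from_labels(["NORMAL"] * 3 + ["AMD"] * 3)
    out = map_labels_binary(m)
    assert out.class_counts() == m.class_counts()


def test_empty_after_filtering_raises():
    with pytest.raises(ValueError, match="empty after filtering"):
        map_labels_binary(manifest_from_labels(["DME"] * 4))


# -------------------------------------------------------------------- splits
@pytest.mark.parametrize("n,expected", [
    (100, (80, 10, 10)),
    (10, (8, 1, 1)),
])
def test_stratified_split_counts_per_class(n, expected):
    m = manifest_from_labels(["NORMAL"] * n + ["AMD"] * n)
    out = split_random_stratified(m, (0.8, 0.1, 0.1), rng_seed=0)
    for label in ("NORMAL", "AMD"):
        sub = out.records[out.records.class_label == label]
        got = tuple(int((sub.split == s).sum()) for s in ("train", "val", "test"))
        assert got == expected


def test_stratified_split_rejects_zero_ratio():
    m = manifest_from_labels(["NORMAL"] * 10 + ["AMD"] * 10)
    with pytest.raises(ValueError, match="positive"):
        split_random_stratified(m, (1.0, 0.0, 0.0), rng_seed=0)


def test_stratified_split_deterministic_and_seed_sensitive():
    m = manifest_from_labels(["NORMAL"] * 40 + ["AMD"] * 40)
    a = split_random_stratified(m, (0.8, 0.1, 0.1), 5).records.split
    b = split_random_stratified(m, (0.8, 0.1, 0.1), 5).records.split
    c = split_random_stratified(m, (0.8, 0.1, 0.1), 6).records.split
    assert a.equals(b)
    assert not a.equals(c)


def test_stratified_split_groups_subjects(small_study):
    _, manifests = small_study
    for m in manifests.values():
        joint = m.records.groupby("subject_id").split.nunique()
        assert (joint == 1).all()


def test_subject_split_counts():
    labels, prefix = [], []
    rows = []
    for lab in ("NORMAL", "AMD"):
        for s in range(15):
            for scan in range(4):
                rows.append({"image_path": f"x/{lab}_{s}_{scan}.png",
                             "source_id": "x",
                             "subject_id": f"{lab}_subj{s:02d}",
                             "class_label": lab, "split": ""})
    m = DatasetManifest(pd.DataFrame(rows))
    out = split_by_subject(m, 10, 2, 3)
    for lab in ("NORMAL", "AMD"):
        sub = out.records[out.records.class_label == lab]
        per_split = sub.groupby("split").subject_id.nunique()
        assert per_split.to_dict() == {"train": 10, "val": 2, "test": 3}
    # subject integrity by enumeration
    assert (out.records.groupby("subject_id").split.nunique() == 1).all()


def test_subject_split_rejects_empty_val_or_test():
    m = manifest_from_labels(["NORMAL"] * 5, subject_prefix="s")
    with pytest.raises(ValueError, match="at least one subject"):
        split_by_subject(m, 5, 0, 0)


def test_subject_split_rejects_mismatched_counts():
    m = manifest_from_labels(["NORMAL"] * 5, subject_prefix="s")
    with pytest.raises(ValueError, match="expected"):
        split_by_subject(m, 10, 2, 3)


def test_subject_integrity_enforced_on_construction():
    rows = pd.DataFrame([
        {"image_path": "x/a.png", "source_id": "x", "subject_id": "s1",
         "class_label": "NORMAL", "split": "test"},
        {"image_path": "x/b.png", "source_id": "x", "subject_id": "s1",
         "class_label": "NORMAL", "split": "train"},
    ])
    with pytest.raises(ValueError, match="straddles"):
        DatasetManifest(rows)


# -------------------------------------------------------------------- fusion
def _assigned(labels, source):
    m = manifest_from_labels(labels, source=source)
    return split_random_stratified(m, (0.8, 0.1, 0.1), rng_seed=1)


def test_fusion_concatenates_train_pools():
    sizes = (100, 125, 150)
    manifests = [_assigned(["NORMAL"] * n + ["AMD"] * n, f"s{k}")
                 for k, n in enumerate(sizes)]
    fusion = fuse_for_pretraining(manifests, rng_seed=0)
    expected_train = sum(int((m.records.split == "train").sum())
                         for m in manifests)
    assert len(fusion.fused_train) == expected_train
    assert set(fusion.held_out_tests) == {"s0", "s1", "s2"}
    # conservation: nothing lost, nothing invented
    total = (len(fusion.fused_train) + len(fusion.fused_val)
             + sum(len(t) for t in fusion.held_out_tests.values()))
    assert total == sum(len(m) for m in manifests)


def test_fusion_is_a_permutation_of_inputs():
    m = _assigned(["NORMAL"] * 50 + ["AMD"] * 50, "solo")
    fusion = fuse_for_pretraining([m], rng_seed=3)
    train_ids = m.records.loc[m.records.split == "train", "image_id"]
    assert fusion.fused_train.image_ids == set(train_ids)


def test_fusion_rejects_duplicate_ids():
    m = _assigned(["NORMAL"] * 20 + ["AMD"] * 20, "dup")
    with pytest.raises(ValueError, match="duplicate"):
        fuse_for_pretraining([m, m], rng_seed=0)


def test_fusion_requires_assigned_splits():
    m = manifest_from_labels(["NORMAL"] * 10 + ["AMD"] * 10)
    with pytest.raises(ValueError, match="assigned"):
        fuse_for_pretraining([m], rng_seed=0)


def test_fusion_keeps_nonbinary_classes_for_pretraining():
    m = _assigned(["NORMAL"] * 10 + ["AMD"] * 10 + ["CNV_LIKE"] * 10, "mix")
    fusion = fuse_for_pretraining([m], rng_seed=0)
    assert "CNV_LIKE" in set(fusion.fused_train.records.class_label)


# ----------------------------------------------------------------------- IO
def test_manifest_csv_round_trip(tmp_path):
    m = _assigned(["NORMAL"] * 10 + ["AMD"] * 10, "io")
    path = m.to_csv(tmp_path / "m.csv")
    back = DatasetManifest.from_csv(path)
    pd.testing.assert_frame_equal(
        m.records.reset_index(drop=True), back.records)


def test_dedup_exact_drops_byte_identical_files(tmp_path):
    from PIL import Image
    img = (np.arange(64, dtype=np.uint8).reshape(8, 8))
    paths = ["src/a.png", "src/b.png", "src/c.png"]
    (tmp_path / "src").mkdir()
    Image.fromarray(img).save(tmp_path / paths[0])
    Image.fromarray(img).save(tmp_path / paths[1])          # identical bytes
    Image.fromarray(img.T.copy()).save(tmp_path / paths[2])  # distinct
    rows = pd.DataFrame([{"image_path": p, "source_id": "src",
                          "subject_id": "", "class_label": "NORMAL",
                          "split": ""} for p in paths])
    out = dedup_exact(DatasetManifest(rows), tmp_path)
    assert list(out.records.image_id) == ["a", "c"]
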