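import numpy as np
import pytest

from retmae import synth
from retmae.manifest import DatasetManifest, split_random_stratified


@pytest.fixture(scope="session")
def domains():
    return synth.default_domains((64, 64))


@pytest.fixture(scope="session")
def small_study(domains):
    """Three small sources with splits assigned; shared across tests.

    Kept deliberately small (18 subjects × 2 scans per source) so the
    whole-suite runtime stays reasonable; subject counts are chosen so
    every class can populate train/val/test.
    """
    store = {}
    manifests = {}
    for k, domain in enumerate(domains):
        images, rows = synth.generate_source(
            domain, n_subjects=18, scans_per_subject=2,
            class_mix={"NORMAL": 0.5, "AMD": 0.5}, rng_seed=100 + k)
        store.update(images)
        m = DatasetManifest(rows, provenance=f"fixture:{domain.source_id}")
        manifests[domain.source_id] = split_random_stratified(
            m, (0.6, 0.2, 0.2), rng_seed=7 + k)
    return store, manifests


def manifest_from_labels(labels, source="srcX", subject_prefix=""):
    """Build an unsplit manifest with one record per label."""
    import pandas as pd
    rows = []
    for i, lab in enumerate(labels):
        rows.append({
            "image_path": f"{source}/{source}_img{i:04d}.png",
            "source_id": source,
            "subject_id": f"{subject_prefix}{i}" if subject_prefix else "",
            "class_label": lab,
            "split": "",
        })
    return DatasetManifest(pd.DataFrame(rows))
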