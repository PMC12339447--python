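"""Published cross-dataset AUROC benchmark values.

These are the reported AUC-ROC scores of the ResNet-50 baseline and the
SwinV2 masked-autoencoder classifier across the three public OCT dataset
sources (DS1, DS2, DS3), each model trained on one source and evaluated on
every source's held-out test set, plus the with/without self-supervised
pre-training ablation of the SwinV2 classifier.  They are inputs to the
paired signed-rank comparisons; this package does not recompute them
(that would require the original datasets at GPU scale).

Layout: ``(train_source, test_source) → AUROC``.
"""

from __future__ import annotations

__all__ = ["RESNET50_AUROC", "SWINV2_AUROC", "SWINV2_WITH_SSL_AUROC",
           "SWINV2_WITHOUT_SSL_AUROC", "paired_auroc"]

#: ResNet-50 baseline, cross-dataset AUROC (9 train/test cells)
RESNET50_AUROC = {
    ("DS1", "DS1"): 0.98, ("DS1", "DS2"): 0.99, ("DS1", "DS3"): 0.56,
    ("DS2", "DS1"): 0.59, ("DS2", "DS2"): 0.80, ("DS2", "DS3"): 0.54,
    ("DS3", "DS1"): 0.72, ("DS3", "DS2"): 0.87, ("DS3", "DS3"): 0.96,
}

#: SwinV2 masked-autoencoder classifier, same 9 cells
SWINV2_AUROC = {
    ("DS1", "DS1"): 0.96, ("DS1", "DS2"): 0.99, ("DS1", "DS3"): 0.93,
    ("DS2", "DS1"): 0.79, ("DS2", "DS2"): 0.99, ("DS2", "DS3"): 0.86,
    ("DS3", "DS1"): 0.75, ("DS3", "DS2"): 0.93, ("DS3", "DS3"): 0.98,
}

#: SwinV2 classifier with self-supervised pre-training (ablation table)
SWINV2_WITH_SSL_AUROC = {
    ("DS1", "DS1"): 0.96, ("DS1", "DS2"): 0.99, ("DS1", "DS3"): 0.93,
    ("DS2", "DS1"): 0.79, ("DS2", "DS2"): 0.99, ("DS2", "DS3"): 0.86,
    ("DS3", "DS1"): 0.75, ("DS3", "DS2"): 0.93, ("DS3", "DS3"): 0.99,
}

#: SwinV2 classifier trained from random initialization (no pre-training)
SWINV2_WITHOUT_SSL_AUROC = {
    ("DS1", "DS1"): 0.95, ("DS1", "DS2"): 0.98, ("DS1", "DS3"): 0.81,
    ("DS2", "DS1"): 0.73, ("DS2", "DS2"): 0.99, ("DS2", "DS3"): 0.71,
    ("DS3", "DS1"): 0.73, ("DS3", "DS2"): 0.88, ("DS3", "DS3"): 0.97,
}


def paired_auroc(a: dict, b: dict) -> tuple[list[float], list[float]]:
    """Align two benchmark matrices into paired vectors (common cells,
    deterministic cell order)."""
    cells = sorted(set(a) & set(b))
    if not cells:
        raise ValueError("no common (train, test) cells")
    return [a[c] for c in cells], [b[c] for c in cells]
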