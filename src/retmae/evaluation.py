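"""Metrics, the (train-source × test-source) cross-evaluation matrix, and
the exact Wilcoxon signed-rank test.

AMD is the positive class throughout.  Accuracy and F1 are computed from
hard labels at threshold 0.5 on the AMD probability (equivalently argmax
of the 2-way softmax); AUROC is the area under the ROC curve (ties receive
half credit, the Mann–Whitney convention) and AUPR is average precision.

The signed-rank test is exact: zero differences are dropped (classical
treatment), tied absolute differences receive mid-ranks, and the two-sided
p-value is computed by enumerating the distribution of the positive-rank
sum over all 2^n sign assignments of the realized rank values — no normal
approximation at any n.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["PredictionSet", "MetricRecord", "EvalReport", "PairedComparison",
           "compute_metrics", "cross_evaluate", "wilcoxon_signed_rank_exact",
           "count_parameters"]


# ------------------------------------------------------------- predictions
@dataclass(frozen=True)
class PredictionSet:
    """Binary ground truth plus AMD-probability scores for a test set."""

    y_true: np.ndarray            # 0/1, AMD = 1
    scores: np.ndarray            # floats in [0,1], P(AMD)
    ids: tuple[str, ...] = ()

    def __post_init__(self):
        y = np.asarray(self.y_true, dtype=int)
        s = np.asarray(self.scores, dtype=float)
        if y.shape != s.shape or y.ndim != 1:
            raise ValueError("y_true and scores must be equal-length vectors")
        if self.ids and len(self.ids) != len(y):
            raise ValueError("ids length mismatch")
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("y_true must be binary 0/1")
        object.__setattr__(self, "y_true", y)
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class MetricRecord:
    accuracy: float
    auroc: float | None           # None when undefined (single-class truth)
    aupr: float | None
    f1: float
    tp: int
    tn: int
    fp: int
    fn: int
    n: int

    @property
    def auroc_defined(self) -> bool:
        return self.auroc is not None


def compute_metrics(preds: PredictionSet, threshold: float = 0.5
                    ) -> MetricRecord:
    """Confusion counts, accuracy, F1 (AMD positive), AUROC and AUPR.

    With single-class ground truth the ranking metrics are undefined and
    reported as ``None`` rather than silently zero.
    """
    y, s = preds.y_true, preds.scores
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    accuracy = (tp + tn) / n
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    if len(set(y.tolist())) < 2:
        auroc, aupr = None, None
    else:
        auroc = float(roc_auc_score(y, s))
        aupr = float(average_precision_score(y, s))
    return MetricRecord(accuracy=float(accuracy), auroc=auroc, aupr=aupr,
                        f1=float(f1), tp=tp, tn=tn, fp=fp, fn=fn, n=n)


# ------------------------------------------------------------------ report
class EvalReport:
    """Nested (train_source → test_source → MetricRecord) matrix."""

    def __init__(self):
        self.cells: dict[str, dict[str, MetricRecord]] = {}

    def add(self, train_source: str, test_source: str,
            record: MetricRecord) -> None:
        self.cells.setdefault(train_source, {})[test_source] = record

    def metric_matrix(self, metric: str) -> dict[str, dict[str, float | None]]:
        return {tr: {te: getattr(rec, metric) for te, rec in row.items()}
                for tr, row in self.cells.items()}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {tr: {te: asdict(rec) for te, rec in row.items()}
                   for tr, row in self.cells.items()}
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EvalReport":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        payload = json.loads(text)
        report = cls()
        for tr, row in payload.items():
            for te, rec in row.items():
                report.add(tr, te, MetricRecord(**rec))
        return report

    def __eq__(self, other) -> bool:
        return isinstance(other, EvalReport) and self.cells == other.cells


def cross_evaluate(classifier, tests: Mapping[str, "DatasetManifest"],
                   store, train_source: str,
                   train_ids: set[str] | None = None) -> EvalReport:
    """Evaluate one trained classifier on every held-out test source.

    ``train_ids`` is the id audit: if any test image id also appears in
    the ids used for any training decision, evaluation refuses to run.
    """
    from .training import binary_labels, resolve_images
    report = EvalReport()
    for source, manifest in tests.items():
        if train_ids:
            overlap = train_ids & manifest.image_ids
            if overlap:
                raise ValueError(
                    f"leakage: test {source} shares ids with training: "
                    f"{sorted(overlap)[:5]}")
        images = resolve_images(manifest, store)
        y = binary_labels(manifest)
        proba = classifier.predict_proba(images)[:, 1]
        preds = PredictionSet(y_true=y, scores=proba,
                              ids=tuple(manifest.records.image_id))
        report.add(train_source, source, compute_metrics(preds))
    return report


# ---------------------------------------------------------------- wilcoxon
@dataclass(frozen=True)
class PairedComparison:
    a: tuple[float, ...]
    b: tuple[float, ...]
    differences: tuple[float, ...]      # b - a, zeros removed
    W: float                            # min(positive-rank sum, negative)
    p_two_sided: float
    n_effective: int


def _exact_rank_sum_distribution(ranks: np.ndarray
                                 ) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of the positive-rank sum over all sign assignments.

    Mid-ranks are multiples of 1/2, so doubling gives integers; the count
    array is built by dynamic programming, which is arithmetic-identical
    to full 2^n enumeration of the realized rank values.
    """
    doubled = np.round(ranks * 2).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts


def wilcoxon_signed_rank_exact(a, b, zero_policy: str = "drop"
                               ) -> PairedComparison:
    """Exact two-sided Wilcoxon signed-rank test on paired vectors.

    ``zero_policy='drop'`` removes zero differences before ranking (the
    classical treatment); ``'split'`` keeps them in the ranking (Pratt)
    while still assigning them no sign.  The two-sided p-value is
    2·min(P(W⁺ ≤ w⁺), P(W⁺ ≥ w⁺)) on the enumerated distribution, capped
    at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length vectors of length >= 2")
    if zero_policy not in ("drop", "split"):
        raise ValueError("zero_policy must be 'drop' or 'split'")
    d = b - a
    nonzero = d != 0
    if not nonzero.any():
        raise ValueError("no nonzero differences")
    if zero_policy == "drop":
        d_used = d[nonzero]
        ranks = rankdata(np.abs(d_used))
    else:
        ranks_all = rankdata(np.abs(d))
        d_used = d[nonzero]
        ranks = ranks_all[nonzero]
    n_eff = len(d_used)
    if n_eff > 25:
        raise ValueError("exact enumeration limited to 25 nonzero pairs")
    w_pos = float(ranks[d_used > 0].sum())
    w_neg = float(ranks[d_used < 0].sum())
    support, counts = _exact_rank_sum_distribution(ranks)
    total_assignments = counts.sum()        # = 2 ** n_eff
    p_le = counts[support <= w_pos + 1e-12].sum() / total_assignments
    p_ge = counts[support >= w_pos - 1e-12].sum() / total_assignments
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return PairedComparison(a=tuple(a), b=tuple(b),
                            differences=tuple(d_used),
                            W=min(w_pos, w_neg), p_two_sided=float(p),
                            n_effective=n_eff)


# ------------------------------------------------------------- param count
def count_parameters(model) -> tuple[int, float]:
    """(raw trainable parameter count, count in millions at one decimal)."""
    if hasattr(model, "n_parameters"):
        raw = int(model.n_parameters())
    else:
        raise TypeError("model does not expose n_parameters()")
    return raw, round(raw / 1e6, 1)
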