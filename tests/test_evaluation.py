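"""Metrics, report plumbing and the exact signed-rank test."""

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from retmae.baselines import build_baseline
from retmae.evaluation import (EvalReport, MetricRecord, PredictionSet,
                               compute_metrics, count_parameters,
                               wilcoxon_signed_rank_exact)

RNG = np.random.default_rng(7)


# ------------------------------------------------------------------ metrics
def test_perfect_separation_gives_unit_areas():
    p = PredictionSet(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))
    m = compute_metrics(p)
    assert m.auroc == 1.0 and m.aupr == 1.0


def test_known_small_example():
    p = PredictionSet(np.array([0, 1, 0, 1]), np.array([0.1, 0.9, 0.8, 0.4]))
    m = compute_metrics(p)
    assert abs(m.auroc - 0.75) < 1e-12          # 3 of 4 concordant pairs
    assert abs(m.aupr - (1.0 + 2 / 3) / 2) < 1e-12


def test_confusion_arithmetic():
    # TP=3, TN=5, FP=1, FN=1
    y = np.array([1] * 4 + [0] * 6)
    s = np.array([0.9, 0.8, 0.7, 0.2] + [0.1] * 5 + [0.6])
    m = compute_metrics(PredictionSet(y, s))
    assert (m.tp, m.tn, m.fp, m.fn) == (3, 5, 1, 1)
    assert abs(m.accuracy - 0.8) < 1e-15
    assert abs(m.f1 - 0.75) < 1e-15


def test_accuracy_identity_holds_on_random_inputs():
    for _ in range(50):
        n = int(RNG.integers(4, 40))
        y = RNG.integers(0, 2, size=n)
        s = RNG.uniform(size=n)
        m = compute_metrics(PredictionSet(y, s))
        assert m.tp + m.tn + m.fp + m.fn == m.n == n
        assert m.accuracy == (m.tp + m.tn) / n


def test_single_class_truth_flags_undefined_ranking_metrics():
    m = compute_metrics(PredictionSet(np.ones(5, dtype=int),
                                      RNG.uniform(size=5)))
    assert m.auroc is None and m.aupr is None
    assert not m.auroc_defined


def test_auroc_matches_pairwise_concordance_oracle():
    """AUROC equals the brute-force count of concordant positive–negative
    pairs (ties half credit) on 200 random instances."""
    for trial in range(200):
        n = int(RNG.integers(4, 50))
        y = RNG.integers(0, 2, size=n)
        if len(set(y.tolist())) < 2:
            continue
        s = np.round(RNG.uniform(size=n), 1)     # coarse grid forces ties
        m = compute_metrics(PredictionSet(y, s))
        pos, neg = s[y == 1], s[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        oracle = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert abs(m.auroc - oracle) < 1e-12


def test_auroc_invariant_under_monotone_transform():
    y = RNG.integers(0, 2, size=30)
    y[:2] = [0, 1]
    s = RNG.uniform(size=30)
    base = compute_metrics(PredictionSet(y, s)).auroc
    for transform in (lambda v: v ** 3, lambda v: np.expm1(v) / np.e,
                      lambda v: 1 / (1 + np.exp(-7 * v))):
        assert abs(compute_metrics(
            PredictionSet(y, transform(s))).auroc - base) < 1e-12


# ----------------------------------------------------------------- wilcoxon
def test_one_signed_distinct_differences_closed_form():
    res = wilcoxon_signed_rank_exact([0, 0, 0, 0, 0], [1, 2, 3, 4, 5])
    assert res.W == 0.0
    assert abs(res.p_two_sided - 2 / 2 ** 5) < 1e-15
    assert res.n_effective == 5


def test_matches_classical_exact_distribution_for_untied_inputs():
    for trial in range(60):
        n = int(RNG.integers(4, 11))
        mags = RNG.choice(np.arange(1, 50), size=n, replace=False)
        d = mags * RNG.choice([-1.0, 1.0], size=n)
        mine = wilcoxon_signed_rank_exact(np.zeros(n), d)
        ref = scipy_wilcoxon(d, mode="exact")
        assert abs(mine.p_two_sided - ref.pvalue) < 1e-12


def test_symmetry_and_sign_invariance():
    a = [0.1, 0.5, 0.3, 0.9, 0.2, 0.6]
    b = [0.4, 0.2, 0.8, 0.7, 0.2, 0.9]
    r1 = wilcoxon_signed_rank_exact(a, b)
    r2 = wilcoxon_signed_rank_exact(b, a)
    assert r1.p_two_sided == r2.p_two_sided
    assert r1.W == r2.W


def test_zero_differences_dropped():
    res = wilcoxon_signed_rank_exact([1.0, 2.0, 3.0, 4.0],
                                     [1.0, 2.5, 2.0, 5.0])
    assert res.n_effective == 3


def test_all_zero_differences_rejected():
    with pytest.raises(ValueError, match="nonzero"):
        wilcoxon_signed_rank_exact([1.0, 2.0], [1.0, 2.0])


def test_tied_ranks_use_midranks():
    # |d| = (1, 1, 2) → ranks (1.5, 1.5, 3)
    res = wilcoxon_signed_rank_exact([0, 0, 0], [1.0, -1.0, 2.0])
    assert res.W == 1.5
    ranks = rankdata([1, 1, 2])
    assert ranks.tolist() == [1.5, 1.5, 3.0]


def test_p_value_always_in_unit_interval():
    for trial in range(30):
        n = int(RNG.integers(2, 12))
        d = RNG.normal(size=n)
        d[np.abs(d) < 1e-3] = 1.0
        res = wilcoxon_signed_rank_exact(np.zeros(n), d)
        assert 0.0 < res.p_two_sided <= 1.0
        assert res.W >= 0.0


# -------------------------------------------------------------- param count
def test_dense_layer_parameter_count():
    from retmae.nn import Linear, Module

    class OneLayer(Module):
        def __init__(self):
            self.fc = Linear(np.random.default_rng(0), 3, 2)

    raw, millions = count_parameters(OneLayer())
    assert raw == 3 * 2 + 2 == 8


def test_baseline_parameter_accounting():
    raw_r, m_r = count_parameters(build_baseline("resnet50", n_classes=2))
    assert m_r == 23.5
    raw_v, _ = count_parameters(build_baseline("vit_base", n_classes=2))
    assert round(raw_v / 1e6) == 86
    assert build_baseline("vit_base").param_shapes["head.weight"] == (2, 768)
    with pytest.raises(ValueError, match="unknown baseline"):
        build_baseline("alexnet")


# ------------------------------------------------------------------- report
def test_report_round_trip(tmp_path):
    report = EvalReport()
    report.add("srcA", "srcB", MetricRecord(
        accuracy=0.9, auroc=0.8, aupr=0.7, f1=0.6,
        tp=3, tn=6, fp=1, fn=0, n=10))
    path = tmp_path / "report.json"
    report.to_json(path)
    assert EvalReport.from_json(path) == report
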