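"""Hierarchical multi-label metrics against an explicit confusion-counting oracle."""

import numpy as np
import pytest

from conftest import annot
from ecbench.ec_core import parse_ec
from ecbench.exact_eval import (
    evaluate_batched,
    evaluate_by_group,
    evaluate_level,
    per_class_table,
)
from ecbench.io_formats import AnnotationTable


# ---------------------------------------------------------------------------
# independent oracle: string-level truncation + explicit per-class counting
# ---------------------------------------------------------------------------

def _trunc_str(ec_text, level):
    toks = ec_text.split(".")
    if sum(1 for t in toks if t != "-") < level:
        return None  # too shallow for this level
    return ".".join(toks[:level] + ["-"] * (4 - level))


def oracle_metrics(truth_strs, pred_strs, level):
    """truth_strs/pred_strs: {pid: set of ec strings}.  Returns
    (per_class, aggregates) computed by direct enumeration."""
    pairs = {}
    for pid, tset in truth_strs.items():
        t = {s for s in (_trunc_str(e, level) for e in tset) if s}
        if not t:
            continue
        p = {s for s in (_trunc_str(e, level) for e in pred_strs.get(pid, set())) if s}
        pairs[pid] = (t, p)
    classes = set()
    for t, p in pairs.values():
        classes |= t | p
    per_class = {}
    for c in classes:
        tp = sum(1 for t, p in pairs.values() if c in t and c in p)
        fp = sum(1 for t, p in pairs.values() if c not in t and c in p)
        fn = sum(1 for t, p in pairs.values() if c in t and c not in p)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = dict(tp=tp, fp=fp, fn=fn, support=tp + fn,
                            precision=prec, recall=rec, f1=f1)
    agg = {}
    TP = sum(v["tp"] for v in per_class.values())
    FP = sum(v["fp"] for v in per_class.values())
    FN = sum(v["fn"] for v in per_class.values())
    agg["micro_precision"] = TP / (TP + FP) if TP + FP else 0.0
    agg["micro_recall"] = TP / (TP + FN) if TP + FN else 0.0
    s = agg["micro_precision"] + agg["micro_recall"]
    agg["micro_f1"] = 2 * agg["micro_precision"] * agg["micro_recall"] / s if s else 0.0
    supported = [v for v in per_class.values() if v["support"] > 0]
    W = sum(v["support"] for v in supported)
    for m in ("precision", "recall", "f1"):
        agg[f"macro_{m}"] = (
            sum(v[m] for v in supported) / len(supported) if supported else 0.0
        )
        agg[f"weighted_{m}"] = (
            sum(v[m] * v["support"] for v in supported) / W if W else 0.0
        )
    return per_class, agg


def random_instance(rng, max_proteins=30, max_classes=10):
    classes = []
    while len(classes) < max_classes:
        toks = [str(rng.integers(1, 4)) for _ in range(4)]
        depth = int(rng.choice([1, 2, 3, 4], p=[0.1, 0.15, 0.15, 0.6]))
        label = ".".join(toks[:depth] + ["-"] * (4 - depth))
        if label not in classes:
            classes.append(label)
    n = int(rng.integers(1, max_proteins + 1))
    truth, preds = {}, {}
    for i in range(n):
        pid = f"P{i}"
        k = int(rng.integers(1, 4))
        truth[pid] = set(rng.choice(classes, size=k, replace=False))
        if rng.random() < 0.9:
            k = int(rng.integers(1, 4))
            preds[pid] = set(rng.choice(classes, size=k, replace=False))
    return truth, preds


class TestEvaluateLevel:
    def test_perfect_prediction_all_levels(self):
        truth = annot({"P1": ["1.1.1.1"]})
        predicted = {"P1": {parse_ec("1.1.1.1")}}
        for level in (1, 2, 3, 4):
            lm = evaluate_level(truth, predicted, level)
            assert lm.aggregates["weighted_f1"] == 1.0

    def test_hand_counted_two_protein_case(self):
        truth = annot({"P1": ["1.1.1.1"], "P2": ["2.3.1.4"]})
        predicted = {"P1": {parse_ec("1.1.1.1")}, "P2": {parse_ec("2.3.1.5")}}
        lm3 = evaluate_level(truth, predicted, 3)
        assert lm3.aggregates["weighted_f1"] == pytest.approx(1.0)
        lm4 = evaluate_level(truth, predicted, 4)
        assert lm4.per_class[parse_ec("1.1.1.1")].f1 == 1.0
        assert lm4.per_class[parse_ec("2.3.1.4")].f1 == 0.0
        assert lm4.aggregates["weighted_f1"] == pytest.approx(0.5)
        assert lm4.aggregates["micro_precision"] == pytest.approx(0.5)
        assert lm4.aggregates["micro_recall"] == pytest.approx(0.5)
        assert lm4.aggregates["micro_f1"] == pytest.approx(0.5)

    def test_partial_truth_excluded_at_deep_levels(self):
        truth = annot({"P1": ["1.1.-.-"]})
        predicted = {"P1": {parse_ec("1.1.1.1")}}
        for level in (1, 2):
            assert evaluate_level(truth, predicted, level).n_proteins == 1
        for level in (3, 4):
            assert evaluate_level(truth, predicted, level).n_proteins == 0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_level(AnnotationTable({}), {}, 1)

    def test_prediction_only_class_has_zero_support(self):
        truth = annot({"P1": ["1.1.1.1"]})
        predicted = {"P1": {parse_ec("1.1.1.1"), parse_ec("5.1.1.1")}}
        lm = evaluate_level(truth, predicted, 4)
        stats = lm.per_class[parse_ec("5.1.1.1")]
        assert stats.support == 0 and stats.fp == 1
        # weighted F1 unchanged by the support-0 class
        assert lm.aggregates["weighted_f1"] == 1.0
        # but micro counts include the false positive
        assert lm.aggregates["micro_precision"] == pytest.approx(0.5)

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(200):
            truth_strs, pred_strs = random_instance(rng)
            truth = annot({p: sorted(s) for p, s in truth_strs.items()})
            predicted = {
                p: {parse_ec(e) for e in s} for p, s in pred_strs.items()
            }
            for level in (1, 2, 3, 4):
                per_class, agg = oracle_metrics(truth_strs, pred_strs, level)
                lm = evaluate_level(truth, predicted, level)
                assert set(str(e) for e in lm.per_class) == set(per_class)
                for ec, stats in lm.per_class.items():
                    ref = per_class[str(ec)]
                    for key in ("tp", "fp", "fn", "support"):
                        assert getattr(stats, key) == ref[key]
                    for key in ("precision", "recall", "f1"):
                        assert abs(getattr(stats, key) - ref[key]) < 1e-12
                for key, val in agg.items():
                    assert abs(lm.aggregates[key] - val) < 1e-12

    def test_single_label_micro_equals_exact_match_accuracy(self):
        rng = np.random.default_rng(7)
        classes = ["1.1.1.1", "2.3.1.4", "3.2.1.1", "4.1.1.1"]
        truth_strs = {f"P{i}": {str(rng.choice(classes))} for i in range(50)}
        pred_strs = {f"P{i}": {str(rng.choice(classes))} for i in range(50)}
        acc = sum(truth_strs[p] == pred_strs[p] for p in truth_strs) / 50
        truth = annot({p: sorted(s) for p, s in truth_strs.items()})
        predicted = {p: {parse_ec(e) for e in s} for p, s in pred_strs.items()}
        lm = evaluate_level(truth, predicted, 4)
        assert lm.aggregates["micro_precision"] == pytest.approx(acc)
        assert lm.aggregates["micro_recall"] == pytest.approx(acc)


class TestBatched:
    def test_batch_sizes_partition(self):
        truth = annot({f"P{i}": ["1.1.1.1"] for i in range(468)})
        predicted = {f"P{i}": {parse_ec("1.1.1.1")} for i in range(468)}
        bm = evaluate_batched(truth, predicted, 4, n_batches=5, seed=1)
        assert sorted(bm.batch_sizes, reverse=True) == [94, 94, 94, 93, 93]
        assert sum(bm.batch_sizes) == 468

    def test_homogeneous_performance_zero_sd(self):
        truth = annot({f"P{i}": ["1.1.1.1"] for i in range(20)})
        predicted = {f"P{i}": {parse_ec("1.1.1.1")} for i in range(20)}
        bm = evaluate_batched(truth, predicted, 4, n_batches=5, seed=3)
        assert bm.sd["weighted_f1"] == 0.0
        assert bm.mean["weighted_f1"] == 1.0

    def test_fewer_proteins_than_batches(self):
        truth = annot({"P1": ["1.1.1.1"], "P2": ["1.1.1.1"]})
        with pytest.raises(ValueError):
            evaluate_batched(truth, {}, 4, n_batches=5, seed=1)

    def test_batch_mean_close_to_pooled_on_homogeneous_data(self):
        # Monte-Carlo: on i.i.d. single-label data the mean of batch micro-F1
        # approaches pooled micro-F1
        rng = np.random.default_rng(11)
        classes = [f"{a}.1.1.1" for a in range(1, 7)]
        truth_strs, pred_strs = {}, {}
        for i in range(2000):
            c = str(rng.choice(classes))
            truth_strs[f"P{i}"] = {c}
            pred_strs[f"P{i}"] = {c if rng.random() < 0.8 else str(rng.choice(classes))}
        truth = annot({p: sorted(s) for p, s in truth_strs.items()})
        predicted = {p: {parse_ec(e) for e in s} for p, s in pred_strs.items()}
        pooled = evaluate_level(truth, predicted, 4).aggregates["micro_f1"]
        bm = evaluate_batched(truth, predicted, 4, n_batches=5, seed=5)
        assert abs(bm.mean["micro_f1"] - pooled) < 0.05


class TestByGroup:
    def test_single_group_matches_evaluate_level(self, simple_truth):
        predicted = {"P1": {parse_ec("1.1.1.1")}, "P2": {parse_ec("2.3.1.4")}}
        groups = {"P1": "g", "P2": "g"}
        by_group = evaluate_by_group(simple_truth, predicted, 4, groups)
        assert by_group["g"].aggregates == evaluate_level(
            simple_truth, predicted, 4
        ).aggregates

    def test_disjoint_groups_perfect_and_empty(self, simple_truth):
        predicted = {"P1": {parse_ec("1.1.1.1")}}
        groups = {"P1": "euk", "P2": "bac"}
        by_group = evaluate_by_group(simple_truth, predicted, 4, groups)
        assert by_group["euk"].aggregates["weighted_f1"] == 1.0
        assert by_group["bac"].aggregates["weighted_f1"] == 0.0

    def test_micro_tp_additivity_over_random_split(self):
        rng = np.random.default_rng(13)
        truth_strs, pred_strs = random_instance(rng, max_proteins=30)
        truth = annot({p: sorted(s) for p, s in truth_strs.items()})
        predicted = {p: {parse_ec(e) for e in s} for p, s in pred_strs.items()}
        groups = {p: ("a" if rng.random() < 0.5 else "b") for p in truth_strs}
        pooled_tp = sum(
            s.tp for s in evaluate_level(truth, predicted, 2).per_class.values()
        )
        group_tp = sum(
            s.tp
            for lm in evaluate_by_group(truth, predicted, 2, groups).values()
            for s in lm.per_class.values()
        )
        assert pooled_tp == group_tp

    def test_ungrouped_bucket(self, simple_truth):
        predicted = {}
        by_group = evaluate_by_group(simple_truth, predicted, 1, {"P1": "euk"})
        assert set(by_group) == {"euk", "ungrouped"}

    def test_unknown_grouped_protein_rejected(self, simple_truth):
        with pytest.raises(ValueError):
            evaluate_by_group(simple_truth, {}, 1, {"P9": "x"})


class TestPerClassTable:
    def test_matches_per_level_stats(self):
        rng = np.random.default_rng(17)
        truth_strs, pred_strs = random_instance(rng)
        truth = annot({p: sorted(s) for p, s in truth_strs.items()})
        predicted = {p: {parse_ec(e) for e in s} for p, s in pred_strs.items()}
        table = per_class_table(truth, predicted)
        for level in (1, 2, 3, 4):
            lm = evaluate_level(truth, predicted, level)
            for ec, stats in lm.per_class.items():
                assert table[ec]["f1"] == stats.f1
                assert table[ec]["support"] == stats.support

    def test_pred_only_node(self):
        truth = annot({"P1": ["1.1.1.1"]})
        predicted = {"P1": {parse_ec("1.1.1.1"), parse_ec("2.1.1.1")}}
        table = per_class_table(truth, predicted)
        assert table[parse_ec("2.1.1.1")]["support"] == 0
        assert table[parse_ec("2.1.1.1")]["f1"] == 0.0
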