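"""Metrics, agreement, and the stratified split."""

import random

import numpy as np
import pytest

from rehab_extract.evaluation import (
    DegenerateAgreementError,
    fleiss_kappa,
    numeric_metrics,
    sequence_metrics,
    span_metrics,
    split_train_test,
)
from rehab_extract.rule_extractor import SequenceLabels
from rehab_extract.standoff import AnnotatedSection, AnnotatedSequence


def _labels(ref, binary=(), **kw):
    return SequenceLabels(sequence_ref=ref, binary=set(binary), **kw)


def _section(sid, seq_specs):
    """seq_specs: list of (label, mentions, labels_kwargs)."""
    seqs = []
    for i, (binary, mentions, kw) in enumerate(seq_specs, 1):
        seqs.append(
            AnnotatedSequence(
                index_label=str(i),
                span=(0, 1),
                labels=_labels(f"{sid}#{i}", binary, **kw),
                mentions=mentions,
            )
        )
    return AnnotatedSection(section_id=sid, text="x", sequences=seqs)


class TestSequenceMetrics:
    def test_identical_labelings_score_one(self):
        sets = {"a#1": {"x", "y"}, "a#2": {"x"}}
        rep = sequence_metrics(sets, sets, min_support=1)
        assert all(s.f1 == 1.0 for s in rep.scores.values())
        assert rep.macro_f1 == 1.0

    def test_half_half_case(self):
        # concept x: TP=1, FP=1, FN=1 over three sequences
        pred = {"s#1": {"x"}, "s#2": {"x"}, "s#3": set()}
        gold = {"s#1": {"x"}, "s#2": set(), "s#3": {"x"}}
        rep = sequence_metrics(pred, gold, min_support=1)
        s = rep.scores["x"]
        assert (s.precision, s.recall, s.f1) == (0.5, 0.5, 0.5)
        assert s.tn == 0

    def test_concept_absent_everywhere_excluded(self):
        pred = {"s#1": {"x"}}
        gold = {"s#1": {"x"}}
        rep = sequence_metrics(pred, gold, min_support=1)
        assert "y" not in rep.scores

    def test_min_support_gates_macro_average(self):
        pred = {f"s#{i}": {"common"} for i in range(12)}
        gold = dict(pred)
        gold["s#0"] = {"common", "rare"}
        rep = sequence_metrics(pred, gold, min_support=10)
        assert "rare" in rep.scores  # reported per-concept
        assert rep.reported_concepts == ["common"]  # but not averaged

    def test_id_mismatch_lists_orphans(self):
        with pytest.raises(ValueError, match="s#2"):
            sequence_metrics({"s#1": set()}, {"s#2": set()})

    def test_swapping_pred_and_gold_swaps_p_and_r(self):
        rng = random.Random(0)
        ids = [f"s#{i}" for i in range(30)]
        pred = {i: {c for c in "abc" if rng.random() < 0.4} for i in ids}
        gold = {i: {c for c in "abc" if rng.random() < 0.4} for i in ids}
        fwd = sequence_metrics(pred, gold, min_support=1)
        rev = sequence_metrics(gold, pred, min_support=1)
        for cid in fwd.scores:
            assert fwd.scores[cid].precision == pytest.approx(
                rev.scores[cid].recall
            )
            assert fwd.scores[cid].f1 == pytest.approx(rev.scores[cid].f1)

    def test_agrees_with_brute_force_on_random_corpora(self):
        rng = random.Random(7)
        concepts = list("abcde")
        for _ in range(50):
            ids = [f"s#{i}" for i in range(rng.randint(1, 20))]
            pred = {i: {c for c in concepts if rng.random() < 0.3} for i in ids}
            gold = {i: {c for c in concepts if rng.random() < 0.3} for i in ids}
            rep = sequence_metrics(pred, gold, min_support=1)
            for cid in concepts:
                tp = sum(cid in pred[i] and cid in gold[i] for i in ids)
                fp = sum(cid in pred[i] and cid not in gold[i] for i in ids)
                fn = sum(cid not in pred[i] and cid in gold[i] for i in ids)
                if tp + fp + fn == 0:
                    assert cid not in rep.scores
                    continue
                s = rep.scores[cid]
                assert (s.tp, s.fp, s.fn) == (tp, fp, fn)
                p = tp / (tp + fp) if tp + fp else 0.0
                r = tp / (tp + fn) if tp + fn else 0.0
                f1 = 2 * p * r / (p + r) if p + r else 0.0
                assert s.f1 == pytest.approx(f1)


class TestSpanMetrics:
    def _pair(self, pred_span):
        gold = [_section("s", [((), [((0, 4), "x")], {})])]
        pred = [_section("s", [((), [(pred_span, "x")], {})])]
        return pred, gold

    def test_identical_standoffs_perfect_both_modes(self):
        pred, gold = self._pair((0, 4))
        reps = span_metrics(pred, gold, min_support=1)
        assert reps["exact"].scores["x"].f1 == 1.0
        assert reps["overlap"].scores["x"].f1 == 1.0

    def test_off_by_one_splits_the_modes(self):
        pred, gold = self._pair((1, 5))
        reps = span_metrics(pred, gold, min_support=1)
        exact = reps["exact"].scores["x"]
        assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
        assert reps["overlap"].scores["x"].f1 == 1.0

    def test_disjoint_spans_fail_both_modes(self):
        pred, gold = self._pair((10, 14))
        reps = span_metrics(pred, gold, min_support=1)
        for mode in ("exact", "overlap"):
            s = reps[mode].scores["x"]
            assert (s.tp, s.fp, s.fn) == (0, 1, 1)

    def test_concept_must_match_even_when_spans_do(self):
        gold = [_section("s", [((), [((0, 4), "x")], {})])]
        pred = [_section("s", [((), [((0, 4), "y")], {})])]
        reps = span_metrics(pred, gold, min_support=1)
        assert reps["overlap"].scores["x"].fn == 1
        assert reps["overlap"].scores["y"].fp == 1

    def test_invalid_span_rejected(self):
        bad = [_section("s", [((), [((4, 4), "x")], {})])]
        with pytest.raises(ValueError, match="invalid"):
            span_metrics(bad, bad)


class TestNumericMetrics:
    def test_matching_reps(self):
        gold = [_section("s", [((), [], {"reps": 10})])]
        pred = [_section("s", [((), [], {"reps": 10})])]
        s = numeric_metrics(pred, gold)["reps"]
        assert (s.tp, s.fp, s.fn) == (1, 0, 0) and s.f1 == 1.0

    def test_minute_normalized_duration_matches_seconds(self):
        # gold authored as 1 minute -> stored normalized as 60 s
        gold = [_section("s", [((), [], {"duration_seconds": 60})])]
        pred = [_section("s", [((), [], {"duration_seconds": 60})])]
        assert numeric_metrics(pred, gold)["duration_seconds"].tp == 1

    def test_kind_mismatch_counts_both_ways(self):
        gold = [_section("s", [((), [], {"reps": 2})])]
        pred = [_section("s", [((), [], {"sets": 2})])]
        res = numeric_metrics(pred, gold)
        assert res["sets"].fp == 1 and res["reps"].fn == 1

    def test_value_mismatch(self):
        gold = [_section("s", [((), [], {"reps": 10})])]
        pred = [_section("s", [((), [], {"reps": 12})])]
        res = numeric_metrics(pred, gold)
        assert res["reps"].fp == 1 and res["reps"].fn == 1


class TestFleissKappa:
    def test_perfect_agreement_is_one(self):
        table = [[3, 0], [0, 3], [3, 0], [0, 3]]
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_hand_computed_worked_instance(self):
        # 4 items, 3 raters, 2 categories.
        # P_i = (sum n_ij^2 - m) / (m(m-1)) -> [1, 1/3, 1/3, 1]
        # Pbar = 2/3; p_j = [.5, .5] -> Pe = .5; kappa = (2/3-.5)/.5 = 1/3
        table = [[3, 0], [2, 1], [1, 2], [0, 3]]
        assert fleiss_kappa(table) == pytest.approx(1 / 3)

    def test_independent_uniform_ratings_approach_zero(self):
        rng = np.random.default_rng(12345)
        n_items, m, k = 10_000, 3, 2
        table = np.zeros((n_items, k), dtype=int)
        draws = rng.integers(0, k, size=(n_items, m))
        for i in range(n_items):
            for c in draws[i]:
                table[i, c] += 1
        assert abs(fleiss_kappa(table)) < 0.02

    def test_single_category_throughout_is_undefined(self):
        with pytest.raises(DegenerateAgreementError):
            fleiss_kappa([[3, 0], [3, 0], [3, 0]])

    def test_invariant_to_item_permutation(self):
        rng = np.random.default_rng(7)
        table = rng.multinomial(4, [0.5, 0.3, 0.2], size=50)
        k1 = fleiss_kappa(table)
        k2 = fleiss_kappa(table[rng.permutation(50)])
        assert k1 == pytest.approx(k2)

    def test_unequal_rating_totals_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            fleiss_kappa([[3, 0], [2, 0]])


class TestSplit:
    def test_paper_arithmetic_150_plus_150(self):
        enr = [f"e{i}" for i in range(150)]
        rnd = [f"r{i}" for i in range(150)]
        train, test = split_train_test(enr, rnd, rng_seed=1)
        assert len(train) == 250 and len(test) == 50
        assert sum(1 for s in train if s.startswith("e")) == 125
        assert set(train).isdisjoint(test)
        assert set(train) | set(test) == set(enr) | set(rnd)

    def test_reproducible_under_seed(self):
        enr, rnd = list(range(150)), list(range(150, 300))
        a = split_train_test(enr, rnd, rng_seed=9)
        b = split_train_test(enr, rnd, rng_seed=9)
        assert a == b
        c = split_train_test(enr, rnd, rng_seed=10)
        assert a != c

    def test_small_strata_fall_back_proportionally(self):
        enr, rnd = list(range(100)), list(range(100, 200))
        with pytest.warns(UserWarning, match="proportional"):
            train, test = split_train_test(enr, rnd, rng_seed=0)
        # 5:1 ratio preserved: 83 of each 100-section stratum to train
        assert len(train) == 166 and len(test) == 34
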