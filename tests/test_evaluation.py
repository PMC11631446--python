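import numpy as np
import pytest
from hypothesis import given, strategies as st

from neurotext.evaluation import (
    classification_report, confusion, cross_validate, match_spans, ner_report, prf,
)
from neurotext.types import EntitySpan, LabeledSentence, RELATION_CLASSES


def random_span_set(rng, n_tokens, max_spans=4):
    """Non-overlapping random spans in a sentence of n_tokens."""
    spans = []
    pos = 0
    for _ in range(max_spans):
        if pos >= n_tokens:
            break
        start = pos + int(rng.integers(0, 3))
        end = start + int(rng.integers(1, 4))
        if end > n_tokens:
            break
        spans.append(EntitySpan(start, end))
        pos = end + int(rng.integers(0, 2))
    return spans


def optimal_match_count(gold, pred):
    """Brute-force maximum bipartite matching under the containment rule."""
    from itertools import permutations
    best = 0
    idx = range(len(gold))
    for perm in permutations(idx, min(len(gold), len(pred))):
        n = sum(1 for p, gi in zip(pred, perm) if gold[gi].contains(p))
        best = max(best, n)
    # permutations fix pred order; also try subsets of pred via masks
    if len(pred) > len(gold):
        from itertools import combinations
        for sub in combinations(range(len(pred)), len(gold)):
            for perm in permutations(idx):
                n = sum(1 for pi, gi in zip(sub, perm) if gold[gi].contains(pred[pi]))
                best = max(best, n)
    return best


class TestMatchSpans:
    def test_smaller_span_is_lenient_only(self):
        gold, pred = [EntitySpan(2, 6)], [EntitySpan(3, 6)]
        assert match_spans(gold, pred, "exact") == (0, 1, 1)
        assert match_spans(gold, pred, "lenient") == (1, 0, 0)

    def test_larger_than_gold_never_matches(self):
        """Predicted boundaries may be smaller or equal, never larger."""
        gold, pred = [EntitySpan(2, 6)], [EntitySpan(1, 6)]
        assert match_spans(gold, pred, "lenient") == (0, 1, 1)

    def test_identical_sets_fully_match(self):
        spans = [EntitySpan(0, 2), EntitySpan(4, 7)]
        for mode in ("exact", "lenient"):
            assert match_spans(spans, spans, mode) == (2, 0, 0)

    def test_gold_credited_once(self):
        gold = [EntitySpan(0, 5)]
        pred = [EntitySpan(0, 2), EntitySpan(3, 5)]
        assert match_spans(gold, pred, "lenient") == (1, 1, 0)

    def test_overlapping_predictions_rejected(self):
        with pytest.raises(ValueError):
            match_spans([], [EntitySpan(0, 3), EntitySpan(2, 4)], "exact")

    @given(st.integers(0, 10_000))
    def test_lenient_dominates_exact(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 16))
        gold, pred = random_span_set(rng, n), random_span_set(rng, n)
        tp_e, *_ = match_spans(gold, pred, "exact")
        tp_l, *_ = match_spans(gold, pred, "lenient")
        assert tp_l >= tp_e

    def test_greedy_equals_optimal_matcher(self):
        """Greedy assignment equals brute-force optimal on <=5x5 sets."""
        rng = np.random.default_rng(8)
        for _ in range(500):
            n = int(rng.integers(6, 20))
            gold, pred = random_span_set(rng, n, 5), random_span_set(rng, n, 5)
            tp, _, _ = match_spans(gold, pred, "lenient")
            assert tp == optimal_match_count(gold, pred)


class TestPRF:
    def test_basic_and_zero_conventions(self):
        assert prf(8, 2, 2) == pytest.approx((0.8, 0.8, 0.8))
        assert prf(0, 0, 0) == (0.0, 0.0, 0.0)
        assert prf(0, 3, 0) == (0.0, 0.0, 0.0)

    def test_matches_formula_recomputation(self):
        rng = np.random.default_rng(9)
        for _ in range(300):
            tp, fp, fn = (int(x) for x in rng.integers(0, 50, 3))
            p, r, f = prf(tp, fp, fn)
            pe = tp / (tp + fp) if tp + fp else 0.0
            re = tp / (tp + fn) if tp + fn else 0.0
            fe = 2 * pe * re / (pe + re) if pe + re else 0.0
            assert (p, r, f) == pytest.approx((pe, re, fe), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            prf(-1, 0, 0)


class TestConfusion:
    def test_perfect_predictions_identity(self):
        labels = list(RELATION_CLASSES) * 3
        cm = confusion(labels, labels)
        assert np.array_equal(cm.normalized, np.eye(4))
        assert cm.total == 12

    def test_collapsed_predictions(self):
        gold = list(RELATION_CLASSES)
        pred = ["unconnected"] * 4
        cm = confusion(gold, pred)
        assert cm.counts[:, 0].sum() == 4 and cm.counts[:, 1:].sum() == 0

    def test_row_normalization_sums_to_one(self):
        rng = np.random.default_rng(10)
        gold = [RELATION_CLASSES[i] for i in rng.integers(0, 4, 100)]
        pred = [RELATION_CLASSES[i] for i in rng.integers(0, 4, 100)]
        cm = confusion(gold, pred)
        sums = cm.normalized.sum(axis=1)
        assert np.allclose(sums[cm.counts.sum(axis=1) > 0], 1.0)
        assert cm.total == 100

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["unconnected"], ["sideways"])

    def test_macro_micro_reports(self):
        gold = ["output", "output", "input", "unconnected"]
        pred = ["output", "input", "input", "unconnected"]
        macro = classification_report(gold, pred)
        micro = classification_report(gold, pred, average="micro")
        assert micro.f1 == pytest.approx(0.75)
        assert 0 < macro.f1 < 1


class TestCrossValidation:
    def _corpus(self, n_docs):
        return [LabeledSentence(f"d{i}", j, ["tok"], ["O"])
                for i in range(n_docs) for j in range(2)]

    @staticmethod
    def _pipeline(train, test):
        docs = {s.doc_id for s in test}
        score = (min(int(d[1:]) for d in docs) + 1) / 10
        return {"precision": score, "recall": score, "f1": score}

    def test_each_unit_tested_once(self):
        corpus = self._corpus(8)
        seen = []
        def pipeline(train, test):
            seen.extend({s.doc_id for s in test})
            return {"precision": 1.0, "recall": 1.0, "f1": 1.0}
        cross_validate(corpus, 8, pipeline, seed=0)
        assert sorted(seen) == sorted({s.doc_id for s in corpus})

    def test_deterministic_given_seed(self):
        corpus = self._corpus(8)
        a = cross_validate(corpus, 4, self._pipeline, seed=3)
        b = cross_validate(corpus, 4, self._pipeline, seed=3)
        assert a.fold_values == b.fold_values

    def test_report_mean_equals_fold_mean(self):
        corpus = self._corpus(9)
        rep = cross_validate(corpus, 3, self._pipeline, seed=1)
        assert rep.f1 == pytest.approx(
            np.mean([m["f1"] for m in rep.fold_values]), abs=1e-12)
        assert rep.sd["f1"] == pytest.approx(
            np.std([m["f1"] for m in rep.fold_values], ddof=1), abs=1e-12)

    def test_k_larger_than_units_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(self._corpus(3), 5, self._pipeline, seed=0)


class TestNerReport:
    def test_lenient_f1_dominates_exact(self, synth_corpus):
        gold = [s.spans() for s in synth_corpus.ground_truth.sentences]
        rng = np.random.default_rng(11)
        pred = []
        for spans in gold:
            row = []
            for sp in spans:
                if rng.random() < 0.3 and len(sp) > 1:
                    row.append(EntitySpan(sp.start + 1, sp.end))
                elif rng.random() < 0.8:
                    row.append(EntitySpan(sp.start, sp.end))
            pred.append(row)
        exact = ner_report(gold, pred, "exact")
        lenient = ner_report(gold, pred, "lenient")
        assert lenient.f1 >= exact.f1
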