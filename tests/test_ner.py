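import numpy as np
import pytest

from neurotext.corpus_io import derive_pointer_tags, labels_from_spans
from neurotext.linking import Gazetteer
from neurotext.ner import (
    DecodeConfig, NERHeads, NERLossConfig, NERPrediction, augment_by_repetition,
    decode_entities, ner_loss, predict_heads, trie_denoise,
)
from neurotext.types import EntitySpan, LabeledSentence

from conftest import random_bio

B, I, O = "B-BrainRegion", "I-BrainRegion", "O"


def brute_force_ce(probs, gold_idx, eps=1e-12):
    """Independent renormalized cross-entropy, one scalar log at a time."""
    total = 0.0
    for row, g in zip(probs, gold_idx):
        p = row[g] / sum(row)
        total += -np.log(max(p, eps))
    return total


def make_prediction(rng, n, peaked_on=None):
    if peaked_on is None:
        return NERPrediction(rng.uniform(0.01, 0.99, (n, 3)),
                             rng.uniform(0.01, 0.99, (n, 2)),
                             rng.uniform(0.01, 0.99, (n, 2)))
    labels, start, end = peaked_on
    pl = np.zeros((n, 3))
    pl[np.arange(n), [["O", B, I].index(l) for l in labels]] = 1.0
    ps = np.eye(2)[start]
    pe = np.eye(2)[end]
    return NERPrediction(pl, ps, pe)


class TestHeads:
    def test_zero_weights_give_half(self):
        heads = NERHeads(8)
        for p in heads.params():
            p.data[:] = 0.0
        pred = predict_heads(np.random.default_rng(0).normal(size=(4, 8)), heads)
        assert np.allclose(pred.label_probs, 0.5)
        assert np.allclose(pred.start_probs, 0.5)

    def test_hand_computed_affine_sigmoid(self):
        """Two tokens, H=2: probabilities equal sigmoid of Wx+b by hand."""
        heads = NERHeads(2)
        heads.Wl.data = np.array([[1.0, 0.0, -1.0], [0.5, 2.0, 0.0]])
        heads.bl.data = np.array([0.1, -0.2, 0.0])
        O_mat = np.array([[1.0, 2.0], [-1.0, 0.5]])
        pred = predict_heads(O_mat, heads)
        expect = 1 / (1 + np.exp(-(O_mat @ heads.Wl.data + heads.bl.data)))
        assert np.allclose(pred.label_probs, expect, atol=1e-12)

    def test_output_shapes(self):
        heads = NERHeads(16)
        pred = predict_heads(np.zeros((7, 16)), heads)
        assert pred.label_probs.shape == (7, 3)
        assert pred.start_probs.shape == (7, 2)
        assert pred.end_probs.shape == (7, 2)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            predict_heads(np.zeros((3, 5)), NERHeads(16))


class TestLoss:
    def _gold(self, labels):
        return LabeledSentence("d", 0, ["t"] * len(labels), list(labels))

    def test_perfect_prediction_is_zero(self):
        labels = [O, B, I, O]
        t, d = derive_pointer_tags(labels)
        pred = make_prediction(None, 4, (labels, t, d))
        assert ner_loss(pred, self._gold(labels)) < 1e-9

    def test_lambda_zero_reduces_to_label_ce(self):
        rng = np.random.default_rng(1)
        labels = random_bio(rng, 6)
        pred = make_prediction(rng, 6)
        got = ner_loss(pred, self._gold(labels), NERLossConfig(lambda_=0.0))
        y = [["O", B, I].index(l) for l in labels]
        assert got == pytest.approx(brute_force_ce(pred.label_probs, y) / 6, abs=1e-9)

    def test_uniform_closed_form(self):
        """Uniform heads, 1 token, lambda=1: loss = ln3 + 2 ln2."""
        pred = NERPrediction(np.full((1, 3), 0.5), np.full((1, 2), 0.5),
                             np.full((1, 2), 0.5))
        got = ner_loss(pred, self._gold([O]), NERLossConfig(lambda_=1.0))
        assert got == pytest.approx(np.log(3) + 2 * np.log(2), abs=1e-9)

    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0, 2.0])
    def test_loss_decomposition(self, lam):
        rng = np.random.default_rng(int(lam * 10) + 2)
        labels = random_bio(rng, 9)
        gold = self._gold(labels)
        pred = make_prediction(rng, 9)
        base = ner_loss(pred, gold, NERLossConfig(lambda_=0.0))
        pointer = (brute_force_ce(pred.start_probs, gold.start_tags)
                   + brute_force_ce(pred.end_probs, gold.end_tags)) / 9
        assert ner_loss(pred, gold, NERLossConfig(lambda_=lam)) == \
            pytest.approx(base + lam * pointer, abs=1e-9)

    def test_zero_probability_is_clamped_not_nan(self):
        pl = np.array([[0.0, 1.0, 0.0]])
        pred = NERPrediction(pl, np.array([[1.0, 0.0]]), np.array([[1.0, 0.0]]))
        loss = ner_loss(pred, self._gold([O]))
        assert np.isfinite(loss) and loss > 0


def oracle_decode(pred, cfg):
    """Exhaustive enumeration of valid start/end pairs under the same rule."""
    n = len(pred)
    norm = lambda p: p[:, 1] / p.sum(axis=1)
    starts = [i for i in range(n) if norm(pred.start_probs)[i] >= cfg.threshold]
    ends = [j for j in range(n) if norm(pred.end_probs)[j] >= cfg.threshold]
    best = pred.label_probs.argmax(axis=1)
    valid = []
    for i in starts:
        within = [j for j in ends if i <= j < i + cfg.max_entity_length]
        if not within:
            continue
        j = min(within)
        if all(best[k] != 0 for k in range(i, j + 1)):
            valid.append((i, j + 1))
    chosen = []
    for s, e in sorted(valid):
        if all(e <= cs or s >= ce for cs, ce in chosen):
            chosen.append((s, e))
    return chosen


class TestDecode:
    def test_one_hot_gold_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            labels = random_bio(rng, int(rng.integers(1, 12)))
            t, d = derive_pointer_tags(labels)
            pred = make_prediction(None, len(labels), (labels, t, d))
            spans = decode_entities(pred)
            expect = [(s.start, s.end) for s in
                      LabeledSentence("d", 0, ["t"] * len(labels), labels).spans()]
            assert [(s.start, s.end) for s in spans] == expect

    def test_unpaired_start_emits_nothing(self):
        pl = np.tile([0.0, 1.0, 0.0], (3, 1))
        ps = np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
        pe = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])  # no end fires
        assert decode_entities(NERPrediction(pl, ps, pe)) == []

    def test_matches_exhaustive_oracle_on_short_sentences(self):
        rng = np.random.default_rng(4)
        cfg = DecodeConfig()
        for _ in range(2000):
            pred = make_prediction(rng, int(rng.integers(1, 9)))
            got = [(s.start, s.end) for s in decode_entities(pred, cfg)]
            assert got == oracle_decode(pred, cfg)

    def test_bio_mode_ignores_pointers(self):
        pl = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        pred = NERPrediction(pl, np.zeros((3, 2)) + 0.5, np.zeros((3, 2)) + 0.5)
        spans = decode_entities(pred, DecodeConfig(mode="bio"))
        assert [(s.start, s.end) for s in spans] == [(0, 2)]


class TestAugmentation:
    def _corpus(self, n):
        return [LabeledSentence("d", i, [f"t{i}"], [O]) for i in range(n)]

    def test_factor_two_duplicates_each(self):
        out = augment_by_repetition(self._corpus(10), 2, seed=0)
        assert len(out) == 20
        counts = {}
        for s in out:
            counts[s.sent_id] = counts.get(s.sent_id, 0) + 1
        assert all(c == 2 for c in counts.values())

    def test_factor_one_is_identity_multiset(self):
        corpus = self._corpus(5)
        out = augment_by_repetition(corpus, 1, seed=1)
        assert sorted(s.sent_id for s in out) == [0, 1, 2, 3, 4]

    def test_seed_determinism_and_factor_error(self):
        corpus = self._corpus(8)
        a = [s.sent_id for s in augment_by_repetition(corpus, 3, seed=5)]
        b = [s.sent_id for s in augment_by_repetition(corpus, 3, seed=5)]
        assert a == b
        with pytest.raises(ValueError):
            augment_by_repetition(corpus, 0, seed=0)


class TestTrieDenoise:
    def _gazetteer(self, forms):
        g = Gazetteer()
        for i, f in enumerate(forms):
            g.add(f, f"G:{i}")
        return g

    def test_truncated_annotation_extended_to_dictionary_form(self):
        tokens = ["the", "anterior", "hypothalamic", "nucleus", "fired", "."]
        labels = labels_from_spans([EntitySpan(2, 4)], 6)  # missing "anterior"
        sent = LabeledSentence("d", 0, tokens, labels)
        gaz = self._gazetteer(["anterior hypothalamic nucleus"])
        out = trie_denoise([sent], gaz)[0]
        assert [(s.start, s.end) for s in out.spans()] == [(1, 4)]

    def test_no_dictionary_hit_leaves_sentence_unchanged(self):
        sent = LabeledSentence("d", 0, ["alpha", "beta"], [B, O])
        out = trie_denoise([sent], self._gazetteer(["gamma delta"]))[0]
        assert out.labels == sent.labels

    def test_empty_gazetteer_is_identity(self):
        sent = LabeledSentence("d", 0, ["alpha"], [B])
        out = trie_denoise([sent], Gazetteer())[0]
        assert out.labels == sent.labels

    def test_idempotent_on_random_synthetic_sentences(self, synth_corpus, synth_ontology):
        _, gaz = synth_ontology
        sents = synth_corpus.ner_sentences[:200]
        once = trie_denoise(sents, gaz)
        twice = trie_denoise(once, gaz)
        assert [s.labels for s in once] == [s.labels for s in twice]

    def test_restores_boundary_noise(self, synth_ontology):
        from neurotext.synthetic import SynthConfig, generate_corpus
        entries, gaz = synth_ontology
        cfg = SynthConfig(n_regions=30, n_documents=20, sentences_per_document=6,
                          boundary_noise_rate=0.5, seed=5)
        corpus = generate_corpus(cfg, entries)
        gaz = Gazetteer.from_entries(corpus.ground_truth.ontology)
        denoised = trie_denoise(corpus.ner_sentences, gaz)
        clean = corpus.ground_truth.sentences
        n_bad_before = sum(a.labels != b.labels
                           for a, b in zip(corpus.ner_sentences, clean))
        n_bad_after = sum(a.labels != b.labels for a, b in zip(denoised, clean))
        assert n_bad_before > 0 and n_bad_after < n_bad_before
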