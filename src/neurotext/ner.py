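"""Pointer-augmented named-entity recognition for brain regions.

The model predicts, for every word, three quantities from a shared
contextual encoding: a BIO label distribution, a binary start-pointer and
a binary end-pointer. Each head is an affine map followed by an
elementwise sigmoid; for the cross-entropy objective the per-row sigmoid
activations are renormalized to a distribution. The joint loss is

    L = (1/N) [ CE(labels) + lambda * ( CE(starts) + CE(ends) ) ]

with N the number of scored word positions (special and padding
positions, and non-initial sub-tokens of a word, are excluded).

Decoding reconciles the three heads ("paired-pointer" mode): starts and
ends are thresholded, each start is paired with the nearest subsequent
end within a maximum entity length, pairs whose tokens look like O are
discarded, and spans are taken greedily left to right without overlaps.
A "bio-only" mode decodes from the label head alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .corpus_io import labels_from_spans, repair_bio, spans_from_labels
from .nn import Adam, EncoderConfig, Tensor, TransformerEncoder, WordPieceTokenizer
from .types import BIO_LABELS, EntitySpan, LabeledSentence

logger = logging.getLogger(__name__)

__all__ = [
    "NERPrediction", "NERLossConfig", "DecodeConfig", "NERHeads",
    "predict_heads", "ner_loss", "decode_entities",
    "augment_by_repetition", "trie_denoise", "NERTagger",
]

EPS = 1e-12


@dataclass
class NERPrediction:
    """Per-word sigmoid activations of the three heads.

    Rows are words; ``label_probs`` has M1 columns (BIO classes) and the
    pointer arrays M2=2 columns (absent, present). Values lie in [0, 1]
    but rows are not normalized — normalization happens inside the loss.
    """

    label_probs: np.ndarray  # (n, M1)
    start_probs: np.ndarray  # (n, M2)
    end_probs: np.ndarray    # (n, M2)

    def __post_init__(self) -> None:
        n = self.label_probs.shape[0]
        if self.start_probs.shape[0] != n or self.end_probs.shape[0] != n:
            raise ValueError("head outputs disagree on token count")
        for arr in (self.label_probs, self.start_probs, self.end_probs):
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("probabilities must lie in [0, 1]")

    def __len__(self) -> int:
        return self.label_probs.shape[0]


@dataclass
class NERLossConfig:
    lambda_: float = 1.0
    M1: int = 3
    M2: int = 2

    def __post_init__(self) -> None:
        if self.lambda_ < 0:
            raise ValueError("lambda must be non-negative")
        if self.M1 < 2 or self.M2 != 2:
            raise ValueError("need M1 >= 2 and M2 == 2")


@dataclass
class DecodeConfig:
    mode: str = "paired"  # paired | bio
    threshold: float = 0.5
    max_entity_length: int = 10


class NERHeads:
    """Three affine-plus-sigmoid prediction heads over encoder outputs."""

    def __init__(self, hidden_size: int, M1: int = 3, M2: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(hidden_size)
        self.Wl = Tensor(rng.normal(0, scale, (hidden_size, M1)), requires_grad=True)
        self.bl = Tensor(np.zeros(M1), requires_grad=True)
        self.Ws = Tensor(rng.normal(0, scale, (hidden_size, M2)), requires_grad=True)
        self.bs = Tensor(np.zeros(M2), requires_grad=True)
        self.We = Tensor(rng.normal(0, scale, (hidden_size, M2)), requires_grad=True)
        self.be = Tensor(np.zeros(M2), requires_grad=True)

    def forward(self, O: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        return (
            (O @ self.Wl + self.bl).sigmoid(),
            (O @ self.Ws + self.bs).sigmoid(),
            (O @ self.We + self.be).sigmoid(),
        )

    def params(self):
        return [self.Wl, self.bl, self.Ws, self.bs, self.We, self.be]


def predict_heads(O: np.ndarray, heads: NERHeads) -> NERPrediction:
    """Apply the three heads to word-aligned encoder outputs (numpy path)."""
    O = np.asarray(O, dtype=float)
    if O.ndim != 2 or O.shape[1] != heads.Wl.shape[0]:
        raise ValueError(f"expected (n, {heads.Wl.shape[0]}) encoder outputs, got {O.shape}")
    pl, ps, pe = heads.forward(Tensor(O))
    return NERPrediction(pl.data, ps.data, pe.data)


def _gold_arrays(gold: LabeledSentence) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    y = np.array([BIO_LABELS.index(lab) for lab in gold.labels])
    return y, np.asarray(gold.start_tags), np.asarray(gold.end_tags)


def _row_ce(probs: np.ndarray, gold_idx: np.ndarray) -> float:
    """Cross-entropy of row-renormalized sigmoid activations at gold classes."""
    norm = probs / np.clip(probs.sum(axis=1, keepdims=True), EPS, None)
    picked = norm[np.arange(len(gold_idx)), gold_idx]
    if np.any(picked <= EPS):
        logger.debug("clamping %d zero probabilities in cross-entropy", int((picked <= EPS).sum()))
    return float(-np.log(np.clip(picked, EPS, None)).sum())


def ner_loss(pred: NERPrediction, gold: LabeledSentence, cfg: NERLossConfig | None = None) -> float:
    """Joint label + pointer cross-entropy, averaged over scored positions."""
    cfg = cfg or NERLossConfig()
    if len(pred) != len(gold.tokens):
        raise ValueError("prediction rows do not match gold tokens")
    if pred.label_probs.shape[1] != cfg.M1 or pred.start_probs.shape[1] != cfg.M2:
        raise ValueError("head widths disagree with loss config")
    y, t, d = _gold_arrays(gold)
    n = len(y)
    label_ce = _row_ce(pred.label_probs, y)
    start_ce = _row_ce(pred.start_probs, t)
    end_ce = _row_ce(pred.end_probs, d)
    return (label_ce + cfg.lambda_ * (start_ce + end_ce)) / n


def _present(pointer_probs: np.ndarray, threshold: float) -> np.ndarray:
    """Thresholded 'pointer present' decision per row (renormalized)."""
    norm = pointer_probs / np.clip(pointer_probs.sum(axis=1, keepdims=True), EPS, None)
    return norm[:, 1] >= threshold


def decode_entities(pred: NERPrediction, cfg: DecodeConfig | None = None) -> list[EntitySpan]:
    """Deterministic span decoding from the three heads."""
    cfg = cfg or DecodeConfig()
    n = len(pred)
    best = pred.label_probs.argmax(axis=1)
    if cfg.mode == "bio":
        labels = repair_bio([BIO_LABELS[i] for i in best])
        return spans_from_labels(labels)
    if cfg.mode != "paired":
        raise ValueError(f"unknown decode mode {cfg.mode!r}")
    starts = _present(pred.start_probs, cfg.threshold)
    ends = _present(pred.end_probs, cfg.threshold)
    spans: list[EntitySpan] = []
    i = 0
    while i < n:
        if not starts[i]:
            i += 1
            continue
        limit = min(n, i + cfg.max_entity_length)
        j = next((j for j in range(i, limit) if ends[j]), None)
        if j is None or np.any(best[i:j + 1] == 0):  # interior looks like O
            i += 1
            continue
        spans.append(EntitySpan(i, j + 1))
        i = j + 1
    return spans


def augment_by_repetition(
    corpus: list[LabeledSentence], factor: int, seed: int = 0
) -> list[LabeledSentence]:
    """Expand the training set by whole-corpus repetition, then shuffle."""
    if factor < 1:
        raise ValueError("repetition factor must be >= 1")
    out = [s.copy() for s in corpus for _ in range(factor)]
    rng = np.random.default_rng(seed)
    return [out[i] for i in rng.permutation(len(out))]


def trie_denoise(corpus: list[LabeledSentence], gazetteer) -> list[LabeledSentence]:
    """Correct annotations against dictionary longest matches.

    Every maximal longest match of a gazetteer surface form becomes one
    annotated entity; gold spans that overlap a dictionary match are
    merged (union) with it, so truncated boundaries get extended back to
    the full dictionary form. Sentences without any dictionary hit are
    returned unchanged. The transform is idempotent.
    """
    if len(gazetteer) == 0:
        logger.warning("trie_denoise called with an empty gazetteer; corpus unchanged")
        return [s.copy() for s in corpus]
    out = []
    for sent in corpus:
        matches = [(m.start, m.end) for m in gazetteer.longest_matches(sent.tokens)]
        if not matches:
            out.append(sent.copy())
            continue
        existing = [(sp.start, sp.end) for sp in sent.spans()]
        touched = [iv for iv in existing
                   if any(iv[0] < e and s < iv[1] for s, e in matches)]
        untouched = [iv for iv in existing if iv not in touched]
        # union-merge matches with the gold spans they overlap
        merged: list[list[int]] = []
        for s, e in sorted(matches + touched):
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        spans = [EntitySpan(s, e) for s, e in merged]
        spans += [EntitySpan(s, e) for s, e in untouched
                  if not any(sp.start < e and s < sp.end for sp in spans)]
        labels = labels_from_spans(spans, len(sent.tokens))
        out.append(sent.with_labels(labels))
    return out


@dataclass
class TrainConfig:
    epochs: int = 12
    batch_size: int = 32
    learning_rate: float = 3e-3
    lambda_: float = 1.0
    seed: int = 0


class NERTagger:
    """End-to-end trainable tagger: tokenizer + encoder + three heads."""

    def __init__(self, encoder_config: EncoderConfig | None = None, seed: int = 0,
                 lambda_: float = 1.0):
        self.cfg = encoder_config or EncoderConfig()
        self.seed = seed
        self.loss_cfg = NERLossConfig(lambda_=lambda_)
        self.tokenizer = WordPieceTokenizer()
        self.encoder: TransformerEncoder | None = None
        self.heads: NERHeads | None = None

    # -- encoding ----------------------------------------------------------

    def _require_model(self) -> None:
        if self.encoder is None or self.heads is None:
            raise RuntimeError("model is not trained or loaded")

    def encode(self, tokens: list[str]) -> tuple[np.ndarray, list[int]]:
        """Contextual vectors for one sentence's sub-tokens.

        Returns an ``(n', H)`` array including the [CLS]/[SEP] positions
        and the sub-token -> word alignment map (-1 on specials).
        """
        self._require_model()
        if not tokens:
            raise ValueError("cannot encode an empty sentence")
        ids, align = self.tokenizer.encode(tokens)
        if len(ids) > self.cfg.max_sequence_length:
            msg = f"sentence of {len(ids)} sub-tokens truncated to {self.cfg.max_sequence_length}"
            if self.cfg.truncate == "error":
                raise ValueError(msg)
            logger.warning(msg)
            ids = ids[: self.cfg.max_sequence_length - 1] + [ids[-1]]
            align = align[: self.cfg.max_sequence_length - 1] + [-1]
        arr = np.array([ids])
        O = self.encoder.forward(arr, np.ones_like(arr, dtype=bool))
        return O.data[0], align

    def _batchify(self, sentences: list[LabeledSentence]):
        """Pad a batch; returns ids, mask, flat first-sub-token indices, gold."""
        encoded = [self.tokenizer.encode(s.tokens) for s in sentences]
        max_len = min(max(len(ids) for ids, _ in encoded), self.cfg.max_sequence_length)
        B = len(sentences)
        ids = np.full((B, max_len), self.tokenizer.pad_id, dtype=int)
        mask = np.zeros((B, max_len), dtype=bool)
        flat_idx, gold_y, gold_t, gold_d, owners = [], [], [], [], []
        for b, (sent, (sids, align)) in enumerate(zip(sentences, encoded)):
            if len(sids) > max_len:
                sids = sids[: max_len - 1] + [sids[-1]]
                align = align[: max_len - 1] + [-1]
            ids[b, : len(sids)] = sids
            mask[b, : len(sids)] = True
            seen: set[int] = set()
            for pos, wi in enumerate(align):
                if wi >= 0 and wi not in seen:
                    seen.add(wi)
                    flat_idx.append(b * max_len + pos)
                    gold_y.append(BIO_LABELS.index(sent.labels[wi]))
                    gold_t.append(sent.start_tags[wi])
                    gold_d.append(sent.end_tags[wi])
                    owners.append((b, wi))
        return (ids, mask, np.array(flat_idx), np.array(gold_y),
                np.array(gold_t), np.array(gold_d), owners)

    @staticmethod
    def _ce_term(probs: Tensor, gold: np.ndarray, n_classes: int) -> Tensor:
        onehot = np.eye(n_classes)[gold]
        norm = probs / probs.sum(axis=-1, keepdims=True)
        return -((norm + EPS).log() * Tensor(onehot)).sum()

    def fit(self, corpus: list[LabeledSentence], train_config: TrainConfig | None = None,
            ) -> list[float]:
        """Train from scratch on a labelled corpus; returns per-epoch losses."""
        tc = train_config or TrainConfig(seed=self.seed, lambda_=self.loss_cfg.lambda_)
        self.loss_cfg = NERLossConfig(lambda_=tc.lambda_)
        self.tokenizer = WordPieceTokenizer().fit([s.tokens for s in corpus])
        self.cfg.vocab_size = len(self.tokenizer)
        self.encoder = TransformerEncoder(self.cfg, seed=tc.seed)
        self.heads = NERHeads(self.cfg.hidden_size, self.loss_cfg.M1,
                              self.loss_cfg.M2, seed=tc.seed + 1)
        opt = Adam(self.encoder.params() + self.heads.params(), lr=tc.learning_rate)
        rng = np.random.default_rng(tc.seed)
        losses = []
        for _ in range(tc.epochs):
            order = rng.permutation(len(corpus))
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, len(corpus), tc.batch_size):
                batch = [corpus[i] for i in order[lo: lo + tc.batch_size]]
                ids, mask, flat, y, t, d, _ = self._batchify(batch)
                if len(flat) == 0:
                    continue
                O = self.encoder.forward(ids, mask)
                rows = O.reshape(-1, self.cfg.hidden_size).take(flat)
                pl, ps, pe = self.heads.forward(rows)
                loss = (self._ce_term(pl, y, self.loss_cfg.M1)
                        + (self._ce_term(ps, t, 2) + self._ce_term(pe, d, 2))
                        * self.loss_cfg.lambda_) * (1.0 / len(flat))
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))
        return losses

    def predict_probs(self, sentences: list[LabeledSentence]) -> list[NERPrediction]:
        """Word-aligned head activations for each sentence."""
        self._require_model()
        out = []
        for lo in range(0, len(sentences), 64):
            batch = sentences[lo: lo + 64]
            ids, mask, flat, *_rest, owners = self._batchify(batch)
            O = self.encoder.forward(ids, mask)
            rows = O.reshape(-1, self.cfg.hidden_size).take(flat)
            pl, ps, pe = self.heads.forward(rows)
            for b, sent in enumerate(batch):
                sel = [k for k, (bb, _) in enumerate(owners) if bb == b]
                out.append(NERPrediction(pl.data[sel], ps.data[sel], pe.data[sel]))
        return out

    def predict(self, sentences: list[LabeledSentence],
                decode: DecodeConfig | None = None) -> list[list[EntitySpan]]:
        preds = self.predict_probs(sentences)
        spans_out = []
        for sent, pred in zip(sentences, preds):
            spans = decode_entities(pred, decode)
            spans_out.append([
                EntitySpan(sp.start, sp.end, " ".join(sent.tokens[sp.start:sp.end]))
                for sp in spans if sp.end <= len(sent.tokens)
            ])
        return spans_out

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        self._require_model()
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "encoder_config": asdict(self.cfg),
            "lambda": self.loss_cfg.lambda_,
            "vocab": self.tokenizer.vocab,
            "special_tokens": sorted(self.tokenizer.special_tokens),
            "seed": self.seed,
        }
        (path / "config.json").write_text(json.dumps(manifest))
        params = self.encoder.params() + self.heads.params()
        np.savez(path / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(params)})

    @classmethod
    def load(cls, path: str | Path) -> "NERTagger":
        path = Path(path)
        manifest = json.loads((path / "config.json").read_text())
        cfg = EncoderConfig(**manifest["encoder_config"])
        tagger = cls(cfg, seed=manifest["seed"], lambda_=manifest["lambda"])
        tagger.tokenizer = WordPieceTokenizer()
        tagger.tokenizer.vocab = {k: int(v) for k, v in manifest["vocab"].items()}
        tagger.tokenizer.special_tokens = set(manifest["special_tokens"])
        tagger.encoder = TransformerEncoder(cfg, seed=manifest["seed"])
        tagger.heads = NERHeads(cfg.hidden_size, seed=manifest["seed"])
        params = tagger.encoder.params() + tagger.heads.params()
        with np.load(path / "weights.npz") as blob:
            for i, p in enumerate(params):
                p.data = blob[f"p{i}"]
        return tagger
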