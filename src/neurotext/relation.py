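"""Marker-based relation classification between two region mentions.

A candidate sentence is rewritten with boundary marker tokens around the
two mentions,

    [CLS] ... <s> subject region </s> ... <o> object region </o> ... [SEP]

encoded, and classified from the four encoder vectors at the marker
positions: each is projected to class space (one affine map per marker),
the four projections are concatenated, and an output affine map produces
class scores which a softmax turns into a distribution. Training
minimizes the multi-class cross-entropy of that distribution.

One implementation serves both tasks: connectivity (2 classes) and
directional (4 classes: unconnected, undirected, output, input).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import Adam, EncoderConfig, Tensor, TransformerEncoder, WordPieceTokenizer, concat
from .types import RELATION_CLASSES, RelationInstance

logger = logging.getLogger(__name__)

__all__ = [
    "MARKERS", "LABEL_SETS", "MarkedSequence", "RelationPrediction",
    "insert_markers", "strip_markers", "pool_marker_vectors",
    "RelationHead", "re_loss", "RelationClassifier",
]

MARKERS = ("<s>", "</s>", "<o>", "</o>")
LABEL_SETS = {
    "connectivity": ("unconnected", "connected"),
    "directional": RELATION_CLASSES,
}
EPS = 1e-12


@dataclass
class MarkedSequence:
    """Token sequence with [CLS]/[SEP] and the four entity markers."""

    tokens: list[str]
    marker_positions: dict[str, int]
    original_map: dict[int, int]  # marked index -> original token index

    def __post_init__(self) -> None:
        pos = [self.marker_positions[m] for m in MARKERS]
        if sorted(pos) != pos or len(set(pos)) != 4:
            raise ValueError("markers must appear once each, in order")
        if not (0 < pos[0] and pos[-1] < len(self.tokens) - 1):
            raise ValueError("markers must lie strictly between [CLS] and [SEP]")


def insert_markers(instance: RelationInstance) -> MarkedSequence:
    """Wrap the two mention spans in boundary marker tokens."""
    toks = instance.sentence.tokens
    subj, obj = instance.subj, instance.obj
    if subj.overlaps(obj):
        raise ValueError("cannot mark overlapping spans")
    out = ["[CLS]"]
    positions: dict[str, int] = {}
    mapping: dict[int, int] = {}
    for i, tok in enumerate(toks):
        if i == subj.start:
            positions["<s>"] = len(out)
            out.append("<s>")
        if i == obj.start:
            positions["<o>"] = len(out)
            out.append("<o>")
        mapping[len(out)] = i
        out.append(tok)
        if i == subj.end - 1:
            positions["</s>"] = len(out)
            out.append("</s>")
        if i == obj.end - 1:
            positions["</o>"] = len(out)
            out.append("</o>")
    out.append("[SEP]")
    return MarkedSequence(out, positions, mapping)


def strip_markers(marked: MarkedSequence) -> list[str]:
    """Recover the original token sequence (inverse of insert_markers)."""
    return [marked.tokens[i] for i in sorted(marked.original_map)]


def pool_marker_vectors(O: np.ndarray, marked: MarkedSequence,
                        token_positions: dict[str, int] | None = None) -> tuple:
    """Encoder output rows at the four marker positions, order (<s>, </s>, <o>, </o>).

    ``token_positions`` overrides the marker row indices when the encoder
    works on sub-tokens rather than the marked word sequence.
    """
    positions = token_positions or marked.marker_positions
    missing = [m for m in MARKERS if m not in positions]
    if missing:
        raise ValueError(f"markers missing from alignment: {missing}")
    return tuple(np.asarray(O)[positions[m]] for m in MARKERS)


@dataclass
class RelationPrediction:
    class_probs: np.ndarray
    predicted_label: str
    confidence: float

    def __post_init__(self) -> None:
        if abs(float(self.class_probs.sum()) - 1.0) > 1e-6:
            raise ValueError("class probabilities must sum to 1")


class RelationHead:
    """Per-marker projections to class space plus the concat output map.

    Scores = Wo . Concat(W1s s1 + b1s, W2s s2 + b2s, W1e e1 + b1e,
    W2e e2 + b2e) + bo, with each projection H -> M and Wo : 4M -> M;
    a softmax yields the class distribution.
    """

    def __init__(self, hidden_size: int, n_classes: int, seed: int = 0,
                 use_cls: bool = False):
        rng = np.random.default_rng(seed)
        scale = 1.0 / np.sqrt(hidden_size)
        self.n_classes = n_classes
        self.use_cls = use_cls
        self.proj = []
        for _ in range(4):
            W = Tensor(rng.normal(0, scale, (hidden_size, n_classes)), requires_grad=True)
            b = Tensor(np.zeros(n_classes), requires_grad=True)
            self.proj.append((W, b))
        width = 4 * n_classes
        if use_cls:
            self.Wc = Tensor(rng.normal(0, scale, (hidden_size, n_classes)), requires_grad=True)
            self.bc = Tensor(np.zeros(n_classes), requires_grad=True)
            width += n_classes
        self.Wo = Tensor(rng.normal(0, 1.0 / np.sqrt(width), (width, n_classes)),
                         requires_grad=True)
        self.bo = Tensor(np.zeros(n_classes), requires_grad=True)

    def logits(self, s1: Tensor, s2: Tensor, e1: Tensor, e2: Tensor,
               cls_vec: Tensor | None = None) -> Tensor:
        parts = [v @ W + b for v, (W, b) in zip((s1, s2, e1, e2), self.proj)]
        if self.use_cls:
            if cls_vec is None:
                raise ValueError("head configured with use_cls but no [CLS] vector given")
            parts.append(cls_vec @ self.Wc + self.bc)
        return concat(parts, axis=-1) @ self.Wo + self.bo

    def probs(self, *args, **kwargs) -> Tensor:
        return self.logits(*args, **kwargs).softmax(axis=-1)

    def params(self):
        out = [w for pair in self.proj for w in pair]
        if self.use_cls:
            out += [self.Wc, self.bc]
        return out + [self.Wo, self.bo]


def relation_logits(head: RelationHead, s1, s2, e1, e2) -> np.ndarray:
    """Numpy convenience wrapper: class scores for one marker quadruple."""
    vecs = [Tensor(np.asarray(v)[None, :]) for v in (s1, s2, e1, e2)]
    return head.logits(*vecs).data[0]


def re_loss(class_probs: np.ndarray, gold_idx: np.ndarray) -> float:
    """Mean multi-class cross-entropy of predicted distributions."""
    probs = np.atleast_2d(np.asarray(class_probs, dtype=float))
    gold = np.atleast_1d(np.asarray(gold_idx))
    if len(gold) != len(probs):
        raise ValueError("batch size mismatch")
    picked = probs[np.arange(len(gold)), gold]
    return float(-np.log(np.clip(picked, EPS, None)).mean())


@dataclass
class RETrainConfig:
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 3e-3
    seed: int = 0
    class_weights: bool = False  # inverse-frequency loss weights


class RelationClassifier:
    """Trainable marker-based relation model (connectivity or directional)."""

    def __init__(self, encoder_config: EncoderConfig | None = None,
                 label_set: str = "directional", seed: int = 0, use_cls: bool = False):
        if label_set not in LABEL_SETS:
            raise ValueError(f"label_set must be one of {sorted(LABEL_SETS)}")
        self.cfg = encoder_config or EncoderConfig()
        self.label_set = label_set
        self.classes = LABEL_SETS[label_set]
        self.seed = seed
        self.use_cls = use_cls
        self.tokenizer = WordPieceTokenizer()
        self.encoder: TransformerEncoder | None = None
        self.head: RelationHead | None = None

    def _gold_index(self, label: str) -> int:
        if self.label_set == "connectivity" and label in ("undirected", "output", "input"):
            label = "connected"
        return self.classes.index(label)

    def _encode_instance(self, instance: RelationInstance) -> tuple[list[int], dict[str, int], int]:
        """Sub-token ids for the marked sequence + marker sub-token positions."""
        marked = insert_markers(instance)
        words = marked.tokens[1:-1]  # tokenizer re-adds [CLS]/[SEP]
        ids, align = self.tokenizer.encode(words)
        if len(ids) > self.cfg.max_sequence_length:
            ids, align = self._truncate(words, marked)
        positions = {}
        for m in MARKERS:
            word_idx = marked.marker_positions[m] - 1
            positions[m] = next(p for p, wi in enumerate(align) if wi == word_idx)
        return ids, positions, 0  # position 0 is [CLS]

    def _truncate(self, words: list[str], marked: MarkedSequence):
        """Symmetric window around the two marked spans when over-length."""
        first = marked.marker_positions["<s>"] - 1
        last = marked.marker_positions["</o>"] - 1
        budget = self.cfg.max_sequence_length
        lo, hi = first, last + 1
        while True:
            ids, align = self.tokenizer.encode(words[lo:hi])
            if len(ids) <= budget or (lo == first and hi == last + 1):
                break
            if first - lo >= hi - (last + 1) and lo < first:
                lo += 1
            elif hi > last + 1:
                hi -= 1
            else:
                lo += 1
        if len(ids) > budget:
            raise ValueError("marked spans alone exceed the encoder length budget")
        align = [a + lo if a >= 0 else a for a in align]
        logger.warning("truncated over-length relation instance to window [%d, %d)", lo, hi)
        return ids, align

    def _batchify(self, instances: list[RelationInstance]):
        encoded = [self._encode_instance(inst) for inst in instances]
        max_len = max(len(ids) for ids, _, _ in encoded)
        B = len(instances)
        ids = np.full((B, max_len), self.tokenizer.pad_id, dtype=int)
        mask = np.zeros((B, max_len), dtype=bool)
        marker_flat = {m: np.zeros(B, dtype=int) for m in MARKERS}
        cls_flat = np.zeros(B, dtype=int)
        for b, (sids, positions, cls_pos) in enumerate(encoded):
            ids[b, : len(sids)] = sids
            mask[b, : len(sids)] = True
            for m in MARKERS:
                marker_flat[m][b] = b * max_len + positions[m]
            cls_flat[b] = b * max_len + cls_pos
        return ids, mask, marker_flat, cls_flat

    def _forward(self, instances: list[RelationInstance]) -> Tensor:
        ids, mask, marker_flat, cls_flat = self._batchify(instances)
        O = self.encoder.forward(ids, mask)
        flatO = O.reshape(-1, self.cfg.hidden_size)
        vecs = [flatO.take(marker_flat[m]) for m in MARKERS]
        cls_vec = flatO.take(cls_flat) if self.use_cls else None
        return self.head.probs(*vecs, cls_vec=cls_vec)

    def fit(self, instances: list[RelationInstance],
            train_config: RETrainConfig | None = None) -> list[float]:
        tc = train_config or RETrainConfig(seed=self.seed)
        if any(inst.label is None for inst in instances):
            raise ValueError("all training instances need labels")
        marked_words = [insert_markers(i).tokens[1:-1] for i in instances]
        self.tokenizer = WordPieceTokenizer()
        self.tokenizer.add_special_tokens(list(MARKERS))
        self.tokenizer.fit(marked_words)
        self.cfg.vocab_size = len(self.tokenizer)
        self.encoder = TransformerEncoder(self.cfg, seed=tc.seed)
        self.head = RelationHead(self.cfg.hidden_size, len(self.classes),
                                 seed=tc.seed + 1, use_cls=self.use_cls)
        opt = Adam(self.encoder.params() + self.head.params(), lr=tc.learning_rate)
        gold = np.array([self._gold_index(i.label) for i in instances])
        weights = np.ones(len(self.classes))
        if tc.class_weights:
            freq = np.bincount(gold, minlength=len(self.classes)).astype(float)
            weights = np.where(freq > 0, freq.sum() / np.maximum(freq, 1), 0.0)
            weights /= weights[freq > 0].mean()
        rng = np.random.default_rng(tc.seed)
        losses = []
        for _ in range(tc.epochs):
            order = rng.permutation(len(instances))
            epoch_loss, n_batches = 0.0, 0
            for lo in range(0, len(instances), tc.batch_size):
                sel = order[lo: lo + tc.batch_size]
                probs = self._forward([instances[i] for i in sel])
                onehot = np.eye(len(self.classes))[gold[sel]] * weights[gold[sel]][:, None]
                loss = -((probs + EPS).log() * Tensor(onehot)).sum() * (1.0 / len(sel))
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))
        return losses

    def predict_proba(self, instances: list[RelationInstance]) -> np.ndarray:
        if self.encoder is None or self.head is None:
            raise RuntimeError("model is not trained or loaded")
        out = []
        for lo in range(0, len(instances), 64):
            out.append(self._forward(instances[lo: lo + 64]).data)
        return np.concatenate(out, axis=0)

    def predict(self, instances: list[RelationInstance]) -> list[RelationPrediction]:
        probs = self.predict_proba(instances)
        preds = []
        for row in probs:
            idx = int(np.argmax(row))  # ties resolve to the lowest class index
            preds.append(RelationPrediction(row, self.classes[idx], float(row[idx])))
        return preds

    def predict_relation(self, instance: RelationInstance) -> RelationPrediction:
        return self.predict([instance])[0]

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        if self.encoder is None:
            raise RuntimeError("model is not trained")
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "encoder_config": asdict(self.cfg),
            "label_set": self.label_set,
            "vocab": self.tokenizer.vocab,
            "special_tokens": sorted(self.tokenizer.special_tokens),
            "seed": self.seed,
            "use_cls": self.use_cls,
        }
        (path / "config.json").write_text(json.dumps(manifest))
        params = self.encoder.params() + self.head.params()
        np.savez(path / "weights.npz", **{f"p{i}": p.data for i, p in enumerate(params)})

    @classmethod
    def load(cls, path: str | Path) -> "RelationClassifier":
        path = Path(path)
        manifest = json.loads((path / "config.json").read_text())
        cfg = EncoderConfig(**manifest["encoder_config"])
        model = cls(cfg, label_set=manifest["label_set"], seed=manifest["seed"],
                    use_cls=manifest["use_cls"])
        model.tokenizer = WordPieceTokenizer()
        model.tokenizer.vocab = {k: int(v) for k, v in manifest["vocab"].items()}
        model.tokenizer.special_tokens = set(manifest["special_tokens"])
        model.encoder = TransformerEncoder(cfg, seed=manifest["seed"])
        model.head = RelationHead(cfg.hidden_size, len(model.classes),
                                  seed=manifest["seed"], use_cls=manifest["use_cls"])
        params = model.encoder.params() + model.head.params()
        with np.load(path / "weights.npz") as blob:
            for i, p in enumerate(params):
                p.data = blob[f"p{i}"]
        return model
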