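"""Corpus readers/writers, pointer-tag derivation, and splits.

NER corpora use a CoNLL-style column format: one token per line, a single
separator (TAB by default), the BIO tag in the last column, blank lines
between sentences, and optional ``-DOCSTART- <doc_id>`` lines delimiting
documents. Relation corpora are TSV with one candidate pair per row.

The pointer tags trained jointly with the BIO labels are derived here:
a start tag marks the first token of each entity and an end tag its last
token, so per sentence the number of start tags, end tags, and entities
coincide.
"""

from __future__ import annotations

import logging
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BIO_LABELS, RELATION_CLASSES, CorpusSplit, EntitySpan, LabeledSentence, RelationInstance

logger = logging.getLogger(__name__)

__all__ = [
    "derive_pointer_tags",
    "spans_from_labels",
    "labels_from_spans",
    "validate_bio",
    "repair_bio",
    "read_conll",
    "write_conll",
    "read_relations_tsv",
    "write_relations_tsv",
    "build_relation_instances",
    "split_corpus",
    "kfold_splits",
]

_RELATION_COLUMNS = [
    "doc_id", "sent_id", "subj_start", "subj_end",
    "obj_start", "obj_end", "label", "sentence_text",
]


class CorpusFormatError(ValueError):
    """Malformed corpus file (carries the offending line number)."""


def validate_bio(labels: list[str]) -> None:
    """Reject unknown tags and I-tags that do not continue an entity."""
    prev = "O"
    for i, lab in enumerate(labels):
        if lab not in BIO_LABELS:
            raise ValueError(f"illegal tag {lab!r} at position {i}")
        if lab.startswith("I") and prev == "O":
            raise ValueError(f"I-BrainRegion at position {i} does not continue an entity")
        prev = lab


def repair_bio(labels: list[str]) -> list[str]:
    """Convert orphan I-tags (after O or sentence-initial) into B-tags."""
    out = list(labels)
    prev = "O"
    for i, lab in enumerate(out):
        if lab.startswith("I") and prev == "O":
            out[i] = "B" + lab[1:]
        prev = out[i]
    return out


def derive_pointer_tags(labels: list[str]) -> tuple[list[int], list[int]]:
    """Start/end pointer indicator sequences for a BIO-valid labelling."""
    validate_bio(labels)
    start = [0] * len(labels)
    end = [0] * len(labels)
    for span in spans_from_labels(labels):
        start[span.start] = 1
        end[span.end - 1] = 1
    return start, end


def spans_from_labels(labels: list[str], tokens: list[str] | None = None) -> list[EntitySpan]:
    """One half-open span per maximal B/I run."""
    validate_bio(labels)
    spans: list[EntitySpan] = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i].startswith("B"):
            j = i + 1
            while j < n and labels[j].startswith("I"):
                j += 1
            surface = " ".join(tokens[i:j]) if tokens else ""
            spans.append(EntitySpan(i, j, surface))
            i = j
        else:
            i += 1
    return spans


def labels_from_spans(spans: list[EntitySpan], length: int) -> list[str]:
    """Inverse of :func:`spans_from_labels`; spans must not overlap."""
    labels = ["O"] * length
    for span in sorted(spans):
        if span.end > length:
            raise ValueError(f"span {span} exceeds sentence length {length}")
        if any(labels[i] != "O" for i in range(span.start, span.end)):
            raise ValueError(f"overlapping span {span}")
        labels[span.start] = "B-BrainRegion"
        for i in range(span.start + 1, span.end):
            labels[i] = "I-BrainRegion"
    return labels


def read_conll(
    path: str | Path,
    sep: str = "\t",
    bio_policy: str = "strict",
) -> list[LabeledSentence]:
    """Read a CoNLL-style NER corpus.

    Parameters
    ----------
    sep
        Column separator (TAB by default).
    bio_policy
        ``"strict"`` rejects I-after-O labellings; ``"repair"`` converts
        orphan I tags to B.
    """
    if bio_policy not in ("strict", "repair"):
        raise ValueError(f"unknown BIO policy {bio_policy!r}")
    sentences: list[LabeledSentence] = []
    doc_id = "d0"
    sent_id = 0
    tokens: list[str] = []
    labels: list[str] = []

    def flush() -> None:
        nonlocal tokens, labels, sent_id
        if tokens:
            labs = repair_bio(labels) if bio_policy == "repair" else labels
            try:
                validate_bio(labs)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}: sentence {doc_id}:{sent_id}: {exc}") from exc
            sentences.append(LabeledSentence(doc_id, sent_id, tokens, labs))
            sent_id += 1
        tokens, labels = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("-DOCSTART-"):
                flush()
                parts = line.split()
                doc_id = parts[1] if len(parts) > 1 else f"d{len(sentences)}"
                sent_id = 0
                continue
            cols = line.split(sep)
            if len(cols) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 columns separated by {sep!r}, got {len(cols)}"
                )
            tokens.append(cols[0])
            labels.append(cols[-1])
    flush()
    return sentences


def write_conll(sentences: list[LabeledSentence], path: str | Path, sep: str = "\t") -> None:
    """Write a corpus in the dialect read by :func:`read_conll`."""
    with open(path, "w", encoding="utf-8") as fh:
        current_doc = None
        for sent in sentences:
            if sent.doc_id != current_doc:
                fh.write(f"-DOCSTART- {sent.doc_id}\n\n")
                current_doc = sent.doc_id
            for tok, lab in zip(sent.tokens, sent.labels):
                fh.write(f"{tok}{sep}{lab}\n")
            fh.write("\n")


def write_relations_tsv(instances: list[RelationInstance], path: str | Path) -> None:
    rows = [
        {
            "doc_id": inst.sentence.doc_id,
            "sent_id": inst.sentence.sent_id,
            "subj_start": inst.subj.start,
            "subj_end": inst.subj.end,
            "obj_start": inst.obj.start,
            "obj_end": inst.obj.end,
            "label": inst.label if inst.label is not None else "",
            "sentence_text": " ".join(inst.sentence.tokens),
        }
        for inst in instances
    ]
    pd.DataFrame(rows, columns=_RELATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_relations_tsv(path: str | Path) -> list[RelationInstance]:
    """Read a relation corpus TSV (whitespace-tokenized sentence text)."""
    df = pd.read_csv(path, sep="\t", dtype={"doc_id": str}, keep_default_na=False)
    missing = set(_RELATION_COLUMNS) - set(df.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing columns {sorted(missing)}")
    instances = []
    for row in df.itertuples(index=False):
        tokens = str(row.sentence_text).split()
        subj = EntitySpan(int(row.subj_start), int(row.subj_end),
                          " ".join(tokens[int(row.subj_start):int(row.subj_end)]))
        obj = EntitySpan(int(row.obj_start), int(row.obj_end),
                         " ".join(tokens[int(row.obj_start):int(row.obj_end)]))
        labels = labels_from_spans([subj, obj], len(tokens))
        sent = LabeledSentence(str(row.doc_id), int(row.sent_id), tokens, labels)
        label = str(row.label) or None
        if label is not None and label not in RELATION_CLASSES:
            raise CorpusFormatError(f"{path}: unknown relation label {label!r}")
        instances.append(RelationInstance(sent, subj, obj, label))
    return instances


def build_relation_instances(
    sentence: LabeledSentence,
    spans: list[EntitySpan] | None = None,
) -> list[RelationInstance]:
    """Unlabeled candidate instances: one per pair of non-overlapping spans.

    Uses the sentence's gold spans unless predicted ``spans`` are given.
    Sentences with fewer than two entities yield no candidates.
    """
    if spans is None:
        spans = sentence.spans()
    spans = sorted(spans)
    instances = []
    for a, b in combinations(spans, 2):
        if a.overlaps(b):
            logger.warning(
                "%s:%s: skipping overlapping span pair %s / %s",
                sentence.doc_id, sentence.sent_id, a, b,
            )
            continue
        instances.append(RelationInstance(sentence, a, b, None))
    return instances


def _unit_ids(corpus: list[LabeledSentence], unit_level: str) -> list[str]:
    if unit_level == "document":
        seen: dict[str, None] = {}
        for s in corpus:
            seen.setdefault(s.doc_id, None)
        return list(seen)
    if unit_level == "sentence":
        return [f"{s.doc_id}:{s.sent_id}" for s in corpus]
    raise ValueError(f"unknown unit level {unit_level!r}")


def split_corpus(
    corpus: list[LabeledSentence],
    ratios: tuple[float, float, float] = (6, 1, 1),
    unit_level: str = "document",
    seed: int = 0,
) -> CorpusSplit:
    """Seeded train/validation/test split at document or sentence level.

    Ratios are normalized; the paper-style defaults are 6:1:1 for NER and
    8:1:1 for relation corpora. Document-level splitting keeps all
    sentences of a document in one part.
    """
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be three positive numbers")
    units = _unit_ids(corpus, unit_level)
    if len(units) < 3:
        raise ValueError(f"only {len(units)} units; need at least 3")
    rng = np.random.default_rng(seed)
    order = [units[i] for i in rng.permutation(len(units))]
    total = sum(ratios)
    n = len(order)
    n_val = int(round(n * ratios[1] / total)) or 1
    n_test = int(round(n * ratios[2] / total)) or 1
    n_train = n - n_val - n_test
    if n_train <= 0:
        raise ValueError("ratios leave no training units")
    return CorpusSplit(
        train=order[:n_train],
        validation=order[n_train:n_train + n_val],
        test=order[n_train + n_val:],
        unit_level=unit_level,
    )


def kfold_splits(
    corpus: list[LabeledSentence],
    k: int,
    unit_level: str = "document",
    seed: int = 0,
) -> list[CorpusSplit]:
    """k folds by rotating the test (and validation) block over a seeded shuffle."""
    if k < 2:
        raise ValueError("k must be >= 2")
    units = _unit_ids(corpus, unit_level)
    if k > len(units):
        raise ValueError(f"k={k} exceeds the {len(units)} available units")
    rng = np.random.default_rng(seed)
    order = [units[i] for i in rng.permutation(len(units))]
    blocks = [list(b) for b in np.array_split(np.array(order, dtype=object), k)]
    folds = []
    for i in range(k):
        test = blocks[i]
        val = blocks[(i + 1) % k]
        train = [u for j, b in enumerate(blocks) if j not in (i, (i + 1) % k) for u in b]
        folds.append(CorpusSplit(train=train, validation=val, test=test, unit_level=unit_level))
    return folds


def select_units(
    corpus: list[LabeledSentence], unit_ids: list[str], unit_level: str
) -> list[LabeledSentence]:
    """Sentences belonging to the given unit ids, in corpus order."""
    wanted = set(unit_ids)
    if unit_level == "document":
        return [s for s in corpus if s.doc_id in wanted]
    return [s for s in corpus if f"{s.doc_id}:{s.sent_id}" in wanted]
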