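"""Core domain types shared across the pipeline.

The pipeline deals with four kinds of objects: token-labelled sentences
(BIO tags plus the start/end position-pointer tags trained jointly with
them), candidate relation instances between two region mentions in one
sentence, ontology entries for neuroanatomical nomenclatures, and the
canonical directed connectivity triples that populate the knowledge graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "BIO_LABELS",
    "RELATION_CLASSES",
    "EntitySpan",
    "LabeledSentence",
    "RelationInstance",
    "CorpusSplit",
    "OntologyEntry",
    "LinkResult",
    "ConnectivityTriple",
    "CircuitSummary",
]

#: Token-label alphabet for region NER, in head-output order.
BIO_LABELS = ("O", "B-BrainRegion", "I-BrainRegion")

#: Four-way directional relation classes, in head-output order. "output"
#: means the first-mentioned region projects to the second; "input" means
#: the first-mentioned region receives a projection from the second.
RELATION_CLASSES = ("unconnected", "undirected", "output", "input")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """Token-level span, 0-based and half-open: tokens[start:end]."""

    start: int
    end: int
    surface: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "EntitySpan") -> bool:
        """True when *other* lies within (or equals) this span."""
        return self.start <= other.start and other.end <= self.end

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class LabeledSentence:
    """A tokenized sentence with BIO labels and derived pointer tags.

    ``start_tags`` carry a 1 exactly on the first token of each entity and
    ``end_tags`` a 1 on its last token; both are derived from ``labels``
    and kept consistent with them.
    """

    doc_id: str
    sent_id: int
    tokens: list[str]
    labels: list[str]
    start_tags: list[int] = field(default_factory=list)
    end_tags: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{self.doc_id}:{self.sent_id}: {len(self.tokens)} tokens "
                f"but {len(self.labels)} labels"
            )
        if not self.start_tags and not self.end_tags:
            from .corpus_io import derive_pointer_tags  # cycle-free at call time

            self.start_tags, self.end_tags = derive_pointer_tags(self.labels)
        if not (
            len(self.start_tags) == len(self.end_tags) == len(self.tokens)
        ):
            raise ValueError(f"{self.doc_id}:{self.sent_id}: pointer tag length mismatch")

    def spans(self) -> list[EntitySpan]:
        from .corpus_io import spans_from_labels

        return spans_from_labels(self.labels, self.tokens)

    def with_labels(self, labels: list[str]) -> "LabeledSentence":
        return LabeledSentence(
            doc_id=self.doc_id, sent_id=self.sent_id,
            tokens=list(self.tokens), labels=list(labels),
        )

    def copy(self) -> "LabeledSentence":
        return replace(
            self,
            tokens=list(self.tokens),
            labels=list(self.labels),
            start_tags=list(self.start_tags),
            end_tags=list(self.end_tags),
        )


@dataclass
class RelationInstance:
    """Two region mentions in one sentence plus a 4-way directional label.

    ``subj`` is always the earlier mention; directionality is carried
    entirely by ``label``.
    """

    sentence: LabeledSentence
    subj: EntitySpan
    obj: EntitySpan
    label: str | None = None

    def __post_init__(self) -> None:
        if self.subj.overlaps(self.obj):
            raise ValueError("subject and object spans overlap")
        if self.subj.start >= self.obj.start:
            raise ValueError("subj must be the earlier mention")
        if self.label is not None and self.label not in RELATION_CLASSES:
            raise ValueError(f"unknown relation label {self.label!r}")


@dataclass
class CorpusSplit:
    """Disjoint train/validation/test unit-id lists."""

    train: list[str]
    validation: list[str]
    test: list[str]
    unit_level: str = "document"

    def parts(self) -> dict[str, list[str]]:
        return {"train": self.train, "validation": self.validation, "test": self.test}


@dataclass
class OntologyEntry:
    """One region in the merged nomenclature dictionary."""

    id: str
    canonical_name: str
    abbreviations: frozenset[str] = frozenset()
    synonyms: frozenset[str] = frozenset()
    species: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.canonical_name:
            raise ValueError(f"entry {self.id}: empty canonical name")
        self.abbreviations = frozenset(self.abbreviations)
        self.synonyms = frozenset(self.synonyms)

    def surface_forms(self) -> set[str]:
        return {self.canonical_name} | set(self.synonyms)


@dataclass(frozen=True)
class LinkResult:
    """Outcome of linking one mention to the dictionary."""

    mention: str
    matched_id: str | None
    score: float
    method: str  # exact | strip_directional | nested | fuzzy_word | none


@dataclass(frozen=True)
class ConnectivityTriple:
    """Canonical directed (or undirected) connectivity edge with provenance."""

    source_id: str
    target_id: str
    relation: str  # projects_to | connected_undirected
    pmid: str
    sent_id: int
    evidence: str = ""
    extraction_label: str = ""

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise ValueError("self-loop triple")
        if self.relation not in ("projects_to", "connected_undirected"):
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.relation == "connected_undirected" and self.source_id > self.target_id:
            raise ValueError("undirected triple must be in canonical order")

    def dedup_key(self) -> tuple:
        return (self.pmid, self.sent_id, self.source_id, self.target_id,
                self.relation, self.extraction_label)


@dataclass
class CircuitSummary:
    """Input/output/undirected partners of one region with evidence counts."""

    region_id: str
    inputs: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, int] = field(default_factory=dict)
    undirected: dict[str, int] = field(default_factory=dict)
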