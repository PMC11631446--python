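"""Synthetic ontologies and corpora with known ground truth.

Every other module is trainable and testable offline against corpora
generated here: a toy merged ontology of multi-word anatomical-style
region names (with synonyms and acronyms), template sentences expressing
directed, undirected or absent connectivity between two regions, BIO +
pointer NER tags, 4-way relation labels, and the gold connectivity graph
implied by the directed templates.

The default relation class mix follows the frequencies of a manually
annotated directional corpus of this domain (unconnected 84.9%,
undirected 5.3%, output 7.1%, input 2.8%). Templates use distinct
trigger lexicons per class, so the tasks are separable by construction
and recovery tests have a known achievable ceiling. Boundary noise
optionally truncates one boundary token of a fraction of NER *training*
spans while ground truth stays clean — the substrate for dictionary-tree
denoising experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus_io import labels_from_spans
from .kg import canonicalize
from .linking import Gazetteer
from .nn import EncoderConfig, TransformerEncoder
from .types import ConnectivityTriple, EntitySpan, LabeledSentence, OntologyEntry, RelationInstance

__all__ = ["SynthConfig", "GroundTruth", "SynthCorpus",
           "generate_ontology", "generate_corpus", "test_encoder"]

_MODIFIERS = [
    "anterior", "posterior", "medial", "lateral", "dorsal", "ventral",
    "rostral", "caudal", "superior", "inferior", "central", "paraventricular",
    "parabrachial", "suprachiasmatic", "arcuate", "reticular", "tegmental",
    "habenular", "geniculate", "accumbal", "olivary", "septal", "pontine",
    "cuneate", "gracile", "preoptic", "premammillary", "supramammillary",
    "interpeduncular", "parafascicular", "rhomboid", "endopiriform",
    "claustral", "entorhinal", "piriform", "cingulate", "retrosplenial",
    "ambiens", "magnocellular", "parvicellular", "intralaminar", "periaqueductal",
]
_HEADS = [
    "nucleus", "area", "cortex", "field", "region", "complex",
    "formation", "tract", "zone", "body", "gray", "band",
]

_TEMPLATES: dict[str, list[list[str]]] = {
    "output": [
        ["the", "{X}", "projects", "to", "the", "{Y}", "."],
        ["projections", "from", "the", "{X}", "to", "the", "{Y}", "were", "traced", "."],
    ],
    "input": [
        ["the", "{X}", "receives", "input", "from", "the", "{Y}", "."],
        ["the", "{X}", "is", "innervated", "by", "fibers", "of", "the", "{Y}", "."],
    ],
    "undirected": [
        ["the", "{X}", "is", "connected", "with", "the", "{Y}", "."],
        ["reciprocal", "connections", "link", "the", "{X}", "and", "the", "{Y}", "."],
    ],
    "unconnected": [
        ["the", "{X}", "and", "the", "{Y}", "were", "examined", "separately", "."],
        ["we", "recorded", "activity", "in", "the", "{X}", "and", "the", "{Y}", "."],
    ],
}
_FILLER = [
    ["the", "animals", "were", "anesthetized", "before", "surgery", "."],
    ["histology", "was", "performed", "after", "each", "experiment", "."],
]
_SINGLE = [
    ["the", "{X}", "was", "examined", "in", "detail", "."],
    ["dense", "terminals", "were", "observed", "in", "the", "{X}", "."],
]


@dataclass
class SynthConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_regions: int = 40
    name_length_distribution: tuple[float, ...] = (0.10, 0.35, 0.30, 0.15, 0.10)
    synonym_rate: float = 0.3
    abbreviation_rate: float = 0.5
    n_documents: int = 100
    sentences_per_document: int = 10
    relation_class_mix: tuple[float, float, float, float] = (0.8488, 0.0527, 0.0710, 0.0275)
    filler_rate: float = 0.1
    boundary_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.synonym_rate, self.abbreviation_rate,
                     self.filler_rate, self.boundary_noise_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if abs(sum(self.relation_class_mix) - 1.0) > 1e-6:
            raise ValueError("relation_class_mix must sum to 1")
        if abs(sum(self.name_length_distribution) - 1.0) > 1e-6:
            raise ValueError("name_length_distribution must sum to 1")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class GroundTruth:
    """Clean labels and the gold graph behind a generated corpus."""

    ontology: list[OntologyEntry]
    sentences: list[LabeledSentence]                    # clean BIO labels
    mentions: dict[tuple[str, int], list[tuple[EntitySpan, str]]]
    relations: list[RelationInstance]                   # labeled, clean spans
    relation_ids: list[tuple[str, str]]                 # (subj_id, obj_id)
    triples: list[ConnectivityTriple]


@dataclass
class SynthCorpus:
    """Training-ready corpus (possibly noisy) plus its ground truth."""

    ner_sentences: list[LabeledSentence]
    relations: list[RelationInstance]
    ground_truth: GroundTruth


def generate_ontology(cfg: SynthConfig) -> tuple[list[OntologyEntry], Gazetteer]:
    """Deterministic toy merged dictionary of unique region names."""
    if cfg.n_regions < 2:
        raise ValueError("need at least two regions")
    rng = np.random.default_rng(cfg.seed)
    names: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(names) < cfg.n_regions:
        attempts += 1
        if attempts > 200 * cfg.n_regions:
            raise RuntimeError("name vocabulary exhausted; lower n_regions")
        k = 1 + rng.choice(len(cfg.name_length_distribution),
                           p=cfg.name_length_distribution)
        if k == 1:
            name = (str(rng.choice(_HEADS)),)
        else:
            mods = tuple(str(m) for m in rng.choice(_MODIFIERS, size=k - 1, replace=False))
            name = mods + (str(rng.choice(_HEADS)),)
        if name not in seen:
            seen.add(name)
            names.append(name)
    entries = []
    used_abbr: set[str] = set()
    for i, name in enumerate(names):
        canonical = " ".join(name)
        synonyms: set[str] = set()
        if len(name) >= 3 and rng.random() < cfg.synonym_rate:
            synonyms.add(f"{name[-1]} of the {' '.join(name[:-1])}")
        abbreviations: set[str] = set()
        if len(name) >= 2 and rng.random() < cfg.abbreviation_rate:
            abbr = "".join(w[0] for w in name).upper()
            if abbr not in used_abbr:  # collisions stay exact-match-only anyway
                used_abbr.add(abbr)
                abbreviations.add(abbr)
        entries.append(OntologyEntry(
            id=f"SYN:{i:04d}", canonical_name=canonical,
            abbreviations=frozenset(abbreviations), synonyms=frozenset(synonyms),
            species="mouse", source="toy",
        ))
    return entries, Gazetteer.from_entries(entries)


def _mention_tokens(entry: OntologyEntry, rng: np.random.Generator) -> list[str]:
    """Pick a surface form: canonical, or sometimes a synonym/abbreviation."""
    r = rng.random()
    if entry.synonyms and r < 0.2:
        return sorted(entry.synonyms)[0].split()
    if entry.abbreviations and r > 0.9:
        return sorted(entry.abbreviations)[0].split()
    return entry.canonical_name.split()


def _instantiate(template: list[str], fills: dict[str, list[str]]
                 ) -> tuple[list[str], dict[str, EntitySpan]]:
    tokens: list[str] = []
    spans: dict[str, EntitySpan] = {}
    for tok in template:
        if tok.startswith("{"):
            slot = tok[1:-1]
            words = fills[slot]
            spans[slot] = EntitySpan(len(tokens), len(tokens) + len(words), " ".join(words))
            tokens.extend(words)
        else:
            tokens.append(tok)
    return tokens, spans


def generate_corpus(cfg: SynthConfig,
                    ontology: list[OntologyEntry] | None = None) -> SynthCorpus:
    """Generate labelled NER + relation corpora and their ground truth."""
    if ontology is None:
        ontology, _ = generate_ontology(cfg)
    if len(ontology) < 2:
        raise ValueError("ontology must contain at least two regions")
    if sum(cfg.relation_class_mix[1:]) > 0 and len(ontology) < 2:
        raise ValueError("relations need at least two regions")
    rng = np.random.default_rng(cfg.seed + 1)
    classes = ("unconnected", "undirected", "output", "input")
    mix = np.array([cfg.relation_class_mix[0], cfg.relation_class_mix[1],
                    cfg.relation_class_mix[2], cfg.relation_class_mix[3]])
    clean_sentences: list[LabeledSentence] = []
    noisy_sentences: list[LabeledSentence] = []
    mentions: dict[tuple[str, int], list[tuple[EntitySpan, str]]] = {}
    relations: list[RelationInstance] = []
    relation_ids: list[tuple[str, str]] = []
    triples: list[ConnectivityTriple] = []

    for d in range(cfg.n_documents):
        doc_id = f"pmid{d:05d}"
        for s in range(cfg.sentences_per_document):
            roll = rng.random()
            if roll < cfg.filler_rate:
                if rng.random() < 0.5:
                    tokens = list(_FILLER[rng.integers(len(_FILLER))])
                    spans = {}
                    ids = {}
                else:
                    entry = ontology[rng.integers(len(ontology))]
                    tmpl = _SINGLE[rng.integers(len(_SINGLE))]
                    tokens, spans = _instantiate(
                        tmpl, {"X": _mention_tokens(entry, rng)})
                    ids = {"X": entry.id}
                label = None
            else:
                label = classes[rng.choice(4, p=mix)]
                i, j = rng.choice(len(ontology), size=2, replace=False)
                ex, ey = ontology[int(i)], ontology[int(j)]
                tmpl = _TEMPLATES[label][rng.integers(len(_TEMPLATES[label]))]
                tokens, spans = _instantiate(tmpl, {
                    "X": _mention_tokens(ex, rng), "Y": _mention_tokens(ey, rng)})
                ids = {"X": ex.id, "Y": ey.id}
            span_list = sorted(spans.values())
            labels = labels_from_spans(span_list, len(tokens))
            sent = LabeledSentence(doc_id, s, tokens, labels)
            clean_sentences.append(sent)
            mentions[(doc_id, s)] = [
                (spans[slot], ids[slot]) for slot in sorted(spans)]
            if label is not None:
                subj, obj = spans["X"], spans["Y"]
                subj_id, obj_id = ids["X"], ids["Y"]
                if obj.start < subj.start:
                    subj, obj = obj, subj
                    subj_id, obj_id = obj_id, subj_id
                inst = RelationInstance(sent, subj, obj, label)
                relations.append(inst)
                relation_ids.append((subj_id, obj_id))
                triple = canonicalize(label, subj_id, obj_id, pmid=doc_id,
                                      sent_id=s, evidence=" ".join(tokens))
                if triple is not None:
                    triples.append(triple)
            noisy_sentences.append(_apply_noise(sent, cfg, rng))

    truth = GroundTruth(ontology, clean_sentences, mentions, relations,
                        relation_ids, triples)
    return SynthCorpus(noisy_sentences, relations, truth)


def _apply_noise(sent: LabeledSentence, cfg: SynthConfig,
                 rng: np.random.Generator) -> LabeledSentence:
    """Truncate one boundary token of a fraction of training spans."""
    if cfg.boundary_noise_rate == 0:
        return sent.copy()
    new_spans = []
    for sp in sent.spans():
        if len(sp) >= 2 and rng.random() < cfg.boundary_noise_rate:
            if rng.random() < 0.5:
                sp = EntitySpan(sp.start + 1, sp.end)
            else:
                sp = EntitySpan(sp.start, sp.end - 1)
        new_spans.append(sp)
    return sent.with_labels(labels_from_spans(new_spans, len(sent.tokens)))


def test_encoder(seed: int = 0, H: int = 32, L: int = 2,
                 vocab_size: int = 128) -> TransformerEncoder:
    """Small deterministic encoder fixture honouring the encode contract."""
    cfg = EncoderConfig(hidden_size=H, num_layers=L, vocab_size=vocab_size)
    return TransformerEncoder(cfg, seed=seed)
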