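"""End-to-end extraction: NER -> candidate pairs -> RE -> linking -> graph."""

from __future__ import annotations

from .corpus_io import build_relation_instances
from .kg import ConnectivityGraph, canonicalize
from .linking import Linker
from .ner import DecodeConfig, NERTagger
from .relation import RelationClassifier
from .types import LabeledSentence


def extract_connectivity(
    sentences: list[LabeledSentence],
    tagger: NERTagger,
    classifier: RelationClassifier,
    linker: Linker,
    decode: DecodeConfig | None = None,
) -> ConnectivityGraph:
    """Run the full pipeline over tokenized sentences and build the graph.

    Sentences may carry dummy labels (only tokens are used). Mentions that
    fail dictionary linking are recorded in the graph's unlinked side
    table rather than dropped silently.
    """
    pred_spans = tagger.predict(sentences, decode)
    candidates = []
    for sent, spans in zip(sentences, pred_spans):
        candidates.extend(build_relation_instances(sent, spans))
    graph = ConnectivityGraph()
    if not candidates:
        return graph
    predictions = classifier.predict(candidates)
    for inst, pred in zip(candidates, predictions):
        if pred.predicted_label == "unconnected":
            continue
        links = [linker.link(inst.subj.surface), linker.link(inst.obj.surface)]
        sent = inst.sentence
        ok = True
        for span, res in zip((inst.subj, inst.obj), links):
            if res.matched_id is None:
                graph.note_unlinked(span.surface, sent.doc_id, sent.sent_id)
                ok = False
        if not ok:
            continue
        triple = canonicalize(
            pred.predicted_label, links[0].matched_id, links[1].matched_id,
            pmid=sent.doc_id, sent_id=sent.sent_id, evidence=" ".join(sent.tokens),
        )
        if triple is not None:
            graph.add(triple)
    return graph
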