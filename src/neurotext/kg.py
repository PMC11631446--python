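"""Directional connectivity knowledge-graph assembly.

Classified relation instances are canonicalized into triples: an
"output" label means the first-mentioned region projects to the second,
an "input" label means the projection runs the other way, and
"undirected" edges are stored once in canonical id order (they are not
expanded into two directed edges, preserving the three-way evidence
distinction). The graph is a multigraph keyed by (source, target,
relation) whose edges accumulate per-sentence evidence records,
deduplicated per (document, sentence, pair, label).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .types import CircuitSummary, ConnectivityTriple, RELATION_CLASSES

logger = logging.getLogger(__name__)

__all__ = ["canonicalize", "ConnectivityGraph", "build_graph", "circuit",
           "export_graph", "load_graph"]


def canonicalize(
    label: str, subj_id: str, obj_id: str, pmid: str = "", sent_id: int = 0,
    evidence: str = "",
) -> ConnectivityTriple | None:
    """Turn a 4-way classified mention pair into a canonical triple.

    output -> subj projects to obj; input -> obj projects to subj;
    undirected -> canonical-order undirected edge; unconnected -> None.
    Pairs that normalize to the same id are dropped (logged).
    """
    if label not in RELATION_CLASSES:
        raise ValueError(f"unknown relation label {label!r}")
    if label == "unconnected":
        return None
    if subj_id == obj_id:
        logger.info("dropping self-link %s (%s) at %s:%s", subj_id, label, pmid, sent_id)
        return None
    if label == "output":
        src, tgt, rel = subj_id, obj_id, "projects_to"
    elif label == "input":
        src, tgt, rel = obj_id, subj_id, "projects_to"
    else:
        src, tgt = sorted((subj_id, obj_id))
        rel = "connected_undirected"
    return ConnectivityTriple(src, tgt, rel, pmid, sent_id, evidence, label)


@dataclass
class ConnectivityGraph:
    """Evidence-bearing connectivity multigraph over dictionary ids."""

    graph: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph)
    _seen: set[tuple] = field(default_factory=set)
    unlinked: list[dict] = field(default_factory=list)

    def add(self, triple: ConnectivityTriple) -> bool:
        """Insert a triple; returns False for duplicate evidence records."""
        key = triple.dedup_key()
        if key in self._seen:
            return False
        self._seen.add(key)
        u, v, rel = triple.source_id, triple.target_id, triple.relation
        if self.graph.has_edge(u, v, key=rel):
            self.graph[u][v][rel]["evidence"].append(triple)
        else:
            self.graph.add_edge(u, v, key=rel, evidence=[triple])
        return True

    def note_unlinked(self, mention: str, pmid: str, sent_id: int) -> None:
        """Record a mention that failed dictionary linking (side table)."""
        self.unlinked.append({"mention": mention, "pmid": pmid, "sent_id": sent_id})

    def edges(self) -> list[tuple[str, str, str, list[ConnectivityTriple]]]:
        return [(u, v, rel, data["evidence"])
                for u, v, rel, data in self.graph.edges(keys=True, data=True)]

    @property
    def n_evidence(self) -> int:
        return sum(len(ev) for *_ignored, ev in self.edges())

    def directed_edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, rel, _ in self.edges() if rel == "projects_to"}


def build_graph(triples: list[ConnectivityTriple | None]) -> ConnectivityGraph:
    """Assemble a graph from canonicalized triples (Nones are skipped)."""
    g = ConnectivityGraph()
    for t in triples:
        if t is not None:
            g.add(t)
    return g


def circuit(region_id: str, kg: ConnectivityGraph,
            known_ids: set[str] | None = None) -> CircuitSummary:
    """Input/output/undirected partner counts for one region.

    A region absent from the graph yields an empty summary; an id outside
    the dictionary (when ``known_ids`` is given) is an error.
    """
    if known_ids is not None and region_id not in known_ids:
        raise KeyError(f"unknown region id {region_id!r}")
    summary = CircuitSummary(region_id)
    for u, v, rel, evidence in kg.edges():
        n = len(evidence)
        if rel == "projects_to":
            if u == region_id:
                summary.outputs[v] = summary.outputs.get(v, 0) + n
            if v == region_id:
                summary.inputs[u] = summary.inputs.get(u, 0) + n
        elif region_id in (u, v):
            partner = v if u == region_id else u
            summary.undirected[partner] = summary.undirected.get(partner, 0) + n
    return summary


def export_graph(kg: ConnectivityGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write edges.tsv (+ counts), evidence.json (provenance), unlinked.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, evidence = [], []
    for u, v, rel, ev in sorted(kg.edges()):
        rows.append({"source": u, "target": v, "relation": rel, "n_evidence": len(ev)})
        evidence.append({
            "source": u, "target": v, "relation": rel,
            "evidence": [{
                "pmid": t.pmid, "sent_id": t.sent_id, "sentence": t.evidence,
                "extraction_label": t.extraction_label,
            } for t in ev],
        })
    paths = {
        "edges": out_dir / "edges.tsv",
        "evidence": out_dir / "evidence.json",
        "unlinked": out_dir / "unlinked.tsv",
    }
    pd.DataFrame(rows, columns=["source", "target", "relation", "n_evidence"]) \
        .to_csv(paths["edges"], sep="\t", index=False)
    paths["evidence"].write_text(json.dumps(evidence, indent=1))
    pd.DataFrame(kg.unlinked, columns=["mention", "pmid", "sent_id"]) \
        .to_csv(paths["unlinked"], sep="\t", index=False)
    return paths


def load_graph(out_dir: str | Path) -> ConnectivityGraph:
    """Inverse of :func:`export_graph` (round-trips the edge multiset)."""
    out_dir = Path(out_dir)
    records = json.loads((out_dir / "evidence.json").read_text())
    g = ConnectivityGraph()
    for rec in records:
        for ev in rec["evidence"]:
            g.add(ConnectivityTriple(
                rec["source"], rec["target"], rec["relation"],
                ev["pmid"], int(ev["sent_id"]), ev.get("sentence", ""),
                ev.get("extraction_label", ""),
            ))
    unlinked_path = out_dir / "unlinked.tsv"
    if unlinked_path.exists():
        df = pd.read_csv(unlinked_path, sep="\t", keep_default_na=False)
        g.unlinked = df.to_dict("records")
    return g
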