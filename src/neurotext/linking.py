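"""Ontology merging and staged entity normalization.

Region mentions extracted from text are mapped to stable ids in a merged
nomenclature dictionary (emulating Allen / NeuroNames / BAMS style
merges). Linking runs in stages, recording which stage succeeded:

1. exact match on canonical names, abbreviations and synonyms;
2. exact match after stripping directional modifiers ("rostral", ...);
3. exact match of nested sub-mentions found by the gazetteer trie;
4. word-overlap fuzzy scoring against every term and synonym, accepting
   the best candidate above a threshold.

Abbreviations are matched exactly only — short forms collide across
nomenclatures (the same structure may be AHN, AHA or AH depending on the
atlas) and word-level fuzzing would amplify that.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .types import LinkResult, OntologyEntry

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_token", "normalize_phrase", "STOPWORDS", "DIRECTIONAL_WORDS",
    "Gazetteer", "GazetteerMatch", "merge_ontologies",
    "read_ontology", "write_ontology",
    "Linker", "exact_link", "strip_directional", "nested_fallback", "fuzzy_word_link",
]

STOPWORDS = frozenset({"of", "the", "a", "an"})
DIRECTIONAL_WORDS = frozenset({
    "rostral", "caudal", "dorsal", "ventral", "anterior", "posterior",
    "medial", "lateral", "superior", "inferior", "left", "right",
})
_PUNCT = str.maketrans("", "", string.punctuation)


def normalize_token(token: str) -> str:
    """Case-fold and strip punctuation from a single token."""
    return token.lower().translate(_PUNCT).strip()


def normalize_phrase(text: str, drop_stopwords: bool = True) -> tuple[str, ...]:
    """Normalized word tuple for phrase-level matching keys."""
    words = [normalize_token(w) for w in text.split()]
    words = [w for w in words if w]
    if drop_stopwords:
        words = [w for w in words if w not in STOPWORDS]
    return tuple(words)


@dataclass(frozen=True)
class GazetteerMatch:
    start: int
    end: int
    ids: frozenset[str]
    surface: str


class Gazetteer:
    """Token-level trie over every dictionary surface form.

    Supports longest-match iteration over a token sequence (the
    "dictionary tree" used both for annotation denoising and for nested
    sub-mention candidates). Surface forms are stored as normalized token
    tuples with inner stopwords kept, so multi-word names match in situ.
    """

    _END = object()

    def __init__(self) -> None:
        self._root: dict = {}
        self._n_forms = 0

    @classmethod
    def from_entries(cls, entries: list[OntologyEntry],
                     include_abbreviations: bool = True) -> "Gazetteer":
        gaz = cls()
        for entry in entries:
            for form in entry.surface_forms():
                gaz.add(form, entry.id)
            if include_abbreviations:
                for abbr in entry.abbreviations:
                    gaz.add(abbr, entry.id)
        return gaz

    def add(self, surface: str, entry_id: str) -> None:
        words = tuple(normalize_token(w) for w in surface.split())
        words = tuple(w for w in words if w)
        if not words:
            return
        node = self._root
        for w in words:
            node = node.setdefault(w, {})
        if self._END not in node:
            self._n_forms += 1
            node[self._END] = set()
        node[self._END].add(entry_id)

    def __len__(self) -> int:
        return self._n_forms

    def __contains__(self, surface: str) -> bool:
        node = self._lookup(tuple(normalize_token(w) for w in surface.split()))
        return node is not None and self._END in node

    def _lookup(self, words: tuple[str, ...]):
        node = self._root
        for w in words:
            node = node.get(w)
            if node is None:
                return None
        return node

    def ids_for(self, surface: str) -> frozenset[str]:
        node = self._lookup(tuple(normalize_token(w) for w in surface.split()))
        if node is None or self._END not in node:
            return frozenset()
        return frozenset(node[self._END])

    def longest_match_at(self, tokens: list[str], start: int) -> GazetteerMatch | None:
        """Longest dictionary form starting at token *start*, if any."""
        node = self._root
        best: tuple[int, set] | None = None
        for j in range(start, len(tokens)):
            node = node.get(normalize_token(tokens[j]))
            if node is None:
                break
            if self._END in node:
                best = (j + 1, node[self._END])
        if best is None:
            return None
        end, ids = best
        return GazetteerMatch(start, end, frozenset(ids), " ".join(tokens[start:end]))

    def longest_matches(self, tokens: list[str]) -> list[GazetteerMatch]:
        """Maximal non-overlapping longest matches, scanning left to right."""
        out = []
        i = 0
        while i < len(tokens):
            m = self.longest_match_at(tokens, i)
            if m is None:
                i += 1
            else:
                out.append(m)
                i = m.end
        return out


def merge_ontologies(sources: list[list[OntologyEntry]]) -> tuple[list[OntologyEntry], pd.DataFrame]:
    """Unify entries across nomenclature sources by exact name/abbreviation match.

    Entries whose canonical names (or abbreviations, when unambiguous)
    coincide are unified under the first-seen id with the union of their
    synonyms; a cross-reference table records every source id. Entries
    that would unify but disagree on species are kept separate (logged).
    Abbreviation collisions (same short form, different structures) never
    unify and are logged.
    """
    if not sources:
        raise ValueError("need at least one ontology source")
    merged: dict[str, OntologyEntry] = {}
    by_name: dict[tuple[str, ...], str] = {}
    by_abbr: dict[str, str] = {}
    xref_rows = []
    for source in sources:
        for entry in source:
            key = normalize_phrase(entry.canonical_name)
            target_id = by_name.get(key)
            if target_id is None:
                for abbr in entry.abbreviations:
                    hit = by_abbr.get(abbr.lower())
                    if hit is None:
                        continue
                    if normalize_phrase(merged[hit].canonical_name) != key:
                        logger.info(
                            "abbreviation collision: %r names both %s and %s",
                            abbr, hit, entry.id,
                        )
                    else:
                        target_id = hit
                        break
            if target_id is not None and merged[target_id].species and entry.species \
                    and merged[target_id].species != entry.species:
                logger.info("species conflict for %r; keeping %s and %s separate",
                            entry.canonical_name, target_id, entry.id)
                target_id = None
            if target_id is None:
                uid = entry.id
                if uid in merged:  # id collision across sources: disambiguate
                    uid = f"{entry.source or 'src'}:{entry.id}"
                merged[uid] = OntologyEntry(
                    uid, entry.canonical_name, frozenset(entry.abbreviations),
                    frozenset(entry.synonyms), entry.species, entry.source,
                )
                by_name.setdefault(key, uid)
                for abbr in entry.abbreviations:
                    by_abbr.setdefault(abbr.lower(), uid)
                target_id = uid
            else:
                old = merged[target_id]
                merged[target_id] = OntologyEntry(
                    old.id, old.canonical_name,
                    old.abbreviations | entry.abbreviations,
                    old.synonyms | entry.synonyms | {entry.canonical_name},
                    old.species or entry.species, old.source,
                )
                for abbr in entry.abbreviations:
                    by_abbr.setdefault(abbr.lower(), target_id)
            xref_rows.append({"unified_id": target_id, "source": entry.source,
                              "source_id": entry.id})
    xref = pd.DataFrame(xref_rows, columns=["unified_id", "source", "source_id"])
    return list(merged.values()), xref


def read_ontology(path: str | Path) -> list[OntologyEntry]:
    """Read an ontology TSV/JSON (abbreviations and synonyms |-separated)."""
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
        records = df.to_dict("records")
    entries = []
    for rec in records:
        def _split(v):
            if isinstance(v, str):
                return frozenset(x for x in v.split("|") if x)
            return frozenset(v or ())
        entries.append(OntologyEntry(
            str(rec["id"]), str(rec["name"]),
            _split(rec.get("abbreviations", "")), _split(rec.get("synonyms", "")),
            str(rec.get("species", "")), str(rec.get("source", "")),
        ))
    return entries


def write_ontology(entries: list[OntologyEntry], path: str | Path) -> None:
    rows = [{
        "id": e.id, "name": e.canonical_name,
        "abbreviations": "|".join(sorted(e.abbreviations)),
        "synonyms": "|".join(sorted(e.synonyms)),
        "species": e.species, "source": e.source,
    } for e in entries]
    pd.DataFrame(rows, columns=["id", "name", "abbreviations", "synonyms",
                                "species", "source"]).to_csv(path, sep="\t", index=False)


def strip_directional(mention: str, lexicon: frozenset[str] = DIRECTIONAL_WORDS) -> str:
    """Remove directional modifier words; never empty the mention."""
    words = mention.split()
    kept = [w for w in words if normalize_token(w) not in lexicon]
    return " ".join(kept) if kept else mention


@dataclass
class Linker:
    """Staged mention -> dictionary-id linker with a trace log."""

    entries: list[OntologyEntry]
    fuzzy_weight: float = 0.5
    fuzzy_threshold: float = 0.5
    directional_lexicon: frozenset[str] = DIRECTIONAL_WORDS
    gazetteer: Gazetteer = field(init=False)
    _exact: dict[tuple[str, ...], set[str]] = field(init=False)
    _abbr: dict[str, set[str]] = field(init=False)
    _term_words: list[tuple[str, frozenset[str], int]] = field(init=False)
    trace: list[str] = field(default_factory=list, init=False)

    def __post_init__(self) -> None:
        self.gazetteer = Gazetteer.from_entries(self.entries)
        self._exact = {}
        self._abbr = {}
        self._term_words = []
        for e in self.entries:
            for form in e.surface_forms():
                key = normalize_phrase(form)
                if key:
                    self._exact.setdefault(key, set()).add(e.id)
                words = frozenset(normalize_phrase(form))
                if words:
                    self._term_words.append((e.id, words, len(words)))
            for abbr in e.abbreviations:
                self._abbr.setdefault(abbr.lower(), set()).add(e.id)

    # -- stages -------------------------------------------------------------

    @staticmethod
    def _pick(ids: set[str]) -> str:
        return sorted(ids)[0]  # deterministic tie rule

    def exact_link(self, mention: str) -> LinkResult:
        key = normalize_phrase(mention)
        ids = set(self._exact.get(key, ())) if key else set()
        ids |= self._abbr.get(mention.strip().lower(), set())
        if ids:
            return LinkResult(mention, self._pick(ids), 1.0, "exact")
        return LinkResult(mention, None, 0.0, "none")

    def nested_fallback(self, mention: str) -> list[str]:
        """Gazetteer sub-mentions strictly inside the mention, longest first."""
        tokens = mention.split()
        if len(tokens) < 2:
            return []
        full = (0, len(tokens))
        candidates = []
        for i in range(len(tokens)):
            m = self.gazetteer.longest_match_at(tokens, i)
            if m is not None and (m.start, m.end) != full:
                candidates.append(m)
        seen: set[tuple[int, int]] = set()
        out = []
        for m in sorted(candidates, key=lambda m: (-len(m.surface), m.start)):
            if (m.start, m.end) not in seen:
                seen.add((m.start, m.end))
                out.append(m.surface)
        return out

    def fuzzy_word_link(self, mention: str) -> list[LinkResult]:
        """Word-overlap scoring of the mention against every term/synonym.

        score = w * |M ∩ T| / |M| + (1 - w) * |M ∩ T| / |T| over normalized
        stopword-free word sets M (mention) and T (term); candidates are
        ranked by score, then fewer term words, then id.
        """
        mention_words = set(normalize_phrase(mention))
        if not mention_words or not self._term_words:
            return []
        w = self.fuzzy_weight
        best: dict[str, tuple[float, int]] = {}
        for entry_id, words, n_words in self._term_words:
            overlap = len(mention_words & words)
            if overlap == 0:
                continue
            score = w * overlap / len(mention_words) + (1 - w) * overlap / n_words
            cur = best.get(entry_id)
            if cur is None or (score, -n_words) > (cur[0], -cur[1]):
                best[entry_id] = (score, n_words)
        ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))
        return [LinkResult(mention, eid, round(s, 12), "fuzzy_word")
                for eid, (s, _) in ranked]

    # -- staged entry point --------------------------------------------------

    def link(self, mention: str) -> LinkResult:
        self.trace.append(f"exact:{mention}")
        res = self.exact_link(mention)
        if res.matched_id is not None:
            return res

        stripped = strip_directional(mention, self.directional_lexicon)
        if stripped != mention:
            self.trace.append(f"strip_directional:{stripped}")
            res = self.exact_link(stripped)
            if res.matched_id is not None:
                return LinkResult(mention, res.matched_id, 1.0, "strip_directional")

        for sub in self.nested_fallback(mention):
            self.trace.append(f"nested:{sub}")
            res = self.exact_link(sub)
            if res.matched_id is not None:
                return LinkResult(mention, res.matched_id, 1.0, "nested")

        self.trace.append(f"fuzzy:{mention}")
        ranked = self.fuzzy_word_link(mention)
        if ranked and ranked[0].score >= self.fuzzy_threshold:
            return ranked[0]
        return LinkResult(mention, None, 0.0, "none")

    def link_all(self, mentions: list[str]) -> list[LinkResult]:
        return [self.link(m) for m in mentions]


def exact_link(mention: str, entries: list[OntologyEntry]) -> LinkResult:
    return Linker(entries).exact_link(mention)


def nested_fallback(mention: str, gazetteer_or_entries) -> list[str]:
    if isinstance(gazetteer_or_entries, Gazetteer):
        linker = Linker.__new__(Linker)
        linker.gazetteer = gazetteer_or_entries
        return Linker.nested_fallback(linker, mention)
    return Linker(gazetteer_or_entries).nested_fallback(mention)


def fuzzy_word_link(mention: str, entries: list[OntologyEntry],
                    weight: float = 0.5, threshold: float = 0.5) -> list[LinkResult]:
    return Linker(entries, fuzzy_weight=weight, fuzzy_threshold=threshold).fuzzy_word_link(mention)
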