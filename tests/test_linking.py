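import numpy as np
import pytest

from neurotext.linking import (
    Gazetteer, Linker, merge_ontologies, normalize_phrase, read_ontology,
    strip_directional, write_ontology,
)
from neurotext.types import OntologyEntry


class TestMerge:
    def test_exact_name_unification(self):
        a = [OntologyEntry("ALN:1", "paraventricular hypothalamic nucleus",
                           frozenset({"PVH"}), source="allen")]
        b = [OntologyEntry("BAMS:9", "Paraventricular hypothalamic nucleus",
                           synonyms=frozenset({"PVN"}), source="bams")]
        merged, xref = merge_ontologies([a, b])
        assert len(merged) == 1
        assert "PVN" in merged[0].synonyms
        assert sorted(xref["source_id"]) == ["ALN:1", "BAMS:9"]

    def test_disjoint_sources_concatenate(self):
        a = [OntologyEntry(f"A:{i}", f"alpha region {i}") for i in range(5)]
        b = [OntologyEntry(f"B:{i}", f"beta region {i}") for i in range(7)]
        merged, _ = merge_ontologies([a, b])
        assert len(merged) == 12

    def test_abbreviation_collision_keeps_both(self, caplog):
        a = [OntologyEntry("A:1", "anterior hypothalamic nucleus", frozenset({"AH"}))]
        b = [OntologyEntry("B:1", "adenohypophysis", frozenset({"AH"}))]
        merged, _ = merge_ontologies([a, b])
        assert len(merged) == 2

    def test_species_conflict_kept_separate(self):
        a = [OntologyEntry("A:1", "arcuate nucleus", species="mouse")]
        b = [OntologyEntry("B:1", "arcuate nucleus", species="rat")]
        merged, _ = merge_ontologies([a, b])
        assert len(merged) == 2

    def test_ontology_tsv_round_trip(self, tmp_path, toy_entries):
        path = tmp_path / "dict.tsv"
        write_ontology(toy_entries, path)
        back = read_ontology(path)
        assert {(e.id, e.canonical_name, e.abbreviations) for e in back} == \
            {(e.id, e.canonical_name, e.abbreviations) for e in toy_entries}


class TestExactLink:
    def test_hit_scores_one(self, toy_linker):
        res = toy_linker.exact_link("ventral tegmental area")
        assert (res.matched_id, res.score, res.method) == ("A:01", 1.0, "exact")

    def test_miss_returns_none(self, toy_linker):
        assert toy_linker.exact_link("cerebellar cortex").matched_id is None

    def test_case_folding(self, toy_linker):
        assert toy_linker.exact_link("Ventral Tegmental Area").matched_id == "A:01"

    def test_abbreviation_exact_only(self, toy_linker):
        assert toy_linker.exact_link("VTA").matched_id == "A:01"


class TestStripDirectional:
    @pytest.mark.parametrize("mention,expected", [
        ("rostral paraventricular nucleus", "paraventricular nucleus"),
        ("dorsal lateral geniculate nucleus", "geniculate nucleus"),
        ("hippocampus", "hippocampus"),
    ])
    def test_lexicon_removal(self, mention, expected):
        assert strip_directional(mention) == expected

    def test_never_empties_mention(self):
        assert strip_directional("dorsal lateral") == "dorsal lateral"


class TestNestedFallback:
    def test_internal_matches_ordered_longest_first(self, toy_linker):
        subs = toy_linker.nested_fallback("CA1 field of the hippocampus")
        assert subs == ["hippocampus", "CA1"]

    def test_no_internal_matches(self, toy_linker):
        assert toy_linker.nested_fallback("unknown wording here") == []

    def test_full_mention_match_excluded(self, toy_linker):
        assert toy_linker.nested_fallback("hippocampus") == []


class TestFuzzy:
    def test_identical_term_scores_one_and_ranks_first(self, toy_linker):
        ranked = toy_linker.fuzzy_word_link("lateral habenula")
        assert ranked[0].matched_id == "A:02"
        assert ranked[0].score == pytest.approx(1.0)

    def test_stopwords_ignored_in_scoring(self, toy_linker):
        """Word sets match fully once 'of the' is dropped."""
        ranked = toy_linker.fuzzy_word_link("paraventricular nucleus thalamus")
        assert ranked[0].matched_id == "A:05"
        assert ranked[0].score == pytest.approx(1.0)

    def test_no_shared_content_words(self, toy_linker):
        ranked = toy_linker.fuzzy_word_link("cerebellar vermis")
        assert not ranked or ranked[0].score < toy_linker.fuzzy_threshold

    def test_ranked_lists_deterministic(self, toy_linker):
        a = toy_linker.fuzzy_word_link("paraventricular nucleus")
        b = toy_linker.fuzzy_word_link("paraventricular nucleus")
        assert [(r.matched_id, r.score) for r in a] == [(r.matched_id, r.score) for r in b]


class TestStagedLink:
    def test_exact_precedence_short_circuits(self, toy_entries):
        linker = Linker(toy_entries)
        res = linker.link("hippocampus")
        assert (res.matched_id, res.method, res.score) == ("A:03", "exact", 1.0)
        assert not any(t.startswith(("strip", "nested", "fuzzy")) for t in linker.trace)

    def test_strip_directional_stage(self, toy_linker):
        res = toy_linker.link("dorsal lateral geniculate nucleus")
        assert (res.matched_id, res.method) == ("A:07", "strip_directional")

    def test_nested_stage(self, toy_linker):
        res = toy_linker.link("CA1 field region complexes")
        assert (res.matched_id, res.method) == ("A:04", "nested")

    def test_all_stages_miss(self, toy_linker):
        res = toy_linker.link("zona incerta")
        assert res.matched_id is None and res.method == "none"

    def test_exact_agreement_with_staged(self, toy_linker, toy_entries):
        for entry in toy_entries:
            res = toy_linker.link(entry.canonical_name)
            assert res.method == "exact" and res.score == 1.0

    def test_fuzzy_extends_exact_coverage(self, synth_ontology):
        """Staged fuzzy linking maps at least as many perturbed mentions."""
        entries, _ = synth_ontology
        linker = Linker(entries)
        rng = np.random.default_rng(13)
        mentions = []
        for e in entries:
            words = e.canonical_name.split()
            mentions.append(e.canonical_name)
            if len(words) >= 2:
                drop = int(rng.integers(len(words) - 1))  # keep the head noun
                mentions.append(" ".join(w for k, w in enumerate(words) if k != drop))
                mentions.append(" ".join(reversed(words)))
        exact_hits = sum(linker.exact_link(m).matched_id is not None for m in mentions)
        staged_hits = sum(linker.link(m).matched_id is not None for m in mentions)
        assert staged_hits >= exact_hits
        assert staged_hits > exact_hits  # perturbations exist that only fuzzy maps


class TestGazetteer:
    def test_longest_match_is_maximal(self):
        g = Gazetteer()
        g.add("anterior hypothalamic nucleus", "X:1")
        g.add("hypothalamic nucleus", "X:2")
        tokens = "the anterior hypothalamic nucleus fired".split()
        matches = g.longest_matches(tokens)
        assert [(m.start, m.end) for m in matches] == [(1, 4)]
        assert matches[0].ids == frozenset({"X:1"})

    def test_every_surface_form_retrievable(self, synth_ontology):
        entries, gaz = synth_ontology
        for e in entries:
            for form in e.surface_forms():
                assert form in gaz
                assert e.id in gaz.ids_for(form)

    def test_normalization_tuple(self):
        assert normalize_phrase("The Paraventricular Nucleus, of the Thalamus") == \
            ("paraventricular", "nucleus", "thalamus")
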