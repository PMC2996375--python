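"""OBO 1.4 export, re-import, and dialect degradation."""

import io
import warnings

import pytest
from hypothesis import given, settings, strategies as st

from neurogloss import fixtures
from neurogloss.model import KnowledgeBase, Quantifier
from neurogloss.obo import OboDialectWarning, from_obo, to_obo


def _stanza(text: str, obo_id: str) -> str:
    chunks = text.split("\n\n")
    for chunk in chunks:
        if f"id: {obo_id}\n" in chunk + "\n":
            return chunk
    raise AssertionError(f"no stanza {obo_id}")


class TestExport:
    def test_commissure_is_a_neurite_bundle_by_id(self, kb):
        text = to_obo(kb)
        stanza = _stanza(text, "NGLO:0000006")
        assert "name: commissure" in stanza
        assert "is_a: NGLO:0000024" in stanza

    def test_brain_carries_two_discouraged_synonym_lines(self, kb):
        stanza = _stanza(to_obo(kb), "NGLO:0000003")
        syns = [l for l in stanza.splitlines() if l.startswith("synonym:")]
        assert syns == [
            'synonym: "cerebral ganglion" RELATED DISCOURAGED []',
            'synonym: "supraesophageal ganglion" RELATED DISCOURAGED []',
        ]

    def test_every_quantifier_travels_as_trailing_modifier(self, kb):
        stanza = _stanza(to_obo(kb), "NGLO:0000004")  # central body
        assert 'relationship: part_of NGLO:0000005 {quantifier="every"}' in stanza

    def test_empty_kb_exports_header_without_term_stanzas(self):
        text = to_obo(KnowledgeBase(primitives=frozenset()))
        assert "format-version: 1.4" in text
        assert "ontology: nglo" in text
        assert "[Term]" not in text

    def test_export_is_deterministic(self, kb):
        assert to_obo(kb) == to_obo(kb)

    def test_side_entries_are_tagged_and_alphabetical(self, kb):
        text = to_obo(kb)
        side_ids = [
            line.split()[1]
            for stanza in text.split("\n\n")
            if "subset: side_entry" in stanza
            for line in stanza.splitlines()
            if line.startswith("id: ")
        ]
        assert side_ids == sorted(side_ids)
        assert side_ids[0] == "NGLO:0001001"


class TestRoundTrip:
    def test_bundled_corpus_round_trips_minus_register(self, kb):
        back = from_obo(to_obo(kb))
        assert back == kb.without_register()
        assert back.register == ()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=25),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_generated_kbs_round_trip(self, n, seed):
        kb = fixtures.random_taxonomy(n, 0.4, seed)
        assert from_obo(to_obo(kb)) == kb.without_register()

    def test_quantifiers_survive(self, kb):
        back = from_obo(to_obo(kb))
        assert back.term("central body").parts[0].quantifier is Quantifier.EVERY
        assert back.term("brain").parts[0].quantifier is Quantifier.SOME


class TestDialectDegradation:
    def test_unknown_relationship_type_warns_but_term_is_imported(self, kb):
        # mushroom body {17} is part of a brain (NGLO:0000003)
        text = to_obo(kb).replace(
            "relationship: part_of NGLO:0000003", "relationship: adjacent_to NGLO:0000003", 1
        )
        with pytest.warns(OboDialectWarning, match="relationship"):
            back = from_obo(text)
        assert back.has_term("mushroom body")
        assert back.term("mushroom body").parts == ()

    def test_missing_synonymtypedef_degrades_discouraged_synonyms(self, kb):
        text = "\n".join(
            line
            for line in to_obo(kb).splitlines()
            if not line.startswith("synonymtypedef:")
        )
        with pytest.warns(OboDialectWarning, match="synonymtypedef"):
            back = from_obo(text)
        assert back.term("brain").discouraged == ()

    def test_foreign_stanza_is_skipped_with_warning(self, kb):
        text = to_obo(kb) + "\n[Instance]\nid: X:1\n"
        with pytest.warns(OboDialectWarning, match="Instance"):
            from_obo(text)


def test_export_parses_under_a_standard_obo_parser(kb):
    obonet = pytest.importorskip("obonet")
    graph = obonet.read_obo(io.StringIO(to_obo(kb)), ignore_obsolete=True)
    assert graph.graph["ontology"] == "nglo"
    # all 47 main entries present as nodes
    mains = [n for n in graph.nodes if n.startswith("NGLO:00000")]
    assert len(mains) == 47
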