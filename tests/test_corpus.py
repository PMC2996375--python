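"""Corpus parsing, canonical writing and round-trip identity."""

import pytest
from hypothesis import given, settings, strategies as st

from neurogloss import corpus, fixtures
from neurogloss.corpus import CorpusError, parse_corpus, write_corpus
from neurogloss.model import ParentKind, PartStatement, Quantifier

MINIMAL = """\
format: 1

[primitive]
label: cell

[term]
id: 1
label: brain
genus: cluster of cell
part: brain sac (some)
differentia: A clause.
register: 1

[term]
id: 2
label: brain sac
genus: brain
discouraged:
register: 2
"""


class TestParsing:
    def test_bundled_corpus_counts(self, kb):
        assert len(kb.terms) == 47
        assert [t.entry_id for t in kb.terms] == list(range(1, 48))
        assert kb.primitives == {
            "cell", "molecule", "cell process", "cell-to-cell junction"
        }
        # every main term has a register row; rows also cover side entries
        assert all(kb.register_row(t.label) for t in kb.terms)
        assert len(kb.register) == 47 + len(kb.sides)

    def test_genus_phrases_map_to_relation_kinds(self, kb):
        commissure = kb.term("commissure")
        assert commissure.genus.kind is ParentKind.MAIN_TERM
        assert commissure.genus.target == "neurite bundle"
        brain = kb.term("brain")
        assert brain.genus.kind is ParentKind.CLUSTER_OF
        assert brain.genus.target == "neuron"
        neurite = kb.term("neurite")
        assert neurite.genus.kind is ParentKind.PRIMITIVE
        assert neurite.genus.target == "cell process"

    def test_part_of_quantifiers(self, kb):
        central_body = kb.term("central body")
        assert central_body.parts == (
            PartStatement("central complex", Quantifier.EVERY),
        )
        brain = kb.term("brain")
        assert brain.parts[0].whole == "nervous system"
        assert brain.parts[0].quantifier is Quantifier.SOME

    def test_discouraged_lists(self, kb):
        assert kb.term("brain").discouraged == (
            "cerebral ganglion",
            "supraesophageal ganglion",
        )
        # entries that discourage nothing have an empty tuple
        assert kb.term("commissure").discouraged == ()

    def test_empty_discouraged_line_parses_to_empty_list(self):
        kb = parse_corpus(MINIMAL)
        assert kb.term("brain sac").discouraged == ()
        assert kb.term("brain").parts == (
            PartStatement("brain sac", Quantifier.SOME),
        )

    @pytest.mark.parametrize(
        "mangle, fragment",
        [
            (lambda t: t.replace("(some)", "(sometimes)"), "quantifier"),
            (lambda t: t.replace("id: 2", "id: 1"), "duplicate"),
            (lambda t: t.replace("label: brain sac", "label: brain"), "duplicate"),
            (lambda t: t.replace("genus: brain\n", "no colon here\n"), "key"),
            (lambda t: t.replace("format: 1", "format: 99"), "format"),
        ],
    )
    def test_malformed_documents_raise_corpus_error(self, mangle, fragment):
        with pytest.raises(CorpusError) as exc:
            parse_corpus(mangle(MINIMAL))
        assert fragment in str(exc.value)

    def test_parse_error_carries_line_number(self):
        bad = MINIMAL.replace("part: brain sac (some)", "part: brain sac")
        with pytest.raises(CorpusError) as exc:
            parse_corpus(bad)
        assert exc.value.line is not None

    def test_checksum_mismatch_detected(self, kb):
        text = corpus.bundled_corpus_text()
        corrupted = text.replace("label: brain\n", "label: brainy\n", 1)
        with pytest.raises(CorpusError) as exc:
            parse_corpus(corrupted)
        assert "checksum" in str(exc.value)


class TestWriting:
    def test_bundled_corpus_round_trips_byte_identically(self, kb):
        text = corpus.bundled_corpus_text()
        assert write_corpus(parse_corpus(text)) == text

    def test_out_of_order_terms_are_canonicalized_by_id(self, kb):
        from dataclasses import replace

        shuffled = replace(kb, terms=tuple(reversed(kb.terms)))
        text = write_corpus(shuffled)
        reparsed = parse_corpus(text)
        assert [t.entry_id for t in reparsed.terms] == list(range(1, 48))
        assert reparsed == kb

    def test_single_term_kb_writes_one_block_with_header(self):
        kb = fixtures.random_taxonomy(1, 0, seed=7)
        text = write_corpus(kb)
        assert text.count("[term]") == 1
        assert text.startswith("# neurogloss corpus")
        assert "format: 1" in text

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=25),
        p=st.floats(min_value=0, max_value=1),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_parse_write_identity_on_generated_kbs(self, n, p, seed):
        kb = fixtures.random_taxonomy(n, p, seed)
        assert parse_corpus(write_corpus(kb)) == kb
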