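"""Lexicon compilation, dictionary matching and discouraged-term rewriting."""

from hypothesis import given, settings, strategies as st

from neurogloss import fixtures
from neurogloss.annotator import annotate, compile_lexicon, rewrite
from neurogloss.model import Status


class TestLexicon:
    def test_discouraged_synonym_maps_to_owner_with_suggestion(self, lexicon):
        entry = lexicon.lookup("supraesophageal ganglion")
        assert entry.resolved_label == "brain"
        assert entry.status is Status.DISCOURAGED
        assert entry.suggestion == "brain"

    def test_preferred_label_maps_to_itself(self, lexicon):
        entry = lexicon.lookup("brain")
        assert entry.resolved_label == "brain"
        assert entry.status is Status.PREFERRED
        assert entry.suggestion is None

    def test_ocellus_collision_resolved_to_discouraged_and_logged(self, lexicon):
        entry = lexicon.lookup("ocellus")
        assert entry.status is Status.DISCOURAGED
        assert entry.resolved_label == "eye"
        assert any("'ocellus'" in line for line in lexicon.collisions)

    def test_no_surface_maps_to_two_targets(self, lexicon):
        # dict keys are unique by construction; spot-check doubly claimed
        # surfaces resolve deterministically to the lower discouraging entry
        entry = lexicon.lookup("photoreceptor")
        assert entry.status is Status.DISCOURAGED
        assert entry.entry_id == 9

    def test_irregular_plural_forms_are_in_the_lexicon(self, lexicon):
        assert lexicon.lookup("ganglia").resolved_label == "ganglion"
        assert lexicon.lookup("ommatidia").resolved_label == "ommatidium"
        assert lexicon.lookup("somata").resolved_label == "soma"


class TestAnnotate:
    def test_discouraged_match_is_leftmost_longest(self, kb, lexicon):
        text = "the supraesophageal ganglion of Astacus"
        anns = annotate(text, lexicon)
        assert len(anns) == 1
        (a,) = anns
        assert (a.start, a.end) == (4, 28)
        assert text[a.start:a.end] == a.surface == "supraesophageal ganglion"
        assert a.status is Status.DISCOURAGED and a.suggestion == "brain"

    def test_case_folding_and_plural_table(self, lexicon):
        (a,) = annotate("GANGLIA", lexicon)
        assert a.resolved_label == "ganglion"
        assert a.status is Status.PREFERRED

    def test_empty_text_yields_no_annotations(self, lexicon):
        assert annotate("", lexicon) == []

    def test_multiword_surface_matches_across_a_line_break(self, lexicon):
        text = "a rope-ladder-like\nnervous system was found"
        anns = annotate(text, lexicon)
        assert anns[0].resolved_label == "rope-ladder-like nervous system"

    def test_no_match_inside_longer_words(self, lexicon):
        assert annotate("eyestalk preganglionic", lexicon) == []

    def test_offsets_are_faithful_on_bundled_prose(self, kb, lexicon):
        text = (
            "The central body is an unpaired midline neuropil of the central "
            "complex; cerebral ganglia and facetted eyes were described."
        )
        for a in annotate(text, lexicon):
            assert text[a.start:a.end] == a.surface

    def test_every_discouraged_synonym_resolves_to_its_owner(self, kb, lexicon):
        """100% coverage: each discouraged surface annotates as DISCOURAGED
        with the owning entry's label suggested.  Where two entries
        discourage the same surface, the documented precedence (lower
        entry id) applies."""
        claimants: dict[str, list] = {}
        for t in kb.terms:
            for syn in t.discouraged:
                claimants.setdefault(syn.lower(), []).append(t)
        assert claimants, "bundled corpus must carry discouraged terms"
        for surface, owners in claimants.items():
            anns = annotate(surface, lexicon)
            assert len(anns) == 1, surface
            (a,) = anns
            assert a.status is Status.DISCOURAGED, surface
            expected = min(owners, key=lambda t: t.entry_id)
            assert a.resolved_label == expected.label
            assert a.suggestion == expected.label
            assert a.entry_id == expected.entry_id


class TestRewrite:
    def test_replaces_discouraged_preserving_capitalization_and_plural(self, lexicon):
        new, log = rewrite("Facetted eyes are common.", lexicon)
        assert new == "Compound eyes are common."
        assert log == [(0, "Facetted eyes", "Compound eyes")]

    def test_text_without_hits_is_unchanged(self, lexicon):
        text = "No anatomical words here."
        assert rewrite(text, lexicon) == (text, [])

    def test_flag_only_keeps_text_and_reports(self, lexicon):
        text = "the supraesophageal ganglion"
        out, log = rewrite(text, lexicon, policy="flag_only")
        assert out == text
        assert log and log[0][1] == "supraesophageal ganglion"

    def test_rewritten_text_reannotates_clean(self, lexicon):
        text = "Apical ganglia and the Markstrang of the nerve net."
        new, _ = rewrite(text, lexicon)
        assert all(
            a.status is not Status.DISCOURAGED for a in annotate(new, lexicon)
        )

    def test_rewrite_is_idempotent(self, lexicon):
        text = "Sense organs with ocelli; nerve fibers of the nerve net."
        once, _ = rewrite(text, lexicon)
        twice, log = rewrite(once, lexicon)
        assert twice == once and log == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seed=st.integers(min_value=0, max_value=10_000),
        kb_seed=st.integers(min_value=0, max_value=500),
    )
    def test_fixed_point_property_on_generated_texts(self, seed, kb_seed):
        kb = fixtures.random_taxonomy(15, 0.2, kb_seed)
        lex = compile_lexicon(kb, plural_table={})
        text = fixtures.random_text(kb, seed)
        new, _ = rewrite(text, lex)
        assert all(a.status is not Status.DISCOURAGED for a in annotate(new, lex))
        again, log = rewrite(new, lex)
        assert again == new and log == []
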