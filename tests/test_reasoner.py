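"""Closure queries, inherited definitions and structural validation."""

import pytest
from hypothesis import given, settings, strategies as st

from neurogloss import fixtures, reasoner
from neurogloss.model import ParentKind, Quantifier, Severity
from neurogloss.reasoner import (
    ancestors,
    descendants,
    expanded_definition,
    part_closure,
    part_closure_edges,
    validate,
)

from .oracles import oracle_ancestors, oracle_descendants, oracle_part_closure


class TestAncestors:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("ommatidium", ["eye", "sensory organ", "cluster_of(cell)"]),
            ("commissure", ["neurite bundle", "cluster_of(neurite)"]),
            ("nervous system", ["cluster_of(neuron)"]),
            ("glial cell", ["cell"]),
        ],
    )
    def test_genus_chains_of_the_glossary(self, kb, label, expected):
        assert [str(ref) for ref in ancestors(kb, label)] == expected

    def test_unknown_label_raises(self, kb):
        with pytest.raises(KeyError):
            ancestors(kb, "spinal cord")

    def test_chain_always_ends_in_a_root(self, kb):
        for t in kb.terms:
            chain = ancestors(kb, t.label)
            assert chain[-1].kind is not ParentKind.MAIN_TERM
            assert all(ref.kind is ParentKind.MAIN_TERM for ref in chain[:-1])


class TestDescendants:
    def test_eye_subtypes(self, kb):
        assert descendants(kb, "eye") >= {
            "compound eye", "median eye", "nauplius eye", "ommatidium"
        }

    def test_unpaired_midline_neuropil_subtypes(self, kb):
        assert descendants(kb, "unpaired midline neuropil") >= {
            "arcuate body", "central body"
        }

    def test_leaf_term_has_no_descendants(self, kb):
        assert descendants(kb, "ommatidium") == set()

    def test_duality_with_ancestors_over_main_terms(self, kb):
        for x in kb.terms:
            for y in kb.terms:
                in_desc = y.label in descendants(kb, x.label)
                in_anc = any(
                    ref.kind is ParentKind.MAIN_TERM and ref.target == x.label
                    for ref in ancestors(kb, y.label)
                )
                assert in_desc == in_anc


class TestExpandedDefinition:
    def test_inherited_clauses_come_before_own_clauses(self, kb):
        pairs = expanded_definition(kb, "commissure")
        sources = [s for s, _ in pairs]
        assert sources.index("neurite bundle") < sources.index("commissure")
        clauses = dict(pairs[:2])
        assert "parallel" in clauses["neurite bundle"]
        assert any("transversely oriented" in c for s, c in pairs if s == "commissure")

    def test_root_child_expands_to_its_own_clauses_only(self, kb):
        pairs = expanded_definition(kb, "nervous system")
        assert {s for s, _ in pairs} == {"nervous system"}
        assert pairs == [
            ("nervous system", c) for c in kb.term("nervous system").differentia
        ]

    def test_source_count_matches_main_term_ancestry_for_all_terms(self, kb):
        for t in kb.terms:
            pairs = expanded_definition(kb, t.label)
            n_main = sum(
                1 for ref in ancestors(kb, t.label)
                if ref.kind is ParentKind.MAIN_TERM
            )
            assert len({s for s, _ in pairs}) == n_main + 1


class TestPartClosure:
    def test_central_body_wholes(self, kb):
        assert part_closure(kb, "central body") >= {
            ("central complex", Quantifier.EVERY),
            ("syncerebrum", Quantifier.SOME),
            ("brain", Quantifier.SOME),
            ("nervous system", Quantifier.SOME),
        }

    def test_top_level_whole_is_empty(self, kb):
        assert part_closure(kb, "nervous system") == set()

    def test_any_chain_with_a_some_link_is_some(self, kb):
        for t in kb.terms:
            for edge in part_closure_edges(kb, t.label):
                kinds = [
                    (pred, _edge_quantifier(kb, s, o))
                    for s, pred, o in edge.derivation
                ]
                if edge.quantifier is Quantifier.EVERY:
                    assert all(
                        pred == "part_of" and q is Quantifier.EVERY
                        for pred, q in kinds
                    )

    def test_derivations_replay_to_the_closure_edge(self, kb):
        for t in kb.terms:
            for edge in part_closure_edges(kb, t.label):
                assert edge.derivation[0][0] == edge.subject
                assert edge.derivation[-1][2] == edge.object
                for (_, _, obj), (nxt, _, _) in zip(
                    edge.derivation, edge.derivation[1:]
                ):
                    assert obj == nxt
                assert any(pred == "part_of" for _, pred, _ in edge.derivation)

    def test_matches_oracle_on_bundled_corpus(self, kb):
        for t in kb.terms:
            assert part_closure(kb, t.label) == oracle_part_closure(kb, t.label)
            assert [str(r) for r in ancestors(kb, t.label)] == oracle_ancestors(
                kb, t.label
            )
        for t in kb.terms:
            assert descendants(kb, t.label) == oracle_descendants(kb, t.label)


def _edge_quantifier(kb, subject, obj):
    t = kb.term(subject)
    for p in t.parts:
        if p.whole == obj:
            return p.quantifier
    return None


class TestClosureAgainstOracleOnRandomKbs:
    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=1, max_value=50),
        seed=st.integers(min_value=0, max_value=100_000),
    )
    def test_all_three_closures_match_the_oracle(self, n, seed):
        kb = fixtures.random_taxonomy(n, 0.3, seed)
        for t in kb.terms:
            assert part_closure(kb, t.label) == oracle_part_closure(kb, t.label)
            assert [str(r) for r in ancestors(kb, t.label)] == oracle_ancestors(
                kb, t.label
            )


class TestValidate:
    def test_bundled_corpus_passes_after_whitelist(self, kb, whitelist):
        report = validate(kb, whitelist)
        assert report.passed, report.render_text()

    def test_without_whitelist_the_nerve_conflict_surfaces(self, kb):
        report = validate(kb, whitelist=None)
        assert not report.passed
        assert {(f.rule, f.subject) for f in report.errors} == {("V8", "nerve")}

    def test_register_rule_v6_holds_for_every_main_entry(self, kb, whitelist):
        report = validate(kb, whitelist)
        assert not report.by_rule("V6")

    def test_synthetic_cycle_reports_v4_with_both_labels(self):
        base = fixtures.random_taxonomy(10, 0.2, seed=3)
        broken = fixtures.mutate_invalid(base, "cycle", seed=1)
        report = validate(broken, whitelist=None)
        v4 = [f for f in report.errors if f.rule == "V4"]
        assert len(v4) == 1
        assert v4[0].message.count("->") >= 2

    def test_validation_is_deterministic(self, kb, whitelist):
        a = validate(kb, whitelist)
        b = validate(kb, whitelist)
        assert a == b

    def test_report_renders_as_tsv_rows(self, kb):
        report = validate(kb, whitelist=None)
        lines = report.render_tsv().strip().splitlines()
        assert lines[0].split("\t") == ["rule", "severity", "subject", "message"]
        assert all(len(line.split("\t")) == 4 for line in lines[1:])


class TestMutants:
    def test_dangling_ref_adds_exactly_one_new_error(self):
        base = fixtures.random_taxonomy(12, 0.2, seed=5)
        before = {f for f in validate(base).findings if f.severity is Severity.ERROR}
        broken = fixtures.mutate_invalid(base, "dangling_ref", seed=2)
        after = {f for f in validate(broken).findings if f.severity is Severity.ERROR}
        new = after - before
        assert len(new) == 1
        assert next(iter(new)).rule in ("V3", "V5")

    def test_bad_register_triggers_v6(self):
        base = fixtures.random_taxonomy(8, 0.2, seed=9)
        broken = fixtures.mutate_invalid(base, "bad_register", seed=4)
        report = validate(broken)
        assert any(f.rule == "V6" for f in report.errors)

    def test_dup_label_triggers_duplicate_finding(self):
        base = fixtures.random_taxonomy(8, 0.2, seed=9)
        broken = fixtures.mutate_invalid(base, "dup_label", seed=4)
        report = validate(broken)
        assert any(f.rule == "dup_label" for f in report.errors)
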