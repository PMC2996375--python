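"""Closure queries, inherited-definition expansion and structural validation.

The taxonomy is a single-inheritance forest: every main entry has exactly
one genus, which is another main entry, one of the four primitive roots,
or a ``cluster of X`` node.  Defining properties are inherited downward,
so the expanded definition of a term concatenates the differentia of all
its main-term ancestors.

Part-whole closure composes the quantified ``part_of`` statements with
the is_a hierarchy:

* ``A part_of W`` and ``W part_of V``  =>  ``A part_of V``
* ``A part_of W`` and ``W is_a V``     =>  ``A part_of V``
* ``A is_a B``    and ``B part_of W``  =>  ``A part_of W``

A composed statement keeps the EVERY quantifier only when the whole chain
consists of EVERY-quantified part links; any SOME link or any is_a step
downgrades it to SOME, because subclasses and superclasses inherit only
the all-some reading of parthood, not the reciprocal "every whole has
such a part".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .model import (
    Finding,
    KnowledgeBase,
    ParentKind,
    ParentRef,
    Quantifier,
    Severity,
    ValidationReport,
    normalize_label,
)

__all__ = [
    "ClosureEdge",
    "ancestors",
    "descendants",
    "expanded_definition",
    "part_closure",
    "part_closure_edges",
    "validate",
]


@dataclass(frozen=True)
class ClosureEdge:
    """A derived statement together with the corpus edges it was composed
    from.  ``derivation`` lists (subject, predicate, object) triples in
    order; replaying them under the composition table reproduces
    (subject, object, quantifier)."""

    subject: str
    predicate: str  # "is_a" | "part_of"
    quantifier: Optional[Quantifier]
    object: str
    derivation: tuple[tuple[str, str, str], ...]


def _require_term(kb: KnowledgeBase, label: str) -> str:
    label = normalize_label(label)
    if not kb.has_term(label):
        raise KeyError(f"unknown main term {label!r}")
    return label


def ancestors(kb: KnowledgeBase, label: str) -> list[ParentRef]:
    """Genus chain from the term up to a primitive or cluster root,
    nearest parent first."""
    label = _require_term(kb, label)
    chain: list[ParentRef] = []
    current = kb.term(label)
    while True:
        ref = current.genus
        chain.append(ref)
        if ref.kind is not ParentKind.MAIN_TERM:
            return chain
        current = kb.term(ref.target)


def descendants(kb: KnowledgeBase, label: str) -> set[str]:
    """All main terms whose ancestor chain contains ``label``.

    ``label`` may be a main term or a primitive root; cluster roots are
    addressed through :func:`ancestors`."""
    label = normalize_label(label)
    if not kb.has_term(label) and label not in kb.primitives:
        raise KeyError(f"unknown label {label!r}")
    out: set[str] = set()
    for t in kb.terms:
        for ref in ancestors(kb, t.label):
            if ref.kind is not ParentKind.CLUSTER_OF and ref.target == label:
                out.add(t.label)
                break
    return out


def expanded_definition(kb: KnowledgeBase, label: str) -> list[tuple[str, str]]:
    """Differentia clauses inherited downward: clauses of the root-most
    main-term ancestor first, the term's own clauses last, each tagged
    with its source label."""
    label = _require_term(kb, label)
    chain = [ref.target for ref in ancestors(kb, label) if ref.kind is ParentKind.MAIN_TERM]
    out: list[tuple[str, str]] = []
    for source in reversed(chain):
        out.extend((source, clause) for clause in kb.term(source).differentia)
    out.extend((label, clause) for clause in kb.term(label).differentia)
    return out


def _closure_graph(kb: KnowledgeBase) -> nx.MultiDiGraph:
    """Edges: is_a between main terms, and quantified part_of."""
    g = nx.MultiDiGraph()
    for t in kb.terms:
        g.add_node(t.label)
        if t.genus.kind is ParentKind.MAIN_TERM:
            g.add_edge(t.label, t.genus.target, predicate="is_a", quantifier=None)
        for p in t.parts:
            g.add_edge(t.label, p.whole, predicate="part_of", quantifier=p.quantifier)
    return g


def part_closure_edges(kb: KnowledgeBase, label: str) -> list[ClosureEdge]:
    """Transitive part-whole statements for ``label`` with derivations."""
    label = _require_term(kb, label)
    g = _closure_graph(kb)

    # state: (node, all links so far are part_of-EVERY); track whether a
    # part edge has been used -- pure is_a chains are not parthood.
    best: dict[str, Quantifier] = {}
    derivations: dict[str, tuple[tuple[str, str, str], ...]] = {}
    seen: set[tuple[str, bool, bool]] = set()
    frontier: list[tuple[str, bool, bool, tuple[tuple[str, str, str], ...]]] = [
        (label, False, True, ())
    ]
    while frontier:
        node, part_used, all_every, path = frontier.pop(0)
        state = (node, part_used, all_every)
        if state in seen:
            continue
        seen.add(state)
        if part_used:
            quant = Quantifier.EVERY if all_every else Quantifier.SOME
            prev = best.get(node)
            if prev is None or (prev is Quantifier.SOME and quant is Quantifier.EVERY):
                best[node] = quant
                derivations[node] = path
        if node not in g:
            continue
        for _, target, data in g.out_edges(node, data=True):
            step = (node, data["predicate"], target)
            if data["predicate"] == "part_of":
                every = all_every and data["quantifier"] is Quantifier.EVERY
                frontier.append((target, True, every, path + (step,)))
            else:
                frontier.append((target, part_used, False, path + (step,)))
    return [
        ClosureEdge(
            subject=label,
            predicate="part_of",
            quantifier=best[node],
            object=node,
            derivation=derivations[node],
        )
        for node in sorted(best)
    ]


def part_closure(kb: KnowledgeBase, label: str) -> set[tuple[str, Quantifier]]:
    """Transitive wholes of ``label`` as (whole label, quantifier) pairs."""
    return {(e.object, e.quantifier) for e in part_closure_edges(kb, label)}


# ---------------------------------------------------------------------------
# validation


def validate(
    kb: KnowledgeBase,
    whitelist: Optional[dict[tuple[str, str], str]] = None,
) -> ValidationReport:
    """Evaluate structural rules V1-V8 and return a report.

    Findings whose (rule, subject) pair appears in ``whitelist`` are
    downgraded to WARNING with the whitelist reason appended; ``passed``
    is true iff no ERROR finding remains.
    """
    findings: list[Finding] = []

    def err(rule: str, subject: str, message: str) -> None:
        findings.append(Finding(rule, Severity.ERROR, subject, message))

    def warn(rule: str, subject: str, message: str) -> None:
        findings.append(Finding(rule, Severity.WARNING, subject, message))

    # V1: contiguous ids
    ids = sorted(t.entry_id for t in kb.terms)
    if ids != list(range(1, len(ids) + 1)):
        err("V1", "corpus", f"entry ids not contiguous 1..{len(ids)}: {ids}")

    labels = kb.all_labels
    term_labels = kb.term_labels

    # duplicate labels across terms/sides/primitives
    all_list = (
        [t.label for t in kb.terms]
        + [s.label for s in kb.sides]
        + sorted(kb.primitives)
    )
    seen: set[str] = set()
    for label in all_list:
        if label in seen:
            err("dup_label", label, "label used by more than one entry")
        seen.add(label)

    for t in kb.terms:
        # V2: exactly one genus -- structurally guaranteed, but reject the
        # degenerate empty target.
        if not t.genus.target:
            err("V2", t.label, "entry without a genus")
        # V3: parent references (genus and part wholes) resolve
        ref = t.genus
        if ref.kind is ParentKind.MAIN_TERM and ref.target not in term_labels:
            err("V3", t.label, f"genus {ref.target!r} does not resolve")
        if ref.kind is ParentKind.PRIMITIVE and ref.target not in kb.primitives:
            err("V3", t.label, f"primitive parent {ref.target!r} unknown")
        if ref.kind is ParentKind.CLUSTER_OF and not (
            ref.target in term_labels or ref.target in kb.primitives
        ):
            err("V3", t.label, f"cluster member {ref.target!r} does not resolve")
        for p in t.parts:
            if p.whole not in term_labels:
                err("V3", t.label, f"part-of whole {p.whole!r} does not resolve")
        # V5: definition cross-references resolve
        for x in sorted(t.def_xrefs):
            if x not in labels:
                err("V5", t.label, f"definition xref {x!r} does not resolve")
        # V8: discouraged synonyms must not be main-term labels
        for syn in t.discouraged:
            if normalize_label(syn) == t.label:
                err("V8", t.label, f"discouraged synonym equals the entry's own label")
            elif normalize_label(syn) in term_labels:
                err(
                    "V8",
                    normalize_label(syn),
                    f"discouraged synonym of {t.label!r} is itself a main-term label",
                )

    # V4: acyclicity of the is_a graph (DFS with cycle extraction)
    g = nx.DiGraph()
    for t in kb.terms:
        if t.genus.kind is ParentKind.MAIN_TERM and t.genus.target in term_labels:
            g.add_edge(t.label, t.genus.target)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        cycle = []
    if cycle:
        path = " -> ".join([u for u, _ in cycle] + [cycle[0][0]])
        err("V4", cycle[0][0], f"is_a cycle: {path}")

    # V6: each main term's register row carries its own id as defining entry
    for t in kb.terms:
        row = kb.register_row(t.label)
        if row is None:
            err("V6", t.label, "main term has no register row")
        elif row.defining_entry != t.entry_id or t.entry_id not in row.entries:
            err(
                "V6",
                t.label,
                f"register row defines entry {row.defining_entry}, "
                f"expected {t.entry_id}",
            )

    # V7 (warning): a definition xref from entry N to term T should be
    # reflected in T's register row containing N
    for t in kb.terms:
        for x in sorted(t.def_xrefs):
            row = kb.register_row(x)
            if row is None:
                warn("V7", x, f"xref target of entry {{{t.entry_id}}} has no register row")
            elif t.entry_id not in row.entries:
                warn(
                    "V7",
                    x,
                    f"register row does not list entry {{{t.entry_id}}}, "
                    f"whose definition references it",
                )

    return apply_whitelist(ValidationReport(tuple(findings)), whitelist)


def apply_whitelist(
    report: ValidationReport,
    whitelist: Optional[dict[tuple[str, str], str]],
) -> ValidationReport:
    """Downgrade whitelisted ERROR findings to WARNING, keeping the trace."""
    if not whitelist:
        return report
    out: list[Finding] = []
    for f in report.findings:
        reason = whitelist.get((f.rule, f.subject))
        if reason is not None and f.severity is Severity.ERROR:
            out.append(
                Finding(
                    f.rule,
                    Severity.WARNING,
                    f.subject,
                    f"{f.message} [whitelisted: {reason}]",
                )
            )
        else:
            out.append(f)
    return ValidationReport(tuple(out))
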