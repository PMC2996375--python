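"""Brute-force closure oracles for property tests.

Deliberately naive O(paths) implementations that enumerate every simple
edge path and apply the composition table step by step.  They live in
the test tree only and are never imported by the library, so they stay
an independent check on the reasoner's closures.
"""

from __future__ import annotations

from neurogloss.model import KnowledgeBase, ParentKind, Quantifier


def _edges(kb: KnowledgeBase) -> list[tuple[str, str, str, Quantifier | None]]:
    """(subject, predicate, object, quantifier) corpus edges over main terms."""
    out = []
    for t in kb.terms:
        if t.genus.kind is ParentKind.MAIN_TERM:
            out.append((t.label, "is_a", t.genus.target, None))
        for p in t.parts:
            out.append((t.label, "part_of", p.whole, p.quantifier))
    return out


def oracle_ancestors(kb: KnowledgeBase, label: str) -> list[str]:
    """Main-term ancestor labels, nearest first, by repeated single-step
    lookup in the raw edge list (plus the final non-main parent)."""
    edges = _edges(kb)
    chain: list[str] = []
    current = label
    while True:
        nexts = [o for s, p, o, _ in edges if s == current and p == "is_a"]
        if not nexts:
            t = kb.term(current)
            chain.append(str(t.genus))
            return chain
        (current,) = nexts
        chain.append(current)


def oracle_descendants(kb: KnowledgeBase, label: str) -> set[str]:
    return {
        t.label
        for t in kb.terms
        if label in oracle_ancestors(kb, t.label)
    }


def oracle_part_closure(kb: KnowledgeBase, label: str) -> set[tuple[str, Quantifier]]:
    """Enumerate all simple paths from ``label``; a path asserts parthood
    iff it uses at least one part_of edge; the quantifier stays EVERY only
    when the path consists purely of EVERY part links."""
    edges = _edges(kb)
    best: dict[str, Quantifier] = {}

    def walk(node: str, visited: tuple[str, ...], used_part: bool, pure_every: bool):
        for s, p, o, q in edges:
            if s != node or o in visited:
                continue
            part = used_part or p == "part_of"
            every = pure_every and p == "part_of" and q is Quantifier.EVERY
            if part:
                quant = Quantifier.EVERY if every else Quantifier.SOME
                prev = best.get(o)
                if prev is None or (
                    prev is Quantifier.SOME and quant is Quantifier.EVERY
                ):
                    best[o] = quant
            walk(o, visited + (o,), part, every)

    walk(label, (label,), False, True)
    return set(best.items())
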