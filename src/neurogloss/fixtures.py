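"""Random knowledge bases and defect injection for property testing.

:func:`random_taxonomy` draws a single-genus forest rooted in synthetic
primitives, optionally decorated with quantified part-of edges,
definition cross-references, discouraged synonyms and side entries, and
always passes structural validation.  :func:`mutate_invalid` injects one
named defect so that the validator's rules can be exercised one at a
time.  The brute-force closure oracle lives in the test tree, not here,
so that the library can never accidentally depend on it.
"""

from __future__ import annotations

import random
from dataclasses import replace

from .model import (
    KnowledgeBase,
    ParentKind,
    ParentRef,
    PartStatement,
    Provenance,
    Quantifier,
    RegisterRow,
    SideEntry,
    TermEntry,
)

__all__ = ["random_taxonomy", "mutate_invalid", "random_text"]

_SYNTH_PRIMITIVES = ("unit", "stuff")


def random_taxonomy(n_terms: int, p_part: float, seed: int) -> KnowledgeBase:
    """Generate a valid random knowledge base with ``n_terms`` main terms.

    Deterministic in (n_terms, p_part, seed).  Genus parents are drawn
    from earlier terms, the synthetic primitive roots, or cluster-of
    nodes over either; each term gains a part-of edge with probability
    ``p_part`` toward an earlier (hence never descendant) term, EVERY
    with probability one half.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if not 0 <= p_part <= 1:
        raise ValueError("p_part must be in [0, 1]")
    rng = random.Random(seed)
    labels = [f"term {i:02d}" for i in range(1, n_terms + 1)]
    terms: list[TermEntry] = []
    for i, label in enumerate(labels):
        roll = rng.random()
        if i == 0 or roll < 0.25:
            genus = ParentRef(ParentKind.PRIMITIVE, rng.choice(_SYNTH_PRIMITIVES))
        elif roll < 0.45:
            member = rng.choice(list(_SYNTH_PRIMITIVES) + labels[:i])
            genus = ParentRef(ParentKind.CLUSTER_OF, member)
        else:
            genus = ParentRef(ParentKind.MAIN_TERM, rng.choice(labels[:i]))
        parts: tuple[PartStatement, ...] = ()
        if i > 0 and rng.random() < p_part:
            whole = rng.choice(labels[:i])
            quant = Quantifier.EVERY if rng.random() < 0.5 else Quantifier.SOME
            parts = (PartStatement(whole, quant),)
        xrefs = frozenset(
            lbl for lbl in labels[:i] if rng.random() < 0.1
        )
        discouraged: tuple[str, ...] = ()
        if rng.random() < 0.2:
            discouraged = (f"old {label}",)
        terms.append(
            TermEntry(
                entry_id=i + 1,
                label=label,
                genus=genus,
                parts=parts,
                differentia=(f"Synthetic clause for {label}.",),
                discouraged=discouraged,
                def_xrefs=xrefs,
            )
        )
    sides = tuple(
        SideEntry(label=f"side {i}")
        for i in range(1, rng.randint(0, 3) + 1)
    )
    register = _register_from_xrefs(terms, sides)
    return KnowledgeBase.create(
        terms=terms,
        sides=sides,
        primitives=frozenset(_SYNTH_PRIMITIVES),
        register=register,
        provenance=Provenance(version="fixture", checksum=f"seed:{seed}"),
    )


def _register_from_xrefs(
    terms: list[TermEntry], sides: tuple[SideEntry, ...]
) -> tuple[RegisterRow, ...]:
    rows: dict[str, set[int]] = {t.label: {t.entry_id} for t in terms}
    for s in sides:
        rows[s.label] = set()
    for t in terms:
        for x in t.def_xrefs:
            rows.setdefault(x, set()).add(t.entry_id)
    defining = {t.label: t.entry_id for t in terms}
    return tuple(
        RegisterRow(label, frozenset(entries), defining.get(label))
        for label, entries in sorted(rows.items())
    )


def mutate_invalid(kb: KnowledgeBase, violation: str, seed: int) -> KnowledgeBase:
    """Return a copy of ``kb`` with exactly the requested defect injected.

    ``violation`` is one of cycle, dangling_ref, dup_label, bad_register.
    Raises ValueError when the defect cannot be injected (e.g. a cycle
    needs a main-term genus chain of length two).
    """
    rng = random.Random(seed)
    terms = list(kb.terms)
    if violation == "cycle":
        chains = [
            t for t in terms if t.genus.kind is ParentKind.MAIN_TERM
        ]
        if not chains:
            raise ValueError("cycle not injectable: no main-term genus edge")
        child = rng.choice(chains)
        parent = kb.term(child.genus.target)
        terms[terms.index(parent)] = replace(
            parent, genus=ParentRef(ParentKind.MAIN_TERM, child.label)
        )
    elif violation == "dangling_ref":
        victim = rng.choice(terms)
        terms[terms.index(victim)] = replace(
            victim, def_xrefs=victim.def_xrefs | {"no such label"}
        )
    elif violation == "dup_label":
        if len(terms) < 2:
            raise ValueError("dup_label not injectable on a 1-term kb")
        a, b = rng.sample(terms, 2)
        terms[terms.index(b)] = replace(b, label=a.label)
    elif violation == "bad_register":
        victim = rng.choice(terms)
        register = tuple(
            replace(row, defining_entry=None, entries=row.entries - {victim.entry_id})
            if row.label == victim.label
            else row
            for row in kb.register
        )
        return replace(kb, register=register)
    else:
        raise ValueError(f"unknown violation {violation!r}")
    return replace(kb, terms=tuple(terms))


_FILLER = (
    "the", "a", "of", "in", "within", "anterior", "posterior", "larval",
    "adult", "paired", "unpaired", "ventral", "dorsal", "prominent",
    "was", "described", "observed", "stained", "section", "specimen",
)


def random_text(kb: KnowledgeBase, seed: int, n_sentences: int = 5) -> str:
    """Compose synthetic prose that mixes filler words with preferred,
    side and discouraged surfaces from ``kb`` -- input for annotator
    round-trip properties."""
    rng = random.Random(seed)
    surfaces: list[str] = [t.label for t in kb.terms]
    surfaces += [s.label for s in kb.sides]
    for t in kb.terms:
        surfaces.extend(t.discouraged)
    sentences = []
    for _ in range(n_sentences):
        words: list[str] = []
        for _ in range(rng.randint(3, 9)):
            if surfaces and rng.random() < 0.4:
                words.append(rng.choice(surfaces))
            else:
                words.append(rng.choice(_FILLER))
        sentence = " ".join(words)
        sentences.append(sentence[:1].upper() + sentence[1:] + ".")
    return " ".join(sentences)
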