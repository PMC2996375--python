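"""Domain types for the invertebrate-neuroanatomy glossary ontology.

The glossary consists of 47 numbered main entries, each carrying an
Aristotelian definition: a *genus* (the parent type) and a *differentia*
(the prose clauses that distinguish the term from its siblings).  Beside
the class-subclass (is_a) hierarchy, entries assert quantified part-whole
statements: "part of the X" means the part is mandatory in every instance
of the whole, "part of a X" means the part sits in some instance of the
whole.  Terms used in the glossary without a definition of their own are
*side entries*; terms the glossary recommends abandoning are *discouraged*
synonyms of the entry that supersedes them.

This module holds the in-memory containers only; parsing lives in
:mod:`neurogloss.corpus`, reasoning in :mod:`neurogloss.reasoner`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional


class Quantifier(Enum):
    """Quantifier of a part-whole statement.

    SOME: every instance of the part is part of some instance of the whole
    (the standard all-some reading of ``part_of``).  EVERY additionally
    asserts the reciprocal: every instance of the whole has such a part.
    """

    SOME = "some"
    EVERY = "every"


class ParentKind(Enum):
    MAIN_TERM = "main_term"
    PRIMITIVE = "primitive"
    CLUSTER_OF = "cluster_of"


class Status(Enum):
    """Annotation status of a surface form."""

    PREFERRED = "PREFERRED"
    SIDE = "SIDE"
    DISCOURAGED = "DISCOURAGED"


class Severity(Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"
    INFO = "INFO"


#: The four parent phrases of the taxonomy that are not themselves defined
#: entries.  Together with the ``cluster of X`` nodes they are the roots of
#: the is_a hierarchy.
PRIMITIVE_ROOTS = frozenset(
    {"cell", "molecule", "cell process", "cell-to-cell junction"}
)

_WS = re.compile(r"\s+")


def normalize_label(text: str) -> str:
    """Normalize a label: lowercase, single internal spaces, stripped."""
    return _WS.sub(" ", text.strip()).lower()


@dataclass(frozen=True)
class ParentRef:
    """Reference to the genus of an entry.

    ``target`` is the parent label for MAIN_TERM/PRIMITIVE kinds, or the
    member label for CLUSTER_OF (e.g. ``cluster_of(neuron)`` for "a brain
    is a cluster of neurons").
    """

    kind: ParentKind
    target: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        if self.kind is ParentKind.CLUSTER_OF:
            return f"cluster_of({self.target})"
        return self.target


@dataclass(frozen=True)
class PartStatement:
    """A quantified part-whole assertion: the defined term is part of
    SOME / EVERY instance of ``whole``."""

    whole: str
    quantifier: Quantifier


@dataclass(frozen=True)
class TermEntry:
    """One numbered main entry of the glossary."""

    entry_id: int
    label: str
    genus: ParentRef
    parts: tuple[PartStatement, ...] = ()
    differentia: tuple[str, ...] = ()
    discouraged: tuple[str, ...] = ()
    def_xrefs: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SideEntry:
    """A bold term used in the glossary without a definition of its own."""

    label: str
    note: Optional[str] = None
    owner: Optional[int] = None


@dataclass(frozen=True)
class RegisterRow:
    """One row of the term register: a label mapped to the set of entry
    numbers under which it is used; for a main entry the bold (defining)
    number is its own entry id."""

    label: str
    entries: frozenset[int]
    defining_entry: Optional[int] = None


@dataclass(frozen=True)
class Finding:
    rule: str
    severity: Severity
    subject: str
    message: str

    def as_tsv_row(self) -> str:
        return "\t".join((self.rule, self.severity.value, self.subject, self.message))


@dataclass(frozen=True)
class ValidationReport:
    """Result of structural validation or register reconciliation.

    ``passed`` is true iff no ERROR-severity finding remains (whitelisted
    findings are downgraded before the report is built).
    """

    findings: tuple[Finding, ...]

    @property
    def passed(self) -> bool:
        return not self.errors

    @property
    def errors(self) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.severity is Severity.ERROR)

    def by_rule(self, rule: str) -> tuple[Finding, ...]:
        return tuple(f for f in self.findings if f.rule == rule)

    def render_text(self) -> str:
        if not self.findings:
            return "no findings\n"
        return "".join(
            f"{f.severity.value:7s} {f.rule:4s} {f.subject}: {f.message}\n"
            for f in self.findings
        )

    def render_tsv(self) -> str:
        header = "rule\tseverity\tsubject\tmessage\n"
        return header + "".join(f.as_tsv_row() + "\n" for f in self.findings)


DiffReport = ValidationReport


@dataclass(frozen=True)
class Annotation:
    """A matched glossary surface in free text.

    Offsets are 0-based half-open character offsets into the annotated
    text; ``surface`` equals ``text[start:end]``.
    """

    start: int
    end: int
    surface: str
    resolved_label: str
    entry_id: Optional[int]
    status: Status
    suggestion: Optional[str] = None


@dataclass(frozen=True)
class Provenance:
    version: str = ""
    checksum: str = ""


class KnowledgeBaseError(ValueError):
    """A hard structural violation, named after the validation rule."""

    def __init__(self, rule: str, message: str):
        self.rule = rule
        super().__init__(f"{rule}: {message}")


@dataclass(frozen=True)
class KnowledgeBase:
    """Validated collection of main entries, side entries, primitive roots
    and register rows.

    Provenance is carried for reporting but excluded from equality so that
    a knowledge base compares equal to its round-tripped self.
    """

    terms: tuple[TermEntry, ...] = ()
    sides: tuple[SideEntry, ...] = ()
    primitives: frozenset[str] = PRIMITIVE_ROOTS
    register: tuple[RegisterRow, ...] = ()
    provenance: Provenance = field(default=Provenance(), compare=False)

    # -- constructors -------------------------------------------------

    @classmethod
    def create(
        cls,
        terms: Iterable[TermEntry],
        sides: Iterable[SideEntry] = (),
        primitives: Iterable[str] = PRIMITIVE_ROOTS,
        register: Iterable[RegisterRow] = (),
        provenance: Provenance = Provenance(),
    ) -> "KnowledgeBase":
        """Build a knowledge base, rejecting hard structural violations.

        Raises :class:`KnowledgeBaseError` naming the violated rule for a
        non-contiguous id range (V1), an unresolvable parent reference
        (V3), an is_a cycle (V4) or a duplicate label.
        """
        kb = cls(
            terms=tuple(sorted(terms, key=lambda t: t.entry_id)),
            sides=tuple(sorted(sides, key=lambda s: s.label)),
            primitives=frozenset(primitives),
            register=tuple(register),
            provenance=provenance,
        )
        kb.check()
        return kb

    # -- lookups ------------------------------------------------------

    @property
    def term_labels(self) -> frozenset[str]:
        return frozenset(t.label for t in self.terms)

    @property
    def all_labels(self) -> frozenset[str]:
        return (
            self.term_labels
            | frozenset(s.label for s in self.sides)
            | self.primitives
        )

    def term(self, label: str) -> TermEntry:
        label = normalize_label(label)
        for t in self.terms:
            if t.label == label:
                return t
        raise KeyError(label)

    def term_by_id(self, entry_id: int) -> TermEntry:
        for t in self.terms:
            if t.entry_id == entry_id:
                return t
        raise KeyError(entry_id)

    def has_term(self, label: str) -> bool:
        return normalize_label(label) in self.term_labels

    def register_row(self, label: str) -> Optional[RegisterRow]:
        label = normalize_label(label)
        for row in self.register:
            if row.label == label:
                return row
        return None

    def without_register(self) -> "KnowledgeBase":
        return replace(self, register=())

    # -- hard invariants ----------------------------------------------

    def check(self) -> None:
        """Raise :class:`KnowledgeBaseError` on a hard structural defect."""
        ids = sorted(t.entry_id for t in self.terms)
        if ids != list(range(1, len(ids) + 1)):
            raise KnowledgeBaseError(
                "V1", f"entry ids not contiguous 1..{len(ids)}: {ids}"
            )
        seen: set[str] = set()
        for label in (
            [t.label for t in self.terms]
            + [s.label for s in self.sides]
            + sorted(self.primitives)
        ):
            if label in seen:
                raise KnowledgeBaseError("dup_label", f"duplicate label {label!r}")
            if not label:
                raise KnowledgeBaseError("dup_label", "empty label")
            seen.add(label)
        for t in self.terms:
            self._check_parent_ref(t)
        self._check_acyclic()

    def _check_parent_ref(self, t: TermEntry) -> None:
        ref = t.genus
        if ref.kind is ParentKind.CLUSTER_OF:
            if not (self.has_term(ref.target) or ref.target in self.primitives):
                raise KnowledgeBaseError(
                    "V3",
                    f"cluster member {ref.target!r} of {t.label!r} does not "
                    f"resolve to a main term or primitive",
                )
        elif ref.kind is ParentKind.PRIMITIVE:
            if ref.target not in self.primitives:
                raise KnowledgeBaseError(
                    "V3", f"primitive parent {ref.target!r} of {t.label!r} unknown"
                )
        else:
            if not self.has_term(ref.target):
                raise KnowledgeBaseError(
                    "V3", f"genus {ref.target!r} of {t.label!r} does not resolve"
                )

    def _check_acyclic(self) -> None:
        # DFS over main-term genus edges with explicit cycle extraction.
        color: dict[str, int] = {}
        stack: list[str] = []

        def visit(label: str) -> None:
            color[label] = 1
            stack.append(label)
            try:
                t = self.term(label)
            except KeyError:
                stack.pop()
                color[label] = 2
                return
            if t.genus.kind is ParentKind.MAIN_TERM:
                parent = t.genus.target
                state = color.get(parent, 0)
                if state == 1:
                    cycle = stack[stack.index(parent):] + [parent]
                    raise KnowledgeBaseError(
                        "V4", "is_a cycle: " + " -> ".join(cycle)
                    )
                if state == 0:
                    visit(parent)
            stack.pop()
            color[label] = 2

        for t in self.terms:
            if color.get(t.label, 0) == 0:
                visit(t.label)
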