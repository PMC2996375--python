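"""Build the term -> entries inverted index and reconcile it with the
transcribed register table.

The printed register indexes every use of a term across whole entries,
including the free-prose background sections; the corpus encodes only the
cross-references of the formal definition blocks.  The expected relation
is therefore *printed row superset of computed row*: a computed reference
missing from the printed row is an error (an indexing omission), while a
printed entry absent from the computed row is informational
(background-only usage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .model import (
    Finding,
    KnowledgeBase,
    RegisterRow,
    Severity,
    ValidationReport,
    normalize_label,
)
from .reasoner import apply_whitelist

__all__ = ["ComputedRegister", "build_register", "reconcile_register", "register_tsv"]


@dataclass(frozen=True)
class ComputedRegister:
    """Label -> entry-id rows derived from the definition blocks."""

    rows: tuple[RegisterRow, ...]

    def row(self, label: str) -> Optional[RegisterRow]:
        label = normalize_label(label)
        for r in self.rows:
            if r.label == label:
                return r
        return None

    def as_register(self) -> tuple[RegisterRow, ...]:
        return self.rows


def build_register(kb: KnowledgeBase) -> ComputedRegister:
    """For each label L: {entry id of L if L is a main term} union
    {N : L appears in the definition xrefs of entry N}."""
    rows: dict[str, set[int]] = {}
    defining: dict[str, int] = {}
    for t in kb.terms:
        rows.setdefault(t.label, set()).add(t.entry_id)
        defining[t.label] = t.entry_id
        for x in t.def_xrefs:
            rows.setdefault(x, set()).add(t.entry_id)
    for s in kb.sides:
        rows.setdefault(s.label, set())
    return ComputedRegister(
        tuple(
            RegisterRow(label, frozenset(entries), defining.get(label))
            for label, entries in sorted(rows.items())
        )
    )


def reconcile_register(
    computed: ComputedRegister,
    printed: tuple[RegisterRow, ...],
    whitelist: Optional[dict[tuple[str, str], str]] = None,
) -> ValidationReport:
    """Diff the computed register against the transcribed table.

    Rules: R1 (ERROR) a definition-level reference is absent from the
    printed row (or the printed row is missing entirely); R2 (ERROR) the
    defining entries disagree; R3 (INFO) a printed entry has no
    definition-level counterpart, i.e. background-only usage.
    """
    findings: list[Finding] = []
    printed_by_label = {row.label: row for row in printed}

    for row in computed.rows:
        p = printed_by_label.get(row.label)
        if p is None:
            if row.entries:
                findings.append(
                    Finding(
                        "R1",
                        Severity.ERROR,
                        row.label,
                        f"no printed register row, but definition references "
                        f"exist in entries {sorted(row.entries)}",
                    )
                )
            continue
        missing = row.entries - p.entries
        if missing:
            findings.append(
                Finding(
                    "R1",
                    Severity.ERROR,
                    row.label,
                    f"definition references {sorted(missing)} absent from the "
                    f"printed row {sorted(p.entries)}",
                )
            )
        if row.defining_entry is not None and p.defining_entry != row.defining_entry:
            findings.append(
                Finding(
                    "R2",
                    Severity.ERROR,
                    row.label,
                    f"printed defining entry {p.defining_entry} differs from "
                    f"computed {row.defining_entry}",
                )
            )
        extra = p.entries - row.entries
        if extra:
            findings.append(
                Finding(
                    "R3",
                    Severity.INFO,
                    row.label,
                    f"printed entries {sorted(extra)} have no definition-level "
                    f"reference (background usage)",
                )
            )
    for row in printed:
        if computed.row(row.label) is None and row.entries:
            findings.append(
                Finding(
                    "R3",
                    Severity.INFO,
                    row.label,
                    f"printed-only row {sorted(row.entries)} (background usage)",
                )
            )
    return apply_whitelist(ValidationReport(tuple(findings)), whitelist)


def register_tsv(rows: tuple[RegisterRow, ...]) -> str:
    """Render register rows as TSV: label, sorted entry list, defining flag."""
    out = ["label\tentries\tdefining"]
    for row in sorted(rows, key=lambda r: r.label):
        entries = ",".join(str(e) for e in sorted(row.entries))
        defining = "" if row.defining_entry is None else str(row.defining_entry)
        out.append(f"{row.label}\t{entries}\t{defining}")
    return "\n".join(out) + "\n"
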