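"""Dictionary-based tagging of glossary terminology in free text.

The lexicon maps every surface form the glossary sanctions or condemns --
preferred main-entry labels, side-entry labels, discouraged synonyms, and
plural variants from a bundled table -- to a resolved label and status.
Matching is case-insensitive, word-boundary anchored and
leftmost-longest; there is deliberately no stemming or fuzzy matching,
because in anatomical text a false positive is costlier than a miss and
the glossary supplies exact forms.

Precedence on surface collisions: DISCOURAGED beats PREFERRED beats
SIDE -- if the glossary explicitly condemns a usage, the annotator flags
it even where the same string occurs as a label elsewhere.  Among two
entries that both discourage the same surface, the lower entry id wins.
All collisions are recorded on the lexicon, never raised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from .model import Annotation, KnowledgeBase, Status, normalize_label

__all__ = ["Lexicon", "LexiconEntry", "compile_lexicon", "annotate", "rewrite", "load_plural_table"]

_STATUS_RANK = {Status.DISCOURAGED: 0, Status.PREFERRED: 1, Status.SIDE: 2}


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    resolved_label: str
    entry_id: Optional[int]
    status: Status
    suggestion: Optional[str] = None
    plural: bool = False


@dataclass
class Lexicon:
    entries: dict[str, LexiconEntry] = field(default_factory=dict)
    collisions: list[str] = field(default_factory=list)
    plural_table: dict[str, str] = field(default_factory=dict)
    _pattern: Optional[re.Pattern] = field(default=None, repr=False, compare=False)

    def lookup(self, surface: str) -> Optional[LexiconEntry]:
        return self.entries.get(normalize_label(surface))

    def pattern(self) -> re.Pattern:
        if self._pattern is None:
            self._pattern = _compile_pattern(self.entries)
        return self._pattern


def load_plural_table(path: Optional[str] = None) -> dict[str, str]:
    """Singular -> plural table for the head nouns of glossary surfaces
    (Latin irregulars such as ganglion/ganglia alongside the regular
    forms needed to pluralize multi-word surfaces)."""
    if path is None:
        text = (
            resources.files("neurogloss.data").joinpath("plurals.tsv").read_text("utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        singular, plural = line.split("\t")
        table[singular] = plural
    return table


def _pluralize(surface: str, table: dict[str, str]) -> Optional[str]:
    head, _, last = surface.rpartition(" ")
    plural_last = table.get(last)
    if plural_last is None:
        return None
    return f"{head} {plural_last}" if head else plural_last


def compile_lexicon(
    kb: KnowledgeBase, plural_table: Optional[dict[str, str]] = None
) -> Lexicon:
    """Compile the annotation lexicon from a knowledge base."""
    if plural_table is None:
        plural_table = load_plural_table()
    lex = Lexicon(plural_table=dict(plural_table))

    candidates: list[LexiconEntry] = []
    for t in kb.terms:
        candidates.append(
            LexiconEntry(t.label, t.label, t.entry_id, Status.PREFERRED)
        )
        for syn in t.discouraged:
            candidates.append(
                LexiconEntry(
                    normalize_label(syn),
                    t.label,
                    t.entry_id,
                    Status.DISCOURAGED,
                    suggestion=t.label,
                )
            )
    for s in kb.sides:
        candidates.append(LexiconEntry(s.label, s.label, s.owner, Status.SIDE))

    for cand in candidates:
        _insert(lex, cand)
    # plural variants never displace an exact glossary surface
    for cand in list(lex.entries.values()):
        plural = _pluralize(cand.surface, plural_table)
        if plural is None or plural in lex.entries:
            continue
        lex.entries[plural] = LexiconEntry(
            plural,
            cand.resolved_label,
            cand.entry_id,
            cand.status,
            suggestion=cand.suggestion,
            plural=True,
        )
    return lex


def _insert(lex: Lexicon, cand: LexiconEntry) -> None:
    existing = lex.entries.get(cand.surface)
    if existing is None:
        lex.entries[cand.surface] = cand
        return
    keep, drop = existing, cand
    if (_STATUS_RANK[cand.status], cand.entry_id or 0) < (
        _STATUS_RANK[existing.status],
        existing.entry_id or 0,
    ):
        keep, drop = cand, existing
        lex.entries[cand.surface] = cand
    lex.collisions.append(
        f"surface {cand.surface!r}: kept {keep.status.value} -> "
        f"{keep.resolved_label!r} (entry {keep.entry_id}), dropped "
        f"{drop.status.value} -> {drop.resolved_label!r} (entry {drop.entry_id})"
    )


# ---------------------------------------------------------------------------
# matching


def _compile_pattern(entries: dict[str, LexiconEntry]) -> re.Pattern:
    # longest surface first => leftmost-longest under re's alternation
    surfaces = sorted(entries, key=len, reverse=True)
    alternatives = []
    for surface in surfaces:
        tokens = [re.escape(tok) for tok in surface.split(" ")]
        alternatives.append(r"\s+".join(tokens))
    body = "|".join(alternatives) if alternatives else r"(?!x)x"
    return re.compile(
        rf"(?<![0-9A-Za-z_-])(?:{body})(?![0-9A-Za-z_-])", re.IGNORECASE
    )


def annotate(text: str, lexicon: Lexicon) -> list[Annotation]:
    """Tag all lexicon surfaces in ``text``.

    Matching is case-insensitive, anchored at word boundaries,
    leftmost-longest and non-overlapping; multi-word surfaces match
    across whitespace runs including line breaks.  Annotations come back
    sorted by start offset and satisfy ``text[start:end] == surface``.
    """
    out: list[Annotation] = []
    for m in lexicon.pattern().finditer(text):
        surface = m.group(0)
        entry = lexicon.lookup(surface)
        if entry is None:  # pragma: no cover - pattern and dict are in sync
            continue
        out.append(
            Annotation(
                start=m.start(),
                end=m.end(),
                surface=surface,
                resolved_label=entry.resolved_label,
                entry_id=entry.entry_id,
                status=entry.status,
                suggestion=entry.suggestion,
            )
        )
    return out


def _match_capitalization(replacement: str, original: str) -> str:
    if original[:1].isupper():
        return replacement[:1].upper() + replacement[1:]
    return replacement


def rewrite(
    text: str, lexicon: Lexicon, policy: str = "replace_discouraged"
) -> tuple[str, list[tuple[int, str, str]]]:
    """Replace or flag discouraged spans.

    ``replace_discouraged`` substitutes every DISCOURAGED span with its
    suggestion (pluralized through the bundled table when the matched
    surface was a plural variant, leading capitalization preserved) and
    returns the new text with a change log of (offset, old, new) rows.
    ``flag_only`` leaves the text untouched and returns the log.
    """
    if policy not in ("replace_discouraged", "flag_only"):
        raise ValueError(f"unknown rewrite policy {policy!r}")
    log: list[tuple[int, str, str]] = []
    pieces: list[str] = []
    cursor = 0
    for ann in annotate(text, lexicon):
        if ann.status is not Status.DISCOURAGED or ann.suggestion is None:
            continue
        entry = lexicon.lookup(ann.surface)
        replacement = ann.suggestion
        if entry is not None and entry.plural:
            plural = _pluralize(replacement, lexicon.plural_table)
            if plural is not None:
                replacement = plural
        replacement = _match_capitalization(replacement, ann.surface)
        log.append((ann.start, ann.surface, replacement))
        if policy == "replace_discouraged":
            pieces.append(text[cursor:ann.start])
            pieces.append(replacement)
            cursor = ann.end
    if policy == "flag_only":
        return text, log
    pieces.append(text[cursor:])
    return "".join(pieces), log


def annotations_tsv(annotations: Iterable[Annotation]) -> str:
    """Standoff TSV rendering: start, end, surface, label, entry, status,
    suggestion."""
    rows = ["start\tend\tsurface\tlabel\tentry_id\tstatus\tsuggestion"]
    for a in annotations:
        rows.append(
            "\t".join(
                (
                    str(a.start),
                    str(a.end),
                    a.surface.replace("\n", " "),
                    a.resolved_label,
                    "" if a.entry_id is None else str(a.entry_id),
                    a.status.value,
                    a.suggestion or "",
                )
            )
        )
    return "\n".join(rows) + "\n"
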