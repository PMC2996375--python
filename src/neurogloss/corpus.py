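"""Read and write the glossary corpus in its line-oriented block format.

The corpus is a UTF-8 plain-text document with a header followed by
``[term]``, ``[side]`` and ``[primitive]`` blocks separated by blank
lines.  Keys are ``key: value`` lines; list values use ``;`` separators;
part-whole statements carry an explicit ``(some)`` or ``(every)``
quantifier suffix.  The full grammar is documented in
``docs/corpus-format.md``.

The canonical form (produced by :func:`write_corpus`) orders primitives
and side entries alphabetically and main entries by id, and round-trips
byte-identically through parse -> write.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from typing import Iterator, Optional

from .model import (
    KnowledgeBase,
    KnowledgeBaseError,
    ParentKind,
    ParentRef,
    PartStatement,
    Provenance,
    Quantifier,
    RegisterRow,
    SideEntry,
    TermEntry,
    normalize_label,
)

FORMAT_VERSION = "1"

_BUNDLED_CORPUS = "glossary.inc"
_BUNDLED_WHITELIST = "whitelist.tsv"


class CorpusError(ValueError):
    """Malformed corpus document, with the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        where = f"line {line}: " if line is not None else ""
        super().__init__(where + message)


# ---------------------------------------------------------------------------
# parsing


def _split_blocks(text: str) -> Iterator[tuple[str, int, list[tuple[int, str, str]]]]:
    """Yield (kind, start line, [(lineno, key, value), ...]) per block."""
    kind = None
    start = 0
    fields: list[tuple[int, str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip()
        if not line or line.lstrip().startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            if kind is not None:
                yield kind, start, fields
            kind = line[1:-1].strip().lower()
            if kind not in ("term", "side", "primitive"):
                raise CorpusError(f"unknown block kind [{kind}]", lineno)
            start = lineno
            fields = []
            continue
        if ":" not in line:
            raise CorpusError(f"expected 'key: value', got {line!r}", lineno)
        key, _, value = line.partition(":")
        key = key.strip().lower()
        value = value.strip()
        if kind is None:
            # header field
            yield "header-field", lineno, [(lineno, key, value)]
        else:
            fields.append((lineno, key, value))
    if kind is not None:
        yield kind, start, fields


def _parse_genus(value: str, lineno: int, primitives: frozenset[str]) -> ParentRef:
    value = value.strip()
    low = normalize_label(value)
    if low.startswith("cluster of "):
        member = low[len("cluster of "):].strip()
        if not member:
            raise CorpusError("empty cluster member in genus", lineno)
        return ParentRef(ParentKind.CLUSTER_OF, member)
    if low in primitives:
        return ParentRef(ParentKind.PRIMITIVE, low)
    return ParentRef(ParentKind.MAIN_TERM, low)


def _parse_part(value: str, lineno: int) -> PartStatement:
    value = value.strip()
    if not value.endswith(")") or "(" not in value:
        raise CorpusError(
            f"part statement {value!r} lacks an explicit (some)/(every) quantifier",
            lineno,
        )
    whole, _, quant = value.rpartition("(")
    quant = quant[:-1].strip().lower()
    try:
        quantifier = Quantifier(quant)
    except ValueError:
        raise CorpusError(f"unknown quantifier keyword {quant!r}", lineno) from None
    return PartStatement(normalize_label(whole), quantifier)


def _parse_list(value: str) -> tuple[str, ...]:
    if not value.strip():
        return ()
    return tuple(part.strip() for part in value.split(";") if part.strip())


def _parse_register(value: str, lineno: int) -> frozenset[int]:
    try:
        return frozenset(int(tok) for tok in value.replace(",", " ").split())
    except ValueError:
        raise CorpusError(f"bad register entry list {value!r}", lineno) from None


def parse_corpus(document: str) -> KnowledgeBase:
    """Parse a corpus document into a :class:`KnowledgeBase`.

    Raises :class:`CorpusError` with a line number on malformed blocks,
    unknown quantifier keywords and duplicate ids or labels.
    """
    header: dict[str, str] = {}
    primitives: set[str] = set()
    raw_terms: list[tuple[int, dict]] = []
    raw_sides: list[tuple[int, dict]] = []

    blocks = list(_split_blocks(document))
    for kind, lineno, fields in blocks:
        if kind == "header-field":
            _, key, value = fields[0]
            header[key] = value
        elif kind == "primitive":
            block = _fields_to_dict(fields, multi=())
            if "label" not in block:
                raise CorpusError("[primitive] block without label", lineno)
            primitives.add(normalize_label(block["label"][0][1]))
        elif kind == "term":
            raw_terms.append((lineno, _fields_to_dict(fields, multi=("part", "differentia"))))
        elif kind == "side":
            raw_sides.append((lineno, _fields_to_dict(fields, multi=())))

    version = header.get("format", "")
    if version != FORMAT_VERSION:
        raise CorpusError(
            f"unsupported or missing format version {version!r} "
            f"(expected {FORMAT_VERSION!r})"
        )
    prim = frozenset(primitives)

    seen_ids: set[int] = set()
    seen_labels: set[str] = set()
    terms: list[TermEntry] = []
    for lineno, block in raw_terms:
        for required in ("id", "label", "genus"):
            if required not in block:
                raise CorpusError(f"[term] block missing {required!r}", lineno)
        id_line, id_value = block["id"][0]
        try:
            entry_id = int(id_value)
        except ValueError:
            raise CorpusError(f"bad entry id {id_value!r}", id_line) from None
        if entry_id in seen_ids:
            raise CorpusError(f"duplicate entry id {entry_id}", id_line)
        seen_ids.add(entry_id)
        label = normalize_label(block["label"][0][1])
        if not label:
            raise CorpusError("empty term label", block["label"][0][0])
        if label in seen_labels:
            raise CorpusError(f"duplicate label {label!r}", block["label"][0][0])
        seen_labels.add(label)
        genus = _parse_genus(block["genus"][0][1], block["genus"][0][0], prim)
        parts = tuple(_parse_part(v, ln) for ln, v in block.get("part", []))
        differentia = tuple(v for _, v in block.get("differentia", []))
        discouraged: tuple[str, ...] = ()
        if "discouraged" in block:
            discouraged = _parse_list(block["discouraged"][0][1])
        xrefs: frozenset[str] = frozenset()
        if "xref" in block:
            xrefs = frozenset(
                normalize_label(x) for x in _parse_list(block["xref"][0][1])
            )
        terms.append(
            TermEntry(
                entry_id=entry_id,
                label=label,
                genus=genus,
                parts=parts,
                differentia=differentia,
                discouraged=discouraged,
                def_xrefs=xrefs,
            )
        )

    sides: list[SideEntry] = []
    register: dict[str, RegisterRow] = {}
    for lineno, block in raw_sides:
        if "label" not in block:
            raise CorpusError("[side] block without label", lineno)
        label = normalize_label(block["label"][0][1])
        if label in seen_labels:
            raise CorpusError(f"duplicate label {label!r}", block["label"][0][0])
        seen_labels.add(label)
        note = block["note"][0][1] if "note" in block else None
        owner = None
        if "owner" in block:
            try:
                owner = int(block["owner"][0][1])
            except ValueError:
                raise CorpusError("bad owner entry id", block["owner"][0][0]) from None
        sides.append(SideEntry(label=label, note=note, owner=owner))
        if "register" in block:
            ln, value = block["register"][0]
            register[label] = RegisterRow(label, _parse_register(value, ln))

    # register rows of main entries: the defining (bold) number is the
    # entry's own id.
    for lineno, block in raw_terms:
        if "register" in block:
            ln, value = block["register"][0]
            label = normalize_label(block["label"][0][1])
            entry_id = int(block["id"][0][1])
            entries = _parse_register(value, ln)
            if entry_id not in entries:
                raise CorpusError(
                    f"register row of {label!r} lacks its own entry id {entry_id}", ln
                )
            register[label] = RegisterRow(label, entries, defining_entry=entry_id)

    checksum = header.get("checksum", "")
    body = _body_of(document)
    if checksum:
        actual = _digest(body)
        if checksum != actual:
            raise CorpusError(
                f"checksum mismatch: header says {checksum}, body is {actual}"
            )

    try:
        return KnowledgeBase.create(
            terms=terms,
            sides=sides,
            primitives=prim,
            register=tuple(register[k] for k in sorted(register)),
            provenance=Provenance(version=version, checksum=checksum or _digest(body)),
        )
    except KnowledgeBaseError as exc:
        raise CorpusError(str(exc)) from exc


def _fields_to_dict(
    fields: list[tuple[int, str, str]], multi: tuple[str, ...]
) -> dict[str, list[tuple[int, str]]]:
    out: dict[str, list[tuple[int, str]]] = {}
    for lineno, key, value in fields:
        if key in out and key not in multi:
            raise CorpusError(f"repeated key {key!r}", lineno)
        out.setdefault(key, []).append((lineno, value))
    return out


# ---------------------------------------------------------------------------
# writing


def _digest(body: str) -> str:
    return "sha256:" + hashlib.sha256(body.encode("utf-8")).hexdigest()


def _body_of(document: str) -> str:
    idx = document.find("\n[")
    return document[idx + 1:] if idx >= 0 else ""


def write_corpus(kb: KnowledgeBase) -> str:
    """Serialize a knowledge base to canonical corpus text.

    Canonical ordering: primitives alphabetically, main entries by id,
    side entries alphabetically.  ``parse_corpus(write_corpus(kb)) == kb``.
    """
    kb.check()
    lines: list[str] = []
    for label in sorted(kb.primitives):
        lines.append("[primitive]")
        lines.append(f"label: {label}")
        lines.append("")
    for t in sorted(kb.terms, key=lambda t: t.entry_id):
        lines.append("[term]")
        lines.append(f"id: {t.entry_id}")
        lines.append(f"label: {t.label}")
        if t.genus.kind is ParentKind.CLUSTER_OF:
            lines.append(f"genus: cluster of {t.genus.target}")
        else:
            lines.append(f"genus: {t.genus.target}")
        for p in t.parts:
            lines.append(f"part: {p.whole} ({p.quantifier.value})")
        for clause in t.differentia:
            lines.append(f"differentia: {clause}")
        if t.def_xrefs:
            lines.append("xref: " + "; ".join(sorted(t.def_xrefs)))
        if t.discouraged:
            lines.append("discouraged: " + "; ".join(t.discouraged))
        row = kb.register_row(t.label)
        if row is not None:
            lines.append("register: " + ", ".join(str(e) for e in sorted(row.entries)))
        lines.append("")
    for s in sorted(kb.sides, key=lambda s: s.label):
        lines.append("[side]")
        lines.append(f"label: {s.label}")
        if s.note is not None:
            lines.append(f"note: {s.note}")
        if s.owner is not None:
            lines.append(f"owner: {s.owner}")
        row = kb.register_row(s.label)
        if row is not None:
            lines.append("register: " + ", ".join(str(e) for e in sorted(row.entries)))
        lines.append("")
    body = "\n".join(lines)
    header = (
        "# neurogloss corpus: invertebrate neuroanatomy glossary\n"
        f"format: {FORMAT_VERSION}\n"
        "source: glossary of invertebrate neuroanatomical terms, 47 main entries\n"
        f"checksum: {_digest(body)}\n"
        "\n"
    )
    return header + body


# ---------------------------------------------------------------------------
# bundled data


def bundled_corpus_text() -> str:
    return (
        resources.files("neurogloss.data").joinpath(_BUNDLED_CORPUS).read_text("utf-8")
    )


def load_bundled_corpus() -> KnowledgeBase:
    """Parse and return the corpus shipped with the package."""
    return parse_corpus(bundled_corpus_text())


def load_whitelist(path: Optional[str] = None) -> dict[tuple[str, str], str]:
    """Load the (rule, subject) -> reason whitelist.

    The bundled whitelist records findings that trace back to internal
    inconsistencies of the transcribed glossary itself; each entry cites
    the two conflicting locations.
    """
    if path is None:
        text = (
            resources.files("neurogloss.data")
            .joinpath(_BUNDLED_WHITELIST)
            .read_text("utf-8")
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    out: dict[tuple[str, str], str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"bad whitelist line: {line!r}")
        rule, subject, reason = parts[0], parts[1], parts[2]
        out[(rule, normalize_label(subject))] = reason
    return out
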