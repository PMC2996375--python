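"""OBO 1.4 export and re-import of the glossary knowledge base.

One ``[Term]`` stanza per main entry (``NGLO:0000001`` .. zero-padded by
entry id), side entries from ``NGLO:0001001`` in alphabetical order
tagged with the ``side_entry`` subset, and additional root stanzas for
the primitive parents (``NGLO:0002001``..) and the ``cluster of X``
parents (``NGLO:0003001``..).

Dialect notes (also recorded in the exported header):

* the EVERY/SOME quantifier of a ``part_of`` relationship travels as an
  OBO 1.4 trailing modifier, ``{quantifier="every"}``;
* differentia clauses travel individually as
  ``property_value: differentia "..." xsd:string`` lines so that the
  clause list survives a round trip (the ``def:`` line carries the
  assembled human-readable definition);
* definition cross-references travel as ``xref:`` lines;
* discouraged synonyms use ``synonym: "..." RELATED DISCOURAGED []``
  with the synonym type declared in the header;
* register rows are not representable in OBO and are dropped on export.

``from_obo`` understands exactly this dialect; foreign constructs are
skipped with a warning.
"""

from __future__ import annotations

import re
import warnings
from typing import Optional

from .model import (
    KnowledgeBase,
    ParentKind,
    ParentRef,
    PartStatement,
    Provenance,
    Quantifier,
    SideEntry,
    TermEntry,
    normalize_label,
)

__all__ = ["to_obo", "from_obo", "OboDialectWarning"]

ONTOLOGY_ID = "nglo"
_TERM_BASE = 0
_SIDE_BASE = 1000
_PRIMITIVE_BASE = 2000
_CLUSTER_BASE = 3000


class OboDialectWarning(UserWarning):
    pass


def _term_id(entry_id: int) -> str:
    return f"NGLO:{_TERM_BASE + entry_id:07d}"


def _seq_id(base: int, index: int) -> str:
    return f"NGLO:{base + index:07d}"


def _cluster_labels(kb: KnowledgeBase) -> list[str]:
    return sorted(
        {t.genus.target for t in kb.terms if t.genus.kind is ParentKind.CLUSTER_OF}
    )


def _id_maps(kb: KnowledgeBase) -> dict[str, str]:
    ids: dict[str, str] = {}
    for t in kb.terms:
        ids[t.label] = _term_id(t.entry_id)
    for i, s in enumerate(sorted(kb.sides, key=lambda s: s.label), start=1):
        ids[s.label] = _seq_id(_SIDE_BASE, i)
    for i, p in enumerate(sorted(kb.primitives), start=1):
        ids[p] = _seq_id(_PRIMITIVE_BASE, i)
    for i, c in enumerate(_cluster_labels(kb), start=1):
        ids[f"cluster of {c}"] = _seq_id(_CLUSTER_BASE, i)
    return ids


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _definition_text(t: TermEntry) -> str:
    article = "An" if t.label[:1] in "aeiou" else "A"
    if t.genus.kind is ParentKind.CLUSTER_OF:
        genus_phrase = f"cluster of {t.genus.target}s"
    else:
        genus_phrase = t.genus.target
    sentences = [f"{article} {t.label} is a {genus_phrase}."]
    for p in t.parts:
        det = "the" if p.quantifier is Quantifier.EVERY else "a"
        sentences.append(f"It is part of {det} {p.whole}.")
    sentences.extend(t.differentia)
    return " ".join(sentences)


def to_obo(kb: KnowledgeBase) -> str:
    """Serialize to OBO 1.4 text with deterministic stanza and line order."""
    kb.check()
    ids = _id_maps(kb)
    out: list[str] = [
        "format-version: 1.4",
        f"data-version: {kb.provenance.checksum or 'unversioned'}",
        f"ontology: {ONTOLOGY_ID}",
        'subsetdef: side_entry "term used in the glossary without its own definition"',
        'synonymtypedef: DISCOURAGED "synonym whose use the glossary discourages"',
        "remark: part_of quantifiers are carried as trailing modifiers, "
        'e.g. relationship: part_of NGLO:0000021 {quantifier="every"}',
        "remark: differentia clauses are carried one per "
        "property_value: differentia line; xref lines are definition-level "
        "cross-references; register rows are not exported",
        "",
    ]

    for t in sorted(kb.terms, key=lambda t: t.entry_id):
        out.append("[Term]")
        out.append(f"id: {_term_id(t.entry_id)}")
        out.append(f"name: {t.label}")
        out.append(
            f"def: {_quote(_definition_text(t))} [NGLO_ENTRY:{t.entry_id}]"
        )
        for syn in t.discouraged:
            out.append(f"synonym: {_quote(syn)} RELATED DISCOURAGED []")
        for x in sorted(t.def_xrefs):
            out.append(f"xref: {ids[x]}")
        for clause in t.differentia:
            out.append(f"property_value: differentia {_quote(clause)} xsd:string")
        if t.genus.kind is ParentKind.CLUSTER_OF:
            parent = ids[f"cluster of {t.genus.target}"]
        else:
            parent = ids[t.genus.target]
        out.append(f"is_a: {parent}")
        for p in t.parts:
            out.append(
                f"relationship: part_of {ids[p.whole]} "
                f'{{quantifier="{p.quantifier.value}"}}'
            )
        out.append("")

    for s in sorted(kb.sides, key=lambda s: s.label):
        out.append("[Term]")
        out.append(f"id: {ids[s.label]}")
        out.append(f"name: {s.label}")
        if s.note is not None:
            out.append(f"comment: {s.note}")
        out.append("subset: side_entry")
        if s.owner is not None:
            out.append(f"property_value: owner {_quote(str(s.owner))} xsd:integer")
        out.append("")

    for p in sorted(kb.primitives):
        out.append("[Term]")
        out.append(f"id: {ids[p]}")
        out.append(f"name: {p}")
        out.append("")

    for c in _cluster_labels(kb):
        out.append("[Term]")
        out.append(f"id: {ids[f'cluster of {c}']}")
        out.append(f"name: cluster of {c}")
        out.append("")

    out.append("[Typedef]")
    out.append("id: part_of")
    out.append("name: part of")
    out.append("is_transitive: true")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# import

_TRAILING = re.compile(r"\s*\{([^}]*)\}\s*$")
_QUOTED = re.compile(r'"((?:[^"\\]|\\.)*)"')


def _unquote(text: str) -> str:
    return text.replace('\\"', '"').replace("\\\\", "\\")


def _split_stanzas(text: str) -> tuple[dict[str, list[str]], list[dict]]:
    header: dict[str, list[str]] = {}
    stanzas: list[dict] = []
    current: Optional[dict] = None
    for raw in text.splitlines():
        line = raw.rstrip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = {"kind": line[1:-1], "tags": []}
            stanzas.append(current)
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        value = value.strip()
        if current is None:
            header.setdefault(key, []).append(value)
        else:
            current["tags"].append((key, value))
    return header, stanzas


def from_obo(text: str) -> KnowledgeBase:
    """Re-import a document produced by :func:`to_obo`.

    All fields representable in the dialect round-trip; register rows do
    not travel through OBO and come back empty.  Unknown relationship
    types and foreign constructs are skipped with an
    :class:`OboDialectWarning`; if the DISCOURAGED synonym type is not
    declared in the header, discouraged synonyms degrade to plain
    RELATED synonyms (and are dropped) with a warning.
    """
    header, stanzas = _split_stanzas(text)
    has_discouraged_type = any(
        v.startswith("DISCOURAGED ") for v in header.get("synonymtypedef", [])
    )
    data_version = (header.get("data-version") or [""])[0]

    # first pass: id -> name
    names: dict[str, str] = {}
    for st in stanzas:
        if st["kind"] != "Term":
            continue
        tags = dict_first(st["tags"])
        if "id" in tags and "name" in tags:
            names[tags["id"]] = normalize_label(tags["name"])

    terms: list[TermEntry] = []
    sides: list[SideEntry] = []
    primitives: set[str] = set()
    cluster_names: set[str] = set()

    for st in stanzas:
        if st["kind"] == "Typedef":
            continue  # part_of is declared by the dialect itself
        if st["kind"] != "Term":
            warnings.warn(
                f"skipping foreign stanza [{st['kind']}]", OboDialectWarning
            )
            continue
        tags = st["tags"]
        first = dict_first(tags)
        obo_id = first.get("id", "")
        label = normalize_label(first.get("name", ""))
        if not obo_id.startswith("NGLO:"):
            warnings.warn(f"skipping foreign term id {obo_id!r}", OboDialectWarning)
            continue
        local = int(obo_id.split(":")[1])
        if _CLUSTER_BASE < local:
            cluster_names.add(label)
            continue
        if _PRIMITIVE_BASE < local:
            primitives.add(label)
            continue
        if _SIDE_BASE < local:
            note = first.get("comment")
            owner = None
            for key, value in tags:
                if key == "property_value" and value.startswith("owner "):
                    m = _QUOTED.search(value)
                    if m:
                        owner = int(_unquote(m.group(1)))
            sides.append(SideEntry(label=label, note=note, owner=owner))
            continue

        entry_id = local
        genus: Optional[ParentRef] = None
        parts: list[PartStatement] = []
        differentia: list[str] = []
        discouraged: list[str] = []
        xrefs: set[str] = set()
        for key, value in tags:
            if key == "is_a":
                parent_label = names.get(value, "")
                parent_local = int(value.split(":")[1]) if value.startswith("NGLO:") else -1
                if parent_local > _CLUSTER_BASE:
                    member = parent_label.removeprefix("cluster of ").strip()
                    genus = ParentRef(ParentKind.CLUSTER_OF, member)
                elif parent_local > _PRIMITIVE_BASE:
                    genus = ParentRef(ParentKind.PRIMITIVE, parent_label)
                else:
                    genus = ParentRef(ParentKind.MAIN_TERM, parent_label)
            elif key == "relationship":
                m = _TRAILING.search(value)
                quant = None
                core = value
                if m:
                    core = value[: m.start()]
                    qm = re.search(r'quantifier="(\w+)"', m.group(1))
                    if qm:
                        quant = qm.group(1)
                fields = core.split()
                if len(fields) != 2 or fields[0] != "part_of":
                    warnings.warn(
                        f"skipping unknown relationship {value!r} on {label!r}",
                        OboDialectWarning,
                    )
                    continue
                parts.append(
                    PartStatement(
                        names.get(fields[1], fields[1]),
                        Quantifier(quant or "some"),
                    )
                )
            elif key == "synonym":
                m = _QUOTED.match(value)
                if not m:
                    continue
                rest = value[m.end():].strip()
                if rest.startswith("RELATED DISCOURAGED"):
                    if has_discouraged_type:
                        discouraged.append(_unquote(m.group(1)))
                    else:
                        warnings.warn(
                            f"synonymtypedef DISCOURAGED missing; synonym "
                            f"{m.group(1)!r} on {label!r} degraded to RELATED",
                            OboDialectWarning,
                        )
                else:
                    warnings.warn(
                        f"skipping synonym of foreign type on {label!r}",
                        OboDialectWarning,
                    )
            elif key == "property_value" and value.startswith("differentia "):
                m = _QUOTED.search(value)
                if m:
                    differentia.append(_unquote(m.group(1)))
            elif key == "xref":
                xrefs.add(names.get(value, value))
        if genus is None:
            warnings.warn(f"term {label!r} without is_a; skipped", OboDialectWarning)
            continue
        terms.append(
            TermEntry(
                entry_id=entry_id,
                label=label,
                genus=genus,
                parts=tuple(parts),
                differentia=tuple(differentia),
                discouraged=tuple(discouraged),
                def_xrefs=frozenset(xrefs),
            )
        )

    return KnowledgeBase.create(
        terms=terms,
        sides=sides,
        primitives=primitives,
        register=(),
        provenance=Provenance(version="obo", checksum=data_version),
    )


def dict_first(tags: list[tuple[str, str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for key, value in tags:
        out.setdefault(key, value)
    return out
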