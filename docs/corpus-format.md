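# Corpus format (version 1)

A corpus document is UTF-8 plain text: a header followed by blocks.
Blank lines and `#` comment lines are ignored. The bundled corpus is
`src/neurogloss/data/glossary.inc`.

## Grammar

```
document    = header block*
header      = headerline+
headerline  = key ":" value            ; before the first block
block       = "[term]" field+
            | "[side]" field+
            | "[primitive]" field+
field       = key ":" value
list        = value (";" value)*       ; items trimmed, empty items dropped
```

### Header keys

| key        | meaning                                             |
|------------|-----------------------------------------------------|
| `format`   | format version; must be `1`                         |
| `source`   | free-text description of the transcribed glossary   |
| `checksum` | `sha256:<hex>` over the body (first `[` to the end) |

The checksum is optional on input and verified when present; the writer
always emits it.

### `[term]` — one numbered main entry

| key           | required | value                                                            |
|---------------|----------|------------------------------------------------------------------|
| `id`          | yes      | integer entry number; ids must be contiguous 1..N                |
| `label`       | yes      | term label (normalized to lowercase, single spaces)              |
| `genus`       | yes      | parent label, or `cluster of <member>`; a label in the primitive set is a primitive parent |
| `part`        | repeat   | `<whole label> (some)` or `<whole label> (every)`; the quantifier suffix is mandatory |
| `differentia` | repeat   | one clause per line, ordered                                     |
| `xref`        | no       | `;`-list of labels cross-referenced in the definition block      |
| `discouraged` | no       | `;`-list of discouraged synonyms; an empty value is an empty list|
| `register`    | no       | comma/space-separated entry numbers of this label's register row; must contain the entry's own id, which is the defining (bold) entry |

### `[side]` — a term used without its own definition

| key        | required | value                              |
|------------|----------|------------------------------------|
| `label`    | yes      | side-entry label                   |
| `note`     | no       | free text                          |
| `owner`    | no       | entry id the side entry belongs to |
| `register` | no       | entry numbers of its register row  |

### `[primitive]` — an undefined root parent

| key     | required | value           |
|---------|----------|-----------------|
| `label` | yes      | primitive label |

## Canonical form

The writer emits: header (comment, `format`, `source`, `checksum`), then
primitives alphabetically, main entries by id, side entries
alphabetically; within a block, keys in the order of the tables above,
`xref` lists sorted, register entries sorted numerically. The canonical
form round-trips byte-identically through parse → write, and
parse(write(kb)) equals kb for every valid knowledge base.

## Errors

Parsing fails with a line number on: unknown block kinds, lines without
`:`, missing required keys, a `part` value without an explicit
quantifier, unknown quantifier keywords, duplicate ids or labels, a
register row lacking its own entry id, an unsupported format version, a
checksum mismatch, and any hard structural defect of the resulting
knowledge base (dangling genus, is_a cycle, non-contiguous ids).
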