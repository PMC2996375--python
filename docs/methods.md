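# Methods

## The knowledge model

Each of the 47 main entries carries exactly one *genus* reference and
zero or more quantified *part-of* statements; everything else the
glossary says about a term is kept as opaque differentia prose. The
genus hierarchy is a single-inheritance forest whose roots are the four
primitive parents that the glossary uses without defining them (*cell*,
*molecule*, *cell process*, *cell-to-cell junction*) and the
parameterized `cluster of X` nodes. `cluster of X` is modelled as its
own root kind rather than as forty-odd ad-hoc strings because nine or
more entries share these parents and keeping them as first-class nodes
keeps the taxonomy rooted and queryable; a cluster node is a root — the
genus chain stops there and does not continue into the member type,
since "a brain is a cluster of neurons" does not make a brain a kind of
neuron.

### Quantifier semantics

The glossary distinguishes "part of **a** X" from "part of **the** X".
We read `SOME` as the standard all-some axiom (every instance of the
part is part of some instance of the whole) and `EVERY` as additionally
asserting the reciprocal (every instance of the whole has such a part).
The one-line phrasing "part of the = part of every" admits a second
reading — every instance of the part is in *every* whole — but that
reading is incoherent for almost all entries (one central body cannot
sit in every central complex), so the toolkit stores the flag verbatim
and reasons under the first reading only.

### Composition table

Transitive parthood composes `P∘P`, `P∘is_a` and `is_a∘P`. A derived
statement keeps `EVERY` only when its derivation consists purely of
`EVERY` part links. Any `SOME` link obviously downgrades; so does any
`is_a` step, because the reciprocal component does not survive
subsumption in either direction — a receptor cell is mandatorily part of
every nervous system, but its subclass *photoreceptor cell* is not, and
a central complex sits in some syncerebrum without every brain (the
superclass of syncerebrum) containing one. Pure `is_a` chains assert no
parthood at all; a derivation must use at least one part edge.

The reasoner's closure is a breadth-first traversal over the state space
(node × part-edge-used × still-pure-every), which terminates on any
input including cyclic ones; per whole it reports the strongest
reachable quantifier and one witness derivation. Its independent check
in the test suite is a deliberately naive enumeration of all simple
paths; the two agree on the bundled corpus and on seeded batteries of
generated knowledge bases.

## Corpus transcription conventions

The corpus (`data/glossary.inc`) transcribes only the formal definition
block of each entry — the first paragraph, before the discouraged-term
list — never the background prose. Consequences:

- **Differentia** are the definition sentences after the genus sentence,
  split at sentence boundaries and kept as opaque text (the glossary
  states them in prose only; no clause-level logic is attempted).
  Sentences that mix a part-of assertion with a property ("It is part of
  a nervous system and consists of …") contribute the part statement to
  the structured fields and the property remainder to the differentia.
- **Definition cross-references** (`xref:`) are exactly the arrow-marked
  terms of the definition block, including the genus target and part
  wholes. This keeps register reconciliation non-circular: the printed
  register indexes usages across whole entries including backgrounds,
  so the expected relation is printed ⊇ computed.
- The cross-cutting qualifier "a *developing* nervous system" (entries
  11, 26, 27, 29, 35) is not representable as a separate whole; those
  statements are recorded against *nervous system* with quantifier
  `SOME`, and the development context stays in the differentia.
- Entry 13 (globuli cell) is "part of a cluster of other globuli cells";
  the whole is not a glossary term, so the sentence is kept as
  differentia only and no part statement is asserted.
- Entry 32 (ommatidium) is "the smallest … unit of **the** compound
  eye"; transcribed as part-of `EVERY` compound eye, since every
  compound eye consists of ommatidia.
- Entry 44 (tract) is part "of a brain **or** of a ganglion";
  disjunction is not representable, so each alternative becomes a
  separate `SOME` statement.

The corpus format itself is line-oriented blocks (grammar in
`corpus-format.md`) rather than OBO, because OBO has no faithful tags
for the `EVERY`/`SOME` distinction or for register rows; OBO is provided
as an export instead. The canonical form (primitives alphabetical,
terms by id, sides alphabetical, checksum over the body) is a fixed
point of parse∘write, and the shipped file is generated through the
writer, so it is canonical by construction.

## Validation and the whitelist

Rules: V1 contiguous ids; V2 exactly one genus; V3 parent and part
references resolve; V4 is_a acyclicity (cycle extracted into the
message); V5 definition xrefs resolve; V6 every main term's register row
carries its own id as the defining (bold) entry; V7 (*warning*) each
definition xref N→T is reflected in T's register row; V8 no discouraged
synonym may equal a main-term label. V7 stays a warning because the
printed register was hand-compiled and the check is directional; misses
indicate glossary-internal inconsistencies, which are recorded, not
"fixed".

The shipped whitelist (`data/whitelist.tsv`, versioned with the corpus)
downgrades exactly three findings, each citing the two conflicting
glossary locations: the glossary both defines *nerve* (entry 19) and
discourages the word under *neurite* (entry 23); entries 27 and 40
cross-reference "cells" although the register has no row for the
primitive *cell*; and the register row for *nerve* omits entry 39, whose
definition references segmental nerves. Faithful transcription
reproduces these conflicts; the whitelist records them instead of
silently editing the corpus.

Register reconciliation is asymmetric by design: computed references
missing from the printed row are errors (R1/R2), printed entries without
a definition-level counterpart are informational background usages (R3).
On the bundled corpus there are zero errors after the whitelist and 195
background-usage notes.

## Annotator

Exact dictionary matching only — case-insensitive, word-boundary
anchored (hyphens count as word characters, so surfaces never match
inside hyphenated compounds), leftmost-longest, non-overlapping,
multi-word surfaces matching across whitespace runs and line breaks.
No stemming and no fuzzy matching: in anatomical text false positives
are costlier than misses, and the glossary supplies exact forms. A
bundled singular→plural table (Latin irregulars such as
ganglion/ganglia, ommatidium/ommatidia, soma/somata, plus the regular
head-noun forms needed for multi-word surfaces) generates plural
variants; a plural variant never displaces an exact glossary surface.

Surface collisions are resolved by precedence DISCOURAGED > PREFERRED >
SIDE and, between two entries discouraging the same surface, by the
lower entry id; every collision is logged on the lexicon. DISCOURAGED
outranks even a preferred label because the glossary explicitly condemns
the usage — the one affected label is *nerve*, which the glossary
restricts to its narrow sense and otherwise condemns; the annotator
therefore flags every occurrence of "nerve" and suggests *neurite*,
which is the conservative behaviour for a terminology linter. Both
entries 9 (eye) and 34 (photoreceptor cell) discourage "photoreceptor";
the precedence resolves it to entry 9.

Rewriting replaces discouraged spans with their suggestions, preserving
leading capitalization and pluralizing the suggestion through the same
table when the matched surface was a plural variant. Because every
suggestion is a preferred label, rewriting is idempotent and its output
re-annotates with zero discouraged hits; both properties are tested on
generated texts.

## OBO dialect

Main entries are `NGLO:0000001`–`NGLO:0000047` (zero-padded entry id),
side entries `NGLO:0001001`… alphabetically with subset `side_entry`,
primitives `NGLO:0002001`… and cluster nodes `NGLO:0003001`… as root
stanzas. Part-of quantifiers travel as OBO 1.4 trailing modifiers
(`{quantifier="every"}`) — the format's native mechanism for annotating
a single tag line; differentia clauses travel one per
`property_value: differentia` line so the clause list survives a round
trip; the `def:` line carries the assembled human-readable definition;
discouraged synonyms use the declared `DISCOURAGED` synonym type.
Register rows have no faithful OBO representation and are deliberately
not embedded, keeping the export standards-conformant; they live only in
the corpus format. Stanzas and lines are emitted in a fixed canonical
order so exports are diff-stable. Import degrades gracefully: foreign
stanzas, unknown relationship types and undeclared synonym types are
skipped with warnings.

Side entries carry no is_a edges: the glossary anchors some of them to a
parent informally (e.g. *hemiganglion* under ganglion), but it defines
no relations for them, and inventing edges would put words in its mouth.

## Synthetic fixtures

`random_taxonomy(n_terms, p_part, seed)` emulates the structural shape
of the glossary: a single-genus forest over synthetic labels rooted in
primitives and cluster nodes, one part-of edge per term with probability
`p_part` toward an earlier term (guaranteeing acyclicity of the combined
graph), `EVERY` with probability 0.5, sparse definition xrefs with the
register derived from them, occasional discouraged synonyms and side
entries. It does *not* emulate the glossary's prose, its multi-word
label structure, register rows fed by background usage, or surface
collisions between statuses — so the property tests establish the
algebra of the closure, round-trip and rewrite operations, while
behaviour on the real terminology is covered by the bundled-corpus
tests. Defaults (`p_part` 0.3, ≤ 50 terms) keep generated taxonomies in
the same density regime as the glossary (47 terms, 44 part statements).

## Determinism, sizes, degenerate inputs

All generators take explicit seeds; validation, exports and reports are
deterministic and diff-stable. The property batteries use 500 generated
knowledge bases of up to 50 terms for the closure-vs-oracle comparison
and 200 generated texts for the rewrite fixed point; the brute-force
oracle enumerates simple paths, which stays cheap at these sizes because
each node has at most two outgoing edges pointing to strictly earlier
terms. Degenerate inputs are defined, not special-cased: a one-term
taxonomy roots directly in a primitive; ancestors of a root are empty;
part closure of a top-level whole is empty; an empty text annotates to
an empty list; an empty knowledge base exports to a header-only OBO
document.

## Known limitations

- Differentia are opaque prose; no description-logic reasoning over
  them, and no consistency checking of the biology itself.
- The annotator does no context-sensitive disambiguation (the vertebrate
  senses of *ganglion*, German legacy terms inside non-German text match
  as printed) and no abbreviation detection.
- Background/comment sections are indexed only through the transcribed
  register, never parsed as knowledge.
- The NGLO id space is local; cross-references to CARO/UBERON would be
  the natural next step and are out of scope.
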