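# neurogloss

A machine-interpretable edition of a consensus glossary of invertebrate
neuroanatomy, for comparative and evolutionary morphologists
("neurophylogeny") and for curators of anatomy ontologies.

Invertebrate nervous systems are described with a rich, inconsistent
terminology: even basic words like *brain*, *nerve* and *eye* mean
different things in different taxa. The glossary this package encodes
defines 47 core neuroanatomical terms taxon-independently and free of
homology assumptions, each by an Aristotelian definition — a *genus*
(the parent type) plus a *differentia* (the distinguishing properties) —
and recommends abandoning a list of legacy synonyms for each term.

`neurogloss` turns that text into data and tools:

- **corpus** — a structured transcription of all 47 entries, their
  quantified part-whole statements, discouraged synonyms, the ~150 side
  terms, and the term register, in a documented plain-text format
  (`src/neurogloss/data/glossary.inc`);
- **reasoner** — genus-chain and subclass queries, inherited
  ("expanded") definitions, transitive part-whole closure, and a
  structural validator (rules V1–V8) with a shipped whitelist for the
  glossary's own internal inconsistencies;
- **register** — recomputes the term→entries index from the definitions
  and reconciles it with the transcribed register table;
- **annotator** — dictionary-based tagging of glossary terminology in
  free text, flagging discouraged terms with the preferred replacement;
- **interchange** — lossless-as-possible OBO 1.4 export/import
  (ontology id `nglo`).

## The model

The 47 terms form a single-inheritance taxonomy rooted in four primitive
parents (*cell*, *molecule*, *cell process*, *cell-to-cell junction*)
and in `cluster of X` nodes ("a brain is a cluster of neurons").
Defining properties propagate downward: the expanded definition of a
term is the concatenation of the differentia of all its ancestors.

Part-whole statements carry an explicit quantifier taken from the
glossary's phrasing: *part of a X* means ∀p ∃w: part_of(p, w) (the
standard all-some reading, `SOME`), while *part of the X* additionally
asserts the reciprocal ∀w ∃p (`EVERY`). Closure composes
`part_of ∘ part_of`, `part_of ∘ is_a` and `is_a ∘ part_of`; a composed
statement stays `EVERY` only along chains made purely of `EVERY` part
links — any `SOME` link or any `is_a` step downgrades it to `SOME`.

## Worked example

```
$ neurogloss term ommatidium
{32} ommatidium
genus chain: eye -> sensory organ -> cluster_of(cell)
part of: compound eye (every), eye (some), nervous system (some), sensory organ (some)
definition:
  [sensory organ] It consists of receptor cells, which form a multicellular unit ...
  [eye] It consists of at least one photoreceptor cell and one separate pigmented supportive cell.
  [eye] An eye allows directional access of light to the photosensitive structures.
  [ommatidium] It is the smallest morphological and functional unit of the compound eye.
  [ommatidium] It consists of a usually limited and often constant number of rhabdomeric photoreceptor cells, ...
discouraged terms: none
```

The card shows the genus chain (an ommatidium is an eye, an eye is a
sensory organ, a sensory organ is a cluster of cells), the derived
part-whole closure — mandatorily part of every compound eye, hence part
of some eye, some sensory organ and some nervous system — and the
definition clauses inherited from each ancestor.

Annotating free text tags preferred, side and discouraged terminology
with character offsets, and can rewrite the discouraged spans:

```
$ echo "The supraesophageal ganglion bears facetted eyes." | neurogloss annotate
start  end  surface                   label         entry_id  status       suggestion
4      28   supraesophageal ganglion  brain         3         DISCOURAGED  brain
35     48   facetted eyes             compound eye  7         DISCOURAGED  compound eye

$ neurogloss annotate example.txt --rewrite
The brain bears compound eyes.
```

Other subcommands: `validate` (structural rules, exit 0 iff clean),
`register-check` (index reconciliation), `export --format obo|tsv`,
`fixtures --seed N` (random valid corpora for testing).

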