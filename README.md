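# compoundalign

Ternary compound matching for biomedical ontologies: given a **source**
ontology and **two target** ontologies, find mappings of the form

```
source class  ≡  target-1 class  ∩  target-2 class
```

for example "Aortic valve stenosis" (HP:0001650) ≡ "aortic valve"
(FMA:7236) ∩ "constricted" (PATO:0001847). Phenotype ontologies (HP, MP,
WBP, crop trait ontologies) are full of such composed classes whose parts
live in anatomy ontologies (FMA, UBERON, CL, PO) and the quality ontology
PATO; ternary mappings make that structure explicit, which supports
cross-ontology data integration and suggests candidate genus–differentia
logical definitions for classes that lack them.

## The method

Each ontology's class labels and synonyms are normalized to bags of
Porter-stemmed words. Every word *w* is weighted per ontology by its
**Evidence Content**

```
EC(w) = 1 − log f(w) / log(T + 1)
```

where *f(w)* is the word's frequency over all names of that ontology and
*T* the total stem count: a word occurring once has EC = 1, ubiquitous
words carry little evidence. Matching then proceeds in three steps:

1. **First-pass recall selection.** For source label *l_s* and target-1
   label *l_t1*,
   `sim₁ = Σ EC(w ∈ l_s ∩ l_t1) / Σ EC(w ∈ l_t1)`,
   scaled by the two names' scope weights; pairs with sim₁ ≥ T₁
   (default 0.4) survive.
2. **Search-space reduction.** Words already matched by the target-1
   partner are removed from the source label ("aortic valve stenosis" →
   "stenosis"); fully consumed labels — binary-equivalence candidates —
   are dropped.
3. **Longest-match precision selection.** The residual is matched against
   target-2 names with
   `sim₂ = Σ EC(w ∈ l_s* ∩ l_t2) / Σ EC(w ∈ longest(l_s*, l_t2))`,
   and the final similarity `(sim₁ + sim₂)/2` must reach T₂
   (default 0.9).

Greedy **top-one / top-two ranked selectors** enforce source-side
cardinality. Reference alignments for evaluation are derived from OBO
`intersection_of` logical definitions whose two fillers come from the two
target namespaces, and alignments are scored by precision, recall and
F-measure with unordered target pairs.

## Worked example

```sh
compound-align match -s hp.obo -1 fma.obo -2 pato.obo --selector top1 -o aln.tsv
```

On a miniature HP/FMA/PATO triple (see `compoundalign.examples`) this
prints `2 compound mappings -> aln.tsv`, and the TSV contains:

```
source_id   source_label           target1_id  target1_label  target2_id    target2_label    relation      mapping      sim1  sim2  similarity
HP:0000337  Broad forehead         FMA:63864   forehead       PATO:0000600  increased width  intersection  equivalence  1.0   1.0   1.0
HP:0001650  Aortic valve stenosis  FMA:7236    aortic valve   PATO:0001847  constricted      intersection  equivalence  1.0   1.0   1.0
```

Both phenotype labels decompose perfectly: the anatomy part matches the
FMA label exactly (sim₁ = 1.0), and the residual word matches a PATO label
or exact synonym ("stenosis" → "constricted", "broad" → "increased
width"), giving sim₂ = 1.0 and a final similarity of 1.0.

Other subcommands: `select` (top-k selection), `build-reference` (gold
standard from logical definitions), `evaluate` (precision/recall/F,
optional correct/missing/conflict categorization), `sweep` (threshold
grids), `patterns` (lexical pattern distribution of a binary alignment),
`suggest-defs` (candidate logical definitions), and `synth` (synthetic
ontology triples with embedded ground truth). `compound-align
--show-config` prints all defaults.

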