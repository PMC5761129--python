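# Methods

## Problem and model

Classical ontology matching produces binary equivalences between two
ontologies. Composed classes — "aortic valve stenosis", "absent thoracic
vertebrae", "leaf length" — cannot be expressed that way: their meaning is
an intersection of an entity from one ontology and a quality from another.
This package finds **ternary compound mappings** `<X, Y, Z, R, M>` where X
is a source-ontology class, Y and Z are classes from two distinct target
ontologies, R is always an intersection (any relation qualifier on the
parts is deliberately ignored) and M an equivalence. An alignment is a set
of such mappings; before selection a source class may participate in
several.

Matching is purely lexical, over bags of words. Assumptions this entails:

* composed source labels contain the words of their parts (possibly
  inflected, reordered, or replaced by synonyms);
* word order carries no meaning (a known limitation: "T-cell dependent
  B-cell activation"-style inversions are indistinguishable);
* every name is in one language (English).

## Lexical normalization and word weighting

Every class contributes one *name* per label and per synonym. Names are
lowercased, split on non-alphanumerics, stop words are removed (a small
fixed English list — articles, common prepositions — configurable off),
tokens are stemmed with an in-package implementation of the classic Porter
algorithm, and stems are deduplicated per name (set semantics: the
similarity sums below range over distinct words, not occurrences).

Each name carries a multiplicative weight by scope: LABEL 1.0, EXACT 1.0,
NARROW 0.9, BROAD 0.9, RELATED 0.8. The *plant* profile raises NARROW to
1.0, because crop and trait ontologies put most of their usable
vocabulary in narrow synonyms and the default discount suppresses
otherwise correct mappings. All weights are configurable.

Word evidence: for a stem with frequency *f* among an ontology's names and
a total of *T* stem occurrences in that ontology,

```
EC = 1 − log f / log(T + 1).
```

The defining requirements are EC ∈ (0, 1], EC = 1 exactly for
single-occurrence words, and strict decrease with frequency; this
normalization satisfies all three and is pinned by tests (e.g.
EC(10, 99) = 0.5). Frequencies are counted per ontology independently, so
the same word can weigh differently in two ontologies — evidence reflects
usage within the ontology that owns the name.

## The three matching steps

**Step 1 (recall).** All (source name, target-1 name) pairs sharing at
least one stem are scored `sim₁ = Σ EC(shared) / Σ EC(l_t1)`, with EC
taken from the target-1 index (the ontology owning the denominator), then
scaled by the two name weights. Per class pair only the best name pair is
kept; pairs below T₁ are discarded. The denominator being the target
name makes sim₁ = 1 whenever the target-1 label is fully contained in the
source label — the signature of a composed class.

**Step 2 (reduction).** Each surviving mapping's source name loses the
stems shared with its matched target-1 name; the remainder is the
*residual*. The residual is computed against the specific winning target-1
name, not the union of all matches, so "aortic valve stenosis" reduces
exactly to "stenosis". Empty residuals are dropped: a fully consumed label
indicates binary equivalence, which a compound alignment must not contain.

**Step 3 (precision).** Residuals are scored against target-2 names with
the longer of the two bags (unique-stem count) as denominator, which
demands an essentially complete match. Interpretation choices made here:
the "source" side of the comparison is the *reduced* bag (using the
unreduced label would suppress nearly all compound mappings, since step 2
just removed its anatomy words); on a length tie the target-2 bag is the
denominator; and EC comes from the index of the ontology owning the
denominator bag, consistent with step 1. The final similarity is the
arithmetic mean of sim₁ and sim₂, thresholded at T₂. Threshold
comparisons use a 1e−12 slack so that exact boundary cases (e.g. an
average of exactly 0.9 computed in floating point) are not lost to
rounding.

Defaults T₁ = 0.4 and T₂ = 0.9: a permissive first pass keeps recall
(and bounds runtime — raising T₁ shrinks the step-3 search space), a
strict final filter keeps precision. `threshold_sweep` reproduces the
selection protocol: per T₁ it reports first-pass recall against the
reference binarized onto target 1 plus mapping counts and wall time
(min-max normalized over the grid so differently sized ontology sets can
be averaged; a constant column or single-point grid normalizes
degenerately to 0 and is flagged); per (T₁, T₂) it scores the full
algorithm. No test asserts on wall time — it is hardware-dependent and
reported only for protocol parity.

The algorithm is formally symmetric in the targets but not in practice:
which ontology is matched first changes the residuals. The quality-like
ontology (PATO) belongs last; the alignment provenance records the order,
thresholds and a configuration digest.

## Selection, evaluation, candidate definitions

The top-one/top-two selectors sort by descending similarity and greedily
accept mappings while a source class has fewer than k. Equal-similarity
ties are broken by ascending (Y, Z) CURIE pair — deterministic and
reproducible — with `tie_break="random"` (seedable) as an escape hatch
mirroring arbitrary-choice behaviour. Only source cardinality is
constrained; target classes may repeat.

Reference alignments are built from `intersection_of` logical definitions
with exactly two elements whose fillers carry the two target prefixes, in
either genus/differentia role, relation qualifiers ignored. Longer
definitions, or definitions with same-namespace or source-namespace
fillers, are routed to a `non_ternary` set (conservation:
|mappings| + |non_ternary| = number of defined terms). Scoring treats
target pairs as unordered — intersection commutes — and counts each
reference mapping at most once, so precision·|A| and recall·|R| are
integers. `categorize` splits an alignment into correct (pair matches),
conflict (source in reference, pair differs) and missing (source absent);
`suggest_logical_definitions` inverts the perspective, reporting mappings
for undefined classes as *new* candidates and disagreeing mappings as
*conflicts* (flagged non-ternary when the stored definition is not itself
a two-foreign-class intersection).

Pattern classification (addition / variation / combination / full match /
synonym) runs on raw tokens with stop words retained, because the
inflections and function words it counts are exactly what stemming and
stop-word removal erase. Precedence when several definitions could fire:
full match > addition > variation > combination > synonym > none; the
synonym label applies only when the mapping was established through a
synonym name and no label-level pattern holds. The bundled
`string_similarity` is a plain difflib character ratio — a convenience for
producing binary alignments to classify, not a canonical matcher.

## Synthetic data

The generator emulates the lexical structure the matcher targets:
target 1 is anatomy-like (labels = one shared positional filler word +
one unique pseudo-Latin token), target 2 is quality-like (unique
single-word labels with 1–2 scoped synonyms), and each source label is
the concatenation of its anatomy label and quality word. Shared fillers
are frequent and get low EC; unique tokens are hapaxes with EC 1 —
exercising the weighting. Each source term embeds its true pair as an
`intersection_of` definition, so the generator's truth file and the
reference builder must agree by construction.

Noise parameters map to the lexical patterns: `p_add` appends one token
drawn from a vocabulary disjoint from both targets (so zero-noise
perfect precision is provable, not incidental), `p_var` pluralizes one
token (stemmable, so matching survives), `p_syn` swaps the quality label
for one of its synonyms. Generation is a pure function of the spec;
identical seeds give byte-identical files. Defaults (n = 200 source
classes, 40 qualities, noise 0) are the baseline study condition; tests
use 25–60 classes to keep the suite fast.

What the generator does **not** emulate: real synonym abundance and
irregular morphology, word-order variation, multi-word qualities,
cross-ontology vocabulary leakage, and any graph structure (the matcher is
purely lexical, so hierarchies are irrelevant to it). Perfect zero-noise
recovery therefore demonstrates correctness of the pipeline mechanics,
not expected performance on real ontology releases, where recall is
limited by exactly the phenomena excluded here.

## Numerical and degenerate-input choices

* Similarities are exact ratios of EC sums; the indexed matcher is
  required (and tested) to agree with a brute-force all-pairs
  implementation to 1e−12.
* Best-name-pair ties within a class pair break lexicographically on
  (text, scope) of the names, keeping results independent of input file
  order.
* Empty alignments score precision 0 with a warning (rather than NaN);
  empty references score recall 0 likewise. F is 0 when P = R = 0.
* Names consisting only of stop words/punctuation are dropped from the
  lexicon with a warning; ontologies with no active terms are an error.
* Unknown synonym scopes parse as RELATED with a warning; a single-element
  `intersection_of` is kept but warned about and never becomes a
  reference mapping.

## Known limitations

Word order is ignored; multi-token residuals must be covered almost
entirely by one target-2 name; no external background knowledge is used;
binary equivalences between source and a target are dropped rather than
reported; relations other than intersection (e.g. location) are out of
scope; OWL input must be converted to OBO first.
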