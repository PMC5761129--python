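"""Synthetic ontology triples with embedded compound ground truth.

Generates a source ontology whose class labels are noisy compositions of one
anatomy-like target-1 label and one quality-like target-2 name — the
structure of entity-quality phenotype labels such as "aortic valve stenosis"
= "aortic valve" + "constricted". Each source term also carries an
``intersection_of`` logical definition naming its true target pair, so the
reference builder recovers the ground truth from the generated file itself.

Noise emulates the lexical patterns seen between real phenotype and
anatomy/quality ontologies:

* ``p_add`` — an extra token (from a vocabulary disjoint from both targets)
  is appended to the source label (the "addition" pattern);
* ``p_var`` — one token is inflected with a stemmable plural suffix
  (the "variation" pattern);
* ``p_syn`` — the quality part uses a synonym of the target-2 class instead
  of its label (the "synonym" pattern).

Anatomy labels share a small pool of positional filler words (dorsal,
ventral, ...) so that Evidence Content weighting is exercised: fillers are
frequent and weigh little, discriminative words are rare and weigh much.
Generation is a pure function of the spec — the same seed yields
byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from compoundalign.obo_io import IntersectionElement, OntologyModel, Term, write_obo
from compoundalign.reference_builder import ReferenceAlignment, build_reference, write_reference

SOURCE_PREFIX = "SRC"
ANATOMY_PREFIX = "ANAT"
QUALITY_PREFIX = "QUAL"

_ANATOMY_FILLERS = ["dorsal", "ventral", "lateral", "medial",
                    "distal", "proximal", "apical", "basal"]
_ANATOMY_ONSETS = ["cardi", "nephr", "derm", "neur", "oste", "hepat",
                   "pulmon", "gastr", "chondr", "angi", "cephal", "splen"]
_ANATOMY_CODAS = ["olobe", "iduct", "osome", "ineme", "ovilla", "icrest"]
_QUALITY_ONSETS = ["vel", "tor", "mir", "gal", "ser", "dol", "fen", "lum", "bar", "cin"]
_QUALITY_CODAS = ["ate", "ine", "escent", "iform", "oid", "al"]
_SYNONYM_SCOPES = ["EXACT", "NARROW", "RELATED"]


def _word_list(onsets: list[str], codas: list[str], n: int) -> list[str]:
    """First n pseudo-words from the onset × coda product, extended numerically."""
    base = [o + c for o in onsets for c in codas]
    words = list(base)
    i = 2
    while len(words) < n:
        words.extend(f"{w}{i}" for w in base)
        i += 1
    return words[:n]


@dataclass(frozen=True)
class SynthSpec:
    """Generation parameters; a pure function of these yields the triple."""

    n_source: int = 200
    anatomy_vocab_size: int = 200
    quality_vocab_size: int = 40
    p_add: float = 0.0
    p_var: float = 0.0
    p_syn: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_add, self.p_var, self.p_syn):
            if not (0.0 <= p <= 1.0):
                raise ValueError("noise probabilities must lie in [0, 1]")
        if self.n_source < 1:
            raise ValueError("n_source must be positive")
        if self.anatomy_vocab_size < self.n_source:
            raise ValueError(
                "anatomy_vocab_size must be >= n_source (one distinct anatomy "
                "class per source class)"
            )
        if self.quality_vocab_size < 1:
            raise ValueError("quality_vocab_size must be positive")


def generate_models(spec: SynthSpec) -> tuple[OntologyModel, OntologyModel,
                                              OntologyModel, ReferenceAlignment]:
    """Build the three ontology models and the embedded ground-truth reference."""
    rng = random.Random(spec.seed)

    anatomy = OntologyModel(ontology_id="anat")
    anat_uniques = _word_list(_ANATOMY_ONSETS, _ANATOMY_CODAS, spec.anatomy_vocab_size)
    anat_ids = []
    for i, uniq in enumerate(anat_uniques, start=1):
        filler = rng.choice(_ANATOMY_FILLERS)
        tid = f"{ANATOMY_PREFIX}:{i:07d}"
        anatomy.add(Term(id=tid, label=f"{filler} {uniq}"))
        anat_ids.append(tid)

    quality = OntologyModel(ontology_id="qual")
    qual_uniques = _word_list(_QUALITY_ONSETS, _QUALITY_CODAS, spec.quality_vocab_size * 3)
    qual_ids = []
    syn_tokens: dict[str, list[tuple[str, str]]] = {}
    for i in range(spec.quality_vocab_size):
        tid = f"{QUALITY_PREFIX}:{i + 1:07d}"
        label, syn_a, syn_b = qual_uniques[3 * i: 3 * i + 3]
        n_syn = rng.randint(1, 2)
        syns = [(syn_a, rng.choice(_SYNONYM_SCOPES)), (syn_b, rng.choice(_SYNONYM_SCOPES))][:n_syn]
        quality.add(Term(id=tid, label=label, synonyms=syns))
        qual_ids.append(tid)
        syn_tokens[tid] = syns

    noise_words = _word_list(["zyx", "zyg", "zyd"], ["ora", "ulo", "eni", "api"],
                             spec.n_source)

    source = OntologyModel(ontology_id="src")
    anat_order = list(range(spec.anatomy_vocab_size))
    rng.shuffle(anat_order)
    for i in range(spec.n_source):
        a_idx = anat_order[i]
        q_idx = rng.randrange(spec.quality_vocab_size)
        anat_id, qual_id = anat_ids[a_idx], qual_ids[q_idx]
        anat_label = anatomy.terms[anat_id].label
        qual_part = quality.terms[qual_id].label
        if syn_tokens[qual_id] and rng.random() < spec.p_syn:
            qual_part = rng.choice(syn_tokens[qual_id])[0]
        tokens = anat_label.split() + [qual_part]
        if rng.random() < spec.p_var:
            j = rng.randrange(len(tokens))
            tokens[j] = tokens[j] + "s"  # stemmable plural inflection
        if rng.random() < spec.p_add:
            tokens.append(noise_words[i])
        source.add(Term(
            id=f"{SOURCE_PREFIX}:{i + 1:07d}",
            label=" ".join(tokens),
            intersection_of=[
                IntersectionElement(filler=qual_id),
                IntersectionElement(relation="inheres_in", filler=anat_id),
            ],
        ))

    truth = build_reference(source, ANATOMY_PREFIX, QUALITY_PREFIX)
    return source, anatomy, quality, truth


def generate(spec: SynthSpec, out_dir: str | Path) -> tuple[Path, Path, Path, Path]:
    """Write source.obo, target1.obo, target2.obo and truth.tsv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    source, anatomy, quality, truth = generate_models(spec)
    paths = (out / "source.obo", out / "target1.obo", out / "target2.obo",
             out / "truth.tsv")
    write_obo(source, paths[0])
    write_obo(anatomy, paths[1])
    write_obo(quality, paths[2])
    labels = {t.id: t.label for t in anatomy.terms.values()}
    labels.update({t.id: t.label for t in quality.terms.values()})
    write_reference(truth, paths[3], target_labels=labels)
    return paths
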