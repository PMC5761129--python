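"""Three-step ternary compound matching.

Produces mappings of the form ``X ≡ Y ∩ Z`` where X is a source-ontology
class and Y, Z are classes from two distinct target ontologies:

1. *First-pass recall selection* — EC-weighted bag-of-words matching of
   source names against target-1 names; the similarity is the EC mass of the
   shared words over the EC mass of the target-1 name, so a target-1 name
   fully contained in a source name scores 1. A low threshold T1 keeps
   recall high.
2. *Search-space reduction* — drops unmapped source classes and removes from
   each mapped source name the words already matched by its target-1
   partner, leaving the residual words ("aortic valve stenosis" matched to
   "aortic valve" leaves "stenosis"). A fully consumed source name is a
   binary-equivalence candidate, not a compound one, and is dropped.
3. *Longest-match precision selection* — matches the residual against
   target-2 names, with the EC mass of the longer of the two bags as the
   denominator to demand a complete match; the final similarity is the mean
   of the two step similarities, filtered at a high threshold T2.

Matching is purely lexical and deterministic; the target order matters in
practice (quality-like ontologies such as PATO are best placed last), so the
alignment records the order used in its provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from compoundalign.config import MatchConfig
from compoundalign.lexicon import Lexicon, Name, WordBag, build_lexicon
from compoundalign.obo_io import OntologyModel

logger = logging.getLogger(__name__)

INTERSECTION = "intersection"
EQUIVALENCE = "equivalence"


@dataclass(frozen=True)
class BinaryMapping:
    """A step-1 source/target-1 candidate, later annotated with its residual."""

    source: str
    target: str
    source_name: Name
    target_name: Name
    sim1: float
    residual: WordBag | None = None


@dataclass(frozen=True)
class CompoundMapping:
    """Ternary mapping <X, Y, Z, intersection, equivalence> with its similarities."""

    x: str
    y: str
    z: str
    sim1: float
    sim2: float
    similarity: float
    relation: str = INTERSECTION
    mapping: str = EQUIVALENCE
    x_label: str = ""
    y_label: str = ""
    z_label: str = ""

    @property
    def key(self) -> tuple[str, frozenset[str]]:
        """Scoring key: source class and UNORDERED target pair (∩ commutes)."""
        return (self.x, frozenset((self.y, self.z)))


@dataclass(frozen=True)
class Provenance:
    source_id: str = ""
    target1_id: str = ""
    target2_id: str = ""
    t1: float | None = None
    t2: float | None = None
    config_digest: str = ""


@dataclass
class CompoundAlignment:
    """A set of compound mappings; before selection, a source class may carry many."""

    mappings: list[CompoundMapping] = field(default_factory=list)
    provenance: Provenance = field(default_factory=Provenance)

    def __len__(self) -> int:
        return len(self.mappings)

    def __iter__(self):
        return iter(self.mappings)


def _name_pair_order(source_name: Name, target_name: Name) -> tuple:
    # deterministic tie-break among equal-similarity name pairs
    return (source_name.text, source_name.scope, target_name.text, target_name.scope)


def similarity_step1(source_stems: frozenset[str], target_stems: frozenset[str],
                     target_ec: dict | "object") -> float:
    """EC mass of the shared words over the EC mass of the target-1 name.

    ``target_ec`` maps stems to EC values (a dict or a WordIndex); every
    target stem is present in its own ontology's index by construction.
    """
    shared = source_stems & target_stems
    if not shared:
        return 0.0
    ec = target_ec.ec if hasattr(target_ec, "ec") else target_ec.__getitem__
    num = sum(ec(w) for w in shared)
    den = sum(ec(w) for w in target_stems)
    return num / den


def similarity_step3(residual_stems: frozenset[str], target_stems: frozenset[str],
                     source_ec, target_ec) -> float:
    """Shared EC mass over the EC mass of the LONGER bag (complete-match bias).

    "Longer" counts unique stems; on a tie the target-2 bag is the
    denominator, and the EC index of the ontology owning the denominator bag
    supplies all EC values.
    """
    shared = residual_stems & target_stems
    if not shared:
        return 0.0
    if len(residual_stems) > len(target_stems):
        denom_bag, idx = residual_stems, source_ec
    else:
        denom_bag, idx = target_stems, target_ec
    ec = idx.ec if hasattr(idx, "ec") else idx.__getitem__
    num = sum(ec(w) for w in shared)
    den = sum(ec(w) for w in denom_bag)
    return num / den


def step1_recall_selection(source_lex: Lexicon, target1_lex: Lexicon,
                           t1: float) -> list[BinaryMapping]:
    """Match every source name against target-1 names sharing at least one stem.

    Per (source class, target class) pair only the best-scoring name pair is
    kept (deterministic tie-break on name texts), and only pairs with
    weighted similarity ≥ T1 survive.
    """
    if not (0.0 < t1 <= 1.0):
        raise ValueError("T1 must lie in (0, 1]")
    if not source_lex.names or not target1_lex.names:
        raise ValueError("cannot match with an empty lexicon")

    best: dict[tuple[str, str], tuple[float, Name, Name]] = {}
    index = target1_lex.index
    for s_name in source_lex.names:
        candidates: set[tuple[str, Name]] = set()
        for stem in s_name.normalized.stems:
            if stem in index:
                candidates.update(index.entries[stem].postings)
        for t_term, t_name in candidates:
            raw = similarity_step1(s_name.normalized.stems, t_name.normalized.stems, index)
            sim = raw * s_name.weight * t_name.weight
            if sim <= 0.0:
                continue
            key = (s_name.term, t_term)
            prev = best.get(key)
            if prev is None or (sim, ) > (prev[0], ) or (
                sim == prev[0]
                and _name_pair_order(s_name, t_name) < _name_pair_order(prev[1], prev[2])
            ):
                best[key] = (sim, s_name, t_name)

    out = [
        BinaryMapping(source=s, target=t, source_name=sn, target_name=tn, sim1=sim)
        for (s, t), (sim, sn, tn) in best.items()
        if sim >= t1 - 1e-12
    ]
    out.sort(key=lambda m: (m.source, m.target))
    logger.info("step 1: %d candidate binary mappings at T1=%.2f", len(out), t1)
    return out


def reduce_search_space(candidates: list[BinaryMapping]) -> list[BinaryMapping]:
    """Annotate each surviving mapping with its residual word bag.

    The residual is the source name's stems minus those shared with its
    matched target-1 name. Mappings whose source name is fully consumed are
    dropped: they indicate binary equivalence rather than a compound concept.
    Source classes without any step-1 mapping are implicitly dropped.
    """
    reduced: list[BinaryMapping] = []
    for m in candidates:
        s_bag = m.source_name.normalized
        shared = s_bag.stems & m.target_name.normalized.stems
        residual_stems = s_bag.stems - shared
        if not residual_stems:
            continue
        # raw tokens whose stem survived, in original order
        raw = tuple(
            tok for tok in s_bag.raw_tokens
            if _stem_lookup(tok, s_bag) in residual_stems
        )
        residual = WordBag(stems=frozenset(residual_stems), raw_tokens=raw)
        reduced.append(replace(m, residual=residual))
    logger.info("step 2: %d mappings with non-empty residuals", len(reduced))
    return reduced


def _stem_lookup(token: str, bag: WordBag) -> str:
    # a token's stem is whichever bag stem it maps to; bags are built with the
    # same tokenizer, so re-stemming is consistent
    from compoundalign.stemming import porter_stem

    stem = porter_stem(token)
    return stem if stem in bag.stems else token


def step3_precision_selection(reduced: list[BinaryMapping], source_lex: Lexicon,
                              target2_lex: Lexicon, t2: float,
                              provenance: Provenance | None = None) -> CompoundAlignment:
    """Match residuals against target-2 names and emit compound mappings.

    The final similarity is the mean of the step-1 and step-3 similarities;
    mappings below T2 are filtered. Per (X, Y, Z) triple the best-scoring
    name combination is kept.
    """
    if not (0.0 < t2 <= 1.0):
        raise ValueError("T2 must lie in (0, 1]")
    index = target2_lex.index
    best: dict[tuple[str, str, str], tuple[float, float, float, tuple]] = {}
    for m in reduced:
        if m.residual is None:
            raise ValueError("step 3 requires reduced mappings (run reduce_search_space)")
        candidates: set[tuple[str, Name]] = set()
        for stem in m.residual.stems:
            if stem in index:
                candidates.update(index.entries[stem].postings)
        for z_term, z_name in candidates:
            raw = similarity_step3(
                m.residual.stems, z_name.normalized.stems,
                source_lex.index, index,
            )
            sim2 = raw * m.source_name.weight * z_name.weight
            if sim2 <= 0.0:
                continue
            similarity = (m.sim1 + sim2) / 2.0
            if similarity < t2 - 1e-12:
                continue
            key = (m.source, m.target, z_term)
            order = _name_pair_order(m.source_name, z_name)
            prev = best.get(key)
            if prev is None or similarity > prev[2] or (
                similarity == prev[2] and order < prev[3]
            ):
                best[key] = (m.sim1, sim2, similarity, order)

    mappings = [
        CompoundMapping(
            x=x, y=y, z=z, sim1=s1, sim2=s2, similarity=sim,
            x_label=source_lex.labels.get(x, ""),
            y_label="",  # filled by match_compound, which holds target-1 labels
            z_label=target2_lex.labels.get(z, ""),
        )
        for (x, y, z), (s1, s2, sim, _) in best.items()
    ]
    mappings.sort(key=lambda m: (m.x, m.y, m.z))
    logger.info("step 3: %d compound mappings at T2=%.2f", len(mappings), t2)
    return CompoundAlignment(mappings=mappings, provenance=provenance or Provenance())


def match_compound(source: OntologyModel, target1: OntologyModel,
                   target2: OntologyModel, config: MatchConfig | None = None,
                   ) -> CompoundAlignment:
    """Run the full three-step compound matching pipeline.

    The three ontologies must carry pairwise-distinct CURIE prefixes — a
    ternary mapping relates classes of three different ontologies. The
    matching order matters empirically; place the quality-like ontology
    (e.g. PATO) as target 2.
    """
    config = config or MatchConfig()
    prefixes = [source.prefix, target1.prefix, target2.prefix]
    if len(set(prefixes)) != 3:
        raise ValueError(
            f"the three ontologies must have pairwise-distinct prefixes, got {prefixes}"
        )
    source_lex = build_lexicon(source, config)
    target1_lex = build_lexicon(target1, config)
    target2_lex = build_lexicon(target2, config)
    logger.info(
        "matching %s -> %s ∩ %s (T1=%.2f, T2=%.2f)",
        source.ontology_id, target1.ontology_id, target2.ontology_id,
        config.t1, config.t2,
    )
    candidates = step1_recall_selection(source_lex, target1_lex, config.t1)
    reduced = reduce_search_space(candidates)
    provenance = Provenance(
        source_id=source.ontology_id,
        target1_id=target1.ontology_id,
        target2_id=target2.ontology_id,
        t1=config.t1, t2=config.t2,
        config_digest=config.digest(),
    )
    alignment = step3_precision_selection(reduced, source_lex, target2_lex,
                                          config.t2, provenance)
    # fill target-1 labels for explainability
    alignment.mappings = [
        replace(m, y_label=target1_lex.labels.get(m.y, "")) for m in alignment.mappings
    ]
    return alignment
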