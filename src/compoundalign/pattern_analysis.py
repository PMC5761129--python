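"""Lexical pattern classification for binary mappings.

An exploratory utility that classifies how the two class names of a binary
mapping relate lexically: one side has extra words (addition), one word is
substituted (variation), both at once (combination), identical word sets
(full match), or the match only exists through a synonym name (synonym).
Classification runs on RAW lowercased tokens — no stemming, stop words
retained — because inflectional variants ("cells"/"cell") are themselves
part of the patterns being counted.
"""

from __future__ import annotations

import difflib
import re
from collections import Counter
from enum import Enum

from compoundalign.compound_matcher import BinaryMapping
from compoundalign.lexicon import Lexicon, Name

_RAW_TOKEN_RE = re.compile(r"[a-z0-9]+")


class PatternLabel(str, Enum):
    ADDITION = "addition"
    VARIATION = "variation"
    COMBINATION = "combination"
    FULL_MATCH = "full_match"
    SYNONYM = "synonym"
    NONE = "none"


def raw_tokens(text: str) -> frozenset[str]:
    return frozenset(_RAW_TOKEN_RE.findall(text.lower()))


def _lexical_label(s: frozenset[str], t: frozenset[str]) -> PatternLabel:
    # precedence: FULL_MATCH > ADDITION > VARIATION > COMBINATION > NONE
    if s == t:
        return PatternLabel.FULL_MATCH
    if s < t or t < s:
        return PatternLabel.ADDITION
    only_s, only_t = s - t, t - s
    if len(s) == len(t) and len(only_s) == 1 and len(only_t) == 1:
        return PatternLabel.VARIATION
    if (s & t) and len(s) != len(t) and only_s and only_t:
        return PatternLabel.COMBINATION
    return PatternLabel.NONE


def classify_pattern(source_name: Name, target_name: Name,
                     via_synonym: bool = False) -> PatternLabel:
    """Classify the lexical relation between two class names.

    ``via_synonym`` marks that the mapping was established through a synonym
    name rather than the labels; it yields SYNONYM only when no label-level
    lexical pattern fires (lexical patterns take precedence).
    """
    if not source_name.text or not target_name.text:
        raise ValueError("pattern classification requires non-empty names")
    label = _lexical_label(raw_tokens(source_name.text), raw_tokens(target_name.text))
    if label is PatternLabel.NONE and via_synonym:
        return PatternLabel.SYNONYM
    return label


def classify_mapping(mapping: BinaryMapping, source_lex: Lexicon,
                     target_lex: Lexicon) -> PatternLabel:
    """Classify a binary mapping by comparing the two class LABELS.

    The matched names decide the ``via_synonym`` flag: if either side of the
    mapping is a synonym name, a label-level mismatch is classified SYNONYM.
    """
    s_label = source_lex.labels.get(mapping.source, mapping.source_name.text)
    t_label = target_lex.labels.get(mapping.target, mapping.target_name.text)
    via_syn = mapping.source_name.scope != "LABEL" or mapping.target_name.scope != "LABEL"
    label = _lexical_label(raw_tokens(s_label), raw_tokens(t_label))
    if label is PatternLabel.NONE and via_syn:
        return PatternLabel.SYNONYM
    return label


def pattern_distribution(mappings: list[BinaryMapping], source_lex: Lexicon,
                         target_lex: Lexicon) -> Counter:
    """Tabulate the pattern label of every mapping; counts sum to the input size."""
    counts: Counter = Counter({label: 0 for label in PatternLabel})
    for m in mappings:
        counts[classify_mapping(m, source_lex, target_lex)] += 1
    return counts


def best_name_pair(source_term: str, target_term: str, source_lex: Lexicon,
                   target_lex: Lexicon) -> BinaryMapping | None:
    """Reconstruct the best-scoring name pair for a given class pair.

    Scores every name combination of the two classes with the step-1
    similarity and returns the winner as a :class:`BinaryMapping`, or None
    when the classes share no stem under any name pair.
    """
    from compoundalign.compound_matcher import similarity_step1

    s_names = [n for n in source_lex.names if n.term == source_term]
    t_names = [n for n in target_lex.names if n.term == target_term]
    best: BinaryMapping | None = None
    best_key: tuple | None = None
    for sn in s_names:
        for tn in t_names:
            sim = similarity_step1(sn.normalized.stems, tn.normalized.stems,
                                   target_lex.index) * sn.weight * tn.weight
            if sim <= 0.0:
                continue
            key = (-sim, sn.text, sn.scope, tn.text, tn.scope)
            if best_key is None or key < best_key:
                best_key = key
                best = BinaryMapping(source=source_term, target=target_term,
                                     source_name=sn, target_name=tn, sim1=sim)
    return best


def string_similarity(a: str, b: str) -> float:
    """Normalized character-sequence similarity in [0, 1].

    A plain ratio over the longest matching blocks (difflib); a convenience
    for producing binary alignments to classify, not a canonical matcher.
    """
    if not a and not b:
        return 1.0
    return difflib.SequenceMatcher(None, a.lower(), b.lower()).ratio()
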