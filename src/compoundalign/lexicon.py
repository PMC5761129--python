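"""Per-ontology lexicon: weighted class names and a stem index with word
frequencies and Evidence Content (EC).

Every class label and synonym becomes a weighted :class:`Name` whose text is
normalized to a bag of stems. The :class:`WordIndex` inverts the names
(stem → postings) and assigns each stem an EC weight that decreases with its
frequency in the ontology's name corpus: rare words carry more matching
evidence than ubiquitous ones. Frequencies and EC are computed per ontology
independently — the same word may weigh differently in two ontologies.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from compoundalign.config import MatchConfig
from compoundalign.obo_io import OntologyModel
from compoundalign.stemming import porter_stem

logger = logging.getLogger(__name__)

_TOKEN_RE = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class WordBag:
    """Deduplicated stem set plus the ordered pre-stem tokens it came from."""

    stems: frozenset[str]
    raw_tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.stems)

    def __bool__(self) -> bool:
        return bool(self.stems)


@dataclass(frozen=True)
class Name:
    """One weighted name (label or synonym) of an ontology class."""

    term: str
    text: str
    normalized: WordBag
    scope: str  # LABEL or a synonym scope
    weight: float


@dataclass(frozen=True)
class WordEntry:
    frequency: int
    ec: float
    postings: frozenset[tuple[str, Name]]


@dataclass
class WordIndex:
    """Inverted stem index over all names of one ontology."""

    total_tokens: int
    entries: dict[str, WordEntry] = field(default_factory=dict)

    def ec(self, stem: str) -> float:
        return self.entries[stem].ec

    def __contains__(self, stem: str) -> bool:
        return stem in self.entries


@dataclass
class Lexicon:
    """Names and word index of one ontology, as used by the matcher."""

    ontology_id: str
    prefix: str
    names: list[Name]
    index: WordIndex
    labels: dict[str, str] = field(default_factory=dict)


def tokenize(text: str, config: MatchConfig | None = None) -> WordBag:
    """Normalize a name to a word bag.

    Lowercases, splits on whitespace/punctuation, drops configured stop
    words, stems with the Porter stemmer when stemming is enabled, and
    deduplicates stems. An empty input yields an empty bag.
    """
    config = config or MatchConfig()
    tokens = _TOKEN_RE.findall(text.lower())
    tokens = [t for t in tokens if t not in config.stop_words]
    stems = [porter_stem(t) for t in tokens] if config.stemming else tokens
    return WordBag(stems=frozenset(stems), raw_tokens=tuple(tokens))


def evidence_content(frequency: int, total_tokens: int) -> float:
    """EC of a word: 1 − log(f) / log(T + 1).

    ``f`` is the word's frequency and ``T`` the total stem occurrences in the
    ontology. The value lies in (0, 1], equals 1 exactly for a hapax word
    (f = 1) and strictly decreases as the frequency grows.
    """
    if frequency < 1 or frequency > total_tokens:
        raise ValueError(
            f"frequency must lie in [1, total_tokens]; got {frequency} / {total_tokens}"
        )
    return 1.0 - math.log(frequency) / math.log(total_tokens + 1)


def build_lexicon(model: OntologyModel, config: MatchConfig | None = None) -> Lexicon:
    """Build the weighted name table and stem index for one ontology.

    One :class:`Name` is created per (term, label) and per (term, synonym) of
    every non-obsolete term; names whose text reduces to an empty bag (only
    stop words/punctuation) are dropped with a warning.
    """
    config = config or MatchConfig()
    names: list[Name] = []
    labels: dict[str, str] = {}
    n_active = 0
    for term in model.active_terms():
        n_active += 1
        labels[term.id] = term.label
        candidates = []
        if term.label:
            candidates.append((term.label, "LABEL"))
        candidates.extend(term.synonyms)
        for text, scope in candidates:
            bag = tokenize(text, config)
            if not bag:
                logger.warning("name %r of %s has no content words; dropped", text, term.id)
                continue
            names.append(
                Name(term=term.id, text=text, normalized=bag,
                     scope=scope, weight=config.weight(scope))
            )
    if n_active == 0:
        raise ValueError(f"ontology {model.ontology_id!r} has no non-obsolete terms")

    counts: dict[str, int] = {}
    postings: dict[str, set[tuple[str, Name]]] = {}
    for name in names:
        for stem in name.normalized.stems:
            counts[stem] = counts.get(stem, 0) + 1
            postings.setdefault(stem, set()).add((name.term, name))
    total = sum(counts.values())
    index = WordIndex(total_tokens=total)
    for stem, freq in counts.items():
        index.entries[stem] = WordEntry(
            frequency=freq,
            ec=evidence_content(freq, total),
            postings=frozenset(postings[stem]),
        )
    return Lexicon(
        ontology_id=model.ontology_id,
        prefix=model.prefix,
        names=names,
        index=index,
        labels=labels,
    )
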