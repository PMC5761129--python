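"""Reader/writer for the subset of the OBO 1.4 flat-file format the matcher needs.

Only the tags the matching algorithms consume are interpreted: ``id``,
``name``, ``synonym``, ``intersection_of``, ``is_obsolete`` and ``namespace``.
Every other tag, and every non-``[Term]`` stanza, is ignored. OWL/RDF input is
out of scope; OBO Foundry ontologies are distributed in this format.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

logger = logging.getLogger(__name__)

SYNONYM_SCOPES = ("EXACT", "NARROW", "BROAD", "RELATED")

#: synonym tag value: quoted text, optional scope keyword, optional xref list
_SYNONYM_RE = re.compile(r'^"(?P<text>.*)"\s*(?P<scope>[A-Z_]+)?\s*(?:\[.*\])?\s*$')


class OboParseError(ValueError):
    """Raised for a structurally invalid stanza (e.g. a [Term] without an id)."""


@dataclass(frozen=True)
class IntersectionElement:
    """One element of a genus-differentia logical definition.

    The first element of an ``intersection_of`` block is the genus and carries
    no relation; later elements (differentiae) may carry one, e.g.
    ``intersection_of: inheres_in CL:0000601``.
    """

    filler: str
    relation: str | None = None


@dataclass
class Term:
    id: str
    label: str = ""
    synonyms: list[tuple[str, str]] = field(default_factory=list)
    intersection_of: list[IntersectionElement] = field(default_factory=list)
    obsolete: bool = False
    namespace: str | None = None

    @property
    def prefix(self) -> str:
        return self.id.split(":", 1)[0]


@dataclass
class OntologyModel:
    """Parsed OBO content: terms with labels, scoped synonyms and logical definitions."""

    ontology_id: str
    terms: dict[str, Term] = field(default_factory=dict)

    @property
    def prefix(self) -> str:
        """Majority CURIE prefix of the term ids (mixed-prefix files keep the majority)."""
        counts = Counter(t.prefix for t in self.terms.values())
        if not counts:
            return self.ontology_id.upper()
        return counts.most_common(1)[0][0]

    def add(self, term: Term) -> None:
        if term.id in self.terms:
            raise ValueError(f"duplicate term id {term.id!r}")
        self.terms[term.id] = term

    def active_terms(self) -> Iterable[Term]:
        """Terms that participate in matching and reference building (non-obsolete)."""
        return (t for t in self.terms.values() if not t.obsolete)

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OntologyModel):
            return NotImplemented
        return self.ontology_id == other.ontology_id and self.terms == other.terms


def _strip_comment(value: str) -> str:
    # OBO trailing comments: " ! free text"
    idx = value.find(" !")
    return (value[:idx] if idx >= 0 else value).strip()


def _parse_synonym(value: str, lineno: int) -> tuple[str, str]:
    m = _SYNONYM_RE.match(value.strip())
    if not m:
        raise OboParseError(f"line {lineno}: malformed synonym tag: {value!r}")
    scope = m.group("scope") or "RELATED"
    if scope not in SYNONYM_SCOPES:
        logger.warning("line %d: unknown synonym scope %r treated as RELATED", lineno, scope)
        scope = "RELATED"
    return m.group("text"), scope


def _parse_intersection(value: str) -> IntersectionElement:
    parts = _strip_comment(value).split()
    if len(parts) == 1:
        return IntersectionElement(filler=parts[0])
    return IntersectionElement(relation=parts[0], filler=parts[1])


def parse_obo(path: str | Path) -> OntologyModel:
    """Parse an OBO 1.4 flat file into an :class:`OntologyModel`.

    Raises :class:`OboParseError` for a [Term] stanza without an ``id`` tag,
    naming the offending line. Unknown synonym scopes degrade to RELATED with
    a warning; tags outside the consumed subset are skipped silently.
    """
    path = Path(path)
    ontology_id = path.stem
    model = OntologyModel(ontology_id=ontology_id)

    in_term = False
    ignored_stanza = False
    current: dict | None = None
    stanza_line = 0

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        if "id" not in current:
            raise OboParseError(f"line {stanza_line}: [Term] stanza is missing an id tag")
        term = Term(
            id=current["id"],
            label=current.get("name", ""),
            synonyms=current.get("synonyms", []),
            intersection_of=current.get("intersection_of", []),
            obsolete=current.get("obsolete", False),
            namespace=current.get("namespace"),
        )
        if len(term.intersection_of) == 1:
            logger.warning("term %s has a single intersection_of element", term.id)
        model.add(term)
        current = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("["):
                flush()
                in_term = line.strip() == "[Term]"
                ignored_stanza = not in_term
                if in_term:
                    current = {}
                    stanza_line = lineno
                continue
            if ignored_stanza:
                continue
            if ":" not in line:
                continue
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.strip()
            if current is None:
                # header clause
                if tag == "ontology":
                    model.ontology_id = _strip_comment(value)
                continue
            if tag == "id":
                current["id"] = _strip_comment(value)
            elif tag == "name":
                current["name"] = value
            elif tag == "synonym":
                current.setdefault("synonyms", []).append(_parse_synonym(value, lineno))
            elif tag == "intersection_of":
                current.setdefault("intersection_of", []).append(_parse_intersection(value))
            elif tag == "is_obsolete":
                current["obsolete"] = value.split()[0].lower() == "true"
            elif tag == "namespace":
                current["namespace"] = _strip_comment(value)
    flush()
    return model


def write_obo(model: OntologyModel, path: str | Path) -> None:
    """Write a model back to an OBO flat file; the output re-parses to an equal model."""
    path = Path(path)
    lines = ["format-version: 1.4", f"ontology: {model.ontology_id}", ""]
    for term in model.terms.values():
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.label:
            lines.append(f"name: {term.label}")
        if term.namespace:
            lines.append(f"namespace: {term.namespace}")
        for text, scope in term.synonyms:
            lines.append(f'synonym: "{text}" {scope} []')
        for elem in term.intersection_of:
            if elem.relation:
                lines.append(f"intersection_of: {elem.relation} {elem.filler}")
            else:
                lines.append(f"intersection_of: {elem.filler}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
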