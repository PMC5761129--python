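"""Derive ternary compound reference alignments from OBO logical definitions.

A genus-differentia logical definition ("X is a G that D") whose genus and
differentia fillers come from two foreign ontologies is exactly a ternary
compound mapping X ≡ G ∩ D, so such definitions serve as a gold standard for
evaluating compound alignments. Definitions that are not two-foreign-class
intersections (more elements, or fillers from the wrong namespaces) are
recorded separately as non-ternary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from compoundalign.obo_io import OntologyModel

logger = logging.getLogger(__name__)


@dataclass
class ReferenceAlignment:
    """Gold-standard ternary mappings X → {Y, Z}, cardinality 1 per source class."""

    prefix1: str
    prefix2: str
    mappings: dict[str, frozenset[str]] = field(default_factory=dict)
    non_ternary: set[str] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)

    @property
    def pairs(self) -> set[tuple[str, frozenset[str]]]:
        """The mappings as a set of (X, unordered target pair) keys."""
        return {(x, pair) for x, pair in self.mappings.items()}

    def __len__(self) -> int:
        return len(self.mappings)


def build_reference(source: OntologyModel, prefix1: str, prefix2: str) -> ReferenceAlignment:
    """Select logical definitions that are two-foreign-class intersections.

    A term qualifies when its ``intersection_of`` has exactly two elements
    whose fillers carry the prefixes ``{prefix1, prefix2}`` in either role
    (genus or differentia; any relation qualifier on the differentia is
    ignored — the compound relation is always an intersection). Every other
    term with a logical definition is routed to ``non_ternary``.
    """
    src_prefix = source.prefix
    if len({src_prefix, prefix1, prefix2}) != 3:
        raise ValueError(
            f"target prefixes must be distinct from each other and from the "
            f"source prefix {src_prefix!r}"
        )
    wanted = {prefix1, prefix2}
    ref = ReferenceAlignment(prefix1=prefix1, prefix2=prefix2)
    for term in source.active_terms():
        if not term.intersection_of:
            continue
        ref.labels[term.id] = term.label
        fillers = [e.filler for e in term.intersection_of]
        filler_prefixes = {f.split(":", 1)[0] for f in fillers}
        if len(term.intersection_of) == 2 and filler_prefixes == wanted:
            ref.mappings[term.id] = frozenset(fillers)
        else:
            ref.non_ternary.add(term.id)
    logger.info(
        "reference from %s: %d ternary mappings, %d non-ternary definitions",
        source.ontology_id, len(ref.mappings), len(ref.non_ternary),
    )
    return ref


def binarize_reference(ref: ReferenceAlignment, keep_prefix: str) -> set[tuple[str, str]]:
    """Project each ternary reference mapping onto its target with ``keep_prefix``."""
    out: set[tuple[str, str]] = set()
    for x, pair in ref.mappings.items():
        for t in pair:
            if t.split(":", 1)[0] == keep_prefix:
                out.add((x, t))
    if ref.mappings and not out:
        logger.warning("prefix %r absent from every reference mapping", keep_prefix)
    return out


def _ordered_pair(pair: frozenset[str], prefix1: str) -> tuple[str, str]:
    a, b = sorted(pair)
    if a.split(":", 1)[0] == prefix1:
        return a, b
    return b, a


def write_reference(ref: ReferenceAlignment, path: str | Path,
                    target_labels: dict[str, str] | None = None) -> None:
    """Write a reference TSV (alignment schema without the similarity columns)."""
    target_labels = target_labels or {}
    rows = []
    for x in sorted(ref.mappings):
        y, z = _ordered_pair(ref.mappings[x], ref.prefix1)
        rows.append({
            "source_id": x, "source_label": ref.labels.get(x, ""),
            "target1_id": y, "target1_label": target_labels.get(y, ""),
            "target2_id": z, "target2_label": target_labels.get(z, ""),
            "relation": "intersection", "mapping": "equivalence",
        })
    cols = ["source_id", "source_label", "target1_id", "target1_label",
            "target2_id", "target2_label", "relation", "mapping"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_reference(path: str | Path) -> ReferenceAlignment:
    """Read a reference TSV written by :func:`write_reference`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("source_id", "target1_id", "target2_id"):
        if col not in df.columns:
            raise ValueError(f"reference file {path} is missing column {col!r}")
    prefixes1 = {t.split(":", 1)[0] for t in df["target1_id"]} if len(df) else set()
    prefixes2 = {t.split(":", 1)[0] for t in df["target2_id"]} if len(df) else set()
    ref = ReferenceAlignment(
        prefix1=sorted(prefixes1)[0] if prefixes1 else "",
        prefix2=sorted(prefixes2)[0] if prefixes2 else "",
    )
    for row in df.itertuples(index=False):
        d = row._asdict()
        ref.mappings[d["source_id"]] = frozenset((d["target1_id"], d["target2_id"]))
        if d.get("source_label"):
            ref.labels[d["source_id"]] = d["source_label"]
    return ref
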