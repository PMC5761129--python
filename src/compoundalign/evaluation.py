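"""Evaluation of compound alignments against reference alignments.

Provides precision/recall/F-measure scoring, the three-way correct /
missing / conflict categorization, logical-definition candidate reports,
and the two-threshold sweep protocol. Target pairs compare as unordered
sets throughout: an intersection is commutative, so <X, Y, Z> and
<X, Z, Y> denote the same mapping.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd

from compoundalign.compound_matcher import (
    CompoundAlignment,
    CompoundMapping,
    reduce_search_space,
    step1_recall_selection,
    step3_precision_selection,
)
from compoundalign.config import MatchConfig
from compoundalign.lexicon import build_lexicon
from compoundalign.obo_io import OntologyModel
from compoundalign.reference_builder import ReferenceAlignment, binarize_reference

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationReport:
    precision: float
    recall: float
    f_measure: float
    n_alignment: int
    n_reference: int
    n_intersection: int


@dataclass
class CategoryReport:
    """Three-way split of an alignment against a reference; the sets partition it."""

    correct: list[CompoundMapping] = field(default_factory=list)
    missing: list[CompoundMapping] = field(default_factory=list)
    conflict: list[CompoundMapping] = field(default_factory=list)


@dataclass(frozen=True)
class DefinitionConflict:
    mapping: CompoundMapping
    non_ternary: bool  # the stored definition is not a two-foreign-class intersection


@dataclass
class CandidateReport:
    """Logical-definition candidates suggested by a selected alignment."""

    new_definitions: list[CompoundMapping] = field(default_factory=list)
    conflicts: list[DefinitionConflict] = field(default_factory=list)


def f_measure(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def score(alignment: CompoundAlignment, reference: ReferenceAlignment) -> EvaluationReport:
    """Precision, recall and F-measure of an alignment against a reference.

    A mapping counts as matched when its source class and its unordered
    target pair both equal a reference entry; with a top-two alignment a
    reference mapping is counted at most once.
    """
    ref_pairs = reference.pairs
    align_keys = {m.key for m in alignment.mappings}
    n_int = len(align_keys & ref_pairs)
    n_a = len(alignment.mappings)
    n_r = len(reference)
    if n_a == 0:
        logger.warning("empty alignment: precision undefined, reported as 0")
    precision = n_int / n_a if n_a else 0.0
    recall = n_int / n_r if n_r else 0.0
    return EvaluationReport(
        precision=precision, recall=recall, f_measure=f_measure(precision, recall),
        n_alignment=n_a, n_reference=n_r, n_intersection=n_int,
    )


def categorize(alignment: CompoundAlignment, reference: ReferenceAlignment) -> CategoryReport:
    """Split an alignment into correct, missing and conflicting mappings.

    Correct mappings match a reference entry exactly; conflicting mappings
    have their source class in the reference but a different target pair;
    missing mappings have a source class absent from the reference.
    """
    report = CategoryReport()
    for m in alignment.mappings:
        pair = reference.mappings.get(m.x)
        if pair is None:
            report.missing.append(m)
        elif pair == frozenset((m.y, m.z)):
            report.correct.append(m)
        else:
            report.conflict.append(m)
    return report


def suggest_logical_definitions(alignment: CompoundAlignment,
                                source: OntologyModel) -> CandidateReport:
    """Report mappings as candidate logical definitions for the source ontology.

    A mapping whose source class has no logical definition is a *new*
    candidate; one whose class has a definition different from the mapped
    pair is a *conflict*, flagged non-ternary when the stored definition is
    not itself a two-foreign-class intersection. Mappings that agree with
    the stored definition are reported in neither list.
    """
    report = CandidateReport()
    src_prefix = source.prefix
    for m in alignment.mappings:
        term = source.terms.get(m.x)
        if term is None or term.obsolete:
            continue
        if not term.intersection_of:
            report.new_definitions.append(m)
            continue
        fillers = [e.filler for e in term.intersection_of]
        if len(fillers) == 2 and frozenset(fillers) == frozenset((m.y, m.z)):
            continue
        filler_prefixes = {f.split(":", 1)[0] for f in fillers}
        non_ternary = (
            len(fillers) != 2
            or len(filler_prefixes) < 2
            or src_prefix in filler_prefixes
        )
        report.conflicts.append(DefinitionConflict(mapping=m, non_ternary=non_ternary))
    return report


def agreement(labels_a: list, labels_b: list) -> float:
    """Proportion of items categorized identically by two annotators."""
    if len(labels_a) != len(labels_b):
        raise ValueError("annotation lists must have equal length")
    if not labels_a:
        return 0.0
    return sum(a == b for a, b in zip(labels_a, labels_b)) / len(labels_a)


def _min_max_normalize(values: list[float]) -> tuple[list[float], bool]:
    lo, hi = min(values), max(values)
    if hi == lo:
        return [0.0] * len(values), True
    return [(v - lo) / (hi - lo) for v in values], False


@dataclass
class SweepResult:
    """Grid results of the two-threshold selection protocol.

    ``step1`` has one row per T1 with the first-pass recall against the
    binarized reference, the mapping count and the wall time (raw and
    min-max normalized over the grid). ``full`` has one row per (T1, T2)
    combination with precision/recall/F of the complete algorithm.
    """

    step1: pd.DataFrame
    full: pd.DataFrame


def threshold_sweep(source: OntologyModel, target1: OntologyModel,
                    target2: OntologyModel, t1_grid: list[float],
                    t2_grid: list[float], reference: ReferenceAlignment,
                    config: MatchConfig | None = None) -> SweepResult:
    """Sweep the two thresholds over grids and tabulate the results.

    For each T1, the first-pass mappings are compared with the reference
    binarized onto target 1; counts and runtimes are min-max normalized to
    [0, 1] across the grid so that differently sized ontology sets can be
    averaged (a degenerate normalization — constant column or single-point
    grid — is defined as 0 and flagged). For each (T1, T2) pair, the full
    algorithm's alignment is scored against the ternary reference.
    """
    config = config or MatchConfig()
    if any(not (0.0 < t <= 1.0) for t in list(t1_grid) + list(t2_grid)):
        raise ValueError("all grid thresholds must lie in (0, 1]")
    source_lex = build_lexicon(source, config)
    target1_lex = build_lexicon(target1, config)
    target2_lex = build_lexicon(target2, config)
    binary_ref = binarize_reference(reference, target1_lex.prefix)

    step1_rows = []
    full_rows = []
    for t1 in t1_grid:
        t_start = time.perf_counter()
        candidates = step1_recall_selection(source_lex, target1_lex, t1)
        elapsed = time.perf_counter() - t_start
        pairs = {(m.source, m.target) for m in candidates}
        rec = len(pairs & binary_ref) / len(binary_ref) if binary_ref else 0.0
        step1_rows.append({"t1": t1, "recall": rec,
                           "n_mappings": len(candidates), "seconds": elapsed})
        reduced = reduce_search_space(candidates)
        for t2 in t2_grid:
            t_start = time.perf_counter()
            alignment = step3_precision_selection(reduced, source_lex, target2_lex, t2)
            elapsed2 = time.perf_counter() - t_start
            rep = score(alignment, reference)
            full_rows.append({
                "t1": t1, "t2": t2, "precision": rep.precision,
                "recall": rep.recall, "f_measure": rep.f_measure,
                "n_mappings": rep.n_alignment, "seconds": elapsed2,
            })

    step1_df = pd.DataFrame(step1_rows)
    degenerate = False
    for col in ("n_mappings", "seconds"):
        normed, deg = _min_max_normalize(list(step1_df[col].astype(float)))
        step1_df[f"{col}_norm"] = normed
        degenerate = degenerate or deg
    step1_df["norm_degenerate"] = degenerate
    if degenerate:
        logger.warning("threshold sweep: degenerate min-max normalization (constant column)")
    return SweepResult(step1=step1_df, full=pd.DataFrame(full_rows))


def average_normalized(frames: list[pd.DataFrame],
                       columns: tuple[str, ...] = ("n_mappings_norm", "seconds_norm"),
                       key: str = "t1") -> pd.DataFrame:
    """Average per-set normalized sweep columns across ontology sets."""
    if not frames:
        raise ValueError("no sweep frames to average")
    merged = pd.concat(frames, ignore_index=True)
    return merged.groupby(key, as_index=False)[list(columns)].mean()
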