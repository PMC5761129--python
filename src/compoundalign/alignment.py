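"""Alignment TSV serialization and the top-one / top-two ranked selectors.

Raw compound alignments carry no cardinality constraint; the selectors
enforce at most k mappings per source class by greedily accepting mappings
in descending order of similarity. Only the source side is constrained —
a target class may appear in many mappings.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from compoundalign.compound_matcher import CompoundAlignment, CompoundMapping, Provenance

logger = logging.getLogger(__name__)

COLUMNS = [
    "source_id", "source_label", "target1_id", "target1_label",
    "target2_id", "target2_label", "relation", "mapping",
    "sim1", "sim2", "similarity",
]
#: columns a reference TSV may omit
OPTIONAL_COLUMNS = ["sim1", "sim2", "similarity"]


@dataclass
class SelectionResult:
    selected: CompoundAlignment
    discarded: int


def select_top_k(alignment: CompoundAlignment, k: int, tie_break: str = "lex",
                 seed: int | None = None) -> SelectionResult:
    """Greedy ranked selection: keep at most k mappings per source class.

    Mappings are processed in descending similarity. Ties are broken
    deterministically by ascending (Y, Z) CURIE pair, or randomly with
    ``tie_break="random"`` (optionally seeded).
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    mappings = list(alignment.mappings)
    if tie_break == "random":
        rng = random.Random(seed)
        rng.shuffle(mappings)
        mappings.sort(key=lambda m: -m.similarity)  # stable: random order within ties
    elif tie_break == "lex":
        mappings.sort(key=lambda m: (-m.similarity, m.y, m.z))
    else:
        raise ValueError(f"unknown tie-break mode {tie_break!r}")

    per_source: dict[str, int] = {}
    kept: list[CompoundMapping] = []
    for m in mappings:
        if per_source.get(m.x, 0) < k:
            per_source[m.x] = per_source.get(m.x, 0) + 1
            kept.append(m)
    kept.sort(key=lambda m: (m.x, m.y, m.z))
    discarded = len(mappings) - len(kept)
    logger.info("top-%d selection kept %d mappings, discarded %d", k, len(kept), discarded)
    return SelectionResult(
        selected=CompoundAlignment(mappings=kept, provenance=alignment.provenance),
        discarded=discarded,
    )


def to_frame(alignment: CompoundAlignment) -> pd.DataFrame:
    rows = [
        {
            "source_id": m.x, "source_label": m.x_label,
            "target1_id": m.y, "target1_label": m.y_label,
            "target2_id": m.z, "target2_label": m.z_label,
            "relation": m.relation, "mapping": m.mapping,
            "sim1": m.sim1, "sim2": m.sim2, "similarity": m.similarity,
        }
        for m in alignment.mappings
    ]
    return pd.DataFrame(rows, columns=COLUMNS)


def write_alignment(alignment: CompoundAlignment, path: str | Path) -> None:
    """Write an alignment as TSV (one row per mapping, fixed column schema)."""
    to_frame(alignment).to_csv(path, sep="\t", index=False)


def read_alignment(path: str | Path) -> CompoundAlignment:
    """Read an alignment TSV.

    Similarity columns are optional (reference alignments omit them); any
    other missing column raises a format error naming it. Duplicate rows are
    dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in COLUMNS if c not in OPTIONAL_COLUMNS]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"alignment file {path} is missing column {col!r}")
    n = len(df)
    df = df.drop_duplicates()
    if len(df) < n:
        logger.warning("%s: dropped %d duplicate rows", path, n - len(df))
    mappings = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def fnum(col: str) -> float:
            v = d.get(col, "")
            return float(v) if v not in ("", None) else float("nan")

        mappings.append(
            CompoundMapping(
                x=d["source_id"], y=d["target1_id"], z=d["target2_id"],
                sim1=fnum("sim1"), sim2=fnum("sim2"), similarity=fnum("similarity"),
                relation=d.get("relation", "intersection"),
                mapping=d.get("mapping", "equivalence"),
                x_label=d.get("source_label", ""),
                y_label=d.get("target1_label", ""),
                z_label=d.get("target2_label", ""),
            )
        )
    mappings.sort(key=lambda m: (m.x, m.y, m.z))
    return CompoundAlignment(mappings=mappings, provenance=Provenance())
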