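"""Brute-force reference implementation of the three-step matcher.

Enumerates every (source name, target name) combination directly — no
inverted index, no candidate pruning — and applies the similarity formulas
with explicit sums. Used to validate the indexed matcher on small inputs.
"""

from __future__ import annotations

from compoundalign.config import MatchConfig
from compoundalign.lexicon import build_lexicon
from compoundalign.obo_io import OntologyModel


def _ec_sum(stems, index):
    return sum(index.entries[s].ec for s in stems)


def brute_force_match(source: OntologyModel, target1: OntologyModel,
                      target2: OntologyModel, config: MatchConfig | None = None,
                      ) -> set[tuple[str, str, str, float, float, float]]:
    """All-pairs, all-names compound matching; returns (X, Y, Z, sim1, sim2, sim)."""
    config = config or MatchConfig()
    s_lex = build_lexicon(source, config)
    t1_lex = build_lexicon(target1, config)
    t2_lex = build_lexicon(target2, config)

    # step 1: best name pair per class pair, then threshold
    best1: dict[tuple[str, str], tuple] = {}
    for sn in s_lex.names:
        for tn in t1_lex.names:
            shared = sn.normalized.stems & tn.normalized.stems
            if not shared:
                continue
            sim = (_ec_sum(shared, t1_lex.index)
                   / _ec_sum(tn.normalized.stems, t1_lex.index)
                   * sn.weight * tn.weight)
            key = (sn.term, tn.term)
            order = (-sim, sn.text, sn.scope, tn.text, tn.scope)
            if key not in best1 or order < best1[key][0]:
                best1[key] = (order, sn, tn, sim)
    step1 = {k: v for k, v in best1.items() if v[3] >= config.t1 - 1e-12}

    # steps 2+3
    best3: dict[tuple[str, str, str], tuple] = {}
    for (x, y), (_, sn, tn, sim1) in step1.items():
        residual = sn.normalized.stems - tn.normalized.stems
        if not residual:
            continue
        for zn in t2_lex.names:
            shared = residual & zn.normalized.stems
            if not shared:
                continue
            if len(residual) > len(zn.normalized.stems):
                denom_bag, idx = residual, s_lex.index
            else:
                denom_bag, idx = zn.normalized.stems, t2_lex.index
            sim2 = (_ec_sum(shared, idx) / _ec_sum(denom_bag, idx)
                    * sn.weight * zn.weight)
            if sim2 <= 0.0:
                continue
            similarity = (sim1 + sim2) / 2.0
            if similarity < config.t2 - 1e-12:
                continue
            key = (x, y, zn.term)
            order = (sn.text, sn.scope, zn.text, zn.scope)
            prev = best3.get(key)
            if (prev is None or similarity > prev[0]
                    or (similarity == prev[0] and order < prev[1])):
                best3[key] = (similarity, order, sim1, sim2)

    return {
        (x, y, z, s1, s2, sim)
        for (x, y, z), (sim, _, s1, s2) in best3.items()
    }
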