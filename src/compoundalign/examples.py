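"""Hand-built miniature ontology triples for demonstration and testing.

Each triple contains a handful of classes from well-known biomedical
ontologies — phenotype sources (HP, MP, CO) against anatomy (FMA, UBERON,
CL, PO) and quality (PATO) targets — with the labels and synonyms the real
ontologies carry, small enough to trace by hand. The expected compound
mappings are classic entity–quality decompositions, e.g. "aortic valve
stenosis" ≡ "aortic valve" ∩ "constricted".
"""

from __future__ import annotations

from compoundalign.obo_io import IntersectionElement, OntologyModel, Term


def _model(ontology_id: str, terms: list[Term]) -> OntologyModel:
    m = OntologyModel(ontology_id=ontology_id)
    for t in terms:
        m.add(t)
    return m


def hp_fma_pato() -> tuple[OntologyModel, OntologyModel, OntologyModel]:
    """Human phenotypes against gross anatomy (FMA) and qualities (PATO)."""
    hp = _model("hp", [
        Term(id="HP:0001650", label="Aortic valve stenosis"),
        Term(id="HP:0000337", label="Broad forehead"),
        Term(id="HP:0010108", label="Aplasia of the hallux"),
    ])
    fma = _model("fma", [
        Term(id="FMA:7236", label="aortic valve"),
        Term(id="FMA:63864", label="forehead"),
        Term(id="FMA:25047", label="big toe", synonyms=[("hallux", "EXACT")]),
    ])
    pato = _model("pato", [
        Term(id="PATO:0001847", label="constricted", synonyms=[("stenosis", "EXACT")]),
        Term(id="PATO:0000600", label="increased width", synonyms=[("broad", "EXACT")]),
        Term(id="PATO:0000574", label="increased length"),
    ])
    return hp, fma, pato


def mp_uberon_pato() -> tuple[OntologyModel, OntologyModel, OntologyModel]:
    """Mammalian phenotypes against cross-species anatomy (UBERON) and PATO."""
    mp = _model("mp", [
        Term(id="MP:0004655", label="absent thoracic vertebrae"),
        Term(id="MP:0000447", label="flattened snout"),
    ])
    uberon = _model("uberon", [
        Term(id="UBERON:0002347", label="thoracic vertebra"),
        Term(id="UBERON:0006333", label="snout"),
        Term(id="UBERON:0004089", label="midface"),
    ])
    pato = _model("pato", [
        Term(id="PATO:0002000", label="lacks all parts of type",
             synonyms=[("absent", "EXACT")]),
        Term(id="PATO:0002254", label="flattened"),
    ])
    return mp, uberon, pato


def mp_cl_pato() -> tuple[OntologyModel, OntologyModel, OntologyModel]:
    """Mammalian phenotypes against cell types (CL) and PATO.

    PATO carries the sibling qualities "degeneration"/"degenerate", which
    stem identically and therefore score identically against the residual of
    "retinal ganglion cell degeneration" — the canonical competing-mapping
    situation the top-two selector exists for. MP:0004403 carries a logical
    definition so candidate-definition reporting can be exercised.
    """
    mp = _model("mp", [
        Term(id="MP:0008067", label="retinal ganglion cell degeneration"),
        Term(id="MP:0004403", label="absent cochlear outer hair cells",
             intersection_of=[
                 IntersectionElement(filler="PATO:0002000"),
                 IntersectionElement(relation="inheres_in", filler="CL:0000601"),
             ]),
    ])
    cl = _model("cl", [
        Term(id="CL:0000740", label="retinal ganglion cell"),
        Term(id="CL:0000601", label="outer hair cell",
             synonyms=[("cochlear outer hair cell", "EXACT")]),
    ])
    pato = _model("pato", [
        Term(id="PATO:0002037", label="degeneration"),
        Term(id="PATO:0000639", label="degenerate"),
        Term(id="PATO:0002000", label="lacks all parts of type",
             synonyms=[("absent", "EXACT")]),
    ])
    return mp, cl, pato


def co_po_pato() -> tuple[OntologyModel, OntologyModel, OntologyModel]:
    """Wheat crop traits against plant anatomy (PO) and PATO."""
    co = _model("co", [
        Term(id="CO:321_0000044", label="Leaf length"),
    ])
    po = _model("po", [
        Term(id="PO:0025034", label="leaf"),
    ])
    pato = _model("pato", [
        Term(id="PATO:0000122", label="length"),
        Term(id="PATO:0000117", label="size"),
    ])
    return co, po, pato


#: compound mappings these triples are expected to yield at T1=0.4, T2=0.9
#: with top-one selection (triple builder → set of (X, Y, Z))
EXPECTED_MAPPINGS = {
    hp_fma_pato: {
        ("HP:0001650", "FMA:7236", "PATO:0001847"),
        ("HP:0000337", "FMA:63864", "PATO:0000600"),
    },
    mp_uberon_pato: {
        ("MP:0004655", "UBERON:0002347", "PATO:0002000"),
        ("MP:0000447", "UBERON:0006333", "PATO:0002254"),
    },
    co_po_pato: {
        ("CO:321_0000044", "PO:0025034", "PATO:0000122"),
    },
}
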