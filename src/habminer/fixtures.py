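"""Self-contained fixture bundle: a mini habitat ontology and standoff
documents exercising every pipeline behaviour, generated programmatically.

The ontology holds roughly twenty concepts wired so that each coordination
scenario has the intended parent structure (e.g. *iron-rich environment* and
*wet environment* share the direct parent *habitat wrt chemico-physical
property*, while *pharyngeal mucosa* and *gut mucosa* do not share one).
Concepts whose real identifiers are publicly established keep them; the rest
are SYNTHETIC ids drawn from the reserved range ``MBTO:099xxxxx`` (see
:data:`SYNTHETIC_IDS`) so they can never collide with real ontology entries.

Each fixture document ships its text, gold ``.a1`` input entities and the
expected ``.a2`` output for the sub-task it exercises (entity detection with
normalizations, or relation extraction).  :data:`DOC_TASKS` records which
sub-task and strategy each document's expected output corresponds to.
"""

from __future__ import annotations

from dataclasses import dataclass

from .analysis import Span
from .ontology import Ontology, OntologyConcept
from .relations import EntityRef, Relation
from .standoff import Normalization, StandoffDocument

# -- concept identifiers ----------------------------------------------------

MUMMY_TISSUE = "MBTO:00001875"
ANIMAL = "MBTO:00001660"
BODY_FLUID = "MBTO:00000921"
INFANT = "MBTO:00000778"

#: Manifest of concepts with SYNTHETIC identifiers (name -> id).
SYNTHETIC_IDS: dict[str, str] = {
    "habitat": "MBTO:09900001",
    "eukaryote host": "MBTO:09900002",
    "plant": "MBTO:09900003",
    "human": "MBTO:09900004",
    "mouse": "MBTO:09900005",
    "food product": "MBTO:09900006",
    "cheese": "MBTO:09900007",
    "respiratory tract part": "MBTO:09900008",
    "digestive tract part": "MBTO:09900009",
    "mucosal tissue": "MBTO:09900010",
    "pharyngeal mucosa": "MBTO:09900011",
    "gut mucosa": "MBTO:09900012",
    "habitat wrt chemico-physical property": "MBTO:09900013",
    "iron-rich environment": "MBTO:09900014",
    "wet environment": "MBTO:09900015",
    "digestive tract": "MBTO:09900016",
}

PLANT = SYNTHETIC_IDS["plant"]
HUMAN = SYNTHETIC_IDS["human"]
MOUSE = SYNTHETIC_IDS["mouse"]
CHEESE = SYNTHETIC_IDS["cheese"]
PHARYNGEAL_MUCOSA = SYNTHETIC_IDS["pharyngeal mucosa"]
GUT_MUCOSA = SYNTHETIC_IDS["gut mucosa"]
IRON_RICH_ENV = SYNTHETIC_IDS["iron-rich environment"]
WET_ENV = SYNTHETIC_IDS["wet environment"]
DIGESTIVE_TRACT = SYNTHETIC_IDS["digestive tract"]


def build_fixture_ontology() -> Ontology:
    """The packaged mini-ontology (a DAG of ~20 habitat concepts)."""
    root = SYNTHETIC_IDS["habitat"]
    euk = SYNTHETIC_IDS["eukaryote host"]
    food = SYNTHETIC_IDS["food product"]
    resp_part = SYNTHETIC_IDS["respiratory tract part"]
    dig_part = SYNTHETIC_IDS["digestive tract part"]
    mucosal = SYNTHETIC_IDS["mucosal tissue"]
    chemphys = SYNTHETIC_IDS["habitat wrt chemico-physical property"]
    concepts = [
        OntologyConcept(root, "habitat"),
        OntologyConcept(euk, "eukaryote host", parents={root}),
        OntologyConcept(ANIMAL, "animal", parents={euk}),
        OntologyConcept(PLANT, "plant", parents={euk}),
        OntologyConcept(HUMAN, "human", parents={euk}),
        OntologyConcept(INFANT, "infant", parents={HUMAN}),
        OntologyConcept(MOUSE, "mouse", parents={ANIMAL}),
        OntologyConcept(food, "food product", parents={root}),
        OntologyConcept(CHEESE, "cheese", parents={food}),
        OntologyConcept(resp_part, "respiratory tract part", parents={root}),
        OntologyConcept(dig_part, "digestive tract part", parents={root}),
        OntologyConcept(mucosal, "mucosal tissue", parents={root}),
        OntologyConcept(PHARYNGEAL_MUCOSA, "pharyngeal mucosa", parents={resp_part}),
        OntologyConcept(GUT_MUCOSA, "gut mucosa", parents={dig_part, mucosal}),
        OntologyConcept(chemphys, "habitat wrt chemico-physical property", parents={root}),
        OntologyConcept(IRON_RICH_ENV, "iron-rich environment", parents={chemphys}),
        OntologyConcept(WET_ENV, "wet environment", parents={chemphys}),
        OntologyConcept(
            DIGESTIVE_TRACT,
            "digestive tract",
            exact_synonyms=("gastrointestinal tract",),
            parents={dig_part},
        ),
        OntologyConcept(MUMMY_TISSUE, "mummy tissue", parents={root}),
        OntologyConcept(
            BODY_FLUID, "body fluid", exact_synonyms=("bodily fluid",), parents={root}
        ),
    ]
    return Ontology(concepts)


# -- document construction helpers ------------------------------------------

def span_of(text: str, fragment: str, occurrence: int = 0) -> Span:
    """Character span of the n-th occurrence of ``fragment`` in ``text``."""
    start = -1
    for _ in range(occurrence + 1):
        start = text.index(fragment, start + 1)
    return (start, start + len(fragment))


@dataclass(frozen=True)
class _Ent:
    etype: str
    pieces: tuple[str, ...]  # one fragment per piece, located in order
    layer: str = "a1"
    occurrence: int = 0  # occurrence index of the first piece


def _build_doc(
    doc_id: str,
    text: str,
    ents: dict[str, _Ent],
    norms: list[tuple[str, str]] = (),
    rels: list[tuple[str, str, str]] = (),
) -> StandoffDocument:
    entities: list[EntityRef] = []
    a2_ids: set[str] = set()
    by_id: dict[str, EntityRef] = {}
    for tid, spec in ents.items():
        fragments: list[Span] = []
        cursor = span_of(text, spec.pieces[0], spec.occurrence)
        fragments.append(cursor)
        for piece in spec.pieces[1:]:
            start = text.index(piece, cursor[1])
            cursor = (start, start + len(piece))
            fragments.append(cursor)
        entity = EntityRef(
            id=tid,
            etype=spec.etype,
            fragments=tuple(fragments),
            text=" ".join(spec.pieces),
        )
        entities.append(entity)
        by_id[tid] = entity
        if spec.layer == "a2":
            a2_ids.add(tid)
    normalizations = tuple(
        Normalization(f"N{i}", tid, referent)
        for i, (tid, referent) in enumerate(norms, start=1)
    )
    relations = tuple(
        Relation(rtype, by_id[a1], by_id[a2]) for rtype, a1, a2 in rels
    )
    return StandoffDocument(
        doc_id=doc_id,
        text=text,
        entities=tuple(entities),
        a2_entity_ids=frozenset(a2_ids),
        normalizations=normalizations,
        relations=relations,
    )


#: Which sub-task each document's expected .a2 answers, and (for relation
#: documents) with which Localization strategy the expectation was derived.
DOC_TASKS: dict[str, dict] = {
    "mummy": {"task": "entities"},
    "bodily-fluid": {"task": "entities"},
    "gastro": {"task": "entities"},
    "coord-mucosa": {"task": "entities"},
    "coord-environment": {"task": "entities"},
    "coord-hosts": {"task": "entities"},
    "coord-disjoint": {"task": "entities"},
    "modifier-infant": {"task": "entities", "modifier_preps": ("in",)},
    "brucella": {"task": "relations", "strategy": "sentence"},
    "borrelia": {"task": "relations", "strategy": "sentence"},
    "bordetella-group": {"task": "relations", "strategy": "sentence"},
    "bordetella-strain": {"task": "relations", "strategy": "paragraph"},
    "this-strain": {"task": "relations", "strategy": "sentence"},
    "partof": {"task": "relations", "strategy": "sentence"},
}


def build_fixture_documents() -> list[StandoffDocument]:
    """One standoff document per pipeline scenario, with gold inputs and the
    expected outputs inline."""
    docs: list[StandoffDocument] = []

    # --- entity detection & normalization scenarios -----------------------

    text = "The mummy tissue was analyzed.\n"
    docs.append(
        _build_doc(
            "mummy",
            text,
            {"T1": _Ent("Habitat", ("mummy tissue",), layer="a2")},
            norms=[("T1", MUMMY_TISSUE)],
        )
    )

    text = "The animal bodily fluid was infected.\n"
    docs.append(
        _build_doc(
            "bodily-fluid",
            text,
            {
                "T1": _Ent("Habitat", ("animal",), layer="a2"),
                "T2": _Ent("Habitat", ("animal bodily fluid",), layer="a2"),
            },
            norms=[("T1", ANIMAL), ("T2", BODY_FLUID)],
        )
    )

    text = (
        "Bifidobacterium\n\n"
        "Bifidobacterium longum is found in the human gastrointestinal tract.\n"
    )
    docs.append(
        _build_doc(
            "gastro",
            text,
            {
                "T1": _Ent("Habitat", ("human",), layer="a2", occurrence=0),
                "T2": _Ent("Habitat", ("human gastrointestinal tract",), layer="a2"),
            },
            norms=[("T1", HUMAN), ("T2", DIGESTIVE_TRACT)],
        )
    )

    text = "Lactobacillus casei was found in the pharyngeal and gut mucosa.\n"
    docs.append(
        _build_doc(
            "coord-mucosa",
            text,
            {
                "T1": _Ent("Habitat", ("pharyngeal", "mucosa"), layer="a2"),
                "T2": _Ent("Habitat", ("gut mucosa",), layer="a2"),
            },
            norms=[("T1", PHARYNGEAL_MUCOSA), ("T2", GUT_MUCOSA)],
        )
    )

    text = "Thiobacillus lives in an iron-rich and wet environment.\n"
    docs.append(
        _build_doc(
            "coord-environment",
            text,
            {"T1": _Ent("Habitat", ("iron-rich and wet environment",), layer="a2")},
            norms=[("T1", IRON_RICH_ENV), ("T1", WET_ENV)],
        )
    )

    text = "These bacteria infect plants and animals.\n"
    docs.append(
        _build_doc(
            "coord-hosts",
            text,
            {
                "T1": _Ent("Habitat", ("plants",), layer="a2"),
                "T2": _Ent("Habitat", ("animals",), layer="a2"),
            },
            norms=[("T1", PLANT), ("T2", ANIMAL)],
        )
    )

    text = "Listeria was found in mouse and cheese.\n"
    docs.append(
        _build_doc(
            "coord-disjoint",
            text,
            {
                "T1": _Ent("Habitat", ("mouse",), layer="a2"),
                "T2": _Ent("Habitat", ("cheese",), layer="a2"),
            },
            norms=[("T1", MOUSE), ("T2", CHEESE)],
        )
    )

    text = "The infected infant in Germany was examined.\n"
    docs.append(
        _build_doc(
            "modifier-infant",
            text,
            {
                "T1": _Ent("Habitat", ("infected infant",), layer="a2"),
                "T2": _Ent("Habitat", ("infected infant in Germany",), layer="a2"),
            },
            norms=[("T1", INFANT), ("T2", INFANT)],
        )
    )

    # --- relation extraction scenarios ------------------------------------

    text = (
        "Brucella canis.\n"
        "This bacterium is highly infectious, and can be spread through the "
        "contact with the infected animal products or through the air.\n"
    )
    docs.append(
        _build_doc(
            "brucella",
            text,
            {
                "T1": _Ent("Bacteria", ("Brucella canis",)),
                "T2": _Ent("Habitat", ("animal products",)),
                "T3": _Ent("Habitat", ("air",)),
            },
            rels=[("Localization", "T1", "T2"), ("Localization", "T1", "T3")],
        )
    )

    text = "Borrelia burgdorferi\n\nIt was isolated from Ixodes scapularis in 1982.\n"
    docs.append(
        _build_doc(
            "borrelia",
            text,
            {
                "T1": _Ent("Bacteria", ("Borrelia burgdorferi",)),
                "T2": _Ent("Habitat", ("Ixodes scapularis",)),
            },
            rels=[("Localization", "T1", "T2")],
        )
    )

    text = (
        "Bordetella. This group of organisms is capable of invading the "
        "respiratory tract of animals and causing severe diseases.\n"
    )
    docs.append(
        _build_doc(
            "bordetella-group",
            text,
            {
                "T1": _Ent("Bacteria", ("Bordetella",)),
                "T2": _Ent("Habitat", ("respiratory tract of animals",)),
                "T3": _Ent("Habitat", ("animals",)),
            },
            rels=[
                ("Localization", "T1", "T2"),
                ("Localization", "T1", "T3"),
                ("PartOf", "T2", "T3"),
            ],
        )
    )

    text = (
        "Bordetella petrii DSM12804 is an aerobic bacterium.\n\n"
        "Bordetella petrii strain DSM12804 was initially isolated from river "
        "sediment.\n"
    )
    docs.append(
        _build_doc(
            "bordetella-strain",
            text,
            {
                "T1": _Ent("Bacteria", ("Bordetella petrii DSM12804",)),
                "T2": _Ent("Bacteria", ("Bordetella petrii strain DSM12804",)),
                "T3": _Ent("Habitat", ("river sediment",)),
            },
            rels=[("Localization", "T1", "T3")],
        )
    )

    text = (
        "Lactobacillus casei is a probiotic bacterium.\n"
        "This strain was isolated from infant feces.\n"
    )
    docs.append(
        _build_doc(
            "this-strain",
            text,
            {
                "T1": _Ent("Bacteria", ("Lactobacillus casei",)),
                "T2": _Ent("Habitat", ("infant feces",)),
                "T3": _Ent("Habitat", ("infant",)),
            },
            rels=[
                ("Localization", "T1", "T2"),
                ("Localization", "T1", "T3"),
                ("PartOf", "T2", "T3"),
            ],
        )
    )

    text = (
        "Azospirillum lives in the rhizosphere of plants.\n"
        "Streptococcus is found in the oral cavity in humans.\n"
        "Borrelia was obtained from a skin lesion from a Lyme disease patient "
        "in Europe.\n"
        "Bradyrhizobium was found in the Aeschynomene stem nodule.\n"
    )
    docs.append(
        _build_doc(
            "partof",
            text,
            {
                "T1": _Ent("Habitat", ("rhizosphere of plants",)),
                "T2": _Ent("Habitat", ("plants",)),
                "T3": _Ent("Habitat", ("oral cavity in humans",)),
                "T4": _Ent("Habitat", ("humans",)),
                "T5": _Ent(
                    "Habitat",
                    ("skin lesion from a Lyme disease patient in Europe",),
                ),
                "T6": _Ent("Habitat", ("Lyme disease patient in Europe",)),
                "T7": _Ent("Habitat", ("Aeschynomene stem nodule",)),
                "T8": _Ent("Habitat", ("Aeschynomene",)),
            },
            rels=[
                ("PartOf", "T1", "T2"),
                ("PartOf", "T3", "T4"),
                ("PartOf", "T5", "T6"),
                ("PartOf", "T7", "T8"),
            ],
        )
    )

    return docs


def fixture_document(doc_id: str) -> StandoffDocument:
    for doc in build_fixture_documents():
        if doc.doc_id == doc_id:
            return doc
    raise KeyError(doc_id)
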