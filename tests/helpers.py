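"""Random generators and small oracles shared by property-style tests."""

from __future__ import annotations

import random
from itertools import permutations

from habminer.ontology import Ontology, OntologyConcept
from habminer.recognition import HabitatMention
from habminer.relations import EntityRef, Relation
from habminer.standoff import Normalization, StandoffDocument

WORDS = [
    "soil", "water", "plant", "root", "leaf", "milk", "cheese", "gut",
    "skin", "blood", "lung", "tick", "host", "cow", "fish", "pond",
]


def random_ontology(rng: random.Random, n: int = 12) -> Ontology:
    """A random valid DAG ontology (parents only among earlier concepts)."""
    concepts = []
    for index in range(n):
        cid = f"MBTO:{90000000 + index}"
        name = f"concept {index}"
        synonyms = []
        if rng.random() < 0.5:
            synonyms.append(f"syn {index} a")
        if rng.random() < 0.3:
            synonyms.append(f"syn {index} b")
        parent_pool = [f"MBTO:{90000000 + j}" for j in range(index)]
        parents = frozenset(
            rng.sample(parent_pool, k=min(len(parent_pool), rng.randint(0, 2)))
        )
        concepts.append(
            OntologyConcept(
                cid,
                name,
                exact_synonyms=tuple(synonyms[:1]),
                related_synonyms=tuple(synonyms[1:]),
                parents=parents,
                obsolete=rng.random() < 0.1,
            )
        )
    return Ontology(concepts)


def brute_force_ancestors(ontology: Ontology, concept_id: str) -> frozenset[str]:
    """DFS path-enumeration oracle for the transitive is_a closure."""
    result: set[str] = set()

    def walk(cid: str) -> None:
        for parent in ontology[cid].parents:
            if parent not in result:
                result.add(parent)
                walk(parent)

    walk(concept_id)
    return frozenset(result)


def random_document(rng: random.Random, doc_id: str = "doc") -> StandoffDocument:
    """A random valid standoff document with entities (possibly
    discontinuous), normalizations, and relations."""
    n_words = rng.randint(4, 14)
    words = [rng.choice(WORDS) for _ in range(n_words)]
    text = " ".join(words) + "\n"
    spans = []
    cursor = 0
    for word in words:
        spans.append((cursor, cursor + len(word)))
        cursor += len(word) + 1

    entities = []
    for index in range(rng.randint(0, 5)):
        n_frag = 1 if rng.random() < 0.7 else 2
        picks = sorted(rng.sample(range(n_words), k=min(n_frag, n_words)))
        fragments = []
        for w in picks:
            frag = spans[w]
            if fragments and frag[0] <= fragments[-1][1]:
                continue
            fragments.append(frag)
        etype = rng.choice(["Bacteria", "Habitat", "Geographical"])
        entities.append(
            EntityRef(
                id=f"T{index + 1}",
                etype=etype,
                fragments=tuple(fragments),
                text=" ".join(text[s:e] for s, e in fragments),
            )
        )
    a2_ids = frozenset(e.id for e in entities if rng.random() < 0.3)
    norms = tuple(
        Normalization(f"N{i + 1}", e.id, f"MBTO:{90000000 + rng.randint(0, 20)}")
        for i, e in enumerate(e for e in entities if e.etype == "Habitat")
        if rng.random() < 0.6
    )
    relations = []
    bacteria = [e for e in entities if e.etype == "Bacteria"]
    targets = [e for e in entities if e.etype in ("Habitat", "Geographical")]
    for b in bacteria:
        for t in targets:
            if rng.random() < 0.3:
                relations.append(Relation("Localization", b, t))
    return StandoffDocument(
        doc_id=doc_id,
        text=text,
        entities=tuple(entities),
        a2_entity_ids=a2_ids,
        normalizations=norms,
        relations=tuple(relations),
    )


def random_mentions(
    rng: random.Random, ontology: Ontology, n: int, text_len: int = 60
) -> list[HabitatMention]:
    """Random habitat mentions with possibly-overlapping spans."""
    ids = sorted(ontology.concepts)
    mentions = []
    for _ in range(n):
        start = rng.randint(0, text_len - 2)
        end = rng.randint(start + 1, min(start + 12, text_len))
        mentions.append(
            HabitatMention(
                fragments=((start, end),),
                concept_ids=(rng.choice(ids),),
                text="x" * (end - start),
            )
        )
    return mentions


def brute_force_best_matching(preds, refs, ontology) -> float:
    """Exhaustive-permutation oracle: the maximum total match credit over all
    one-to-one matchings restricted to overlapping (J > 0) pairs."""
    from habminer.evaluation import jaccard_span, mention_similarity_W

    n_pred, n_ref = len(preds), len(refs)
    score = [
        [
            jaccard_span(p.fragments, r.fragments)
            * mention_similarity_W(ontology, p, r)
            for r in refs
        ]
        for p in preds
    ]
    best = 0.0
    if n_pred <= n_ref:
        for perm in permutations(range(n_ref), n_pred):
            best = max(best, sum(score[i][perm[i]] for i in range(n_pred)))
    else:
        for perm in permutations(range(n_pred), n_ref):
            best = max(best, sum(score[perm[j]][j] for j in range(n_ref)))
    return best
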