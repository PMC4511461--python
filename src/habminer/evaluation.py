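"""Scoring for entity detection (Slot Error Rate) and relation extraction.

Entity scoring pairs predicted and reference mentions one-to-one and scores
each pair with a match credit ``M = J * W``:

* ``J`` — Jaccard similarity of the character positions covered by the two
  mentions' fragments; 1 for identical boundaries, 0 for disjoint ones.
* ``W`` — Jaccard similarity of the ancestor sets (including the concepts
  themselves) of the assigned ontology concepts; 1 when both mentions carry
  the same concept.  When a mention carries several concepts, the best
  concept pair is used.

A matched pair contributes a substitution score ``1 - M``; reference
mentions with no overlapping prediction are deletions (``D``), spurious
predictions insertions (``I``).  With ``N`` reference mentions,

    SER = (S + D + I) / N,    recall = M_total / N,
    precision = M_total / (number of predictions).

Pairing maximizes total match credit with an optimal one-to-one assignment
(Hungarian algorithm); a greedy fallback is available for comparison.  An
aggregate mode recomputes SER and recall from externally reported
``S, D, I, M`` totals using the identity ``N = S + M + D`` (each matched
pair contributes exactly 1 to ``S + M``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ontology import Ontology
from .recognition import HabitatMention
from .standoff import StandoffDocument

Span = tuple[int, int]


class Mention(Protocol):
    """Anything scoreable: character fragments plus assigned concept ids."""

    @property
    def fragments(self) -> tuple[Span, ...]: ...

    @property
    def concept_ids(self) -> tuple[str, ...]: ...


@dataclass(frozen=True)
class PairScore:
    """Scores of one matched prediction/reference pair."""

    pred: Mention
    ref: Mention
    J: float
    W: float

    @property
    def M(self) -> float:
        return self.J * self.W

    @property
    def S_pair(self) -> float:
        return 1.0 - self.M


@dataclass(frozen=True)
class Matching:
    pairs: tuple[PairScore, ...]
    unmatched_preds: tuple[Mention, ...]
    unmatched_refs: tuple[Mention, ...]


@dataclass(frozen=True)
class SEROutcome:
    """Aggregated slot-error-rate bookkeeping.

    ``precision``/``fscore`` are ``None`` in aggregate mode, where the
    prediction count is not recoverable from the totals.
    """

    S: float
    D: int
    I: int
    M_total: float
    N: float
    n_predictions: int | None = None

    @property
    def ser(self) -> float:
        return (self.S + self.D + self.I) / self.N

    @property
    def recall(self) -> float:
        return self.M_total / self.N

    @property
    def precision(self) -> float | None:
        if self.n_predictions is None:
            return None
        if self.n_predictions == 0:
            return 0.0
        return self.M_total / self.n_predictions

    @property
    def fscore(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None:
            return None
        if p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)


# ---------------------------------------------------------------------------
# Pair similarities
# ---------------------------------------------------------------------------

def jaccard_span(
    pred_fragments: Sequence[Span], ref_fragments: Sequence[Span]
) -> float:
    """Jaccard coefficient over the character positions covered by two
    fragment lists.  Raises if both cover nothing."""
    pred = {pos for s, e in pred_fragments for pos in range(s, e)}
    ref = {pos for s, e in ref_fragments for pos in range(s, e)}
    union = pred | ref
    if not union:
        raise ValueError("both fragment lists cover no characters")
    return len(pred & ref) / len(union)


def concept_similarity(ontology: Ontology, pred_id: str, ref_id: str) -> float:
    """Jaccard coefficient of the self-inclusive ancestor sets of two
    concepts: 1 for identical concepts, shrinking with ontology distance."""
    a = ontology.ancestors(pred_id, include_self=True)
    b = ontology.ancestors(ref_id, include_self=True)
    return len(a & b) / len(a | b)


def mention_similarity_W(ontology: Ontology, pred: Mention, ref: Mention) -> float:
    """Concept similarity between mentions; the best pair of assigned
    concepts wins when a mention carries several."""
    return max(
        concept_similarity(ontology, p, r)
        for p in pred.concept_ids
        for r in ref.concept_ids
    )


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------

def pair_entities(
    preds: Sequence[Mention],
    refs: Sequence[Mention],
    ontology: Ontology,
    greedy: bool = False,
) -> Matching:
    """One-to-one matching between predictions and references.

    Only pairs with overlapping boundaries (``J > 0``) may match; among
    admissible matchings the total match credit is maximized (or accumulated
    greedily when ``greedy=True``).  Unmatched references are deletions,
    unmatched predictions insertions.
    """
    if not preds or not refs:
        return Matching((), tuple(preds), tuple(refs))
    score = np.zeros((len(preds), len(refs)))
    for i, pred in enumerate(preds):
        for j, ref in enumerate(refs):
            J = jaccard_span(pred.fragments, ref.fragments)
            if J > 0.0:
                score[i, j] = J * mention_similarity_W(ontology, pred, ref)

    chosen: list[tuple[int, int]]
    if greedy:
        chosen = []
        used_i: set[int] = set()
        used_j: set[int] = set()
        order = sorted(
            ((i, j) for i in range(len(preds)) for j in range(len(refs))),
            key=lambda ij: (-score[ij], ij),
        )
        for i, j in order:
            if score[i, j] > 0 and i not in used_i and j not in used_j:
                chosen.append((i, j))
                used_i.add(i)
                used_j.add(j)
    else:
        rows, cols = linear_sum_assignment(-score)
        chosen = list(zip(rows.tolist(), cols.tolist()))

    pairs = []
    matched_i: set[int] = set()
    matched_j: set[int] = set()
    for i, j in chosen:
        J = jaccard_span(preds[i].fragments, refs[j].fragments)
        if J == 0.0:
            continue  # forced assignment of non-overlapping entities is no match
        pairs.append(
            PairScore(
                pred=preds[i],
                ref=refs[j],
                J=J,
                W=mention_similarity_W(ontology, preds[i], refs[j]),
            )
        )
        matched_i.add(i)
        matched_j.add(j)
    return Matching(
        pairs=tuple(pairs),
        unmatched_preds=tuple(p for i, p in enumerate(preds) if i not in matched_i),
        unmatched_refs=tuple(r for j, r in enumerate(refs) if j not in matched_j),
    )


# ---------------------------------------------------------------------------
# SER aggregation
# ---------------------------------------------------------------------------

def score_ser(
    preds: Sequence[Mention],
    refs: Sequence[Mention],
    ontology: Ontology,
    greedy: bool = False,
) -> SEROutcome:
    """Slot error rate of predictions against references."""
    if not refs:
        raise ValueError("SER is undefined without reference entities")
    matching = pair_entities(preds, refs, ontology, greedy=greedy)
    return SEROutcome(
        S=sum(pair.S_pair for pair in matching.pairs),
        D=len(matching.unmatched_refs),
        I=len(matching.unmatched_preds),
        M_total=sum(pair.M for pair in matching.pairs),
        N=len(refs),
        n_predictions=len(preds),
    )


def score_ser_from_totals(S: float, D: float, I: float, M_total: float) -> SEROutcome:
    """Aggregate mode: rebuild the outcome from reported totals.

    The reference count follows from the per-pair identity
    ``S_pair + M = 1``: the number of matched pairs is ``S + M_total``, so
    ``N = S + M_total + D``.
    """
    N = S + M_total + D
    if N <= 0:
        raise ValueError("totals imply no reference entities")
    return SEROutcome(S=S, D=int(D), I=int(I), M_total=M_total, N=N)


# ---------------------------------------------------------------------------
# Relation precision / recall / F-score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRFResult:
    tp: int
    fp: int
    fn: int
    #: True when precision was conventionally set to 0 because there were no
    #: predictions.
    precision_undefined: bool = False

    @property
    def precision(self) -> float:
        if self.tp + self.fp == 0:
            return 0.0
        return self.tp / (self.tp + self.fp)

    @property
    def recall(self) -> float:
        if self.tp + self.fn == 0:
            return 0.0
        return self.tp / (self.tp + self.fn)

    @property
    def fscore(self) -> float:
        p, r = self.precision, self.recall
        if p + r == 0:
            return 0.0
        return 2 * p * r / (p + r)


def relation_prf(pred_keys: Sequence, ref_keys: Sequence) -> PRFResult:
    """Exact-match precision/recall/F over relation identity keys.

    Keys are typically ``(doc id, relation type, arg1 id, arg2 id)`` tuples;
    anything hashable works.
    """
    pred_set = set(pred_keys)
    ref_set = set(ref_keys)
    tp = len(pred_set & ref_set)
    return PRFResult(
        tp=tp,
        fp=len(pred_set) - tp,
        fn=len(ref_set) - tp,
        precision_undefined=not pred_set,
    )


def relation_keys(doc_id: str, relations: Sequence) -> list[tuple]:
    """Identity keys for a document's relations (exact-match comparison by
    relation type and argument entity ids)."""
    return [(doc_id, r.rtype, r.arg1.id, r.arg2.id) for r in relations]


# ---------------------------------------------------------------------------
# Mentions from standoff documents
# ---------------------------------------------------------------------------

def mentions_from_document(doc: StandoffDocument) -> list[HabitatMention]:
    """Habitat mentions (fragments + concept ids) from a document's a2
    entities and normalization lines; unnormalized entities are skipped."""
    by_entity: dict[str, list[str]] = {}
    for norm in doc.normalizations:
        by_entity.setdefault(norm.entity_id, []).append(norm.referent)
    mentions = []
    entity_map = doc.entity_map
    for entity_id in sorted(by_entity, key=lambda tid: entity_map[tid].start):
        entity = entity_map[entity_id]
        mentions.append(
            HabitatMention(
                fragments=entity.fragments,
                concept_ids=tuple(sorted(set(by_entity[entity_id]))),
                text=entity.text,
            )
        )
    return mentions


def corpus_ser(
    ref_docs: Sequence[StandoffDocument],
    pred_docs: Sequence[StandoffDocument],
    ontology: Ontology,
    greedy: bool = False,
) -> tuple[SEROutcome, dict[str, SEROutcome]]:
    """Corpus-level SER: totals summed over documents paired by id.

    Returns the corpus outcome and the per-document outcomes (documents
    without reference mentions are tallied for insertions only).
    """
    pred_by_id = {d.doc_id: d for d in pred_docs}
    S = M = 0.0
    D = I = N = n_pred = 0
    per_doc: dict[str, SEROutcome] = {}
    for ref_doc in ref_docs:
        refs = mentions_from_document(ref_doc)
        pred_doc = pred_by_id.get(ref_doc.doc_id)
        preds = mentions_from_document(pred_doc) if pred_doc else []
        matching = pair_entities(preds, refs, ontology, greedy=greedy)
        doc_S = sum(p.S_pair for p in matching.pairs)
        doc_M = sum(p.M for p in matching.pairs)
        S += doc_S
        M += doc_M
        D += len(matching.unmatched_refs)
        I += len(matching.unmatched_preds)
        N += len(refs)
        n_pred += len(preds)
        if refs:
            per_doc[ref_doc.doc_id] = SEROutcome(
                S=doc_S,
                D=len(matching.unmatched_refs),
                I=len(matching.unmatched_preds),
                M_total=doc_M,
                N=len(refs),
                n_predictions=len(preds),
            )
    if N == 0:
        raise ValueError("no reference entities in the corpus")
    return (
        SEROutcome(S=S, D=D, I=I, M_total=M, N=N, n_predictions=n_pred),
        per_doc,
    )
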