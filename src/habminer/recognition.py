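"""Habitat entity recognition: from noun-phrase chunks to normalized mentions.

The recognizer turns each noun phrase into a candidate by stripping
non-informative words (determiners, possessive pronouns and kin), optionally
extends candidates across the prepositions *in*/*of*/*with* to capture
modifier-bearing habitat boundaries, handles coordinated phrases such as
``pharyngeal and gut mucosa`` (which hides the discontinuous entity
``pharyngeal ... mucosa``), and matches candidates against ontology labels on
both surface and lemma streams.

Three boundary rules translate matches into mentions:

* an **exact** match (the label covers the whole candidate) yields a mention
  spanning the candidate;
* a **prefix partial** match (starts at the first word but stops short)
  yields a mention spanning only the matching sub-phrase;
* an **internal partial** match (starts later in the candidate) yields a
  mention spanning the whole candidate, normalized to the matched concept.

Coordinated candidates are split at ``and`` with shared-head completion
(``pharyngeal and gut mucosa`` -> ``pharyngeal mucosa`` + ``gut mucosa``).
When both halves map to concepts sharing a direct ontology parent the phrase
is kept as one entity — unless both halves are bare nouns, which stay two
entities (``plants and animals``).  Without a shared parent the halves are
two entities, the first usually discontinuous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .analysis import AnalyzedDocument, AnalyzedSentence, NounPhrase, Span, Token
from .ontology import Ontology, normalize_label

#: POS tags removed during noun-phrase simplification: determiners,
#: possessive pronouns, and their close analogues.
NON_INFORMATIVE_POS = frozenset({"DT", "PRP$", "PDT", "WDT", "POS"})

#: Prepositions eligible for modifier attachment.
MODIFIER_PREPOSITIONS = frozenset({"in", "of", "with"})

MatchKind = Literal["exact", "prefix_partial", "internal_partial"]
_KIND_RANK = {"exact": 0, "prefix_partial": 1, "internal_partial": 2}


@dataclass(frozen=True)
class RecognitionConfig:
    """Switches for the recognition pipeline.

    Modifier attachment is off by default: extending habitat boundaries
    across prepositions trades precision for recall and measurably hurts the
    slot error rate, mostly through prepositional-phrase attachment
    ambiguity (*"patient in 1993"*).
    """

    coordination: bool = True
    modifier_preps: frozenset[str] = frozenset()
    lemma_matching: bool = True
    related_synonyms: bool = True


@dataclass(frozen=True)
class CandidatePhrase:
    """A (possibly simplified or merged) habitat candidate.

    ``indices`` are positions into ``sentence.tokens``; they are ordered but
    need not be contiguous once simplification or coordination has removed
    words.  ``fragments`` merge runs of consecutive tokens into character
    spans over the original document.
    """

    sentence: AnalyzedSentence
    indices: tuple[int, ...]
    source: Literal["np", "modifier-extended", "coordination-derived"] = "np"

    @property
    def tokens(self) -> tuple[Token, ...]:
        return tuple(self.sentence.tokens[i] for i in self.indices)

    @property
    def surface_form(self) -> str:
        return " ".join(t.surface for t in self.tokens)

    @property
    def lemma_form(self) -> str:
        return " ".join(t.lemma for t in self.tokens)

    @property
    def fragments(self) -> tuple[Span, ...]:
        return self._fragments_for(range(len(self.indices)))

    def _fragments_for(self, positions: Iterable[int]) -> tuple[Span, ...]:
        """Character fragments covering the given candidate-token positions,
        with sentence-adjacent tokens merged into one span."""
        spans: list[Span] = []
        run: list[int] = []
        for pos in positions:
            index = self.indices[pos]
            if run and index == run[-1] + 1:
                run.append(index)
            else:
                if run:
                    spans.append(self._span_of(run))
                run = [index]
        if run:
            spans.append(self._span_of(run))
        return tuple(spans)

    def _span_of(self, run: Sequence[int]) -> Span:
        toks = self.sentence.tokens
        return (toks[run[0]].start, toks[run[-1]].end)

    def fragment_text(self, fragments: Sequence[Span]) -> str:
        """Surface rendering of fragments, single-space joined."""
        base = self.sentence.start
        return " ".join(
            self.sentence.text[s - base : e - base] for s, e in fragments
        )

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class OntologyMatch:
    """One ontology label matched against a contiguous candidate token run.

    ``token_range`` is (start, stop] over candidate token positions."""

    concept_id: str
    token_range: tuple[int, int]
    kind: MatchKind
    via: Literal["surface", "lemma"]
    label: str


@dataclass(frozen=True)
class HabitatMention:
    """A detected habitat entity: character fragments plus concept ids.

    More than one fragment encodes a discontinuous entity; ``text`` joins
    fragment surfaces with single spaces.
    """

    fragments: tuple[Span, ...]
    concept_ids: tuple[str, ...]
    text: str

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("a mention needs at least one fragment")
        if not self.concept_ids:
            raise ValueError("a mention needs at least one concept id")
        last = None
        for start, end in self.fragments:
            if start >= end or (last is not None and start < last):
                raise ValueError(f"fragments not ordered/disjoint: {self.fragments}")
            last = end
        deduped = tuple(dict.fromkeys(self.concept_ids))
        object.__setattr__(self, "concept_ids", deduped)

    @property
    def start(self) -> int:
        return self.fragments[0][0]


# ---------------------------------------------------------------------------
# Simplification and modifier attachment
# ---------------------------------------------------------------------------

def simplify_noun_phrase(np: NounPhrase, sentence: AnalyzedSentence) -> CandidatePhrase:
    """Drop non-informative tokens (``the mummy tissue`` -> ``mummy tissue``,
    ``its small intestine`` -> ``small intestine``) wherever they occur.

    May return an empty candidate (all tokens dropped); callers discard it.
    """
    kept = tuple(
        i
        for i in range(np.token_start, np.token_stop)
        if sentence.tokens[i].pos not in NON_INFORMATIVE_POS
    )
    return CandidatePhrase(sentence=sentence, indices=kept, source="np")


def attach_modifiers(
    candidates: Sequence[CandidatePhrase],
    sentence: AnalyzedSentence,
    preps: Iterable[str] = MODIFIER_PREPOSITIONS,
) -> list[CandidatePhrase]:
    """Add merged ``NP prep NP`` candidates for each preposition in ``preps``.

    For consecutive candidates separated by exactly one preposition token
    whose surface is in ``preps``, a candidate spanning both plus the
    preposition is appended (source ``modifier-extended``).  Originals are
    always retained.
    """
    prep_set = {p.lower() for p in preps}
    merged: list[CandidatePhrase] = list(candidates)
    for left, right in zip(candidates, candidates[1:]):
        if not left.indices or not right.indices:
            continue
        gap = range(left.indices[-1] + 1, right.indices[0])
        between = [sentence.tokens[i] for i in gap]
        if len(between) == 1 and between[0].surface.lower() in prep_set:
            merged.append(
                CandidatePhrase(
                    sentence=sentence,
                    indices=left.indices + (gap[0],) + right.indices,
                    source="modifier-extended",
                )
            )
    return merged


# ---------------------------------------------------------------------------
# Coordination
# ---------------------------------------------------------------------------

def split_coordination(
    candidate: CandidatePhrase,
) -> tuple[CandidatePhrase, CandidatePhrase] | None:
    """Split a candidate containing exactly one ``and`` into two sub-phrases.

    With left part L and right part R, shared-head completion yields
    ``L + R[1:]`` and ``R`` when R has several tokens (``pharyngeal and gut
    mucosa`` -> ``pharyngeal mucosa`` / ``gut mucosa``); a single-token R
    gives the plain split (``plants and animals`` -> ``plants`` /
    ``animals``).  Returns ``None`` when no (or more than one) ``and`` is
    present or the conjunction sits at either edge.
    """
    positions = [
        pos
        for pos, token in enumerate(candidate.tokens)
        if token.surface.lower() == "and"
    ]
    if len(positions) != 1:
        return None
    cut = positions[0]
    if cut == 0 or cut == len(candidate) - 1:
        return None
    left = candidate.indices[:cut]
    right = candidate.indices[cut + 1 :]
    if len(right) >= 2:
        sub1 = left + right[1:]
    else:
        sub1 = left
    return (
        CandidatePhrase(candidate.sentence, sub1, source="coordination-derived"),
        CandidatePhrase(candidate.sentence, right, source="coordination-derived"),
    )


def resolve_coordination(
    sub1: CandidatePhrase,
    sub2: CandidatePhrase,
    whole: CandidatePhrase,
    ontology: Ontology,
    config: RecognitionConfig = RecognitionConfig(),
) -> list[HabitatMention]:
    """Decide whether a coordinated phrase is one entity or two.

    Both sub-phrases are mapped to their best ontology concept.  If both map
    and the concepts share a direct parent, the phrase stays a single entity
    spanning the whole candidate (normalized to both concepts) — except when
    both sub-phrases are single noun tokens, which remain two entities.
    Without a shared parent, or when only one sub-phrase maps, each mapped
    sub-phrase becomes its own entity.
    """
    best1 = _best_match(sub1, ontology, config)
    best2 = _best_match(sub2, ontology, config)
    if best1 is None and best2 is None:
        return []
    if best1 is None or best2 is None:
        sub, best = (sub1, best1) if best1 is not None else (sub2, best2)
        return apply_boundary_rules(sub, [best])
    common = ontology.direct_parents(best1.concept_id) & ontology.direct_parents(
        best2.concept_id
    )
    both_single_nouns = all(
        len(sub) == 1 and sub.tokens[0].pos.startswith("NN") for sub in (sub1, sub2)
    )
    if common and not both_single_nouns:
        ids = tuple(dict.fromkeys((best1.concept_id, best2.concept_id)))
        fragments = whole.fragments
        return [
            HabitatMention(
                fragments=fragments,
                concept_ids=ids,
                text=whole.fragment_text(fragments),
            )
        ]
    return apply_boundary_rules(sub1, [best1]) + apply_boundary_rules(sub2, [best2])


def _best_match(
    candidate: CandidatePhrase, ontology: Ontology, config: RecognitionConfig
) -> OntologyMatch | None:
    """Best single match: exact > prefix > internal, then longer range,
    then lexicographically smallest concept id."""
    matches = match_ontology(candidate, ontology, config)
    if not matches:
        return None
    return min(
        matches,
        key=lambda m: (
            _KIND_RANK[m.kind],
            -(m.token_range[1] - m.token_range[0]),
            m.concept_id,
        ),
    )


# ---------------------------------------------------------------------------
# Ontology matching and boundary rules
# ---------------------------------------------------------------------------

def match_ontology(
    candidate: CandidatePhrase,
    ontology: Ontology,
    config: RecognitionConfig = RecognitionConfig(),
) -> list[OntologyMatch]:
    """All ontology labels matching a contiguous run of candidate tokens.

    Surface and lemma streams are searched simultaneously (surface wins when
    both hit the same concept and range); per concept only maximal token
    ranges survive.  Matching is whole-token: a label never matches inside a
    token.
    """
    n = len(candidate)
    if n == 0:
        return []
    surfaces = [t.surface for t in candidate.tokens]
    lemmas = [t.lemma for t in candidate.tokens]
    streams: list[tuple[str, list[str]]] = [("surface", surfaces)]
    if config.lemma_matching:
        streams.append(("lemma", lemmas))
    found: dict[tuple[str, tuple[int, int]], tuple[str, str]] = {}
    for start in range(n):
        for stop in range(start + 1, n + 1):
            for via, stream in streams:
                key = normalize_label(" ".join(stream[start:stop]))
                if not key:
                    continue
                for cid in ontology.lookup_label(
                    key, include_related=config.related_synonyms
                ):
                    slot = (cid, (start, stop))
                    prev = found.get(slot)
                    if prev is None or (prev[0] == "lemma" and via == "surface"):
                        found[slot] = (via, _matched_label(ontology, cid, key))
    # keep only maximal ranges per concept
    maximal: list[OntologyMatch] = []
    for (cid, (start, stop)), (via, label) in found.items():
        dominated = any(
            ocid == cid
            and (ostart, ostop) != (start, stop)
            and ostart <= start
            and ostop >= stop
            for (ocid, (ostart, ostop)) in found
        )
        if dominated:
            continue
        if start == 0 and stop == n:
            kind: MatchKind = "exact"
        elif start == 0:
            kind = "prefix_partial"
        else:
            kind = "internal_partial"
        maximal.append(
            OntologyMatch(
                concept_id=cid,
                token_range=(start, stop),
                kind=kind,
                via=via,  # type: ignore[arg-type]
                label=label,
            )
        )
    maximal.sort(key=lambda m: (m.token_range[0], -m.token_range[1], m.concept_id))
    return maximal


def _matched_label(ontology: Ontology, concept_id: str, key: str) -> str:
    for label in ontology[concept_id].labels:
        if normalize_label(label) == key:
            return label
    return key


def apply_boundary_rules(
    candidate: CandidatePhrase, matches: Sequence[OntologyMatch]
) -> list[HabitatMention]:
    """Turn matches into mentions via the three boundary rules; mentions with
    identical fragments are merged, concatenating their concept ids."""
    by_fragments: dict[tuple[Span, ...], list[str]] = {}
    for match in matches:
        if match.kind == "prefix_partial":
            fragments = candidate._fragments_for(range(*match.token_range))
        else:  # exact and internal_partial cover the whole candidate
            fragments = candidate.fragments
        by_fragments.setdefault(fragments, []).append(match.concept_id)
    return [
        HabitatMention(
            fragments=fragments,
            concept_ids=tuple(dict.fromkeys(ids)),
            text=candidate.fragment_text(fragments),
        )
        for fragments, ids in by_fragments.items()
    ]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def detect_entities(
    doc: AnalyzedDocument,
    ontology: Ontology,
    config: RecognitionConfig = RecognitionConfig(),
) -> list[HabitatMention]:
    """Full recognition pipeline over an analyzed document.

    Extract noun phrases, simplify, optionally attach prepositional
    modifiers, route coordinated candidates through the split/resolve path
    and the rest through match + boundary rules; output is deduplicated by
    (fragments, concept ids) and ordered by first fragment start.
    """
    from .analysis import extract_noun_phrases  # local to avoid cycle at import time

    mentions: list[HabitatMention] = []
    for sentence in doc.sentences:
        candidates = [
            simplify_noun_phrase(np, sentence)
            for np in extract_noun_phrases(sentence)
        ]
        candidates = [c for c in candidates if len(c) > 0]
        if config.modifier_preps:
            candidates = attach_modifiers(candidates, sentence, config.modifier_preps)
        for candidate in candidates:
            split = split_coordination(candidate) if config.coordination else None
            if split is not None:
                mentions.extend(
                    resolve_coordination(split[0], split[1], candidate, ontology, config)
                )
            else:
                matches = match_ontology(candidate, ontology, config)
                mentions.extend(apply_boundary_rules(candidate, matches))
    unique: dict[tuple, HabitatMention] = {}
    for mention in mentions:
        unique.setdefault((mention.fragments, mention.concept_ids), mention)
    return sorted(unique.values(), key=lambda m: (m.fragments[0][0], m.fragments[-1][1]))
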