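"""Bacteria-habitat relation extraction.

Two strategies produce Localization relations between bacteria and
habitat/geographical entities:

* **paragraph-based** — discourse is assumed to change with a new paragraph;
  the first bacterium mentioned in a paragraph is its topic and is linked to
  every habitat in the paragraph.  If the same name (or, for ``strain``-
  bearing names, the name with the word ``strain`` removed) occurs earlier in
  the document, the relation anchors to that first occurrence.
* **sentence-based** — every *specific* bacterium in a sentence is linked to
  every habitat in the sentence.  Generic words such as ``bacteria`` and
  ``bacterium``, although annotated as bacteria entities, are not specific.
  Sentences without a specific bacterium go through anaphora resolution.

Anaphora resolution covers three patterns: (1) a sentence containing one of a
keyword list of anaphoric expressions (``this organism``, ``the bacterium``,
...) resolves to the first bacterium of the previous sentence, falling back
to the first bacterium of the document; (2) a sentence beginning with ``it``
resolves to the first bacterium of the previous sentence; (3) a sentence
beginning with ``this strain`` resolves to the first bacterium of the
document.

PartOf relations between habitats come from two syntax rules over
overlapping mentions: the contained habitat directly follows *of*/*in*/*from*
inside the containing mention (``rhizosphere of plants`` PartOf ``plants``),
or it is a prefix of the containing mention (``Aeschynomene stem nodule``
PartOf ``Aeschynomene``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .analysis import AnalyzedDocument, AnalyzedSentence, Span

#: Bacteria entity surfaces considered non-specific.
GENERIC_BACTERIA = frozenset({"bacteria", "bacterium"})

#: Determiner-like words skipped between a preposition and a habitat start
#: when testing PartOf syntax rule 1 (the annotated habitat boundary often
#: excludes a leading article, as in "from a Lyme disease patient ...").
_SKIPPABLE_BEFORE_HOST = frozenset({"a", "an", "the", "this", "that", "these", "those"})

_WORD_RE = re.compile(r"\w+(?:[-'’]\w+)*", re.UNICODE)


@dataclass(frozen=True)
class EntityRef:
    """An annotated entity: standoff id, type, fragments, surface text.

    ``sentence_index``/``paragraph_index`` locate the first fragment once
    :func:`assign_positions` has been applied.
    """

    id: str
    etype: str  # Bacteria | Habitat | Geographical
    fragments: tuple[Span, ...]
    text: str
    sentence_index: int | None = None
    paragraph_index: int | None = None

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError(f"entity {self.id}: no fragments")
        last = None
        for start, end in self.fragments:
            if start >= end or (last is not None and start < last):
                raise ValueError(f"entity {self.id}: bad fragments {self.fragments}")
            last = end

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]


@dataclass(frozen=True)
class Relation:
    """A typed binary relation.

    Localization: ``arg1`` is the bacterium, ``arg2`` the habitat or
    geographical location.  PartOf: ``arg1`` is the part (the contained,
    more specific habitat mention), ``arg2`` the host.
    """

    rtype: str  # Localization | PartOf
    arg1: EntityRef
    arg2: EntityRef

    def __post_init__(self) -> None:
        if self.arg1.id == self.arg2.id and self.arg1.fragments == self.arg2.fragments:
            raise ValueError("a relation needs two distinct entities")
        if self.rtype == "Localization":
            if self.arg1.etype != "Bacteria":
                raise ValueError("Localization arg1 must be a Bacteria entity")
            if self.arg2.etype not in ("Habitat", "Geographical"):
                raise ValueError("Localization arg2 must be Habitat or Geographical")
        elif self.rtype == "PartOf":
            if self.arg1.etype != "Habitat" or self.arg2.etype != "Habitat":
                raise ValueError("PartOf relates two Habitat entities")
        else:
            raise ValueError(f"unknown relation type {self.rtype!r}")

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.rtype, self.arg1.id, self.arg2.id)


@dataclass(frozen=True)
class AnaphoraConfig:
    """Anaphora machinery settings; expressions are lowercase token strings."""

    type1_expressions: tuple[str, ...]
    type2_pronoun: str = "it"
    type3_prefix: str = "this strain"

    def __post_init__(self) -> None:
        if not self.type1_expressions:
            raise ValueError("type1_expressions must be non-empty")
        lowered = tuple(e.strip().lower() for e in self.type1_expressions)
        if any(not e for e in lowered):
            raise ValueError("empty anaphoric expression")
        object.__setattr__(self, "type1_expressions", lowered)


#: Default anaphoric-expression list: the documented core expressions plus
#: systematic number/lexical variants.  Fully overridable.
DEFAULT_TYPE1_EXPRESSIONS: tuple[str, ...] = (
    "the bacterium",
    "this organism",
    "this species",
    "this genus",
    "this group of organisms",
    "this bacterium",
    "the organism",
    "the species",
    "the genus",
    "this bacteria",
    "the bacteria",
    "these bacteria",
    "these organisms",
    "these species",
    "this group of bacteria",
    "this microorganism",
    "the microorganism",
    "these microorganisms",
    "this microbe",
    "the microbe",
    "this pathogen",
    "the pathogen",
    "these pathogens",
)


def default_anaphora_config() -> AnaphoraConfig:
    return AnaphoraConfig(type1_expressions=DEFAULT_TYPE1_EXPRESSIONS)


def load_anaphora_keywords(lines: Iterable[str]) -> AnaphoraConfig:
    """Build a config from a plain-text keyword list, one expression per line
    (blank lines and ``#`` comments ignored)."""
    expressions = tuple(
        line.strip().lower()
        for line in lines
        if line.strip() and not line.lstrip().startswith("#")
    )
    return AnaphoraConfig(type1_expressions=expressions)


# ---------------------------------------------------------------------------
# Positioning helpers
# ---------------------------------------------------------------------------

def assign_positions(
    entities: Iterable[EntityRef], doc: AnalyzedDocument
) -> list[EntityRef]:
    """Attach sentence and paragraph indices based on each entity's first
    fragment start."""
    positioned = []
    for entity in entities:
        sentence = doc.sentence_containing(entity.start)
        if sentence is None:
            raise ValueError(
                f"entity {entity.id} at offset {entity.start} lies outside "
                "every sentence"
            )
        positioned.append(
            replace(
                entity,
                sentence_index=sentence.sentence_index,
                paragraph_index=sentence.paragraph_index,
            )
        )
    return positioned


def _first(entities: Iterable[EntityRef]) -> EntityRef | None:
    ordered = sorted(entities, key=lambda e: (e.start, e.end))
    return ordered[0] if ordered else None


# ---------------------------------------------------------------------------
# Specificity
# ---------------------------------------------------------------------------

def is_specific_bacteria(
    entity: EntityRef, generic: frozenset[str] = GENERIC_BACTERIA
) -> bool:
    """Whether a bacteria entity names an actual taxon rather than a generic
    word like ``bacteria``/``bacterium`` (case-insensitive)."""
    if entity.etype != "Bacteria":
        raise ValueError(f"entity {entity.id} is not a Bacteria entity")
    return entity.text.strip().lower() not in generic


# ---------------------------------------------------------------------------
# Paragraph-based Localization
# ---------------------------------------------------------------------------

def extract_paragraph_based(
    doc: AnalyzedDocument, entities: Sequence[EntityRef]
) -> list[Relation]:
    """Link every habitat/geographical entity in a paragraph to the
    paragraph's topic bacterium (with the earlier-occurrence and ``strain``
    re-anchoring rules)."""
    positioned = assign_positions(entities, doc)
    bacteria = [e for e in positioned if e.etype == "Bacteria"]
    targets = [e for e in positioned if e.etype in ("Habitat", "Geographical")]
    relations: list[Relation] = []
    seen: set[tuple[str, str, str]] = set()
    for p_index in range(len(doc.paragraphs)):
        para_bacteria = [b for b in bacteria if b.paragraph_index == p_index]
        para_targets = sorted(
            (t for t in targets if t.paragraph_index == p_index),
            key=lambda e: (e.start, e.end),
        )
        if not para_bacteria or not para_targets:
            continue
        anchor = _first(para_bacteria)
        assert anchor is not None
        anchor = _reanchor(anchor, bacteria)
        for target in para_targets:
            rel = Relation("Localization", anchor, target)
            if rel.key not in seen:
                seen.add(rel.key)
                relations.append(rel)
    return relations


def _reanchor(anchor: EntityRef, bacteria: Sequence[EntityRef]) -> EntityRef:
    """Earlier-occurrence re-anchoring, with the ``strain`` removal rule."""
    tokens = anchor.text.split()
    if "strain" in tokens:
        stripped = " ".join(t for t in tokens if t != "strain")
        matches = [b for b in bacteria if b.text == stripped]
        if matches:
            return min(matches, key=lambda e: (e.start, e.end))
        return anchor
    earlier = [b for b in bacteria if b.text == anchor.text and b.start < anchor.start]
    if earlier:
        return min(earlier, key=lambda e: (e.start, e.end))
    return anchor


# ---------------------------------------------------------------------------
# Anaphora resolution and sentence-based Localization
# ---------------------------------------------------------------------------

def _sentence_words(sentence: AnalyzedSentence) -> list[str]:
    return [t.surface.lower() for t in sentence.tokens]


def _contains_expression(words: Sequence[str], expression: str) -> bool:
    needle = expression.split()
    n = len(needle)
    return any(words[i : i + n] == needle for i in range(len(words) - n + 1))


def resolve_anaphora(
    sentence: AnalyzedSentence,
    doc: AnalyzedDocument,
    entities: Sequence[EntityRef],
    config: AnaphoraConfig,
) -> EntityRef | None:
    """Antecedent for a sentence without a specific bacteria entity, or None.

    Checked in order: keyword-list expressions (type 1), sentence-initial
    ``it`` (type 2), sentence-initial ``this strain`` (type 3).
    """
    positioned = (
        list(entities)
        if all(e.sentence_index is not None for e in entities)
        else assign_positions(entities, doc)
    )
    bacteria = [e for e in positioned if e.etype == "Bacteria"]
    words = _sentence_words(sentence)
    if not words:
        return None
    prev_index = sentence.sentence_index - 1
    prev_bacteria = [b for b in bacteria if b.sentence_index == prev_index]

    if any(_contains_expression(words, expr) for expr in config.type1_expressions):
        return _first(prev_bacteria) or _first(bacteria)
    if words[0] == config.type2_pronoun.lower():
        if prev_index < 0:
            return None
        return _first(prev_bacteria)
    prefix = config.type3_prefix.lower().split()
    if words[: len(prefix)] == prefix:
        return _first(bacteria)
    return None


def extract_sentence_based(
    doc: AnalyzedDocument,
    entities: Sequence[EntityRef],
    config: AnaphoraConfig | None = None,
    generic: frozenset[str] = GENERIC_BACTERIA,
) -> list[Relation]:
    """Sentence-level co-occurrence extraction with optional anaphora.

    Every specific bacterium in a sentence pairs with every habitat or
    geographical entity in that sentence; sentences without one fall back to
    anaphora resolution when ``config`` is given.  Relations are deduplicated
    document-wide.
    """
    positioned = assign_positions(entities, doc)
    relations: list[Relation] = []
    seen: set[tuple[str, str, str]] = set()
    for sentence in doc.sentences:
        in_sentence = [e for e in positioned if e.sentence_index == sentence.sentence_index]
        specific = sorted(
            (
                e
                for e in in_sentence
                if e.etype == "Bacteria" and is_specific_bacteria(e, generic)
            ),
            key=lambda e: (e.start, e.end),
        )
        targets = sorted(
            (e for e in in_sentence if e.etype in ("Habitat", "Geographical")),
            key=lambda e: (e.start, e.end),
        )
        if not targets:
            continue
        anchors: list[EntityRef] = specific
        if not anchors and config is not None:
            antecedent = resolve_anaphora(sentence, doc, positioned, config)
            if antecedent is not None:
                anchors = [antecedent]
        for bacterium in anchors:
            for target in targets:
                rel = Relation("Localization", bacterium, target)
                if rel.key not in seen:
                    seen.add(rel.key)
                    relations.append(rel)
    return relations


# ---------------------------------------------------------------------------
# PartOf extraction
# ---------------------------------------------------------------------------

def _coverage(entity: EntityRef) -> set[int]:
    return {pos for start, end in entity.fragments for pos in range(start, end)}


def _words_of(text: str) -> list[str]:
    return [w.lower() for w in _WORD_RE.findall(text)]


def extract_partof(
    entities: Sequence[EntityRef], doc: AnalyzedDocument
) -> list[Relation]:
    """PartOf relations between overlapping habitat mentions.

    Rule 1: the containing mention A embeds mention B right after one of the
    prepositions *of*/*in*/*from* (articles between the preposition and B are
    tolerated) -> A PartOf B, i.e. part=A, host=B.  Rule 2: B is a proper
    prefix of A's token sequence -> A PartOf B.  Results deduplicated and
    ordered by position.
    """
    habitats = [e for e in entities if e.etype == "Habitat"]
    relations: list[Relation] = []
    seen: set[tuple[str, str, str]] = set()
    for part in habitats:
        part_cov = _coverage(part)
        part_words = _words_of(part.text)
        for host in habitats:
            if host.id == part.id:
                continue
            host_cov = _coverage(host)
            if not host_cov <= part_cov or host_cov == part_cov:
                continue
            host_words = _words_of(host.text)
            if not _is_subsequence(host_words, part_words):
                continue
            fired = False
            if _follows_preposition(part, host, doc):
                fired = True
            elif part_words[: len(host_words)] == host_words and len(host_words) < len(
                part_words
            ):
                fired = True
            if fired:
                rel = Relation("PartOf", part, host)
                if rel.key not in seen:
                    seen.add(rel.key)
                    relations.append(rel)
    relations.sort(key=lambda r: (r.arg1.start, r.arg2.start))
    return relations


def _is_subsequence(needle: list[str], haystack: list[str]) -> bool:
    n = len(needle)
    return n > 0 and any(
        haystack[i : i + n] == needle for i in range(len(haystack) - n + 1)
    )


def _follows_preposition(
    part: EntityRef, host: EntityRef, doc: AnalyzedDocument
) -> bool:
    """Is the host mention, inside the part mention, directly preceded by
    *of*/*in*/*from* (skipping determiners)?"""
    offset = host.start
    part_start = part.start
    while True:
        token = doc.token_before(offset)
        if token is None or token.start < part_start:
            return False
        word = token.surface.lower()
        if word in _SKIPPABLE_BEFORE_HOST:
            offset = token.start
            continue
        return word in ("of", "in", "from")
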