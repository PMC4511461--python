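"""Habitat ontology store backed by the OBO 1.2 flat-file format.

The habitat vocabulary (OntoBiotope-style, ``MBTO:NNNNNNNN`` identifiers) is a
DAG of concepts linked by ``is_a`` relations.  Each concept carries a preferred
name plus exact and related synonyms; all labels are indexed after a light
normalization (lowercasing, whitespace collapsing, edge-punctuation stripping)
so that dictionary lookup is insensitive to case and spacing.

Beyond parsing and querying, the module supports expanding an ontology with
surface forms harvested from annotated training data: an annotated string is
added as an exact synonym of the concept it was labeled with, unless that
concept already carries it as a name or synonym.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter
from typing import IO, Iterable, Iterator, Mapping, Union


class OntologyError(Exception):
    """Base class for ontology-related failures."""


class OboParseError(OntologyError):
    """A stanza in an OBO stream is malformed."""


class OntologyValidationError(OntologyError):
    """The concept set violates a structural invariant."""


class UnknownConceptError(OntologyError, KeyError):
    """A concept id was looked up that is not in the ontology."""


_WS_RE = re.compile(r"\s+")
_EDGE_RE = re.compile(r"^[\W_]+|[\W_]+$", re.UNICODE)


def normalize_label(label: str) -> str:
    """Normalize a label for indexing: lowercase, collapse internal
    whitespace, strip surrounding (but not internal) punctuation."""
    collapsed = _WS_RE.sub(" ", label.strip().lower())
    return _EDGE_RE.sub("", collapsed)


@dataclass(frozen=True)
class OntologyConcept:
    """A single habitat concept.

    Parameters
    ----------
    id:
        Concept identifier, conventionally ``MBTO:`` followed by digits.
    name:
        Preferred label (non-empty).
    exact_synonyms, related_synonyms:
        Alternative labels.  No synonym may duplicate the name or another
        synonym of the same concept (case-insensitive).
    parents:
        Ids of direct ``is_a`` ancestors.
    obsolete:
        Obsolete concepts are retained but excluded from label indexing.
    """

    id: str
    name: str
    exact_synonyms: tuple[str, ...] = ()
    related_synonyms: tuple[str, ...] = ()
    parents: frozenset[str] = frozenset()
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("concept id must be non-empty")
        if not self.name or not self.name.strip():
            raise ValueError(f"concept {self.id!r}: name must be non-empty")
        object.__setattr__(self, "exact_synonyms", tuple(self.exact_synonyms))
        object.__setattr__(self, "related_synonyms", tuple(self.related_synonyms))
        object.__setattr__(self, "parents", frozenset(self.parents))
        seen = {normalize_label(self.name)}
        for syn in (*self.exact_synonyms, *self.related_synonyms):
            key = normalize_label(syn)
            if key in seen:
                raise ValueError(
                    f"concept {self.id!r}: synonym {syn!r} duplicates the name "
                    "or another synonym (case-insensitive)"
                )
            seen.add(key)

    @property
    def labels(self) -> tuple[str, ...]:
        """Name followed by all synonyms."""
        return (self.name, *self.exact_synonyms, *self.related_synonyms)


@dataclass(frozen=True)
class TrainingAnnotation:
    """A training-set surface string labeled with an ontology concept."""

    surface_text: str
    concept_id: str


class Ontology:
    """An immutable collection of :class:`OntologyConcept` with label lookup.

    Construction validates the structural invariants: unique ids, every
    referenced parent present, and an acyclic ``is_a`` graph.
    """

    def __init__(self, concepts: Iterable[OntologyConcept]):
        store: dict[str, OntologyConcept] = {}
        for concept in concepts:
            if concept.id in store:
                raise OntologyValidationError(f"duplicate concept id {concept.id!r}")
            store[concept.id] = concept
        missing = sorted(
            {p for c in store.values() for p in c.parents if p not in store}
        )
        if missing:
            raise OntologyValidationError(
                "dangling is_a target(s): " + ", ".join(missing)
            )
        sorter = TopologicalSorter(
            {cid: sorted(c.parents) for cid, c in store.items()}
        )
        try:
            sorter.prepare()
        except CycleError as exc:
            raise OntologyValidationError(f"is_a graph contains a cycle: {exc.args[1]}") from exc
        self._concepts = store
        # label -> {(concept id, is_related)}; obsolete terms are not indexed
        entries: dict[str, set[tuple[str, bool]]] = {}
        for c in store.values():
            if c.obsolete:
                continue
            for label in (c.name, *c.exact_synonyms):
                key = normalize_label(label)
                if key:
                    entries.setdefault(key, set()).add((c.id, False))
            for label in c.related_synonyms:
                key = normalize_label(label)
                if key:
                    entries.setdefault(key, set()).add((c.id, True))
        self._label_entries = entries

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._concepts)

    def __iter__(self) -> Iterator[OntologyConcept]:
        return iter(self._concepts.values())

    def __contains__(self, concept_id: object) -> bool:
        return concept_id in self._concepts

    def __getitem__(self, concept_id: str) -> OntologyConcept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise UnknownConceptError(concept_id) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return self._concepts == other._concepts

    @property
    def concepts(self) -> Mapping[str, OntologyConcept]:
        return dict(self._concepts)

    @property
    def label_index(self) -> dict[str, frozenset[str]]:
        """Normalized label -> ids of the (non-obsolete) concepts carrying it."""
        return {
            label: frozenset(cid for cid, _ in entries)
            for label, entries in self._label_entries.items()
        }

    # -- queries ------------------------------------------------------------

    def lookup_label(self, label: str, include_related: bool = True) -> frozenset[str]:
        """Ids of concepts whose name or synonym matches ``label`` after
        normalization.  With ``include_related=False`` only names and EXACT
        synonyms participate."""
        entries = self._label_entries.get(normalize_label(label), ())
        return frozenset(
            cid for cid, related in entries if include_related or not related
        )

    def direct_parents(self, concept_id: str) -> frozenset[str]:
        """The distance-1 ``is_a`` ancestors of a concept (empty for roots)."""
        return self[concept_id].parents

    def ancestors(self, concept_id: str, include_self: bool = False) -> frozenset[str]:
        """Transitive closure of ``is_a``; optionally includes the concept."""
        self[concept_id]  # raise for unknown ids
        seen: set[str] = set()
        frontier = [concept_id]
        while frontier:
            current = frontier.pop()
            for parent in self._concepts[current].parents:
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        if include_self:
            seen.add(concept_id)
        return frozenset(seen)


# ---------------------------------------------------------------------------
# OBO parsing and serialization
# ---------------------------------------------------------------------------

_SYNONYM_RE = re.compile(r'synonym:\s*"((?:[^"\\]|\\.)*)"\s*([A-Z_]*)')
_IS_A_RE = re.compile(r"is_a:\s*(\S+)")

Source = Union[str, IO[str], Iterable[str]]


def _iter_lines(source: Source) -> Iterator[str]:
    if isinstance(source, str):
        yield from source.splitlines()
    else:
        for line in source:
            yield line.rstrip("\n")


def parse_obo(source: Source) -> Ontology:
    """Parse OBO 1.2-style ``[Term]`` stanzas into an :class:`Ontology`.

    Recognized tags: ``id``, ``name``, ``synonym`` (EXACT scope gives an exact
    synonym; any other scope a related one), ``is_a``, ``is_obsolete``.  A
    stanza missing ``id`` or ``name`` raises :class:`OboParseError` naming the
    line; a dangling ``is_a`` target raises :class:`OntologyValidationError`.
    """
    concepts: list[OntologyConcept] = []
    stanza: dict[str, object] | None = None
    stanza_line = 0

    def finish(line_no: int) -> None:
        nonlocal stanza
        if stanza is None:
            return
        if "id" not in stanza:
            raise OboParseError(f"[Term] stanza at line {stanza_line} has no id")
        if "name" not in stanza:
            raise OboParseError(
                f"[Term] stanza at line {stanza_line} (id {stanza['id']!r}) has no name"
            )
        name_key = normalize_label(str(stanza["name"]))
        seen = {name_key}
        exact: list[str] = []
        related: list[str] = []
        for syn, scope in stanza.get("synonyms", []):  # type: ignore[union-attr]
            key = normalize_label(syn)
            if not key or key in seen:
                continue
            seen.add(key)
            (exact if scope == "EXACT" else related).append(syn)
        concepts.append(
            OntologyConcept(
                id=str(stanza["id"]),
                name=str(stanza["name"]),
                exact_synonyms=tuple(exact),
                related_synonyms=tuple(related),
                parents=frozenset(stanza.get("parents", ())),  # type: ignore[arg-type]
                obsolete=bool(stanza.get("obsolete", False)),
            )
        )
        stanza = None

    line_no = 0
    for line_no, raw in enumerate(_iter_lines(source), start=1):
        line = raw.strip()
        if line.startswith("!"):
            continue
        if line.startswith("["):
            finish(line_no)
            if line == "[Term]":
                stanza = {"synonyms": [], "parents": set()}
                stanza_line = line_no
            continue
        if stanza is None or not line:
            continue
        if line.startswith("id:"):
            stanza["id"] = line[3:].split("!", 1)[0].strip()
        elif line.startswith("name:"):
            stanza["name"] = line[5:].split("!", 1)[0].strip()
        elif line.startswith("synonym:"):
            m = _SYNONYM_RE.match(line)
            if not m:
                raise OboParseError(f"malformed synonym line {line_no}: {line!r}")
            text = m.group(1).replace('\\"', '"')
            stanza["synonyms"].append((text, m.group(2) or "RELATED"))  # type: ignore[union-attr]
        elif line.startswith("is_a:"):
            m = _IS_A_RE.match(line.split("!", 1)[0])
            if not m:
                raise OboParseError(f"malformed is_a line {line_no}: {line!r}")
            stanza["parents"].add(m.group(1))  # type: ignore[union-attr]
        elif line.startswith("is_obsolete:"):
            stanza["obsolete"] = line.split(":", 1)[1].strip().lower() == "true"
        # other tags are ignored
    finish(line_no + 1)
    return Ontology(concepts)


def serialize_obo(ontology: Ontology) -> str:
    """Write an ontology back to OBO text; deterministic (stanzas sorted by
    id, parents sorted), so serialize -> parse -> serialize is bit-stable."""
    parts = ["format-version: 1.2", ""]
    for cid in sorted(ontology.concepts):
        concept = ontology[cid]
        parts.append("[Term]")
        parts.append(f"id: {concept.id}")
        parts.append(f"name: {concept.name}")
        for syn in concept.exact_synonyms:
            parts.append(f'synonym: "{syn.replace(chr(34), chr(92) + chr(34))}" EXACT')
        for syn in concept.related_synonyms:
            parts.append(f'synonym: "{syn.replace(chr(34), chr(92) + chr(34))}" RELATED')
        for parent in sorted(concept.parents):
            parts.append(f"is_a: {parent} ! {ontology[parent].name}")
        if concept.obsolete:
            parts.append("is_obsolete: true")
        parts.append("")
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# Training-set expansion
# ---------------------------------------------------------------------------

def expand_from_annotations(
    ontology: Ontology, annotations: Iterable[TrainingAnnotation]
) -> Ontology:
    """Return a new ontology where each annotated surface form has been added
    as an exact synonym of its concept, unless the concept already defines it
    as a name or synonym (compared case-insensitively, after normalization).

    The operation is idempotent and leaves the input ontology untouched.
    Annotations naming unknown concepts are collected and reported together.
    """
    annotations = list(annotations)
    unknown = sorted({a.concept_id for a in annotations if a.concept_id not in ontology})
    if unknown:
        raise OntologyValidationError(
            "annotation(s) reference unknown concept id(s): " + ", ".join(unknown)
        )
    added: dict[str, list[str]] = {}
    known: dict[str, set[str]] = {}
    for ann in annotations:
        concept = ontology[ann.concept_id]
        if ann.concept_id not in known:
            known[ann.concept_id] = {normalize_label(l) for l in concept.labels}
        key = normalize_label(ann.surface_text)
        if not key or key in known[ann.concept_id]:
            continue
        known[ann.concept_id].add(key)
        added.setdefault(ann.concept_id, []).append(ann.surface_text)
    if not added:
        return Ontology(ontology.concepts.values())
    rebuilt = []
    for cid, concept in ontology.concepts.items():
        extra = added.get(cid)
        if extra:
            concept = OntologyConcept(
                id=concept.id,
                name=concept.name,
                exact_synonyms=concept.exact_synonyms + tuple(extra),
                related_synonyms=concept.related_synonyms,
                parents=concept.parents,
                obsolete=concept.obsolete,
            )
        rebuilt.append(concept)
    return Ontology(rebuilt)


def expansion_report(original: Ontology, expanded: Ontology) -> list[tuple[str, str]]:
    """(concept id, added synonym) pairs distinguishing ``expanded`` from
    ``original``; suitable for a tab-separated report."""
    report: list[tuple[str, str]] = []
    for cid in sorted(expanded.concepts):
        before = set(original[cid].exact_synonyms) if cid in original else set()
        for syn in expanded[cid].exact_synonyms:
            if syn not in before:
                report.append((cid, syn))
    return report
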