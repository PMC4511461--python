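"""Reader/writer for the BioNLP-ST standoff dialect (.txt / .a1 / .a2).

Entities are ``T#`` lines with possibly discontinuous, semicolon-separated
offset fragments; normalizations are ``N#`` lines tying an entity to an
``MBTO:`` concept (``OntoBiotope Annotation:T# Referent:MBTO:#``); relations
are ``R#`` lines (``Localization Bacterium:T# Localization:T#`` and
``PartOf Host:T# Part:T#``).  Offsets count 0-based, end-exclusive code
points.  The recorded entity text of a discontinuous span may be either the
exact concatenation of the fragments or their single-space join; the writer
always emits the single-space join.

Serialization is canonical — entities keep their ids but are ordered by
first fragment start, and normalization/relation lines are renumbered
sequentially — so writing is deterministic and re-reading a written
document reproduces it structurally.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import TrainingAnnotation
from .relations import EntityRef, Relation

logger = logging.getLogger(__name__)


class StandoffError(Exception):
    """Base class for standoff I/O failures."""


class StandoffIntegrityError(StandoffError):
    """An annotation contradicts the document text or references are broken."""


_ENTITY_RE = re.compile(r"^(T\d+)\t(\S+) (\d+ \d+(?:;\d+ \d+)*)\t(.*)$")
_NORM_RE = re.compile(r"^(N\d+)\t(\S+) Annotation:(T\d+) Referent:(\S+)$")
_REL_RE = re.compile(r"^(R\d+)\t(\S+) (\S+):(T\d+) (\S+):(T\d+)$")


@dataclass(frozen=True)
class Normalization:
    id: str
    entity_id: str
    referent: str  # MBTO concept id


@dataclass(frozen=True)
class StandoffDocument:
    doc_id: str
    text: str
    entities: tuple[EntityRef, ...] = ()
    a2_entity_ids: frozenset[str] = frozenset()
    normalizations: tuple[Normalization, ...] = ()
    relations: tuple[Relation, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "entities", tuple(self.entities))
        object.__setattr__(self, "normalizations", tuple(self.normalizations))
        object.__setattr__(self, "relations", tuple(self.relations))
        object.__setattr__(self, "a2_entity_ids", frozenset(self.a2_entity_ids))
        validate_document(self)

    @property
    def entity_map(self) -> dict[str, EntityRef]:
        return {e.id: e for e in self.entities}

    def a1_entities(self) -> list[EntityRef]:
        return [e for e in self.entities if e.id not in self.a2_entity_ids]

    def a2_entities(self) -> list[EntityRef]:
        return [e for e in self.entities if e.id in self.a2_entity_ids]

    def content_key(self):
        """Structural identity ignoring identifier numbering."""
        ents = {
            e.id: (e.etype, e.fragments, e.text, e.id in self.a2_entity_ids)
            for e in self.entities
        }
        return (
            self.doc_id,
            self.text,
            frozenset(ents.values()),
            frozenset((ents[n.entity_id], n.referent) for n in self.normalizations),
            frozenset(
                (r.rtype, ents[r.arg1.id], ents[r.arg2.id]) for r in self.relations
            ),
        )


def validate_document(doc: StandoffDocument) -> None:
    ids: set[str] = set()
    for entity in doc.entities:
        if entity.id in ids:
            raise StandoffIntegrityError(
                f"{doc.doc_id}: duplicate entity id {entity.id}"
            )
        ids.add(entity.id)
        _check_entity_text(doc.text, entity, doc.doc_id)
    norm_ids: set[str] = set()
    for norm in doc.normalizations:
        if norm.id in norm_ids:
            raise StandoffIntegrityError(f"{doc.doc_id}: duplicate id {norm.id}")
        norm_ids.add(norm.id)
        if norm.entity_id not in ids:
            raise StandoffIntegrityError(
                f"{doc.doc_id}: normalization {norm.id} references missing "
                f"entity {norm.entity_id}"
            )
    entity_map = doc.entity_map
    for relation in doc.relations:
        for arg in (relation.arg1, relation.arg2):
            known = entity_map.get(arg.id)
            # positioned copies (sentence/paragraph indices filled in) are fine
            if known is None or (known.etype, known.fragments, known.text) != (
                arg.etype,
                arg.fragments,
                arg.text,
            ):
                raise StandoffIntegrityError(
                    f"{doc.doc_id}: relation references entity {arg.id} that is "
                    "absent or inconsistent"
                )


def _check_entity_text(text: str, entity: EntityRef, doc_id: str) -> None:
    if entity.end > len(text):
        raise StandoffIntegrityError(
            f"{doc_id}: entity {entity.id} offset {entity.end} beyond text end "
            f"({len(text)})"
        )
    pieces = [text[s:e] for s, e in entity.fragments]
    if entity.text not in ("".join(pieces), " ".join(pieces)):
        raise StandoffIntegrityError(
            f"{doc_id}: entity {entity.id} text {entity.text!r} does not match "
            f"fragments {pieces!r}"
        )


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_standoff(
    txt: str,
    a1: str = "",
    a2: str | None = None,
    doc_id: str = "",
) -> StandoffDocument:
    """Parse a document from its text plus ``.a1`` and optional ``.a2``
    annotation streams into a validated :class:`StandoffDocument`."""
    entities: list[EntityRef] = []
    a2_ids: set[str] = set()
    normalizations: list[Normalization] = []
    raw_relations: list[tuple[str, str, str, str, str, str]] = []

    def consume(stream: str, layer: str) -> None:
        for line_no, line in enumerate(stream.splitlines(), start=1):
            if not line.strip():
                continue
            m = _ENTITY_RE.match(line)
            if m:
                tid, etype, offsets, text = m.groups()
                fragments = tuple(
                    (int(pair.split()[0]), int(pair.split()[1]))
                    for pair in offsets.split(";")
                )
                entities.append(EntityRef(tid, etype, fragments, text))
                if layer == "a2":
                    a2_ids.add(tid)
                continue
            m = _NORM_RE.match(line)
            if m:
                nid, _kind, tid, referent = m.groups()
                normalizations.append(Normalization(nid, tid, referent))
                continue
            m = _REL_RE.match(line)
            if m:
                raw_relations.append(m.groups())
                continue
            logger.warning("%s (%s line %d): skipping unknown line %r",
                           doc_id, layer, line_no, line)

    consume(a1, "a1")
    if a2 is not None:
        consume(a2, "a2")

    entity_map = {e.id: e for e in entities}
    relations: list[Relation] = []
    for rid, rtype, role1, id1, role2, id2 in raw_relations:
        for tid in (id1, id2):
            if tid not in entity_map:
                raise StandoffIntegrityError(
                    f"{doc_id}: relation {rid} references missing entity {tid}"
                )
        roles = {role1: entity_map[id1], role2: entity_map[id2]}
        if rtype == "Localization":
            try:
                arg1, arg2 = roles["Bacterium"], roles["Localization"]
            except KeyError:
                raise StandoffIntegrityError(
                    f"{doc_id}: relation {rid} has unexpected roles "
                    f"{sorted(roles)}"
                ) from None
        elif rtype == "PartOf":
            try:
                arg1, arg2 = roles["Part"], roles["Host"]
            except KeyError:
                raise StandoffIntegrityError(
                    f"{doc_id}: relation {rid} has unexpected roles "
                    f"{sorted(roles)}"
                ) from None
        else:
            logger.warning("%s: skipping unknown relation type %r", doc_id, rtype)
            continue
        relations.append(Relation(rtype, arg1, arg2))

    return StandoffDocument(
        doc_id=doc_id,
        text=txt,
        entities=tuple(entities),
        a2_entity_ids=frozenset(a2_ids),
        normalizations=tuple(normalizations),
        relations=tuple(relations),
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_standoff(doc: StandoffDocument) -> tuple[str, str]:
    """Canonical serialization to ``(a1 text, a2 text)``.

    Entities keep their ids but are ordered by first fragment start, span
    end, then numeric id; normalization and relation lines are renumbered
    sequentially in that entity order.
    """
    validate_document(doc)

    def sort_key(entity: EntityRef):
        return (entity.start, entity.end, _id_number(entity.id))

    a1_entities = sorted(doc.a1_entities(), key=sort_key)
    a2_entities = sorted(doc.a2_entities(), key=sort_key)
    order = {e.id: pos for pos, e in enumerate(a1_entities + a2_entities)}

    def entity_line(entity: EntityRef) -> str:
        offsets = ";".join(f"{s} {e}" for s, e in entity.fragments)
        text = " ".join(doc.text[s:e] for s, e in entity.fragments)
        return f"{entity.id}\t{entity.etype} {offsets}\t{text}"

    a1_lines = [entity_line(e) for e in a1_entities]
    a2_lines = [entity_line(e) for e in a2_entities]

    norms = sorted(
        doc.normalizations, key=lambda n: (order[n.entity_id], n.referent)
    )
    for counter, norm in enumerate(norms, start=1):
        a2_lines.append(
            f"N{counter}\tOntoBiotope Annotation:{norm.entity_id} "
            f"Referent:{norm.referent}"
        )

    def rel_sort_key(relation: Relation):
        return (relation.rtype, order[relation.arg1.id], order[relation.arg2.id])

    for counter, relation in enumerate(sorted(doc.relations, key=rel_sort_key), start=1):
        if relation.rtype == "Localization":
            a2_lines.append(
                f"R{counter}\tLocalization Bacterium:{relation.arg1.id} "
                f"Localization:{relation.arg2.id}"
            )
        else:
            a2_lines.append(
                f"R{counter}\tPartOf Host:{relation.arg2.id} "
                f"Part:{relation.arg1.id}"
            )

    def render(lines: list[str]) -> str:
        return "\n".join(lines) + ("\n" if lines else "")

    return render(a1_lines), render(a2_lines)


def _id_number(tid: str) -> int:
    return int(re.sub(r"\D", "", tid) or 0)


# ---------------------------------------------------------------------------
# Directory-level helpers
# ---------------------------------------------------------------------------

def read_directory(path: str | Path) -> list[StandoffDocument]:
    """Read all ``<stem>.txt`` files under ``path``, pairing each with its
    ``.a1``/``.a2`` siblings when present."""
    root = Path(path)
    documents = []
    for txt_path in sorted(root.glob("*.txt")):
        stem = txt_path.stem
        a1_path = root / f"{stem}.a1"
        a2_path = root / f"{stem}.a2"
        documents.append(
            read_standoff(
                txt_path.read_text("utf-8"),
                a1_path.read_text("utf-8") if a1_path.exists() else "",
                a2_path.read_text("utf-8") if a2_path.exists() else None,
                doc_id=stem,
            )
        )
    return documents


def write_files(
    doc: StandoffDocument,
    directory: str | Path,
    layers: Sequence[str] = ("txt", "a1", "a2"),
) -> None:
    """Materialize selected layers of a document under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    a1_text, a2_text = write_standoff(doc)
    if "txt" in layers:
        (directory / f"{doc.doc_id}.txt").write_text(doc.text, "utf-8")
    if "a1" in layers:
        (directory / f"{doc.doc_id}.a1").write_text(a1_text, "utf-8")
    if "a2" in layers:
        (directory / f"{doc.doc_id}.a2").write_text(a2_text, "utf-8")


def read_predictions(
    ref_docs: Sequence[StandoffDocument], pred_dir: str | Path
) -> list[StandoffDocument]:
    """Read prediction ``.a2`` files paired with reference documents by stem.

    Prediction directories carry only ``.a2`` files; the reference document
    supplies the text.  Relation predictions reference the gold ``.a1``
    entities, so the reference ``.a1`` stream is included whenever the
    prediction file defines no entities of its own.  References without a
    prediction file yield a document with empty a2 annotations.
    """
    pred_dir = Path(pred_dir)
    predictions = []
    for ref_doc in ref_docs:
        a2_path = pred_dir / f"{ref_doc.doc_id}.a2"
        a2_text = a2_path.read_text("utf-8") if a2_path.exists() else ""
        defines_entities = any(
            _ENTITY_RE.match(line) for line in a2_text.splitlines()
        )
        if defines_entities:
            a1_text = ""
        else:
            a1_text = write_standoff(
                StandoffDocument(
                    doc_id=ref_doc.doc_id,
                    text=ref_doc.text,
                    entities=tuple(ref_doc.a1_entities()),
                )
            )[0]
        predictions.append(
            read_standoff(ref_doc.text, a1_text, a2_text, doc_id=ref_doc.doc_id)
        )
    return predictions


def training_annotations(docs: Iterable[StandoffDocument]) -> list[TrainingAnnotation]:
    """Harvest (surface text, concept id) pairs from the normalization lines
    of annotated documents, for ontology expansion."""
    annotations = []
    for doc in docs:
        entity_map = doc.entity_map
        for norm in doc.normalizations:
            annotations.append(
                TrainingAnnotation(entity_map[norm.entity_id].text, norm.referent)
            )
    return annotations
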