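"""Reading and writing BioC-style collections of figure captions and full texts.

The supported dialect is the one used for caption-level organism annotation:
``collection > document > passage > annotation``, where passages carry a
document-global ``offset`` and annotations carry ``location`` elements with
``offset``/``length``.  All offsets are 0-based, half-open, and counted in
Unicode *code points* — never bytes or UTF-16 units.  Source corpora are not
always consistent about this (captions containing characters such as α or β
are a known source of off-by-a-few span errors), so :func:`repair_annotation_spans`
re-anchors any annotation whose declared span does not slice to its recorded
surface text.

Linked organism annotations store an integer NCBI Taxonomy ID on
:attr:`SpanAnnotation.taxon_id`; the textual ``NCBI taxon:`` prefix is purely
a serialization concern.  Type-only annotations (e.g. "organism: bacteria")
carry :attr:`SpanAnnotation.type_only_label` instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from lxml import etree

__all__ = [
    "Collection",
    "Document",
    "Passage",
    "SpanAnnotation",
    "RepairResult",
    "read_collection",
    "write_collection",
    "repair_annotation_spans",
]


@dataclass(frozen=True)
class SpanAnnotation:
    """A contiguous annotated span with document-global code-point offsets."""

    start: int
    end: int
    surface: str
    entity_type: str = "organism"
    taxon_id: Optional[int] = None
    type_only_label: Optional[str] = None
    ann_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty or inverted span [{self.start},{self.end})")


@dataclass(frozen=True)
class Passage:
    offset: int
    text: str
    section_label: str = ""
    annotations: tuple[SpanAnnotation, ...] = ()

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("passage offset must be >= 0")

    def slice(self, ann: SpanAnnotation) -> str:
        """Text under ``ann`` using document-global offsets."""
        return self.text[ann.start - self.offset : ann.end - self.offset]

    def is_consistent(self, ann: SpanAnnotation) -> bool:
        return (
            ann.start >= self.offset
            and ann.end <= self.offset + len(self.text)
            and self.slice(ann) == ann.surface
        )


@dataclass(frozen=True)
class Document:
    doc_id: str
    passages: tuple[Passage, ...] = ()

    def __post_init__(self) -> None:
        offs = [p.offset for p in self.passages]
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError(f"passage offsets not strictly increasing in {self.doc_id!r}")


@dataclass(frozen=True)
class Collection:
    source_id: str = ""
    documents: tuple[Document, ...] = ()

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate document identifiers in collection")


_TAXON_RE = re.compile(r"^\s*NCBI\s*tax(?:on)?\s*:\s*(\d+)\s*$", re.IGNORECASE)
_TYPE_ONLY_RE = re.compile(r"^\s*organism\s*:\s*(.+?)\s*$", re.IGNORECASE)


def _parse_type_infon(value: str) -> tuple[Optional[int], Optional[str]]:
    """Split an annotation type infon into (taxon_id, type_only_label)."""
    m = _TAXON_RE.match(value)
    if m:
        return int(m.group(1)), None
    if value.strip().isdigit():
        return int(value.strip()), None
    m = _TYPE_ONLY_RE.match(value)
    if m:
        return None, m.group(1)
    return None, None


def read_collection(xml_text: str) -> Collection:
    """Parse a BioC XML string into a :class:`Collection`.

    Offsets in the file are interpreted as code-point offsets (the only unit
    this dialect defines); the surface text of every element is preserved
    exactly.  Malformed XML raises :class:`lxml.etree.XMLSyntaxError`, which
    names the offending line.
    """
    root = etree.fromstring(xml_text.encode("utf-8"))
    if root.tag != "collection":
        raise ValueError(f"expected <collection> root, found <{root.tag}>")
    source = root.findtext("source", default="")
    documents = []
    for del_ in root.iterfind("document"):
        doc_id = del_.findtext("id", default="")
        passages = []
        for pel in del_.iterfind("passage"):
            offset_text = pel.findtext("offset")
            if offset_text is None:
                raise ValueError(f"passage without <offset> in document {doc_id!r}")
            offset = int(offset_text)
            text = pel.findtext("text", default="")
            label = ""
            for inf in pel.iterfind("infon"):
                if inf.get("key") in ("type", "section_type", "section"):
                    label = inf.text or ""
                    break
            anns = []
            for ael in pel.iterfind("annotation"):
                loc = ael.find("location")
                if loc is None:
                    raise ValueError(f"annotation without <location> in {doc_id!r}")
                start = int(loc.get("offset"))
                length = int(loc.get("length"))
                surface = ael.findtext("text", default="")
                entity_type = "organism"
                taxon_id = None
                type_only = None
                for inf in ael.iterfind("infon"):
                    key = (inf.get("key") or "").lower()
                    val = inf.text or ""
                    if key == "type":
                        tid, tlabel = _parse_type_infon(val)
                        if tid is not None:
                            taxon_id = tid
                        elif tlabel is not None:
                            entity_type, type_only = "organism", tlabel
                        else:
                            entity_type = val
                    elif key in ("ncbi taxonomy", "taxonomy_id", "ncbi_taxonomy_id"):
                        tid, _ = _parse_type_infon(val)
                        taxon_id = tid if tid is not None else int(val)
                anns.append(
                    SpanAnnotation(
                        start=start,
                        end=start + length,
                        surface=surface,
                        entity_type=entity_type,
                        taxon_id=taxon_id,
                        type_only_label=type_only,
                        ann_id=ael.get("id", ""),
                    )
                )
            passages.append(
                Passage(offset=offset, text=text, section_label=label, annotations=tuple(anns))
            )
        documents.append(Document(doc_id=doc_id, passages=tuple(passages)))
    return Collection(source_id=source, documents=tuple(documents))


def write_collection(c: Collection) -> str:
    """Serialize a :class:`Collection` back to BioC XML.

    Inverse of :func:`read_collection` field-for-field.  Refuses to serialize
    an annotation whose span falls outside its passage.
    """
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = c.source_id
    for doc in c.documents:
        del_ = etree.SubElement(root, "document")
        etree.SubElement(del_, "id").text = doc.doc_id
        for p in doc.passages:
            pel = etree.SubElement(del_, "passage")
            if p.section_label:
                inf = etree.SubElement(pel, "infon", key="type")
                inf.text = p.section_label
            etree.SubElement(pel, "offset").text = str(p.offset)
            etree.SubElement(pel, "text").text = p.text
            for ann in p.annotations:
                if ann.start < p.offset or ann.end > p.offset + len(p.text):
                    raise ValueError(
                        f"annotation [{ann.start},{ann.end}) outside passage "
                        f"at offset {p.offset} in document {doc.doc_id!r}"
                    )
                ael = etree.SubElement(pel, "annotation",
                                       **({"id": ann.ann_id} if ann.ann_id else {}))
                tinf = etree.SubElement(ael, "infon", key="type")
                if ann.taxon_id is not None:
                    tinf.text = f"NCBI taxon:{ann.taxon_id}"
                elif ann.type_only_label is not None:
                    tinf.text = f"organism:{ann.type_only_label}"
                else:
                    tinf.text = ann.entity_type
                etree.SubElement(
                    ael, "location", offset=str(ann.start), length=str(ann.end - ann.start)
                )
                etree.SubElement(ael, "text").text = ann.surface
    return etree.tostring(root, encoding="unicode", pretty_print=True)


@dataclass(frozen=True)
class RepairResult:
    passage: Passage
    flagged: tuple[SpanAnnotation, ...] = ()

    @property
    def n_flagged(self) -> int:
        return len(self.flagged)


def repair_annotation_spans(p: Passage, search_window: int = 10) -> RepairResult:
    """Re-anchor annotations whose declared span does not slice to their surface.

    For each inconsistent annotation, the surface string is searched within
    ``±search_window`` code points of the declared start; the nearest
    occurrence wins (earlier side on ties).  Annotations that cannot be
    repaired are returned in :attr:`RepairResult.flagged` rather than dropped.
    """
    repaired = []
    flagged = []
    for ann in p.annotations:
        if p.is_consistent(ann):
            repaired.append(ann)
            continue
        rel = ann.start - p.offset
        found = None
        for delta in sorted(range(-search_window, search_window + 1), key=lambda d: (abs(d), d)):
            cand = rel + delta
            if cand < 0 or cand + len(ann.surface) > len(p.text):
                continue
            if p.text[cand : cand + len(ann.surface)] == ann.surface:
                found = cand
                break
        if found is None:
            flagged.append(ann)
            repaired.append(ann)
        else:
            repaired.append(
                replace(ann, start=p.offset + found, end=p.offset + found + len(ann.surface))
            )
    return RepairResult(passage=replace(p, annotations=tuple(repaired)), flagged=tuple(flagged))
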