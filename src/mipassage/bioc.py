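"""In-memory model and XML I/O for BioC collections.

BioC is a simple stand-off XML interchange format for biomedical text:
a ``collection`` holds ``document`` elements, each document holds
``passage`` elements (paragraphs, titles, table captions, ...), and each
passage may carry ``annotation`` elements that point back into the text
via a ``location`` with character ``offset``/``length`` attributes.
Arbitrary key-value metadata travels on any element as ``infon`` tags.

Annotations emitted by this package mark passages describing an
experimental interaction detection method.  They always carry two
infons: ``type`` (the constant ``"ExperimentalMethod"``) and ``PSIMI``
(the 4-digit local identifier of the method in the PSI-MI ontology,
e.g. ``"0018"`` for two hybrid).

Conventions
-----------
* Offsets are 0-based character offsets into the document, counted in
  code points exactly as the text is stored in the XML; lengths are
  character counts.
* Annotation identifiers are rendered integers, document-scoped, and
  increment by one throughout the article.  Numbering starts at 0 by
  default (configurable via the ``counter`` argument of
  :func:`append_annotation`).
* Unknown infon keys are preserved verbatim on round-trip.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

from lxml import etree

ANNOTATION_TYPE = "ExperimentalMethod"


class BiocParseError(ValueError):
    """Raised for XML that cannot be parsed as BioC."""


class BiocSchemaError(ValueError):
    """Raised when required BioC structure (e.g. an offset) is missing."""


class AnnotationConsistencyError(ValueError):
    """Raised when an annotation's text disagrees with its span."""


def local_method_id(method_id: str) -> str:
    """Normalize ``"MI:0018"`` / ``"0018"`` to the 4-digit local form."""
    local = method_id.split(":")[-1].strip()
    return local


@dataclass
class BiocAnnotation:
    id: str
    infons: dict[str, str]
    offset: int
    length: int
    text: str

    @property
    def end(self) -> int:
        return self.offset + self.length

    @property
    def method_id(self) -> str | None:
        return self.infons.get("PSIMI")

    def validate(self) -> None:
        if self.offset < 0:
            raise BiocSchemaError(f"annotation {self.id}: negative offset")
        if self.length != len(self.text):
            raise AnnotationConsistencyError(
                f"annotation {self.id}: length {self.length} != "
                f"len(text) {len(self.text)}"
            )


@dataclass
class BiocPassage:
    offset: int
    infons: dict[str, str] = field(default_factory=dict)
    text: str = ""
    annotations: list[BiocAnnotation] = field(default_factory=list)

    @property
    def infon_type(self) -> str | None:
        return self.infons.get("type")

    @property
    def end(self) -> int:
        return self.offset + len(self.text)

    def validate(self) -> None:
        if self.offset < 0:
            raise BiocSchemaError("passage: negative offset")
        prev = -1
        for ann in self.annotations:
            ann.validate()
            if ann.offset < self.offset or ann.end > self.end:
                raise AnnotationConsistencyError(
                    f"annotation {ann.id} span [{ann.offset}, {ann.end}) "
                    f"outside passage span [{self.offset}, {self.end})"
                )
            if ann.offset < prev:
                raise BiocSchemaError("passage annotations not sorted by offset")
            prev = ann.offset


@dataclass
class BiocDocument:
    doc_id: str
    passages: list[BiocPassage] = field(default_factory=list)

    def validate(self) -> None:
        prev = -1
        for passage in self.passages:
            passage.validate()
            if passage.offset <= prev:
                raise BiocSchemaError(
                    f"document {self.doc_id}: passage offsets not strictly increasing"
                )
            prev = passage.offset

    def annotations(self):
        for passage in self.passages:
            yield from passage.annotations


@dataclass
class BiocCollection:
    source: str = ""
    date: str = ""
    documents: list[BiocDocument] = field(default_factory=list)

    def validate(self) -> None:
        for doc in self.documents:
            doc.validate()


# ---------------------------------------------------------------------------
# XML reading / writing
# ---------------------------------------------------------------------------

def _parse_infons(element) -> dict[str, str]:
    return {el.get("key", ""): el.text or "" for el in element.findall("infon")}


def _required_int(element, parent_desc: str, what: str) -> int:
    value = element.findtext(what) if element is not None else None
    if value is None:
        raise BiocSchemaError(f"{parent_desc}: missing <{what}>")
    try:
        return int(value)
    except ValueError as exc:
        raise BiocSchemaError(f"{parent_desc}: non-integer <{what}>: {value!r}") from exc


def _parse_annotation(a_el, where: str) -> BiocAnnotation:
    loc = a_el.find("location")
    if loc is None:
        raise BiocSchemaError(f"{where}: annotation without <location>")
    offset = loc.get("offset")
    length = loc.get("length")
    if offset is None or length is None:
        raise BiocSchemaError(f"{where}: location missing offset/length")
    return BiocAnnotation(
        id=a_el.get("id", ""),
        infons=_parse_infons(a_el),
        offset=int(offset),
        length=int(length),
        text=a_el.findtext("text", default=""),
    )


def read_collection(path) -> BiocCollection:
    """Read a BioC XML file losslessly into a :class:`BiocCollection`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise BiocParseError(
            f"{path}: malformed XML at line {exc.lineno}: {exc.msg}"
        ) from exc
    root = tree.getroot()
    if root.tag != "collection":
        raise BiocSchemaError(f"{path}: root element is <{root.tag}>, not <collection>")
    collection = BiocCollection(
        source=root.findtext("source", default=""),
        date=root.findtext("date", default=""),
    )
    for doc_el in root.findall("document"):
        doc = BiocDocument(doc_id=doc_el.findtext("id", default=""))
        for p_el in doc_el.findall("passage"):
            where = f"document {doc.doc_id}"
            offset_text = p_el.findtext("offset")
            if offset_text is None:
                raise BiocSchemaError(f"{where}: passage without <offset>")
            passage = BiocPassage(
                offset=int(offset_text),
                infons=_parse_infons(p_el),
                text=p_el.findtext("text", default=""),
            )
            for a_el in p_el.findall("annotation"):
                passage.annotations.append(_parse_annotation(a_el, where))
            doc.passages.append(passage)
        collection.documents.append(doc)
    return collection


def _write_infons(parent, infons: dict[str, str]) -> None:
    for key, value in infons.items():
        el = etree.SubElement(parent, "infon", key=key)
        el.text = value


def write_collection(collection: BiocCollection, path) -> None:
    """Serialize a collection as BioC XML; re-reading yields an equal object."""
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = collection.source
    etree.SubElement(root, "date").text = collection.date
    etree.SubElement(root, "key").text = ""
    for doc in collection.documents:
        doc_el = etree.SubElement(root, "document")
        etree.SubElement(doc_el, "id").text = doc.doc_id
        for passage in doc.passages:
            p_el = etree.SubElement(doc_el, "passage")
            _write_infons(p_el, passage.infons)
            etree.SubElement(p_el, "offset").text = str(passage.offset)
            etree.SubElement(p_el, "text").text = passage.text
            for ann in passage.annotations:
                a_el = etree.SubElement(p_el, "annotation", id=ann.id)
                _write_infons(a_el, ann.infons)
                etree.SubElement(
                    a_el,
                    "location",
                    offset=str(ann.offset),
                    length=str(ann.length),
                )
                etree.SubElement(a_el, "text").text = ann.text
    tree = etree.ElementTree(root)
    tree.write(
        str(path),
        xml_declaration=True,
        encoding="UTF-8",
        pretty_print=True,
    )


def append_annotation(
    passage: BiocPassage,
    method_id: str,
    span: tuple[int, int],
    text: str,
    counter: int,
) -> int:
    """Append an ExperimentalMethod annotation to *passage*.

    ``span`` is ``(offset, length)`` in document coordinates.  The text
    must equal the passage substring at the span.  The annotation is
    inserted keeping the passage's annotations sorted by offset.
    Returns ``counter + 1`` (the next annotation id to use).
    """
    offset, length = span
    if offset < passage.offset or offset + length > passage.end:
        raise AnnotationConsistencyError(
            f"span [{offset}, {offset + length}) outside passage "
            f"[{passage.offset}, {passage.end})"
        )
    local_start = offset - passage.offset
    substring = passage.text[local_start : local_start + length]
    if substring != text:
        raise AnnotationConsistencyError(
            "annotation text does not equal the passage substring at its span"
        )
    ann = BiocAnnotation(
        id=str(counter),
        infons={"type": ANNOTATION_TYPE, "PSIMI": local_method_id(method_id)},
        offset=offset,
        length=length,
        text=text,
    )
    index = bisect.bisect_right([a.offset for a in passage.annotations], offset)
    passage.annotations.insert(index, ann)
    return counter + 1
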