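"""Import pipeline: extract an XML report, transform it to EAV rows, load.

The three stages are exposed separately so each is testable on its own:

* :func:`parse_document` — build a :class:`DocTree` from raw bytes.  Element
  and attribute names keep their prefixed qualified form verbatim and
  ``xmlns``/``xmlns:prefix`` declarations are kept as ordinary attributes,
  so the stored rows can reproduce the source exactly.  Comments and
  processing instructions are dropped, as are whitespace-only text nodes
  (pretty-printing must not create facts).
* :func:`shred_document` — flatten the tree into entity / attribute-name /
  fact protorecords with 1-based sibling positions assigned over all kept
  children (elements and text pseudo-nodes) in document order.
* :func:`import_document` — run both stages and load the batch atomically,
  retaining the raw bytes for restorability.

Datatype routing is per-value and purely lexical (no schema is consulted):
boolean -> integer -> real -> date -> timestamp -> string, first match wins.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union
from xml.parsers import expat

from .core_model import (
    EAVStore,
    SourceDocMeta,
    TEXT_NODE,
    ValidationError,
    ValueFact,
)

__all__ = [
    "DocTree",
    "ElementNode",
    "TextNode",
    "ParseError",
    "ShredBatch",
    "ImportReport",
    "ImportConfig",
    "parse_document",
    "infer_datatype",
    "classify_header_body",
    "shred_document",
    "import_document",
]


class ParseError(ValidationError):
    """Malformed XML, with the expat location in the message."""


@dataclass
class TextNode:
    text: str


@dataclass
class ElementNode:
    name: str
    attrs: list[tuple[str, str]] = field(default_factory=list)
    children: list[Union["ElementNode", TextNode]] = field(default_factory=list)


@dataclass
class DocTree:
    """Parsed document: ordered element tree plus the source bytes."""

    root: ElementNode
    raw: bytes


@dataclass(frozen=True)
class ImportConfig:
    """Knobs for the transform stage.

    ``body_chain`` names the descendant chain that marks the body region:
    a value row is flagged body (``is_metadata = False``) iff its entity
    lies at or below an element whose name is ``body_chain[-1]`` and whose
    ancestors immediately above match the rest of the chain.  The default
    matches the CDA dialect (``component/structuredBody``).
    """

    body_chain: tuple[str, ...] = ("component", "structuredBody")


@dataclass
class ShredBatch:
    """Flattened document ready for loading.

    ``entities`` is parent-before-child; each protorecord is
    (index, name, parent_index | None, sibling_pos, path).  ``facts`` are
    (entity_index, attribute_name, lexical, is_metadata).
    """

    entities: list[tuple[int, str, Optional[int], int, str]]
    attribute_names: list[str]
    facts: list[tuple[int, str, str, bool]]
    doc_meta: SourceDocMeta


@dataclass(frozen=True)
class ImportReport:
    source_doc_id: int
    n_entities: int
    n_new_attributes: int
    n_values: int
    n_header_values: int
    n_body_values: int


# ---------------------------------------------------------------------------
# Extract

def parse_document(raw: bytes) -> DocTree:
    """Parse XML bytes into a :class:`DocTree`.

    Raises :class:`ParseError` (with line/column) on malformed input.
    """
    if isinstance(raw, str):
        raw = raw.encode("utf-8")
    root: Optional[ElementNode] = None
    stack: list[ElementNode] = []
    pending_text: list[str] = []

    def flush_text() -> None:
        if not pending_text:
            return
        text = "".join(pending_text)
        pending_text.clear()
        if text.strip() and stack:
            stack[-1].children.append(TextNode(text))

    def start(name: str, attrs: list[str]) -> None:
        nonlocal root
        flush_text()
        pairs = [(attrs[i], attrs[i + 1]) for i in range(0, len(attrs), 2)]
        node = ElementNode(name, pairs)
        if stack:
            stack[-1].children.append(node)
        elif root is None:
            root = node
        stack.append(node)

    def end(name: str) -> None:
        flush_text()
        stack.pop()

    def chardata(data: str) -> None:
        pending_text.append(data)

    parser = expat.ParserCreate()  # namespace processing off: raw names
    parser.ordered_attributes = True
    parser.StartElementHandler = start
    parser.EndElementHandler = end
    parser.CharacterDataHandler = chardata
    try:
        parser.Parse(raw, True)
    except expat.ExpatError as exc:
        raise ParseError(
            f"malformed XML at line {parser.ErrorLineNumber}, "
            f"column {parser.ErrorColumnNumber}: {exc}"
        )
    if root is None:
        raise ParseError("document has no root element")
    return DocTree(root=root, raw=raw)


# ---------------------------------------------------------------------------
# Transform

def infer_datatype(lexical: str, store: Optional[EAVStore] = None) -> str:
    """Route a lexical value to a datatype tag.

    Deterministic, total: first match in the precedence
    boolean -> integer -> real -> date -> timestamp wins, else ``string``
    (the empty string is a string).  When ``store`` is given its registry
    is consulted, so user-registered tags participate only through the
    fallthrough (they never pre-empt the built-in precedence).
    """
    from .core_model import DEFAULT_DATATYPES

    registry = store.datatypes if store is not None else {
        dt.tag: dt for dt in DEFAULT_DATATYPES
    }
    for tag in ("boolean", "integer", "real", "date", "timestamp"):
        dt = registry.get(tag)
        if dt is not None and dt.matches(lexical):
            return tag
    return "string"


def classify_header_body(path: str, config: ImportConfig = ImportConfig()) -> bool:
    """True iff a node at ``path`` belongs to the document *header*.

    A node is body iff its path contains the configured body chain as a
    consecutive run of segment names (the body root itself included); a
    document with no body root is all header.
    """
    names = [seg.rsplit("[", 1)[0] for seg in path.strip("/").split("/")]
    chain = config.body_chain
    k = len(chain)
    for i in range(len(names) - k + 1):
        if tuple(names[i:i + k]) == chain:
            return False
    return True


def _walk(node: ElementNode, parent_index: Optional[int], sibling_pos: int,
          parent_path: str, batch_entities: list, batch_facts: list,
          attr_names: dict, config: ImportConfig) -> None:
    index = len(batch_entities)
    path = f"{parent_path}/{node.name}[{sibling_pos}]"
    batch_entities.append((index, node.name, parent_index, sibling_pos, path))
    is_meta = classify_header_body(path, config)
    for aname, avalue in node.attrs:
        attr_names.setdefault(aname, None)
        batch_facts.append((index, aname, avalue, is_meta))
    for pos, child in enumerate(node.children, start=1):
        if isinstance(child, TextNode):
            tindex = len(batch_entities)
            tpath = f"{path}/{TEXT_NODE}[{pos}]"
            batch_entities.append((tindex, TEXT_NODE, index, pos, tpath))
            attr_names.setdefault(TEXT_NODE, None)
            batch_facts.append((tindex, TEXT_NODE, child.text, is_meta))
        else:
            _walk(child, index, pos, path, batch_entities, batch_facts,
                  attr_names, config)


def _default_meta(tree: DocTree, meta: SourceDocMeta) -> SourceDocMeta:
    """Fill doc_type/template defaults from the document itself."""
    doc_type = meta.doc_type
    template = meta.template
    if doc_type == "unknown":
        doc_type = tree.root.name
    if template == "unknown":
        for child in tree.root.children:
            if isinstance(child, ElementNode) and "templateId" in child.name:
                for aname, avalue in child.attrs:
                    if aname in ("root", "extension"):
                        template = avalue
                        break
                break
    from dataclasses import replace
    return replace(meta, doc_type=doc_type, template=template)


def shred_document(tree: DocTree, meta: SourceDocMeta,
                   config: ImportConfig = ImportConfig()) -> ShredBatch:
    """Flatten a parsed tree into EAV protorecords.

    One entity per element plus one ``#text`` pseudo-entity per kept text
    node; one fact per XML attribute plus one ``#text`` fact per text node.
    Sibling positions run 1..k over all kept children of each parent in
    document order.
    """
    entities: list[tuple[int, str, Optional[int], int, str]] = []
    facts: list[tuple[int, str, str, bool]] = []
    attr_names: dict[str, None] = {}
    _walk(tree.root, None, 1, "", entities, facts, attr_names, config)
    return ShredBatch(
        entities=entities,
        attribute_names=list(attr_names),
        facts=facts,
        doc_meta=_default_meta(tree, meta),
    )


# ---------------------------------------------------------------------------
# Load

def import_document(store: EAVStore, raw: bytes, meta: SourceDocMeta,
                    config: ImportConfig = ImportConfig(),
                    on_duplicate: Optional[str] = None) -> ImportReport:
    """Parse, shred and load one document atomically.

    On any error (malformed XML, duplicate digest under the reject policy)
    the store is left untouched.  Ancestor paths are materialized for every
    loaded entity so path-returning queries need no recursive traversal.
    """
    tree = parse_document(raw)  # before any write: parse errors cost nothing
    batch = shred_document(tree, meta, config)
    conn = store.connection
    n_attrs_before = store.n_attributes()
    conn.execute("BEGIN")
    try:
        doc_id = store.register_source_doc(batch.doc_meta, tree.raw,
                                           on_duplicate=on_duplicate)
        entity_ids: list[int] = []
        for index, name, parent_index, pos, path in batch.entities:
            parent_id = entity_ids[parent_index] if parent_index is not None else None
            eid = store.insert_entity(name, parent_id, pos)
            entity_ids.append(eid)
            conn.execute(
                "INSERT INTO entity_path (entity_id, source_doc_id, path) "
                "VALUES (?,?,?)", (eid, doc_id, path),
            )
        store.set_root_entity(doc_id, entity_ids[0])
        attr_ids = {name: store.upsert_attribute(name)
                    for name in batch.attribute_names}
        n_header = n_body = 0
        for entity_index, aname, lexical, is_meta in batch.facts:
            tag = infer_datatype(lexical, store)
            store.insert_value(ValueFact(
                entity_id=entity_ids[entity_index],
                attribute_id=attr_ids[aname],
                source_doc_id=doc_id,
                datatype=tag,
                lexical=lexical,
                is_metadata=is_meta,
            ))
            if is_meta:
                n_header += 1
            else:
                n_body += 1
    except Exception:
        conn.rollback()
        raise
    conn.commit()
    return ImportReport(
        source_doc_id=doc_id,
        n_entities=len(batch.entities),
        n_new_attributes=store.n_attributes() - n_attrs_before,
        n_values=len(batch.facts),
        n_header_values=n_header,
        n_body_values=n_body,
    )
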