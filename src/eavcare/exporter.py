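"""Restorability and rule-based export of new standardized reports.

Two distinct outputs leave the store through this module:

* :func:`reconstruct_document` rebuilds an imported report purely from the
  EAV rows — entities ordered by sibling position, attribute and ``#text``
  facts re-attached, verbatim lexical forms emitted — and the result equals
  the original under the canonical comparison below.
* :func:`export_document` runs the five-step export loop: *preselect*
  candidate facts by criteria, let a selector (the modeled manual step)
  refine the selection, *transform* it into a target tree via declarative
  rules, *check completeness* against a required-content spec, and loop
  back to selection until the check passes, then *generate* the bytes.

Canonical equality — the operational meaning of "no data is lost" — is
attribute-order-insensitive and ignores whitespace-only text, comments,
processing instructions and the XML declaration, exactly the information
the importer deliberately does not store.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

from . import query_engine
from ._patterns import PathPattern, match_fact, parse_pattern
from .core_model import (
    ConflictError,
    EAVError,
    EAVStore,
    TEXT_NODE,
    UnknownDocumentError,
    ValidationError,
)
from .importer import ElementNode, TextNode, parse_document
from .query_engine import FactRecord

__all__ = [
    "reconstruct_document",
    "canonical_form",
    "canonical_equal",
    "Selection",
    "SelectionCriteria",
    "preselect",
    "TransformRule",
    "TargetTree",
    "apply_rules",
    "CompletenessSpec",
    "check_completeness",
    "export_document",
    "ExportIncompleteError",
    "register_transform",
    "load_rules",
    "load_completeness_spec",
]


class ExportIncompleteError(EAVError):
    """The export loop hit its iteration bound with paths still missing."""

    def __init__(self, missing: Sequence[str], iterations: int):
        self.missing = list(missing)
        self.iterations = iterations
        super().__init__(
            f"export incomplete after {iterations} iterations; "
            f"missing: {', '.join(self.missing)}"
        )


# ---------------------------------------------------------------------------
# Reconstruction

def _escape_text(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")


def _escape_attr(s: str) -> str:
    return (_escape_text(s).replace('"', "&quot;")
            .replace("\n", "&#10;").replace("\t", "&#9;").replace("\r", "&#13;"))


def _serialize(node: Union[ElementNode, TextNode], out: list[str]) -> None:
    if isinstance(node, TextNode):
        out.append(_escape_text(node.text))
        return
    attrs = "".join(f' {k}="{_escape_attr(v)}"' for k, v in node.attrs)
    if node.children:
        out.append(f"<{node.name}{attrs}>")
        for child in node.children:
            _serialize(child, out)
        out.append(f"</{node.name}>")
    else:
        out.append(f"<{node.name}{attrs}/>")


def serialize_tree(root: ElementNode) -> bytes:
    out: list[str] = []
    _serialize(root, out)
    return "".join(out).encode("utf-8")


def reconstruct_document(store: EAVStore, source_doc_id: int) -> bytes:
    """Rebuild an imported document from its EAV rows alone.

    Raw stored bytes are *not* consulted; this is the restorability
    guarantee made executable.  Attributes are emitted name-sorted (the
    canonical comparison is order-insensitive), lexical forms verbatim.
    """
    root_id = store.root_entity_of(source_doc_id)
    if root_id is None:
        raise UnknownDocumentError(
            f"document {source_doc_id} has no root entity"
        )
    conn = store.connection
    entities = conn.execute(
        "SELECT e.entity_id, e.name, e.parent_id, e.sibling_pos "
        "FROM entity e JOIN entity_path p ON p.entity_id = e.entity_id "
        "WHERE p.source_doc_id = ?", (source_doc_id,)
    ).fetchall()
    children: dict[Optional[int], list[tuple[int, int, str]]] = {}
    for eid, name, pid, pos in entities:
        children.setdefault(pid, []).append((pos, eid, name))
    facts: dict[int, list[tuple[str, str]]] = {}
    for tag in store.datatypes:
        for eid, aname, lexical in conn.execute(
            f"SELECT v.entity_id, a.name, v.lexical FROM {tag}_value v "
            "JOIN attribute a ON a.attribute_id = v.attribute_id "
            "WHERE v.source_doc_id = ? AND v.superseded = 0", (source_doc_id,)
        ):
            facts.setdefault(eid, []).append((aname, lexical))

    def build(eid: int, name: str) -> Union[ElementNode, TextNode]:
        own = facts.get(eid, [])
        if name == TEXT_NODE:
            text = next((v for a, v in own if a == TEXT_NODE), "")
            return TextNode(text)
        attrs = sorted((a, v) for a, v in own if a != TEXT_NODE)
        node = ElementNode(name, list(attrs))
        for _pos, cid, cname in sorted(children.get(eid, [])):
            node.children.append(build(cid, cname))
        return node

    root_name = store.get_entity(root_id).name
    tree = build(root_id, root_name)
    assert isinstance(tree, ElementNode)
    return serialize_tree(tree)


# ---------------------------------------------------------------------------
# Canonical comparison

def _canon(node: Union[ElementNode, TextNode]):
    if isinstance(node, TextNode):
        return ("text", node.text)
    return (
        "elem",
        node.name,
        tuple(sorted(node.attrs)),
        tuple(_canon(c) for c in node.children),
    )


def canonical_form(raw: bytes):
    """Hashable canonical structure of an XML document.

    Parses with the import-side rules (whitespace-only text, comments and
    processing instructions dropped), then sorts attributes.
    """
    return _canon(parse_document(raw).root)


def canonical_equal(a: bytes, b: bytes) -> bool:
    return canonical_form(a) == canonical_form(b)


# ---------------------------------------------------------------------------
# Selection

@dataclass(frozen=True)
class SelectionCriteria:
    """Preselection filter: all fields are optional restrictions (AND-ed)."""

    doc_ids: Optional[Sequence[int]] = None
    received_from: Optional[_dt.datetime] = None
    received_to: Optional[_dt.datetime] = None
    is_metadata: Optional[bool] = None
    path_patterns: Optional[Sequence[str]] = None


@dataclass(frozen=True)
class Selection:
    """A doc-scoped set of fact references chosen for export."""

    facts: tuple[FactRecord, ...]

    def __len__(self) -> int:
        return len(self.facts)

    def without(self, n: int) -> "Selection":
        """Drop the last ``n`` facts (test scaffolding for partial selects)."""
        return Selection(self.facts[: len(self.facts) - n])

    def plus(self, extra: Sequence[FactRecord]) -> "Selection":
        have = {f.value_id for f in self.facts}
        added = tuple(f for f in extra if f.value_id not in have)
        return Selection(self.facts + added)


def preselect(store: EAVStore, criteria: SelectionCriteria) -> Selection:
    """All facts matching the criteria; an empty match is not an error."""
    records = query_engine.fact_records(store, doc_ids=criteria.doc_ids)
    patterns = ([parse_pattern(p) for p in criteria.path_patterns]
                if criteria.path_patterns else None)
    metas: dict[int, _dt.datetime] = {}
    kept: list[FactRecord] = []
    for rec in records:
        if criteria.is_metadata is not None \
                and rec.is_metadata != criteria.is_metadata:
            continue
        if criteria.received_from is not None or criteria.received_to is not None:
            if rec.source_doc_id not in metas:
                metas[rec.source_doc_id] = \
                    store.get_meta(rec.source_doc_id).received_at
            received = metas[rec.source_doc_id]
            if criteria.received_from is not None \
                    and received < criteria.received_from:
                continue
            if criteria.received_to is not None \
                    and received >= criteria.received_to:
                continue
        if patterns is not None and not any(
            match_fact(p, rec.entity_path, rec.attribute) for p in patterns
        ):
            continue
        kept.append(rec)
    return Selection(tuple(kept))


# ---------------------------------------------------------------------------
# Transformation rules

_TRANSFORMS: dict[str, Callable[[str], str]] = {}


def register_transform(name: str, fn: Callable[[str], str]) -> None:
    """Register a named total value transform usable in rules."""
    if not name:
        raise ValidationError("transform name must be nonempty")
    _TRANSFORMS[name] = fn


def _iso_to_german(s: str) -> str:
    try:
        return _dt.date.fromisoformat(s).strftime("%d.%m.%Y")
    except ValueError:
        return s


def _compact_to_iso(s: str) -> str:
    if len(s) >= 8 and s[:8].isdigit():
        return f"{s[:4]}-{s[4:6]}-{s[6:8]}"
    return s


register_transform("identity", lambda s: s)
register_transform("upper", str.upper)
register_transform("lower", str.lower)
register_transform("date_iso_to_german", _iso_to_german)
register_transform("date_compact_to_iso", _compact_to_iso)


@dataclass(frozen=True)
class TransformRule:
    """Map source facts matching ``source_pattern`` into the target tree.

    ``target_path`` is a concrete slot path in the target document: element
    segments (``name`` or ``name[pos]``, position defaulting to 1) ending
    in ``@attr`` for an XML attribute slot or ``#text`` for a text slot.
    ``value_transform`` names a registered total function on lexicals.
    """

    name: str
    source_pattern: str
    target_path: str
    value_transform: str = "identity"
    required: bool = False

    def __post_init__(self):
        parse_pattern(self.source_pattern)  # validate eagerly
        _parse_target(self.target_path)
        if self.value_transform not in _TRANSFORMS:
            raise ValidationError(
                f"rule {self.name!r}: transform {self.value_transform!r} "
                "is not registered"
            )


def _parse_target(text: str) -> tuple[list[tuple[str, int]], str]:
    """Split a target path into element steps and the slot component."""
    if not text.startswith("/"):
        raise ValidationError(f"target path must start with '/': {text!r}")
    parts = text.strip("/").split("/")
    if not parts or not (parts[-1].startswith("@") or parts[-1] == TEXT_NODE):
        raise ValidationError(
            f"target path must end in @attr or {TEXT_NODE}: {text!r}"
        )
    slot = parts.pop()
    steps: list[tuple[str, int]] = []
    for seg in parts:
        if "[" in seg:
            name, _, idx = seg.partition("[")
            if not idx.endswith("]") or not idx[:-1].isdigit():
                raise ValidationError(f"bad target segment {seg!r}")
            steps.append((name, int(idx[:-1])))
        else:
            steps.append((seg, 1))
    if not steps:
        raise ValidationError(f"target path has no element steps: {text!r}")
    return steps, slot


# ---------------------------------------------------------------------------
# Target tree

class TargetTree:
    """In-progress export document; well-formed by construction."""

    def __init__(self) -> None:
        self.root: Optional[ElementNode] = None
        self._slots: dict[tuple, tuple[str, str]] = {}  # slot -> (value, rule)
        self.notices: list[str] = []

    def _ensure_element(self, steps: list[tuple[str, int]]) -> ElementNode:
        name, pos = steps[0]
        if self.root is None:
            self.root = ElementNode(name)
        if self.root.name != name or pos != 1:
            raise ConflictError(
                f"target root {name!r}[{pos}] conflicts with existing root "
                f"{self.root.name!r}"
            )
        node = self.root
        for name, pos in steps[1:]:
            same = [c for c in node.children
                    if isinstance(c, ElementNode) and c.name == name]
            while len(same) < pos:  # create occurrences up to pos
                child = ElementNode(name)
                node.children.append(child)
                same.append(child)
            node = same[pos - 1]
        return node

    def set_slot(self, steps: list[tuple[str, int]], slot: str, value: str,
                 rule_name: str) -> None:
        key = (tuple(steps), slot)
        prior = self._slots.get(key)
        if prior is not None:
            if prior[0] != value:
                raise ConflictError(
                    f"rules {prior[1]!r} and {rule_name!r} write different "
                    f"values to the same target slot "
                    f"{'/'.join(f'{n}[{p}]' for n, p in steps)}/{slot}"
                )
            return
        node = self._ensure_element(steps)
        if slot == TEXT_NODE:
            node.children.insert(0, TextNode(value))
        else:
            node.attrs.append((slot[1:], value))
        self._slots[key] = (value, rule_name)

    def has_slot(self, steps: list[tuple[str, int]], slot: Optional[str]) -> bool:
        if slot is not None:
            return (tuple(steps), slot) in self._slots
        # bare element requirement: the element exists
        try:
            node = self.root
            if node is None:
                return False
            name, pos = steps[0]
            if node.name != name or pos != 1:
                return False
            for name, pos in steps[1:]:
                same = [c for c in node.children
                        if isinstance(c, ElementNode) and c.name == name]
                if len(same) < pos:
                    return False
                node = same[pos - 1]
            return True
        except (IndexError, AttributeError):
            return False

    def serialize(self) -> bytes:
        if self.root is None:
            raise ValidationError("target tree is empty")
        return b'<?xml version="1.0" encoding="UTF-8"?>' + \
            serialize_tree(self.root)


def apply_rules(selection: Selection, rules: Sequence[TransformRule],
                store: EAVStore) -> TargetTree:
    """Instantiate target slots for every (selected fact, matching rule).

    Deterministic given selection and rules: facts are processed in the
    selection's (doc, path, attribute) order, rules in list order.  A
    selected fact matched by no rule is recorded as a notice, not an error;
    two rules writing *different* values to one slot raise
    :class:`ConflictError` naming both.
    """
    tree = TargetTree()
    compiled = [(r, parse_pattern(r.source_pattern)) for r in rules]
    ordered = sorted(selection.facts,
                     key=lambda f: (f.source_doc_id, f.entity_path, f.attribute))
    for fact in ordered:
        matched = False
        for rule, pattern in compiled:
            if not match_fact(pattern, fact.entity_path, fact.attribute):
                continue
            matched = True
            value = _TRANSFORMS[rule.value_transform](fact.lexical)
            steps, slot = _parse_target(rule.target_path)
            tree.set_slot(steps, slot, value, rule.name)
        if not matched:
            tree.notices.append(
                f"unmatched fact {fact.entity_path} {fact.attribute!r}"
            )
    return tree


# ---------------------------------------------------------------------------
# Completeness

@dataclass(frozen=True)
class CompletenessSpec:
    """Required content of a standardized target document.

    ``required_paths`` are target slot paths (same syntax as rule targets;
    a path without slot component requires the element to exist).
    ``root_name``, when set, additionally requires that root element name.
    """

    required_paths: tuple[str, ...]
    root_name: Optional[str] = None


def check_completeness(tree: TargetTree,
                       spec: CompletenessSpec) -> list[str]:
    """Return exactly the required paths not populated in the tree.

    A wrong or absent root is a validity failure reported alongside the
    missing paths as a ``root:`` entry.
    """
    missing: list[str] = []
    if spec.root_name is not None:
        if tree.root is None or tree.root.name != spec.root_name:
            missing.append(f"root:{spec.root_name}")
    for req in spec.required_paths:
        parts = req.strip("/").split("/")
        if parts and (parts[-1].startswith("@") or parts[-1] == TEXT_NODE):
            steps, slot = _parse_target(req)
        else:
            steps = []
            for seg in parts:
                if "[" in seg:
                    name, _, idx = seg.partition("[")
                    steps.append((name, int(idx[:-1])))
                else:
                    steps.append((seg, 1))
            slot = None
        if not tree.has_slot(steps, slot):
            missing.append(req)
    return missing


# ---------------------------------------------------------------------------
# The export loop

def export_document(store: EAVStore, criteria: SelectionCriteria,
                    rules: Sequence[TransformRule], spec: CompletenessSpec,
                    selector: Callable[[Selection, list[str]], Selection],
                    max_iterations: int = 10) -> tuple[bytes, int]:
    """Run preselect -> select -> transform -> completeness-check to a fix.

    ``selector`` models the manual selection step: it is called once with
    the preselection and an empty missing list, then after each failed
    completeness check with the current selection and the missing target
    paths, and must return the refined selection.  Returns the serialized
    target document and the number of transform+check iterations.

    Raises :class:`ExportIncompleteError` when ``max_iterations`` passes
    did not produce a complete document.
    """
    selection = selector(preselect(store, criteria), [])
    missing: list[str] = []
    for iteration in range(1, max_iterations + 1):
        tree = apply_rules(selection, rules, store)
        missing = check_completeness(tree, spec)
        if not missing:
            return tree.serialize(), iteration
        selection = selector(selection, missing)
    raise ExportIncompleteError(missing, max_iterations)


# ---------------------------------------------------------------------------
# Declarative configuration

def load_rules(path: str) -> list[TransformRule]:
    """Read transformation rules from a YAML file (key ``rules``)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    rules = []
    for i, entry in enumerate(data.get("rules", [])):
        rules.append(TransformRule(
            name=entry.get("name", f"rule{i + 1}"),
            source_pattern=entry["source"],
            target_path=entry["target"],
            value_transform=entry.get("transform", "identity"),
            required=bool(entry.get("required", False)),
        ))
    return rules


def load_completeness_spec(path: str) -> CompletenessSpec:
    """Read a completeness spec from a YAML file (key ``completeness``)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    section = data.get("completeness", {})
    return CompletenessSpec(
        required_paths=tuple(section.get("required", [])),
        root_name=section.get("root"),
    )
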