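"""View-based access rights: horizontal/vertical fragments per role.

A view selects a fragment of the store: the *horizontal* part is a
predicate over facts' provenance (a time window on the document receipt
time, a document-type set, the header/body flag) and the *vertical* part
restricts by entity-path patterns and/or attribute names.  Grants attach a
subset of {read, add, delete, update} rights on a view to a role; a role
with several grants sees the union of its readable fragments.

Enforcement happens in the query layer — every tuple returned by
:func:`query_as` is intersected with the role's readable fragment — so
rights apply at the granularity of single facts, finer than whole
documents, and the contract is independent of any DBMS view mechanism.
Updates never overwrite an imported fact: the old row is marked superseded
and a fresh row is inserted, preserving the version history.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import query_engine
from ._patterns import match_fact, parse_pattern
from .core_model import (
    AuthorizationError,
    ConflictError,
    EAVStore,
    ReferentialError,
    ValidationError,
    ValueFact,
)
from .query_engine import EAVTuple, FactRecord, QuerySpec

__all__ = [
    "ViewSpec",
    "Grant",
    "RIGHTS",
    "define_view",
    "get_view",
    "list_views",
    "grant",
    "revoke",
    "grants_for",
    "evaluate_view",
    "readable_fragment",
    "query_as",
    "add_fact_as",
    "delete_fact_as",
    "update_fact_as",
    "load_access_config",
]

RIGHTS = frozenset({"read", "add", "delete", "update"})


@dataclass(frozen=True)
class ViewSpec:
    """A named horizontal+vertical fragment of the store.

    All restriction fields default to None = unrestricted; a spec with no
    restrictions evaluates to the whole store ("all").
    """

    name: str
    received_from: Optional[_dt.datetime] = None
    received_to: Optional[_dt.datetime] = None
    doc_types: Optional[frozenset[str]] = None
    is_metadata: Optional[bool] = None
    path_patterns: Optional[tuple[str, ...]] = None
    attributes: Optional[frozenset[str]] = None

    def __post_init__(self):
        if not self.name:
            raise ValidationError("view name must be nonempty")
        if self.path_patterns:
            for p in self.path_patterns:
                parse_pattern(p)

    def to_json(self) -> str:
        return json.dumps({
            "name": self.name,
            "received_from": self.received_from.isoformat()
            if self.received_from else None,
            "received_to": self.received_to.isoformat()
            if self.received_to else None,
            "doc_types": sorted(self.doc_types) if self.doc_types else None,
            "is_metadata": self.is_metadata,
            "path_patterns": list(self.path_patterns)
            if self.path_patterns else None,
            "attributes": sorted(self.attributes) if self.attributes else None,
        })

    @classmethod
    def from_json(cls, text: str) -> "ViewSpec":
        d = json.loads(text)
        return cls(
            name=d["name"],
            received_from=_dt.datetime.fromisoformat(d["received_from"])
            if d["received_from"] else None,
            received_to=_dt.datetime.fromisoformat(d["received_to"])
            if d["received_to"] else None,
            doc_types=frozenset(d["doc_types"]) if d["doc_types"] else None,
            is_metadata=d["is_metadata"],
            path_patterns=tuple(d["path_patterns"])
            if d["path_patterns"] else None,
            attributes=frozenset(d["attributes"]) if d["attributes"] else None,
        )


@dataclass(frozen=True)
class Grant:
    grant_id: int
    role: str
    view_id: int
    rights: frozenset[str]


# ---------------------------------------------------------------------------
# Registration

def define_view(store: EAVStore, spec: ViewSpec) -> int:
    """Register a view; duplicate names conflict."""
    existing = store.connection.execute(
        "SELECT 1 FROM view_spec WHERE name = ?", (spec.name,)
    ).fetchone()
    if existing is not None:
        raise ConflictError(f"view {spec.name!r} already defined")
    cur = store.connection.execute(
        "INSERT INTO view_spec (name, spec_json) VALUES (?,?)",
        (spec.name, spec.to_json()),
    )
    return cur.lastrowid


def get_view(store: EAVStore, view_id: int) -> ViewSpec:
    row = store.connection.execute(
        "SELECT spec_json FROM view_spec WHERE view_id = ?", (view_id,)
    ).fetchone()
    if row is None:
        raise ReferentialError(f"no view {view_id}")
    return ViewSpec.from_json(row[0])


def list_views(store: EAVStore) -> dict[str, int]:
    return dict(store.connection.execute(
        "SELECT name, view_id FROM view_spec ORDER BY view_id"
    ).fetchall())


def grant(store: EAVStore, role: str, view_id: int,
          rights: Sequence[str]) -> int:
    """Grant rights on a view to a role; fragments union across grants."""
    if not role:
        raise ValidationError("role must be nonempty")
    rightset = frozenset(rights)
    if not rightset:
        raise ValidationError("rights must be nonempty")
    if not rightset <= RIGHTS:
        raise ValidationError(f"unknown rights: {sorted(rightset - RIGHTS)}")
    get_view(store, view_id)  # must exist
    cur = store.connection.execute(
        "INSERT INTO grant_entry (role, view_id, rights) VALUES (?,?,?)",
        (role, view_id, json.dumps(sorted(rightset))),
    )
    return cur.lastrowid


def revoke(store: EAVStore, grant_id: int) -> None:
    cur = store.connection.execute(
        "DELETE FROM grant_entry WHERE grant_id = ?", (grant_id,)
    )
    if cur.rowcount == 0:
        raise ReferentialError(f"no grant {grant_id}")


def grants_for(store: EAVStore, role: str) -> list[Grant]:
    rows = store.connection.execute(
        "SELECT grant_id, role, view_id, rights FROM grant_entry "
        "WHERE role = ? ORDER BY grant_id", (role,)
    ).fetchall()
    return [Grant(g, r, v, frozenset(json.loads(rt))) for g, r, v, rt in rows]


# ---------------------------------------------------------------------------
# Fragment evaluation

def _fact_in_view(store: EAVStore, spec: ViewSpec, rec: FactRecord,
                  meta_cache: dict) -> bool:
    if spec.is_metadata is not None and rec.is_metadata != spec.is_metadata:
        return False
    if (spec.received_from is not None or spec.received_to is not None
            or spec.doc_types is not None):
        if rec.source_doc_id not in meta_cache:
            meta_cache[rec.source_doc_id] = store.get_meta(rec.source_doc_id)
        meta = meta_cache[rec.source_doc_id]
        if spec.received_from is not None \
                and meta.received_at < spec.received_from:
            return False
        if spec.received_to is not None \
                and meta.received_at >= spec.received_to:
            return False
        if spec.doc_types is not None and meta.doc_type not in spec.doc_types:
            return False
    if spec.path_patterns is None and spec.attributes is None:
        return True
    # vertical: union of the pattern list and the attribute-name list
    if spec.path_patterns is not None:
        for p in spec.path_patterns:
            if match_fact(parse_pattern(p), rec.entity_path, rec.attribute):
                return True
    if spec.attributes is not None and rec.attribute in spec.attributes:
        return True
    return False


def evaluate_view(store: EAVStore, spec: ViewSpec) -> list[FactRecord]:
    """All live facts inside the view's fragment."""
    cache: dict = {}
    return [r for r in query_engine.fact_records(store)
            if _fact_in_view(store, spec, r, cache)]


def _views_with_right(store: EAVStore, role: str,
                      right: str) -> list[ViewSpec]:
    return [get_view(store, g.view_id) for g in grants_for(store, role)
            if right in g.rights]


def readable_fragment(store: EAVStore, role: str) -> list[FactRecord]:
    """Union of the role's read-granted view fragments."""
    specs = _views_with_right(store, role, "read")
    if not specs:
        raise AuthorizationError(f"role {role!r} has no read grant")
    cache: dict = {}
    out = []
    for rec in query_engine.fact_records(store):
        if any(_fact_in_view(store, s, rec, cache) for s in specs):
            out.append(rec)
    return out


def query_as(store: EAVStore, role: str, spec: QuerySpec) -> list[EAVTuple]:
    """Run a query as a role: unrestricted result ∩ readable fragment."""
    readable = {r.value_id for r in readable_fragment(store, role)}
    if spec.kind == "all":
        records = query_engine.fact_records(store)
    else:
        docs = query_engine.find_documents(store, spec.term)  # type: ignore
        records = query_engine.fact_records(store, doc_ids=docs)
    return [r.as_tuple() for r in records if r.value_id in readable]


# ---------------------------------------------------------------------------
# Write rights

def _record_for(store: EAVStore, fact: ValueFact) -> FactRecord:
    return FactRecord(
        value_id="", source_doc_id=fact.source_doc_id,
        entity_id=fact.entity_id,
        entity_path=query_engine.ancestor_path(store, fact.entity_id),
        attribute=store.attribute_name(fact.attribute_id),
        lexical=fact.lexical, datatype=fact.datatype,
        is_metadata=fact.is_metadata,
    )


def _authorize(store: EAVStore, role: str, right: str,
               rec: FactRecord) -> None:
    specs = _views_with_right(store, role, right)
    cache: dict = {}
    if not any(_fact_in_view(store, s, rec, cache) for s in specs):
        raise AuthorizationError(
            f"role {role!r} may not {right} fact at {rec.entity_path} "
            f"({rec.attribute!r})"
        )


def add_fact_as(store: EAVStore, role: str, fact: ValueFact) -> str:
    """Insert a fact if the role holds the add right over it."""
    _authorize(store, role, "add", _record_for(store, fact))
    return store.insert_value(fact)


def _find_record(store: EAVStore, value_id: str) -> FactRecord:
    fact = store.get_value(value_id)
    rec = _record_for(store, fact)
    return FactRecord(
        value_id=value_id, source_doc_id=rec.source_doc_id,
        entity_id=rec.entity_id, entity_path=rec.entity_path,
        attribute=rec.attribute, lexical=rec.lexical,
        datatype=rec.datatype, is_metadata=rec.is_metadata,
    )


def delete_fact_as(store: EAVStore, role: str, value_id: str) -> None:
    rec = _find_record(store, value_id)
    _authorize(store, role, "delete", rec)
    tag, _, rowid = value_id.partition(":")
    store.connection.execute(
        f"DELETE FROM {tag}_value WHERE value_id = ?", (int(rowid),)
    )


def update_fact_as(store: EAVStore, role: str, value_id: str,
                   new_lexical: str) -> str:
    """Supersede a fact with a new version holding ``new_lexical``.

    The imported row is never overwritten: it is flagged superseded (and so
    drops out of live queries) and a fresh row with a re-routed datatype is
    inserted.
    """
    from .importer import infer_datatype

    rec = _find_record(store, value_id)
    _authorize(store, role, "update", rec)
    old = store.get_value(value_id)
    new_id = store.insert_value(ValueFact(
        entity_id=old.entity_id, attribute_id=old.attribute_id,
        source_doc_id=old.source_doc_id,
        datatype=infer_datatype(new_lexical, store),
        lexical=new_lexical, is_metadata=old.is_metadata,
    ))
    tag, _, rowid = value_id.partition(":")
    store.connection.execute(
        f"UPDATE {tag}_value SET superseded = 1 WHERE value_id = ?",
        (int(rowid),),
    )
    return new_id


# ---------------------------------------------------------------------------
# Declarative configuration

def load_access_config(store: EAVStore, path: str) -> dict[str, int]:
    """Define views and grants from a YAML file.

    Schema::

        views:
          - name: header-only
            horizontal: {is_metadata: true}
          - name: meds
            vertical: {paths: ["/ClinicalDocument[1]/**"], attributes: [code]}
        grants:
          - {role: nurse, view: header-only, rights: [read]}

    Returns the name -> view_id mapping of the defined views.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    ids: dict[str, int] = {}
    for entry in data.get("views", []):
        horiz = entry.get("horizontal", {}) or {}
        vert = entry.get("vertical", {}) or {}
        spec = ViewSpec(
            name=entry["name"],
            received_from=_dt.datetime.fromisoformat(horiz["received_from"])
            if horiz.get("received_from") else None,
            received_to=_dt.datetime.fromisoformat(horiz["received_to"])
            if horiz.get("received_to") else None,
            doc_types=frozenset(horiz["doc_types"])
            if horiz.get("doc_types") else None,
            is_metadata=horiz.get("is_metadata"),
            path_patterns=tuple(vert["paths"]) if vert.get("paths") else None,
            attributes=frozenset(vert["attributes"])
            if vert.get("attributes") else None,
        )
        ids[spec.name] = define_view(store, spec)
    for entry in data.get("grants", []):
        view_id = ids.get(entry["view"]) or list_views(store)[entry["view"]]
        grant(store, entry["role"], view_id, entry["rights"])
    return ids
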