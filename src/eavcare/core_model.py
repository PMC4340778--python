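"""Extended entity-attribute-value (EAV) schema and storage contract.

The store keeps one *entity* row per XML element occurrence (plus ``#text``
pseudo-entities for text nodes), a deduplicated *attribute* dictionary, and
one *value* table per registered datatype.  Hierarchy lives in the entity
relation itself: every non-root entity carries a ``parent_id`` and its
1-based ``sibling_pos`` among the kept children of that parent.  There is
deliberately no direct entity<->attribute link — the pairing exists only in
the value rows — so an attribute name is stored exactly once no matter how
many entities use it.

Each value row also references the source document it was shredded from and
carries a boolean ``is_metadata`` flag (header vs body origin), the verbatim
lexical form from the source, and the parsed typed value.  Raw document
bytes are retained alongside the per-document provenance record so imported
reports remain restorable.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import re
import sqlite3
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Iterable, Optional

__all__ = [
    "DataType",
    "DEFAULT_DATATYPES",
    "EntityNode",
    "ValueFact",
    "SourceDocMeta",
    "EAVStore",
    "open_store",
    "EAVError",
    "ConfigurationError",
    "ValidationError",
    "ReferentialError",
    "OrderingError",
    "DuplicateDocumentError",
    "UnknownDocumentError",
    "UnknownEntityError",
    "ConflictError",
    "AuthorizationError",
]


# ---------------------------------------------------------------------------
# Errors

class EAVError(Exception):
    """Base class for all storage-engine errors."""


class ConfigurationError(EAVError):
    """The store location or configuration is unusable."""


class ValidationError(EAVError):
    """An input violates a precondition (empty name, bad datatype...)."""


class ReferentialError(EAVError):
    """A reference points at a row that does not exist."""


class OrderingError(EAVError):
    """A sibling_pos collision or contiguity violation."""


class DuplicateDocumentError(EAVError):
    """Same raw bytes registered twice under the reject policy."""


class UnknownDocumentError(EAVError):
    """No source document with that id."""


class UnknownEntityError(EAVError):
    """No entity with that id."""


class ConflictError(EAVError):
    """Two definitions compete for the same slot or name."""


class AuthorizationError(EAVError):
    """A role lacks the right required for an operation."""


# ---------------------------------------------------------------------------
# Datatype registry

_INT_RE = re.compile(r"[+-]?\d+\Z")
_REAL_RE = re.compile(r"[+-]?(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?\Z")
_DATE_RE = re.compile(r"\d{4}-\d{2}-\d{2}\Z")
_TS_RE = re.compile(
    r"\d{4}-\d{2}-\d{2}[T ]\d{2}:\d{2}(:\d{2}(\.\d+)?)?(Z|[+-]\d{2}:?\d{2})?\Z"
)


@dataclass(frozen=True)
class DataType:
    """One entry of the datatype registry.

    Each tag owns a dedicated value table (``<tag>_value``).  ``parse`` turns
    a lexical string into the typed domain (raising ``ValueError`` when it
    does not belong), ``matches`` is the cheap membership test the datatype
    router uses, and ``to_sql``/``from_sql`` map the typed value onto the
    SQLite column.  The shipped set is a representative subset of the ISO
    21090 primitive types; new tags can be registered on any store.
    """

    tag: str
    sql_affinity: str
    parse: Callable[[str], Any]
    matches: Callable[[str], bool]
    to_sql: Callable[[Any], Any] = lambda v: v
    from_sql: Callable[[Any], Any] = lambda v: v


def _parse_bool(s: str) -> bool:
    low = s.strip().lower()
    if low == "true":
        return True
    if low == "false":
        return False
    raise ValueError(f"not a boolean lexical: {s!r}")


def _parse_date(s: str) -> _dt.date:
    if not _DATE_RE.match(s):
        raise ValueError(f"not an ISO date: {s!r}")
    return _dt.date.fromisoformat(s)


def _parse_timestamp(s: str) -> _dt.datetime:
    if not _TS_RE.match(s):
        raise ValueError(f"not an ISO timestamp: {s!r}")
    return _dt.datetime.fromisoformat(s.replace("Z", "+00:00"))


def _parses(parse: Callable[[str], Any], s: str) -> bool:
    try:
        parse(s)
        return True
    except ValueError:
        return False


DEFAULT_DATATYPES: tuple[DataType, ...] = (
    DataType("string", "TEXT", str, lambda s: True),
    DataType(
        "integer", "INTEGER", int,
        lambda s: bool(_INT_RE.match(s.strip())) and s.strip() == s,
    ),
    DataType(
        "real", "REAL", float,
        lambda s: bool(_REAL_RE.match(s)),
    ),
    DataType(
        "boolean", "INTEGER", _parse_bool,
        lambda s: s.lower() in ("true", "false"),
        to_sql=lambda v: int(v),
        from_sql=lambda v: bool(v),
    ),
    DataType(
        "date", "TEXT", _parse_date,
        lambda s: _parses(_parse_date, s),  # shape AND calendar validity
        to_sql=lambda v: v.isoformat(),
        from_sql=_dt.date.fromisoformat,
    ),
    DataType(
        "timestamp", "TEXT", _parse_timestamp,
        lambda s: _parses(_parse_timestamp, s),
        to_sql=lambda v: v.isoformat(),
        from_sql=_dt.datetime.fromisoformat,
    ),
)


# ---------------------------------------------------------------------------
# Domain records

#: Reserved name for text-node pseudo-entities and their attribute.
TEXT_NODE = "#text"


@dataclass(frozen=True)
class EntityNode:
    """One XML element (or ``#text`` pseudo-node) occurrence."""

    entity_id: int
    name: str
    parent_id: Optional[int]
    sibling_pos: int


@dataclass(frozen=True)
class ValueFact:
    """One typed datum tying an entity, an attribute and a source document.

    ``lexical`` is the verbatim source string; ``typed_value`` its parsed
    form under ``datatype``.  ``is_metadata`` is true for facts shredded
    from the document header region.
    """

    entity_id: int
    attribute_id: int
    source_doc_id: int
    datatype: str
    lexical: str
    typed_value: Any = None
    is_metadata: bool = False


@dataclass(frozen=True)
class SourceDocMeta:
    """Provenance record for one imported document."""

    author: str
    doc_type: str = "unknown"
    template: str = "unknown"
    received_at: _dt.datetime = field(
        default_factory=lambda: _dt.datetime(1970, 1, 1)
    )
    source_doc_id: Optional[int] = None
    original_digest: Optional[str] = None
    version: int = 1


def _digest(raw: bytes) -> str:
    return hashlib.sha256(raw).hexdigest()


# ---------------------------------------------------------------------------
# Store

_FIXED_SCHEMA = """
CREATE TABLE IF NOT EXISTS source_doc (
    source_doc_id INTEGER PRIMARY KEY,
    author        TEXT NOT NULL,
    doc_type      TEXT NOT NULL,
    template      TEXT NOT NULL,
    received_at   TEXT NOT NULL,
    digest        TEXT NOT NULL,
    version       INTEGER NOT NULL DEFAULT 1,
    raw           BLOB NOT NULL,
    root_entity_id INTEGER
);
CREATE TABLE IF NOT EXISTS entity (
    entity_id   INTEGER PRIMARY KEY,
    name        TEXT NOT NULL,
    parent_id   INTEGER REFERENCES entity(entity_id),
    sibling_pos INTEGER NOT NULL CHECK (sibling_pos >= 1),
    UNIQUE (parent_id, sibling_pos)
);
CREATE TABLE IF NOT EXISTS attribute (
    attribute_id INTEGER PRIMARY KEY,
    name         TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS entity_path (
    entity_id     INTEGER PRIMARY KEY REFERENCES entity(entity_id),
    source_doc_id INTEGER NOT NULL REFERENCES source_doc(source_doc_id),
    path          TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS view_spec (
    view_id   INTEGER PRIMARY KEY,
    name      TEXT NOT NULL UNIQUE,
    spec_json TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS grant_entry (
    grant_id INTEGER PRIMARY KEY,
    role     TEXT NOT NULL,
    view_id  INTEGER NOT NULL REFERENCES view_spec(view_id),
    rights   TEXT NOT NULL
);
"""

_VALUE_TABLE_TEMPLATE = """
CREATE TABLE IF NOT EXISTS {tag}_value (
    value_id      INTEGER PRIMARY KEY,
    entity_id     INTEGER NOT NULL REFERENCES entity(entity_id),
    attribute_id  INTEGER NOT NULL REFERENCES attribute(attribute_id),
    source_doc_id INTEGER NOT NULL REFERENCES source_doc(source_doc_id),
    typed_value   {affinity},
    lexical       TEXT NOT NULL,
    is_metadata   INTEGER NOT NULL,
    superseded    INTEGER NOT NULL DEFAULT 0
);
CREATE INDEX IF NOT EXISTS idx_{tag}_value_doc ON {tag}_value(source_doc_id);
CREATE INDEX IF NOT EXISTS idx_{tag}_value_entity ON {tag}_value(entity_id);
"""

_TAG_RE = re.compile(r"[a-z][a-z0-9_]*\Z")


class EAVStore:
    """Handle on one EAV database (SQLite file or in-memory).

    All writes done through the public methods keep the schema invariants:
    contiguous sibling positions per parent, acyclic parent links, unique
    attribute names, and referentially closed value rows.
    """

    def __init__(self, target: str = ":memory:",
                 on_duplicate: str = "reject",
                 datatypes: Iterable[DataType] = DEFAULT_DATATYPES):
        if on_duplicate not in ("reject", "version"):
            raise ConfigurationError(
                f"on_duplicate must be 'reject' or 'version', got {on_duplicate!r}"
            )
        self.target = target
        self.on_duplicate = on_duplicate
        self.datatypes: dict[str, DataType] = {}
        try:
            # autocommit: single operations persist immediately; the importer
            # opens an explicit transaction for its all-or-nothing load.
            self._conn = sqlite3.connect(target, isolation_level=None)
        except sqlite3.OperationalError as exc:  # unwritable path etc.
            raise ConfigurationError(f"cannot open store at {target!r}: {exc}")
        self._conn.execute("PRAGMA foreign_keys = ON")
        self._conn.executescript(_FIXED_SCHEMA)
        for dt in datatypes:
            self.register_datatype(dt)
        self._conn.commit()

    # -- plumbing -----------------------------------------------------------

    @property
    def connection(self) -> sqlite3.Connection:
        return self._conn

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "EAVStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def list_tables(self) -> list[str]:
        rows = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%' ORDER BY name"
        ).fetchall()
        return [r[0] for r in rows]

    def register_datatype(self, dt: DataType) -> None:
        """Register a datatype tag and create its value table (idempotent)."""
        if not _TAG_RE.match(dt.tag):
            raise ValidationError(f"invalid datatype tag {dt.tag!r}")
        if dt.tag in self.datatypes:
            return
        self.datatypes[dt.tag] = dt
        self._conn.executescript(
            _VALUE_TABLE_TEMPLATE.format(tag=dt.tag, affinity=dt.sql_affinity)
        )

    # -- attribute dictionary ----------------------------------------------

    def upsert_attribute(self, name: str) -> int:
        """Return the id for ``name``, inserting it only if absent."""
        if not name:
            raise ValidationError("attribute name must be nonempty")
        cur = self._conn.execute(
            "SELECT attribute_id FROM attribute WHERE name = ?", (name,)
        )
        row = cur.fetchone()
        if row is not None:
            return row[0]
        cur = self._conn.execute(
            "INSERT INTO attribute (name) VALUES (?)", (name,)
        )
        return cur.lastrowid

    def attribute_name(self, attribute_id: int) -> str:
        row = self._conn.execute(
            "SELECT name FROM attribute WHERE attribute_id = ?", (attribute_id,)
        ).fetchone()
        if row is None:
            raise ReferentialError(f"no attribute {attribute_id}")
        return row[0]

    # -- entities -----------------------------------------------------------

    def insert_entity(self, name: str, parent_id: Optional[int],
                      sibling_pos: int) -> int:
        if not name:
            raise ValidationError("entity name must be nonempty")
        if sibling_pos < 1:
            raise OrderingError(f"sibling_pos must be >= 1, got {sibling_pos}")
        if parent_id is not None:
            exists = self._conn.execute(
                "SELECT 1 FROM entity WHERE entity_id = ?", (parent_id,)
            ).fetchone()
            if exists is None:
                raise ReferentialError(f"parent entity {parent_id} does not exist")
        try:
            cur = self._conn.execute(
                "INSERT INTO entity (name, parent_id, sibling_pos) VALUES (?,?,?)",
                (name, parent_id, sibling_pos),
            )
        except sqlite3.IntegrityError as exc:
            raise OrderingError(
                f"sibling_pos {sibling_pos} already taken under parent "
                f"{parent_id}: {exc}"
            )
        return cur.lastrowid

    def get_entity(self, entity_id: int) -> EntityNode:
        row = self._conn.execute(
            "SELECT entity_id, name, parent_id, sibling_pos FROM entity "
            "WHERE entity_id = ?", (entity_id,)
        ).fetchone()
        if row is None:
            raise UnknownEntityError(f"no entity {entity_id}")
        return EntityNode(*row)

    def children_of(self, entity_id: Optional[int]) -> list[EntityNode]:
        """Children ordered by sibling_pos (document order)."""
        rows = self._conn.execute(
            "SELECT entity_id, name, parent_id, sibling_pos FROM entity "
            "WHERE parent_id IS ? ORDER BY sibling_pos", (entity_id,)
        ).fetchall()
        return [EntityNode(*r) for r in rows]

    # -- values -------------------------------------------------------------

    def insert_value(self, fact: ValueFact) -> str:
        """Store a fact in the value table selected by its datatype tag.

        Returns an opaque value id (stable string).  The lexical form is
        reparsed under the datatype and must agree with ``typed_value`` when
        one is supplied.
        """
        dt = self.datatypes.get(fact.datatype)
        if dt is None:
            raise ReferentialError(f"datatype {fact.datatype!r} not registered")
        for table, col, ref in (
            ("entity", "entity_id", fact.entity_id),
            ("attribute", "attribute_id", fact.attribute_id),
            ("source_doc", "source_doc_id", fact.source_doc_id),
        ):
            if self._conn.execute(
                f"SELECT 1 FROM {table} WHERE {col} = ?", (ref,)
            ).fetchone() is None:
                raise ReferentialError(f"no {table} row {ref}")
        try:
            typed = dt.parse(fact.lexical)
        except ValueError as exc:
            raise ValidationError(str(exc))
        if fact.typed_value is not None and fact.typed_value != typed:
            raise ValidationError(
                f"typed_value {fact.typed_value!r} disagrees with lexical "
                f"{fact.lexical!r} under datatype {fact.datatype}"
            )
        cur = self._conn.execute(
            f"INSERT INTO {dt.tag}_value "
            "(entity_id, attribute_id, source_doc_id, typed_value, lexical, "
            " is_metadata) VALUES (?,?,?,?,?,?)",
            (fact.entity_id, fact.attribute_id, fact.source_doc_id,
             dt.to_sql(typed), fact.lexical, int(fact.is_metadata)),
        )
        return f"{dt.tag}:{cur.lastrowid}"

    def get_value(self, value_id: str) -> ValueFact:
        tag, _, rowid = value_id.partition(":")
        dt = self.datatypes.get(tag)
        if dt is None or not rowid.isdigit():
            raise ReferentialError(f"malformed value id {value_id!r}")
        row = self._conn.execute(
            f"SELECT entity_id, attribute_id, source_doc_id, typed_value, "
            f"lexical, is_metadata FROM {tag}_value WHERE value_id = ?",
            (int(rowid),),
        ).fetchone()
        if row is None:
            raise ReferentialError(f"no value {value_id}")
        return ValueFact(
            entity_id=row[0], attribute_id=row[1], source_doc_id=row[2],
            datatype=tag, lexical=row[4],
            typed_value=dt.from_sql(row[3]), is_metadata=bool(row[5]),
        )

    # -- source documents ---------------------------------------------------

    def register_source_doc(self, meta: SourceDocMeta, raw: bytes,
                            on_duplicate: Optional[str] = None) -> int:
        if not raw:
            raise ValidationError("raw document bytes must be nonempty")
        policy = on_duplicate or self.on_duplicate
        digest = _digest(raw)
        version = 1
        prior = self._conn.execute(
            "SELECT MAX(version) FROM source_doc WHERE digest = ?", (digest,)
        ).fetchone()[0]
        if prior is not None:
            if policy == "reject":
                raise DuplicateDocumentError(
                    f"document with digest {digest[:12]}... already imported"
                )
            version = prior + 1
        cur = self._conn.execute(
            "INSERT INTO source_doc (author, doc_type, template, received_at, "
            "digest, version, raw) VALUES (?,?,?,?,?,?,?)",
            (meta.author, meta.doc_type, meta.template,
             meta.received_at.isoformat(), digest, version, raw),
        )
        return cur.lastrowid

    def set_root_entity(self, source_doc_id: int, entity_id: int) -> None:
        """Link a document's root entity into its provenance record."""
        self.get_entity(entity_id)
        if self._conn.execute(
            "SELECT 1 FROM source_doc WHERE source_doc_id = ?", (source_doc_id,)
        ).fetchone() is None:
            raise UnknownDocumentError(f"no source document {source_doc_id}")
        self._conn.execute(
            "UPDATE source_doc SET root_entity_id = ? WHERE source_doc_id = ?",
            (entity_id, source_doc_id),
        )

    def get_meta(self, source_doc_id: int) -> SourceDocMeta:
        row = self._conn.execute(
            "SELECT source_doc_id, author, doc_type, template, received_at, "
            "digest, version FROM source_doc WHERE source_doc_id = ?",
            (source_doc_id,),
        ).fetchone()
        if row is None:
            raise UnknownDocumentError(f"no source document {source_doc_id}")
        return SourceDocMeta(
            source_doc_id=row[0], author=row[1], doc_type=row[2],
            template=row[3], received_at=_dt.datetime.fromisoformat(row[4]),
            original_digest=row[5], version=row[6],
        )

    def get_raw(self, source_doc_id: int) -> bytes:
        row = self._conn.execute(
            "SELECT raw FROM source_doc WHERE source_doc_id = ?",
            (source_doc_id,),
        ).fetchone()
        if row is None:
            raise UnknownDocumentError(f"no source document {source_doc_id}")
        return bytes(row[0])

    def root_entity_of(self, source_doc_id: int) -> Optional[int]:
        row = self._conn.execute(
            "SELECT root_entity_id FROM source_doc WHERE source_doc_id = ?",
            (source_doc_id,),
        ).fetchone()
        if row is None:
            raise UnknownDocumentError(f"no source document {source_doc_id}")
        return row[0]

    def list_documents(self) -> list[int]:
        return [r[0] for r in self._conn.execute(
            "SELECT source_doc_id FROM source_doc ORDER BY source_doc_id"
        )]

    # -- counts and integrity ----------------------------------------------

    def count(self, table: str) -> int:
        if not re.match(r"[A-Za-z_][A-Za-z0-9_]*\Z", table):
            raise ValidationError(f"bad table name {table!r}")
        return self._conn.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]

    def n_entities(self) -> int:
        return self.count("entity")

    def n_attributes(self) -> int:
        return self.count("attribute")

    def n_values(self, include_superseded: bool = False) -> int:
        total = 0
        for tag in self.datatypes:
            q = f"SELECT COUNT(*) FROM {tag}_value"
            if not include_superseded:
                q += " WHERE superseded = 0"
            total += self._conn.execute(q).fetchone()[0]
        return total

    def validate(self) -> None:
        """Check structural invariants; raise on the first violation.

        Verifies per-parent sibling contiguity (positions exactly 1..k),
        acyclic parent chains, and referential closure of every value row.
        """
        rows = self._conn.execute(
            "SELECT parent_id, sibling_pos FROM entity WHERE parent_id "
            "IS NOT NULL ORDER BY parent_id, sibling_pos"
        ).fetchall()
        by_parent: dict[int, list[int]] = {}
        for pid, pos in rows:
            by_parent.setdefault(pid, []).append(pos)
        for pid, positions in by_parent.items():
            if positions != list(range(1, len(positions) + 1)):
                raise OrderingError(
                    f"children of entity {pid} have positions {positions}"
                )
        parent = dict(self._conn.execute(
            "SELECT entity_id, parent_id FROM entity"
        ).fetchall())
        for start in parent:
            seen = set()
            node = start
            while node is not None:
                if node in seen:
                    raise OrderingError(f"parent cycle through entity {start}")
                seen.add(node)
                if node not in parent:
                    raise ReferentialError(f"dangling parent link at {node}")
                node = parent[node]
        for tag in self.datatypes:
            bad = self._conn.execute(
                f"SELECT COUNT(*) FROM {tag}_value v "
                "LEFT JOIN entity e ON e.entity_id = v.entity_id "
                "LEFT JOIN attribute a ON a.attribute_id = v.attribute_id "
                "LEFT JOIN source_doc s ON s.source_doc_id = v.source_doc_id "
                "WHERE e.entity_id IS NULL OR a.attribute_id IS NULL "
                "OR s.source_doc_id IS NULL"
            ).fetchone()[0]
            if bad:
                raise ReferentialError(f"{bad} dangling rows in {tag}_value")


def open_store(target: str = ":memory:", on_duplicate: str = "reject",
               datatypes: Iterable[DataType] = DEFAULT_DATATYPES) -> EAVStore:
    """Open (creating if needed) an EAV store at ``target``.

    ``target`` is a filesystem path or ``":memory:"``.  Re-opening an
    existing file store is idempotent: the schema statements are all
    ``IF NOT EXISTS`` and existing rows are untouched.
    """
    return EAVStore(target, on_duplicate=on_duplicate, datatypes=datatypes)
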