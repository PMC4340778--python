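"""Queries over the EAV store: ancestor paths, tuple retrieval, term search.

Query results come back as ``{entity path, attribute, value}`` tuples where
the path is composed from the ancestors' names and sibling positions
(``/ClinicalDocument[1]/recordTarget[7]/...``).  Paths are materialized
into a cache table at import time — the adjacency-list recursion runs once
per document, not per query — with an on-demand parent walk as fallback for
entities inserted outside the importer.

A small timing harness splits each query into the three phases a client
observes: *before* (obtaining the connection/cursor), *querying* (statement
execution) and *after* (traversing the result set), reporting first-run and
multi-run averages separately.
"""

from __future__ import annotations

import statistics
import time
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .core_model import (
    EAVStore,
    UnknownDocumentError,
    UnknownEntityError,
    ValidationError,
)

__all__ = [
    "EAVTuple",
    "FactRecord",
    "PhaseTimings",
    "QuerySpec",
    "BenchResult",
    "ancestor_path",
    "all_tuples",
    "fact_records",
    "find_documents",
    "tuples_for_documents",
    "timed_query",
    "bench",
    "format_bench_report",
]


class EAVTuple(NamedTuple):
    """One query result row."""

    entity_path: str
    attribute: str
    value: str


@dataclass(frozen=True)
class FactRecord:
    """Internal fat row used by the exporter and access-control filters."""

    value_id: str
    source_doc_id: int
    entity_id: int
    entity_path: str
    attribute: str
    lexical: str
    datatype: str
    is_metadata: bool

    def as_tuple(self) -> EAVTuple:
        return EAVTuple(self.entity_path, self.attribute, self.lexical)


@dataclass(frozen=True)
class PhaseTimings:
    before_ms: float
    query_ms: float
    after_ms: float
    n_rows: int


@dataclass(frozen=True)
class QuerySpec:
    """Names one of the two evaluation queries.

    ``kind`` is ``"all"`` (every tuple in the store) or ``"term"`` (all
    tuples of the documents containing ``term``).
    """

    kind: str = "all"
    term: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("all", "term"):
            raise ValidationError(f"unknown query kind {self.kind!r}")
        if self.kind == "term" and not self.term:
            raise ValidationError("term query needs a nonempty term")


# ---------------------------------------------------------------------------
# Paths

def ancestor_path(store: EAVStore, entity_id: int) -> str:
    """Compose ``/name[pos]/.../name[pos]`` from root to ``entity_id``.

    Prefers the materialized path cache; falls back to walking parent
    links for entities the importer did not load.
    """
    row = store.connection.execute(
        "SELECT path FROM entity_path WHERE entity_id = ?", (entity_id,)
    ).fetchone()
    if row is not None:
        return row[0]
    segments: list[str] = []
    node = store.get_entity(entity_id)  # raises UnknownEntityError
    while True:
        segments.append(f"{node.name}[{node.sibling_pos}]")
        if node.parent_id is None:
            break
        node = store.get_entity(node.parent_id)
    return "/" + "/".join(reversed(segments))


def _path_map(store: EAVStore) -> dict[int, tuple[int, str]]:
    return {
        eid: (doc, path)
        for eid, doc, path in store.connection.execute(
            "SELECT entity_id, source_doc_id, path FROM entity_path"
        )
    }


# ---------------------------------------------------------------------------
# Tuple queries

def fact_records(store: EAVStore,
                 doc_ids: Optional[Sequence[int]] = None) -> list[FactRecord]:
    """All live (non-superseded) facts, sorted by (doc, path, attribute).

    The fat variant of :func:`all_tuples`; one record per value row.
    """
    paths = _path_map(store)
    wanted = set(doc_ids) if doc_ids is not None else None
    records: list[FactRecord] = []
    for tag in store.datatypes:
        rows = store.connection.execute(
            f"SELECT v.value_id, v.source_doc_id, v.entity_id, a.name, "
            f"v.lexical, v.is_metadata FROM {tag}_value v "
            "JOIN attribute a ON a.attribute_id = v.attribute_id "
            "WHERE v.superseded = 0"
        )
        for value_id, doc, eid, aname, lexical, is_meta in rows:
            if wanted is not None and doc not in wanted:
                continue
            cached = paths.get(eid)
            path = cached[1] if cached else ancestor_path(store, eid)
            records.append(FactRecord(
                value_id=f"{tag}:{value_id}", source_doc_id=doc,
                entity_id=eid, entity_path=path, attribute=aname,
                lexical=lexical, datatype=tag, is_metadata=bool(is_meta),
            ))
    records.sort(key=lambda r: (r.source_doc_id, r.entity_path, r.attribute))
    return records


def all_tuples(store: EAVStore) -> list[EAVTuple]:
    """The general query: every entity-attribute-value tuple in the store."""
    return [r.as_tuple() for r in fact_records(store)]


def find_documents(store: EAVStore, term: str) -> list[int]:
    """Source-document ids whose stored facts contain ``term``.

    Case-insensitive substring match over fact lexicals, spanning header
    and body.  This is the subquery of the attribute-centric evaluation
    query.
    """
    if not term:
        raise ValidationError("search term must be nonempty")
    found: set[int] = set()
    low = term.lower()
    for tag in store.datatypes:
        rows = store.connection.execute(
            f"SELECT DISTINCT source_doc_id FROM {tag}_value "
            "WHERE superseded = 0 AND instr(lower(lexical), ?) > 0", (low,)
        )
        found.update(r[0] for r in rows)
    return sorted(found)


def tuples_for_documents(store: EAVStore,
                         doc_ids: Sequence[int]) -> list[EAVTuple]:
    """All tuples belonging to the given documents."""
    known = set(store.list_documents())
    for d in doc_ids:
        if d not in known:
            raise UnknownDocumentError(f"no source document {d}")
    return [r.as_tuple() for r in fact_records(store, doc_ids=doc_ids)]


def term_query(store: EAVStore, term: str) -> list[EAVTuple]:
    """The attribute-centric query: all tuples of term-matching documents."""
    return tuples_for_documents(store, find_documents(store, term))


# ---------------------------------------------------------------------------
# Timing harness

def _run_spec(store: EAVStore, spec: QuerySpec) -> list[EAVTuple]:
    if spec.kind == "all":
        return all_tuples(store)
    return term_query(store, spec.term)  # type: ignore[arg-type]


def timed_query(store: EAVStore,
                spec: QuerySpec) -> tuple[list[EAVTuple], PhaseTimings]:
    """Run a query with the three client-side phases timed separately.

    *Before* covers connection/cursor acquisition, *querying* the statement
    executions, *after* the traversal of the result set into tuples.  The
    result is identical to the untimed operation.
    """
    t0 = time.perf_counter()
    conn = store.connection
    conn.execute("SELECT 1").fetchone()  # touch the connection
    paths = _path_map(store)
    t1 = time.perf_counter()

    if spec.kind == "term":
        doc_ids = set(find_documents(store, spec.term))  # type: ignore[arg-type]
    else:
        doc_ids = None
    cursors = []
    for tag in store.datatypes:
        cur = store.connection.execute(
            f"SELECT v.value_id, v.source_doc_id, v.entity_id, a.name, "
            f"v.lexical FROM {tag}_value v "
            "JOIN attribute a ON a.attribute_id = v.attribute_id "
            "WHERE v.superseded = 0"
        )
        cursors.append(cur)
    t2 = time.perf_counter()

    rows: list[tuple[int, str, str, str]] = []
    for cur in cursors:
        for _vid, doc, eid, aname, lexical in cur:
            if doc_ids is not None and doc not in doc_ids:
                continue
            path = paths.get(eid)
            rows.append((doc, path[1] if path else ancestor_path(store, eid),
                         aname, lexical))
    rows.sort()
    result = [EAVTuple(p, a, v) for _d, p, a, v in rows]
    t3 = time.perf_counter()

    return result, PhaseTimings(
        before_ms=(t1 - t0) * 1e3,
        query_ms=(t2 - t1) * 1e3,
        after_ms=(t3 - t2) * 1e3,
        n_rows=len(result),
    )


@dataclass(frozen=True)
class BenchResult:
    spec: QuerySpec
    first: PhaseTimings
    average: PhaseTimings
    runs: tuple[PhaseTimings, ...]


def bench(store: EAVStore, spec: QuerySpec, repeat: int = 10) -> BenchResult:
    """Run a query ``repeat`` times, reporting first run and the average.

    The first run is reported separately because caching typically makes
    later runs faster; the average is over all ``repeat`` runs.
    """
    if repeat < 1:
        raise ValidationError("repeat must be >= 1")
    runs: list[PhaseTimings] = []
    for _ in range(repeat):
        _result, timing = timed_query(store, spec)
        runs.append(timing)
    avg = PhaseTimings(
        before_ms=statistics.mean(r.before_ms for r in runs),
        query_ms=statistics.mean(r.query_ms for r in runs),
        after_ms=statistics.mean(r.after_ms for r in runs),
        n_rows=runs[0].n_rows,
    )
    return BenchResult(spec=spec, first=runs[0], average=avg, runs=tuple(runs))


def format_bench_report(results: Sequence[BenchResult]) -> str:
    """Three-phase table: one row per query, first run vs average."""
    header = (
        f"{'Query':<24} {'Rows':>7} "
        f"{'Before(1st)':>12} {'Before(avg)':>12} "
        f"{'Query(1st)':>11} {'Query(avg)':>11} "
        f"{'After(1st)':>11} {'After(avg)':>11}"
    )
    lines = [header, "-" * len(header)]
    for res in results:
        label = res.spec.kind if res.spec.kind == "all" else \
            f"term {res.spec.term!r}"
        lines.append(
            f"{label:<24} {res.first.n_rows:>7} "
            f"{res.first.before_ms:>12.2f} {res.average.before_ms:>12.2f} "
            f"{res.first.query_ms:>11.2f} {res.average.query_ms:>11.2f} "
            f"{res.first.after_ms:>11.2f} {res.average.after_ms:>11.2f}"
        )
    return "\n".join(lines)
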