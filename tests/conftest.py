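"""Shared fixtures and the independent single-pass XML oracle.

The oracle re-derives, in one flat expat pass without building any tree,
everything the store is supposed to hold for a document: element / text /
attribute counts and the full set of (entity path, attribute, lexical)
facts with sibling positions.  It shares no code with the importer, so
agreement between the two is evidence, not tautology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from xml.parsers import expat

import pytest

from eavcare import open_store


@dataclass
class OracleResult:
    n_elements: int = 0
    n_text_nodes: int = 0
    n_attributes: int = 0
    facts: list[tuple[str, str, str]] = field(default_factory=list)
    entity_paths: list[str] = field(default_factory=list)

    @property
    def n_entities(self) -> int:
        return self.n_elements + self.n_text_nodes

    def fact_set(self) -> set[tuple[str, str, str]]:
        return set(self.facts)


def oracle_scan(raw: bytes) -> OracleResult:
    """Flat one-pass enumeration of entities and facts in document order.

    Whitespace-only text is skipped; sibling positions count the kept
    children (elements and non-whitespace text runs) of each parent,
    1-based, in document order.
    """
    res = OracleResult()
    # stack frames: [path, kept_child_count]
    stack: list[list] = [["", 0]]
    buf: list[str] = []

    def flush() -> None:
        if not buf:
            return
        text = "".join(buf)
        buf.clear()
        if text.strip():
            frame = stack[-1]
            frame[1] += 1
            path = f"{frame[0]}/#text[{frame[1]}]"
            res.n_text_nodes += 1
            res.entity_paths.append(path)
            res.facts.append((path, "#text", text))

    def start(name, attrs):
        flush()
        parent = stack[-1]
        parent[1] += 1
        path = f"{parent[0]}/{name}[{parent[1]}]"
        res.n_elements += 1
        res.entity_paths.append(path)
        for i in range(0, len(attrs), 2):
            res.n_attributes += 1
            res.facts.append((path, attrs[i], attrs[i + 1]))
        stack.append([path, 0])

    def end(name):
        flush()
        stack.pop()

    p = expat.ParserCreate()
    p.ordered_attributes = True
    p.StartElementHandler = start
    p.EndElementHandler = end
    p.CharacterDataHandler = lambda d: buf.append(d)
    p.Parse(raw, True)
    return res


def oracle_is_header(path: str) -> bool:
    """Header/body oracle: body iff component/structuredBody occurs in path."""
    names = [seg.rsplit("[", 1)[0] for seg in path.strip("/").split("/")]
    for i in range(len(names) - 1):
        if names[i] == "component" and names[i + 1] == "structuredBody":
            return False
    return True


@pytest.fixture
def store():
    with open_store() as s:
        yield s
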