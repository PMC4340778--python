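"""Path-pattern language shared by export rules and view fragments.

A pattern addresses facts by entity path and, optionally, by attribute:

    /ClinicalDocument[1]/component[*]/structuredBody[1]/**
    /a[1]/b[2]/@x          -- the XML attribute x of that element
    /a[1]/#text            -- the text fact of a #text pseudo-node's parent? no:
                              matches facts whose attribute is #text
    /*[1]/item             -- "*" matches any name; a bare name matches any position

Segment forms: ``name[pos]``, ``name[*]``, ``*[pos]``, ``*[*]``, bare
``name`` (any position).  A final ``**`` segment matches any remaining
suffix, including the empty one, so it selects the whole subtree rooted at
the prefix.  The optional final component ``@attr`` / ``@*`` / ``#text``
constrains the fact's attribute; without it any attribute matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .core_model import TEXT_NODE, ValidationError

__all__ = ["PathPattern", "parse_pattern", "split_path", "match_fact"]

_SEG_RE = re.compile(r"(?P<name>[^/\[\]@#]+|\*)(?:\[(?P<pos>\d+|\*)\])?\Z")
_PATH_SEG_RE = re.compile(r"(?P<name>.+)\[(?P<pos>\d+)\]\Z")


@dataclass(frozen=True)
class PathPattern:
    segments: tuple[tuple[str, Optional[int]], ...]  # (name|'*', pos|None)
    subtree: bool
    attr: Optional[str]  # attribute name, '*' (any XML attr), '#text', or None

    def __str__(self) -> str:
        parts = []
        for name, pos in self.segments:
            parts.append(name if pos is None else f"{name}[{pos}]")
        if self.subtree:
            parts.append("**")
        if self.attr == TEXT_NODE:
            parts.append(TEXT_NODE)
        elif self.attr is not None:
            parts.append(f"@{self.attr}")
        return "/" + "/".join(parts)


def parse_pattern(text: str) -> PathPattern:
    if not text.startswith("/"):
        raise ValidationError(f"pattern must start with '/': {text!r}")
    raw = text.strip("/").split("/")
    attr: Optional[str] = None
    if raw and (raw[-1].startswith("@") or raw[-1] == TEXT_NODE):
        last = raw.pop()
        attr = TEXT_NODE if last == TEXT_NODE else last[1:]
        if attr == "":
            raise ValidationError(f"empty attribute component in {text!r}")
    subtree = False
    if raw and raw[-1] == "**":
        raw.pop()
        subtree = True
    segments: list[tuple[str, Optional[int]]] = []
    for seg in raw:
        m = _SEG_RE.match(seg)
        if m is None:
            raise ValidationError(f"bad pattern segment {seg!r} in {text!r}")
        pos = m.group("pos")
        segments.append((m.group("name"),
                         None if pos in (None, "*") else int(pos)))
    if not segments and not subtree:
        raise ValidationError(f"empty pattern {text!r}")
    return PathPattern(tuple(segments), subtree, attr)


def split_path(path: str) -> list[tuple[str, int]]:
    """Split ``/name[pos]/...`` into (name, pos) pairs."""
    out = []
    for seg in path.strip("/").split("/"):
        m = _PATH_SEG_RE.match(seg)
        if m is None:
            raise ValidationError(f"bad path segment {seg!r} in {path!r}")
        out.append((m.group("name"), int(m.group("pos"))))
    return out


def _match_segments(pattern: PathPattern, segs: list[tuple[str, int]]) -> bool:
    want = pattern.segments
    if pattern.subtree:
        if len(segs) < len(want):
            return False
    elif len(segs) != len(want):
        return False
    for (pname, ppos), (name, pos) in zip(want, segs):
        if pname != "*" and pname != name:
            return False
        if ppos is not None and ppos != pos:
            return False
    return True


def match_fact(pattern: PathPattern, path: str,
               attribute: Optional[str] = None) -> bool:
    """Does a fact at ``path`` with ``attribute`` match the pattern?

    With ``attribute=None`` only the path is tested (any-attribute
    semantics).  ``#text`` facts sit on ``#text`` pseudo-entities; for
    convenience a pattern ending in ``#text`` matches both the pseudo-node
    path itself and its element parent's path.
    """
    segs = split_path(path)
    if pattern.attr is not None and attribute is not None:
        if pattern.attr == TEXT_NODE:
            if attribute != TEXT_NODE:
                return False
        elif pattern.attr == "*":
            if attribute == TEXT_NODE:
                return False
        elif pattern.attr != attribute:
            return False
    if _match_segments(pattern, segs):
        return True
    # a '#text'-slot pattern may name the element; the fact path has the
    # trailing /#text[pos] pseudo-segment
    if pattern.attr == TEXT_NODE and segs and segs[-1][0] == TEXT_NODE:
        return _match_segments(pattern, segs[:-1])
    return False
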