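"""Synthetic CDA-like nursing-report corpora with a ground-truth manifest.

No real transition reports are shipped, so tests and benchmarks run on
generated documents that mirror the shape of a German nursing transition
report (ePflegebericht): a header region with document, patient and author
metadata, and a body region (``component/structuredBody``) holding the five
main care sections, each structured by subsections nested up to four levels
deep.  Optional body fields are present independently with probability
``fill_rate`` — the sparsity the EAV store exists to handle — and search
terms can be planted into a chosen number of documents to exercise the
attribute-centric query (the 9-of-129 / 30-of-129 shape).

The generator is an oracle, not just a data source: while building each
document it records every (entity path, attribute, lexical) fact, the
element/text/attribute counts, the planted-term placements and a
section -> fact index, all derived from its own node tree without touching
the importer.  The emitted dialect is CDA-like, not schema-valid CDA.

Everything is deterministic in ``seed``: the same parameters produce
byte-identical corpora.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union
from xml.sax.saxutils import escape as _esc, quoteattr as _qattr

from .core_model import EAVStore, SourceDocMeta, ValidationError

__all__ = [
    "DEFAULT_SECTIONS",
    "GenParams",
    "ManifestFact",
    "DocManifest",
    "CorpusManifest",
    "generate_document",
    "generate_corpus",
    "meta_for",
    "import_corpus",
    "write_corpus",
]

#: The five main body sections of the nursing transition report.
DEFAULT_SECTIONS: tuple[str, ...] = (
    "NursingProcess",
    "SocialInformation",
    "HomeCareStatus",
    "LegalDocuments",
    "MedicalInformation",
)

_GIVEN = ("Anna", "Karl", "Ilse", "Jonas", "Marta", "Peter", "Frieda", "Omar")
_FAMILY = ("Schmidt", "Weber", "Fischer", "Koch", "Brandt", "Vogel")
_AUTHORS = ("Nurse Albrecht", "Nurse Becker", "Dr. Clausen", "Nurse Dreyer")

_BASE_RECEIVED = _dt.datetime(2013, 2, 4, 8, 0, 0)


@dataclass(frozen=True)
class GenParams:
    """Corpus generation parameters.

    Defaults reflect the target document family: five main sections,
    subsections to depth four, and a moderately sparse fill.  Corpus sizes
    of interest are 10, 100 and 129 documents (the evaluation scales).
    ``planted_terms`` lists (term, number of documents to contain it).
    """

    seed: int = 0
    n_docs: int = 10
    sections: tuple[str, ...] = DEFAULT_SECTIONS
    max_depth: int = 4
    fields_per_section: int = 8
    fill_rate: float = 0.7
    planted_terms: tuple[tuple[str, int], ...] = ()
    plant_in_header: bool = False

    def __post_init__(self):
        if self.n_docs < 0:
            raise ValidationError("n_docs must be >= 0")
        if self.max_depth < 1:
            raise ValidationError("max_depth must be >= 1")
        if not (0 < self.fill_rate <= 1):
            raise ValidationError("fill_rate must be in (0, 1]")
        for term, count in self.planted_terms:
            if not term:
                raise ValidationError("planted terms must be nonempty")
            if count > self.n_docs:
                raise ValidationError(
                    f"cannot plant {term!r} in {count} of {self.n_docs} docs"
                )


# ---------------------------------------------------------------------------
# Node scratch tree (generator-private, independent of the importer)

@dataclass
class _El:
    name: str
    attrs: list[tuple[str, str]] = field(default_factory=list)
    children: list[Union["_El", str]] = field(default_factory=list)  # str = text


@dataclass(frozen=True)
class ManifestFact:
    path: str
    attribute: str
    lexical: str
    is_header: bool


@dataclass
class DocManifest:
    """Ground truth for one generated document."""

    doc_index: int
    n_elements: int = 0
    n_text_nodes: int = 0
    n_attributes: int = 0
    facts: list[ManifestFact] = field(default_factory=list)
    planted: dict[str, list[str]] = field(default_factory=dict)
    section_facts: dict[str, list[int]] = field(default_factory=dict)

    @property
    def n_entities(self) -> int:
        return self.n_elements + self.n_text_nodes

    @property
    def n_facts(self) -> int:
        return len(self.facts)

    @property
    def body_fact_count(self) -> int:
        return sum(1 for f in self.facts if not f.is_header)

    def fact_triples(self) -> set[tuple[str, str, str]]:
        return {(f.path, f.attribute, f.lexical) for f in self.facts}


@dataclass
class CorpusManifest:
    """Merged ground truth across a generated corpus."""

    docs: list[DocManifest]
    term_docs: dict[str, list[int]] = field(default_factory=dict)

    @property
    def total_entities(self) -> int:
        return sum(d.n_entities for d in self.docs)

    @property
    def total_elements(self) -> int:
        return sum(d.n_elements for d in self.docs)

    @property
    def total_text_nodes(self) -> int:
        return sum(d.n_text_nodes for d in self.docs)

    @property
    def total_attributes(self) -> int:
        return sum(d.n_attributes for d in self.docs)

    @property
    def total_facts(self) -> int:
        return sum(d.n_facts for d in self.docs)

    def distinct_attribute_names(self) -> set[str]:
        return {f.attribute for d in self.docs for f in d.facts}


# ---------------------------------------------------------------------------
# Document construction

def _filler(rng: random.Random) -> str:
    kind = rng.randrange(4)
    if kind == 0:
        return f"v{rng.getrandbits(24):06x}"
    if kind == 1:
        return str(rng.randint(0, 99999))
    if kind == 2:
        return f"{rng.uniform(0, 200):.1f}"
    day = _dt.date(2012, 1, 1) + _dt.timedelta(days=rng.randrange(400))
    return day.isoformat()


def _header_children(rng: random.Random, doc_index: int) -> list[_El]:
    given = rng.choice(_GIVEN)
    family = rng.choice(_FAMILY)
    author = rng.choice(_AUTHORS)
    eff = _BASE_RECEIVED + _dt.timedelta(hours=6 * doc_index)
    return [
        _El("typeId", [("root", "2.16.840.1.113883.1.3"),
                       ("extension", "POCD_HD000040")]),
        _El("templateId", [("root", "1.2.276.0.76.10.1019")]),
        _El("id", [("root", "1.2.276.0.76.4.17"),
                   ("extension", f"doc-{doc_index:04d}")]),
        _El("code", [("code", "34133-9"),
                     ("codeSystem", "2.16.840.1.113883.6.1")]),
        _El("effectiveTime", [("value", eff.strftime("%Y%m%d%H%M"))]),
        _El("recordTarget", children=[
            _El("patientRole", children=[
                _El("id", [("root", "1.2.276.0.76.4.8"),
                           ("extension", f"pat-{doc_index:04d}")]),
                _El("patient", children=[
                    _El("name", children=[
                        _El("given", children=[given]),
                        _El("family", children=[family]),
                    ]),
                    _El("birthTime", [("value", (
                        _dt.date(1920, 1, 1) + _dt.timedelta(
                            days=rng.randrange(25000))
                    ).strftime("%Y%m%d"))]),
                ]),
            ]),
        ]),
        _El("author", children=[
            _El("time", [("value", eff.strftime("%Y%m%d%H%M"))]),
            _El("assignedAuthor", children=[
                _El("assignedPerson", children=[
                    _El("name", children=[author]),
                ]),
            ]),
        ]),
    ]


def _build_section(rng: random.Random, name: str, params: GenParams,
                   plants: list[str]) -> _El:
    """One main section: a subsection chain to max_depth, sparse fields.

    Containers (section and ``subsection`` elements) carry no attributes or
    text, so each *filled field* contributes exactly one fact (its text
    node); a planted term adds one dedicated ``text`` fact.
    """
    section = _El(name)
    chain = [section]
    for _depth in range(2, params.max_depth + 1):
        sub = _El("subsection")
        chain[-1].children.append(sub)
        chain.append(sub)
    for j in range(1, params.fields_per_section + 1):
        if rng.random() >= params.fill_rate:
            continue
        host = chain[(j - 1) % len(chain)]
        host.children.append(_El(f"field{j:02d}", children=[_filler(rng)]))
    for term in plants:
        section.children.append(
            _El("text", children=[f"observation includes {term}"])
        )
    return section


def _build_document(params: GenParams, doc_index: int,
                    terms: list[str]) -> _El:
    rng = random.Random(f"{params.seed}|doc|{doc_index}")
    root = _El("ClinicalDocument", [("xmlns", "urn:eavcare:cda-like")])
    root.children.extend(_header_children(rng, doc_index))
    header_terms = terms if params.plant_in_header else []
    body_terms = [] if params.plant_in_header else terms
    for term in header_terms:
        root.children.append(
            _El("note", children=[f"observation includes {term}"])
        )
    body = _El("structuredBody")
    # assign each planted term to one section
    per_section: dict[int, list[str]] = {}
    for term in body_terms:
        per_section.setdefault(rng.randrange(len(params.sections)), []).append(term)
    for i, sec_name in enumerate(params.sections):
        section = _build_section(rng, sec_name, params, per_section.get(i, []))
        body.children.append(_El("component", children=[section]))
    root.children.append(_El("component", children=[body]))
    return root


# ---------------------------------------------------------------------------
# Serialization (pretty where safe: text-bearing elements stay inline)

def _has_text(node: _El) -> bool:
    return any(isinstance(c, str) for c in node.children)


def _ser(node: _El, depth: int, out: list[str]) -> None:
    pad = "  " * depth
    attrs = "".join(f" {k}={_qattr(v)}" for k, v in node.attrs)
    if not node.children:
        out.append(f"{pad}<{node.name}{attrs}/>\n")
    elif _has_text(node):
        inner = "".join(
            _esc(c) if isinstance(c, str) else _inline(c)
            for c in node.children
        )
        out.append(f"{pad}<{node.name}{attrs}>{inner}</{node.name}>\n")
    else:
        out.append(f"{pad}<{node.name}{attrs}>\n")
        for child in node.children:
            _ser(child, depth + 1, out)  # type: ignore[arg-type]
        out.append(f"{pad}</{node.name}>\n")


def _inline(node: _El) -> str:
    attrs = "".join(f" {k}={_qattr(v)}" for k, v in node.attrs)
    if not node.children:
        return f"<{node.name}{attrs}/>"
    inner = "".join(
        _esc(c) if isinstance(c, str) else _inline(c) for c in node.children
    )
    return f"<{node.name}{attrs}>{inner}</{node.name}>"


def _serialize_doc(root: _El) -> bytes:
    out = ['<?xml version="1.0" encoding="UTF-8"?>\n']
    _ser(root, 0, out)
    return "".join(out).encode("utf-8")


# ---------------------------------------------------------------------------
# Manifest derivation (from the generator's own tree)

def _walk_manifest(node: _El, path_prefix: str, pos: int, in_body: bool,
                   section: Optional[str], params: GenParams,
                   man: DocManifest) -> None:
    path = f"{path_prefix}/{node.name}[{pos}]"
    man.n_elements += 1
    if node.name == "structuredBody":
        in_body = True
    if node.name in params.sections:
        section = node.name
    is_header = not in_body
    for aname, avalue in node.attrs:
        man.n_attributes += 1
        idx = len(man.facts)
        man.facts.append(ManifestFact(path, aname, avalue, is_header))
        if section is not None:
            man.section_facts.setdefault(section, []).append(idx)
    for cpos, child in enumerate(node.children, start=1):
        if isinstance(child, str):
            man.n_text_nodes += 1
            tpath = f"{path}/#text[{cpos}]"
            idx = len(man.facts)
            man.facts.append(ManifestFact(tpath, "#text", child, is_header))
            if section is not None:
                man.section_facts.setdefault(section, []).append(idx)
        else:
            _walk_manifest(child, path, cpos, in_body, section, params, man)


def _plant_plan(params: GenParams) -> dict[int, list[str]]:
    plan: dict[int, list[str]] = {}
    for term, count in params.planted_terms:
        rng = random.Random(f"{params.seed}|plant|{term}")
        for idx in sorted(rng.sample(range(params.n_docs), count)):
            plan.setdefault(idx, []).append(term)
    return plan


# ---------------------------------------------------------------------------
# Public API

def generate_document(params: GenParams,
                      doc_index: int) -> tuple[bytes, DocManifest]:
    """Generate one document and its ground-truth manifest."""
    if not (0 <= doc_index < params.n_docs):
        raise ValidationError(f"doc_index {doc_index} out of range")
    terms = _plant_plan(params).get(doc_index, [])
    root = _build_document(params, doc_index, terms)
    man = DocManifest(doc_index=doc_index)
    _walk_manifest(root, "", 1, False, None, params, man)
    for term in terms:
        man.planted[term] = [
            f.path for f in man.facts if term in f.lexical.lower()
        ]
    return _serialize_doc(root), man


def generate_corpus(params: GenParams) -> tuple[list[bytes], CorpusManifest]:
    """Generate the whole corpus; planted-term placements are exact.

    Verifies as it goes that no planted term leaks into a document it was
    not assigned to (term collisions would silently break the ground
    truth), raising :class:`ValidationError` on a collision.
    """
    plan = _plant_plan(params)
    docs: list[bytes] = []
    manifests: list[DocManifest] = []
    for i in range(params.n_docs):
        raw, man = generate_document(params, i)
        docs.append(raw)
        manifests.append(man)
    term_docs: dict[str, list[int]] = {}
    for term, _count in params.planted_terms:
        low = term.lower()
        hits = [m.doc_index for m in manifests
                if any(low in f.lexical.lower() for f in m.facts)]
        planted = sorted(i for i, terms in plan.items() if term in terms)
        if hits != planted:
            raise ValidationError(
                f"term {term!r} occurs accidentally outside its planted "
                f"documents (planted {planted}, found {hits}); "
                "choose more distinctive terms"
            )
        term_docs[term] = planted
    return docs, CorpusManifest(docs=manifests, term_docs=term_docs)


def meta_for(params: GenParams, doc_index: int) -> SourceDocMeta:
    """Deterministic provenance record for a generated document.

    Receipt times are spaced 6 hours apart from a fixed base, so a corpus
    spans several days and time-window views have something to cut.
    """
    rng = random.Random(f"{params.seed}|meta|{doc_index}")
    return SourceDocMeta(
        author=rng.choice(_AUTHORS),
        doc_type="ePflegebericht",
        template="1.2.276.0.76.10.1019",
        received_at=_BASE_RECEIVED + _dt.timedelta(hours=6 * doc_index),
    )


def import_corpus(store: EAVStore, params: GenParams):
    """Generate and import a corpus; returns (manifest, import reports)."""
    from .importer import import_document

    docs, manifest = generate_corpus(params)
    reports = [
        import_document(store, raw, meta_for(params, i))
        for i, raw in enumerate(docs)
    ]
    return manifest, reports


def write_corpus(params: GenParams, out_dir: str) -> list[str]:
    """Write corpus files plus a JSON manifest; returns the file names."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    docs, manifest = generate_corpus(params)
    names = []
    for i, raw in enumerate(docs):
        name = f"doc_{i:04d}.xml"
        (out / name).write_bytes(raw)
        names.append(name)
    payload = {
        "term_docs": manifest.term_docs,
        "docs": [
            {
                "doc_index": d.doc_index,
                "n_elements": d.n_elements,
                "n_text_nodes": d.n_text_nodes,
                "n_attributes": d.n_attributes,
                "facts": [[f.path, f.attribute, f.lexical, f.is_header]
                          for f in d.facts],
                "planted": d.planted,
            }
            for d in manifest.docs
        ],
    }
    (out / "manifest.json").write_text(json.dumps(payload, indent=1))
    return names
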