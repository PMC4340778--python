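# eavcare

An entity–attribute–value (EAV) storage engine for integrating
heterogeneous, hierarchical healthcare documents — the storage layer of a
digital patient care record for home healthcare, where information arrives
as standardized XML reports (HL7 CDA–style, e.g. the German
ePflegebericht nursing transition report) from many stakeholders and must
be stored *without designing a schema per report type and without losing a
byte of content*.

## Who this is for

Health-informatics engineers building document-integration backends, and
anyone who needs a generic, schema-evolution-proof store for sparse
hierarchical records with per-fact provenance, restorability and
sub-document access control.

## The model

Classical EAV stores facts as rows `(entity, attribute, value)` instead of
wide sparse tables. This package implements an *extended* EAV schema:

- **entity** — one row per XML element occurrence, with `parent` and
  `sibling_pos` columns so the document hierarchy and order live in the
  entity relation itself (adjacency list, positions `1..k` per parent).
  Text nodes become `#text` pseudo-entities so mixed content survives.
- **attribute** — a deduplicated dictionary of attribute names; there is
  deliberately *no* entity↔attribute link (it would re-store each shared
  name once per entity); the pairing exists only in the value rows.
- **`<type>_value`** — one table per datatype (`string`, `integer`,
  `real`, `boolean`, `date`, `timestamp`; an extensible subset of the ISO
  21090 primitives). Each row references its entity, attribute and source
  document, keeps the *verbatim lexical form* next to the typed value, and
  carries an `is_metadata` flag separating the document header (patient,
  author, document metadata) from the clinical body.
- **source_doc** — per-document provenance (author, type, template,
  receipt time, content digest) plus the raw bytes.

Because only *present* fields create rows, highly sparse records are
stored compactly: the row count follows the number of filled fields, not
the number of possible ones.

On top of the schema sit four engines:

- **importer** — extract (expat parse preserving qualified names and
  `xmlns` attributes), transform (shred to EAV protorecords, route each
  value by lexical datatype inference), load (atomic, with ancestor paths
  materialized per document).
- **query_engine** — tuples come back as `{entity path, attribute,
  value}` with paths like `/ClinicalDocument[1]/recordTarget[7]/…`
  composed from ancestors' names and sibling positions; a general
  all-tuples query; an attribute-centric term search (find the documents
  containing a term, return all their tuples); a three-phase timing
  harness (*Before / Querying / After*).
- **exporter** — `reconstruct_document` (lossless restorability) and the
  five-step export loop *preselect → select → transform (declarative path
  rules) → completeness check → generate*, iterating until the target
  report is complete.
- **access_control** — views define horizontal (time window, document
  type, header/body) and vertical (path patterns, attribute names)
  fragments; grants attach `{read, add, delete, update}` rights per role;
  enforcement is per fact, finer than whole documents.

A first-class **fixtures** module generates seeded CDA-like corpora (five
main nursing-report sections, subsections to depth 4, sparse optional
fields, planted search terms) together with a ground-truth manifest used
as the test oracle.

## Worked example

```python
import eavcare as ec
from eavcare.fixtures import GenParams, import_corpus

store = ec.open_store()                      # in-memory; or a file path
params = GenParams(seed=1, n_docs=5, planted_terms=(("hemoglobin", 2),))
manifest, reports = import_corpus(store, params)
print([(r.n_entities, r.n_values) for r in reports])
# [(91, 37), (109, 46), (103, 43), (97, 40), (117, 50)]

print(ec.all_tuples(store)[0])
# EAVTuple(entity_path='/ClinicalDocument[1]', attribute='xmlns',
#          value='urn:eavcare:cda-like')

print(ec.find_documents(store, "hemoglobin"))
# [2, 4]           <- exactly the two documents the term was planted in

raw = ec.reconstruct_document(store, 2)      # rebuilt purely from EAV rows
print(ec.canonical_equal(raw, store.get_raw(2)))
# True             <- lossless round-trip
```

The first line shows per-document entity and value row counts (a 91-entity
document produced 37 facts: one per XML attribute and one per text node —
nothing more, nothing less). The term search returns store document ids;
reconstruction equals the original under canonical comparison
(attribute-order- and whitespace-insensitive).

The same flows are available from the shell:

```sh
eavcare --store care.db gen --seed 1 --n 10 --plant hemoglobin:3 --out corpus/
eavcare --store care.db import corpus/doc_*.xml --author "Nurse A"
eavcare --store care.db query --term hemoglobin
eavcare --store care.db bench --query all --repeat 10
eavcare --store care.db restore --doc 1 --out restored.xml
```

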