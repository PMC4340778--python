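# Methods

This note records how the engine models documents, which choices were open
and how they were resolved, what the synthetic corpus does and does not
emulate, and the numerical/structural conventions tests rely on.

## Storage model

One imported XML report becomes:

- one **entity** row per element occurrence and per non-whitespace text
  node (`#text` pseudo-entity). Hierarchy is an adjacency list: `parent_id`
  plus `sibling_pos`. `sibling_pos` counts *all* kept children of a parent
  — elements and text pseudo-nodes together — 1-based in document order.
  (An alternative reading, counting only same-named siblings, was rejected:
  same-named indexing is derivable from the all-siblings numbering but not
  vice versa.)
- one **attribute** row per distinct attribute name in the whole store
  (shared dictionary; the reserved name `#text` covers text facts).
- one **value** row per XML attribute instance and per text node, in the
  value table chosen by datatype, holding the verbatim lexical, the parsed
  typed value, the source-document reference and the header/body flag.
  Elements with neither attributes nor text yield *no* value rows; such
  entities are tied to their document through the root chain — each
  document's provenance row records its root entity, and the materialized
  path cache (below) records per-entity document membership.

Duplicate imports are detected by content digest; the default policy
rejects them, `on_duplicate="version"` imports the same bytes again as a
new version.

### Datatypes

The registry ships `string`, `integer`, `real`, `boolean`, `date`,
`timestamp` — a representative subset of the ISO 21090 primitive types
with a registration hook for more (each new tag gets its own value
table). Lexical-to-type routing is per value, schema-free and total, with
fixed precedence *boolean → integer → real → date → timestamp → string*.
Consequences worth knowing: `"042"` types as integer 42 (the lexical is
kept, so nothing is lost), compact HL7 timestamps like `20130204` type as
integers, and only dashed ISO 8601 forms count as dates/timestamps —
including calendar validation, so `2013-13-99` is a string. Empty strings
are strings.

### Header vs body

A value row is flagged body when its entity path contains the configured
descendant chain `component/structuredBody` (CDA dialect default),
*including* the body-root element itself; everything else — and every fact
of a document with no body root — is header metadata. The chain is
configurable per import.

## Import

Parsing uses the stdlib expat event API with namespace processing off, so
element and attribute names keep their prefixed qualified form verbatim
and namespace declarations are stored as ordinary `xmlns`/`xmlns:p`
attribute facts — this is what makes byte-faithful reconstruction
possible. Comments and processing instructions are dropped, as are
whitespace-only text runs (pretty-printing must not create facts);
adjacent character-data events are coalesced into one text node. Loading
is transactional: a malformed document or rejected duplicate leaves no
partial state. Ancestor paths (`/name[pos]/…`) are materialized into a
cache table once per import — the recursive path composition runs at
write time, not per query.

## Queries

Results are `{entity path, attribute, value}` tuples in a stable
(document, path, attribute) order; the order is a package convention, and
path segments sort lexicographically (`[10]` before `[2]`), which is
deliberate — nothing downstream depends on numeric segment order. Term
search is a case-insensitive substring match over stored fact lexicals
(header and body); matching over raw bytes was rejected because it would
also hit tag names. The timing harness reports *Before* (connection and
path-cache acquisition), *Querying* (statement execution) and *After*
(result-set traversal) separately, first run versus the average of n runs,
because first runs are typically not cache-warmed. Absolute milliseconds
are hardware-bound and are never asserted — only the report structure is.

## Export

Reconstruction rebuilds the tree purely from rows (entities ordered by
`sibling_pos`, attributes name-sorted, lexicals verbatim) and must equal
the source under the canonical comparison: attribute-order-insensitive,
whitespace-only-text-insensitive, comments/PIs/XML-declaration excluded.
That comparison is the operational meaning of "lossless" here; attribute
order and cosmetic whitespace are declared out of scope.

Rule-based export uses a small path-pattern language: segments
`name[pos]`, with `*` for any name and `[*]` for any position, a trailing
`**` for whole subtrees, and a final `@attr` / `#text` component for the
fact's attribute. A rule maps matching facts through a named total value
transform (identity, case folds, date reformatters; extensible via
`register_transform`) to a concrete target slot. Two rules writing
different values to one slot raise a conflict naming both; equal values
coexist; selected facts matched by no rule are logged as notices. The
manual selection step of the export workflow is modeled as an injected
callback `selector(selection, missing) -> selection`, called once before
the first transform (with an empty missing list) and once after each
failed completeness check, so the loop is testable without a UI; an
iteration bound (default 10) guards termination, and hitting it raises an
error listing the still-missing paths.

## Access control

Views are horizontal (receipt-time window, document types, header/body
flag) and vertical (path patterns and/or attribute names, unioned)
fragments; grants give roles subsets of `{read, add, delete, update}` per
view, and a role's readable set is the union over its read-granted views.
Enforcement is predicate push-down in the query layer, not DBMS view
objects, so the same contract holds on any backend and applies per fact —
one value of a document can be hidden while its siblings show. Updates
never overwrite: the old row is flagged superseded (dropping out of live
queries and reconstruction) and a new row is inserted. Deleting removes
the row and therefore degrades reconstruction of that document — that is
the granted right doing what it says.

## Synthetic corpus

The generator emulates the target document family structurally: a CDA-like
header (typeId/templateId/id/code/effectiveTime, patient record target,
author) and a `component/structuredBody` body with the five main
nursing-report sections (*NursingProcess, SocialInformation,
HomeCareStatus, LegalDocuments, MedicalInformation*), subsection chains to
depth 4 (default), and `fields_per_section` optional leaf fields each
present with probability `fill_rate` (default 8 fields at 0.7 — a
moderately sparse report; evaluation corpus sizes of interest are 10, 100
and 129 documents). Section and subsection containers carry no attributes
or text, so every filled field contributes exactly one value row — this
makes the sparse-storage row count a clean binomial and gives the closed
form `5·f` body facts at full fill. Planted search terms add one dedicated
text fact in a random section (or in a header note with
`plant_in_header`); generation fails loudly if a planted term collides
with any other document's content, so the manifest's term→document map is
exact by construction. Receipt times are spaced 6 hours from a fixed base
date so time-window views have days to cut.

The manifest (counts, every `(path, attribute, lexical)` fact, term
placements, per-section fact index) is derived from the generator's own
node tree, independent of the importer; tests additionally check it
against a flat single-pass expat oracle.

What the corpus does *not* emulate: schema-valid CDA, realistic clinical
vocabulary or terminology codes (ICNP/NANDA-I), scanned narrative text,
character-encoding variety, or malformed real-world exports. Passing
tests therefore demonstrate the storage contract (losslessness,
conservation, query equivalence, fragments) on structurally faithful
documents, not robustness to arbitrary real-world CDA instances.

## Problem sizes and determinism

The shipped checks use the corpus scales above (100 / 129 / 50 / 20
documents), which exercise every code path at tens of thousands of rows
and run in seconds. All randomness flows from explicit seeds; the same
seed reproduces corpora byte-for-byte (string seeds feed Python's
deterministic SHA-512 seeding). Property-based tests run derandomized.

## Known limitations

- DTD internal subsets, CDATA boundaries and character references are
  normalized by parsing (text content is preserved, their syntax is not);
  comments and processing instructions are dropped by design.
- Composite ISO 21090 types (intervals, coded values with qualifiers) are
  not modeled; register custom tags or store lexically as strings.
- The attribute-centric query is a substring search; no inverted index is
  built, so it scans the value tables (fine at patient-record scale).
- Access control covers authorization structure only — no authentication,
  encryption or audit logging.
- Import is XML-only; relational/spreadsheet sources are extension points,
  not features.
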