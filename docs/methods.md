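# Methods

## The standard being implemented

The package models annotation metadata for volumetric connectomics as a
versioned, typed schema. A *schema* is a set of classes — broad anatomical
definitions such as `neuron`, `soma`, `synapse` — each carrying typed
properties and exactly one of eight category tags (neuron type; soma;
cellular compartments and organelles; axon-/dendrite-/soma-specific
properties; synapse; gap junction; organelle-specific classes; organelles
commonly associated with synapses). An *annotation document* is a bundle of
objects, each claiming a class, a property map, and optionally a spatial
anchor (`BoundSpatialPoint`) binding it to a segmentation segment.

Two structural rules do most of the work:

- **Single-home.** A property name belongs to exactly one class schema-wide.
  The canonical case: `spine_id` is a spine-*associated* optional property of
  `synapse`, and must not also appear on `spine`. The loader rejects any
  schema violating this; the validator reports `WRONG_HOME`, naming the true
  home, when a document puts a property on the wrong class.
- **Type/value separation.** Counts and categorical designations are kept
  apart from free-text descriptions: `neuron` carries `interneurons`
  (an enumeration with stable named codes) *and* `interneuron_type`
  (a string), so two annotators recording different facets of the same
  entity never collide.

Enumerations are extensible: built-in values are bare and carry frozen
numeric codes assigned in declaration order from 0 (new values append, codes
never reassign); user extensions must be namespaced `x-` and validate as
warnings, keeping the codified core machine-stable while allowing the
standard to grow.

## Canonical vocabulary and the crosswalk

`soma` is the canonical class name for the cell body (the category diagram
uses that name); "cell body" is a schema synonym. Study-specific terms
("Passant boutons", "Layer", "Putative interneurons", "Cleft") live in the
crosswalk table rather than as schema synonyms, so the provenance of each
mapping (which study used which term) is preserved and the matching order is
meaningful: exact class name, then schema synonym, then crosswalk — all
case-insensitive, whitespace-collapsing, folding `_`/`-` to spaces and a
trailing plural "s" (so "Interneurons" → `interneuron`, "Clefts" →
`synaptic_cleft`). Multi-term cells split on commas and a leading "and"
("Cortex, Striatum, Thalamus, and Zona Incerta" yields four region terms).

Misspelling handling is deliberately conservative: suggestions are ranked by
exact Levenshtein distance (edlib's global alignment; default cut-off 2,
ascending by distance then lexicographic, exact matches excluded) and are
never auto-applied — normalization rewrites only exact/synonym/crosswalk
matches.

The `region_of_interest` class does not map cleanly onto any of the eight
closed categories, which describe cellular-scale entities. It is tagged
`cellular_compartment_organelle` as the least-strained fit (a region is a
tissue-scale compartment); this is a recorded judgement call, not a claim of
the standard.

The validator reports non-canonical-but-resolvable class terms as
`UNKNOWN_CLASS` at *warning* severity with the canonical name in the
message. The code set is closed by design, and "the class term is not the
canonical spelling" is the nearest member; error severity is reserved for
terms that resolve to nothing.

## Versioning semantics

Backward compatibility is defined operationally: every document valid under
the old schema must stay valid under the new one. The verdict derives only
from the structural diff:

- never blocking — added classes, added *optional* properties, appended enum
  values;
- always blocking — removed classes or properties, property type changes
  (type is part of the contract, e.g. `interneuron_type` switching from
  string to enumeration), removed enum values, optional→required
  tightening, and *newly added required properties* on existing classes
  (old documents cannot carry them; they are reported under
  `required_tightened`). A required property on a brand-new class does not
  block — no old document instantiates that class.

A class rename is remove+add (breaking) unless the new class lists the old
name as a synonym, in which case the existing synonym machinery carries old
documents across and the rename is compatible. Migration across a
compatible diff rewrites only the document's `schema_version`; migration
across an incompatible diff is refused rather than made lossy.

Document-vs-schema version mismatch is an *error*, not a warning: validating
a v1.0.0 document against a v1.1.0 schema is the versioning module's job
(migrate, then validate), and bundles must declare one consistent schema
version throughout.

## Query semantics

Queries are conjunctions of four predicate kinds (`class=X`, `has=P`,
`P=V`, `P in A,B`). There is no OR/NOT — disjunction over values is
expressed by `in`. List values tokenize on any run of commas, vertical bars
and whitespace, making the engine invariant to the separator styles observed
in hand-entered lists. Object class terms and the query's own `class=` token
are normalized before comparison, so legacy documents participate without
rewriting. Enumeration values compare by name or numeric code; booleans by
`true/false/1/0`. Unknown property names in a query raise an error carrying
nearest-term suggestions instead of silently matching nothing.

## Synthetic fixtures: what they emulate, and what they do not

The fixture generator fabricates annotation documents with objects sampled
*uniformly* across the twelve classes, property presence at 0.7 for optional
fields, anchors at 0.8, within a default 2048×2048×1024-voxel extent. Real
volumes are heavily synapse-dominated and properties are far from
independent; uniform sampling is chosen to maximize per-class test coverage,
not realism (a class-frequency override exists at call level via the schema
argument). Passing tests therefore demonstrate the *logic* of validation,
normalization, versioning and querying — not calibrated performance on any
real dataset's label distribution.

The defect injector mirrors the error classes observed in hand-entered
metadata, each mapped to the detector that must fire on 100 % of injected
instances:

| mode              | what it does                                   | detector |
|-------------------|------------------------------------------------|----------|
| `synonym_swap`    | class term → printed synonym/crosswalk variant | normalization change log |
| `misspell`        | one character edit (distance exactly 1, never landing on another valid term) | `UNKNOWN_CLASS` + suggestion recovery at distance ≤ 2 |
| `separator_noise` | separators injected into the class term        | `UNKNOWN_CLASS`; tokenizer recovers the tokens |
| `wrong_home`      | foreign property added to an object            | `WRONG_HOME` |
| `bad_enum`        | bare out-of-vocabulary enum value              | `ENUM_VIOLATION` |
| `version_skew`    | document's schema_version bumped               | `VERSION_MISMATCH` |
| `missing_required`| required property deleted                      | `MISSING_REQUIRED` |

All generators are pure functions of (inputs, seed) — `random.Random(seed)`
streams, no global state — and the seed is recorded in each document's
extensions block, so every fixture is self-describing and replayable.
Defect rates are interpreted per eligible object per mode; an object already
corrupted by an earlier mode is skipped by later ones so each truth-log
entry has an unambiguous cause.

## Numerical and formatting choices

- Serialization is deterministic everywhere: JSON with sorted keys inside
  objects and declaration order for lists, two-space indent, trailing
  newline; `load ∘ serialize` is the identity and double serialization is
  byte-identical.
- Coordinates are 0-based voxel indices in (x, y, z) order; extent checks
  are half-open (`0 ≤ c < extent`). `segment_id` 0 means unbound/background.
- Integer-typed properties accept exactly-integral floats (3.0) — a common
  JSON serialization artifact — but never booleans.
- Versions are strict `MAJOR.MINOR.PATCH` semver; the standard's "v1.1" is
  represented as "1.1.0".
- Hierarchy record names are restricted to `[a-z0-9_-]` so slash-paths stay
  URL-safe; `grant_number` and `publications` are recommended (warnings),
  title and description required (errors).

## Problem sizes

The test suite and the acceptance script use: 200 clean documents
(2,000 objects) for generator/validator coherence; 500 seeded schema
mutations (each compatible verdict confirmed by re-validating 40 clean
objects under the mutated schema); 50 random queries over a 1,000-object
collection checked against an independent full-scan oracle; and the full
printed crosswalk (8 rows × 7 studies). These sizes exercise every code
path and every defect mode while keeping the whole cycle in the
seconds range.

## Known limitations

- The built-in schema carries the properties the standard's own examples
  mandate plus one or two implementation-extension properties per class
  (marked as such in their descriptions); it is not a complete inventory of
  community-annotated entities, and glia/blood-vessel classes are deferred.
- Anchors are validated against declared extents only, never against actual
  segmentation volumes.
- The crosswalk is a flat term→class function; qualified terms ("Putative
  synapses") lose their qualifier on normalization (a change-log entry
  records the rewrite).
- Query scope is annotation objects only; hierarchy metadata is reachable as
  the ordinary `dataset_path` string, not through dedicated predicates.
- No three-way schema merges and no storage-layer versioning: the
  compatibility checker covers linear, checkpoint-style evolution.
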