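# bma — annotation-metadata tools for nanoscale connectomics

High-resolution electron-microscopy (EM) and X-ray-microtomography (XRM)
volumes are annotated by many labs, and each lab writes its labels
differently: one dataset's "cell body" is another's "soma", "passant
boutons" and "boutons" name the same structure, hand-entered lists mix
commas, bars and spaces, and the same entity (a spine ID) gets duplicated
across classes. Those discrepancies break cross-dataset queries and
comparative analyses.

`bma` is a reference implementation of the BENCHMARK annotation-metadata
standard v1.1 for EM/XRM connectomics. It provides, fully offline:

- **a typed, versioned annotation schema** — twelve core classes (neuron,
  interneuron, soma, axon, dendrite, spine, bouton, synapse, gap_junction,
  synaptic_cleft, spine_apparatus, region_of_interest), each tagged with one
  of eight anatomical categories, with typed properties (integer, float,
  string, Boolean, extensible enumeration, spatial point, identifier). The
  **single-home rule** guarantees each property has exactly one home class:
  `spine_id` lives on `synapse` as a spine-*associated* property, never on
  `spine` too.
- **a validator** emitting machine-readable issue reports with a closed code
  set (`UNKNOWN_CLASS`, `WRONG_HOME`, `TYPE_MISMATCH`, `ENUM_VIOLATION`,
  `MISSING_REQUIRED`, `VERSION_MISMATCH`, `DUPLICATE_ID`, `BAD_ANCHOR`,
  `UNKNOWN_PROPERTY`), including spatial-anchor checks: a
  `BoundSpatialPoint` binds a voxel coordinate (x, y, z) to a segmentation
  segment id.
- **a controlled-vocabulary normalizer** driven by a study-term crosswalk
  (one row per canonical class, one column per published study) with
  Levenshtein-distance suggestions for misspelled terms — flagged, never
  silently corrected.
- **a schema-versioning engine**: structural diffs, a backward-compatibility
  verdict (additions never block; removals, type changes and requiredness
  tightening always do), and document migration across compatible versions.
- **a separator-tolerant query engine**: `class=synapse & has=spine_id`,
  with `P in A,B|C` lists parsed identically under any comma/bar/space mix.
- **the four-level dataset hierarchy** (project → collection → experiment →
  channel) with required title/description metadata per record.
- **seeded fixtures**: clean documents, the printed study crosswalk, and a
  defect injector reproducing the observed hand-entry error classes
  (misspelling, synonym drift, separator noise, wrong-home properties, bad
  enum values, version skew, dropped required fields) with a replayable
  truth log.

## Worked example

```python
from bma import (builtin_schema_v1_1, load_crosswalk, normalize_term,
                 validate_document, AnnotationDocument, AnnotationObject,
                 BoundSpatialPoint)
from bma.fixtures import table1_fixture

schema = builtin_schema_v1_1()
crosswalk = load_crosswalk(table1_fixture(), schema)

doc = AnnotationDocument(
    schema_version="1.1.0",
    objects=[
        AnnotationObject("syn-001", "synapse",
                         {"spine_id": "sp-42", "confidence": "high"},
                         anchor=BoundSpatialPoint((512.0, 301.0, 64.0),
                                                  segment_id=86751)),
        AnnotationObject("cb-001", "Cell body", {"soma_volume_um3": 1450.2}),
        AnnotationObject("sp-042", "spine", {"spine_id": "sp-42"}),
    ],
)
report = validate_document(schema, doc)
print("ok:", report.ok)
for issue in report.issues:
    print(f"{issue.severity.value:8s} {issue.code.value:14s} "
          f"{issue.path}: {issue.message}")
```

prints

```
ok: False
warning  UNKNOWN_CLASS  cb-001: class term 'Cell body' is not canonical; use 'soma' (normalize_document rewrites it)
error    WRONG_HOME     sp-042.spine_id: property 'spine_id' is housed under class 'synapse', not 'spine' (single-home rule)
```

The first object is fully valid. The second uses the legacy display term
"Cell body": it still validates (warning only) because `soma` declares it as
a synonym, and `normalize_document` will rewrite it. The third places
`spine_id` on a `spine` object — an error, because the standard homes that
identifier on `synapse` alone.

Vocabulary normalization and misspelling recovery:

```python
normalize_term(schema, crosswalk, "Passant boutons")
# -> canonical_class='bouton', matched_via='crosswalk'
normalize_term(schema, crosswalk, "snyapse").suggestions
# -> (('synapse', 2),)     # edit distance 2; suggested, never auto-applied
```

The same operations are available from the shell:

```bash
bma schema show --builtin           # canonical v1.1 schema as JSON
bma validate --format json DOC...   # nonzero exit iff any error
bma normalize DOC                   # rewrite legacy terms, log to stderr
bma suggest snyapse                 # 2<TAB>synapse
bma query "class=synapse & has=spine_id" DOC...
bma schema compat OLD.json NEW.json # exit 0 iff backward compatible
bma generate -n 200 --seed 7 --out fixtures/
```

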