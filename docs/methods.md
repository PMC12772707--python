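# Methods

This note documents the modeling and engineering choices behind the
package: how the standard's text was turned into a machine-readable
registry, what the validator's rules mean, how fixtures are generated, and
what the numeric tolerances are. It states no result the tests or
`scripts/acceptance.py` do not themselves compute.

## The schema registry

The standard defines 18 metadata classes. For several of them the text
prints the class's *field count* and a prose description but not the field
names themselves. The bundled definition
(`src/benchmark_metadata/data/schema_v1_1.json`) therefore distinguishes two
kinds of content:

* **Printed verbatim** — field names, types, required flags and enumeration
  member lists that appear in the standard's field table (Contributor,
  License, Funding, the Project rows, Taxonomy, CoordinateFrame,
  Publication, Link), reproduced in PascalCase exactly as printed, in table
  order.
* **Frozen here** — named field lists for classes where only the count and
  description are given (Collection 18, Experiment 20, Channel 19,
  BrainLocation 4, DataLocation 5, LightMicroscopySpecific 28,
  ElectronMicroscopySpecific 14, ImageOrientation, Landmark). The names
  follow the prose (e.g. the Experiment's protocol identifier, single
  coordinate frame and channel list) and, for the light-microscopy class,
  the 3D-microscopy standard's vocabulary it is imported from. A validatable
  standard needs the names fixed *somewhere*; this registry is that place,
  and each such class's description says so.

Three printed counts exceed the printed rows; the registry resolves them the
way the surrounding prose implies: Project's 36th field is `Identifiers`
(the superset that the collection subset rule presupposes), Contributor's
11th is `Role`, Publication's 8th is `PMCID`, and License's 4 fields are
`Rights`, `RightsURI`, `RightsIdentifier`, `RightsIdentifierDOI`. The table
types `Taxonomy.GenBankCommonName` as Integer; it is stored as String (it is
a name). `GRID` is accepted on read as an alias of the printed `GRDI` enum
member.

Open-ended enumerations (Species, DataType, GeneralModality,
ImagingModalityGeneral, ImagingModalitySpecific, VoxelUnit) ship with
documented provisional member lists — Species is seeded with the organisms
the standard's motivating datasets cover (C. elegans, Mus musculus,
Drosophila, Homo sapiens) — and can be extended through a JSON config
(`load_registry(config)`); the DataCite-derived vocabularies
(ContributorType, NameType, identifier schemes, relation types) are closed.
`DataType` is modeled as the channel volume's numeric storage type
(`uint8 … float64`), which is what the container cross-check compares
against; `ChannelType` carries the raw/segmentation/annotation distinction.

## Entities, coercion, canonical JSON

Entities are generic records driven by the registry rather than one static
class per type. Building coerces only losslessly: numeric strings to
Int/Float, Int to Float, calendar dates and bare years to ISO-8601 text;
everything else is a typed error naming the field. Unknown field names are
quarantined in an `extras` map — never dropped — and surface as
`UNKNOWN_FIELD` warnings; they also survive serialization.

A bundle document holds entity tables keyed by ID for the five hierarchy
classes (Project, Collection, Experiment, Channel, CoordinateFrame);
supporting records (contributors, licenses, ...) are inline. Children may be
written inline inside their parent instead of by ID reference; reading
hoists them into the tables (a coordinate frame written inline without an
`ID` gets `<owner>-frame`), so both spellings parse to the same bundle, and
an inline duplicate that conflicts with an existing ID is a parse error.
Canonical serialization is UTF-8 JSON with sections in a fixed order, table
keys sorted, entity keys in registry declaration order, and Python's
shortest round-trip float representation; writing a canonical document is a
byte-level fixpoint, which the round-trip suite checks across seeds.

## Validation rules and severities

All findings are report entries; validation never raises on content.
Severity follows the standard's own emphasis: missing required fields,
cardinality ("must be at least one"), subset, coordinate-frame, degenerate
extent, type/enum and dangling-reference violations are errors; quarantined
unknown fields, identifier-syntax failures and the recommended-but-not-
required practices are warnings. Reports are sorted by (entity path, rule
code, message), so identical bundles produce byte-identical reports.

Details worth noting:

* **Subset equality** is identifier-first (ORCID/`RightsIdentifier`), with
  a fallback to Unicode-NFC case-folded names. A parent's creator superset
  is its `Creator` plus `Contributor`/`PointOfContact` roster; a child's
  claimed creators are its `Creator` list. The empty set passes trivially.
* **Coordinate frames** are compared by ID: every channel must reference
  its experiment's frame. Frame geometry (each axis `[min, max]` with
  min < max, positive voxel sizes) is checked wherever the frame is
  validated (`EXTENT_DEGENERATE`).
* **Frame sharing** is recommended, not required, and the standard does not
  define the consistency test. The one precise, deterministic reading
  implemented: if two experiments in a project reference *distinct* frame
  IDs whose extents and voxel sizes are structurally identical, a
  `FRAME_NOT_SHARED` warning fires (duplicate frames that could have been
  one). BrainLocation consistency with an established reference frame is
  not checkable offline and is not attempted.
* **Identifier syntax** is offline-only: ORCID/ISNI use the ISO 7064
  mod 11-2 check character, DOI matches `10.<registrant>/<suffix>`, ROR is
  `0` plus eight Crockford base-32 characters, RRID requires its prefix,
  ISBN-10/13 checksums are verified; no network resolution ever happens.

## Container compliance

Compliance is metadata-only: the standard governs format choice and declared
geometry, not pixel values, so chunk payloads are never decoded. Presence of
at least one non-metadata object is probed as a warning-level completeness
check (`CHUNKS_MISSING`). Detection is sentinel-based and exclusive —
`.zattrs` with `multiscales` (OME-Zarr v2, multiscales metadata v0.4
assumed, since the standard pins only "Zarr specification v2"), `info` with
`scales` (Neuroglancer precomputed), `attributes.json` with an `n5` key —
with ambiguous stores reported as such and Zarr v3 stores (`zarr.json`)
rejected with a versioned message, matching the standard's intent to adopt
v3 later. A cloud-volume store is the precomputed layout plus its
`provenance` file; it is reported as precomputed with a provenance note
rather than a fifth parser. N5 has no single multiscale convention; the
n5-viewer-style root attributes (`resolution`, `units`, `scales`) with
per-scale `s<i>/attributes.json` datasets are adopted and documented here.

Cross-check tolerances: declared voxel resolution must match the channel's
`VoxelSize` within a relative 1e-6 after unit conversion to nanometers
(precomputed resolutions are nanometers by definition); the frame extent in
voxels, `(max − min) / resolution` per axis, must match the scale-0 extent
within half a voxel. Both thresholds separate exact agreement from genuine
mismatch without penalizing float round-trips.

## Fixture generation

All randomness flows from the recipe seed through a single `random.Random`;
text comes from a fixed word list and dates from the seeded year, so equal
recipes give byte-identical bundles on any platform. Defaults are the
smallest structurally complete hierarchy (1 collection / 1 experiment /
1 channel); every one of the 18 classes is instantiated even then, voxel
sizes are typical EM values (4×4×40 nm, 8 nm isotropic), extents are
16–128 voxels per axis, and identifiers are generated *valid* (real ISO 7064
check characters) so clean fixtures carry zero warnings as well as zero
errors. The generator aims for structural realism only — field-value
distributions of real archives are out of scope, so passing tests certify
rule coverage, not that real-world documents are statistically represented.

The mutation catalog covers every error-severity rule with one targeted,
single-site defect (the generator shares contributor objects across the
hierarchy, so mutators copy before editing); warning-severity rules are
exercised by dedicated handcrafted fixtures in the tests. Container fixtures
are capped at 128 voxels per axis and written with one zero-filled chunk;
corruption kinds (wrong dtype, wrong resolution, truncated extent, deleted
sentinel, malformed metadata, dropped chunks) each map to exactly one
expected rule or error code per format.

## Catalog

Only bundles with zero validation errors are indexable. Facets are species,
imaging modality, year, contributor name, brain-region name and the public
flag, all case-folded; filtering is conjunctive with results ordered by
project ID. The standard's prose also motivates specimen age and sex
queries, but no printed class carries such fields, so they are not facets —
a gap in the standard, not in the index. Correctness is defined by oracle
equivalence: every query must return exactly what a brute-force scan over
the same bundles returns, and the suite checks this across filters and
seeds.

## Problem sizes

The conformance suite and `scripts/acceptance.py` use 50 seeds for
valid-fixture cleanliness, 100 seeds for round-trip fixpoints, the full
10-mutation catalog, all 4 container formats × 6 corruptions, and 12-bundle
catalogs with 8 filter combinations — comfortably exhaustive for a schema
standard, where conformance is discrete rather than statistical, and small
enough that the whole suite runs in seconds.

## Known limitations

* Field names frozen here for count-only classes are faithful to the prose
  but not bit-compatible with any other implementation's choices until the
  community publishes the authoritative list.
* Identifier checks are syntactic; a well-formed ORCID that belongs to
  nobody passes.
* The catalog is in-memory and rebuilt per process; no persistence or HTTP
  layer is provided.
* OME-Zarr validation targets multiscales v0.4 on Zarr spec v2; v3 stores
  are rejected rather than parsed.
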