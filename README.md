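# benchmark-metadata

Schema registry, validator and tooling for the **BENCHMARK v1.1 EM/XRM
connectomics Image and Experimental Metadata Standard** — the community
metadata model for petascale electron-microscopy and X-ray-tomography
connectomics datasets.

## Who this is for

Teams publishing EM/XRM volumes (and the archives ingesting them) need their
experimental metadata to be *checkable*: a dataset description is a tree of
typed records — `Project → Collection → Experiment → Channel` plus
coordinate frames, contributors, licenses, funding, publications and
taxonomy — with structural rules that plain JSON cannot enforce by itself.
This package is a reference implementation of that model: it loads the
standard's 18 classes and all enumerations as a self-describing registry,
validates documents against every rule, serializes them canonically, checks
the four sanctioned volumetric container formats, and generates
deterministic test fixtures so the whole standard is exercisable offline.

## The model in brief

* A **Project** (36 fields) describes a dataset: title, species, taxonomy,
  contributors, licenses, funding, publications, modalities. It must
  reference ≥ 1 Collection, Experiment and Channel, and carry ≥ 1 creator
  and point of contact.
* A **Collection** (18 fields) groups experiments; an **Experiment**
  (20 fields) is a set of channels sharing exactly one **CoordinateFrame**
  (per-axis `[min, max]` extents + `VoxelSize`); a **Channel** (19 fields)
  is one 3-D volume with exactly one data type and its experiment's frame.
* **Subset rule**: a child's creators, licenses and identifiers must be a
  subset of its parent's (channel ⊆ experiment ⊆ collection ⊆ project).
* Contributor/license/publication records follow DataCite-style vocabulary,
  with syntax checking for ORCID and ISNI (ISO 7064 mod 11-2 check
  character), DOI, ROR, RRID, PMID, arXiv, ISBN and GRID identifiers.
* Image volumes must be stored as **OME-Zarr (Zarr spec v2)**,
  **Neuroglancer precomputed**, **cloud-volume** (precomputed layout) or
  **N5**; compliance checking reads only the container metadata files and
  cross-checks dtype, voxel resolution and frame extent
  (`(max − min) / resolution` per axis) against the channel's declaration.

Validation never raises on bad metadata: every finding is a report entry
with a stable rule code (`REQ_MISSING`, `ENUM_INVALID`, `CARDINALITY`,
`SUBSET_LICENSE`, `COORD_MISMATCH`, `REF_DANGLING`, ...), an entity path and
a severity, so untrusted documents can be checked end to end.

## Worked example

```python
from benchmark_metadata import (
    FixtureRecipe, generate_bundle, load_registry, mutate_bundle, validate_bundle,
)

registry = load_registry()
bundle = generate_bundle(registry, FixtureRecipe(seed=7, n_collections=2,
                                                 n_experiments_per_collection=2,
                                                 n_channels_per_experiment=2))
print(validate_bundle(registry, bundle).counts)

mutant, path = mutate_bundle(bundle, "SUBSET_LICENSE")
for v in validate_bundle(registry, mutant).errors:
    print(v.rule_code, "@", v.entity_path)
```

prints

```
{'error': 0, 'warning': 0}
SUBSET_LICENSE @ project/proj00007/collection/proj00007-col0
```

— the generated bundle (1 project, 2 collections, 4 experiments with their
own coordinate frames, 8 channels, 19 entities in all) is fully compliant,
and injecting a license on one collection that the project does not carry
yields exactly one subset-rule error at that collection's path. The
`examples/` directory holds one narrative script per capability (schema
introspection, validation and mutation, volume inspection, catalog queries).

## Command line

```sh
benchmark describe Taxonomy            # fields, types, required flags
benchmark enums ContributorType        # enumeration members
benchmark generate --seed 3 -o b.json  # deterministic fixture bundle
benchmark validate b.json              # exit 0 iff zero errors
benchmark convert b.json               # canonical serialization
benchmark generate-volume --format ome-zarr -o vol/
benchmark inspect-volume vol/ --channel b.json#<channel-id>
benchmark query b1.json b2.json --species Drosophila --modality EM
```

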