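"""Deterministic fixture generation: valid bundles, known-bad mutants, and
tiny on-disk container stores.

The generator and the validator are mutual oracles: every bundle generated
from a recipe validates with zero errors (and zero warnings), and every
mutation in the catalog injects exactly one defect that validation reports
with exactly the targeted rule code.  All randomness flows from the recipe
seed through one ``random.Random`` — no clock, locale or filesystem-order
dependence — so the same recipe always yields byte-identical output.

Generated bundles are structurally realistic (project -> collections ->
experiments with their own coordinate frames -> channels, every supporting
class exercised) but make no attempt at statistical realism: names are drawn
from a fixed word list and values from simple ranges.
"""

from __future__ import annotations

import copy
import json
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Callable

from .bundle import MetadataBundle
from .entities import Entity, build_entity
from .identifiers import iso7064_mod11_2_check_char
from .registry import SchemaRegistry
from .volumes import (
    N5, NEUROGLANCER_PRECOMPUTED, OME_ZARR_V2, ContainerDescriptor, ScaleLevel,
)

_WORDS = (
    "cortex", "lobula", "medulla", "synapse", "axon", "dendrite", "glia",
    "neuropil", "ganglion", "lamina", "calyx", "antennal", "mushroom",
    "optic", "columnar", "tract", "commissure", "fascicle", "soma", "bouton",
)

_SPECIES = ("Drosophila", "Mus musculus", "C. elegans", "Homo sapiens")
_TAXA = {
    "Drosophila": (7227, "Drosophila melanogaster", "fruit fly"),
    "Mus musculus": (10090, "Mus musculus", "house mouse"),
    "C. elegans": (6239, "Caenorhabditis elegans", "nematode"),
    "Homo sapiens": (9606, "Homo sapiens", "human"),
}


@dataclass(frozen=True)
class FixtureRecipe:
    """Seeded parameters from which a synthetic bundle is generated."""

    seed: int
    n_collections: int = 1
    n_experiments_per_collection: int = 1
    n_channels_per_experiment: int = 1
    violation_kind: str | None = None

    def __post_init__(self) -> None:
        for name in ("n_collections", "n_experiments_per_collection",
                     "n_channels_per_experiment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


def _orcid(rng: random.Random) -> str:
    base = "".join(str(rng.randrange(10)) for _ in range(15))
    full = base + iso7064_mod11_2_check_char(base)
    return "-".join(full[i : i + 4] for i in range(0, 16, 4))


def _ror(rng: random.Random) -> str:
    alphabet = "0123456789abcdefghjkmnpqrstvwxyz"
    return "0" + "".join(rng.choice(alphabet) for _ in range(8))


def _doi(rng: random.Random) -> str:
    return f"10.{rng.randrange(1000, 99999)}/{rng.choice(_WORDS)}.{rng.randrange(10, 999)}"


def _name(rng: random.Random, n: int = 2) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n))


def _contributor(registry, rng: random.Random, *, creator: bool,
                 ctype: str = "Researcher") -> Entity:
    surname = _name(rng, 1).title()
    return build_entity(registry, "Contributor", {
        "Name": [f"{surname}, {rng.choice('ABCDEFG')}."],
        "Email": [f"{surname.lower()}@example.org"],
        "Creator": creator,
        "ContributorType": ctype,
        "NameType": "Personal",
        "NameIdentifier": _orcid(rng),
        "NameIdentifierScheme": "ORCID",
        "Affiliation": _name(rng, 2).title() + " Institute",
        "AffiliationIdentifier": _ror(rng),
        "AffiliationIdentifierScheme": "ROR",
        "Role": "generated fixture contributor",
    })


def _license(registry) -> Entity:
    return build_entity(registry, "License", {
        "Rights": "Creative Commons Attribution 4.0 International",
        "RightsURI": "https://creativecommons.org/licenses/by/4.0/",
        "RightsIdentifier": "CC-BY-4.0",
        "RightsIdentifierDOI": "10.5555/cc-by-4.0",
    })


def generate_bundle(registry: SchemaRegistry, recipe: FixtureRecipe) -> MetadataBundle:
    """Generate a bundle that validates with zero errors and zero warnings.

    The hierarchy mirrors the standard's data model: one project holding
    ``n_collections`` collections, each with its experiments (every
    experiment carries its own coordinate frame) and channels.  Every class
    of the standard appears at least once, including EM- and LM-specific
    acquisition metadata, brain locations, taxonomy, funding, publications
    and links.  If the recipe names a ``violation_kind``, the corresponding
    mutation is applied before returning.
    """
    rng = random.Random(recipe.seed)
    bundle = MetadataBundle(standard_version=registry.version)

    species = rng.choice(_SPECIES)
    tax_id, sci_name, common = _TAXA[species]
    creator = _contributor(registry, rng, creator=True, ctype="ProjectLeader")
    poc = _contributor(registry, rng, creator=False, ctype="ContactPerson")
    others = [_contributor(registry, rng, creator=False)
              for _ in range(rng.randrange(1, 3))]
    lic = _license(registry)
    project_identifiers = [f"doi:{_doi(rng)}", f"RRID:SCR_{rng.randrange(10000, 99999)}"]
    pid = f"proj{recipe.seed % 100000:05d}"
    year = 2018 + rng.randrange(7)

    collection_ids, experiment_ids, channel_ids = [], [], []
    image_locations = []

    for ci in range(recipe.n_collections):
        cid = f"{pid}-col{ci}"
        collection_ids.append(cid)
        col_exp_ids = []
        for ei in range(recipe.n_experiments_per_collection):
            eid = f"{cid}-exp{ei}"
            col_exp_ids.append(eid)
            experiment_ids.append(eid)
            frame_id = f"{eid}-frame"

            res = rng.choice([(4.0, 4.0, 40.0), (8.0, 8.0, 8.0), (4.0, 4.0, 33.0)])
            nx, ny, nz = (rng.randrange(16, 129) for _ in range(3))
            x0, y0, z0 = (float(rng.randrange(0, 1000)) for _ in range(3))
            frame = build_entity(registry, "CoordinateFrame", {
                "Xs": [x0, x0 + nx * res[0]],
                "Ys": [y0, y0 + ny * res[1]],
                "Zs": [z0, z0 + nz * res[2]],
                "VoxelSize": {"X": res[0], "Y": res[1], "Z": res[2], "Unit": "nanometer"},
            })
            bundle.tables["CoordinateFrame"][frame_id] = frame

            region = rng.choice(["optic lobe", "antennal lobe", "mushroom body",
                                 "protocerebrum", "ventral nerve cord"])
            brain_location = {
                "Position": [float(rng.randrange(100)) for _ in range(3)],
                "Orientation": [0.0, 0.0, float(rng.randrange(360))],
                "RegionName": region,
                "ReferenceFrame": "specimen-local",
            }
            image_locations.append(copy.deepcopy(brain_location))

            exp_channel_ids = []
            for ki in range(recipe.n_channels_per_experiment):
                chid = f"{eid}-ch{ki}"
                exp_channel_ids.append(chid)
                channel_ids.append(chid)
                ctype = "RawData" if ki == 0 else rng.choice(["Segmentation", "Annotation"])
                dtype = "uint8" if ctype == "RawData" else rng.choice(["uint32", "uint64"])
                channel = build_entity(registry, "Channel", {
                    "Name": f"{_name(rng)} {ctype.lower()}",
                    "Description": f"{ctype} volume of the {region}",
                    "ID": chid,
                    "ChannelType": ctype,
                    "DataType": dtype,
                    "ImageResolution": {"X": res[0], "Y": res[1], "Z": res[2],
                                        "Unit": "nanometer"},
                    "CoordinateFrame": frame_id,
                    "StorageFormat": rng.choice(["OME_ZARR_V2", "NEUROGLANCER_PRECOMPUTED",
                                                 "N5", "CLOUDVOLUME"]),
                    "StorageURI": f"s3://fixtures/{pid}/{eid}/{chid}",
                    "DataLocation": {
                        "Origin": [0.0, 0.0, 0.0],
                        "Extent": [float(nx), float(ny), float(nz)],
                        "ImageResolution": {"X": res[0], "Y": res[1], "Z": res[2],
                                            "Unit": "nanometer"},
                        "CoordinateFrame": frame_id,
                        "URI": f"s3://fixtures/{pid}/{eid}/{chid}",
                    },
                    "DateCreated": f"{year}-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}",
                    "Version": "1.0",
                })
                bundle.tables["Channel"][chid] = channel

            experiment = build_entity(registry, "Experiment", {
                "Name": f"{_name(rng)} experiment",
                "Description": f"Volume of {species} {region}",
                "ID": eid,
                "Creator": [creator],
                "License": [lic],
                "Identifiers": [project_identifiers[0]],
                "Channels": exp_channel_ids,
                "CoordinateFrame": frame_id,
                "Protocol": f"dx.doi.org/{_doi(rng)}",
                "BrainLocation": brain_location,
                "EMSpecific": {
                    "MicroscopeManufacturer": rng.choice(["Zeiss", "FEI", "JEOL"]),
                    "MicroscopeModel": f"EM-{rng.randrange(100, 999)}",
                    "MicroscopeRRID": f"RRID:SCR_{rng.randrange(10000, 99999)}",
                    "ImagingTechnique": rng.choice(["FIB_SEM", "SS_TEM", "ATUM_SEM"]),
                    "AcceleratingVoltage": float(rng.choice([5, 30, 120, 300])),
                    "BeamCurrent": round(rng.uniform(0.1, 10.0), 2),
                    "DwellTime": round(rng.uniform(0.2, 8.0), 2),
                    "SectionThickness": res[2],
                    "Detector": "backscatter",
                    "Operator": creator["Name"][0],
                },
                "LMSpecific": {
                    "MicroscopeType": "confocal",
                    "MicroscopeManufacturer": "Leica",
                    "ObjectiveNA": 1.4,
                    "ObjectiveMagnification": 63.0,
                    "ZStep": 0.3,
                    "ImageOrientation": {"XAngle": 0.0, "YAngle": 0.0,
                                         "ZAngle": float(rng.randrange(360)),
                                         "Convention": "intrinsic-XYZ"},
                    "Landmarks": [{"Name": region,
                                   "Position": [float(rng.randrange(100)) for _ in range(3)]}],
                },
                "DateCreated": f"{year}-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}",
                "Version": "1.0",
            })
            bundle.tables["Experiment"][eid] = experiment

        collection = build_entity(registry, "Collection", {
            "Name": f"{_name(rng)} collection",
            "Description": f"Experiments on {species} ({_name(rng)})",
            "ID": cid,
            "Creator": [creator],
            "License": [lic],
            "Identifiers": list(project_identifiers),
            "Experiments": col_exp_ids,
            "DateCreated": str(year),
            "Keywords": [rng.choice(_WORDS) for _ in range(2)],
            "Version": "1.0",
            "PointOfContact": [poc],
        })
        bundle.tables["Collection"][cid] = collection

    project = build_entity(registry, "Project", {
        "Title": f"{_name(rng, 3).title()} Connectome",
        "ShortTitle": _name(rng, 1).title(),
        "ID": pid,
        "Keywords": ["connectomics", species, rng.choice(_WORDS)],
        "Description": f"Synthetic {species} EM dataset exercising every metadata class.",
        "Public": True,
        "Year": str(year),
        "Publications": [{
            "Name": [f"The {_name(rng)} connectome"],
            "URI": [f"https://doi.org/{_doi(rng)}"],
            "Authors": [creator["Name"][0], poc["Name"][0]],
            "RelatedIdentifier": _doi(rng),
            "RelatedIdentifierType": "DOI",
            "RelationType": "IsCitedBy",
            "Citation": f"{creator['Name'][0]} et al. ({year})",
            "PMCID": f"PMC{rng.randrange(1000000, 9999999)}",
        }],
        "Links": [{"Name": ["project site"], "URI": [f"https://example.org/{pid}"]}],
        "License": [lic],
        "Creator": creator,
        "PointOfContact": [poc],
        "Contributor": [creator, poc, *others],
        "Acknowledgements": "Generated fixture; thanks to the word list.",
        "Funding": [{
            "FundingEntity": "National Synthetic Data Fund",
            "AwardIdentifier": f"NSDF-{rng.randrange(1000, 9999)}",
            "FundingReferenceIdentifier": _ror(rng),
            "FundingReferenceIdentifierType": "ROR",
            "AwardTitle": f"{_name(rng, 2).title()} Award",
        }],
        "Species": [species],
        "Taxonomy": [{
            "TaxonomyID": tax_id,
            "CurrentName": sci_name,
            "GenBankCommonName": common,
            "Rank": "species",
            "CommonName": [common],
        }],
        "DateCreated": f"{year}-01-{rng.randrange(1, 29):02d}",
        "Channels": channel_ids,
        "Experiments": experiment_ids,
        "Collections": collection_ids,
        "DataTypes": ["uint8", "uint32"],
        "GeneralModality": ["Microscopy"],
        "ImagingModalities": ["EM"],
        "ImagingModalitySpecific": ["FIB_SEM"],
        "ImageLocations": image_locations,
        "Version": "1.1",
        "UniqueIdentifier": {"Name": ["dataset DOI"],
                             "URI": [f"https://doi.org/{_doi(rng)}"]},
        "Identifiers": list(project_identifiers),
    })
    bundle.tables["Project"][pid] = project

    if recipe.violation_kind is not None:
        bundle, _ = mutate_bundle(bundle, recipe.violation_kind, recipe.seed)
    return bundle


# ---------------------------------------------------------------------------
# mutation catalog — one targeted defect per error-severity rule code

def _first_project(bundle) -> tuple[str, Entity]:
    pid = sorted(bundle.tables["Project"])[0]
    return pid, bundle.tables["Project"][pid]


def _first_of(bundle, cls: str) -> tuple[str, Entity]:
    eid = sorted(bundle.tables[cls])[0]
    return eid, bundle.tables[cls][eid]


def _project_child_path(bundle, cls: str, eid: str) -> str:
    pid, _ = _first_project(bundle)
    if cls == "Collection":
        return f"project/{pid}/collection/{eid}"
    raise AssertionError(cls)


def _mut_req_missing(bundle, rng) -> str:
    pid, project = _first_project(bundle)
    del project.values["Title"]
    return f"project/{pid}"


def _mut_type_mismatch(bundle, rng) -> str:
    pid, project = _first_project(bundle)
    project.values["Taxonomy"][0].values["TaxonomyID"] = "not-a-number"
    return f"project/{pid}.Taxonomy"


def _mut_enum_invalid(bundle, rng) -> str:
    # the generator deliberately shares one Contributor object across the
    # hierarchy, so mutate a private copy to keep the defect single-site
    pid, project = _first_project(bundle)
    rogue = copy.deepcopy(project.values["Creator"])
    rogue.values["ContributorType"] = "Janitor"
    project.values["Creator"] = rogue
    return f"project/{pid}.Creator"


def _mut_cardinality(bundle, rng) -> str:
    pid, project = _first_project(bundle)
    project.values["Collections"] = []
    return f"project/{pid}"


def _rogue_license(rng) -> Entity:
    return Entity("License", {
        "Rights": "All rights reserved",
        "RightsURI": "https://example.org/proprietary",
        "RightsIdentifier": f"PROP-{rng.randrange(100, 999)}",
    })


def _mut_subset_license(bundle, rng) -> str:
    cid, collection = _first_of(bundle, "Collection")
    collection.values.setdefault("License", []).append(_rogue_license(rng))
    return _project_child_path(bundle, "Collection", cid)


def _mut_subset_creator(bundle, rng) -> str:
    cid, collection = _first_of(bundle, "Collection")
    rogue = Entity("Contributor", {"Name": ["Rogue, R."], "Creator": True})
    collection.values.setdefault("Creator", []).append(rogue)
    return _project_child_path(bundle, "Collection", cid)


def _mut_subset_identifier(bundle, rng) -> str:
    cid, collection = _first_of(bundle, "Collection")
    collection.values.setdefault("Identifiers", []).append("doi:10.9999/not-in-project")
    return _project_child_path(bundle, "Collection", cid)


def _mut_coord_mismatch(bundle, rng) -> str:
    chid, channel = _first_of(bundle, "Channel")
    frame_id = channel.values["CoordinateFrame"]
    rogue_id = f"{frame_id}-rogue"
    rogue = copy.deepcopy(bundle.tables["CoordinateFrame"][frame_id])
    rogue.values["Xs"] = [rogue.values["Xs"][0], rogue.values["Xs"][1] + 64.0]
    bundle.tables["CoordinateFrame"][rogue_id] = rogue
    channel.values["CoordinateFrame"] = rogue_id
    pid, project = _first_project(bundle)
    for cid in project.values["Collections"]:
        collection = bundle.tables["Collection"][cid]
        for eid in collection.values["Experiments"]:
            if chid in bundle.tables["Experiment"][eid].values["Channels"]:
                return f"project/{pid}/collection/{cid}/experiment/{eid}/channel/{chid}"
    raise AssertionError("channel not reachable")


def _mut_extent_degenerate(bundle, rng) -> str:
    fid, frame = _first_of(bundle, "CoordinateFrame")
    frame.values["Xs"] = [5.0, 5.0]
    return f"coordinate_frame/{fid}"


def _mut_ref_dangling(bundle, rng) -> str:
    eid, experiment = _first_of(bundle, "Experiment")
    experiment.values["Channels"] = ["no-such-channel"] + experiment.values["Channels"][1:]
    pid, project = _first_project(bundle)
    for cid in project.values["Collections"]:
        if eid in bundle.tables["Collection"][cid].values["Experiments"]:
            return f"project/{pid}/collection/{cid}/experiment/{eid}"
    raise AssertionError("experiment not reachable")


_MUTATORS: dict[str, Callable] = {
    "REQ_MISSING": _mut_req_missing,
    "TYPE_MISMATCH": _mut_type_mismatch,
    "ENUM_INVALID": _mut_enum_invalid,
    "CARDINALITY": _mut_cardinality,
    "SUBSET_LICENSE": _mut_subset_license,
    "SUBSET_CREATOR": _mut_subset_creator,
    "SUBSET_IDENTIFIER": _mut_subset_identifier,
    "COORD_MISMATCH": _mut_coord_mismatch,
    "EXTENT_DEGENERATE": _mut_extent_degenerate,
    "REF_DANGLING": _mut_ref_dangling,
}

#: rule codes :func:`mutate_bundle` can inject (the error-severity catalog)
MUTATION_CATALOG = tuple(sorted(_MUTATORS))


def mutate_bundle(bundle: MetadataBundle, rule_code: str, seed: int = 0
                  ) -> tuple[MetadataBundle, str]:
    """Return a deep-copied mutant with exactly one ``rule_code`` defect.

    The second element of the returned pair is the entity path where
    validation is expected to report the violation.
    """
    try:
        mutator = _MUTATORS[rule_code]
    except KeyError:
        raise ValueError(
            f"no mutation for rule code {rule_code!r}; catalog: "
            f"{', '.join(MUTATION_CATALOG)}"
        ) from None
    mutant = copy.deepcopy(bundle)
    try:
        path = mutator(mutant, random.Random(seed))
    except (KeyError, IndexError) as exc:
        raise ValueError(
            f"bundle has no applicable site for {rule_code}: {exc}"
        ) from exc
    return mutant, path


# ---------------------------------------------------------------------------
# container fixtures

_ZARR_DTYPE = {"uint8": "|u1", "uint16": "<u2", "uint32": "<u4", "uint64": "<u8",
               "float32": "<f4", "float64": "<f8"}
_ITEMSIZE = {"uint8": 1, "uint16": 2, "uint32": 4, "uint64": 8,
             "float32": 4, "float64": 8}

_FORMAT_ALIASES = {
    "OME_ZARR_V2": OME_ZARR_V2, "ome-zarr": OME_ZARR_V2, "zarr": OME_ZARR_V2,
    "NEUROGLANCER_PRECOMPUTED": NEUROGLANCER_PRECOMPUTED,
    "precomputed": NEUROGLANCER_PRECOMPUTED,
    "CLOUDVOLUME": "CLOUDVOLUME", "cloud-volume": "CLOUDVOLUME",
    "N5": N5, "n5": N5,
}


def _put(store: dict | Path, key: str, payload: bytes | str) -> None:
    data = payload.encode("utf-8") if isinstance(payload, str) else payload
    if isinstance(store, dict):
        store[key] = data
    else:
        target = Path(store) / key
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_bytes(data)


def _jdump(obj: Any) -> str:
    return json.dumps(obj, indent=2) + "\n"


def generate_container(
    format_kind: str,
    dtype: str,
    extent: tuple[int, int, int],
    resolution: tuple[float, float, float],
    seed: int = 0,
    out_tree: Path | dict | None = None,
    n_scales: int = 1,
) -> tuple[Path | dict, ContainerDescriptor]:
    """Write a tiny, compliant container fixture and return (store, expected).

    ``out_tree`` may be a directory path or a dict used as an in-memory
    key-value store (default: a fresh dict).  Extents are capped at 128 per
    axis — fixtures are desk-scale by design.  The expected descriptor is
    computed from the declared values, so parser tests can compare
    ``parse_container(store)`` against it.  One zero-filled placeholder chunk
    is written per store; compliance checking never decodes it.
    """
    kind = _FORMAT_ALIASES.get(format_kind)
    if kind is None:
        raise ValueError(f"unknown container format {format_kind!r}")
    if dtype not in _ZARR_DTYPE:
        raise ValueError(f"unsupported dtype {dtype!r}; one of {sorted(_ZARR_DTYPE)}")
    extent = tuple(int(v) for v in extent)
    if len(extent) != 3 or any(v < 1 or v > 128 for v in extent):
        raise ValueError(f"extent must be three values in [1, 128], got {extent}")
    resolution = tuple(float(v) for v in resolution)
    store: Path | dict = {} if out_tree is None else out_tree

    def level_geometry(i: int) -> tuple[tuple[int, int, int], tuple[float, float, float]]:
        f = 2 ** i
        return (tuple(max(1, math.ceil(v / f)) for v in extent),
                tuple(r * f for r in resolution))

    chunk = tuple(min(32, v) for v in extent)
    expected_scales = []

    if kind in (NEUROGLANCER_PRECOMPUTED, "CLOUDVOLUME"):
        scales = []
        for i in range(n_scales):
            size, res = level_geometry(i)
            key = "_".join(f"{r:g}" for r in res)
            scales.append({
                "key": key,
                "size": list(size),
                "resolution": list(res),
                "chunk_sizes": [list(tuple(min(c, s) for c, s in zip(chunk, size)))],
                "encoding": "raw",
            })
            expected_scales.append(
                ScaleLevel(size, tuple(min(c, s) for c, s in zip(chunk, size)),
                           res, "nanometer"))
        info = {"type": "image", "data_type": dtype, "num_channels": 1, "scales": scales}
        _put(store, "info", _jdump(info))
        if kind == "CLOUDVOLUME":
            _put(store, "provenance",
                 _jdump({"description": "synthetic fixture", "sources": [],
                         "owners": [], "processing": []}))
        c = scales[0]["chunk_sizes"][0]
        chunk_key = f"{scales[0]['key']}/0-{c[0]}_0-{c[1]}_0-{c[2]}"
        _put(store, chunk_key, bytes(c[0] * c[1] * c[2] * _ITEMSIZE[dtype]))
        descriptor = ContainerDescriptor(
            NEUROGLANCER_PRECOMPUTED, dtype, expected_scales, True,
            "cloud-volume layout (precomputed plus provenance file)"
            if kind == "CLOUDVOLUME" else None)

    elif kind == OME_ZARR_V2:
        datasets = []
        for i in range(n_scales):
            size, res = level_geometry(i)
            datasets.append({
                "path": str(i),
                "coordinateTransformations": [
                    {"type": "scale", "scale": [res[2], res[1], res[0]]}],  # z, y, x
            })
            level_chunk = tuple(min(c, s) for c, s in zip(chunk, size))
            _put(store, f"{i}/.zarray", _jdump({
                "zarr_format": 2,
                "shape": [size[2], size[1], size[0]],
                "chunks": [level_chunk[2], level_chunk[1], level_chunk[0]],
                "dtype": _ZARR_DTYPE[dtype],
                "compressor": None,
                "fill_value": 0,
                "order": "C",
                "filters": None,
            }))
            expected_scales.append(ScaleLevel(size, level_chunk, res, "nanometer"))
        _put(store, ".zgroup", _jdump({"zarr_format": 2}))
        _put(store, ".zattrs", _jdump({"multiscales": [{
            "version": "0.4",
            "name": f"fixture-{seed}",
            "axes": [{"name": "z", "type": "space", "unit": "nanometer"},
                     {"name": "y", "type": "space", "unit": "nanometer"},
                     {"name": "x", "type": "space", "unit": "nanometer"}],
            "datasets": datasets,
        }]}))
        c0 = expected_scales[0].chunk_shape
        _put(store, "0/0.0.0", bytes(c0[0] * c0[1] * c0[2] * _ITEMSIZE[dtype]))
        descriptor = ContainerDescriptor(OME_ZARR_V2, dtype, expected_scales, True)

    else:  # N5
        factors = [[2 ** i] * 3 for i in range(n_scales)]
        _put(store, "attributes.json", _jdump({
            "n5": "2.5.1",
            "resolution": list(resolution),
            "units": ["nm", "nm", "nm"],
            "scales": factors,
        }))
        for i in range(n_scales):
            size, res = level_geometry(i)
            level_chunk = tuple(min(c, s) for c, s in zip(chunk, size))
            _put(store, f"s{i}/attributes.json", _jdump({
                "dimensions": list(size),
                "blockSize": list(level_chunk),
                "dataType": dtype,
                "compression": {"type": "raw"},
            }))
            expected_scales.append(ScaleLevel(size, level_chunk, res, "nm"))
        _put(store, "s0/0/0/0", bytes(16))
        descriptor = ContainerDescriptor(N5, dtype, expected_scales, True)

    return store, descriptor


# -- seeded container corruptions -------------------------------------------

def _edit_json(store, key: str, editor: Callable[[dict], None]) -> None:
    raw = store[key] if isinstance(store, dict) else (Path(store) / key).read_bytes()
    obj = json.loads(raw.decode("utf-8"))
    editor(obj)
    _put(store, key, _jdump(obj))


def _del(store, key: str) -> None:
    if isinstance(store, dict):
        store.pop(key, None)
    else:
        p = Path(store) / key
        if p.is_file():
            p.unlink()


#: corruption kind -> rule/error it must trigger (see tests and methods note)
CONTAINER_CORRUPTIONS = (
    "wrong_dtype",        # cross-check DTYPE_MISMATCH
    "wrong_resolution",   # cross-check RESOLUTION_MISMATCH
    "truncated_extent",   # cross-check EXTENT_MISMATCH
    "deleted_sentinel",   # detect_format UNRECOGNIZED_FORMAT
    "malformed_metadata", # parse_container CONTAINER_MALFORMED
    "dropped_chunks",     # cross-check CHUNKS_MISSING warning
)


def corrupt_container(store: Path | dict, format_kind: str, corruption: str) -> None:
    """Apply one seeded corruption in place (the container mutation catalog)."""
    kind = _FORMAT_ALIASES.get(format_kind)
    meta = {OME_ZARR_V2: ".zattrs", NEUROGLANCER_PRECOMPUTED: "info",
            "CLOUDVOLUME": "info", N5: "attributes.json"}[kind]

    if corruption == "deleted_sentinel":
        _del(store, meta)
        return
    if corruption == "malformed_metadata":
        if kind == NEUROGLANCER_PRECOMPUTED or kind == "CLOUDVOLUME":
            _edit_json(store, "info", lambda o: o.pop("data_type"))
        elif kind == OME_ZARR_V2:
            _edit_json(store, "0/.zarray", lambda o: o.pop("shape"))
        else:
            _edit_json(store, "s0/attributes.json", lambda o: o.pop("dimensions"))
        return
    if corruption == "dropped_chunks":
        for key in [k for k in (_keys_of(store))
                    if not k.endswith((".zattrs", ".zgroup", ".zarray",
                                       "info", "provenance", "attributes.json"))]:
            _del(store, key)
        return

    def precomputed(o: dict) -> None:
        if corruption == "wrong_dtype":
            o["data_type"] = "uint16" if o["data_type"] != "uint16" else "uint8"
        elif corruption == "wrong_resolution":
            o["scales"][0]["resolution"][2] *= 3
        elif corruption == "truncated_extent":
            o["scales"][0]["size"][0] = max(1, o["scales"][0]["size"][0] - 7)

    def zarray(o: dict) -> None:
        if corruption == "wrong_dtype":
            o["dtype"] = "<u2" if o["dtype"] != "<u2" else "|u1"
        elif corruption == "truncated_extent":
            o["shape"][2] = max(1, o["shape"][2] - 7)

    def zattrs(o: dict) -> None:
        if corruption == "wrong_resolution":
            o["multiscales"][0]["datasets"][0]["coordinateTransformations"][0]["scale"][0] *= 3

    def n5_root(o: dict) -> None:
        if corruption == "wrong_resolution":
            o["resolution"][2] *= 3

    def n5_ds(o: dict) -> None:
        if corruption == "wrong_dtype":
            o["dataType"] = "uint16" if o["dataType"] != "uint16" else "uint8"
        elif corruption == "truncated_extent":
            o["dimensions"][0] = max(1, o["dimensions"][0] - 7)

    if corruption not in CONTAINER_CORRUPTIONS:
        raise ValueError(f"unknown corruption {corruption!r}; "
                         f"one of {', '.join(CONTAINER_CORRUPTIONS)}")
    if kind in (NEUROGLANCER_PRECOMPUTED, "CLOUDVOLUME"):
        _edit_json(store, "info", precomputed)
    elif kind == OME_ZARR_V2:
        if corruption == "wrong_resolution":
            _edit_json(store, ".zattrs", zattrs)
        else:
            _edit_json(store, "0/.zarray", zarray)
    else:
        if corruption == "wrong_resolution":
            _edit_json(store, "attributes.json", n5_root)
        else:
            _edit_json(store, "s0/attributes.json", n5_ds)


def _keys_of(store) -> list[str]:
    from .volumes import _keys
    return _keys(store)


# -- channel/frame pair matching a generated container -----------------------

def channel_for_container(
    registry: SchemaRegistry,
    dtype: str,
    extent: tuple[int, int, int],
    resolution: tuple[float, float, float],
    storage_format: str = "NEUROGLANCER_PRECOMPUTED",
) -> tuple[Entity, Entity]:
    """Build a (channel, coordinate_frame) pair consistent with a container
    generated from the same dtype/extent/resolution."""
    frame = build_entity(registry, "CoordinateFrame", {
        "Xs": [0.0, extent[0] * resolution[0]],
        "Ys": [0.0, extent[1] * resolution[1]],
        "Zs": [0.0, extent[2] * resolution[2]],
        "VoxelSize": {"X": resolution[0], "Y": resolution[1], "Z": resolution[2],
                      "Unit": "nanometer"},
    })
    channel = build_entity(registry, "Channel", {
        "Name": "fixture channel",
        "ID": "fixture-ch0",
        "ChannelType": "RawData" if dtype == "uint8" else "Segmentation",
        "DataType": dtype,
        "ImageResolution": {"X": resolution[0], "Y": resolution[1], "Z": resolution[2],
                            "Unit": "nanometer"},
        "CoordinateFrame": "fixture-frame",
        "StorageFormat": storage_format,
    })
    return channel, frame
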