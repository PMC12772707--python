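"""Rules engine: per-entity rules, subset constraints, frame consistency,
determinism and monotonicity."""

import copy
import json

import pytest

from benchmark_metadata import (
    FixtureRecipe,
    RULES,
    build_entity,
    check_coordinate_consistency,
    check_subset_constraint,
    generate_bundle,
    validate_bundle,
    validate_entity,
)


def codes(report_or_list):
    items = getattr(report_or_list, "violations", report_or_list)
    return [v.rule_code for v in items]


# -- per-entity -------------------------------------------------------------

def test_project_missing_title_is_req_missing(registry, minimal_bundle):
    project = copy.deepcopy(minimal_bundle.projects[0])
    del project.values["Title"]
    report = validate_entity(registry, project)
    assert codes(report.errors) == ["REQ_MISSING"]
    assert "Title" in report.errors[0].message


def test_non_member_contributor_type_is_enum_invalid(registry):
    c = build_entity(registry, "Contributor",
                     {"Name": ["Doe, J."], "ContributorType": "Janitor"})
    report = validate_entity(registry, c)
    assert codes(report) == ["ENUM_INVALID"]
    assert report.errors[0].severity == "error"


def test_minimal_link_is_valid(registry):
    link = build_entity(registry, "Link",
                        {"Name": ["BossDB"], "URI": ["https://bossdb.org"]})
    report = validate_entity(registry, link)
    assert report.valid and not report.violations


def test_quarantined_extras_are_warnings(registry):
    link = build_entity(registry, "Link",
                        {"Name": ["x"], "URI": ["https://x"], "Frob": 1})
    report = validate_entity(registry, link)
    assert codes(report) == ["UNKNOWN_FIELD"]
    assert report.valid  # warnings alone leave the entity valid


def test_malformed_orcid_is_a_syntax_warning(registry):
    c = build_entity(registry, "Contributor", {
        "Name": ["Doe, J."], "NameIdentifier": "0000-0002-1825-0090",
        "NameIdentifierScheme": "ORCID",
    })
    report = validate_entity(registry, c)
    assert codes(report) == ["ID_SYNTAX"]
    assert report.warnings and report.valid


# -- subset constraints -----------------------------------------------------

def _entity_with_licenses(registry, idents):
    return build_entity(registry, "Collection", {
        "Name": "c", "ID": "c1", "Experiments": ["e1"],
        "License": [
            {"Rights": f"Rights {i}", "RightsURI": "https://x", "RightsIdentifier": i}
            for i in idents
        ],
    })


def test_identical_license_sets_pass(registry):
    child = _entity_with_licenses(registry, ["CC-BY-4.0"])
    parent = _entity_with_licenses(registry, ["CC-BY-4.0"])
    assert check_subset_constraint(child, parent, "licenses") == []


def test_license_outside_parent_set_is_one_violation(registry):
    child = _entity_with_licenses(registry, ["CC0"])
    parent = _entity_with_licenses(registry, ["CC-BY-4.0"])
    violations = check_subset_constraint(child, parent, "licenses")
    assert codes(violations) == ["SUBSET_LICENSE"]
    assert "CC0" in violations[0].message


def test_empty_child_facet_is_always_a_subset(registry):
    child = build_entity(registry, "Collection",
                         {"Name": "c", "ID": "c1", "Experiments": ["e1"]})
    parent = _entity_with_licenses(registry, ["CC-BY-4.0"])
    for facet in ("creators", "licenses", "identifiers"):
        assert check_subset_constraint(child, parent, facet) == []


def test_creator_equality_falls_back_to_folded_name(registry):
    child = build_entity(registry, "Collection", {
        "Name": "c", "ID": "c1", "Experiments": ["e1"],
        "Creator": [{"Name": ["DOE, J."], "Creator": True}],
    })
    parent = build_entity(registry, "Project", {
        "Creator": {"Name": ["doe, j."], "Creator": True},
    })
    assert check_subset_constraint(child, parent, "creators") == []


def test_subset_transitivity_along_the_generated_chain(registry, small_bundle):
    """channel ⊆ experiment ⊆ collection ⊆ project pairwise implies no
    SUBSET_* violation anywhere in the full bundle validation."""
    report = validate_bundle(registry, small_bundle)
    assert not [c for c in codes(report) if c.startswith("SUBSET_")]


# -- coordinate frames ------------------------------------------------------

def _experiment(registry, frame="cf1"):
    return build_entity(registry, "Experiment", {
        "Name": "e", "ID": "e1", "Channels": ["ch1"], "CoordinateFrame": frame,
    })


def _channel(registry, frame="cf1", chid="ch1"):
    return build_entity(registry, "Channel", {
        "Name": chid, "ID": chid, "ChannelType": "RawData", "DataType": "uint8",
        "CoordinateFrame": frame,
        "ImageResolution": {"X": 4.0, "Y": 4.0, "Z": 40.0, "Unit": "nanometer"},
    })


def test_channels_on_the_experiment_frame_pass(registry):
    channels = [(f"ch{i}", _channel(registry, chid=f"ch{i}")) for i in range(3)]
    assert check_coordinate_consistency(_experiment(registry), channels) == []


def test_one_channel_on_another_frame_is_one_mismatch(registry):
    channels = [("a", _channel(registry)), ("b", _channel(registry, frame="cf2", chid="ch2"))]
    violations = check_coordinate_consistency(_experiment(registry), channels)
    assert codes(violations) == ["COORD_MISMATCH"]
    assert violations[0].entity_path == "b"


def test_degenerate_frame_extent_is_reported(registry):
    frame = build_entity(registry, "CoordinateFrame", {
        "Xs": [5.0, 5.0], "Ys": [0.0, 64.0], "Zs": [0.0, 64.0],
        "VoxelSize": {"X": 4.0, "Y": 4.0, "Z": 40.0, "Unit": "nanometer"},
    })
    violations = check_coordinate_consistency(
        _experiment(registry), [], frames={"cf1": frame})
    assert codes(violations) == ["EXTENT_DEGENERATE"]


def test_identical_duplicate_frames_warn_but_do_not_fail(registry):
    bundle = generate_bundle(
        registry, FixtureRecipe(seed=11, n_experiments_per_collection=2))
    frames = bundle.tables["CoordinateFrame"]
    ids = sorted(frames)
    frames[ids[1]] = copy.deepcopy(frames[ids[0]])  # force an exact duplicate
    report = validate_bundle(registry, bundle)
    assert report.valid
    assert "FRAME_NOT_SHARED" in codes(report.warnings)


# -- whole-bundle properties ------------------------------------------------

def test_dangling_reference_is_reported_not_raised(registry, minimal_bundle):
    bundle = copy.deepcopy(minimal_bundle)
    eid = sorted(bundle.tables["Experiment"])[0]
    bundle.tables["Experiment"][eid].values["Channels"] = ["ghost-channel"]
    report = validate_bundle(registry, bundle)
    assert "REF_DANGLING" in codes(report.errors)


def test_report_is_deterministic_and_ordered(registry, small_bundle):
    bundle = copy.deepcopy(small_bundle)
    del bundle.projects[0].values["Title"]
    bundle.projects[0].values["Species"] = ["Martian"]
    r1 = validate_bundle(registry, bundle)
    r2 = validate_bundle(registry, bundle)
    assert json.dumps(r1.to_dict()) == json.dumps(r2.to_dict())
    keys = [(v.entity_path, v.rule_code) for v in r1.violations]
    assert keys == sorted(keys)


def test_adding_an_optional_valid_field_never_breaks_validity(registry, minimal_bundle):
    bundle = copy.deepcopy(minimal_bundle)
    assert validate_bundle(registry, bundle).valid
    project = bundle.projects[0]
    project.values["TechnicalInfo"] = "8-bit volumes, serial sections"
    project.values["DateModified"] = "2024-06-01"
    cid = sorted(bundle.tables["Collection"])[0]
    bundle.tables["Collection"][cid].values["Description"] = "appended later"
    report = validate_bundle(registry, bundle)
    assert report.valid and not report.errors


def test_valid_iff_zero_errors(registry, minimal_bundle):
    report = validate_bundle(registry, minimal_bundle)
    assert report.valid == (report.counts["error"] == 0)


def test_rule_registry_is_closed():
    from benchmark_metadata import Violation
    from benchmark_metadata.errors import BenchmarkError

    assert set(RULES.values()) == {"error", "warning"}
    with pytest.raises(BenchmarkError):
        Violation("NOT_A_RULE", "x", "error", "nope")
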