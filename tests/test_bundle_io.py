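"""Canonical serialization: lossless round-trip, fixpoint, normalization."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benchmark_metadata import (
    BundleParseError,
    FixtureRecipe,
    bundles_equal,
    generate_bundle,
    read_bundle,
    serialize_bundle,
    validate_bundle,
)

MINIMAL_DOC = {
    "StandardVersion": "1.1",
    "Projects": {
        "p1": {
            "Title": "T", "ShortTitle": "T", "Keywords": ["k"],
            "Description": "d", "Public": True, "Year": "2020",
            "License": [{"Rights": "CC BY 4.0",
                         "RightsURI": "https://creativecommons.org/licenses/by/4.0/"}],
            "Creator": {"Name": ["Doe, J."], "Creator": True},
            "PointOfContact": [{"Name": ["Doe, J."]}],
            "Contributor": [{"Name": ["Doe, J."]}],
            "Species": ["Drosophila"], "DateCreated": "2020-01-01",
            "Channels": ["ch1"], "Experiments": ["e1"], "Collections": ["c1"],
            "GeneralModality": ["Microscopy"], "ImagingModalities": ["EM"],
            "Version": "1.0",
        }
    },
    "Collections": {"c1": {"Name": "c", "Experiments": ["e1"]}},
    "Experiments": {"e1": {"Name": "e", "Channels": ["ch1"], "CoordinateFrame": "cf1"}},
    "Channels": {
        "ch1": {"Name": "ch", "ChannelType": "RawData", "DataType": "uint8",
                "CoordinateFrame": "cf1",
                "ImageResolution": {"X": 4.0, "Y": 4.0, "Z": 40.0, "Unit": "nanometer"}}
    },
    "CoordinateFrames": {
        "cf1": {"Xs": [0.0, 256.0], "Ys": [0.0, 256.0], "Zs": [0.0, 2560.0],
                "VoxelSize": {"X": 4.0, "Y": 4.0, "Z": 40.0, "Unit": "nanometer"}}
    },
}


def test_minimal_document_counts_five_entities(registry):
    bundle = read_bundle(registry, MINIMAL_DOC)
    assert bundle.entity_count() == 5
    assert validate_bundle(registry, bundle).valid


def test_nested_inline_children_normalize_to_references(registry):
    """Inlining a channel (and frame) inside the experiment parses to the
    same bundle as the fully referenced form."""
    doc = json.loads(json.dumps(MINIMAL_DOC))
    channel = doc.pop("Channels")["ch1"]
    channel["ID"] = "ch1"
    frame = doc.pop("CoordinateFrames")["cf1"]
    frame["ID"] = "cf1"
    doc["Experiments"]["e1"]["Channels"] = [channel]
    doc["Experiments"]["e1"]["CoordinateFrame"] = frame
    nested = read_bundle(registry, doc)
    referenced = read_bundle(registry, MINIMAL_DOC)
    assert bundles_equal(nested, referenced)
    assert serialize_bundle(registry, nested) == serialize_bundle(registry, referenced)


def test_duplicate_project_id_is_a_parse_error(registry):
    text = json.dumps(MINIMAL_DOC)
    # splice a second "p1" key into the Projects object of the raw text
    dup = text.replace('"Projects": {', '"Projects": {"p1": {"Title": "other"}, ', 1)
    with pytest.raises(BundleParseError, match="duplicate"):
        read_bundle(registry, dup)


def test_conflicting_inline_duplicate_is_a_parse_error(registry):
    doc = json.loads(json.dumps(MINIMAL_DOC))
    rogue = dict(doc["Channels"]["ch1"], Name="different")
    rogue["ID"] = "ch1"
    doc["Experiments"]["e1"]["Channels"] = [rogue]
    with pytest.raises(BundleParseError, match="conflicting"):
        read_bundle(registry, doc)


def test_non_object_document_is_a_parse_error(registry):
    with pytest.raises(BundleParseError):
        read_bundle(registry, "[1, 2, 3]")


def test_non_utf8_bytes_are_a_parse_error(registry):
    with pytest.raises(BundleParseError, match="UTF-8"):
        read_bundle(registry, b"\xff\xfe{}")


def test_table_key_must_match_declared_id(registry):
    doc = json.loads(json.dumps(MINIMAL_DOC))
    doc["Channels"]["ch1"]["ID"] = "other"
    with pytest.raises(BundleParseError):
        read_bundle(registry, doc)


def test_unknown_top_level_sections_are_quarantined(registry):
    doc = dict(MINIMAL_DOC, Frobnications={"f": 1})
    bundle = read_bundle(registry, doc)
    assert bundle.extras == {"Frobnications": {"f": 1}}
    report = validate_bundle(registry, bundle)
    assert report.valid
    assert any(v.rule_code == "UNKNOWN_FIELD" and "Frobnications" in v.message
               for v in report.warnings)


def test_write_read_write_is_a_fixpoint(registry):
    bundle = read_bundle(registry, MINIMAL_DOC)
    once = serialize_bundle(registry, bundle)
    twice = serialize_bundle(registry, read_bundle(registry, once))
    assert once == twice


def test_float_values_survive_round_trip_exactly(registry):
    doc = json.loads(json.dumps(MINIMAL_DOC))
    doc["CoordinateFrames"]["cf1"]["Xs"] = [0.1, 6400.3]
    bundle = read_bundle(registry, doc)
    text = serialize_bundle(registry, bundle)
    assert '0.1' in text and '6400.3' in text
    again = read_bundle(registry, text)
    assert again.tables["CoordinateFrame"]["cf1"]["Xs"] == [0.1, 6400.3]


def test_key_order_follows_registry_not_input(registry):
    doc = json.loads(json.dumps(MINIMAL_DOC))
    frame = doc["CoordinateFrames"]["cf1"]
    doc["CoordinateFrames"]["cf1"] = dict(reversed(list(frame.items())))
    text = serialize_bundle(registry, read_bundle(registry, doc))
    parsed = json.loads(text)
    assert list(parsed["CoordinateFrames"]["cf1"]) == ["Xs", "Ys", "Zs", "VoxelSize"]


@given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3), st.integers(1, 2), st.integers(1, 2))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_round_trip_losslessness_over_generated_bundles(registry, seed, nc, ne, nk):
    bundle = generate_bundle(registry, FixtureRecipe(seed, nc, ne, nk))
    text = serialize_bundle(registry, bundle)
    again = read_bundle(registry, text)
    assert bundles_equal(bundle, again)
    assert serialize_bundle(registry, again) == text
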