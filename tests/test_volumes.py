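"""Container-format detection, metadata parsing, and channel cross-checks."""

import json

import pytest

from benchmark_metadata import (
    ContainerError,
    FormatDetectionError,
    channel_for_container,
    cross_check_channel,
    detect_format,
    generate_container,
    parse_container,
)

FORMATS = ["precomputed", "cloud-volume", "ome-zarr", "n5"]
KINDS = {"precomputed": "NEUROGLANCER_PRECOMPUTED",
         "cloud-volume": "NEUROGLANCER_PRECOMPUTED",
         "ome-zarr": "OME_ZARR_V2", "n5": "N5"}


# -- detection --------------------------------------------------------------

def test_info_with_scales_detects_precomputed():
    store = {"info": json.dumps({"data_type": "uint8", "scales": []})}
    assert detect_format(store) == "NEUROGLANCER_PRECOMPUTED"


def test_zattrs_with_multiscales_detects_ome_zarr():
    store = {".zgroup": '{"zarr_format": 2}', ".zattrs": '{"multiscales": []}'}
    assert detect_format(store) == "OME_ZARR_V2"


def test_attributes_with_n5_key_detects_n5():
    store = {"attributes.json": '{"n5": "2.5.1"}'}
    assert detect_format(store) == "N5"


def test_empty_tree_is_unrecognized(tmp_path):
    with pytest.raises(FormatDetectionError) as exc:
        detect_format(tmp_path)
    assert exc.value.code == "UNRECOGNIZED_FORMAT"
    with pytest.raises(FormatDetectionError):
        detect_format({})


def test_ambiguous_store_reports_all_matches():
    store = {"info": '{"scales": []}', "attributes.json": '{"n5": "2"}'}
    with pytest.raises(FormatDetectionError) as exc:
        detect_format(store)
    assert exc.value.code == "AMBIGUOUS_FORMAT"
    assert "NEUROGLANCER_PRECOMPUTED" in str(exc.value) and "N5" in str(exc.value)


def test_zarr_v3_is_rejected_with_versioned_message():
    store = {"zarr.json": '{"zarr_format": 3}'}
    with pytest.raises(FormatDetectionError) as exc:
        detect_format(store)
    assert exc.value.code == "ZARR_V3_UNSUPPORTED"
    assert "v2" in str(exc.value)


@pytest.mark.parametrize("fmt", FORMATS)
def test_detection_is_exclusive_on_generated_fixtures(fmt):
    store, _ = generate_container(fmt, "uint8", (16, 16, 16), (4, 4, 40))
    assert detect_format(store) == KINDS[fmt]


# -- parsing ----------------------------------------------------------------

@pytest.mark.parametrize("fmt", FORMATS)
def test_parser_recovers_generated_values(fmt, tmp_path):
    store, expected = generate_container(
        fmt, "uint16", (64, 48, 32), (8.0, 8.0, 30.0), out_tree=tmp_path / fmt,
        n_scales=2)
    descriptor = parse_container(store)
    assert descriptor == expected
    assert descriptor.dtype == "uint16"
    assert descriptor.num_scales == 2
    assert descriptor.scales[0].extent == (64, 48, 32)
    assert descriptor.scales[1].extent == (32, 24, 16)


def test_precomputed_descriptor_from_declared_values():
    store, _ = generate_container("precomputed", "uint8", (64, 64, 64), (4, 4, 40))
    d = parse_container(store, "NEUROGLANCER_PRECOMPUTED")
    assert d.dtype == "uint8"
    assert d.scales[0].extent == (64, 64, 64)
    assert d.scales[0].resolution == (4.0, 4.0, 40.0)
    assert d.scales[0].unit == "nanometer"


def test_cloudvolume_layout_gets_a_provenance_note():
    store, _ = generate_container("cloud-volume", "uint8", (8, 8, 8), (4, 4, 40))
    d = parse_container(store)
    assert d.format_kind == "NEUROGLANCER_PRECOMPUTED"
    assert "cloud-volume" in (d.provenance_note or "")


def test_missing_data_type_is_container_malformed():
    store, _ = generate_container("precomputed", "uint8", (8, 8, 8), (4, 4, 40))
    info = json.loads(store["info"])
    del info["data_type"]
    store["info"] = json.dumps(info)
    with pytest.raises(ContainerError) as exc:
        parse_container(store, "NEUROGLANCER_PRECOMPUTED")
    assert "data_type" in exc.value.key_path


def test_invalid_json_names_the_offending_key():
    store = {".zgroup": '{"zarr_format": 2}', ".zattrs": '{"multiscales": [}'}
    with pytest.raises(ContainerError) as exc:
        parse_container(store, "OME_ZARR_V2")
    assert exc.value.key_path == ".zattrs"


def test_ome_zarr_fixture_is_readable_by_zarr_library(tmp_path):
    """Independent oracle: the zarr package reads the generated store and
    agrees on shape and dtype (axes are written z, y, x)."""
    zarr = pytest.importorskip("zarr")
    store, _ = generate_container("ome-zarr", "uint16", (48, 32, 16), (8, 8, 30),
                                  out_tree=tmp_path)
    arr = zarr.open_array(str(tmp_path / "0"), mode="r", zarr_format=2)
    assert tuple(arr.shape) == (16, 32, 48)
    assert str(arr.dtype) == "uint16"
    descriptor = parse_container(tmp_path)
    assert descriptor.scales[0].extent == (48, 32, 16)
    assert descriptor.dtype == "uint16"


# -- cross-check ------------------------------------------------------------

def test_matching_channel_frame_and_container_yield_no_violations(registry):
    # frame X spans 6400 nm at 4 nm/voxel -> container extent 1600 voxels
    store, _ = generate_container("n5", "uint8", (128, 128, 100), (4, 4, 40))
    descriptor = parse_container(store)
    channel, frame = channel_for_container(registry, "uint8", (128, 128, 100), (4, 4, 40))
    assert frame["Xs"] == [0.0, 512.0]
    assert cross_check_channel(channel, frame, descriptor) == []


def test_dtype_mismatch(registry):
    store, _ = generate_container("precomputed", "uint16", (16, 16, 16), (4, 4, 40))
    descriptor = parse_container(store)
    channel, frame = channel_for_container(registry, "uint8", (16, 16, 16), (4, 4, 40))
    assert [v.rule_code for v in cross_check_channel(channel, frame, descriptor)] == [
        "DTYPE_MISMATCH"
    ]


def test_resolution_mismatch_on_one_axis(registry):
    store, _ = generate_container("precomputed", "uint8", (16, 16, 16), (4, 4, 30))
    descriptor = parse_container(store)
    channel, frame = channel_for_container(registry, "uint8", (16, 16, 16), (4, 4, 40))
    codes = [v.rule_code for v in cross_check_channel(channel, frame, descriptor)]
    assert "RESOLUTION_MISMATCH" in codes


def test_resolution_comparison_converts_units(registry):
    """A container declaring 0.004 micrometer matches a 4 nanometer frame."""
    store, _ = generate_container("n5", "uint8", (16, 16, 16), (4, 4, 40))
    root = json.loads(store["attributes.json"])
    root["resolution"] = [0.004, 0.004, 0.040]
    root["units"] = ["um", "um", "um"]
    store["attributes.json"] = json.dumps(root)
    descriptor = parse_container(store)
    channel, frame = channel_for_container(registry, "uint8", (16, 16, 16), (4, 4, 40))
    assert cross_check_channel(channel, frame, descriptor) == []


def test_extent_mismatch_beyond_half_a_voxel(registry):
    store, _ = generate_container("precomputed", "uint8", (16, 16, 16), (4, 4, 40))
    descriptor = parse_container(store)
    channel, frame = channel_for_container(registry, "uint8", (17, 16, 16), (4, 4, 40))
    codes = [v.rule_code for v in cross_check_channel(channel, frame, descriptor)]
    assert codes == ["EXTENT_MISMATCH"]


def test_store_without_chunk_payload_warns(registry):
    store, _ = generate_container("precomputed", "uint8", (16, 16, 16), (4, 4, 40))
    for key in [k for k in store if k != "info"]:
        del store[key]
    descriptor = parse_container(store)
    channel, frame = channel_for_container(registry, "uint8", (16, 16, 16), (4, 4, 40))
    violations = cross_check_channel(channel, frame, descriptor)
    assert [v.rule_code for v in violations] == ["CHUNKS_MISSING"]
    assert violations[0].severity == "warning"
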