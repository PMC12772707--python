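"""Compliance checking of the four sanctioned volumetric container formats.

The standard requires published imaging volumes to be stored as OME-Zarr
(Zarr spec v2), Neuroglancer precomputed, N5, or a cloud-volume layout (which
is the precomputed layout plus a ``provenance`` file).  Compliance here is
*metadata-only*: the standard governs format choice and declared geometry,
not pixel values, so chunk payloads are never decoded — only their presence
is probed, as a warning-level completeness check.

A *store* is either a directory path or an in-memory mapping of POSIX-style
relative key -> bytes/str, mirroring the key-value stores these formats
live in.

Sentinels honored bit-exactly:

* OME-Zarr v2 — ``.zgroup``/``.zattrs`` with a ``multiscales`` attribute
  (multiscales metadata version 0.4), per-dataset ``.zarray``
* Neuroglancer precomputed — top-level ``info`` JSON with ``scales``
* N5 — ``attributes.json`` carrying an ``n5`` version key; n5-viewer style
  ``resolution``/``units``/``scales`` root attributes
* Zarr v3 stores (``zarr.json``) are explicitly rejected: the standard
  pins Zarr spec v2 until it is revised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .entities import Entity
from .errors import ContainerError, FormatDetectionError
from .validation import RULES, Violation

OME_ZARR_V2 = "OME_ZARR_V2"
NEUROGLANCER_PRECOMPUTED = "NEUROGLANCER_PRECOMPUTED"
N5 = "N5"
FORMAT_KINDS = (OME_ZARR_V2, NEUROGLANCER_PRECOMPUTED, N5)

#: nanometers per unit, for resolution comparison across declared units
_UNIT_NM = {
    "nanometer": 1.0, "nm": 1.0,
    "micrometer": 1e3, "um": 1e3, "µm": 1e3, "micron": 1e3,
    "millimeter": 1e6, "mm": 1e6,
    "centimeter": 1e7, "cm": 1e7,
}

RESOLUTION_RTOL = 1e-6     # relative tolerance on declared voxel size
EXTENT_TOL_VOXELS = 0.5    # frame extent may differ by < half a voxel


@dataclass(frozen=True)
class ScaleLevel:
    extent: tuple[int, int, int]                 # voxels, (x, y, z)
    chunk_shape: tuple[int, int, int] | None
    resolution: tuple[float, float, float] | None  # per axis, in `unit`
    unit: str | None


@dataclass
class ContainerDescriptor:
    format_kind: str
    dtype: str
    scales: list[ScaleLevel] = field(default_factory=list)
    has_chunks: bool = False
    provenance_note: str | None = None

    @property
    def num_scales(self) -> int:
        return len(self.scales)


# ---------------------------------------------------------------------------
# store access

def _get(store: Path | Mapping, key: str) -> bytes | None:
    if isinstance(store, (str, Path)):
        p = Path(store) / key
        return p.read_bytes() if p.is_file() else None
    value = store.get(key)
    if value is None:
        return None
    return value.encode("utf-8") if isinstance(value, str) else value


def _keys(store: Path | Mapping) -> list[str]:
    if isinstance(store, (str, Path)):
        root = Path(store)
        if not root.is_dir():
            return []
        return sorted(p.relative_to(root).as_posix() for p in root.rglob("*") if p.is_file())
    return sorted(store)


def _json(store, key: str, *, required: bool, kind: str) -> Any:
    raw = _get(store, key)
    if raw is None:
        if required:
            raise ContainerError(f"{kind}: missing {key}", key)
        return None
    try:
        return json.loads(raw.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        raise ContainerError(f"{kind}: {key} is not valid JSON: {exc}", key) from exc


# ---------------------------------------------------------------------------
# detection

def detect_format(store: Path | Mapping) -> str:
    """Identify the container format from its sentinel files.

    Raises :class:`FormatDetectionError` when no sentinel is found
    (``UNRECOGNIZED_FORMAT``), when several match (``AMBIGUOUS_FORMAT``,
    listing all candidates), or for a Zarr v3 store (``ZARR_V3_UNSUPPORTED``).
    """
    if _get(store, "zarr.json") is not None:
        raise FormatDetectionError(
            "Zarr specification v3 store found; the standard (v1.1) pins Zarr "
            "spec v2 and will adopt v3 in a future revision",
            code="ZARR_V3_UNSUPPORTED",
        )
    matches: list[str] = []

    zattrs = _get(store, ".zattrs")
    if zattrs is not None:
        attrs = _json(store, ".zattrs", required=True, kind="OME-Zarr")
        if isinstance(attrs, dict) and "multiscales" in attrs:
            matches.append(OME_ZARR_V2)

    info_raw = _get(store, "info")
    if info_raw is not None:
        try:
            info = json.loads(info_raw.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError):
            info = None
        if isinstance(info, dict) and "scales" in info:
            matches.append(NEUROGLANCER_PRECOMPUTED)

    attributes = _get(store, "attributes.json")
    if attributes is not None:
        try:
            attrs = json.loads(attributes.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError):
            attrs = None
        if isinstance(attrs, dict) and "n5" in attrs:
            matches.append(N5)

    if not matches:
        raise FormatDetectionError(
            "no sanctioned container sentinel found "
            "(.zattrs multiscales / info scales / attributes.json n5)",
            code="UNRECOGNIZED_FORMAT",
        )
    if len(matches) > 1:
        raise FormatDetectionError(
            f"ambiguous store: sentinels match {', '.join(matches)}",
            code="AMBIGUOUS_FORMAT",
        )
    return matches[0]


def _is_cloudvolume_layout(store) -> bool:
    raw = _get(store, "provenance")
    if raw is None:
        return False
    try:
        json.loads(raw.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError):
        return False
    return True


# ---------------------------------------------------------------------------
# parsing (metadata files only, never chunk payloads)

def _triple(value: Any, key_path: str, kind: str, cast=float) -> tuple:
    if not isinstance(value, (list, tuple)) or len(value) != 3:
        raise ContainerError(f"{kind}: expected a 3-element list", key_path)
    try:
        return tuple(cast(v) for v in value)
    except (TypeError, ValueError) as exc:
        raise ContainerError(f"{kind}: non-numeric entry {value!r}", key_path) from exc


def _check_positive(values, key_path: str, kind: str) -> None:
    if any(v <= 0 for v in values):
        raise ContainerError(f"{kind}: entries must be positive, got {values}", key_path)


def _parse_precomputed(store) -> ContainerDescriptor:
    info = _json(store, "info", required=True, kind="precomputed")
    if not isinstance(info, dict):
        raise ContainerError("precomputed: info must be a JSON object", "info")
    if "data_type" not in info:
        raise ContainerError("precomputed: missing mandatory key", "info/data_type")
    if "scales" not in info or not isinstance(info["scales"], list) or not info["scales"]:
        raise ContainerError("precomputed: missing or empty scales", "info/scales")
    scales = []
    meta_keys = {"info", "provenance"}
    for i, s in enumerate(info["scales"]):
        kp = f"info/scales[{i}]"
        if not isinstance(s, dict):
            raise ContainerError("precomputed: scale must be an object", kp)
        for req in ("size", "resolution", "chunk_sizes"):
            if req not in s:
                raise ContainerError("precomputed: missing mandatory key", f"{kp}/{req}")
        size = _triple(s["size"], f"{kp}/size", "precomputed", int)
        resolution = _triple(s["resolution"], f"{kp}/resolution", "precomputed")
        if not s["chunk_sizes"]:
            raise ContainerError("precomputed: empty chunk_sizes", f"{kp}/chunk_sizes")
        chunk = _triple(s["chunk_sizes"][0], f"{kp}/chunk_sizes[0]", "precomputed", int)
        _check_positive(size, f"{kp}/size", "precomputed")
        _check_positive(chunk, f"{kp}/chunk_sizes[0]", "precomputed")
        # precomputed resolutions are nanometers by definition
        scales.append(ScaleLevel(size, chunk, resolution, "nanometer"))
    note = "cloud-volume layout (precomputed plus provenance file)" \
        if _is_cloudvolume_layout(store) else None
    has_chunks = any(k not in meta_keys for k in _keys(store))
    return ContainerDescriptor(
        NEUROGLANCER_PRECOMPUTED, str(info["data_type"]), scales, has_chunks, note
    )


_ZARR_DTYPES = {
    "|u1": "uint8", "<u2": "uint16", ">u2": "uint16", "<u4": "uint32", ">u4": "uint32",
    "<u8": "uint64", ">u8": "uint64", "|i1": "int8", "<i2": "int16", "<i4": "int32",
    "<i8": "int64", "<f4": "float32", ">f4": "float32", "<f8": "float64", ">f8": "float64",
}


def _parse_ome_zarr(store) -> ContainerDescriptor:
    attrs = _json(store, ".zattrs", required=True, kind="OME-Zarr")
    multiscales = attrs.get("multiscales")
    if not isinstance(multiscales, list) or not multiscales:
        raise ContainerError("OME-Zarr: multiscales must be a non-empty list",
                             ".zattrs/multiscales")
    ms = multiscales[0]
    axes = ms.get("axes")
    if not isinstance(axes, list) or not axes:
        raise ContainerError("OME-Zarr: missing axes", ".zattrs/multiscales[0]/axes")
    axis_names = [a.get("name") for a in axes]
    spatial = [n for n in axis_names if n in ("x", "y", "z")]
    if sorted(spatial) != ["x", "y", "z"]:
        raise ContainerError("OME-Zarr: axes must include x, y and z",
                             ".zattrs/multiscales[0]/axes")
    units = {a.get("name"): a.get("unit") for a in axes}
    datasets = ms.get("datasets")
    if not isinstance(datasets, list) or not datasets:
        raise ContainerError("OME-Zarr: missing datasets", ".zattrs/multiscales[0]/datasets")

    def to_xyz(values, cast=float):
        by_name = dict(zip(axis_names, values))
        return tuple(cast(by_name[n]) for n in ("x", "y", "z"))

    scales, dtype = [], None
    meta_keys = {".zgroup", ".zattrs"}
    for i, ds in enumerate(datasets):
        kp = f".zattrs/multiscales[0]/datasets[{i}]"
        path = ds.get("path")
        if not isinstance(path, str):
            raise ContainerError("OME-Zarr: dataset missing path", f"{kp}/path")
        zarray = _json(store, f"{path}/.zarray", required=True, kind="OME-Zarr")
        meta_keys.add(f"{path}/.zarray")
        if zarray.get("zarr_format") != 2:
            raise ContainerError("OME-Zarr: zarr_format must be 2", f"{path}/.zarray/zarr_format")
        for req in ("shape", "chunks", "dtype"):
            if req not in zarray:
                raise ContainerError("OME-Zarr: missing mandatory key", f"{path}/.zarray/{req}")
        if len(zarray["shape"]) != len(axis_names):
            raise ContainerError("OME-Zarr: shape rank != axes rank", f"{path}/.zarray/shape")
        level_dtype = _ZARR_DTYPES.get(zarray["dtype"], str(zarray["dtype"]))
        dtype = dtype or level_dtype
        resolution = None
        for tf in ds.get("coordinateTransformations", []):
            if tf.get("type") == "scale":
                resolution = to_xyz(tf.get("scale", []))
        extent = to_xyz(zarray["shape"], int)
        chunk = to_xyz(zarray["chunks"], int)
        _check_positive(extent, f"{path}/.zarray/shape", "OME-Zarr")
        unit = units.get("x") or "nanometer"
        scales.append(ScaleLevel(extent, chunk, resolution, unit))
    has_chunks = any(k not in meta_keys for k in _keys(store))
    return ContainerDescriptor(OME_ZARR_V2, dtype or "unknown", scales, has_chunks)


def _parse_n5(store) -> ContainerDescriptor:
    root = _json(store, "attributes.json", required=True, kind="N5")
    if "n5" not in root:
        raise ContainerError("N5: missing version key", "attributes.json/n5")
    factors = root.get("scales") or [[1, 1, 1]]
    resolution = root.get("resolution")
    units = root.get("units")
    unit = units[0] if isinstance(units, list) and units else None
    base = _triple(resolution, "attributes.json/resolution", "N5") if resolution else None
    scales = []
    meta_keys = {"attributes.json"}
    for i, factor in enumerate(factors):
        key = f"s{i}/attributes.json"
        ds = _json(store, key, required=True, kind="N5")
        meta_keys.add(key)
        for req in ("dimensions", "blockSize", "dataType"):
            if req not in ds:
                raise ContainerError("N5: missing mandatory key", f"{key}/{req}")
        extent = _triple(ds["dimensions"], f"{key}/dimensions", "N5", int)
        chunk = _triple(ds["blockSize"], f"{key}/blockSize", "N5", int)
        _check_positive(extent, f"{key}/dimensions", "N5")
        fx = _triple(factor, f"attributes.json/scales[{i}]", "N5")
        level_res = tuple(b * f for b, f in zip(base, fx)) if base else None
        scales.append(ScaleLevel(extent, chunk, level_res, unit))
    if not scales:
        raise ContainerError("N5: no scale levels declared", "attributes.json/scales")
    dtype = _json(store, "s0/attributes.json", required=True, kind="N5")["dataType"]
    has_chunks = any(k not in meta_keys for k in _keys(store))
    return ContainerDescriptor(N5, str(dtype), scales, has_chunks)


def parse_container(store: Path | Mapping, format_kind: str | None = None) -> ContainerDescriptor:
    """Parse a store's container metadata into a :class:`ContainerDescriptor`.

    ``format_kind`` defaults to :func:`detect_format`'s answer.  Raises
    :class:`ContainerError` (with the offending key path) when mandatory
    metadata is missing or malformed.
    """
    if format_kind is None:
        format_kind = detect_format(store)
    if format_kind == NEUROGLANCER_PRECOMPUTED or format_kind == "CLOUDVOLUME":
        return _parse_precomputed(store)
    if format_kind == OME_ZARR_V2:
        return _parse_ome_zarr(store)
    if format_kind == N5:
        return _parse_n5(store)
    raise FormatDetectionError(f"unknown format kind {format_kind!r}", code="UNRECOGNIZED_FORMAT")


# ---------------------------------------------------------------------------
# cross-check against channel metadata

def _to_nm(value: float, unit: str | None) -> float | None:
    factor = _UNIT_NM.get((unit or "").strip().lower())
    return None if factor is None else value * factor


def cross_check_channel(
    channel: Entity, coordinate_frame: Entity, descriptor: ContainerDescriptor
) -> list[Violation]:
    """Check a channel + frame pair against a parsed container.

    Fires DTYPE_MISMATCH when the container's dtype differs from the
    channel's declared DataType, RESOLUTION_MISMATCH when the container's
    scale-0 voxel size differs from VoxelSize beyond relative tolerance
    1e-6 (units converted), and EXTENT_MISMATCH when the frame extent in
    voxels — (max - min) / resolution per axis, nearest integer within half
    a voxel — differs from the container's scale-0 extent.  A store with no
    chunk payload at all gets a CHUNKS_MISSING warning.
    """
    out: list[Violation] = []
    path = f"channel/{channel.id or '?'}"

    declared = channel.get("DataType")
    if isinstance(declared, str) and declared != descriptor.dtype:
        out.append(Violation("DTYPE_MISMATCH", path, RULES["DTYPE_MISMATCH"],
                             f"channel DataType {declared!r} != container dtype "
                             f"{descriptor.dtype!r}"))

    voxel = coordinate_frame.get("VoxelSize")
    scale0 = descriptor.scales[0] if descriptor.scales else None
    frame_res_nm: list[float | None] = [None, None, None]
    if isinstance(voxel, Entity):
        unit = voxel.get("Unit")
        for i, axis in enumerate(("X", "Y", "Z")):
            v = voxel.get(axis)
            if isinstance(v, (int, float)):
                frame_res_nm[i] = _to_nm(float(v), unit)

    if scale0 is not None and scale0.resolution is not None:
        for i, axis in enumerate(("X", "Y", "Z")):
            want = frame_res_nm[i]
            got = _to_nm(scale0.resolution[i], scale0.unit)
            if want is None or got is None:
                continue
            if abs(got - want) > RESOLUTION_RTOL * max(abs(want), 1e-30):
                out.append(Violation(
                    "RESOLUTION_MISMATCH", path, RULES["RESOLUTION_MISMATCH"],
                    f"{axis}: container resolution {scale0.resolution[i]} {scale0.unit} "
                    f"!= VoxelSize {want} nanometer"))
                break

    if scale0 is not None:
        for i, axis_field in enumerate(("Xs", "Ys", "Zs")):
            ext = coordinate_frame.get(axis_field)
            res = None
            if isinstance(voxel, Entity):
                res = voxel.get(("X", "Y", "Z")[i])
            if (not isinstance(ext, list) or len(ext) != 2
                    or not isinstance(res, (int, float)) or res <= 0):
                continue
            voxels = (float(ext[1]) - float(ext[0])) / float(res)
            if abs(voxels - scale0.extent[i]) > EXTENT_TOL_VOXELS:
                out.append(Violation(
                    "EXTENT_MISMATCH", path, RULES["EXTENT_MISMATCH"],
                    f"{axis_field}: frame spans {voxels:g} voxels but container "
                    f"declares {scale0.extent[i]}"))

    if not descriptor.has_chunks:
        out.append(Violation("CHUNKS_MISSING", path, RULES["CHUNKS_MISSING"],
                             "container declares data but holds no chunk payload"))
    return out
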