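"""Reading and writing metadata bundles as canonical JSON documents.

A *bundle* is one JSON document holding one or more Project trees together
with tables of the hierarchy entities (Collections, Experiments, Channels,
CoordinateFrames) keyed by ID.  Parents reference children by ID string;
children may equivalently be written inline, in which case reading hoists
them into the tables and replaces them with references, so both spellings
parse to the same bundle.

Canonical serialization: UTF-8, top-level sections in fixed order, table
keys sorted, entity keys in registry declaration order, dates ISO-8601,
floats in their shortest round-trip form.  Writing a canonical document is a
fixpoint: ``write(read(doc)) == doc`` byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .entities import Entity, build_entity, entities_equal, entity_to_plain
from .errors import BundleParseError
from .registry import HIERARCHY_CLASSES, SchemaRegistry

#: top-level document section name per hierarchy class, in canonical order
SECTIONS = {
    "Project": "Projects",
    "Collection": "Collections",
    "Experiment": "Experiments",
    "Channel": "Channels",
    "CoordinateFrame": "CoordinateFrames",
}
_SECTION_TO_CLASS = {v: k for k, v in SECTIONS.items()}


@dataclass
class MetadataBundle:
    """One deserialized document: entity tables cross-linked by ID."""

    standard_version: str
    tables: dict[str, dict[str, Entity]] = field(default_factory=dict)
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in HIERARCHY_CLASSES:
            self.tables.setdefault(cls, {})

    @property
    def projects(self) -> list[Entity]:
        return list(self.tables["Project"].values())

    def get(self, class_name: str, entity_id: str) -> Entity | None:
        return self.tables.get(class_name, {}).get(entity_id)

    def entity_count(self) -> int:
        return sum(len(t) for t in self.tables.values())


def _reject_duplicate_keys(pairs: list[tuple[str, Any]]) -> dict:
    seen: set[str] = set()
    for key, _ in pairs:
        if key in seen:
            raise BundleParseError(f"duplicate key {key!r} in document")
        seen.add(key)
    return dict(pairs)


def _hoist(
    registry: SchemaRegistry,
    bundle: MetadataBundle,
    class_name: str,
    raw: Mapping,
    location: str,
    implied_id: str | None = None,
) -> str:
    """Register an inline entity in its table; return its ID."""
    raw = dict(raw)
    entity_id = raw.pop("ID", None) if class_name == "CoordinateFrame" else raw.get("ID")
    if entity_id is None:
        entity_id = implied_id
    if entity_id is None:
        raise BundleParseError(f"inline {class_name} lacks an ID", location)
    if not isinstance(entity_id, str):
        raise BundleParseError(f"{class_name} ID must be a string", location)
    entity = _build_hierarchy_entity(registry, bundle, class_name, raw, f"{location}/{entity_id}")
    table = bundle.tables[class_name]
    if entity_id in table:
        if not entities_equal(table[entity_id], entity):
            raise BundleParseError(
                f"duplicate {class_name} ID {entity_id!r} with conflicting content", location
            )
    else:
        table[entity_id] = entity
    return entity_id


def _build_hierarchy_entity(
    registry: SchemaRegistry,
    bundle: MetadataBundle,
    class_name: str,
    raw: Mapping,
    location: str,
) -> Entity:
    """Build an entity, normalizing any inline children to ID references."""
    desc = registry.describe_class(class_name)
    normalized: dict[str, Any] = {}
    for key, value in raw.items():
        if key in desc and desc.field(key).reference:
            fd = desc.field(key)
            target = fd.datatype.name
            if fd.datatype.is_list:
                if not isinstance(value, (list, tuple)):
                    raise BundleParseError(
                        f"{class_name}.{key} must be a list", location
                    )
                refs = []
                for i, item in enumerate(value):
                    if isinstance(item, Mapping):
                        refs.append(_hoist(registry, bundle, target, item, f"{location}/{key}[{i}]"))
                    else:
                        refs.append(item)
                normalized[key] = refs
            else:
                if isinstance(value, Mapping):
                    implied = None
                    if target == "CoordinateFrame":
                        owner = raw.get("ID") or location.rsplit("/", 1)[-1]
                        implied = f"{owner}-frame"
                    normalized[key] = _hoist(
                        registry, bundle, target, value, f"{location}/{key}", implied_id=implied
                    )
                else:
                    normalized[key] = value
        else:
            normalized[key] = value
    return build_entity(registry, class_name, normalized)


def read_bundle(
    registry: SchemaRegistry, document: Mapping | str | bytes | Path
) -> MetadataBundle:
    """Parse a JSON document (mapping, JSON text/bytes, or file path).

    Raises :class:`BundleParseError` on anything that prevents building the
    bundle at all: non-object documents, duplicate IDs, malformed JSON or
    non-UTF-8 input.  Everything else — missing required fields, bad enum
    members, dangling references — is left for validation to report.
    """
    if isinstance(document, Path):
        document = document.read_bytes()
    if isinstance(document, bytes):
        try:
            document = document.decode("utf-8")
        except UnicodeDecodeError as exc:
            raise BundleParseError(f"document is not UTF-8: {exc}") from exc
    if isinstance(document, str):
        try:
            document = json.loads(document, object_pairs_hook=_reject_duplicate_keys)
        except json.JSONDecodeError as exc:
            raise BundleParseError(
                f"malformed JSON: {exc.msg}", f"line {exc.lineno} column {exc.colno}"
            ) from exc
    if not isinstance(document, Mapping):
        raise BundleParseError("document must be a JSON object")

    bundle = MetadataBundle(standard_version=str(document.get("StandardVersion", registry.version)))

    for section, raw_table in document.items():
        if section == "StandardVersion":
            continue
        cls = _SECTION_TO_CLASS.get(section)
        if cls is None:
            bundle.extras[section] = raw_table  # quarantined, flagged by validation
            continue
        if isinstance(raw_table, Mapping):
            items = list(raw_table.items())
        elif isinstance(raw_table, (list, tuple)):
            items = [(None, item) for item in raw_table]
        else:
            raise BundleParseError(f"section {section} must be an object or list", section)
        for key, raw_entity in items:
            if not isinstance(raw_entity, Mapping):
                raise BundleParseError(f"entries of {section} must be objects", section)
            raw_entity = dict(raw_entity)
            declared = raw_entity.get("ID")
            if key is not None and declared is not None and key != declared:
                raise BundleParseError(
                    f"table key {key!r} != entity ID {declared!r}", f"{section}/{key}"
                )
            if key is not None and cls != "CoordinateFrame":
                raw_entity.setdefault("ID", key)
            if key is not None and cls == "CoordinateFrame":
                raw_entity.setdefault("ID", key)
            _hoist(registry, bundle, cls, raw_entity, section)
    return bundle


def write_bundle(registry: SchemaRegistry, bundle: MetadataBundle) -> dict[str, Any]:
    """Render a bundle as a plain canonical document (JSON-ready dict)."""
    doc: dict[str, Any] = {"StandardVersion": bundle.standard_version}
    for cls in HIERARCHY_CLASSES:
        table = bundle.tables.get(cls, {})
        if not table and cls != "Project":
            continue
        section: dict[str, Any] = {}
        for entity_id in sorted(table):
            section[entity_id] = entity_to_plain(registry, table[entity_id])
        doc[SECTIONS[cls]] = section
    for key in sorted(bundle.extras):
        doc[key] = bundle.extras[key]
    return doc


def serialize_bundle(registry: SchemaRegistry, bundle: MetadataBundle) -> str:
    """Canonical JSON text for a bundle (the fixpoint form)."""
    return json.dumps(write_bundle(registry, bundle), indent=2, ensure_ascii=False) + "\n"


def bundles_equal(a: MetadataBundle, b: MetadataBundle) -> bool:
    """Deep structural equality between two bundles."""
    if a.standard_version != b.standard_version or a.extras != b.extras:
        return False
    for cls in HIERARCHY_CLASSES:
        ta, tb = a.tables.get(cls, {}), b.tables.get(cls, {})
        if set(ta) != set(tb):
            return False
        if any(not entities_equal(ta[k], tb[k]) for k in ta):
            return False
    return True
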