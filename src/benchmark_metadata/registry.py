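"""Schema registry for the BENCHMARK v1.1 connectomics metadata standard.

The standard defines 18 metadata classes (Project down to Link), their fields
with declared types and required flags, and a set of closed enumerations. The
authoritative machine-readable definition ships with the package as JSON; this
module loads it into typed descriptors that validation, serialization and the
CLI all introspect, so there is a single source of truth.

Datatype grammar used in the definition:

* primitives: ``String``, ``Int``, ``Float``, ``Boolean``, ``Date``
* enum reference: ``Enum:<EnumName>``
* class reference: ``Class:<ClassName>``
* list of any of the above: wrapped in brackets, e.g. ``[Class:Channel]``

A field may additionally carry ``reference: true``, meaning its values are ID
strings resolved against the bundle's entity tables rather than inline
objects, and ``min_items`` for "must be at least one" cardinality rules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import SchemaError, UnknownClassError, UnknownEnumError

PRIMITIVES = frozenset({"String", "Int", "Float", "Boolean", "Date"})

#: Classes that live in bundle-level tables keyed by ID and may be referenced
#: by ID string from other entities.  All other classes are always inline.
HIERARCHY_CLASSES = ("Project", "Collection", "Experiment", "Channel", "CoordinateFrame")


@dataclass(frozen=True)
class Datatype:
    """Parsed form of a datatype string."""

    kind: str          # "primitive" | "enum" | "class"
    name: str          # e.g. "String", "Species", "Channel"
    is_list: bool

    def __str__(self) -> str:
        inner = self.name if self.kind == "primitive" else f"{self.kind.title()}:{self.name}"
        return f"[{inner}]" if self.is_list else inner


def parse_datatype(spec: str) -> Datatype:
    is_list = spec.startswith("[") and spec.endswith("]")
    inner = spec[1:-1] if is_list else spec
    if inner in PRIMITIVES:
        return Datatype("primitive", inner, is_list)
    if inner.startswith("Enum:"):
        return Datatype("enum", inner[5:], is_list)
    if inner.startswith("Class:"):
        return Datatype("class", inner[6:], is_list)
    raise SchemaError(f"unparseable datatype {spec!r}")


@dataclass(frozen=True)
class FieldDescriptor:
    name: str
    description: str
    datatype: Datatype
    required: bool
    reference: bool = False
    min_items: int | None = None


@dataclass(frozen=True)
class ClassDescriptor:
    name: str
    description: str
    fields: tuple[FieldDescriptor, ...]

    @property
    def field_count(self) -> int:
        return len(self.fields)

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def field(self, name: str) -> FieldDescriptor:
        for f in self.fields:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.fields)


@dataclass
class SchemaRegistry:
    """All classes and enumerations of one version of the standard."""

    version: str
    classes: dict[str, ClassDescriptor]
    enums: dict[str, tuple[str, ...]]
    enum_aliases: dict[str, str] = field(default_factory=dict)

    # -- lookups ------------------------------------------------------------

    def describe_class(self, class_name: str) -> ClassDescriptor:
        try:
            return self.classes[class_name]
        except KeyError:
            raise UnknownClassError(class_name, sorted(self.classes)) from None

    def list_enum_members(self, enum_name: str) -> list[str]:
        try:
            return list(self.enums[enum_name])
        except KeyError:
            raise UnknownEnumError(enum_name, sorted(self.enums)) from None

    def is_enum_member(self, enum_name: str, value: object) -> bool:
        """Case-sensitive membership test; non-strings are never members."""
        return isinstance(value, str) and value in self.enums.get(enum_name, ())

    def normalize_enum_value(self, value: object) -> object:
        """Apply registered read-aliases (e.g. GRID -> GRDI)."""
        if isinstance(value, str) and value in self.enum_aliases:
            return self.enum_aliases[value]
        return value

    # -- integrity ----------------------------------------------------------

    def check_integrity(self) -> None:
        """Raise SchemaError if any registry invariant fails."""
        if len(self.classes) != 18:
            raise SchemaError(f"expected 18 classes, found {len(self.classes)}")
        for cls in self.classes.values():
            seen: set[str] = set()
            for f_ in cls.fields:
                if f_.name in seen:
                    raise SchemaError(f"duplicate field {cls.name}.{f_.name}")
                seen.add(f_.name)
                dt = f_.datatype
                if dt.kind == "enum" and dt.name not in self.enums:
                    raise SchemaError(
                        f"{cls.name}.{f_.name} references unknown enum {dt.name}"
                    )
                if dt.kind == "class" and dt.name not in self.classes:
                    raise SchemaError(
                        f"{cls.name}.{f_.name} references unknown class {dt.name}"
                    )
                if f_.reference and (dt.kind != "class" or dt.name not in HIERARCHY_CLASSES):
                    raise SchemaError(
                        f"{cls.name}.{f_.name} is a reference to a non-hierarchy type"
                    )


def _default_definition() -> dict:
    text = resources.files("benchmark_metadata").joinpath("data/schema_v1_1.json").read_text(
        encoding="utf-8"
    )
    return json.loads(text)


def load_registry(config: Mapping | str | Path | None = None) -> SchemaRegistry:
    """Load the bundled schema definition into a :class:`SchemaRegistry`.

    Parameters
    ----------
    config
        Optional extension config: a mapping (or path to a JSON file) of the
        form ``{"enums": {"Species": ["Danio rerio", ...]}}``.  Open-ended
        enumerations (Species, DataType, GeneralModality,
        ImagingModalityGeneral, ImagingModalitySpecific, VoxelUnit) may be
        extended; the DataCite-derived closed vocabularies may not.
    """
    try:
        raw = _default_definition()
        classes = {}
        for c in raw["classes"]:
            fields = tuple(
                FieldDescriptor(
                    name=fr["name"],
                    description=fr.get("description", ""),
                    datatype=parse_datatype(fr["datatype"]),
                    required=bool(fr["required"]),
                    reference=bool(fr.get("reference", False)),
                    min_items=fr.get("min_items"),
                )
                for fr in c["fields"]
            )
            classes[c["name"]] = ClassDescriptor(c["name"], c.get("description", ""), fields)
        enums = {name: tuple(members) for name, members in raw["enums"].items()}
        registry = SchemaRegistry(
            version=raw["version"],
            classes=classes,
            enums=enums,
            enum_aliases=dict(raw.get("enum_aliases", {})),
        )
    except (KeyError, TypeError, json.JSONDecodeError) as exc:
        raise SchemaError(f"bundled schema definition is malformed: {exc}") from exc

    if config is not None:
        registry = _apply_config(registry, config)
    registry.check_integrity()
    return registry


_EXTENSIBLE_ENUMS = frozenset(
    {"Species", "DataType", "GeneralModality", "ImagingModalityGeneral",
     "ImagingModalitySpecific", "VoxelUnit"}
)


def _apply_config(registry: SchemaRegistry, config: Mapping | str | Path) -> SchemaRegistry:
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text(encoding="utf-8"))
    if not isinstance(config, Mapping):
        raise SchemaError("config must be a mapping or a path to a JSON file")
    extra: Mapping[str, Iterable[str]] = config.get("enums", {})
    enums = dict(registry.enums)
    for name, members in extra.items():
        if name not in enums:
            raise UnknownEnumError(name, sorted(enums))
        if name not in _EXTENSIBLE_ENUMS:
            raise SchemaError(f"enum {name!r} is closed and cannot be extended")
        merged = list(enums[name]) + [m for m in members if m not in enums[name]]
        enums[name] = tuple(merged)
    return SchemaRegistry(
        version=registry.version,
        classes=registry.classes,
        enums=enums,
        enum_aliases=registry.enum_aliases,
    )


def describe_class(registry: SchemaRegistry, class_name: str) -> ClassDescriptor:
    """Functional alias for :meth:`SchemaRegistry.describe_class`."""
    return registry.describe_class(class_name)


def list_enum_members(registry: SchemaRegistry, enum_name: str) -> list[str]:
    """Functional alias for :meth:`SchemaRegistry.list_enum_members`."""
    return registry.list_enum_members(enum_name)
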