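"""Generic metadata entities built against the schema registry.

Rather than one static class per metadata type, entities are generic records
whose shape is dictated by the registry — the registry is the single source of
truth, so a new standard version means a new definition file, not new code.

Unknown field names are never silently dropped: they are quarantined in the
entity's ``extras`` map and surface later as validation warnings.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field as _field
from typing import Any, Mapping

from .errors import FieldTypeError
from .registry import ClassDescriptor, Datatype, FieldDescriptor, SchemaRegistry

_YEAR_RE = re.compile(r"^\d{4}$")
_INT_RE = re.compile(r"^[+-]?\d+$")


@dataclass
class Entity:
    """One instance of a registry class: declared fields plus quarantined extras."""

    class_name: str
    values: dict[str, Any] = _field(default_factory=dict)
    extras: dict[str, Any] = _field(default_factory=dict)

    def get(self, name: str, default: Any = None) -> Any:
        return self.values.get(name, default)

    def __getitem__(self, name: str) -> Any:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    @property
    def id(self) -> str | None:
        return self.values.get("ID")


def _coerce_primitive(value: Any, kind: str, cls: str, name: str) -> Any:
    err = lambda: FieldTypeError(cls, name, kind, value)
    if kind == "String":
        if isinstance(value, str):
            return value
        raise err()
    if kind == "Boolean":
        if isinstance(value, bool):
            return value
        raise err()
    if kind == "Int":
        if isinstance(value, bool):
            raise err()
        if isinstance(value, int):
            return value
        if isinstance(value, str) and _INT_RE.match(value.strip()):
            return int(value)
        raise err()
    if kind == "Float":
        if isinstance(value, bool):
            raise err()
        if isinstance(value, float):
            return value
        if isinstance(value, int):
            return float(value)
        if isinstance(value, str):
            try:
                return float(value)
            except ValueError:
                raise err() from None
        raise err()
    if kind == "Date":
        return _coerce_date(value, cls, name)
    raise AssertionError(f"unhandled primitive {kind}")


def _coerce_date(value: Any, cls: str, name: str) -> str:
    """Normalize to ISO-8601: full dates to YYYY-MM-DD, bare years to YYYY."""
    if isinstance(value, _dt.datetime):
        return value.date().isoformat()
    if isinstance(value, _dt.date):
        return value.isoformat()
    if isinstance(value, int) and not isinstance(value, bool) and 1000 <= value <= 9999:
        return str(value)
    if isinstance(value, str):
        s = value.strip()
        if _YEAR_RE.match(s):
            return s
        try:
            return _dt.date.fromisoformat(s).isoformat()
        except ValueError:
            pass
    raise FieldTypeError(cls, name, "Date (ISO-8601 or bare year)", value)


def _coerce_value(
    registry: SchemaRegistry, fd: FieldDescriptor, dt: Datatype, value: Any, cls: str
) -> Any:
    if dt.kind == "primitive":
        return _coerce_primitive(value, dt.name, cls, fd.name)
    if dt.kind == "enum":
        if not isinstance(value, str):
            raise FieldTypeError(cls, fd.name, f"Enum:{dt.name} (string)", value)
        # aliases (e.g. GRID -> GRDI) normalize on read; membership itself is
        # checked at validation time so building never hides a bad document
        return registry.normalize_enum_value(value)
    if dt.kind == "class":
        if fd.reference and isinstance(value, str):
            return value  # ID reference into a bundle table
        if isinstance(value, Entity):
            if value.class_name != dt.name:
                raise FieldTypeError(cls, fd.name, f"Class:{dt.name}", value)
            return value
        if isinstance(value, Mapping):
            return build_entity(registry, dt.name, value)
        expected = f"Class:{dt.name}" + (" or ID string" if fd.reference else "")
        raise FieldTypeError(cls, fd.name, expected, value)
    raise AssertionError(dt.kind)


def build_entity(
    registry: SchemaRegistry, class_name: str, field_values: Mapping[str, Any]
) -> Entity:
    """Build an entity of ``class_name`` from a field-name -> value mapping.

    Values are coerced per the standard's types (string->int/float only when
    the text is a number, int->float always, bare years to Date).  A value
    that cannot be coerced raises :class:`FieldTypeError` naming the field.
    Unknown keys land in ``extras`` and are reported by validation as
    warnings, never dropped.
    """
    desc: ClassDescriptor = registry.describe_class(class_name)
    entity = Entity(class_name=class_name)
    for key, raw in field_values.items():
        if key not in desc:
            entity.extras[key] = raw
            continue
        fd = desc.field(key)
        dt = fd.datatype
        if dt.is_list:
            if not isinstance(raw, (list, tuple)):
                raise FieldTypeError(class_name, key, str(dt), raw)
            value = [
                _coerce_value(registry, fd, Datatype(dt.kind, dt.name, False), v, class_name)
                for v in raw
            ]
        else:
            value = _coerce_value(registry, fd, dt, raw, class_name)
        entity.values[key] = value
    return entity


def entity_to_plain(registry: SchemaRegistry, entity: Entity) -> dict[str, Any]:
    """Convert an entity tree to plain JSON-serializable dicts.

    Keys follow the registry's declaration order (canonical order); extras
    follow, sorted, so nothing quarantined is lost on write.
    """
    desc = registry.describe_class(entity.class_name)
    out: dict[str, Any] = {}
    for fd in desc.fields:
        if fd.name not in entity.values:
            continue
        value = entity.values[fd.name]
        if isinstance(value, Entity):
            out[fd.name] = entity_to_plain(registry, value)
        elif isinstance(value, list):
            out[fd.name] = [
                entity_to_plain(registry, v) if isinstance(v, Entity) else v for v in value
            ]
        else:
            out[fd.name] = value
    for key in sorted(entity.extras):
        out[key] = entity.extras[key]
    return out


def entities_equal(a: Entity, b: Entity) -> bool:
    """Deep structural equality (used by round-trip oracles)."""
    if a.class_name != b.class_name or a.extras != b.extras:
        return False
    if set(a.values) != set(b.values):
        return False
    for key, va in a.values.items():
        vb = b.values[key]
        if isinstance(va, Entity) and isinstance(vb, Entity):
            if not entities_equal(va, vb):
                return False
        elif isinstance(va, list) and isinstance(vb, list):
            if len(va) != len(vb):
                return False
            for xa, xb in zip(va, vb):
                if isinstance(xa, Entity) and isinstance(xb, Entity):
                    if not entities_equal(xa, xb):
                        return False
                elif xa != xb:
                    return False
        elif va != vb:
            return False
    return True
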