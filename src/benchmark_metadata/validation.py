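"""Rules engine checking entities and bundles against the standard.

Every finding is a :class:`Violation` carried in a :class:`ValidationReport`;
validation never raises on bad metadata — untrusted documents must be
checkable end to end (the archive-ingest use case).  Rule codes are drawn
from the closed registry :data:`RULES`.

Structural rules (per entity)
    REQ_MISSING, TYPE_MISMATCH, ENUM_INVALID, CARDINALITY, EXTENT_DEGENERATE,
    UNKNOWN_FIELD (warning), ID_SYNTAX (warning)

Cross-entity rules (per bundle)
    REF_DANGLING, SUBSET_CREATOR / SUBSET_LICENSE / SUBSET_IDENTIFIER
    (children may carry their own creators, licenses and identifiers only if
    they are a subset of their parent's), COORD_MISMATCH (every channel must
    use its experiment's coordinate frame), FRAME_NOT_SHARED (warning: two
    experiments in one project carry structurally identical but distinct
    frames that could be shared).
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Any, Iterable

from .entities import Entity, entities_equal
from .errors import BenchmarkError
from .identifiers import validate_identifier
from .registry import Datatype, FieldDescriptor, SchemaRegistry

ERROR = "error"
WARNING = "warning"

#: Closed registry of rule codes and their severities.
RULES: dict[str, str] = {
    "REQ_MISSING": ERROR,
    "TYPE_MISMATCH": ERROR,
    "ENUM_INVALID": ERROR,
    "CARDINALITY": ERROR,
    "EXTENT_DEGENERATE": ERROR,
    "REF_DANGLING": ERROR,
    "SUBSET_CREATOR": ERROR,
    "SUBSET_LICENSE": ERROR,
    "SUBSET_IDENTIFIER": ERROR,
    "COORD_MISMATCH": ERROR,
    # container cross-check rules (volume compliance)
    "DTYPE_MISMATCH": ERROR,
    "RESOLUTION_MISMATCH": ERROR,
    "EXTENT_MISMATCH": ERROR,
    # warnings
    "UNKNOWN_FIELD": WARNING,
    "ID_SYNTAX": WARNING,
    "FRAME_NOT_SHARED": WARNING,
    "CHUNKS_MISSING": WARNING,
}

_SUBSET_CODES = {"creators": "SUBSET_CREATOR", "licenses": "SUBSET_LICENSE",
                 "identifiers": "SUBSET_IDENTIFIER"}


@dataclass(frozen=True)
class Violation:
    rule_code: str
    entity_path: str
    severity: str
    message: str

    def __post_init__(self) -> None:
        if self.rule_code not in RULES:
            raise BenchmarkError(f"unregistered rule code {self.rule_code!r}")

    def to_dict(self) -> dict[str, str]:
        return {
            "rule_code": self.rule_code,
            "entity_path": self.entity_path,
            "severity": self.severity,
            "message": self.message,
        }


def _v(code: str, path: str, message: str) -> Violation:
    return Violation(code, path, RULES[code], message)


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == ERROR]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == WARNING]

    @property
    def valid(self) -> bool:
        return not self.errors

    @property
    def counts(self) -> dict[str, int]:
        return {ERROR: len(self.errors), WARNING: len(self.warnings)}

    def extend(self, violations: Iterable[Violation]) -> None:
        self.violations.extend(violations)

    def finalize(self) -> "ValidationReport":
        """Deterministic ordering: entity path, then rule code, then message."""
        self.violations.sort(key=lambda v: (v.entity_path, v.rule_code, v.message))
        return self

    def to_dict(self) -> dict[str, Any]:
        return {
            "report_version": "1",
            "valid": self.valid,
            "counts": self.counts,
            "violations": [v.to_dict() for v in self.violations],
        }


# ---------------------------------------------------------------------------
# per-entity structural validation

_YEAR_RE = re.compile(r"^\d{4}$")
_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

#: (class, identifier field, scheme field or fixed scheme) pairs whose syntax
#: is linted when both are present
_IDENTIFIER_FIELDS = [
    ("Contributor", "NameIdentifier", "NameIdentifierScheme"),
    ("Contributor", "AffiliationIdentifier", "AffiliationIdentifierScheme"),
    ("Funding", "FundingReferenceIdentifier", "FundingReferenceIdentifierType"),
    ("Publication", "RelatedIdentifier", "RelatedIdentifierType"),
    ("License", "RightsIdentifierDOI", "=DOI"),
]


def _type_ok(value: Any, kind: str) -> bool:
    if kind == "String":
        return isinstance(value, str)
    if kind == "Boolean":
        return isinstance(value, bool)
    if kind == "Int":
        return isinstance(value, int) and not isinstance(value, bool)
    if kind == "Float":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if kind == "Date":
        return isinstance(value, str) and bool(_YEAR_RE.match(value) or _DATE_RE.match(value))
    raise AssertionError(kind)


def _nearest_enum_member(value: str, members: Iterable[str]) -> str | None:
    folded = value.casefold()
    for m in members:
        if m.casefold() == folded:
            return m
    return None


def _check_scalar(
    registry: SchemaRegistry, fd: FieldDescriptor, dt: Datatype, value: Any,
    path: str, cls: str, report: ValidationReport,
) -> None:
    where = f"{path}.{fd.name}"
    if dt.kind == "primitive":
        if not _type_ok(value, dt.name):
            report.violations.append(
                _v("TYPE_MISMATCH", path, f"{cls}.{fd.name}: expected {dt.name}, got {value!r}")
            )
    elif dt.kind == "enum":
        if not registry.is_enum_member(dt.name, value):
            hint = ""
            if isinstance(value, str):
                near = _nearest_enum_member(value, registry.enums[dt.name])
                if near:
                    hint = f"; did you mean {near!r}?"
            report.violations.append(
                _v("ENUM_INVALID", path,
                   f"{cls}.{fd.name}: {value!r} is not a member of {dt.name}{hint}")
            )
    elif dt.kind == "class":
        if fd.reference:
            if not isinstance(value, (str, Entity)):
                report.violations.append(
                    _v("TYPE_MISMATCH", path,
                       f"{cls}.{fd.name}: expected {dt.name} ID reference, got {value!r}")
                )
        elif isinstance(value, Entity) and value.class_name == dt.name:
            _validate_entity_into(registry, value, where, report)
        else:
            report.violations.append(
                _v("TYPE_MISMATCH", path, f"{cls}.{fd.name}: expected inline {dt.name}")
            )


def _check_frame_geometry(entity: Entity, path: str, report: ValidationReport) -> None:
    for axis in ("Xs", "Ys", "Zs"):
        ext = entity.get(axis)
        if not isinstance(ext, list) or len(ext) != 2:
            if ext is not None:
                report.violations.append(
                    _v("EXTENT_DEGENERATE", path, f"{axis} must be [min, max], got {ext!r}")
                )
            continue
        lo, hi = ext
        if isinstance(lo, (int, float)) and isinstance(hi, (int, float)) and not lo < hi:
            report.violations.append(
                _v("EXTENT_DEGENERATE", path, f"{axis} min must be < max, got [{lo}, {hi}]")
            )


def _check_resolution_positive(entity: Entity, path: str, report: ValidationReport) -> None:
    for axis in ("X", "Y", "Z"):
        value = entity.get(axis)
        if isinstance(value, (int, float)) and not isinstance(value, bool) and value <= 0:
            report.violations.append(
                _v("EXTENT_DEGENERATE", path, f"voxel resolution {axis}={value} must be > 0")
            )


def _check_identifier_syntax(entity: Entity, path: str, report: ValidationReport) -> None:
    for cls, id_field, scheme_field in _IDENTIFIER_FIELDS:
        if entity.class_name != cls:
            continue
        value = entity.get(id_field)
        if not isinstance(value, str) or not value:
            continue
        if scheme_field.startswith("="):
            scheme = scheme_field[1:]
        else:
            scheme = entity.get(scheme_field)
        if not isinstance(scheme, str):
            continue
        try:
            check = validate_identifier(scheme, value)
        except BenchmarkError:
            continue  # bad scheme value is already an ENUM_INVALID finding
        if not check.valid:
            report.violations.append(
                _v("ID_SYNTAX", path,
                   f"{cls}.{id_field}: {value!r} fails {scheme} syntax ({check.reason})")
            )


def _validate_entity_into(
    registry: SchemaRegistry, entity: Entity, path: str, report: ValidationReport
) -> None:
    desc = registry.describe_class(entity.class_name)
    for fd in desc.fields:
        present = fd.name in entity.values
        if fd.required and not present:
            report.violations.append(
                _v("REQ_MISSING", path, f"required field {entity.class_name}.{fd.name} is missing")
            )
            continue
        if not present:
            continue
        value = entity.values[fd.name]
        dt = fd.datatype
        if dt.is_list:
            if not isinstance(value, list):
                report.violations.append(
                    _v("TYPE_MISMATCH", path,
                       f"{entity.class_name}.{fd.name}: expected a list, got {value!r}")
                )
                continue
            if fd.min_items and len(value) < fd.min_items:
                report.violations.append(
                    _v("CARDINALITY", path,
                       f"{entity.class_name}.{fd.name} must have at least "
                       f"{fd.min_items} entr{'y' if fd.min_items == 1 else 'ies'}, has {len(value)}")
                )
            for item in value:
                _check_scalar(registry, fd, Datatype(dt.kind, dt.name, False), item,
                              path, entity.class_name, report)
        else:
            _check_scalar(registry, fd, dt, value, path, entity.class_name, report)
    for extra in sorted(entity.extras):
        report.violations.append(
            _v("UNKNOWN_FIELD", path,
               f"unknown field {entity.class_name}.{extra} quarantined")
        )
    if entity.class_name == "CoordinateFrame":
        _check_frame_geometry(entity, path, report)
    if entity.class_name == "ImageResolution":
        _check_resolution_positive(entity, path, report)
    _check_identifier_syntax(entity, path, report)


def validate_entity(registry: SchemaRegistry, entity: Entity, path: str = "") -> ValidationReport:
    """Structurally validate one entity (and its inline children)."""
    report = ValidationReport()
    _validate_entity_into(registry, entity, path or entity.class_name.lower(), report)
    return report.finalize()


# ---------------------------------------------------------------------------
# subset constraints

def _norm_name(name: str) -> str:
    return unicodedata.normalize("NFC", name).casefold()


def _facet_keys(entity: Entity, facet: str, is_parent: bool) -> tuple[set[str], dict[str, str]]:
    """Return the facet's equality keys and a key -> display-label map.

    Equality is identifier-first (NameIdentifier / RightsIdentifier), falling
    back to the Unicode-NFC case-folded name.
    """
    keys: set[str] = set()
    labels: dict[str, str] = {}

    def add(key: str, label: str) -> None:
        keys.add(key)
        labels.setdefault(key, label)

    if facet == "creators":
        people: list[Entity] = []
        creator = entity.get("Creator")
        if isinstance(creator, Entity):
            people.append(creator)
        elif isinstance(creator, list):
            people.extend(p for p in creator if isinstance(p, Entity))
        if is_parent:  # a parent's full contributor roster counts as its superset
            for extra_field in ("Contributor", "PointOfContact"):
                people.extend(
                    p for p in entity.get(extra_field) or [] if isinstance(p, Entity)
                )
        for person in people:
            ident = person.get("NameIdentifier")
            names = person.get("Name") or []
            label = names[0] if names and isinstance(names[0], str) else "<unnamed>"
            if isinstance(ident, str) and ident:
                add(f"id:{ident}", label)
            elif names and isinstance(names[0], str):
                add(f"name:{_norm_name(names[0])}", label)
    elif facet == "licenses":
        for lic in entity.get("License") or []:
            if not isinstance(lic, Entity):
                continue
            ident = lic.get("RightsIdentifier")
            rights = lic.get("Rights")
            label = ident or rights or "<unnamed license>"
            if isinstance(ident, str) and ident:
                add(f"id:{ident}", label)
            elif isinstance(rights, str) and rights:
                add(f"name:{_norm_name(rights)}", label)
    elif facet == "identifiers":
        for ident in entity.get("Identifiers") or []:
            if isinstance(ident, str) and ident:
                add(_norm_name(ident), ident)
    else:
        raise BenchmarkError(f"unknown subset facet {facet!r}")
    return keys, labels


def check_subset_constraint(
    child: Entity, parent: Entity, facet: str, path: str = ""
) -> list[Violation]:
    """One violation per child facet element absent from the parent's facet.

    The empty set is a subset of everything, so a child that declares no
    creators/licenses/identifiers of its own simply inherits the parent's.
    """
    code = _SUBSET_CODES.get(facet)
    if code is None:
        raise BenchmarkError(f"unknown subset facet {facet!r}")
    child_keys, labels = _facet_keys(child, facet, is_parent=False)
    parent_keys, _ = _facet_keys(parent, facet, is_parent=True)
    path = path or child.class_name.lower()
    return [
        _v(code, path,
           f"{child.class_name} {facet} entry {labels[k]!r} is not among the "
           f"{parent.class_name}'s {facet}")
        for k in sorted(child_keys - parent_keys)
    ]


# ---------------------------------------------------------------------------
# coordinate-frame consistency

def check_coordinate_consistency(
    experiment: Entity,
    channels: list[tuple[str, Entity]],
    frames: dict[str, Entity] | None = None,
    path: str = "",
) -> list[Violation]:
    """COORD_MISMATCH for channels not on the experiment's frame (compared by
    ID); EXTENT_DEGENERATE findings for the frame itself when ``frames`` is
    supplied.  ``channels`` is a list of (path, channel) pairs."""
    out: list[Violation] = []
    exp_frame = experiment.get("CoordinateFrame")
    path = path or f"experiment/{experiment.id or '?'}"
    for ch_path, channel in channels:
        ch_frame = channel.get("CoordinateFrame")
        if ch_frame is not None and exp_frame is not None and ch_frame != exp_frame:
            out.append(
                _v("COORD_MISMATCH", ch_path,
                   f"channel frame {ch_frame!r} differs from experiment frame {exp_frame!r}")
            )
    if frames and isinstance(exp_frame, str) and exp_frame in frames:
        sub = ValidationReport()
        _check_frame_geometry(frames[exp_frame], f"coordinate_frame/{exp_frame}", sub)
        out.extend(sub.violations)
    return out


# ---------------------------------------------------------------------------
# whole-bundle validation

def _resolve(bundle, cls: str, ref: Any, path: str, field_name: str,
             report: ValidationReport) -> Entity | None:
    if not isinstance(ref, str):
        return None
    target = bundle.get(cls, ref)
    if target is None:
        report.violations.append(
            _v("REF_DANGLING", path,
               f"{field_name} references {cls} {ref!r} which does not exist in the bundle")
        )
    return target


def validate_bundle(registry: SchemaRegistry, bundle) -> ValidationReport:
    """Validate every entity plus all cross-entity rules of the standard."""
    report = ValidationReport()
    seen: dict[str, set[str]] = {cls: set() for cls in bundle.tables}

    for extra in sorted(bundle.extras):
        report.violations.append(
            _v("UNKNOWN_FIELD", "bundle", f"unknown top-level section {extra!r} quarantined")
        )

    for project in bundle.projects:
        p_path = f"project/{project.id or '?'}"
        seen["Project"].add(project.id or "")
        _validate_entity_into(registry, project, p_path, report)
        frames_used: dict[str, str] = {}  # frame id -> first experiment path

        for col_ref in project.get("Collections") or []:
            collection = _resolve(bundle, "Collection", col_ref, p_path, "Collections", report)
            if collection is None:
                continue
            c_path = f"{p_path}/collection/{collection.id or '?'}"
            if collection.id not in seen["Collection"]:
                seen["Collection"].add(collection.id or "")
                _validate_entity_into(registry, collection, c_path, report)
            for facet in ("creators", "licenses", "identifiers"):
                report.extend(check_subset_constraint(collection, project, facet, c_path))

            for exp_ref in collection.get("Experiments") or []:
                experiment = _resolve(bundle, "Experiment", exp_ref, c_path, "Experiments", report)
                if experiment is None:
                    continue
                e_path = f"{c_path}/experiment/{experiment.id or '?'}"
                if experiment.id not in seen["Experiment"]:
                    seen["Experiment"].add(experiment.id or "")
                    _validate_entity_into(registry, experiment, e_path, report)
                for facet in ("creators", "licenses", "identifiers"):
                    report.extend(check_subset_constraint(experiment, collection, facet, e_path))

                exp_frame = experiment.get("CoordinateFrame")
                if isinstance(exp_frame, str):
                    frame = _resolve(bundle, "CoordinateFrame", exp_frame, e_path,
                                     "CoordinateFrame", report)
                    if frame is not None and exp_frame not in frames_used:
                        frames_used[exp_frame] = e_path

                channel_pairs: list[tuple[str, Entity]] = []
                for ch_ref in experiment.get("Channels") or []:
                    channel = _resolve(bundle, "Channel", ch_ref, e_path, "Channels", report)
                    if channel is None:
                        continue
                    ch_path = f"{e_path}/channel/{channel.id or '?'}"
                    if channel.id not in seen["Channel"]:
                        seen["Channel"].add(channel.id or "")
                        _validate_entity_into(registry, channel, ch_path, report)
                        ch_frame = channel.get("CoordinateFrame")
                        if isinstance(ch_frame, str):
                            _resolve(bundle, "CoordinateFrame", ch_frame, ch_path,
                                     "CoordinateFrame", report)
                    for facet in ("creators", "licenses", "identifiers"):
                        report.extend(check_subset_constraint(channel, experiment, facet, ch_path))
                    channel_pairs.append((ch_path, channel))
                report.extend(
                    check_coordinate_consistency(experiment, channel_pairs, path=e_path)
                )

        # project-level reference checks (Channels/Experiments listed directly)
        for field_name, cls in (("Experiments", "Experiment"), ("Channels", "Channel")):
            for ref in project.get(field_name) or []:
                _resolve(bundle, cls, ref, p_path, field_name, report)

        # recommended (not required): coordinate frames shared within a project
        frame_ids = sorted(frames_used)
        for i, fa in enumerate(frame_ids):
            for fb in frame_ids[i + 1:]:
                ea, eb = bundle.get("CoordinateFrame", fa), bundle.get("CoordinateFrame", fb)
                if ea is not None and eb is not None and entities_equal(ea, eb):
                    report.violations.append(
                        _v("FRAME_NOT_SHARED", p_path,
                           f"frames {fa!r} and {fb!r} are identical and could be shared")
                    )

    # entities never reached from a project still get structural validation;
    # coordinate frames always land here (they are validated once, by table)
    prefixes = {"Collection": "collection", "Experiment": "experiment",
                "Channel": "channel", "CoordinateFrame": "coordinate_frame"}
    for cls, prefix in prefixes.items():
        for entity_id, entity in bundle.tables.get(cls, {}).items():
            if entity_id not in seen.get(cls, set()):
                _validate_entity_into(registry, entity, f"{prefix}/{entity_id}", report)
    return report.finalize()
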