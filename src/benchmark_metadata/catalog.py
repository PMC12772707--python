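"""In-memory faceted index over validated bundles.

Approximates the programmatic metadata access a hosted archive service
provides (cross-archive indexing, dashboard queries) without any server:
projects from error-free bundles are flattened into search facets and
queried conjunctively.  Only bundles with zero validation errors are
indexable — the catalog is a view over *compliant* metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

from .bundle import MetadataBundle
from .entities import Entity
from .errors import BenchmarkError
from .registry import SchemaRegistry
from .validation import ValidationReport, validate_bundle

FACETS = ("species", "modality", "year", "contributor", "region", "public")


class BundleRejectedError(BenchmarkError):
    """Raised when a bundle with validation errors is offered for indexing."""

    def __init__(self, report: ValidationReport):
        self.report = report
        lines = "; ".join(
            f"{v.rule_code}@{v.entity_path}" for v in report.errors[:5]
        )
        more = "" if len(report.errors) <= 5 else f" (+{len(report.errors) - 5} more)"
        super().__init__(f"bundle has {len(report.errors)} validation error(s): {lines}{more}")


def _fold(value: str) -> str:
    return value.casefold().strip()


@dataclass(frozen=True)
class ProjectSummary:
    project_id: str
    title: str
    facets: Mapping[str, tuple]

    def to_dict(self) -> dict[str, Any]:
        return {"project_id": self.project_id, "title": self.title,
                "facets": {k: list(v) for k, v in self.facets.items()}}


def _project_facets(project: Entity) -> dict[str, tuple]:
    species = tuple(s for s in project.get("Species") or [] if isinstance(s, str))
    modality = tuple(m for m in project.get("ImagingModalities") or []
                     if isinstance(m, str))
    year = project.get("Year")
    contributors = []
    creator = project.get("Creator")
    people = [creator] if isinstance(creator, Entity) else []
    people += [p for p in project.get("Contributor") or [] if isinstance(p, Entity)]
    people += [p for p in project.get("PointOfContact") or [] if isinstance(p, Entity)]
    for person in people:
        names = person.get("Name") or []
        contributors.extend(n for n in names if isinstance(n, str))
    regions = tuple(
        loc.get("RegionName") for loc in project.get("ImageLocations") or []
        if isinstance(loc, Entity) and isinstance(loc.get("RegionName"), str)
    )
    return {
        "species": species,
        "modality": modality,
        "year": (year,) if isinstance(year, str) else (),
        "contributor": tuple(dict.fromkeys(contributors)),  # order-stable dedup
        "region": tuple(dict.fromkeys(regions)),
        "public": (project.get("Public"),) if "Public" in project else (),
    }


@dataclass
class Catalog:
    """Deterministic index of project summaries with normalized facet values."""

    summaries: dict[str, ProjectSummary] = field(default_factory=dict)
    _index: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.summaries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        return self.summaries == other.summaries

    def _add(self, project: Entity) -> None:
        pid = project.id
        if pid is None:
            return
        facets = _project_facets(project)
        self.summaries[pid] = ProjectSummary(pid, project.get("Title", ""), facets)
        for facet, values in facets.items():
            bucket = self._index.setdefault(facet, {})
            for value in values:
                key = _fold(value) if isinstance(value, str) else str(value).casefold()
                bucket.setdefault(key, set()).add(pid)

    def query(self, filters: Mapping[str, Any] | None = None) -> list[ProjectSummary]:
        """Conjunctive facet filtering; results ordered by project ID.

        Filter keys must come from :data:`FACETS`; string values match
        case-insensitively.  An empty/absent filter returns every project.
        """
        filters = dict(filters or {})
        for key in filters:
            if key not in FACETS:
                raise ValueError(
                    f"unknown facet {key!r}; valid facets: {', '.join(FACETS)}"
                )
        hit: set[str] = set(self.summaries)
        for facet, wanted in filters.items():
            key = _fold(wanted) if isinstance(wanted, str) else str(wanted).casefold()
            hit &= self._index.get(facet, {}).get(key, set())
        return [self.summaries[pid] for pid in sorted(hit)]


def index_bundles(
    registry: SchemaRegistry, bundles: Iterable[MetadataBundle]
) -> Catalog:
    """Validate and index bundles; any bundle with errors is rejected.

    Indexing the same bundle set twice produces equal catalogs (the index is
    rebuilt deterministically from scratch each time).
    """
    catalog = Catalog()
    for bundle in bundles:
        report = validate_bundle(registry, bundle)
        if not report.valid:
            raise BundleRejectedError(report)
        for project in bundle.projects:
            catalog._add(project)
    return catalog


def scan_query(
    bundles: Iterable[MetadataBundle], filters: Mapping[str, Any] | None = None
) -> list[str]:
    """Brute-force linear scan returning matching project IDs, sorted.

    Reference oracle for :meth:`Catalog.query`: no index, just a pass over
    every project's facet values with the same normalization.
    """
    filters = dict(filters or {})
    for key in filters:
        if key not in FACETS:
            raise ValueError(f"unknown facet {key!r}; valid facets: {', '.join(FACETS)}")
    out = []
    for bundle in bundles:
        for project in bundle.projects:
            facets = _project_facets(project)
            ok = True
            for facet, wanted in filters.items():
                wanted_key = (_fold(wanted) if isinstance(wanted, str)
                              else str(wanted).casefold())
                values = {
                    _fold(v) if isinstance(v, str) else str(v).casefold()
                    for v in facets.get(facet, ())
                }
                if wanted_key not in values:
                    ok = False
                    break
            if ok and project.id is not None:
                out.append(project.id)
    return sorted(out)
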