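"""The registry must reproduce the standard's class and enum inventory exactly."""

import pytest

from benchmark_metadata import (
    SchemaError,
    UnknownClassError,
    UnknownEnumError,
    describe_class,
    list_enum_members,
    load_registry,
)

# field counts the standard states per class
PRINTED_FIELD_COUNTS = {
    "Project": 36,
    "Collection": 18,
    "Experiment": 20,
    "Channel": 19,
    "CoordinateFrame": 4,
    "BrainLocation": 4,
    "DataLocation": 5,
    "LightMicroscopySpecific": 28,
    "ElectronMicroscopySpecific": 14,
    "Taxonomy": 8,
    "Contributor": 11,
    "License": 4,
    "Funding": 5,
    "Publication": 8,
    "Link": 2,
}


def test_registry_has_exactly_18_classes(registry):
    assert len(registry.classes) == 18
    assert registry.version == "1.1"


@pytest.mark.parametrize("class_name,count", sorted(PRINTED_FIELD_COUNTS.items()))
def test_printed_field_counts(registry, class_name, count):
    assert describe_class(registry, class_name).field_count == count


def test_link_fields_are_name_and_uri(registry):
    assert describe_class(registry, "Link").field_names == ["Name", "URI"]


def test_coordinate_frame_fields(registry):
    assert describe_class(registry, "CoordinateFrame").field_names == [
        "Xs", "Ys", "Zs", "VoxelSize",
    ]


def test_taxonomy_fields(registry):
    desc = describe_class(registry, "Taxonomy")
    assert desc.field_names == [
        "TaxonomyID", "CurrentName", "GenBankCommonName", "NCBIBlastName",
        "Rank", "GeneticCode", "MitochondrialGeneticCode", "CommonName",
    ]
    assert desc.field("TaxonomyID").required


@pytest.mark.parametrize(
    "enum_name,members",
    [
        ("ContributorType",
         ["ContactPerson", "DataCollector", "DataCurator", "ProjectLeader",
          "ProjectManager", "ProjectMember", "RelatedPerson", "Researcher",
          "ResearchGroup", "Other"]),
        ("NameType", ["Organizational", "Personal"]),
        ("NameIdentifierScheme", ["GRDI", "ISNI", "ORCID", "ROR", "RRID", "Other"]),
        ("AffiliationIdentifierScheme", ["GRDI", "ISNI", "ORCID", "ROR", "RRID", "Other"]),
        ("FundingReferenceIdentifierType", ["GRDI", "ISNI", "ORCID", "ROR", "RRID", "Other"]),
        ("RelatedIdentifierType", ["arXiv", "DOI", "ISBN", "PMID", "Other"]),
        ("RelationType", ["IsCitedBy", "IsDocumentedBy"]),
        ("ChannelType", ["RawData", "Segmentation", "Annotation"]),
    ],
)
def test_enum_member_lists(registry, enum_name, members):
    assert list_enum_members(registry, enum_name) == members


def test_technique_enum_covers_the_abbreviation_table(registry):
    members = list_enum_members(registry, "ImagingModalitySpecific")
    assert members[0] == "AET" and members[-1] == "XRM"
    assert {"FIB_SEM", "SS_TEM", "ATUM_SEM", "TEM", "SEM", "XRM"} <= set(members)


@pytest.mark.parametrize(
    "class_name,field_name,required",
    [
        ("Project", "Title", True),
        ("Project", "Public", True),
        ("Project", "Links", False),
        ("Project", "DateModified", False),
        ("Contributor", "Name", True),
        ("Contributor", "Email", False),
        ("License", "Rights", True),
        ("License", "RightsURI", True),
        ("Funding", "FundingEntity", True),
        ("Funding", "AwardTitle", False),
        ("Publication", "Authors", True),
        ("Publication", "Citation", False),
        ("Link", "Name", True),
        ("Link", "URI", True),
    ],
)
def test_required_flags_match_the_standard(registry, class_name, field_name, required):
    assert describe_class(registry, class_name).field(field_name).required is required


def test_project_must_reference_at_least_one_of_each_child(registry):
    project = describe_class(registry, "Project")
    for name in ("Channels", "Experiments", "Collections"):
        fd = project.field(name)
        assert fd.required and fd.min_items == 1 and fd.reference


def test_unknown_class_error_lists_valid_names(registry):
    with pytest.raises(UnknownClassError) as exc:
        describe_class(registry, "NoSuchClass")
    assert "Taxonomy" in str(exc.value)


def test_unknown_enum_error(registry):
    with pytest.raises(UnknownEnumError):
        list_enum_members(registry, "NoSuchEnum")


def test_enum_membership_is_case_sensitive_and_rejects_empty(registry):
    assert registry.is_enum_member("ContributorType", "ProjectLeader")
    assert not registry.is_enum_member("ContributorType", "projectleader")
    for enum_name in registry.enums:
        assert not registry.is_enum_member(enum_name, "")


def test_every_field_type_resolves(registry):
    """Field types are primitives, registered enums, or registered classes."""
    registry.check_integrity()  # raises on any dangling reference


def test_config_extends_open_enums_only(registry):
    extended = load_registry({"enums": {"Species": ["Danio rerio"]}})
    assert "Danio rerio" in extended.list_enum_members("Species")
    # base members keep their order
    base = registry.list_enum_members("Species")
    assert extended.list_enum_members("Species")[: len(base)] == base
    with pytest.raises(SchemaError):
        load_registry({"enums": {"RelationType": ["IsSupplementTo"]}})


def test_grid_alias_normalizes_to_grdi(registry):
    assert registry.normalize_enum_value("GRID") == "GRDI"
    assert registry.normalize_enum_value("GRDI") == "GRDI"
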