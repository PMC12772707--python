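"""Walk the schema registry: the 18 metadata classes and their enumerations.

The registry is the machine-readable form of the standard itself — every
class, field, type, required flag and enumeration the validator enforces.
"""

from benchmark_metadata import load_registry

registry = load_registry()

print(f"standard version {registry.version}: {len(registry.classes)} classes\n")
for name in registry.classes:
    desc = registry.describe_class(name)
    required = sum(f.required for f in desc.fields)
    print(f"  {name:<27} {desc.field_count:>2} fields ({required} required)")

print("\nContributorType members (the DataCite-style roles a contributor may hold):")
for member in registry.list_enum_members("ContributorType"):
    print(f"  - {member}")

taxonomy = registry.describe_class("Taxonomy")
print(f"\nTaxonomy ({taxonomy.field_count} fields, NCBI-derived):")
for f in taxonomy.fields:
    flag = "required" if f.required else "optional"
    print(f"  {f.name:<26} {str(f.datatype):<10} {flag}")

# The class counts printed above are the standard's own inventory: a
# conforming implementation must expose exactly these classes and sizes.
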