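"""Check a volumetric store against its channel's declared metadata.

Writes a tiny Neuroglancer-precomputed fixture (metadata plus one
placeholder chunk), detects its format from the sentinel files, parses the
container metadata — never the pixels — and cross-checks dtype, voxel
resolution, and frame extent against a Channel/CoordinateFrame pair.
"""

import tempfile
from pathlib import Path

from benchmark_metadata import (
    channel_for_container, cross_check_channel, detect_format,
    generate_container, load_registry, parse_container,
)

registry = load_registry()

with tempfile.TemporaryDirectory() as tmp:
    store = Path(tmp) / "volume"
    # a 64x64x64-voxel uint8 volume at 4x4x40 nm, two pyramid levels
    generate_container("precomputed", "uint8", (64, 64, 64), (4.0, 4.0, 40.0),
                       out_tree=store, n_scales=2)

    kind = detect_format(store)
    descriptor = parse_container(store, kind)
    print(f"detected {kind}: dtype={descriptor.dtype}, "
          f"{descriptor.num_scales} scales")
    for i, s in enumerate(descriptor.scales):
        print(f"  scale {i}: extent={s.extent} voxels at {s.resolution} {s.unit}")

    # a channel whose frame spans 64 voxels * 4 nm = 256 nm per lateral axis
    channel, frame = channel_for_container(registry, "uint8", (64, 64, 64),
                                           (4.0, 4.0, 40.0))
    violations = cross_check_channel(channel, frame, descriptor)
    print(f"cross-check violations: {len(violations)}")

    # now pretend the channel claims 16-bit data: the container disagrees
    channel.values["DataType"] = "uint16"
    for v in cross_check_channel(channel, frame, descriptor):
        print(f"  {v.rule_code}: {v.message}")

# Expected output: zero violations for the matching pair, then one
# DTYPE_MISMATCH once the channel's declared data type contradicts the store.
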