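"""Browse the registry of mouse brain spatial reference systems.

Each SRS is a named brain coordinate system (origin, oriented axes, units,
extents, region of validity) with an EPSG-style code.  The fixture holds the
seven registered mouse atlas spaces; the two Waxholm Space (WHS) versions
form the common go-between family.
"""

from atlasdai import make_table1_registry, validate_srs, waxml

registry, _ = make_table1_registry()

print("All registered mouse SRSs (code / name / family / version):")
for desc in registry.list_srs(species="Mouse"):
    print(f"  {desc.code}  {desc.name:26s} {desc.srs_family:14s}"
          f" {desc.version}")

print("\nWHS family only:", [d.name for d in registry.list_srs(family='WHS')])

whs10 = registry.get_srs("Mouse_WHS_1.0")
print(f"\n{whs10.name}: {whs10.description}")
print("violations:", validate_srs(whs10))  # [] = a valid record

print("\nThe same record as a WaxML document:")
print(waxml.encode_srs(whs10))
# The document round-trips field-equal, so registries can be exchanged
# between atlas hubs without loss.
assert waxml.decode_srs(waxml.encode_srs(whs10)) == whs10
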