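"""Design a DNAzyme against a 12-nt RNA substrate, end to end by hand.

A toy RNA-cleaving DNAzyme recognizes the dinucleotide GU and cuts the
phosphodiester bond between G and U (cleavage offset 1). On the substrate
AAAAAGUCCCCC that site sits at positions 6-7, so with 6-nt binding arms the
DNAzyme's arms must reverse-complement the flanks AAAAAG and UCCCCC.
"""

from dnazymekit import (
    ArmSpec,
    DnazymeRecord,
    ReactionType,
    SubstrateClass,
    design_site,
    diagram,
    find_sites,
    substrate_from_string,
)

substrate = substrate_from_string("AAAAAGUCCCCC", "RNA")
record = DnazymeRecord(
    name="toy-10-23-like", variant_id="",
    substrate_class=SubstrateClass.RNA,
    reaction_type=ReactionType.TRANSESTERIFICATION,
    core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
)

site = find_sites(substrate, record)[0]
print(f"recognition site at RSS {site.rss}, scissile bond after position "
      f"{site.cleavage_position}")

result = design_site(substrate, site, ArmSpec(length=6))
print(f"arm1 (pairs the 3' flank): {result.arms.arm1}  Tm {result.arms.tm1_C} C")
print(f"arm2 (pairs the 5' flank): {result.arms.arm2}  Tm {result.arms.tm2_C} C")
print(f"assembled DNAzyme 5'->3': {result.full_sequence}")
print(f"products: {result.product_5p.sequence} ({result.product_5p.end3}) + "
      f"{result.product_3p.sequence} ({result.product_3p.end5})")
print()
print(diagram(result))
# The arms are exact DNA reverse complements of the substrate flanks; the
# Wallace Tms (2C per A/T, 4C per G/C) quantify how tightly each arm binds.
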