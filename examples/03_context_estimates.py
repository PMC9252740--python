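"""How relative rate/yield estimates depend on the matched sequence context.

A DNAzyme characterized in an original context (k_obs 2.0/min, 85% yield)
and one mutant context (0.5/min, 40%) is scanned against a substrate
carrying both contexts. The original site reports RRk = RRY = 100 by
definition; the mutant site reports ratios to the original.
"""

from dnazymekit import (
    ContextEntry,
    DnazymeRecord,
    ReactionType,
    SubstrateClass,
    estimate,
    find_sites,
    match_context,
    substrate_from_string,
)

record = DnazymeRecord(
    name="ctx-demo", variant_id="",
    substrate_class=SubstrateClass.RNA,
    reaction_type=ReactionType.TRANSESTERIFICATION,
    core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
    contexts=(
        ContextEntry("AGUC", 1, 1, k_obs=2.0, yield_percent=85.0,
                     is_original=True),
        ContextEntry("AGUA", 1, 1, k_obs=0.5, yield_percent=40.0),
    ),
)

substrate = substrate_from_string("AAGUCAGUA", "RNA")
for raw_site in find_sites(substrate, record):
    site = match_context(substrate, raw_site, record)
    est = estimate(site, record)
    print(f"site at RSS {site.rss}: observed context {site.context_observed!r} "
          f"-> basis={est.basis.value}")
    print(f"  RRk={est.rrk_percent}  RRY={est.rry_percent}  RCY={est.rcy_percent}")
# RRk 25 means the mutant context's reported rate is 25% of the original's;
# RCY is the matched context's own reported yield.
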