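# Column-mapping template for importing an external DNAzyme-substrate table
# (e.g. a published supplementary database) via `dnazymekit db import`.
#
# Edit the right-hand side to match the table's actual column headers, then:
#   dnazymekit db import data/<table>.tsv --mapping data/supplementary_mapping.yaml --out kb.json
#
# Required fields: name, substrate_class, core_sequence, rs_pattern,
# cleavage_offset. All others are optional (nullable in the schema).
columns:
  name: "DNAzyme name"
  variant_id: "Catalytic core mutant"
  substrate_class: "Substrate type"          # values: RNA | DNA | chimeric
  reaction_type: "Reaction type"             # transesterification | hydrolysis | other
  core_sequence: "Catalytic core"
  rs_pattern: "Recognition site"
  cleavage_offset: "Cleavage offset"         # RS nucleotides 5' of the scissile bond
  context_pattern: "Context"
  flank5_len: "5' flank length"
  flank3_len: "3' flank length"
  k_obs: "kobs"
  yield_percent: "Yield"
  is_original: "Original context"
  cofactors: "Cofactors"
  ph_min: "pH min"
  ph_max: "pH max"
  temperature_C: "Temperature"
  incubation: "Incubation"
  citation: "Reference"

# Unit handling: k_obs values are normalized to min^-1 at import.
kobs_unit: "min-1"      # one of: min-1, s-1, h-1
yield_fraction: false   # true if the yield column holds 0-1 fractions
sep: "\t"               # delimiter for .tsv/.csv tables
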