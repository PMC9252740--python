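# Methods

## Substrate model

A substrate is a single sequence of ≤ 2000 nt over the 15 IUPAC nucleotide
letters, annotated per residue with its sugar (deoxy/ribo). DNA and RNA
substrates have uniform backbones; chimeric substrates encode ribonucleotides
as lowercase letters in the input (a common oligo-ordering convention that
round-trips through plain text) and are stored uppercase with explicit
per-residue flags. Characters outside the accepted alphabet are deleted —
no complementary nucleotide is defined for them — and every deletion is
recorded as (original position, character), so users can map reported
coordinates back to their raw input. All downstream positions are 1-based on
the sanitized sequence; a cleavage site is the bond identified by the index
of its 5′ residue, matching bench convention.

Input parsing (FASTA, EMBL, GenBank) delegates to Biopython's `SeqIO`;
format auto-detection is by leading token (`>` → FASTA, `LOCUS` → GenBank,
`ID` → EMBL, otherwise RAW) with an explicit override. Exactly one record is
accepted per run; multi-record files are rejected with the count rather than
silently truncated.

## Knowledge-base schema

One record per DNAzyme variant (original selections and catalytic-core
mutants are distinct `(name, variant_id)` keys) with: the catalytic core
(DNA letters), the recognition-site pattern (IUPAC, possibly degenerate),
the cleavage offset (number of RS nucleotides 5′ of the scissile bond,
0 ≤ offset ≤ |RS|), characterized contexts (RS plus fixed 5′/3′ flanks, each
with nullable k_obs in min⁻¹ and yield in percent, at most one flagged as
the originally characterized context), the binding-arm archetype, cofactors,
and reaction conditions (pH window, temperature, incubation). Records
lacking kinetics are kept — characterization depth is heterogeneous across
the literature — and are simply ranked last. k_obs is normalized to min⁻¹
and yields to percent at import so comparisons share one scale; original
strings live in a provenance field.

The arm archetype is encoded as bond-relative duplex borders
(`left_cover_end` ≤ 0 ≤ `right_cover_start`), substrate offsets left
unpaired, and terminal overrides that force a non-Watson–Crick letter at a
junction-adjacent arm position (e.g. a wobble partner). Full coverage of
both flanks is the all-zero default; the vocabulary extends if records need
arrangements beyond border shifts plus junction overrides.

Serialization is a versioned JSON document validated on load (field-level
messages, duplicate-key detection), with a TSV flat view for curation. A
mapping-driven importer ingests external tables: a YAML config maps schema
fields to column headers and declares units, one record is built per
distinct (name, variant) with one context per row, and unusable rows are
returned in a skip report rather than silently dropped.

## Recognition-site scanning

For each record the RS pattern slides over every window of the substrate.
A pattern letter matches only fully specified substrate letters (A, C, G,
T, U) drawn from its IUPAC expansion; ambiguous substrate letters never
match — even N against pattern N — because no unique complement exists to
build an arm against. T and U are treated as equivalent so one pattern
alphabet serves both substrate types. Matches whose implied cleavage
position leaves no bond on one side are dropped. Substrate-class gating:
RNA-cleaving records scan RNA and chimeric substrates, DNA-cleaving records
DNA and chimeric ones, and the residue 5′ of the scissile bond must carry
the backbone the chemistry requires (transesterification proceeds through
the 2′-OH, hence a ribo residue). The implementation is the straightforward
O(L·|RS|) scan; at the 2000-nt input cap nothing faster is warranted, and
the test suite holds it equal to an independently written brute-force
oracle over randomized substrates and records.

Context classification extracts the window `[RSS − flank5, RSS + |RS| − 1 +
flank3]` for each context entry, tries the original context first and then
file order (the first match wins — the ranking among reported contexts is
otherwise arbitrary), and reports a clipped, unmatched window when the
flanks run off a substrate end.

## Arm design and assembly

The DNAzyme is `arm1 + core + arm2` (5′→3′). Arm 1 pairs the substrate
interval starting at `p + right_cover_start + 1` extending 3′; arm 2 pairs
the interval ending at `p + left_cover_end` extending 5′; both antiparallel,
so each arm is the DNA-letter reverse complement of its covered positions,
with archetype-unpaired positions skipped and terminal overrides applied
last. Extension stops at a substrate end or at an ambiguity letter (which
has no defined partner, so it behaves as a border); either marks the design
clipped. Arms are sized by fixed length (default 10 nt, the midpoint of the
6–15 nt range in common use) or by target Tm (shortest arm reaching the
target). Arms shorter than 5 nt are rejected as design-infeasible rather
than emitted: such duplexes are too weak to direct cleavage.

Melting temperatures use the Wallace rule, Tm = 2·(A+T) + 4·(G+C) °C —
exact in integer arithmetic, deterministic, and the standard quick estimate
for oligos this short. The Tm interface is a single pluggable function;
RNA·DNA duplex corrections are not applied and every report names the model
used. An empty arm is defined as 0 °C but cannot reach output (assembly
rejects empty arms upstream).

Products split the substrate at the bond: the 5′ product has length equal
to the cleavage position. Transesterification labels the new termini
2′,3′-cyclic phosphate / 5′-OH; hydrolysis defaults to 3′-OH /
5′-phosphate.

## Relative kinetics estimates

The estimates are relative because absolute rates transfer poorly across
contexts. With the site's matched context *m* and the record's original
context *o*:

- basis `original_context` (*m* = *o*): RRk = RRY = 100, RCY = yield(*o*).
- basis `reported_mutant_context`: RRk = 100·k_obs(*m*)/k_obs(*o*),
  RRY = 100·yield(*m*)/yield(*o*) (null when either term is missing),
  RCY = yield(*m*).
- basis `model` (no context matched): RCY is the mean reported yield over
  the record's contexts whose pattern differs from the observed window at
  ≤ *d* positions (*d* = 1 by default; position-wise IUPAC mismatch count);
  null when none qualify. RRk/RRY are null.
- basis `unavailable`: the record has no characterized contexts.

The ratio-to-original definitions and the nearest-context fallback are this
package's explicit choices; the `basis` (and, for the model route, the
distance used) is emitted with every estimate so its provenance is
auditable. A learned context-position model could replace the
nearest-context average behind the same interface.

## Filtering, ranking, reports

All present constraints must hold: the Tm window applies to both arms, a
cofactor list passes if any record cofactor is allowed, a pH request passes
if it intersects the record's window. Ranking defaults to k_obs descending
with nulls last (the candidate table leads with kinetics); `tm` ranks by
mean arm Tm descending and `position` by cleavage position ascending, each
with the deterministic tie-break (name, variant, RSS), so repeated runs are
byte-identical. Summaries are RFC-4180 CSV or JSON with identical fields;
per-design details carry the assembly segmentation, products with termini,
conditions, estimates with basis, notes (clipping, overrides, model
distance), and a text duplex diagram whose bar line ('|' Watson–Crick, '.'
override/unpaired, space uncovered) is machine-recoverable back to the arm
windows.

## Synthetic knowledge bases

`generate_fixture_db(seed, n)` emulates the shape of the curated literature:
half RNA-cleaving (transesterification) and half DNA-cleaving (hydrolysis)
records, cores of 8–20 nt, recognition sites of 2–6 nt with a 15% degenerate
letter fraction, 1–3 contexts per record with 1–3 nt flanks, k_obs
log-uniform over 0.001–10 min⁻¹ (the spread of reported trans-cleavage
rates spans roughly these four decades), yields uniform on 20–95%, common
divalent cofactors, and occasional junction overrides. Generation is fully
deterministic per seed and every emitted record passes schema validation.
What it does not emulate: real covariance between context and kinetics,
realistic RS composition biases, and multi-paper characterization of one
DNAzyme — so green tests demonstrate algorithmic correctness on
schema-conformant data, not biochemical accuracy on the curated corpus.

## Problem sizes and numerical notes

The scanner cross-check runs 1000 random (substrate ≤ 200 nt, record)
pairs; the design soundness sweep 1000 random designs; filter monotonicity
500 random specifications — ample to exercise every code path while keeping
the default suite fast. Wallace Tm is exact float arithmetic on integer
sums (no tolerance needed). Ties in ranking are broken lexicographically;
degenerate inputs (empty result sets, zero-match scans, clipped contexts)
are normal outcomes, reported rather than raised.

## Known limitations

- No substrate structure prediction: a site buried in a hairpin scores the
  same as an accessible one.
- No hybridization thermodynamics beyond Wallace Tm; no RNA·DNA or
  nearest-neighbor correction (flagged in every output).
- No off-target search across a transcriptome/genome.
- No chemically modified arms (LNA/XNA).
- The nearest-context yield model is a deliberate, auditable simplification.
- Importing an external database requires adjusting the mapping YAML to the
  file's actual layout; no layout is assumed.
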