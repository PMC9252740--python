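# dnazymekit

Design of trans-cleaving RNA/DNA-cleaving DNAzymes from sequence.

DNAzymes (deoxyribozymes) are single-stranded DNA catalysts built from a
conserved catalytic core flanked by two exchangeable binding arms. To cleave a
chosen substrate, a researcher must (1) find a recognition site (RS) the
DNAzyme accepts on the substrate, (2) design two arms that base-pair the
substrate on either side of the scissile bond, and (3) pick the DNAzyme whose
reported kinetics, cofactors, and reaction conditions fit the experiment.
Doing this by hand requires deep literature scrutiny; `dnazymekit` automates
it against a structured knowledge base of characterized DNAzymes.

Given a substrate (DNA, RNA, or chimeric; ≤ 2000 nt; FASTA/EMBL/GenBank/RAW)
and a knowledge base, the tool:

- sanitizes the input to the 15-letter IUPAC alphabet (deleted characters are
  reported with their positions) and optionally reverse-complements or
  converts DNA↔RNA;
- scans every record's RS pattern over the substrate. A pattern letter matches
  only fully specified substrate letters (A/C/G/T/U) from its IUPAC expansion,
  with T ≡ U; each match yields the RS start (RSS) and the cleavage position
  *p* (the bond sits between residues *p* and *p*+1, with
  *p* = RSS + offset − 1);
- designs the binding arms per the record's arm archetype. The 5′ arm
  reverse-complements the substrate window 3′ of the bond and the 3′ arm the
  window 5′ of it (DNA letters, fixed length or target Tm), assembles
  `arm1 + core + arm2`, and computes each arm's Wallace melting temperature
  Tm = 2·(A+T) + 4·(G+C) °C;
- predicts the cleavage products with their termini (transesterification:
  2′,3′-cyclic phosphate / 5′-OH; hydrolysis: 3′-OH / 5′-phosphate);
- classifies the sequence context around each site against the record's
  characterized contexts and reports relative estimates — RRk (relative
  reported k_obs), RRY (relative reported yield), RCY (relative calculated
  yield) — with an explicit `basis` field stating how each was derived;
- filters and ranks candidates (region, arm length, Tm, mechanism, cofactor,
  pH, DNAzyme name) and writes CSV/JSON summaries, per-design JSON details
  with a plain-text duplex diagram, and a run manifest.

## Worked example

```bash
python examples/01_design_worked_example.py
```

prints

```
recognition site at RSS 6, scissile bond after position 6
arm1 (pairs the 3' flank): GGGGGA  Tm 22.0 C
arm2 (pairs the 5' flank): CTTTTT  Tm 14.0 C
assembled DNAzyme 5'->3': GGGGGAGGCTAGCCTTTTT
products: AAAAAG (2',3'-cyclic phosphate) + UCCCCC (5'-OH)

5'-AAAAAGUCCCCC-3'
   ||||||||||||
3'-TTTTTCAGGGGG-5'   [core as loop between arms, 5'->3': GGCTAGC]
        ^
```

The toy DNAzyme recognizes GU and cuts after the G at position 6. Its 5′ arm
GGGGGA is the DNA reverse complement of the downstream flank UCCCCC (Tm
5·4 + 1·2 = 22 °C); its 3′ arm CTTTTT pairs the upstream flank AAAAAG (Tm
1·4 + 5·2 = 14 °C). Transesterification leaves a 2′,3′-cyclic phosphate on the
5′ product and a 5′-OH on the 3′ product. `examples/02_scan_with_fixture_db.py`
and `examples/03_context_estimates.py` show full-database scans and
context-dependent RRk/RRY/RCY estimates.

The same pipeline is available from the shell:

```bash
dnazymekit fixtures --seed 11 --n-records 20 --out kb.json
dnazymekit design --substrate AAGUCAGUAGCUAGC --type rna --db kb.json \
    --arm-length 7 --out results_dir
dnazymekit db summary kb.json
```

An importer for external tabular DNAzyme databases is included
(`dnazymekit db import <table> --mapping data/supplementary_mapping.yaml`);
edit the mapping YAML to the table's column headers.

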