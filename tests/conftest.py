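"""Shared fixtures: toy substrates/records and independent oracles.

The oracle helpers here deliberately re-derive IUPAC matching and
Watson–Crick pairing from first principles (their own tables) so the tests
check the implementation against an independent route, not against itself.
"""

from __future__ import annotations

import random

import pytest

from dnazymekit import (
    ArchetypeSpec,
    ContextEntry,
    DnazymeRecord,
    ReactionType,
    SubstrateClass,
    substrate_from_string,
)

# ---------------------------------------------------------------------------
# independent oracle tables (do not import from the package)

ORACLE_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "M": "AC", "K": "GT", "S": "CG", "W": "AT",
    "H": "ACT", "B": "CGT", "V": "ACG", "D": "AGT", "N": "ACGT",
}

WATSON_CRICK = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"),
                ("A", "U"), ("U", "A")}


def oracle_letter_match(pattern: str, substrate: str) -> bool:
    if substrate not in "ACGTU":
        return False
    s = "T" if substrate == "U" else substrate
    return s in ORACLE_EXPANSION[pattern]


def oracle_find_sites(residues: str, rs_pattern: str, cleavage_offset: int):
    """Naive O(L*|RS|) window scan; returns [(rss, cleavage_position)]."""
    L, k = len(residues), len(rs_pattern)
    out = []
    for rss in range(1, L - k + 2):
        window = residues[rss - 1 : rss - 1 + k]
        if all(oracle_letter_match(p, s) for p, s in zip(rs_pattern, window)):
            p = rss + cleavage_offset - 1
            if 1 <= p <= L - 1:
                out.append((rss, p))
    return out


def realize_pattern(pattern: str, rng: random.Random, rna: bool) -> str:
    """Draw one concrete specified-letter sequence matching an IUPAC pattern."""
    out = []
    for letter in pattern:
        choice = rng.choice(ORACLE_EXPANSION[letter])
        out.append("U" if rna and choice == "T" else choice)
    return "".join(out)


# ---------------------------------------------------------------------------
# toy fixtures (the hand-derived worked example)

@pytest.fixture
def toy_substrate():
    return substrate_from_string("AAAAAGUCCCCC", "RNA")


@pytest.fixture
def toy_record():
    """RS 'GU' with the bond after its first residue; no contexts."""
    return DnazymeRecord(
        name="toy", variant_id="",
        substrate_class=SubstrateClass.RNA,
        reaction_type=ReactionType.TRANSESTERIFICATION,
        core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
    )


@pytest.fixture
def context_record():
    """Same RS, characterized in an original and one mutant context."""
    return DnazymeRecord(
        name="ctx", variant_id="",
        substrate_class=SubstrateClass.RNA,
        reaction_type=ReactionType.TRANSESTERIFICATION,
        core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
        contexts=(
            ContextEntry("AGUC", 1, 1, k_obs=2.0, yield_percent=85.0,
                         is_original=True),
            ContextEntry("AGUA", 1, 1, k_obs=0.5, yield_percent=40.0),
        ),
    )
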