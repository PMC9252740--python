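"""Arm design, assembly, product prediction, Tm, and diagram tests."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from dnazymekit import (
    ArchetypeSpec,
    ArmSpec,
    DnazymeRecord,
    ReactionType,
    SubstrateClass,
    TerminalOverride,
    assemble,
    design_arms,
    design_site,
    diagram,
    find_sites,
    generate_fixture_db,
    predict_products,
    substrate_from_string,
    tm_wallace,
)
from dnazymekit.designer import diagram_arm_windows
from dnazymekit.errors import DesignInfeasibleError
from conftest import WATSON_CRICK, realize_pattern


class TestWorkedExample:
    """Substrate AAAAAGUCCCCC, RS GU/offset 1, 6-nt arms — derived by hand."""

    @pytest.fixture
    def design(self, toy_substrate, toy_record):
        sites = find_sites(toy_substrate, toy_record)
        assert [(s.rss, s.cleavage_position) for s in sites] == [(6, 6)]
        return design_site(toy_substrate, sites[0], ArmSpec(length=6))

    def test_arm_sequences_and_windows(self, design):
        arms = design.arms
        assert arms.arm1 == "GGGGGA"      # pairs UCCCCC (7..12)
        assert arms.arm2 == "CTTTTT"      # pairs AAAAAG (1..6)
        assert arms.arm1_window == (7, 12)
        assert arms.arm2_window == (1, 6)

    def test_wallace_tms(self, design):
        assert design.arms.tm1_C == 22.0  # 5*4 + 1*2
        assert design.arms.tm2_C == 14.0  # 1*4 + 5*2

    def test_assembly(self, design):
        assert design.full_sequence == "GGGGGA" + "GGCTAGC" + "CTTTTT"
        assert design.components == (
            ("arm1", 1, 6), ("core", 7, 13), ("arm2", 14, 19),
        )

    def test_products(self, design):
        assert design.product_5p.sequence == "AAAAAG"
        assert design.product_3p.sequence == "UCCCCC"
        assert design.product_5p.end3 == "2',3'-cyclic phosphate"
        assert design.product_3p.end5 == "5'-OH"

    def test_diagram_round_trip(self, design):
        text = diagram(design)
        lines = text.split("\n")
        assert lines[0] == "5'-AAAAAGUCCCCC-3'"
        assert lines[1] == "   " + "|" * 12
        assert diagram_arm_windows(text) == [(1, 6), (7, 12)]
        assert "^" in lines[3]


class TestTmWallace:
    @pytest.mark.parametrize("arm,expected", [
        ("GGGGGA", 22.0), ("CTTTTT", 14.0), ("", 0.0), ("ACGT", 12.0),
    ])
    def test_examples(self, arm, expected):
        assert tm_wallace(arm) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGT", max_size=40),
           st.text(alphabet="ACGT", max_size=40))
    def test_additivity(self, x, y):
        assert tm_wallace(x + y) == tm_wallace(x) + tm_wallace(y)

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGT", max_size=40),
           st.sampled_from("ACGT"))
    def test_monotone_under_extension(self, x, extra):
        assert tm_wallace(x + extra) >= tm_wallace(x)


class TestDesignArms:
    def test_clipping_flags_long_request(self, toy_substrate, toy_record):
        site = find_sites(toy_substrate, toy_record)[0]
        arms = design_arms(toy_substrate, site, ArmSpec(length=20))
        assert arms.clipped
        assert arms.arm1_window == (7, 12) and arms.arm2_window == (1, 6)
        assert len(arms.arm1) == 6 and len(arms.arm2) == 6

    def test_terminal_override_forces_letter(self, toy_substrate, toy_record):
        arch = ArchetypeSpec(terminal_overrides=(
            TerminalOverride(arm="arm2", position_from_junction=1, letter="T"),
        ))
        site = find_sites(toy_substrate, toy_record)[0]
        arms = design_arms(toy_substrate, site, ArmSpec(length=6), arch)
        # arm2's junction-adjacent (5') letter pairs substrate G at position 6
        assert arms.arm2[0] == "T"
        assert arms.arm2 == "TTTTTT"
        assert arms.overridden == (("arm2", 6, "T"),)

    def test_unpaired_offset_shifts_coverage(self, toy_substrate, toy_record):
        arch = ArchetypeSpec(unpaired_substrate_offsets=(1,))  # position 7 unpaired
        site = find_sites(toy_substrate, toy_record)[0]
        arms = design_arms(toy_substrate, site, ArmSpec(length=5), arch)
        assert 7 not in arms.arm1_positions
        assert arms.arm1_window == (8, 12)

    def test_target_tm_mode_shortest_window(self, toy_substrate, toy_record):
        site = find_sites(toy_substrate, toy_record)[0]
        arms = design_arms(toy_substrate, site, ArmSpec(target_tm=18.0))
        # arm1 grows into CCCCC...: 5 nt (GGGGG) reach Tm 20 >= 18
        assert arms.tm1_C >= 18.0
        assert len(arms.arm1) == 5
        assert arms.tm2_C < 18.0 and arms.clipped  # AT-rich flank cannot reach it

    def test_too_short_flank_is_infeasible(self):
        sub = substrate_from_string("AAGUCCCCCC", "RNA")
        rec = DnazymeRecord(
            name="t", variant_id="", substrate_class=SubstrateClass.RNA,
            reaction_type=ReactionType.TRANSESTERIFICATION,
            core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
        )
        site = find_sites(sub, rec)[0]  # rss=3 -> only 3 nt 5' of the bond
        with pytest.raises(DesignInfeasibleError):
            design_arms(sub, site, ArmSpec(length=6))

    def test_ambiguity_letter_borders_the_arm(self):
        # an N two residues into the 3' flank leaves only 3 pairable nt there
        sub = substrate_from_string("AAAAAGUCCNCC", "RNA")
        rec = DnazymeRecord(
            name="t", variant_id="", substrate_class=SubstrateClass.RNA,
            reaction_type=ReactionType.TRANSESTERIFICATION,
            core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
        )
        site = find_sites(sub, rec)[0]
        with pytest.raises(DesignInfeasibleError):
            design_arms(sub, site, ArmSpec(length=6))
        # with a longer specified flank past the N the arm stops before it
        sub2 = substrate_from_string("AAAAAGUCCCCNCC", "RNA")
        site2 = find_sites(sub2, rec)[0]
        arms = design_arms(sub2, site2, ArmSpec(length=8))
        assert arms.arm1_window == (7, 11)  # stops before the N at 12
        assert arms.clipped

    def test_products_at_boundary(self):
        sub = substrate_from_string("GUAAAA", "RNA")
        rec = DnazymeRecord(
            name="t", variant_id="", substrate_class=SubstrateClass.RNA,
            reaction_type=ReactionType.TRANSESTERIFICATION,
            core_sequence="GGCTAGC", rs_pattern="GU", cleavage_offset=1,
        )
        site = find_sites(sub, rec)[0]
        p5, p3 = predict_products(sub, site)
        assert (len(p5.sequence), len(p3.sequence)) == (1, 5)
        assert p5.sequence + p3.sequence == sub.residues

    def test_hydrolysis_termini_labels(self):
        sub = substrate_from_string("AAAAAGTCCCCC", "DNA")
        rec = DnazymeRecord(
            name="h", variant_id="", substrate_class=SubstrateClass.DNA,
            reaction_type=ReactionType.HYDROLYSIS,
            core_sequence="GGCTAGC", rs_pattern="GT", cleavage_offset=1,
        )
        site = find_sites(sub, rec)[0]
        p5, p3 = predict_products(sub, site)
        assert p5.end3 == "3'-OH" and p3.end5 == "5'-phosphate"


def random_designs(n, seed, arm_len=(5, 12)):
    """Yield n random (substrate, site, design) triples from fixture records."""
    rng = random.Random(seed)
    db = generate_fixture_db(seed=seed, n_records=40)
    produced = 0
    while produced < n:
        rec = rng.choice(db.records)
        rna = rec.substrate_class is SubstrateClass.RNA
        alphabet = "ACGU" if rna else "ACGT"
        flank = "".join(rng.choice(alphabet) for _ in range(rng.randint(12, 30)))
        flank2 = "".join(rng.choice(alphabet) for _ in range(rng.randint(12, 30)))
        text = flank + realize_pattern(rec.rs_pattern, rng, rna) + flank2
        sub = substrate_from_string(text, "RNA" if rna else "DNA")
        sites = find_sites(sub, rec)
        if not sites:
            continue
        site = rng.choice(sites)
        try:
            design = design_site(sub, site, ArmSpec(length=rng.randint(*arm_len)))
        except DesignInfeasibleError:
            continue
        yield sub, site, design
        produced += 1


def assert_design_sound(sub, site, design):
    arms = design.arms
    overridden = {(arm, pos) for arm, pos, _ in arms.overridden}
    # hybridization oracle: antiparallel Watson–Crick pairing over coverage
    for positions, arm, label in (
        (arms.arm1_positions, arms.arm1, "arm1"),
        (arms.arm2_positions, arms.arm2, "arm2"),
    ):
        assert len(positions) == len(arm)
        for q, letter in zip(positions, reversed(arm)):
            if (label, q) in overridden:
                continue
            assert (letter, sub.residue(q)) in WATSON_CRICK, (
                f"{label} letter {letter} does not pair substrate "
                f"{sub.residue(q)} at {q}"
            )
    rec = site.record
    assert design.full_sequence == arms.arm1 + rec.core_sequence + arms.arm2
    assert (design.product_5p.sequence + design.product_3p.sequence
            == sub.residues)
    assert len(design.product_5p.sequence) == site.cleavage_position
    labels = [c[0] for c in design.components]
    assert labels == ["arm1", "core", "arm2"]
    spans = [(s, e) for _, s, e in design.components]
    assert spans[0][0] == 1 and spans[-1][1] == len(design.full_sequence)
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        assert s2 == e1 + 1


class TestDesignSoundnessSweep:
    def test_random_designs_sound(self):
        for sub, site, design in random_designs(300, seed=11):
            assert_design_sound(sub, site, design)

    def test_extension_never_lowers_tm(self):
        for sub, site, design in random_designs(50, seed=17):
            arms = design.arms
            shorter = design_arms(sub, site, ArmSpec(length=max(5, len(arms.arm1) - 1)))
            assert arms.tm1_C >= shorter.tm1_C
            assert arms.tm2_C >= shorter.tm2_C
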