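"""Binding-arm design, DNAzyme assembly, and cleavage-product prediction.

A trans-cleaving DNAzyme is assembled as ``arm1 + catalytic core + arm2``
(5'->3'). The 5' arm (arm1) base-pairs the substrate region 3' of the
scissile bond and the 3' arm (arm2) the region 5' of it, both antiparallel,
so each arm is the DNA-alphabet reverse complement of the substrate window
it covers. The record's archetype shifts the duplex borders away from the
junction, leaves listed substrate positions unpaired, and may force
non-Watson–Crick letters at junction-adjacent arm positions (wobbles).

Arm melting temperatures use the Wallace rule (2 deg C per A/T, 4 deg C per
G/C) — exact, deterministic, and standard for the short (< ~14 nt) arms
this tool emits. RNA·DNA duplex corrections are not applied and outputs
flag the model used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple, TYPE_CHECKING, Union

from .errors import DesignInfeasibleError, DnazymekitError
from .knowledgebase import ArchetypeSpec, DnazymeRecord, ReactionType
from .scanner import SiteMatch
from .seqio import SubstrateSequence

if TYPE_CHECKING:  # pragma: no cover
    from .estimator_report import Estimates

#: complement into DNA letters (arms are synthesized as DNA)
_DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}

#: substrate letters an arm can pair; ambiguity codes have no defined partner
_PAIRABLE = frozenset("ACGTU")

MIN_ARM_LENGTH = 5
DEFAULT_ARM_LENGTH = 10


@dataclass(frozen=True)
class ArmSpec:
    """How to size the binding arms: a fixed length or a target Wallace Tm."""

    length: Optional[int] = None
    target_tm: Optional[float] = None

    def __post_init__(self):
        if self.length is not None and self.target_tm is not None:
            raise DnazymekitError("give either a fixed arm length or a target Tm")
        if self.length is not None and self.length < 1:
            raise DnazymekitError("arm length must be >= 1")


@dataclass(frozen=True)
class ArmPair:
    """The two designed binding arms, with coverage and melting temperatures.

    ``arm1`` (DNAzyme 5' arm) pairs ``arm1_window`` = the substrate interval
    3' of the scissile bond; ``arm2`` pairs the interval 5' of it. Windows
    are 1-based inclusive. ``armN_positions`` lists the covered substrate
    positions (ascending) — equal to the window span unless the archetype
    leaves positions unpaired.
    """

    arm1: str
    arm2: str
    arm1_window: Tuple[int, int]
    arm2_window: Tuple[int, int]
    tm1_C: float
    tm2_C: float
    arm1_positions: Tuple[int, ...] = ()
    arm2_positions: Tuple[int, ...] = ()
    overridden: Tuple[Tuple[str, int, str], ...] = ()  # (arm, substrate pos, letter)
    clipped: bool = False
    notes: Tuple[str, ...] = ()


@dataclass(frozen=True)
class Product:
    """One cleavage product with its termini chemistry."""

    sequence: str
    end5: str
    end3: str


@dataclass(frozen=True)
class Assembly:
    full_sequence: str
    components: Tuple[Tuple[str, int, int], ...]  # (label, start, end) on full_sequence


@dataclass(frozen=True)
class DesignResult:
    """One fully assembled DNAzyme for one recognition site."""

    site: SiteMatch
    arms: ArmPair
    full_sequence: str
    components: Tuple[Tuple[str, int, int], ...]
    product_5p: Product
    product_3p: Product
    conditions: dict
    estimates: Optional["Estimates"] = None
    notes: Tuple[str, ...] = ()

    @property
    def record(self) -> DnazymeRecord:
        return self.site.record


def tm_wallace(arm: str) -> float:
    """Wallace-rule Tm in deg C: 2*(A+T) + 4*(G+C). Empty arm -> 0 (flagged upstream)."""
    if not arm:
        return 0.0
    if not set(arm) <= set("ACGT"):
        raise DnazymekitError(f"Wallace Tm is defined for DNA letters only, got {arm!r}")
    at = arm.count("A") + arm.count("T")
    gc = arm.count("G") + arm.count("C")
    return float(2 * at + 4 * gc)


def _collect_positions(
    substrate: SubstrateSequence,
    start: int,
    step: int,
    excluded: frozenset,
    spec: ArmSpec,
) -> Tuple[List[int], bool, List[str]]:
    """Walk outward from the junction collecting pairable positions.

    Extension stops at the substrate end or at an ambiguity letter (no
    complement is defined for those, so they behave like a border). Returns
    (positions in walk order, clipped flag, notes).
    """
    notes: List[str] = []
    positions: List[int] = []
    want_len = spec.length if spec.length is not None else None
    tm_so_far = 0.0
    pos = start
    while 1 <= pos <= substrate.length:
        if pos in excluded:
            pos += step
            continue
        letter = substrate.residue(pos)
        if letter not in _PAIRABLE:
            notes.append(
                f"arm extension stopped at ambiguous substrate letter "
                f"{letter} (position {pos})"
            )
            break
        positions.append(pos)
        tm_so_far += 2.0 if _DNA_COMPLEMENT[letter] in "AT" else 4.0
        if want_len is not None and len(positions) >= want_len:
            return positions, False, notes
        if (
            spec.target_tm is not None
            and tm_so_far >= spec.target_tm
            and len(positions) >= MIN_ARM_LENGTH
        ):
            return positions, False, notes
        pos += step
    # ran out of substrate (or hit an ambiguity letter)
    clipped = True
    if spec.target_tm is not None and len(positions) >= MIN_ARM_LENGTH:
        notes.append(
            f"target Tm {spec.target_tm} deg C unreachable; arm clipped at "
            f"{len(positions)} nt"
        )
    return positions, clipped, notes


def design_arms(
    substrate: SubstrateSequence,
    site: SiteMatch,
    arm_spec: Optional[ArmSpec] = None,
    archetype: Optional[ArchetypeSpec] = None,
) -> ArmPair:
    """Design both binding arms for a site per the record's archetype.

    Arm 1 starts at ``cleavage_position + right_cover_start + 1`` and grows
    3'; arm 2 ends at ``cleavage_position + left_cover_end`` and grows 5'.
    In fixed-length mode each arm takes that many pairable residues (clipped
    at substrate ends); in target-Tm mode each arm is the shortest window
    whose Wallace Tm reaches the target (minimum 5 nt). Arms that end up
    shorter than 5 nt are rejected as design-infeasible.
    """
    spec = arm_spec or ArmSpec(length=DEFAULT_ARM_LENGTH)
    arch = archetype if archetype is not None else site.record.archetype
    p = site.cleavage_position
    excluded = frozenset(p + off for off in arch.unpaired_substrate_offsets)

    pos1, clip1, notes1 = _collect_positions(
        substrate, p + arch.right_cover_start + 1, +1, excluded, spec
    )
    pos2, clip2, notes2 = _collect_positions(
        substrate, p + arch.left_cover_end, -1, excluded, spec
    )
    pos2 = pos2[::-1]  # ascending substrate order

    for label, pos in (("arm1", pos1), ("arm2", pos2)):
        if len(pos) < MIN_ARM_LENGTH:
            raise DesignInfeasibleError(
                f"{label} has only {len(pos)} pairable residue(s) at cleavage "
                f"position {p}; minimum is {MIN_ARM_LENGTH} nt"
            )

    # antiparallel: arm letters 5'->3' pair descending substrate positions
    arm1_letters = [_DNA_COMPLEMENT[substrate.residue(q)] for q in reversed(pos1)]
    arm2_letters = [_DNA_COMPLEMENT[substrate.residue(q)] for q in reversed(pos2)]

    overridden: List[Tuple[str, int, str]] = []
    for ov in arch.terminal_overrides:
        if ov.arm == "arm1":
            idx = len(arm1_letters) - ov.position_from_junction  # 3' end abuts core
            if 0 <= idx < len(arm1_letters):
                arm1_letters[idx] = ov.letter
                overridden.append(("arm1", pos1[ov.position_from_junction - 1], ov.letter))
        elif ov.arm == "arm2":
            idx = ov.position_from_junction - 1  # 5' end abuts core
            if 0 <= idx < len(arm2_letters):
                arm2_letters[idx] = ov.letter
                overridden.append(("arm2", pos2[-ov.position_from_junction], ov.letter))

    arm1 = "".join(arm1_letters)
    arm2 = "".join(arm2_letters)
    clipped = clip1 or clip2
    notes = tuple(notes1 + notes2 + (["arm clipped at substrate end"] if clipped else []))
    return ArmPair(
        arm1=arm1,
        arm2=arm2,
        arm1_window=(min(pos1), max(pos1)),
        arm2_window=(min(pos2), max(pos2)),
        tm1_C=tm_wallace(arm1),
        tm2_C=tm_wallace(arm2),
        arm1_positions=tuple(pos1),
        arm2_positions=tuple(pos2),
        overridden=tuple(overridden),
        clipped=clipped,
        notes=notes,
    )


def assemble(arms: ArmPair, record: DnazymeRecord) -> Assembly:
    """Concatenate arm1 + core + arm2 with a gap-free component segmentation."""
    if not arms.arm1 or not arms.arm2:
        raise DesignInfeasibleError("cannot assemble a DNAzyme with an empty arm")
    core = record.core_sequence
    full = arms.arm1 + core + arms.arm2
    a1, c = len(arms.arm1), len(core)
    components = (
        ("arm1", 1, a1),
        ("core", a1 + 1, a1 + c),
        ("arm2", a1 + c + 1, len(full)),
    )
    return Assembly(full_sequence=full, components=components)


def predict_products(
    substrate: SubstrateSequence,
    site: SiteMatch,
    reaction_type: Optional[ReactionType] = None,
) -> Tuple[Product, Product]:
    """Split the substrate at the scissile bond and label the new termini.

    Transesterification (2'-OH attack) leaves a 2',3'-cyclic phosphate on
    the 5' product and a 5'-OH on the 3' product; hydrolysis leaves 3'-OH /
    5'-phosphate by default.
    """
    rt = reaction_type if reaction_type is not None else site.record.reaction_type
    p = site.cleavage_position
    seq5 = substrate.residues[:p]
    seq3 = substrate.residues[p:]
    if rt is ReactionType.TRANSESTERIFICATION:
        new3, new5 = "2',3'-cyclic phosphate", "5'-OH"
    else:
        new3, new5 = "3'-OH", "5'-phosphate"
    return (
        Product(sequence=seq5, end5="substrate 5' end", end3=new3),
        Product(sequence=seq3, end5=new5, end3="substrate 3' end"),
    )


def conditions_snapshot(record: DnazymeRecord) -> dict:
    """The record's reaction conditions, frozen into the design result."""
    return {
        "cofactors": [
            {"name": c.name, "concentration": c.concentration, "unit": c.unit}
            for c in record.cofactors
        ],
        "ph_min": record.ph_min,
        "ph_max": record.ph_max,
        "temperature_C": record.temperature_C,
        "incubation": record.incubation,
        "tm_model": "Wallace rule (no RNA-DNA duplex correction)",
    }


def design_site(
    substrate: SubstrateSequence,
    site: SiteMatch,
    arm_spec: Optional[ArmSpec] = None,
) -> DesignResult:
    """Arms + assembly + products for one site (estimates attached later)."""
    arms = design_arms(substrate, site, arm_spec)
    assembly = assemble(arms, site.record)
    p5, p3 = predict_products(substrate, site)
    notes = list(arms.notes)
    if site.context_clipped:
        notes.append("context clipped at substrate end")
    if arms.overridden:
        for arm, pos, letter in arms.overridden:
            notes.append(
                f"terminal override: {arm} forces {letter} opposite substrate "
                f"position {pos}"
            )
    return DesignResult(
        site=site,
        arms=arms,
        full_sequence=assembly.full_sequence,
        components=assembly.components,
        product_5p=p5,
        product_3p=p3,
        conditions=conditions_snapshot(site.record),
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# plain-text duplex diagram

_PREFIX = "5'-"


def diagram(result: DesignResult) -> str:
    """Render the DNAzyme–substrate duplex as aligned text.

    Line 1: substrate 5'->3'. Line 2: pairing bars ('|' Watson–Crick, '.'
    override or unpaired-by-archetype, ' ' uncovered). Line 3: the DNAzyme
    arms 3'->5' under their paired regions, with the catalytic core noted as
    a loop at the end of the line. Line 4: a caret under the residue 5' of
    the scissile bond.
    """
    substrate_line = _PREFIX + _substrate_string(result) + "-3'"
    L = len(_substrate_string(result))
    arms = result.arms
    bars = [" "] * L
    dz = [" "] * L
    override_cols = {pos for _, pos, _ in arms.overridden}

    for positions, arm, window in (
        (arms.arm1_positions, arms.arm1, arms.arm1_window),
        (arms.arm2_positions, arms.arm2, arms.arm2_window),
    ):
        # arm letters 5'->3' pair descending substrate positions; rendering
        # left-to-right along the substrate therefore reverses the arm
        for col, letter in zip(positions, reversed(arm)):
            bars[col - 1] = "." if col in override_cols else "|"
            dz[col - 1] = letter
        lo, hi = window
        for col in range(lo, hi + 1):  # archetype-unpaired gaps inside the window
            if bars[col - 1] == " ":
                bars[col - 1] = "."
                dz[col - 1] = "-"

    p = result.site.cleavage_position
    caret_line = " " * (len(_PREFIX) + p - 1) + "^"
    core = result.record.core_sequence
    dz_line = (
        "3'-" + "".join(dz) + "-5'" + f"   [core as loop between arms, 5'->3': {core}]"
    )
    bar_line = " " * len(_PREFIX) + "".join(bars)
    return "\n".join([substrate_line, bar_line, dz_line, caret_line])


def _substrate_string(result: DesignResult) -> str:
    return result.product_5p.sequence + result.product_3p.sequence


def diagram_arm_windows(text: str) -> List[Tuple[int, int]]:
    """Recover covered substrate intervals from a diagram's bar line.

    Returns the contiguous non-space runs of line 2 as 1-based inclusive
    intervals, left to right (arm2's window precedes arm1's). When the two
    arms abut at the cleavage junction their bars form one run; the caret
    line locates the scissile bond and the run is split there.
    """
    lines = text.split("\n")
    bar_line = lines[1][len(_PREFIX):]
    runs: List[Tuple[int, int]] = []
    start = None
    for i, ch in enumerate(bar_line, start=1):
        if ch != " " and start is None:
            start = i
        elif ch == " " and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(bar_line)))
    if len(lines) > 3 and "^" in lines[3]:
        p = lines[3].index("^") - len(_PREFIX) + 1  # residue 5' of the bond
        split: List[Tuple[int, int]] = []
        for lo, hi in runs:
            if lo <= p < hi:
                split.extend([(lo, p), (p + 1, hi)])
            else:
                split.append((lo, hi))
        runs = split
    return runs
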