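"""Recognition-site scanning with IUPAC degeneracy.

A DNAzyme's recognition site (RS) is a short, possibly degenerate pattern
the substrate must present around the scissile bond. The scanner slides
each record's pattern over the sanitized substrate and reports every
occurrence as a :class:`SiteMatch` carrying the recognition-site start
(RSS), the cleavage position (the 1-based index of the residue 5' of the
scissile bond), and the context classification used later for kinetics
estimates.

Matching rules: a pattern letter matches only fully specified substrate
letters (A, C, G, T, U) drawn from its IUPAC expansion — ambiguity codes on
the substrate never match, since no unique complementary nucleotide exists
for them — and T and U are equivalent so one pattern alphabet serves DNA
and RNA substrates alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .errors import DnazymekitError
from .knowledgebase import (
    ContextEntry,
    DnazymeRecord,
    KnowledgeBase,
    ReactionType,
    SubstrateClass,
)
from .seqio import Backbone, SubstrateSequence, SubstrateType

#: IUPAC expansions over the T-normalized specified alphabet.
IUPAC_EXPANSION = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "M": frozenset("AC"),
    "K": frozenset("GT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "H": frozenset("ACT"), "B": frozenset("CGT"), "V": frozenset("ACG"),
    "D": frozenset("AGT"), "N": frozenset("ACGT"),
}

_SPECIFIED = frozenset("ACGTU")


@dataclass(frozen=True)
class SiteMatch:
    """One recognition-site occurrence on the substrate."""

    record: DnazymeRecord
    rss: int                     # 1-based RS start
    rs_observed: str
    cleavage_position: int       # bond between this residue and the next
    context_observed: str = ""
    matched_context: Optional[ContextEntry] = None
    context_clipped: bool = False


def iupac_match(pattern_letter: str, substrate_letter: str) -> bool:
    """True iff the substrate letter is specified and in the pattern's expansion.

    T and U are interchangeable on both sides. An ambiguous substrate letter
    (R, Y, ... N) never matches, even against pattern N.
    """
    if pattern_letter not in IUPAC_EXPANSION:
        raise DnazymekitError(f"invalid IUPAC pattern letter {pattern_letter!r}")
    if substrate_letter not in IUPAC_EXPANSION:
        raise DnazymekitError(f"invalid IUPAC substrate letter {substrate_letter!r}")
    if substrate_letter not in _SPECIFIED:
        return False
    normalized = "T" if substrate_letter == "U" else substrate_letter
    return normalized in IUPAC_EXPANSION[pattern_letter]


def _pattern_matches(pattern: str, window: str) -> bool:
    return len(pattern) == len(window) and all(
        iupac_match(p, s) for p, s in zip(pattern, window)
    )


def record_compatible(substrate: SubstrateSequence, record: DnazymeRecord) -> bool:
    """Class compatibility: RNA-cleavers take RNA/chimeric substrates, DNA-cleavers DNA/chimeric."""
    if record.substrate_class is SubstrateClass.RNA:
        return substrate.substrate_type in (SubstrateType.RNA, SubstrateType.CHIMERIC)
    if record.substrate_class is SubstrateClass.DNA:
        return substrate.substrate_type in (SubstrateType.DNA, SubstrateType.CHIMERIC)
    return True  # chimeric-substrate records scan anything


def _required_backbone(record: DnazymeRecord) -> Optional[Backbone]:
    """Backbone the scissile residue must carry (2'-OH chemistry for transesterification)."""
    if record.reaction_type is ReactionType.TRANSESTERIFICATION:
        return Backbone.RIBO
    if record.substrate_class is SubstrateClass.RNA:
        return Backbone.RIBO
    if record.substrate_class is SubstrateClass.DNA:
        return Backbone.DEOXY
    return None


def find_sites(
    substrate: SubstrateSequence, record: DnazymeRecord
) -> List[SiteMatch]:
    """All RS occurrences of ``record`` on ``substrate``, in ascending RSS.

    A window matches when every pattern position satisfies
    :func:`iupac_match`. Matches whose implied cleavage position leaves no
    bond on one side (p < 1 or p >= L) are dropped, as are matches where the
    scissile residue's backbone contradicts the record's chemistry (relevant
    for chimeric substrates).
    """
    if not record_compatible(substrate, record):
        return []
    pattern = record.rs_pattern
    L = substrate.length
    k = len(pattern)
    need_bb = _required_backbone(record)
    out: List[SiteMatch] = []
    for rss in range(1, L - k + 2):
        window = substrate.slice(rss, rss + k - 1)
        if not _pattern_matches(pattern, window):
            continue
        p = rss + record.cleavage_offset - 1
        if not 1 <= p <= L - 1:
            continue
        if need_bb is not None and substrate.backbone_at(p) is not need_bb:
            continue
        out.append(
            SiteMatch(
                record=record,
                rss=rss,
                rs_observed=window,
                cleavage_position=p,
            )
        )
    return out


def match_context(
    substrate: SubstrateSequence, site: SiteMatch, record: DnazymeRecord
) -> SiteMatch:
    """Classify the sequence context around a site.

    The context window spans ``[rss - flank5, rss + |RS| - 1 + flank3]``.
    Contexts are tried original-first, then in record order; the first whose
    pattern matches position-wise wins. When the window runs off either
    substrate end it is clipped, reported, and left unmatched (kinetics then
    fall back to the nearest-context model).
    """
    k = len(record.rs_pattern)
    L = substrate.length
    ordered = sorted(record.contexts, key=lambda c: not c.is_original)
    observed = ""
    clipped = False
    matched: Optional[ContextEntry] = None
    for ctx in ordered:
        start = site.rss - ctx.flank5_len
        end = site.rss + k - 1 + ctx.flank3_len
        win_clipped = start < 1 or end > L
        window = substrate.slice(max(1, start), min(L, end))
        if not observed:  # report the first (original-priority) window
            observed, clipped = window, win_clipped
        if win_clipped:
            continue
        if _pattern_matches(ctx.context_pattern, window):
            matched, observed, clipped = ctx, window, False
            break
    return SiteMatch(
        record=site.record,
        rss=site.rss,
        rs_observed=site.rs_observed,
        cleavage_position=site.cleavage_position,
        context_observed=observed,
        matched_context=matched,
        context_clipped=clipped,
    )


def scan_all(substrate: SubstrateSequence, db: KnowledgeBase) -> List[SiteMatch]:
    """Every context-classified site of every record, in (name, variant, rss) order."""
    sites: List[SiteMatch] = []
    for record in sorted(db.records, key=lambda r: (r.name, r.variant_id)):
        for site in find_sites(substrate, record):
            sites.append(match_context(substrate, site, record))
    return sites
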