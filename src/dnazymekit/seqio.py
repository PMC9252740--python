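"""Substrate input: parsing, sanitization, and strand/alphabet transforms.

A substrate arrives as FASTA, EMBL, GenBank, or RAW text (one record only),
is sanitized to the 15-letter IUPAC nucleotide alphabet, and is stored with
a per-residue backbone flag (deoxy/ribo) so DNA, RNA, and chimeric
substrates share one representation. All downstream coordinates are 1-based
on the sanitized sequence; characters deleted during sanitization are kept
in a ``removed`` map for traceability.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Tuple, Union

from Bio import SeqIO

from .errors import (
    AlphabetConflictError,
    EmptySubstrateError,
    FormatError,
    MultiRecordError,
    SubstrateLengthError,
    UnsupportedConversionError,
)

MAX_SUBSTRATE_LENGTH = 2000

#: The 15 accepted IUPAC nucleotide letters.
IUPAC_LETTERS = frozenset("ACGTURYMKSWHBVDN")

#: Fully specified nucleotides; ambiguity letters never take part in design.
SPECIFIED_LETTERS = frozenset("ACGTU")

#: IUPAC complement table (T/U handled by alphabet at render time).
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "M": "K", "K": "M", "S": "S", "W": "W",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


class SeqFormat(str, Enum):
    FASTA = "FASTA"
    EMBL = "EMBL"
    GENBANK = "GENBANK"
    RAW = "RAW"


class SubstrateType(str, Enum):
    DNA = "DNA"
    RNA = "RNA"
    CHIMERIC = "chimeric"


class Backbone(str, Enum):
    DEOXY = "deoxy"
    RIBO = "ribo"


@dataclass(frozen=True)
class RawInput:
    """One sequence record as read from its source, before sanitization."""

    source_id: str
    body: str
    format: SeqFormat


@dataclass(frozen=True)
class SubstrateSequence:
    """A sanitized substrate with per-residue backbone annotation.

    ``residues`` is an uppercase string over the 15 IUPAC letters;
    ``backbone[i]`` gives the sugar of residue ``i`` (0-based internally,
    but all reported positions are 1-based). ``removed`` records every
    character deleted during sanitization as ``(1-based index in the raw
    body, original character)``, in increasing position order.
    """

    id: str
    residues: str
    backbone: Tuple[Backbone, ...]
    substrate_type: SubstrateType
    removed: Tuple[Tuple[int, str], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if len(self.residues) != len(self.backbone):
            raise ValueError("residues and backbone lengths differ")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def residue(self, pos: int) -> str:
        """Residue at 1-based position ``pos``."""
        return self.residues[pos - 1]

    def backbone_at(self, pos: int) -> Backbone:
        """Backbone flag at 1-based position ``pos``."""
        return self.backbone[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """Substring over the 1-based inclusive interval [start, end]."""
        return self.residues[start - 1 : end]


def detect_format(text: str) -> SeqFormat:
    """Auto-detect the input format.

    Detection order is fixed: leading ``>`` means FASTA, leading ``LOCUS``
    GenBank, leading ``ID`` EMBL; anything else is treated as RAW text.
    """
    stripped = text.lstrip()
    if stripped.startswith(">"):
        return SeqFormat.FASTA
    if stripped.startswith("LOCUS"):
        return SeqFormat.GENBANK
    if stripped.startswith("ID"):
        return SeqFormat.EMBL
    return SeqFormat.RAW


_BIOPYTHON_FORMAT = {
    SeqFormat.FASTA: "fasta",
    SeqFormat.EMBL: "embl",
    SeqFormat.GENBANK: "genbank",
}


def read_sequence(
    source: Union[str, os.PathLike],
    format_hint: Optional[Union[SeqFormat, str]] = None,
) -> RawInput:
    """Read exactly one substrate record from a file path or literal text.

    ``source`` is first tried as a path; if no such file exists it is taken
    as the sequence text itself. Without ``format_hint`` the format is
    auto-detected (FASTA -> GenBank -> EMBL -> RAW, by leading token).

    Raises
    ------
    MultiRecordError
        if the file holds more than one record.
    FormatError
        if the text cannot be parsed in the detected/forced format.
    """
    if isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.isfile(source)
    ):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
        default_id = os.path.splitext(os.path.basename(os.fspath(source)))[0]
    else:
        text = str(source)
        default_id = "substrate"

    if not text.strip():
        raise FormatError("input is empty")

    fmt = SeqFormat(format_hint) if format_hint is not None else detect_format(text)

    if fmt is SeqFormat.RAW:
        return RawInput(source_id=default_id, body=text, format=fmt)

    try:
        records = list(SeqIO.parse(io.StringIO(text), _BIOPYTHON_FORMAT[fmt]))
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FormatError(f"could not parse input as {fmt.value}: {exc}") from exc
    if len(records) == 0:
        raise FormatError(f"no sequence record found in {fmt.value} input")
    if len(records) > 1:
        raise MultiRecordError(len(records))
    rec = records[0]
    return RawInput(source_id=rec.id or default_id, body=str(rec.seq), format=fmt)


def sanitize(
    raw: RawInput,
    substrate_type: Union[SubstrateType, str] = SubstrateType.DNA,
) -> SubstrateSequence:
    """Sanitize a raw record into a :class:`SubstrateSequence`.

    Letters outside the 15 IUPAC codes (whitespace, digits, punctuation, X,
    ...) are deleted and recorded in ``removed``. For DNA/RNA substrates the
    backbone is uniform; for chimeric substrates lowercase input letters
    denote ribonucleotides and uppercase deoxynucleotides (a common
    oligo-ordering convention), and all residues are stored uppercase with
    explicit per-residue flags.

    Raises
    ------
    EmptySubstrateError
        if nothing remains after sanitization.
    SubstrateLengthError
        if more than 2000 residues remain.
    AlphabetConflictError
        on a type/letter conflict (U in DNA, T in RNA, or — chimeric — a
        deoxy U / ribo T).
    """
    stype = SubstrateType(substrate_type)
    residues: list[str] = []
    backbone: list[Backbone] = []
    removed: list[Tuple[int, str]] = []

    for idx, ch in enumerate(raw.body, start=1):
        upper = ch.upper()
        if upper not in IUPAC_LETTERS:
            removed.append((idx, ch))
            continue
        if stype is SubstrateType.DNA:
            bb = Backbone.DEOXY
        elif stype is SubstrateType.RNA:
            bb = Backbone.RIBO
        else:
            bb = Backbone.RIBO if ch.islower() else Backbone.DEOXY
        if upper == "U" and bb is Backbone.DEOXY:
            raise AlphabetConflictError(
                f"U at raw position {idx} conflicts with a deoxyribose backbone "
                f"(substrate type {stype.value})"
            )
        if upper == "T" and bb is Backbone.RIBO:
            raise AlphabetConflictError(
                f"T at raw position {idx} conflicts with a ribose backbone "
                f"(substrate type {stype.value})"
            )
        residues.append(upper)
        backbone.append(bb)

    if not residues:
        raise EmptySubstrateError("no IUPAC nucleotide letters remain after sanitization")
    if len(residues) > MAX_SUBSTRATE_LENGTH:
        raise SubstrateLengthError(len(residues))

    return SubstrateSequence(
        id=raw.source_id,
        residues="".join(residues),
        backbone=tuple(backbone),
        substrate_type=stype,
        removed=tuple(removed),
    )


def _render(letter: str, bb: Backbone) -> str:
    """Render a complemented letter in the alphabet its backbone dictates."""
    if letter == "T" and bb is Backbone.RIBO:
        return "U"
    if letter == "U" and bb is Backbone.DEOXY:
        return "T"
    return letter


def reverse_complement(seq: SubstrateSequence) -> SubstrateSequence:
    """Reverse complement in the substrate's own alphabet.

    A pairs T on a deoxy backbone and U on a ribo one; ambiguity codes
    complement by the IUPAC rules (R<->Y, M<->K, S<->S, W<->W, B<->V,
    D<->H, N<->N). Backbone flags are reversed in order, and each
    complemented letter is rendered in the alphabet of its own backbone.
    """
    new_backbone = tuple(reversed(seq.backbone))
    comp = [_COMPLEMENT[c] for c in reversed(seq.residues)]
    residues = "".join(_render(c, bb) for c, bb in zip(comp, new_backbone))
    return replace(seq, residues=residues, backbone=new_backbone)


def convert_type(
    seq: SubstrateSequence, target: Union[SubstrateType, str]
) -> SubstrateSequence:
    """Convert a DNA substrate to RNA or vice versa (T<->U swap).

    Chimeric substrates have no single target alphabet and are rejected.
    """
    target = SubstrateType(target)
    if seq.substrate_type is SubstrateType.CHIMERIC or target is SubstrateType.CHIMERIC:
        raise UnsupportedConversionError(
            "DNA<->RNA conversion is defined only for uniform-backbone substrates"
        )
    if target is SubstrateType.DNA:
        residues = seq.residues.replace("U", "T")
        bb = Backbone.DEOXY
    else:
        residues = seq.residues.replace("T", "U")
        bb = Backbone.RIBO
    return replace(
        seq,
        residues=residues,
        backbone=tuple(bb for _ in residues),
        substrate_type=target,
    )


def substrate_from_string(
    text: str,
    substrate_type: Union[SubstrateType, str] = SubstrateType.DNA,
    seq_id: str = "substrate",
) -> SubstrateSequence:
    """Convenience: sanitize a literal sequence string (RAW path)."""
    return sanitize(
        RawInput(source_id=seq_id, body=text, format=SeqFormat.RAW), substrate_type
    )
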