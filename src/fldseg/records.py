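"""Shared record model for the pipeline.

All coordinates are 0-based, half-open. Conversion to 1-based inclusive
happens only at GFF/report boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_NUC_RE = re.compile(r"^[ACGTN]+$")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class NucSequence:
    """A named nucleotide sequence (contig, segment, or region).

    The sequence is uppercased on construction and must be a non-empty
    string over the alphabet {A, C, G, T, N} with no whitespace.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"sequence {self.id!r}: empty sequence")
        if not _NUC_RE.match(self.seq):
            bad = sorted(set(self.seq) - set("ACGTN"))
            raise ValueError(
                f"sequence {self.id!r}: invalid characters {bad} "
                "(alphabet is A/C/G/T/N, no whitespace)"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadRecord:
    """A sequencing read, optionally with per-base qualities."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass
class AlignmentRecord:
    """A mapped read in reference coordinates.

    ``identity`` is matched bases divided by aligned read bases (aligned
    length including insertions), derived from the NM tag when reading SAM;
    ``None`` means the mapper provided neither NM nor MD and the identity
    is unknown. ``clipped_prefix``/``clipped_suffix`` hold the soft-clipped
    read sequence on the reference-left/right side, stored in reference
    orientation (as in SAM).
    """

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str  # "+" or "-"
    identity: float | None = None
    indel_count: int = 0
    clipped_prefix: str = ""
    clipped_suffix: str = ""
    seq: str | None = None  # full read sequence in reference orientation

    def __post_init__(self) -> None:
        if not (0 <= self.ref_start < self.ref_end):
            raise ValueError(
                f"alignment {self.read_id!r}: bad interval "
                f"[{self.ref_start}, {self.ref_end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"alignment {self.read_id!r}: bad strand {self.strand!r}")
        if self.identity is not None and not (0.0 <= self.identity <= 1.0):
            raise ValueError(f"alignment {self.read_id!r}: identity {self.identity}")
        if self.indel_count < 0:
            raise ValueError(f"alignment {self.read_id!r}: negative indel count")


@dataclass
class OrfAnnotation:
    """An ORF call with optional Shine-Dalgarno and transmembrane evidence.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand of the parent segment; ``end`` includes the stop codon,
    so the protein length is (end - start) / 3 - 1.
    """

    segment_id: str
    start: int
    end: int
    strand: str
    protein: str
    sd_motif: str | None = None
    sd_spacer: int | None = None
    tm_segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError(
                f"ORF on {self.segment_id}: span {self.end - self.start} "
                "not divisible by 3"
            )
        expect = (self.end - self.start) // 3 - 1
        if len(self.protein) != expect:
            raise ValueError(
                f"ORF on {self.segment_id}: protein length {len(self.protein)} "
                f"!= (end-start)/3 - 1 = {expect}"
            )
        if self.sd_motif is not None and not (3 <= self.sd_spacer <= 15):
            raise ValueError(
                f"ORF on {self.segment_id}: SD spacer {self.sd_spacer} outside [3, 15]"
            )

    @property
    def aa_length(self) -> int:
        return len(self.protein)
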