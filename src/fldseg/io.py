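"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython, SAM through pysam (text SAM only; BAM and
CRAM are out of scope). GFF3 output is produced here because annotations are
born in memory, never parsed back.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AlignmentRecord, NucSequence, OrfAnnotation, ReadRecord

log = logging.getLogger(__name__)

# CIGAR operation codes (pysam numeric encoding)
_CIG_M, _CIG_I, _CIG_D, _CIG_N, _CIG_S, _CIG_H = 0, 1, 2, 3, 4, 5
_CIG_EQ, _CIG_X = 7, 8
_REF_CONSUMING = {_CIG_M, _CIG_D, _CIG_N, _CIG_EQ, _CIG_X}
_READ_ALIGNED = {_CIG_M, _CIG_I, _CIG_EQ, _CIG_X}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def read_fasta(path: str | Path) -> list[NucSequence]:
    """Read a FASTA file into a list of :class:`NucSequence`.

    Sequences are uppercased; record order is preserved. Empty sequences
    and duplicate ids raise :class:`ParseError`.
    """
    out: list[NucSequence] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq)
        if not seq:
            raise ParseError(f"{path}: record {i} ({rec.id!r}) has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r} (record {i})")
        seen.add(rec.id)
        try:
            out.append(NucSequence(rec.id, seq, rec.description))
        except ValueError as exc:
            raise ParseError(f"{path}: record {i}: {exc}") from exc
    if not out and Path(path).stat().st_size > 0:
        raise ParseError(f"{path}: no FASTA records parsed (malformed header?)")
    return out


def write_fasta(seqs: Iterable[NucSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}" + (f" {s.description}" if s.description else "") + "\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


def _mismatches_from_md(md: str) -> tuple[int, int]:
    """Return (substitutions, deleted_bases) encoded in an MD tag."""
    subs = dels = 0
    for m in _MD_TOKEN.finditer(md):
        if m.group(2):
            dels += len(m.group(2)) - 1
        elif m.group(3):
            subs += 1
    return subs, dels


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read mapped records from a SAM file into :class:`AlignmentRecord`.

    The CIGAR string is reduced to reference start/end, an indel count
    (total inserted plus deleted bases) and soft-clipped prefix/suffix
    sequences. Identity is computed from the NM tag when present, else
    reconstructed from MD plus CIGAR insertions, else left ``None``.
    Unmapped records are skipped (count logged).
    """
    out: list[AlignmentRecord] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=True) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.cigartuples is None:
                n_unmapped += 1
                continue
            if rec.reference_id < 0 or rec.reference_name is None:
                raise ParseError(f"{path}: record {rec.query_name!r} has no @SQ reference")
            cig = rec.cigartuples
            seq = rec.query_sequence or ""
            pre = seq[: cig[0][1]] if seq and cig[0][0] == _CIG_S else ""
            suf = seq[len(seq) - cig[-1][1] :] if seq and cig[-1][0] == _CIG_S else ""
            indels = sum(ln for op, ln in cig if op in (_CIG_I, _CIG_D))
            aligned = sum(ln for op, ln in cig if op in _READ_ALIGNED)
            identity: float | None = None
            if rec.has_tag("NM"):
                nm = rec.get_tag("NM")
                identity = max(0, aligned - nm) / aligned if aligned else 0.0
            elif rec.has_tag("MD"):
                subs, dels = _mismatches_from_md(str(rec.get_tag("MD")))
                ins = sum(ln for op, ln in cig if op == _CIG_I)
                nm = subs + dels + ins
                identity = max(0, aligned - nm) / aligned if aligned else 0.0
            out.append(
                AlignmentRecord(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    ref_start=rec.reference_start,
                    ref_end=rec.reference_end,
                    strand="-" if rec.is_reverse else "+",
                    identity=identity,
                    indel_count=indels,
                    clipped_prefix=pre,
                    clipped_suffix=suf,
                    seq=seq or None,
                )
            )
    if n_unmapped:
        log.info("read_sam(%s): skipped %d unmapped records", path, n_unmapped)
    return out


def write_sam(
    alignments: Sequence[AlignmentRecord],
    ref_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write simple soft-clip/match alignments as text SAM.

    Each record must carry ``seq`` (reference-orientation read sequence);
    the CIGAR is ``<pre>S <span>M <suf>S``. Used to materialize simulated
    alignments for tools (and tests) that consume SAM.
    """
    header = pysam.AlignmentHeader.from_references(
        list(ref_lengths), [ref_lengths[k] for k in ref_lengths]
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as sam:
        for a in alignments:
            if a.seq is None:
                raise ValueError(f"alignment {a.read_id!r}: no sequence to write")
            span = a.ref_end - a.ref_start
            rec = pysam.AlignedSegment(header)
            rec.query_name = a.read_id
            rec.reference_name = a.ref_id
            rec.reference_start = a.ref_start
            rec.mapping_quality = 60
            rec.flag = 16 if a.strand == "-" else 0
            cig = ""
            if a.clipped_prefix:
                cig += f"{len(a.clipped_prefix)}S"
            cig += f"{span}M"
            if a.clipped_suffix:
                cig += f"{len(a.clipped_suffix)}S"
            rec.cigarstring = cig
            rec.query_sequence = a.seq
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(a.seq))
            if a.identity is not None:
                rec.set_tag("NM", round((1.0 - a.identity) * span))
            sam.write(rec)


def write_gff(
    annotations: Sequence[OrfAnnotation],
    path: str | Path,
    seq_lengths: dict[str, int] | None = None,
) -> None:
    """Write ORF annotations as GFF3 (1-based inclusive coordinates).

    SD motif/spacer and transmembrane segments are emitted as attributes;
    the transmembrane method is labelled ``hydropathy_surrogate`` so calls
    are not mistaken for dedicated topology predictions.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seq_lengths:
            for sid, ln in seq_lengths.items():
                fh.write(f"##sequence-region {sid} 1 {ln}\n")
        for i, a in enumerate(annotations, start=1):
            if seq_lengths is not None:
                parent = seq_lengths.get(a.segment_id)
                if parent is None:
                    raise ValueError(f"GFF: unknown parent sequence {a.segment_id!r}")
                if a.end > parent:
                    raise ValueError(
                        f"GFF: ORF end {a.end} outside {a.segment_id!r} (length {parent})"
                    )
            attrs = [f"ID=orf{i}", f"protein_length={a.aa_length}"]
            if a.sd_motif is not None:
                attrs += [f"sd_motif={a.sd_motif}", f"sd_spacer={a.sd_spacer}"]
            if a.tm_segments:
                tm = ",".join(f"{s}-{e}" for s, e in a.tm_segments)
                attrs += [f"tm_segments={tm}", "tm_method=hydropathy_surrogate"]
            fh.write(
                "\t".join(
                    [
                        a.segment_id,
                        "fldseg",
                        "CDS",
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def translate_orf(nt: str) -> str:
    """Translate an ORF (with stop codon) using the bacterial table (11).

    Alternative starts (GTG/TTG) are rendered as methionine, following CDS
    convention.
    """
    prot = str(Seq(nt[:-3]).translate(table=11))
    if prot and nt[:3] in ("GTG", "TTG", "ATG"):
        prot = "M" + prot[1:]
    return prot


def as_seqrecords(seqs: Iterable[NucSequence]) -> list[SeqRecord]:
    return [SeqRecord(Seq(s.seq), id=s.id, description=s.description) for s in seqs]
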