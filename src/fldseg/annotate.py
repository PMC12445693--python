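"""ORF calling with Shine-Dalgarno (SD) ribosome-binding-site detection.

The ORF scanner is deterministic: every stop-to-stop region in all six
frames is reported from its most upstream permitted start codon, provided
the encoded protein reaches ``min_aa``. Bacterial-type SD motifs are
searched as contiguous substrings of the AGGAGG consensus a short spacer
upstream of the start. Transmembrane segments are flagged with a
Kyte-Doolittle hydropathy scan — a sliding-window surrogate, not a
topology model — and labelled as such in all output.
"""

from __future__ import annotations

from .records import NucSequence, OrfAnnotation, revcomp
from .io import translate_orf

DEFAULT_STARTS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
SD_CONSENSUS = "AGGAGG"

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


def _scan_strand(seq: str, min_aa: int, starts: tuple[str, ...]):
    """Yield (start, end) on `seq` for maximal ORFs in the three frames.

    ``end`` includes the stop codon; regions without a terminal stop are
    not reported (the ORF may run off the contig and its extent is
    unknowable).
    """
    n = len(seq)
    for frame in range(3):
        first_start: int | None = None
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if codon in STOP_CODONS:
                if first_start is not None:
                    aa = (p - first_start) // 3  # protein length excl. stop
                    if aa >= min_aa:
                        yield first_start, p + 3
                first_start = None
            elif first_start is None and codon in starts:
                first_start = p


def find_orfs(
    seg: NucSequence,
    min_aa: int = 60,
    starts: tuple[str, ...] = DEFAULT_STARTS,
) -> list[OrfAnnotation]:
    """Find all maximal ORFs on both strands of a segment.

    Within each stop-to-stop region the most upstream permitted start is
    used, so overlapping same-frame calls cannot occur. Coordinates are
    forward-strand 0-based half-open including the stop codon; results are
    sorted by start position.
    """
    seq = seg.seq
    n = len(seq)
    out: list[OrfAnnotation] = []
    for s, e in _scan_strand(seq, min_aa, starts):
        out.append(
            OrfAnnotation(seg.id, s, e, "+", translate_orf(seq[s:e]))
        )
    rc = revcomp(seq)
    for s, e in _scan_strand(rc, min_aa, starts):
        out.append(
            OrfAnnotation(seg.id, n - e, n - s, "-", translate_orf(rc[s:e]))
        )
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _mismatch_free_hits(window: str, sub: str) -> list[int]:
    hits = []
    start = window.find(sub)
    while start != -1:
        hits.append(start)
        start = window.find(sub, start + 1)
    return hits


def detect_sd(
    seg: NucSequence,
    orf: OrfAnnotation,
    motif: str = SD_CONSENSUS,
    min_match: int = 4,
    spacer_range: tuple[int, int] = (3, 15),
) -> tuple[str, int] | None:
    """Search for a Shine-Dalgarno motif upstream of an ORF start.

    The window ``[start - (max_spacer + len(motif)), start - min_spacer)``
    on the coding strand is scanned for the longest contiguous exact match
    to any substring of the consensus of length >= ``min_match``; ties are
    broken toward the spacer closest to the 8-nt optimum. Returns
    ``(matched_motif, spacer)`` or ``None``. Windows running past the
    segment end are clipped.
    """
    smin, smax = spacer_range
    if orf.strand == "+":
        win_start = max(0, orf.start - (smax + len(motif)))
        win_end = max(0, orf.start - smin)
        window = seg.seq[win_start:win_end]
        # distance from a window position p's motif end to the start codon
        def spacer_of(p: int, ln: int) -> int:
            return orf.start - (win_start + p + ln)
    else:
        cds_start = orf.end  # exclusive end on forward = start codon on minus
        win_start = min(len(seg.seq), cds_start + smin)
        win_end = min(len(seg.seq), cds_start + smax + len(motif))
        window = revcomp(seg.seq[win_start:win_end])

        def spacer_of(p: int, ln: int) -> int:
            return (win_end - cds_start) - (p + ln)

    best: tuple[int, int, str, int] | None = None  # (-len, |spacer-8|, motif, spacer)
    for ln in range(len(motif), min_match - 1, -1):
        for off in range(0, len(motif) - ln + 1):
            sub = motif[off : off + ln]
            for p in _mismatch_free_hits(window, sub):
                spacer = spacer_of(p, ln)
                if spacer < smin or spacer > smax:
                    continue
                key = (-ln, abs(spacer - 8), sub, spacer)
                if best is None or key < best:
                    best = key
    if best is None:
        return None
    return best[2], best[3]


def hydropathy_tm_scan(
    protein: str, window: int = 19, threshold: float = 1.6
) -> list[tuple[int, int]]:
    """Flag candidate transmembrane segments by mean hydropathy.

    Sliding windows of ``window`` residues whose mean Kyte-Doolittle
    hydropathy reaches ``threshold`` are merged into maximal runs reported
    as (aa_start, aa_end) half-open intervals. Proteins shorter than the
    window yield an empty list. This is a hydropathy surrogate for a real
    topology predictor and is labelled as such downstream.
    """
    n = len(protein)
    if n < window:
        return []
    vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in protein]
    prefix = [0.0]
    for v in vals:
        prefix.append(prefix[-1] + v)
    runs: list[tuple[int, int]] = []
    cur: tuple[int, int] | None = None
    for i in range(0, n - window + 1):
        mean = (prefix[i + window] - prefix[i]) / window
        if mean >= threshold:
            if cur is not None and i <= cur[1]:
                cur = (cur[0], i + window)
            else:
                if cur is not None:
                    runs.append(cur)
                cur = (i, i + window)
    if cur is not None:
        runs.append(cur)
    return runs


def annotate_segment(
    seg: NucSequence,
    min_aa: int = 60,
    starts: tuple[str, ...] = DEFAULT_STARTS,
    sd_motif: str = SD_CONSENSUS,
    sd_min_match: int = 4,
    sd_spacer_range: tuple[int, int] = (3, 15),
    tm_window: int = 19,
    tm_threshold: float = 1.6,
) -> list[OrfAnnotation]:
    """Full annotation of one segment: ORFs + SD motifs + TM flags."""
    orfs = find_orfs(seg, min_aa=min_aa, starts=starts)
    for orf in orfs:
        hit = detect_sd(seg, orf, motif=sd_motif, min_match=sd_min_match,
                        spacer_range=sd_spacer_range)
        if hit is not None:
            orf.sd_motif, orf.sd_spacer = hit
        orf.tm_segments = hydropathy_tm_scan(orf.protein, tm_window, tm_threshold)
    return orfs
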