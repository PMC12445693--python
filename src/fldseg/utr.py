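"""Untranslated-region characterization.

Long noncoding 5'UTRs are diagnosed by two signals: stop codons scattered
through all six translation frames (a coding region keeps one frame
clear), and a trinucleotide composition distinct from the codon-driven
composition of protein-coding regions. Conserved blocks between UTRs of
related genomes are located by ungapped window comparison at a nucleotide
identity threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .records import NucSequence, revcomp

BASES = "ACGT"
TRINUCS = ["".join(t) for t in itertools.product(BASES, repeat=3)]
_TRI_INDEX = {t: i for i, t in enumerate(TRINUCS)}
STOPS = ("TAA", "TAG", "TGA")


@dataclass
class StopCodonMap:
    """Stop-codon start positions in all six frames, forward coordinates.

    ``frames[0..2]`` are the forward frames (offset 0, 1, 2);
    ``frames[3..5]`` are the reverse-complement frames, with each position
    given as the forward-strand coordinate of the codon's first base.
    """

    segment_id: str
    frames: list[list[int]]


@dataclass
class RegionCompositionProfile:
    region_id: str
    kind: str  # utr | cds_capsid | cds_rdrp | other
    trinuc_freq: np.ndarray  # 64 overlapping 3-mer frequencies


@dataclass
class ConservedLink:
    seq_a: str
    seq_b: str
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float


def stop_codon_map(seg: NucSequence) -> StopCodonMap:
    """Exhaustive six-frame stop-codon scan."""
    seq = seg.seq
    n = len(seq)
    frames: list[list[int]] = [[] for _ in range(6)]
    for f in range(3):
        for p in range(f, n - 2, 3):
            if seq[p : p + 3] in STOPS:
                frames[f].append(p)
    rc = revcomp(seq)
    for f in range(3):
        for p in range(f, n - 2, 3):
            if rc[p : p + 3] in STOPS:
                frames[3 + f].append(n - 3 - p)  # forward coord of first base
    for f in range(3, 6):
        frames[f].sort()
    return StopCodonMap(seg.id, frames)


def trinuc_profile(region: NucSequence, kind: str = "other") -> RegionCompositionProfile:
    """Overlapping 3-mer frequencies; windows containing N are excluded
    from both numerator and denominator."""
    seq = region.seq
    if len(seq) < 3:
        raise ValueError(f"region {region.id!r}: length < 3")
    counts = np.zeros(64)
    for i in range(len(seq) - 2):
        idx = _TRI_INDEX.get(seq[i : i + 3])
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(f"region {region.id!r}: no N-free trinucleotides")
    return RegionCompositionProfile(region.id, kind, counts / total)


def composition_distance(
    p: RegionCompositionProfile, q: RegionCompositionProfile
) -> float:
    """Euclidean distance between two trinucleotide frequency vectors."""
    return float(np.linalg.norm(p.trinuc_freq - q.trinuc_freq))


def _merge_diagonal_hits(
    hits: list[tuple[int, int, float]], window: int, step: int
) -> list[tuple[int, int, int, int, float]]:
    """Merge window hits on the same diagonal into maximal links."""
    by_diag: dict[int, list[tuple[int, float]]] = {}
    for qa, pb, ident in hits:
        by_diag.setdefault(pb - qa, []).append((qa, ident))
    links = []
    for diag, entries in sorted(by_diag.items()):
        entries.sort()
        start, prev, best = entries[0][0], entries[0][0], entries[0][1]
        for qa, ident in entries[1:]:
            if qa - prev <= step:
                prev = qa
                best = max(best, ident)
            else:
                links.append((start, prev + window, start + diag, prev + window + diag, best))
                start, prev, best = qa, qa, ident
        links.append((start, prev + window, start + diag, prev + window + diag, best))
    return links


def find_conserved_links(
    seqs: list[NucSequence],
    window: int = 100,
    step: int = 10,
    min_id: float = 0.68,
) -> list[ConservedLink]:
    """Ungapped all-window comparison between every pair of sequences.

    Each query window (every ``step`` nt) is compared against all
    same-sized windows of the partner; windows exceeding ``min_id``
    identity are merged along diagonals into maximal links. Output is
    symmetric in the sense that each link names both intervals.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    for s in seqs:
        if len(s.seq) < window:
            raise ValueError(f"sequence {s.id!r} shorter than window {window}")
    arrays = [np.frombuffer(s.seq.encode(), dtype=np.uint8) for s in seqs]
    out: list[ConservedLink] = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            a, b = arrays[i], arrays[j]
            b_windows = np.lib.stride_tricks.sliding_window_view(b, window)
            hits = []
            for qa in range(0, len(a) - window + 1, step):
                ident = (b_windows == a[qa : qa + window]).mean(axis=1)
                for pb in np.nonzero(ident > min_id)[0]:
                    hits.append((qa, int(pb), float(ident[pb])))
            for a0, a1, b0, b1, ident in _merge_diagonal_hits(hits, window, step):
                out.append(ConservedLink(seqs[i].id, seqs[j].id, a0, a1, b0, b1, ident))
    return out
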