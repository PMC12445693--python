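"""Grouping of full-length segments into multipartite genome sets.

Cognate segments of a segmented RNA virus share conserved 5' and 3'
terminal sequences; two segments are linked when both terminal windows
exceed an identity threshold (best ungapped match over a small offset
range), and single-linkage clustering of the link relation yields the
genome sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .records import NucSequence


@dataclass
class TerminalSignature:
    contig_id: str
    t5: str
    t3: str
    W: int


@dataclass
class GenomeSet:
    genome_id: str
    member_contigs: list[str]
    consensus_t5: str
    consensus_t3: str

    @property
    def n_segments(self) -> int:
        return len(self.member_contigs)


def terminal_signature(contig: NucSequence, W: int = 30) -> TerminalSignature:
    """Literal prefix/suffix windows of a full-length segment."""
    if len(contig.seq) < 2 * W:
        raise ValueError(
            f"contig {contig.id!r}: length {len(contig.seq)} < 2*W ({2 * W})"
        )
    return TerminalSignature(contig.id, contig.seq[:W], contig.seq[-W:], W)


def _best_offset_identity(a: str, b: str, max_offset: int) -> float:
    """Best ungapped identity over relative offsets, overhangs excluded
    from the denominator."""
    best = 0.0
    n = len(a)
    for off in range(-max_offset, max_offset + 1):
        if off >= 0:
            x, y = a[off:], b[: n - off]
        else:
            x, y = a[: n + off], b[-off:]
        if not x:
            continue
        ident = sum(1 for u, v in zip(x, y) if u == v) / len(x)
        best = max(best, ident)
    return best


def terminal_identity(
    a: TerminalSignature, b: TerminalSignature, max_offset: int = 5
) -> tuple[float, float]:
    """Per-terminus best ungapped identity between two signatures."""
    if a.W != b.W:
        raise ValueError("signatures have different window lengths")
    return (
        _best_offset_identity(a.t5, b.t5, max_offset),
        _best_offset_identity(a.t3, b.t3, max_offset),
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _majority_consensus(strings: list[str]) -> str:
    out = []
    for col in zip(*strings):
        counts = Counter(col)
        top = max(counts.values())
        out.append(min(c for c, n in counts.items() if n == top))
    return "".join(out)


def group_segments(
    signatures: Sequence[TerminalSignature],
    min_id: float = 0.8,
    max_offset: int = 5,
) -> list[GenomeSet]:
    """Single-linkage clustering on the relation "both termini at least
    ``min_id`` identical"; singletons become one-segment sets.

    Output sets are ordered by their first member's input position and
    named GS001, GS002, ...; consensus terminals are per-position majority
    over members (ties alphabetical).
    """
    if not signatures:
        raise ValueError("no signatures to group")
    n = len(signatures)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            id5, id3 = terminal_identity(signatures[i], signatures[j], max_offset)
            if id5 >= min_id and id3 >= min_id:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    out = []
    for k, root in enumerate(sorted(clusters, key=lambda r: min(clusters[r])), start=1):
        members = sorted(clusters[root])
        out.append(
            GenomeSet(
                genome_id=f"GS{k:03d}",
                member_contigs=[signatures[i].contig_id for i in members],
                consensus_t5=_majority_consensus([signatures[i].t5 for i in members]),
                consensus_t3=_majority_consensus([signatures[i].t3 for i in members]),
            )
        )
    return out
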