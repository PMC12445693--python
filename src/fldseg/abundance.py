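"""Contig clustering, fragment counting and FPKM community composition.

Representative contigs are formed by length-sorted greedy incremental
clustering at a global-identity threshold (97% by default). Mapped
fragments are filtered at a minimum identity of 0.97 and a maximum of 3
indel bases, multi-mapped fragments go to their best-identity hit, and
abundance is expressed as FPKM: fragments per kilobase of contig per
million cleaned-up reads. Community composition pools taxa below 2% of
total abundance into "other dsRNA"/"other ssRNA" bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd

from .records import AlignmentRecord, NucSequence


@dataclass
class ContigCluster:
    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    identity_threshold: float = 0.97


def _kmer_set(seq: str, k: int = 16) -> set[int]:
    return {hash(seq[i : i + k]) for i in range(0, len(seq) - k + 1, k)}


def _global_identity(short: str, long_: str) -> float:
    """Identity of the best semi-global alignment of the shorter sequence
    inside the longer (CD-HIT-like: full coverage of the shorter)."""
    res = edlib.align(short, long_, mode="HW", task="distance")
    dist = res["editDistance"]
    if dist < 0:
        return 0.0
    return max(0.0, 1.0 - dist / len(short))


def greedy_cluster(
    contigs: Sequence[NucSequence], min_id: float = 0.97
) -> list[ContigCluster]:
    """Length-sorted greedy incremental clustering.

    Contigs are processed longest first; each joins the first existing
    representative whose identity (over the full shorter sequence) reaches
    ``min_id``, else founds a new cluster. A sampled-k-mer prefilter skips
    hopeless alignments at high thresholds. Deterministic: ties in length
    are broken by id.
    """
    if not contigs:
        raise ValueError("no contigs to cluster")
    ordered = sorted(contigs, key=lambda c: (-len(c.seq), c.id))
    clusters: list[ContigCluster] = []
    reps: list[NucSequence] = []
    rep_kmers: list[set[int]] = []
    for c in ordered:
        kms = _kmer_set(c.seq)
        placed = False
        for cl, rep, rk in zip(clusters, reps, rep_kmers):
            if min_id >= 0.9 and kms and rk and not (kms & rk):
                continue
            if _global_identity(c.seq, rep.seq) >= min_id:
                cl.member_ids.append(c.id)
                placed = True
                break
        if not placed:
            clusters.append(ContigCluster(c.id, [c.id], min_id))
            reps.append(c)
            rep_kmers.append(kms)
    return clusters


def count_fragments(
    alignments: Iterable[AlignmentRecord],
    clusters: Sequence[ContigCluster],
    contig_lengths: Mapping[str, int],
    min_identity: float = 0.97,
    max_indel: int = 3,
) -> dict[str, int]:
    """Count mapped fragments per cluster representative.

    Alignments failing the identity or indel filter (or with unknown
    identity) are discarded. A fragment is a read pair when ids carry
    ``/1``/``/2`` suffixes, else a single read; multi-mapped fragments are
    assigned to the best-identity hit, ties broken toward the longest
    representative, then lexicographically.
    """
    rep_of = {m: cl.representative_id for cl in clusters for m in cl.member_ids}
    best: dict[str, tuple[float, int, str]] = {}
    for a in alignments:
        if a.identity is None or a.identity < min_identity or a.indel_count > max_indel:
            continue
        rep = rep_of.get(a.ref_id)
        if rep is None:
            continue
        frag = a.read_id
        if frag.endswith("/1") or frag.endswith("/2"):
            frag = frag[:-2]
        key = (a.identity, contig_lengths.get(rep, 0), rep)
        prev = best.get(frag)
        if (
            prev is None
            or key[0] > prev[0]
            or (key[0] == prev[0] and key[1] > prev[1])
            or (key[0] == prev[0] and key[1] == prev[1] and key[2] < prev[2])
        ):
            best[frag] = key
    counts: dict[str, int] = {cl.representative_id: 0 for cl in clusters}
    for _, _, rep in best.values():
        counts[rep] += 1
    return counts


def fpkm_table(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    total_cleaned_reads: int,
    taxon_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """FPKM per contig: fragments / (length_kb * total_cleaned_reads/1e6),
    plus each contig's share of total FPKM."""
    if total_cleaned_reads <= 0:
        raise ValueError("total_cleaned_reads must be positive")
    rows = []
    for cid, n in counts.items():
        ln = lengths[cid]
        if ln <= 0:
            raise ValueError(f"contig {cid!r}: non-positive length")
        length_kb = ln / 1000.0
        fpkm = n / (length_kb * total_cleaned_reads / 1e6)
        rows.append(
            {
                "contig_id": cid,
                "taxon_label": (taxon_map or {}).get(cid, "unclassified"),
                "mapped_fragments": n,
                "length_kb": length_kb,
                "fpkm": fpkm,
            }
        )
    df = pd.DataFrame(rows)
    total = df["fpkm"].sum()
    df["relative_share"] = df["fpkm"] / total if total > 0 else 0.0
    return df


def composition_summary(
    rows: pd.DataFrame,
    class_map: Mapping[str, str] | None = None,
    pool_below: float = 0.02,
) -> pd.DataFrame:
    """Per-taxon relative abundance with minor taxa pooled.

    Taxa whose share of total FPKM falls below ``pool_below`` are folded
    into "other dsRNA" or "other ssRNA" according to ``class_map``
    (taxon label -> "dsRNA"/"ssRNA"); unclassified rows go to "others".
    Shares sum to 1.
    """
    class_map = dict(class_map or {})
    per_taxon = rows.groupby("taxon_label")["fpkm"].sum()
    total = per_taxon.sum()
    if total <= 0:
        raise ValueError("total FPKM is zero")
    shares = per_taxon / total
    pooled: dict[str, float] = {}
    for taxon, share in shares.items():
        if taxon == "unclassified":
            label = "others"
        elif share < pool_below:
            cls = class_map.get(taxon)
            label = f"other {cls}" if cls in ("dsRNA", "ssRNA") else "others"
        else:
            label = taxon
        pooled[label] = pooled.get(label, 0.0) + float(share)
    out = pd.DataFrame(
        sorted(pooled.items(), key=lambda kv: -kv[1]), columns=["taxon", "share"]
    )
    return out
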