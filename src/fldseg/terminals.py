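"""Terminal-sequence determination from adaptor-bearing read alignments.

In FLDS libraries the adaptor is ligated to the 3' end of every dsRNA
fragment on both strands, so reads crossing a ligation junction carry the
adaptor in their soft-clipped tail. Junctions pile up at true genome
termini (every fragmentation of the molecule ends there) while internal
breakpoints scatter; a contig end is therefore called complete when (i)
adaptor-junction reads align at that extremity and (ii) their frequency
clearly exceeds the junction background in the central region of the
contig.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import AlignmentRecord, NucSequence, revcomp

#: reported in place of an infinite enrichment ratio
ENRICHMENT_CAP = 1e6


@dataclass
class TerminalProfile:
    """Per-position junction and coverage counts for one contig.

    ``j5[p]`` counts adaptor-junction events placing a 5' extremity at
    position ``p`` (reference-left clip ending in the reverse-complemented
    adaptor); ``j3[p]`` counts 3'-extremity events (reference-right clip
    beginning with the adaptor). Both strands contribute: dsRNA symmetry
    means an adaptor at the minus-strand 3' end evidences the plus-strand
    5' terminus, and the alignment geometry already encodes this.
    """

    contig_id: str
    length: int
    j5: np.ndarray
    j3: np.ndarray
    coverage: np.ndarray


@dataclass
class CompletenessCall:
    contig_id: str
    status5: str  # complete | incomplete | ambiguous
    status3: str
    peak5_pos: int | None
    peak3_pos: int | None
    enrichment5: float
    enrichment3: float


def _hamming_leq(a: str, b: str, max_mm: int) -> bool:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > max_mm:
                return False
    return True


def detect_adaptor_junctions(
    alignments: Iterable[AlignmentRecord],
    contig_lengths: dict[str, int],
    adaptor: str,
    max_mismatch: int = 1,
) -> dict[str, TerminalProfile]:
    """Accumulate adaptor-junction events and coverage per contig.

    A read whose clipped suffix begins with the adaptor (at most
    ``max_mismatch`` mismatches) contributes one j3 event at its
    ``ref_end - 1``; a clipped prefix ending with the reverse-complemented
    adaptor contributes one j5 event at ``ref_start``. Clips shorter than
    ``min(len(adaptor), 10)`` are never counted.
    """
    if len(adaptor) < 10:
        raise ValueError(f"adaptor length {len(adaptor)} < 10: matching unreliable")
    rc_adaptor = revcomp(adaptor)
    min_len = min(len(adaptor), 10)
    profiles = {
        cid: TerminalProfile(
            cid, ln, np.zeros(ln, dtype=np.int64), np.zeros(ln, dtype=np.int64),
            np.zeros(ln, dtype=np.int64),
        )
        for cid, ln in contig_lengths.items()
    }
    for a in alignments:
        prof = profiles.get(a.ref_id)
        if prof is None:
            raise KeyError(f"alignment references unknown contig {a.ref_id!r}")
        prof.coverage[a.ref_start : a.ref_end] += 1
        suf = a.clipped_suffix
        if suf:
            n = min(len(suf), len(adaptor))
            if n >= min_len and _hamming_leq(suf[:n], adaptor[:n], max_mismatch):
                prof.j3[a.ref_end - 1] += 1
        pre = a.clipped_prefix
        if pre:
            n = min(len(pre), len(rc_adaptor))
            if n >= min_len and _hamming_leq(pre[-n:], rc_adaptor[-n:], max_mismatch):
                prof.j5[a.ref_start] += 1
    return profiles


def _poisson_sf(k: int, mu: float) -> float:
    """P(X >= k) for X ~ Poisson(mu)."""
    if k <= 0:
        return 1.0
    term = math.exp(-mu)
    cdf = term
    for i in range(1, k):
        term *= mu / i
        cdf += term
    return max(0.0, 1.0 - cdf)


def call_completeness(
    profile: TerminalProfile,
    window: int = 50,
    min_events: int = 3,
    enrich: float = 5.0,
    alpha: float = 1e-3,
) -> CompletenessCall:
    """Call each contig end complete, incomplete or ambiguous.

    Internal fragmentation junctions are adaptor-ligated too, so a
    background junction rate is estimated from the middle half of the
    contig (j5+j3 pooled, per window-sized bin, floored at one event per
    window). A terminal count consistent with that background — a
    one-sided Poisson test at level ``alpha`` — is called ``incomplete``;
    a significant count short of ``enrich``-fold enrichment is
    ``ambiguous``; ``complete`` requires ``min_events`` events,
    significance, and the enrichment.
    """
    L = profile.length
    if L <= 4 * window:
        raise ValueError(f"contig {profile.contig_id!r}: length {L} <= 4*window")
    if profile.coverage.sum() == 0:
        raise ValueError(f"contig {profile.contig_id!r}: no alignments")
    mid = slice(L // 4, L // 4 + L // 2)
    background_total = int(profile.j5[mid].sum() + profile.j3[mid].sum())
    background = background_total / (L // 2) * window  # events per window bin
    floor = max(background, 1.0)

    def call_one(arr: np.ndarray, terminal: str) -> tuple[str, int | None, float]:
        if terminal == "5":
            counts = arr[:window]
            peak = int(np.argmax(counts))  # argmax ties -> lowest = outermost
        else:
            counts = arr[L - window :]
            rev = counts[::-1]
            peak = L - 1 - int(np.argmax(rev))  # ties toward the contig end
        total = int(counts.sum())
        if total == 0:
            return "incomplete", None, 0.0
        ratio = total / background if background > 0 else math.inf
        ratio = min(ratio, ENRICHMENT_CAP)
        significant = _poisson_sf(total, floor) < alpha
        if total >= min_events and significant and total >= enrich * floor:
            return "complete", peak, ratio
        if total >= min_events and significant:
            return "ambiguous", peak, ratio
        return "incomplete", peak, ratio

    s5, p5, e5 = call_one(profile.j5, "5")
    s3, p3, e3 = call_one(profile.j3, "3")
    return CompletenessCall(profile.contig_id, s5, s3, p5, p3, e5, e3)


def trim_to_termini(contig: NucSequence, call: CompletenessCall) -> NucSequence:
    """Emit the full-length segment between the called terminal peaks."""
    if call.status5 != "complete" or call.status3 != "complete":
        raise ValueError(
            f"contig {contig.id!r}: both termini must be complete to trim "
            f"(got 5'={call.status5}, 3'={call.status3})"
        )
    return NucSequence(
        contig.id, contig.seq[call.peak5_pos : call.peak3_pos + 1], contig.description
    )


def terminal_report(calls: Sequence[CompletenessCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig_id": [c.contig_id for c in calls],
            "status5": [c.status5 for c in calls],
            "status3": [c.status3 for c in calls],
            "peak5_pos": [c.peak5_pos for c in calls],
            "peak3_pos": [c.peak3_pos for c in calls],
            "enrichment5": [c.enrichment5 for c in calls],
            "enrichment3": [c.enrichment3 for c in calls],
        }
    )


def analyze_terminals(
    contigs: Sequence[NucSequence],
    alignments: Iterable[AlignmentRecord],
    adaptor: str,
    window: int = 50,
    min_events: int = 3,
    enrich: float = 5.0,
    max_mismatch: int = 1,
) -> tuple[list[CompletenessCall], list[NucSequence]]:
    """Profile, call and trim every contig; contigs whose termini are not
    both complete are reported but not trimmed."""
    lengths = {c.id: len(c.seq) for c in contigs}
    profiles = detect_adaptor_junctions(alignments, lengths, adaptor, max_mismatch)
    calls = []
    trimmed = []
    by_id = {c.id: c for c in contigs}
    for cid, prof in profiles.items():
        if prof.coverage.sum() == 0:
            continue
        call = call_completeness(prof, window, min_events, enrich)
        calls.append(call)
        if call.status5 == "complete" and call.status3 == "complete":
            trimmed.append(trim_to_termini(by_id[cid], call))
    return calls, trimmed
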