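"""Synthetic multipartite dsRNA virus genomes and FLDS-style reads.

The generator emulates the statistical structure the downstream analysis
relies on: bisegmented genomes whose two segments share conserved 5'/3'
terminal sequences; physical fragmentation of the dsRNA into ~1.5-kb
pieces with an adaptor ligated to every fragment 3' end (on both strands,
so both genome termini are marked); 300-nt reads taken from fragment ends,
so reads crossing a fragment 3' junction carry genomic suffix + adaptor
prefix; several ORFs per segment, most preceded by a Shine-Dalgarno motif;
and, on a fraction of RNA1 segments, a long noncoding 5'UTR whose
trinucleotide composition (order-2 Markov chain) differs from the
codon-driven composition of the coding regions.

Every genome ships with a ground-truth table (ORF coordinates, SD motifs,
read provenance, terminal-junction labels) so recovery can be scored
exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate
from .records import AlignmentRecord, NucSequence, ReadRecord, revcomp

BASES = "ACGT"
TRINUCS = ["".join(t) for t in itertools.product(BASES, repeat=3)]
_TRI_INDEX = {t: i for i, t in enumerate(TRINUCS)}

#: fixed 20-nt adaptor standing in for the (unpublished) laboratory oligo
DEFAULT_ADAPTOR = "CTGTAGGCACCATCAATCGT"

_STOPS = {"TAA", "TAG", "TGA"}


def _default_codon_weights() -> dict[str, float]:
    """Fixed nonuniform codon-usage table for simulated coding regions.

    Codons whose reverse complement is a stop (TTA, CTA, TCA) are
    over-weighted so that the antisense strand of simulated genes is
    stop-dense, as in real compact phage genomes; this keeps long spurious
    antisense ORFs rare.
    """
    w = {}
    rng = np.random.default_rng(20240817)  # fixed table, not per-run
    for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
        if codon in _STOPS:
            continue
        w[codon] = 0.4 + 1.2 * rng.random()
    w["TTA"] = 6.0
    w["CTA"] = 3.0
    w["TCA"] = 4.5
    w["ATG"] = 0.8
    return w


CODON_WEIGHTS = _default_codon_weights()
_CODONS = list(CODON_WEIGHTS)
_CODON_P = np.array([CODON_WEIGHTS[c] for c in _CODONS])
_CODON_P = _CODON_P / _CODON_P.sum()


def default_utr_bias() -> np.ndarray:
    """Default trinucleotide composition for simulated noncoding regions.

    AT-rich with stop-codon trinucleotides boosted, so UTRs are stop-dense
    in every frame and compositionally distinct from codon-driven coding
    sequence.
    """
    base_p = {"A": 0.34, "C": 0.13, "G": 0.17, "T": 0.36}
    v = np.array([base_p[t[0]] * base_p[t[1]] * base_p[t[2]] for t in TRINUCS])
    for s in _STOPS:
        v[_TRI_INDEX[s]] *= 2.0
    return v / v.sum()


@dataclass
class SimConfig:
    """Study conditions for the simulation.

    Defaults reflect the protocol the analysis targets: dsRNA fragmented to
    ~1.5 kb (SD 300 nt, floor 200 nt), an adaptor on every fragment 3'
    end, 300-nt reads, and bisegmented genomes of a few kb with a long
    (1.5 kb) noncoding 5'UTR on a subset of RNA1 segments.
    """

    n_genomes: int = 10
    segment_len_range: tuple[int, int] = (2600, 4200)
    fragment_len_mean: int = 1500
    fragment_len_sd: int = 300
    fragment_len_min: int = 200
    read_len: int = 300
    coverage: float = 50.0
    adaptor: str = DEFAULT_ADAPTOR
    utr5_len: int = 1500
    long_utr_frac: float = 0.6
    short_utr_len: int = 60
    sd_prob: float = 0.9
    utr_trinuc_bias: np.ndarray | None = None
    error_rate: float = 0.002
    min_orf_aa: int = 80
    terminal_len: int = 30
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.adaptor:
            raise ValueError("adaptor must be non-empty")
        if not (0.0 <= self.error_rate <= 1.0):
            raise ValueError("error_rate must be in [0, 1]")
        if not (0.0 <= self.long_utr_frac <= 1.0):
            raise ValueError("long_utr_frac must be in [0, 1]")
        if not (0.0 <= self.sd_prob <= 1.0):
            raise ValueError("sd_prob must be in [0, 1]")
        if self.utr_trinuc_bias is not None:
            v = np.asarray(self.utr_trinuc_bias, dtype=float)
            if v.shape != (64,) or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
                raise ValueError("utr_trinuc_bias must be 64 nonnegative probs summing to 1")
            self.utr_trinuc_bias = v
        if self.segment_len_range[0] > self.segment_len_range[1]:
            raise ValueError("segment_len_range min > max")

    def bias(self) -> np.ndarray:
        return self.utr_trinuc_bias if self.utr_trinuc_bias is not None else default_utr_bias()


@dataclass
class TruthGenome:
    """A simulated bisegmented genome with full ground truth."""

    genome_id: str
    segments: list[NucSequence]
    terminal5: str
    terminal3: str
    utr5_len: int
    #: (segment_id, start, end, strand, has_sd) per designed ORF
    orf_truth: list[tuple[str, int, int, str, bool]]
    #: (segment_id, start) -> designed protein sequence
    orf_proteins: dict[tuple[str, int], str] = field(default_factory=dict)
    #: (segment_id, start) -> (sd_motif, sd_spacer) for has_sd ORFs
    sd_truth: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)


def _markov_noncoding(rng: np.random.Generator, n: int, bias: np.ndarray) -> str:
    """Sample an order-2 Markov sequence whose trinucleotide stationary
    composition follows ``bias``."""
    if n <= 0:
        return ""
    tri = bias.reshape(4, 4, 4)
    # initial dinucleotide from the marginal over the first two positions
    di = tri.sum(axis=2).ravel()
    di = di / di.sum()
    start = rng.choice(16, p=di)
    a, b = divmod(start, 4)
    out = [BASES[a], BASES[b]]
    cond = tri / np.maximum(tri.sum(axis=2, keepdims=True), 1e-300)
    flat_draws = rng.random(max(0, n - 2))
    for i in range(n - 2):
        p = cond[a, b]
        c = int(np.searchsorted(np.cumsum(p), flat_draws[i], side="right"))
        c = min(c, 3)
        out.append(BASES[c])
        a, b = b, c
    return "".join(out[:n])


def _coding_nt(rng: np.random.Generator, aa_len: int) -> str:
    """An ORF of ``aa_len`` residues: ATG + sampled codons + TAA."""
    idx = rng.choice(len(_CODONS), size=aa_len - 1, p=_CODON_P)
    return "ATG" + "".join(_CODONS[i] for i in idx) + "TAA"


_SD = annotate.SD_CONSENSUS
_SD_SUBS = {
    _SD[o : o + ln]
    for ln in range(4, len(_SD) + 1)
    for o in range(len(_SD) - ln + 1)
}


def _contains_sd_like(s: str) -> bool:
    return any(sub in s for sub in _SD_SUBS)


def _pre_orf_block(rng: np.random.Generator, has_sd: bool) -> tuple[str, str | None, int | None]:
    """The region placed immediately before an ORF.

    Layout: in-frame TAA guard, C-padding to keep the guard in the ORF's
    frame, then either the SD motif plus a spacer, or an SD-free filler.
    The guard stop pins the upstream boundary of the stop-to-stop region
    so the designed start codon is also the most upstream one.
    """
    for _ in range(100):
        if has_sd:
            spacer = int(rng.integers(5, 12))
            pad = (-spacer) % 3  # guard(3) + pad + SD(6) + spacer multiple of 3
            filler = "".join(rng.choice(list("ACT"), size=spacer))
            block = "TAA" + "C" * pad + _SD + filler
            tail = _SD + filler
        else:
            u = int(rng.integers(10, 17))
            pad = (-u) % 3
            filler = "".join(rng.choice(list("ACT"), size=u))
            block = "TAA" + "C" * pad + filler
            tail = filler
            if _contains_sd_like(tail):
                continue
        # no permitted start codon in frame between guard and the real start
        inframe = [block[i : i + 3] for i in range(3, len(block) - 2, 3)]
        if any(c in annotate.DEFAULT_STARTS for c in inframe):
            continue
        if has_sd:
            return block, _SD, spacer
        return block, None, None
    raise RuntimeError("could not construct a pre-ORF block")


def _syn_codons() -> dict[str, list[str]]:
    """Synonymous alternatives per sense codon under translation table 11."""
    from Bio.Seq import Seq

    by_aa: dict[str, list[str]] = {}
    aa_of: dict[str, str] = {}
    for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
        aa = str(Seq(codon).translate(table=11))
        aa_of[codon] = aa
        if aa != "*":
            by_aa.setdefault(aa, []).append(codon)
    return {c: [x for x in by_aa[aa_of[c]] if x != c] for c in aa_of if aa_of[c] != "*"}


_SYNONYMS = _syn_codons()


def _try_recode(
    seq: list[str],
    fwd_pos: tuple[int, int, int],
    goal_oriented: str,
    strand: str,
    mutable: np.ndarray,
    codon_of: dict[int, tuple[int, int]],
) -> bool:
    """Attempt to rewrite three forward positions so the strand-oriented
    trimer becomes ``goal_oriented``, honoring the mutability mask.

    Free noncoding positions may take any base; positions inside a real
    ORF may only change if every affected real codon stays synonymous.
    Returns True and applies the edit in place on success.
    """
    goal_fwd = goal_oriented if strand == "+" else revcomp(goal_oriented)
    changed = [
        (p, b) for p, b in zip(fwd_pos, goal_fwd) if seq[p] != b
    ]
    if not changed:
        return False
    touched_codons: dict[int, list[tuple[int, str]]] = {}
    for p, b in changed:
        if p in codon_of:
            touched_codons.setdefault(codon_of[p][0], []).append((p, b))
        elif not mutable[p]:
            return False
    for cstart, edits in touched_codons.items():
        old = "".join(seq[cstart : cstart + 3])
        new = list(old)
        for p, b in edits:
            new[p - cstart] = b
        new = "".join(new)
        if new == old:
            continue
        if old not in _SYNONYMS or new not in _SYNONYMS[old]:
            return False
    for p, b in changed:
        seq[p] = b
    return True


_ALL_TRIMERS = ["".join(t) for t in itertools.product(BASES, repeat=3)]
_NON_START_TRIMERS = [t for t in _ALL_TRIMERS if t not in ("ATG", "GTG", "TTG")]


def _kill_spurious_orf(
    seq: list[str],
    orf,
    min_aa: int,
    mutable: np.ndarray,
    codon_of: dict[int, tuple[int, int]],
) -> bool:
    """Destroy a spurious ORF by breaking its start codon or planting an
    early in-frame stop, without altering any designed protein."""
    n_codons = (orf.end - orf.start) // 3 - 1

    def codon_positions(k: int) -> tuple[int, int, int]:
        if orf.strand == "+":
            p = orf.start + 3 * k
        else:
            p = orf.end - 3 * (k + 1)
        return (p, p + 1, p + 2)

    # break the start codon (any non-start replacement will do)
    for goal in _NON_START_TRIMERS:
        if _try_recode(seq, codon_positions(0), goal, orf.strand, mutable, codon_of):
            return True
    # or plant a stop early enough that the remainder is sub-threshold
    for k in range(1, min(n_codons, min_aa)):
        for goal in ("TAA", "TAG", "TGA"):
            if _try_recode(seq, codon_positions(k), goal, orf.strand, mutable, codon_of):
                return True
    return False


def _scramble_codons(
    seq: list[str],
    span: tuple[int, int],
    codon_of: dict[int, tuple[int, int]],
    rng: np.random.Generator,
) -> bool:
    """Synonymously re-draw every designed codon overlapping ``span``.

    Last-resort move when no single edit can kill a spurious ORF: the
    encoded proteins are unchanged, but the nucleotide context of the
    offending frame is reshuffled so the next kill attempt sees fresh
    sequence.
    """
    starts = sorted({codon_of[p][0] for p in range(*span) if p in codon_of})
    changed = False
    for cs in starts:
        old = "".join(seq[cs : cs + 3])
        alts = _SYNONYMS.get(old)
        if not alts:
            continue
        new = alts[int(rng.integers(len(alts)))]
        seq[cs : cs + 3] = list(new)
        changed = True
    return changed


def _build_segment(
    rng: np.random.Generator,
    seg_id: str,
    terminal5: str,
    terminal3: str,
    utr_len: int,
    orf_aa_lens: list[int],
    has_sd_flags: list[bool],
    bias: np.ndarray,
    min_aa_scan: int = 60,
    max_attempts: int = 8,
):
    """Assemble one segment and make the ORF scanner recover exactly the
    designed ORFs.

    Random coding sequence inevitably contains incidental open frames on
    shifted and antisense frames; these are removed by breaking their
    start codons or planting early stops, using only free noncoding bases
    and synonymous recoding of designed codons, so every designed protein
    is preserved exactly. A final check requires that no unplanted SD
    motif appears upstream of an SD-free ORF.
    """
    for _ in range(max_attempts):
        parts = [terminal5, _markov_noncoding(rng, utr_len, bias)]
        pos = len(terminal5) + utr_len
        orfs = []
        proteins = {}
        sds = {}
        immutable_ranges = [(0, len(terminal5))]
        coding_ranges = []
        for aa_len, has_sd in zip(orf_aa_lens, has_sd_flags):
            block, motif, spacer = _pre_orf_block(rng, has_sd)
            nt = _coding_nt(rng, aa_len)
            parts.append(block)
            start = pos + len(block)
            end = start + len(nt)
            parts.append(nt)
            orfs.append((seg_id, start, end, "+", has_sd))
            proteins[(seg_id, start)] = annotate.translate_orf(nt)
            if has_sd:
                sds[(seg_id, start)] = (motif, spacer)
            # freeze the whole SD search window so repair edits cannot
            # plant or destroy a motif
            immutable_ranges.append((max(0, start - 21), start))
            coding_ranges.append((start, end))
            pos = end
            gap = _markov_noncoding(rng, int(rng.integers(15, 41)), bias)
            parts.append(gap)
            pos += len(gap)
        parts.append(terminal3)
        seq = list("".join(parts))
        immutable_ranges.append((len(seq) - len(terminal3), len(seq)))
        mutable = np.ones(len(seq), dtype=bool)
        for a, b in immutable_ranges:
            mutable[a:b] = False
        codon_of: dict[int, tuple[int, int]] = {}
        for a, b in coding_ranges:
            mutable[a:b] = False
            # the start codon and stop codon of a designed ORF are frozen
            for p in range(a + 3, b - 3):
                codon_of[p] = (a + 3 * ((p - a) // 3), (p - a) // 3)
        want = {(s, e, st) for _, s, e, st, _ in orfs}

        ok = False
        for _round in range(400):
            seg = NucSequence(seg_id, "".join(seq))
            found = annotate.find_orfs(seg, min_aa=min_aa_scan)
            spurious = [o for o in found if (o.start, o.end, o.strand) not in want]
            if {(o.start, o.end, o.strand) for o in found} >= want and not spurious:
                ok = True
                break
            if not spurious:
                break  # a designed ORF went missing: rebuild
            target = spurious[0]
            if not _kill_spurious_orf(seq, target, min_aa_scan, mutable, codon_of):
                if not _scramble_codons(seq, (target.start, target.end), codon_of, rng):
                    break
        if not ok:
            continue
        seg = NucSequence(seg_id, "".join(seq))
        found_orfs = annotate.find_orfs(seg, min_aa=min_aa_scan)
        if {(o.start, o.end, o.strand) for o in found_orfs} != want:
            continue
        sd_ok = True
        for (_, s, e, st, has_sd) in orfs:
            ann = next(o for o in found_orfs if (o.start, o.end, o.strand) == (s, e, st))
            hit = annotate.detect_sd(seg, ann)
            if has_sd and hit != sds[(seg_id, s)]:
                sd_ok = False
                break
            if not has_sd and hit is not None:
                sd_ok = False
                break
        if sd_ok:
            return seg, orfs, proteins, sds
    raise RuntimeError(f"segment {seg_id}: could not realize the designed ORF layout")


def simulate_genomes(cfg: SimConfig) -> list[TruthGenome]:
    """Simulate ``cfg.n_genomes`` bisegmented genomes, deterministically
    for a given seed.

    Each genome draws its own terminal sequences (so distinct genomes
    share no termini beyond chance); RNA1 carries a single long ORF (the
    RdRP stand-in) behind a 5'UTR that is long (``utr5_len``) for a
    ``long_utr_frac`` fraction of genomes; RNA2 carries 1-4 ORFs.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    bias = cfg.bias()
    lo, hi = cfg.segment_len_range
    genomes: list[TruthGenome] = []
    for g in range(cfg.n_genomes):
        gid = f"G{g + 1:03d}"
        t5 = "".join(rng.choice(list(BASES), size=cfg.terminal_len))
        t3 = "".join(rng.choice(list(BASES), size=cfg.terminal_len))
        long_utr = rng.random() < cfg.long_utr_frac
        utr1 = cfg.utr5_len if long_utr else cfg.short_utr_len

        def aa_budget(L: int, utr: int, n_orfs: int) -> int:
            overhead = 2 * cfg.terminal_len + utr + n_orfs * 18 + n_orfs * 30
            return (L - overhead) // 3 - 1

        L1 = int(rng.integers(lo, hi + 1))
        aa1 = aa_budget(L1, utr1, 1)
        if aa1 < cfg.min_orf_aa:
            raise ValueError(
                f"segment_len_range {cfg.segment_len_range} too small to host "
                f"an ORF of {cfg.min_orf_aa} aa behind a {utr1}-nt UTR"
            )
        seg1, orfs1, prot1, sd1 = _build_segment(
            rng, f"{gid}_RNA1", t5, t3, utr1, [aa1],
            [bool(rng.random() < cfg.sd_prob)], bias,
        )

        L2 = int(rng.integers(lo, hi + 1))
        n2 = int(rng.integers(1, 5))
        while n2 > 1 and aa_budget(L2, cfg.short_utr_len, n2) < n2 * cfg.min_orf_aa:
            n2 -= 1
        total_aa = aa_budget(L2, cfg.short_utr_len, n2)
        if total_aa < cfg.min_orf_aa:
            raise ValueError(
                f"segment_len_range {cfg.segment_len_range} too small to host "
                f"{cfg.min_orf_aa}-aa ORFs"
            )
        w = rng.dirichlet(np.ones(n2))
        extra = total_aa - n2 * cfg.min_orf_aa
        aa2 = [cfg.min_orf_aa + int(extra * wi) for wi in w]
        seg2, orfs2, prot2, sd2 = _build_segment(
            rng, f"{gid}_RNA2", t5, t3, cfg.short_utr_len, aa2,
            [bool(rng.random() < cfg.sd_prob) for _ in aa2], bias,
        )
        genomes.append(
            TruthGenome(
                genome_id=gid,
                segments=[seg1, seg2],
                terminal5=t5,
                terminal3=t3,
                utr5_len=utr1,
                orf_truth=orfs1 + orfs2,
                orf_proteins={**prot1, **prot2},
                sd_truth={**sd1, **sd2},
            )
        )
    return genomes


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0 or not seq:
        return seq
    k = rng.binomial(len(seq), rate)
    if k == 0:
        return seq
    pos = rng.choice(len(seq), size=k, replace=False)
    s = list(seq)
    for p in pos:
        alt = [b for b in BASES if b != s[p]]
        s[p] = alt[int(rng.integers(3))]
    return "".join(s)


def simulate_flds_reads(
    genomes: list[TruthGenome], cfg: SimConfig
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Fragment both strands of every segment, ligate the adaptor to each
    fragment 3' end, and emit reads from fragment ends.

    Per fragment, one read is taken from the fragment 5' end and one from
    the 3' end; the 3'-end read crosses the ligation junction and carries
    genomic suffix + adaptor. Fragmentation rounds repeat until the target
    coverage is reached. The truth table labels each junction-carrying read
    ``terminal5``/``terminal3`` (a true genome terminus) or ``internal``.

    Returns the reads and a truth table with columns: read_id, segment_id,
    strand, mol_start, mol_end (molecule coordinates of the genomic part),
    adaptor_bases, junction.
    """
    if not cfg.adaptor:
        raise ValueError("adaptor must be non-empty")
    if cfg.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng([cfg.seed, 1])
    reads: list[ReadRecord] = []
    rows: list[dict] = []
    counter = itertools.count()
    n_short = 0
    for genome in genomes:
        for seg in genome.segments:
            L = len(seg.seq)
            target = cfg.coverage * L / 2.0  # per strand
            for strand in "+-":
                mol = seg.seq if strand == "+" else revcomp(seg.seq)
                bases = 0
                while bases < target:
                    pos = 0
                    while pos < L:
                        fl = int(rng.normal(cfg.fragment_len_mean, cfg.fragment_len_sd))
                        fl = max(cfg.fragment_len_min, min(fl, L))
                        if pos + fl > L:
                            fl = L - pos
                        a, b = pos, pos + fl
                        pos = b
                        junction = "internal"
                        if b == L:
                            junction = "terminal3" if strand == "+" else "terminal5"
                        frag = mol[a:b] + cfg.adaptor
                        stem = f"{seg.id}|{strand}|r{next(counter)}"
                        if fl <= cfg.read_len:
                            n_short += 1
                            emit = [(frag, a, b, len(cfg.adaptor), junction, "")]
                        else:
                            left = mol[a : a + cfg.read_len]
                            right = frag[-cfg.read_len :]
                            gpart = cfg.read_len - len(cfg.adaptor)
                            emit = [
                                (left, a, a + cfg.read_len, 0, "none", "/1" if cfg.paired else "L"),
                                (right, b - gpart, b, len(cfg.adaptor), junction, "/2" if cfg.paired else "R"),
                            ]
                        for seq_r, ga, gb, adn, junc, tag in emit:
                            rid = f"{stem}{tag}" if tag.startswith("/") else f"{stem}_{tag}" if tag else stem
                            seq_err = _apply_errors(rng, seq_r, cfg.error_rate)
                            reads.append(ReadRecord(rid, seq_err))
                            bases += len(seq_r)
                            rows.append(
                                {
                                    "read_id": rid,
                                    "segment_id": seg.id,
                                    "segment_length": L,
                                    "strand": strand,
                                    "mol_start": ga,
                                    "mol_end": gb,
                                    "adaptor_bases": adn,
                                    "junction": junc,
                                }
                            )
    truth = pd.DataFrame(rows)
    return reads, truth


def truncate_contig(seg: NucSequence, n5: int, n3: int) -> NucSequence:
    """Remove ``n5``/``n3`` nt from the 5'/3' ends (negative controls for
    completeness calling)."""
    if n5 < 0 or n3 < 0 or n5 + n3 >= len(seg.seq):
        raise ValueError(
            f"cannot truncate {seg.id!r} (length {len(seg.seq)}) by {n5}+{n3}"
        )
    return NucSequence(seg.id, seg.seq[n5 : len(seg.seq) - n3], seg.description)


def align_reads(
    reads: list[ReadRecord],
    truth: pd.DataFrame,
    contigs: list[NucSequence],
    origin: dict[str, tuple[str, int]] | None = None,
    min_anchor: int = 30,
) -> list[AlignmentRecord]:
    """Project simulated reads onto contigs using their known provenance.

    This is a truth-based mapper: each read is placed at its generating
    coordinates, overhangs beyond the contig (including adaptor bases)
    become soft clips, and identity is recomputed from the actual bases,
    so sequencing errors are reflected. ``origin`` maps a contig id to
    ``(segment_id, trim5)`` when the contig is a (possibly truncated) copy
    of a simulated segment; by default contig ids are segment ids with no
    truncation. Reads whose genomic anchor on the contig is shorter than
    ``min_anchor`` are dropped, as a real mapper would.
    """
    seq_of = {r.id: r.seq for r in reads}
    contig_by_id = {c.id: c for c in contigs}
    if origin is None:
        origin = {c.id: (c.id, 0) for c in contigs}
    by_segment: dict[str, list[tuple[str, int]]] = {}
    for cid, (sid, trim5) in origin.items():
        by_segment.setdefault(sid, []).append((cid, trim5))
    out: list[AlignmentRecord] = []
    for row in truth.itertuples(index=False):
        for cid, trim5 in by_segment.get(row.segment_id, ()):
            contig = contig_by_id[cid]
            Lc = len(contig.seq)
            read_seq = seq_of[row.read_id]
            adn = row.adaptor_bases
            if row.strand == "+":
                g0, g1 = row.mol_start, row.mol_end
                ref_orient = read_seq  # [genomic][adaptor]
                lead = 0
            else:
                # molecule coords are on the revcomp; map to forward
                seg_len = int(row.segment_length)
                g0 = seg_len - row.mol_end
                g1 = seg_len - row.mol_start
                ref_orient = revcomp(read_seq)  # [rc(adaptor)][genomic fwd]
                lead = adn
            c0, c1 = g0 - trim5, g1 - trim5
            left_over = max(0, -c0)
            right_over = max(0, c1 - Lc)
            c0c, c1c = c0 + left_over, c1 - right_over
            span = c1c - c0c
            if span < min_anchor:
                continue
            a_start = lead + left_over
            aligned = ref_orient[a_start : a_start + span]
            ref_slice = contig.seq[c0c:c1c]
            matches = sum(1 for x, y in zip(aligned, ref_slice) if x == y)
            out.append(
                AlignmentRecord(
                    read_id=row.read_id,
                    ref_id=cid,
                    ref_start=c0c,
                    ref_end=c1c,
                    strand=row.strand,
                    identity=matches / span,
                    indel_count=0,
                    clipped_prefix=ref_orient[:a_start],
                    clipped_suffix=ref_orient[a_start + span :],
                    seq=ref_orient,
                )
            )
    return out


def segments_as_contigs(genomes: list[TruthGenome]) -> list[NucSequence]:
    """Error-free copies of every simulated segment, standing in for
    assembly output."""
    return [NucSequence(s.id, s.seq, f"genome={g.genome_id}")
            for g in genomes for s in g.segments]
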