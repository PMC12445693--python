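"""Consensus-expansion alignment preparation for RdRP phylogenetics.

Family-level protein alignments are summarized by consensus sequences,
the consensuses are aligned into a master alignment (by an external
aligner, consumed here as input), and each consensus residue is then
expanded back into the full column of its family alignment, producing one
"complete" mega-alignment. Columns are trimmed by gap fraction and by
homogeneity (mean pairwise identity of non-gap residues), and up to k
maximally diverse representatives per family can be selected.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

GAP = "-"
#: consensus sentinel for columns too gappy to contribute a residue
SENTINEL = "."


@dataclass
class FamilyAlignment:
    family_id: str
    row_ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.row_ids):
            raise ValueError(f"family {self.family_id!r}: ids/rows mismatch")
        if not self.rows:
            raise ValueError(f"family {self.family_id!r}: empty alignment")
        ln = len(self.rows[0])
        if any(len(r) != ln for r in self.rows):
            raise ValueError(f"family {self.family_id!r}: unequal row lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass
class ColumnStats:
    column_index: int
    gap_fraction: float
    homogeneity: float


def family_consensus(fam: FamilyAlignment, max_gap: float = 0.5) -> str:
    """Per-column majority consensus.

    Columns with gap fraction above ``max_gap`` yield the sentinel and are
    not emitted to the master aligner; ties go to the alphabetically first
    residue.
    """
    if len(fam.rows) < 2:
        raise ValueError(f"family {fam.family_id!r}: need >= 2 rows for a consensus")
    out = []
    for col in zip(*fam.rows):
        gaps = col.count(GAP)
        if gaps / len(col) > max_gap:
            out.append(SENTINEL)
            continue
        counts = Counter(c for c in col if c != GAP)
        top = max(counts.values())
        out.append(min(c for c, n in counts.items() if n == top))
    return "".join(out)


def emitted_consensus(consensus: str) -> str:
    """The consensus as sent to the master aligner: sentinels removed."""
    return consensus.replace(SENTINEL, "")


def expand_master(
    master_rows: dict[str, str],
    families: Sequence[FamilyAlignment],
    consensuses: dict[str, str] | None = None,
) -> tuple[list[str], list[str]]:
    """Expand each master-consensus residue into its family's column.

    ``master_rows`` maps family_id to that family's aligned consensus row
    (gaps allowed); its ungapped content must equal the family's emitted
    consensus. For master column j, a family contributes its original
    alignment column where the master row has a residue, else all gaps.
    Sentinel (too-gappy) family columns are never emitted and are thereby
    dropped. Returns (row_ids, rows); row order is family input order,
    then family-internal order.
    """
    consensuses = consensuses or {f.family_id: family_consensus(f) for f in families}
    width = None
    for fid, row in master_rows.items():
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(f"master row {fid!r}: length {len(row)} != {width}")
    col_sources: dict[str, list[int | None]] = {}
    for fam in families:
        fid = fam.family_id
        if fid not in master_rows:
            raise ValueError(f"family {fid!r} missing from the master alignment")
        cons = consensuses[fid]
        emitted_cols = [i for i, c in enumerate(cons) if c != SENTINEL]
        emitted = "".join(cons[i] for i in emitted_cols)
        ungapped = master_rows[fid].replace(GAP, "")
        if ungapped != emitted:
            k = next(
                (i for i, (x, y) in enumerate(zip(ungapped, emitted)) if x != y),
                min(len(ungapped), len(emitted)),
            )
            raise ValueError(
                f"family {fid!r}: master row content diverges from its "
                f"consensus at consensus position {k}"
            )
        src: list[int | None] = []
        next_col = 0
        for ch in master_rows[fid]:
            if ch == GAP:
                src.append(None)
            else:
                src.append(emitted_cols[next_col])
                next_col += 1
        col_sources[fid] = src
    row_ids: list[str] = []
    rows: list[list[str]] = []
    for fam in families:
        src = col_sources[fam.family_id]
        for rid, row in zip(fam.row_ids, fam.rows):
            row_ids.append(f"{fam.family_id}|{rid}")
            rows.append([GAP if s is None else row[s] for s in src])
    return row_ids, ["".join(r) for r in rows]


def column_stats(rows: Sequence[str]) -> list[ColumnStats]:
    """Gap fraction and homogeneity per column of an alignment.

    Homogeneity is the mean pairwise identity among non-gap residues:
    sum over residues of C(n_r, 2) divided by C(n, 2). Columns with fewer
    than two non-gap residues are reported as 1.0 (undefined, never
    triggering removal).
    """
    if not rows:
        raise ValueError("empty alignment")
    n_rows = len(rows)
    out = []
    for j, col in enumerate(zip(*rows)):
        gaps = col.count(GAP)
        residues = [c for c in col if c != GAP]
        n = len(residues)
        if n < 2:
            hom = 1.0
        else:
            counts = Counter(residues)
            same = sum(k * (k - 1) // 2 for k in counts.values())
            hom = same / (n * (n - 1) // 2)
        out.append(ColumnStats(j, gaps / n_rows, hom))
    return out


def trim_columns(
    rows: Sequence[str],
    max_gap: float = 0.67,
    min_homogeneity: float = 0.05,
) -> tuple[list[str], list[int]]:
    """Remove columns with gap fraction above ``max_gap`` or homogeneity
    below ``min_homogeneity`` (two independent filters; either condition
    removes). Returns (trimmed rows, kept column indices)."""
    stats = column_stats(rows)
    keep = [
        s.column_index
        for s in stats
        if s.gap_fraction <= max_gap and s.homogeneity >= min_homogeneity
    ]
    trimmed = ["".join(r[j] for j in keep) for r in rows]
    return trimmed, keep


def pairwise_row_identity(a: str, b: str) -> float:
    """Identity over columns where both rows have residues; 0 when no
    such column exists."""
    both = [(x, y) for x, y in zip(a, b) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return sum(1 for x, y in both if x == y) / len(both)


def select_diverse(fam: FamilyAlignment, k: int = 40) -> list[str]:
    """Greedy maxi-min selection of up to ``k`` diverse rows.

    Starts from the pair with lowest pairwise identity, then repeatedly
    adds the row whose maximum identity to the chosen set is smallest;
    ties resolve to the earliest row. Families with at most ``k`` rows are
    returned whole. Returns selected row ids in input order.
    """
    n = len(fam.rows)
    if n <= k:
        return list(fam.row_ids)
    ident = [[0.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ident[i][j] = ident[j][i] = pairwise_row_identity(fam.rows[i], fam.rows[j])
    best_pair = (0, 1)
    best_val = 2.0
    for i in range(n):
        for j in range(i + 1, n):
            if ident[i][j] < best_val:
                best_val = ident[i][j]
                best_pair = (i, j)
    chosen = [best_pair[0], best_pair[1]]
    chosen_set = set(chosen)
    while len(chosen) < k:
        best_i = None
        best_maxid = 2.0
        for i in range(n):
            if i in chosen_set:
                continue
            m = max(ident[i][j] for j in chosen)
            if m < best_maxid:
                best_maxid = m
                best_i = i
        chosen.append(best_i)
        chosen_set.add(best_i)
    chosen.sort()
    return [fam.row_ids[i] for i in chosen]


def read_alignment_fasta(path) -> FamilyAlignment:
    """Read an aligned protein FASTA as a FamilyAlignment (family id =
    file stem)."""
    from pathlib import Path

    from Bio import SeqIO

    p = Path(path)
    ids, rows = [], []
    for rec in SeqIO.parse(str(p), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return FamilyAlignment(p.stem, ids, rows)
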