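"""Consensus expansion, column statistics, trimming, representative
selection."""

import itertools
import random

import numpy as np
import pytest

from fldseg.consensus import (
    SENTINEL,
    ColumnStats,
    FamilyAlignment,
    column_stats,
    emitted_consensus,
    expand_master,
    family_consensus,
    pairwise_row_identity,
    select_diverse,
    trim_columns,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestFamilyConsensus:
    def test_majority(self):
        fam = FamilyAlignment("f", ["a", "b", "c"], ["A", "A", "G"])
        assert family_consensus(fam) == "A"

    def test_gappy_column_sentinel(self):
        fam = FamilyAlignment("f", ["a", "b", "c"], ["A", "-", "-"])
        assert family_consensus(fam) == SENTINEL

    def test_tie_alphabetical(self):
        fam = FamilyAlignment("f", list("abcd"), ["A", "A", "G", "G"])
        assert family_consensus(fam) == "A"

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            family_consensus(FamilyAlignment("f", ["a"], ["AAA"]))


def _random_family(rng, fid, n_rows, n_cols, gap_p=0.2):
    rows = [
        "".join(
            "-" if rng.random() < gap_p else AA[rng.integers(len(AA))]
            for _ in range(n_cols)
        )
        for _ in range(n_rows)
    ]
    # ensure no all-gap rows
    rows = [r if set(r) != {"-"} else "A" * n_cols for r in rows]
    return FamilyAlignment(fid, [f"{fid}_r{i}" for i in range(n_rows)], rows)


class TestExpandMaster:
    def _setup(self, master_gaps=False):
        famA = FamilyAlignment("A", ["a1", "a2"], ["AC", "AD"])
        famB = FamilyAlignment("B", ["b1", "b2"], ["CE", "CF"])
        consA = family_consensus(famA)  # "AC" (ties alphabetical)
        consB = family_consensus(famB)  # "CE"
        if master_gaps:
            master = {"A": "AC-", "B": "C-E"}
        else:
            master = {"A": "AC", "B": "CE"}
        return famA, famB, master

    def test_no_gap_expansion(self):
        famA, famB, master = self._setup()
        ids, rows = expand_master(master, [famA, famB])
        assert ids == ["A|a1", "A|a2", "B|b1", "B|b2"]
        assert rows == ["AC", "AD", "CE", "CF"]

    def test_master_gap_emits_gap_block(self):
        famA, famB, master = self._setup(master_gaps=True)
        ids, rows = expand_master(master, [famA, famB])
        assert rows[0] == "AC-" and rows[1] == "AD-"
        assert rows[2] == "C-E" and rows[3] == "C-F"

    def test_mismatch_rejected_with_position(self):
        famA, famB, master = self._setup()
        master["A"] = "AA"
        with pytest.raises(ValueError, match="family 'A'.*position 1"):
            expand_master(master, [famA, famB])

    def test_roundtrip_recovers_family_columns(self):
        """Extracting one family's rows from the expansion and dropping
        all-gap columns reproduces its non-sentinel columns."""
        rng = np.random.default_rng(13)
        fams = [_random_family(rng, f"F{k}", 3, 12) for k in range(3)]
        consensuses = {f.family_id: family_consensus(f) for f in fams}
        emitted = {fid: emitted_consensus(c) for fid, c in consensuses.items()}
        # build a master by interleaving each consensus with gaps
        master = {}
        width = max(len(e) for e in emitted.values()) + 4
        for i, (fid, e) in enumerate(sorted(emitted.items())):
            pad = width - len(e)
            master[fid] = "-" * min(i, pad) + e + "-" * (pad - min(i, pad))
        ids, rows = expand_master(master, fams, consensuses)
        for fam in fams:
            cons = consensuses[fam.family_id]
            keep_cols = [i for i, c in enumerate(cons) if c != SENTINEL]
            fam_rows = [
                r for rid, r in zip(ids, rows) if rid.startswith(fam.family_id + "|")
            ]
            nongap_cols = [
                j for j in range(len(fam_rows[0]))
                if any(r[j] != "-" for r in fam_rows)
            ]
            collapsed = ["".join(r[j] for j in nongap_cols) for r in fam_rows]
            expected = ["".join(r[j] for j in keep_cols) for r in fam.rows]
            assert collapsed == expected


class TestColumnStats:
    def test_uniform_column(self):
        (st,) = column_stats(["A", "A", "A"])
        assert st.gap_fraction == 0.0 and st.homogeneity == 1.0

    def test_all_distinct(self):
        rows = [a for a in AA]
        (st,) = column_stats(rows)
        assert st.homogeneity == 0.0

    def test_half_and_half(self):
        rows = ["A"] * 5 + ["C"] * 5
        (st,) = column_stats(rows)
        assert st.homogeneity == pytest.approx(20 / 45)

    def test_sparse_column_undefined_homogeneity(self):
        (st,) = column_stats(["A", "-", "-"])
        assert st.homogeneity == 1.0
        assert st.gap_fraction == pytest.approx(2 / 3)

    def test_brute_force_pair_oracle(self):
        """Mean pairwise identity agrees with explicit pair enumeration on
        1,000 random columns."""
        rng = random.Random(99)
        alphabet = AA + "-"
        for _ in range(1000):
            n = rng.randint(2, 12)
            col = [rng.choice(alphabet) for _ in range(n)]
            (st,) = column_stats(["".join(c) for c in col])
            residues = [c for c in col if c != "-"]
            if len(residues) < 2:
                expected = 1.0
            else:
                pairs = list(itertools.combinations(residues, 2))
                expected = sum(1 for x, y in pairs if x == y) / len(pairs)
            assert st.homogeneity == pytest.approx(expected)


class TestTrimColumns:
    def test_gap_threshold_boundary(self):
        rows = ["AAA"] * 3 + ["-A-"] * 7
        # col0 gap 0.7 -> removed; col1 gap 0 kept; col2 gap 0.7 removed
        trimmed, kept = trim_columns(rows, max_gap=0.67)
        assert kept == [1]
        rows = ["AAA"] * 4 + ["-A-"] * 6  # gap 0.6 kept
        _, kept = trim_columns(rows, max_gap=0.67)
        assert kept == [0, 1, 2]

    def test_heterogeneous_column_removed(self):
        col = list("ACDEFGHIKLMNPQRSTVWY")
        rows = [c + "A" for c in col]
        _, kept = trim_columns(rows, min_homogeneity=0.05)
        assert kept == [1]

    def test_conserved_alignment_untouched(self):
        rows = ["MKV"] * 10
        trimmed, kept = trim_columns(rows)
        assert trimmed == rows and kept == [0, 1, 2]

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        fam = _random_family(rng, "F", 10, 40, gap_p=0.3)
        once, _ = trim_columns(fam.rows)
        twice, kept2 = trim_columns(once)
        assert twice == once and kept2 == list(range(len(once[0])))

    def test_planted_core_retained_family_flanks_dropped(self):
        """Five families sharing a conserved 30-column core, each with a
        private 10-column flank: after consensus expansion the flank
        columns are mostly gaps and get trimmed, the core survives."""
        rng = np.random.default_rng(17)
        core = "".join(AA[rng.integers(len(AA))] for _ in range(30))
        fams, master = [], {}
        n_fam, flank_w = 5, 10
        for k in range(n_fam):
            rows = []
            for _ in range(10):
                flank = "".join(AA[rng.integers(len(AA))] for _ in range(flank_w))
                mutated = list(core)
                for i in range(len(mutated)):
                    if rng.random() < 0.1:
                        mutated[i] = AA[rng.integers(len(AA))]
                rows.append(flank + "".join(mutated))
            fam = FamilyAlignment(f"F{k}", [f"F{k}_r{i}" for i in range(10)], rows)
            fams.append(fam)
            cons = family_consensus(fam)
            # flanks occupy disjoint master blocks, cores stack together
            master[fam.family_id] = (
                "-" * (flank_w * k)
                + cons[:flank_w]
                + "-" * (flank_w * (n_fam - 1 - k))
                + cons[flank_w:]
            )
        ids, rows = expand_master(master, fams)
        _, kept = trim_columns(rows)
        core_cols = set(range(flank_w * n_fam, flank_w * n_fam + 30))
        kept_core = len(core_cols & set(kept)) / 30
        kept_flank = len(set(kept) - core_cols) / (flank_w * n_fam)
        assert kept_core >= 0.95
        assert kept_flank <= 0.05


class TestSelectDiverse:
    def test_small_family_returned_whole(self):
        fam = FamilyAlignment("f", ["a", "b"], ["AA", "AC"])
        assert select_diverse(fam, k=40) == ["a", "b"]

    def test_identical_rows_first_two(self):
        fam = FamilyAlignment("f", ["a", "b", "c"], ["AA", "AA", "AA"])
        assert select_diverse(fam, k=2) == ["a", "b"]

    def test_planted_haplogroups_one_each(self):
        rng = np.random.default_rng(23)
        groups = []
        for _ in range(5):
            proto = "".join(AA[rng.integers(len(AA))] for _ in range(40))
            groups.append(proto)
        ids, rows = [], []
        for gi, proto in enumerate(groups):
            for ri in range(20):
                s = list(proto)
                j = rng.integers(len(s))
                s[j] = AA[rng.integers(len(AA))]
                ids.append(f"g{gi}_r{ri}")
                rows.append("".join(s))
        fam = FamilyAlignment("f", ids, rows)
        chosen = select_diverse(fam, k=5)
        assert len(chosen) == 5
        assert {c.split("_")[0] for c in chosen} == {f"g{i}" for i in range(5)}


def test_pairwise_identity_ignores_mutual_gaps():
    assert pairwise_row_identity("A-C", "A-D") == pytest.approx(0.5)
    assert pairwise_row_identity("---", "---") == 0.0
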