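"""Greedy 97% clustering, fragment filters, FPKM and composition."""

import numpy as np
import pandas as pd
import pytest

from fldseg.abundance import (
    composition_summary,
    count_fragments,
    fpkm_table,
    greedy_cluster,
    ContigCluster,
)
from fldseg.records import AlignmentRecord, NucSequence


def _mutate(rng, seq, rate):
    s = list(seq)
    for i in range(len(s)):
        if rng.random() < rate:
            s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    return "".join(s)


class TestGreedyCluster:
    def test_identical_contigs_one_cluster(self):
        c = NucSequence("a", "ACGT" * 300)
        d = NucSequence("b", "ACGT" * 300)
        (cl,) = greedy_cluster([c, d])
        assert sorted(cl.member_ids) == ["a", "b"]

    def test_mutant_identity_threshold(self):
        """A 99%-identity mutant joins its parent's cluster; a 95% mutant
        founds its own at the 97% threshold."""
        rng = np.random.default_rng(8)
        parent = "".join(rng.choice(list("ACGT"), size=2000))
        near = _mutate(np.random.default_rng(1), parent, 0.01)
        far = _mutate(np.random.default_rng(2), parent, 0.05)
        import edlib  # independent identity oracle on the mutants

        for s, lo, hi in ((near, 0.985, 0.995), (far, 0.94, 0.96)):
            d = edlib.align(s, parent, mode="NW", task="distance")["editDistance"]
            assert lo <= 1 - d / len(parent) <= hi
        clusters = greedy_cluster(
            [NucSequence("parent", parent), NucSequence("near", near),
             NucSequence("far", far)],
            min_id=0.97,
        )
        members = {frozenset(c.member_ids) for c in clusters}
        assert frozenset({"parent", "near"}) in members
        assert frozenset({"far"}) in members

    def test_zero_threshold_single_cluster(self):
        rng = np.random.default_rng(3)
        contigs = [
            NucSequence(f"c{i}", "".join(rng.choice(list("ACGT"), size=500)))
            for i in range(4)
        ]
        assert len(greedy_cluster(contigs, min_id=0.0)) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([])


def _aln(read_id, ref, identity, indels=0):
    return AlignmentRecord(read_id, ref, 0, 100, "+", identity, indels)


class TestCountFragments:
    CL = [ContigCluster("rep", ["rep", "member"])]
    LEN = {"rep": 2000, "member": 1500}

    def test_identity_filter(self):
        counts = count_fragments([_aln("r1", "rep", 0.96)], self.CL, self.LEN)
        assert counts["rep"] == 0
        counts = count_fragments([_aln("r1", "rep", 0.97)], self.CL, self.LEN)
        assert counts["rep"] == 1

    def test_indel_filter(self):
        counts = count_fragments([_aln("r1", "rep", 0.98, indels=4)], self.CL, self.LEN)
        assert counts["rep"] == 0

    def test_pair_counts_once(self):
        alns = [_aln("f1/1", "rep", 0.99), _aln("f1/2", "member", 0.99)]
        counts = count_fragments(alns, self.CL, self.LEN)
        assert counts["rep"] == 1

    def test_multimapper_best_identity_wins(self):
        cl = [ContigCluster("a", ["a"]), ContigCluster("b", ["b"])]
        lens = {"a": 1000, "b": 3000}
        alns = [_aln("r", "a", 0.99), _aln("r", "b", 0.98)]
        counts = count_fragments(alns, cl, lens)
        assert counts == {"a": 1, "b": 0}
        # tie -> longest representative
        alns = [_aln("r", "a", 0.99), _aln("r", "b", 0.99)]
        counts = count_fragments(alns, cl, lens)
        assert counts == {"a": 0, "b": 1}

    def test_simulated_counts_close_to_truth(self, sim3_aligned):
        cfg, genomes, contigs, alignments = sim3_aligned
        clusters = [ContigCluster(c.id, [c.id]) for c in contigs]
        lengths = {c.id: len(c.seq) for c in contigs}
        counts = count_fragments(alignments, clusters, lengths)
        truth_counts = {c.id: 0 for c in contigs}
        for a in alignments:
            truth_counts[a.ref_id] += 1
        for cid in truth_counts:
            assert counts[cid] == pytest.approx(truth_counts[cid], rel=0.05)


class TestFpkm:
    def test_reference_arithmetic(self):
        df = fpkm_table({"c": 200}, {"c": 2000}, 2_000_000)
        assert df.loc[0, "fpkm"] == 50.0

    def test_zero_fragments_zero_fpkm(self):
        df = fpkm_table({"c": 0}, {"c": 2000}, 1_000_000)
        assert df.loc[0, "fpkm"] == 0.0

    def test_doubling_library_halves_fpkm_but_not_shares(self):
        counts, lens = {"a": 100, "b": 300}, {"a": 1000, "b": 3000}
        d1 = fpkm_table(counts, lens, 1_000_000).set_index("contig_id")
        d2 = fpkm_table(counts, lens, 2_000_000).set_index("contig_id")
        assert np.allclose(d2["fpkm"], d1["fpkm"] / 2)
        assert np.allclose(d2["relative_share"], d1["relative_share"])

    def test_scale_invariance_counts_and_library(self):
        counts, lens = {"a": 100, "b": 300}, {"a": 1000, "b": 3000}
        d1 = fpkm_table(counts, lens, 1_000_000)
        d2 = fpkm_table({k: 7 * v for k, v in counts.items()}, lens, 7_000_000)
        assert np.allclose(d1["fpkm"], d2["fpkm"])

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            fpkm_table({"c": 1}, {"c": 0}, 1000)

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = rng.integers(1, 8)
            counts = {f"c{i}": int(rng.integers(1, 1000)) for i in range(n)}
            lens = {f"c{i}": int(rng.integers(500, 5000)) for i in range(n)}
            df = fpkm_table(counts, lens, 1_000_000)
            assert df["relative_share"].sum() == pytest.approx(1.0, abs=1e-9)


class TestComposition:
    def _rows(self, shares):
        return pd.DataFrame(
            {"taxon_label": list(shares), "fpkm": list(shares.values())}
        )

    def test_single_taxon(self):
        out = composition_summary(self._rows({"Cystoviridae": 3.0}))
        assert out.loc[0, "taxon"] == "Cystoviridae"
        assert out.loc[0, "share"] == 1.0

    def test_minor_taxon_pooled_by_class(self):
        out = composition_summary(
            self._rows({"A": 50.0, "B": 49.0, "C": 1.0}),
            class_map={"C": "dsRNA"},
        )
        assert set(out["taxon"]) == {"A", "B", "other dsRNA"}
        assert out["share"].sum() == pytest.approx(1.0)

    def test_unclassified_goes_to_others(self):
        out = composition_summary(self._rows({"A": 90.0, "unclassified": 10.0}))
        assert set(out["taxon"]) == {"A", "others"}

    def test_mixture_proportions_recovered(self):
        """Coverage-weighted 3-genome mixture: FPKM shares recover the
        designed proportions within +/-0.05."""
        from fldseg.abundance import fpkm_table
        from fldseg.synthgen import (
            SimConfig, align_reads, segments_as_contigs,
            simulate_flds_reads, simulate_genomes,
        )

        props = {0: 0.5, 1: 0.3, 2: 0.2}
        genomes = simulate_genomes(SimConfig(n_genomes=3, seed=21))
        contigs = segments_as_contigs(genomes)
        all_alns, total_reads = [], 0
        for i, g in enumerate(genomes):
            cfg_i = SimConfig(n_genomes=3, seed=100 + i, coverage=100 * 3 * props[i])
            reads, truth = simulate_flds_reads([g], cfg_i)
            total_reads += len(reads)
            all_alns += align_reads(reads, truth, contigs)
        clusters = [ContigCluster(c.id, [c.id]) for c in contigs]
        lengths = {c.id: len(c.seq) for c in contigs}
        counts = count_fragments(all_alns, clusters, lengths)
        df = fpkm_table(counts, lengths, total_reads)
        df["genome"] = df["contig_id"].str.split("_").str[0]
        got = df.groupby("genome")["relative_share"].sum()
        for i, g in enumerate(genomes):
            assert got[g.genome_id] == pytest.approx(props[i], abs=0.05)
        assert list(got.sort_values(ascending=False).index) == [
            genomes[0].genome_id, genomes[1].genome_id, genomes[2].genome_id
        ]
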