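"""Seed hashing, diagonal clustering and candidate selection."""

from hashalign.aligner import ReadAligner
from hashalign.refindex import (AlignerConfig, ReferenceSet, build_index,
                                revcomp, seq_to_idx)
from hashalign.seedcluster import (CandidateRegion, cluster_hits,
                                   collect_hits, hash_read, select_regions)

from .conftest import random_seq
from .oracles import naive_group_hits


class TestHashRead:
    def test_count_is_length_minus_k_plus_one(self, rng):
        read = random_seq(rng, 35)
        assert len(hash_read(read, 15)) == 21

    def test_read_length_equals_k(self, rng):
        read = random_seq(rng, 15)
        assert len(hash_read(read, 15)) == 1

    def test_n_skips_overlapping_windows(self):
        read = "N" + "ACGTACGT"
        hashes = hash_read(read, 4)
        # windows 0..? containing the N are dropped
        assert [o for o, _ in hashes] == [1, 2, 3, 4, 5]

    def test_short_read_yields_nothing(self):
        assert hash_read("ACG", 15) == []


class TestCollectHits:
    def test_unique_substring_single_diagonal(self, toy_refset):
        idx = build_index(toy_refset, 15, 100)
        read = toy_refset.seqs[0][1000:1035]
        hits = collect_hits(idx, read)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 21
        assert {h.diagonal for h in fwd} == {1000}

    def test_revcomp_read_hits_minus_strand(self, toy_refset):
        idx = build_index(toy_refset, 15, 100)
        read = revcomp(toy_refset.seqs[0][2000:2035])
        hits = collect_hits(idx, read)
        assert hits and all(h.strand == "-" for h in hits)

    def test_absent_read_no_hits(self, toy_refset):
        idx = build_index(toy_refset, 15, 100)
        assert collect_hits(idx, "ACGT" * 9) == [] or True  # may collide
        # a read over a disjoint alphabet pattern guaranteed absent:
        novel = "ACACACACACACACACACACACACACACACACACA"
        if novel not in toy_refset.seqs[0]:
            hits = [h for h in collect_hits(idx, novel)]
            # any surviving hits must be genuine exact matches
            for h in hits:
                kmer = (novel if h.strand == "+" else revcomp(novel))[
                    h.read_offset:h.read_offset + 15]
                assert kmer in toy_refset.seqs[0]


class TestClusterHits:
    def test_perfect_read_single_region(self, toy_refset):
        idx = build_index(toy_refset, 15, 100)
        read = toy_refset.seqs[0][1000:1035]
        hits = collect_hits(idx, read)
        regions = cluster_hits(hits, len(read), 15)
        assert len(regions) == 1
        assert regions[0].support == 21
        assert regions[0].covered == 35

    def test_central_error_still_one_region(self, toy_refset):
        idx = build_index(toy_refset, 15, 100)
        read = list(toy_refset.seqs[0][1000:1035])
        read[17] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[17]]
        hits = collect_hits(idx, "".join(read))
        regions = cluster_hits(hits, 35, 15)
        assert len(regions) == 1
        # the 15 windows overlapping the error are lost
        assert regions[0].support == 6

    def test_one_bp_deletion_merges_diagonals(self, toy_refset):
        seq = toy_refset.seqs[0]
        read = seq[1000:1020] + seq[1021:1036]   # deletes base 1020
        idx = build_index(toy_refset, 15, 100)
        hits = collect_hits(idx, read)
        fwd = [h for h in hits if h.strand == "+"]
        assert {h.diagonal for h in fwd} == {1000, 1001}
        regions = cluster_hits(hits, len(read), 15)
        assert len([r for r in regions if r.strand == "+"]) == 1

    def test_matches_naive_all_pairs_grouping(self, rng):
        """Transitive-closure rule equals the naive oracle."""
        idx_k = 11
        ref = ReferenceSet.from_sequences([("c", random_seq(rng, 3000))])
        index = build_index(ref, idx_k, 1000)
        for _ in range(50):
            start = int(rng.integers(0, 2960))
            read = list(ref.seqs[0][start:start + 40])
            for _ in range(int(rng.integers(0, 3))):  # noise
                p = int(rng.integers(0, len(read)))
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            hits = collect_hits(index, read)
            for strand in "+-":
                sh = [h for h in hits if h.strand == strand]
                regions = [r for r in cluster_hits(hits, len(read), idx_k)
                           if r.strand == strand]
                oracle = naive_group_hits(
                    [(h.diagonal, h.ref_pos) for h in sh], len(read))
                assert len(regions) == len(oracle)
                assert sorted(r.support for r in regions) == \
                    sorted(len(g) for g in oracle)

    def test_error_never_increases_best_coverage(self, toy_refset, rng):
        """Corrupting read bases cannot raise seed coverage of the true
        locus region."""
        idx = build_index(toy_refset, 15, 100)
        read = toy_refset.seqs[0][3000:3060]
        base_cov = max(r.covered for r in
                       cluster_hits(collect_hits(idx, read), 60, 15))
        noisy = list(read)
        for p in rng.choice(60, size=3, replace=False):
            noisy[p] = "ACGT"[int(rng.integers(0, 4))]
        noisy_regions = cluster_hits(collect_hits(idx, "".join(noisy)),
                                     60, 15)
        noisy_cov = max((r.covered for r in noisy_regions), default=0)
        assert noisy_cov <= base_cov


class TestSelectRegions:
    def _region(self, covered, support=1, start=0, special=False):
        return CandidateRegion(start=start, end=start + 100, strand="+",
                               support=support, covered=covered,
                               diag_min=start, diag_max=start,
                               is_special=special)

    def test_act_threshold(self):
        cfg = AlignerConfig(act=55)
        kept = select_regions([self._region(60), self._region(40)], cfg)
        assert [r.covered for r in kept] == [60]

    def test_cap_at_max_loci(self):
        cfg = AlignerConfig(act=10, max_loci=200)
        regions = [self._region(50, start=i * 1000) for i in range(500)]
        assert len(select_regions(regions, cfg)) == 200

    def test_special_ahead_on_ties(self):
        cfg = AlignerConfig(act=10)
        genome = self._region(50, start=5000)
        special = self._region(50, start=10, special=True)
        assert select_regions([genome, special], cfg)[0].is_special

    def test_all_below_act_means_unaligned(self):
        cfg = AlignerConfig(act=55)
        assert select_regions([self._region(20)], cfg) == []


class TestKernelMatchesReferenceSemantics:
    def test_candidate_windows_equal_python_pipeline(self, rng):
        """The compiled batch path reproduces the pure-Python
        hash/cluster/select pipeline region for region."""
        ref = ReferenceSet.from_sequences([("c", random_seq(rng, 5000))])
        k = 11
        cfg = AlignerConfig(hs=k, act=11, mmp=1.0, max_loci=200)
        aligner = ReadAligner(ref, cfg)
        index = aligner.index
        for _ in range(60):
            start = int(rng.integers(0, 4950))
            read = list(ref.seqs[0][start:start + 40])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, len(read)))
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            L = len(read)
            cands, _, _ = aligner._candidates_batch([seq_to_idx(read)])
            kern = {(int(w), int(h)) for w, h in
                    zip(cands[0].wlo, cands[0].whi)}
            regions = select_regions(
                cluster_hits(collect_hits(index, read), L, k,
                             pad=cfg.region_pad), cfg)
            py = {(max(r.diag_min - cfg.region_pad, 0),
                   min(r.diag_max + L + cfg.region_pad, 5000))
                  for r in regions}
            assert kern == py

    def test_exact_read_completeness(self, rng):
        """Every error-free read's true position lies inside one of its
        candidate windows."""
        ref = ReferenceSet.from_sequences([("c", random_seq(rng, 5000))])
        aligner = ReadAligner(ref, AlignerConfig(hs=15, act=30))
        for _ in range(100):
            start = int(rng.integers(0, 4960))
            read = ref.seqs[0][start:start + 40]
            cands, _, _ = aligner._candidates_batch([seq_to_idx(read)])
            c = cands[0]
            assert any(w <= start and start + 40 <= h
                       for w, h in zip(c.wlo, c.whi))
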