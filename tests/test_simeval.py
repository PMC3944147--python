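"""Synthetic genomes, mutation, reads, insertions and the statistics."""

import numpy as np
import pandas as pd
import pytest

from hashalign.simeval import (attach_truth, evaluate_ppv, generate_genome,
                               indel_sensitivity, insert_elements,
                               mei_sensitivity, mutate_genome, roc_points,
                               simulate_reads, simulate_spanning_reads)


class TestGenerateGenome:
    def test_deterministic(self):
        a = generate_genome(20_000, 5)
        b = generate_genome(20_000, 5)
        assert a.seqs[0] == b.seqs[0]

    def test_planted_exact_repeats_found(self):
        rs = generate_genome(50_000, 5, [{"length": 400, "copies": 10,
                                          "divergence": 0.0}])
        seq = rs.seqs[0]
        # locate one copy via a rare 40-mer and count occurrences
        from collections import Counter
        counts = Counter(seq[i:i + 40] for i in range(0, len(seq) - 40))
        assert max(counts.values()) >= 10

    def test_gc_fraction_near_half(self):
        rs = generate_genome(1_000_000, 6)
        seq = rs.seqs[0]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 0.02

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            generate_genome(500, 1)


class TestMutateGenome:
    def test_snp_count_binomial_bound(self):
        rs = generate_genome(1_000_000, 7)
        _, ms = mutate_genome(rs.seqs[0], snp_rate=0.001, seed=8)
        n = len(ms.snps)
        # 3 sigma around Binomial(1e6, 1e-3)
        assert abs(n - 1000) < 3 * np.sqrt(1000) + 5

    def test_exact_indel_counts(self):
        rs = generate_genome(500_000, 7)
        _, ms = mutate_genome(rs.seqs[0], indel_spec={5: 100}, seed=9)
        assert len(ms.indels) == 100
        assert all(ev.length == 5 for ev in ms.indels)
        kinds = {ev.kind for ev in ms.indels}
        assert kinds == {"ins", "del"}

    def test_coordinate_map_roundtrip(self):
        rs = generate_genome(50_000, 7)
        seq = rs.seqs[0]
        hap, ms = mutate_genome(seq, indel_spec={3: 10, 7: 10}, seed=10)
        hidx = np.arange(0, len(hap), 97)
        for h in hidx:
            o = ms.to_original(int(h))
            assert 0 <= o < len(seq)
        # outside events, the haplotype base equals the original base
        ev_hap = {ev.hap_pos for ev in ms.indels}
        for h in range(1000, 2000):
            if all(abs(h - e) > 50 for e in ev_hap):
                assert hap[h] == seq[ms.to_original(h)]

    def test_snp_records_match_sequences(self):
        rs = generate_genome(20_000, 7)
        seq = rs.seqs[0]
        hap, ms = mutate_genome(seq, snp_rate=0.01, seed=11)
        for pos, ref, alt in ms.snps[:50]:
            assert seq[pos] == ref
            assert hap[pos] == alt != ref


class TestSimulateReads:
    def test_zero_error_reads_are_substrings(self):
        rs = generate_genome(50_000, 12)
        sim = simulate_reads(rs.seqs[0], 50, seed=13, error=False)
        from hashalign.refindex import revcomp
        for reads in (sim.reads1, sim.reads2):
            for name, seq, _ in reads:
                assert seq in rs.seqs[0] or revcomp(seq) in rs.seqs[0]

    def test_truth_matches_haplotype_placement(self):
        rs = generate_genome(50_000, 12)
        sim = simulate_reads(rs.seqs[0], 100, seed=14, error=False)
        from hashalign.refindex import revcomp
        g = rs.seqs[0]
        for (name, seq, _), row in zip(sim.reads1,
                                       sim.truth[sim.truth.mate == 0]
                                       .itertuples()):
            fwd = seq if row.strand == "+" else revcomp(seq)
            assert g[row.start:row.start + 100] == fwd

    def test_error_rate_within_binomial_bound(self):
        rs = generate_genome(100_000, 12)
        g = rs.seqs[0]
        sim = simulate_reads(g, 2000, seed=15)
        mism = total = 0
        for (name, seq, _), row in zip(sim.reads1,
                                       sim.truth[sim.truth.mate == 0]
                                       .itertuples()):
            from hashalign.refindex import revcomp
            fwd = seq if row.strand == "+" else revcomp(seq)
            ref = g[row.start:row.start + 100]
            mism += sum(a != b for a, b in zip(fwd, ref))
            total += 100
        # linear error ramp averages (0.001 + 0.01) / 2
        expected = 0.0055
        assert abs(mism / total - expected) < 0.002

    def test_seed_reproducible(self):
        rs = generate_genome(50_000, 12)
        a = simulate_reads(rs.seqs[0], 50, seed=16)
        b = simulate_reads(rs.seqs[0], 50, seed=16)
        assert [r[1] for r in a.reads1] == [r[1] for r in b.reads1]
        assert a.truth.equals(b.truth)

    def test_spanning_reads_cover_events_with_flank(self):
        rs = generate_genome(200_000, 12)
        hap, ms = mutate_genome(rs.seqs[0], indel_spec={8: 20}, seed=17)
        sim = simulate_spanning_reads(hap, ms, reads_per_event=4, seed=18)
        spanning = sim.truth[sim.truth.events != ""]
        # one spanning mate per simulated pair, possibly a few more by
        # chance from the partner mate
        assert len(spanning) >= 20 * 4


class TestInsertElements:
    def test_truth_count_and_length(self, rng):
        rs = generate_genome(200_000, 19)
        elements = [("E1", "".join("ACGT"[i] for i in
                                   rng.integers(0, 4, 300)))]
        donor, truth = insert_elements(rs.seqs[0], elements, 50, seed=20)
        assert len(truth) == 50
        assert len(donor) == 200_000 + 50 * 300

    def test_junctions_recoverable_by_string_search(self, rng):
        rs = generate_genome(60_000, 19)
        elt = "".join("ACGT"[i] for i in rng.integers(0, 4, 250))
        donor, truth = insert_elements(rs.seqs[0], [("E", elt)], 5,
                                       seed=21)
        g = rs.seqs[0]
        for row in truth.itertuples():
            # 30 bp of genome flank followed by the element (either
            # orientation) must occur in the donor
            flank = g[row.site - 30:row.site]
            assert flank in donor

    def test_short_element_rejected(self):
        rs = generate_genome(60_000, 19)
        with pytest.raises(ValueError):
            insert_elements(rs.seqs[0], [("E", "ACGT" * 10)], 5, seed=1)


def toy_results():
    """10-record table with hand-computed statistics."""
    df = pd.DataFrame({
        "name": [f"r{i}" for i in range(10)],
        "mate": [0] * 10,
        "mapped": [True] * 9 + [False],
        "ref": ["chr1"] * 10,
        "pos": [100, 200, 300, 400, 515, 600, 700, 800, 900, 0],
        "strand": ["+"] * 10,
        "mapq": [60, 60, 40, 40, 20, 20, 0, 0, 0, -1],
        "cigar": ["100M"] * 10,
    })
    truth = pd.DataFrame({
        "name": [f"r{i}" for i in range(10)],
        "mate": [0] * 10,
        "ref": ["chr1"] * 10,
        # r4 is off by 115 (wrong); r7 off by 30 (wrong); rest correct
        "start": [100, 205, 290, 395, 400, 610, 690, 830, 905, 0],
        "strand": ["+"] * 10,
        "events": [""] * 10,
    })
    return attach_truth(df, truth)


class TestStatistics:
    def test_ppv_hand_computed(self):
        df = toy_results()
        ppv = evaluate_ppv(df, mq_cutoffs=(0, 20, 40, 61))
        # mapped: 9; wrong: r4 (MQ 20) and r7 (MQ 0)
        assert ppv[0] == pytest.approx(100 * 7 / 9)
        assert ppv[20] == pytest.approx(100 * 5 / 6)
        assert ppv[40] == pytest.approx(100.0)
        assert ppv[61] is None

    def test_ppv_all_correct(self):
        df = toy_results()
        df = df[df["correct"] | ~df["mapped"]]
        assert evaluate_ppv(df, (0,))[0] == 100.0

    def test_roc_monotone(self):
        df = toy_results()
        roc = roc_points(df)
        assert list(roc.columns) == ["mq", "mapped", "incorrect"]
        assert (roc.sort_values("mq", ascending=False)["mapped"]
                .is_monotonic_increasing)
        assert (roc.sort_values("mq", ascending=False)["incorrect"]
                .is_monotonic_increasing)
        total = roc[roc.mq == 0]
        assert int(total["mapped"].iloc[0]) == 9
        assert int(total["incorrect"].iloc[0]) == 2

    def test_indel_sensitivity_cigar_containment(self):
        df = pd.DataFrame({
            "name": ["a", "b", "c"],
            "mate": [0, 0, 0],
            "mapped": [True, True, True],
            "ref": ["chr1"] * 3,
            "pos": [100, 100, 100],
            "strand": ["+"] * 3,
            "mapq": [60] * 3,
            # a: deletion of 14 at ref 150; b: deletion misplaced; c: no gap
            "cigar": ["50M14D50M", "30M14D70M", "100M"],
            "correct": [True, True, True],
            "events": ["del:14:150", "del:14:150", "del:14:150"],
        })
        strict = indel_sensitivity(df, "strict")
        assert strict.loc[0, "n_spanning"] == 3
        assert strict.loc[0, "n_correct"] == 1   # only 'a' places the gap
        partial = indel_sensitivity(df, "partial")
        assert partial.loc[0, "n_correct"] == 3
        assert (partial["sensitivity"] >= strict["sensitivity"]).all()

    def test_mei_support_threshold(self, tmp_path):
        cands = pd.DataFrame({"ref": ["chr1"], "pos": [5000],
                              "support": [4]})
        assert mei_sensitivity(cands, [5100]) == 100.0
        assert mei_sensitivity(cands, [9000]) == 0.0
        assert mei_sensitivity(cands, [5100, 9000]) == 50.0
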