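"""SAM/BAM emission, ZA annotation, multi-mapping stream."""

import subprocess

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hashalign.aligner import ReadAligner
from hashalign.pairing import FragmentModel
from hashalign.refindex import AlignerConfig, ReferenceSet, revcomp
from hashalign.samio import (ZaAnnotation, format_za, parse_za,
                             write_multimap, write_primary)

from .conftest import random_seq


class TestZaTag:
    def test_basic_serialization(self):
        ann = ZaAnnotation("chr1", 100, 60, 1, "")
        assert format_za(ann) == "ZA:Z:chr1;100;60;1;"

    def test_special_hit_roundtrip(self):
        ann = ZaAnnotation("AluY", 1, 0, 154, "AluY")
        assert parse_za(format_za(ann)) == ann

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(ref=st.text(alphabet="ACGTchr0123_", min_size=1, max_size=10),
           pos=st.integers(1, 10 ** 9), mq=st.integers(0, 60),
           nloci=st.integers(1, 10 ** 4),
           special=st.sampled_from(["", "AluY", "L1", "SVA_0"]))
    def test_fuzzed_roundtrip(self, ref, pos, mq, nloci, special):
        ann = ZaAnnotation(ref, pos, mq, nloci, special)
        assert parse_za(format_za(ann)) == ann

    def test_malformed_rejected(self):
        with pytest.raises(ValueError):
            parse_za("ZA:Z:chr1;100;60")


@pytest.fixture
def aligned_pairs(rng):
    seq = random_seq(rng, 20_000)
    refset = ReferenceSet.from_sequences([("chr1", seq)])
    aligner = ReadAligner(refset, AlignerConfig())
    r1s, r2s = [], []
    for i in range(30):
        s = 200 + i * 600
        r1s.append((f"p{i}", seq[s:s + 100],
                    np.full(100, 35, np.int16)))
        r2s.append((f"p{i}", revcomp(seq[s + 200:s + 300]),
                    np.full(100, 35, np.int16)))
    # one unalignable pair
    r1s.append(("bad", "ACGT" * 25, np.full(100, 35, np.int16)))
    r2s.append(("bad", "TTTTTTTTTT" * 10, np.full(100, 35, np.int16)))
    pairs = aligner.align_pairs(r1s, r2s,
                                fallback_model=FragmentModel(300, 30))
    return refset, aligner, pairs


class TestWritePrimary:
    def test_proper_pair_flags_and_mate_fields(self, aligned_pairs,
                                               tmp_path):
        refset, _, pairs = aligned_pairs
        out = tmp_path / "out.sam"
        write_primary(pairs, refset, out)
        with pysam.AlignmentFile(out) as fh:
            recs = list(fh)
        by_name = {}
        for r in recs:
            by_name.setdefault(r.query_name, []).append(r)
        for name, (a, b) in by_name.items():
            if name == "bad":
                continue
            assert {a.flag & 0xC0, b.flag & 0xC0} == {0x40, 0x80}
            assert a.is_proper_pair and b.is_proper_pair
            assert a.next_reference_start == b.reference_start
            assert b.next_reference_start == a.reference_start
            assert a.template_length == -b.template_length != 0

    def test_unaligned_read_conventions(self, aligned_pairs, tmp_path):
        refset, _, pairs = aligned_pairs
        out = tmp_path / "out.sam"
        write_primary(pairs, refset, out)
        with pysam.AlignmentFile(out) as fh:
            bad = [r for r in fh if r.query_name == "bad"]
        assert len(bad) == 2
        for r in bad:
            if r.is_unmapped:
                assert r.reference_id == -1
                assert r.cigarstring is None

    def test_za_describes_mate(self, aligned_pairs, tmp_path):
        refset, _, pairs = aligned_pairs
        out = tmp_path / "out.sam"
        write_primary(pairs, refset, out)
        with pysam.AlignmentFile(out) as fh:
            recs = [r for r in fh if r.query_name == "p0"]
        a, b = recs
        za_a = parse_za(a.get_tag("ZA"))
        assert za_a.mate_ref == b.reference_name
        assert za_a.mate_pos == b.reference_start + 1
        assert za_a.mate_nloci >= 1

    def test_external_validator_passes(self, aligned_pairs, tmp_path):
        refset, _, pairs = aligned_pairs
        bam = tmp_path / "out.bam"
        write_primary(pairs, refset, bam)
        res = subprocess.run(["samtools", "quickcheck", "-u", str(bam)],
                             capture_output=True)
        assert res.returncode == 0
        res = subprocess.run(["samtools", "flagstat", str(bam)],
                             capture_output=True, text=True)
        assert "in total" in res.stdout

    def test_unknown_reference_rejected(self, aligned_pairs, tmp_path):
        refset, _, pairs = aligned_pairs
        rogue = pairs[0][0]
        rogue.ref_name = "chrMissing"
        with pytest.raises(ValueError, match="unknown"):
            write_primary([(rogue, pairs[0][1])], refset,
                          tmp_path / "x.sam")


class TestWriteMultimap:
    def test_stripped_records_per_locus(self, rng, tmp_path):
        # a genome carrying 5 copies of a unit: one read, five records
        unit = random_seq(rng, 120)
        spacer = [random_seq(rng, 500) for _ in range(6)]
        seq = spacer[0]
        for i in range(5):
            seq += unit + spacer[i + 1]
        refset = ReferenceSet.from_sequences([("chr1", seq)])
        aligner = ReadAligner(refset, AlignerConfig(act=50))
        read = unit[:100]
        from hashalign.refindex import seq_to_idx
        cands, _, _ = aligner._candidates_batch([seq_to_idx(read)])
        c = cands[0]
        alns = []
        idx_f = seq_to_idx(read)
        idx_r = idx_f[::-1].copy()
        idx_r[idx_r < 4] = 3 - idx_r[idx_r < 4]
        for i in range(len(c)):
            aln = aligner._traceback(c, i, idx_f, idx_r)
            name, local = refset.global_to_local(aln.ref_start)
            alns.append((name, local, aln.strand, aln.cigar_string,
                         aln.score))
        out = tmp_path / "multi.sam"
        write_multimap([(0, alns)], refset, out)
        with pysam.AlignmentFile(out) as fh:
            recs = list(fh)
        assert len(recs) == 5
        assert sum(1 for r in recs if not r.is_secondary) == 1
        assert all(r.query_sequence is None for r in recs)
        assert all(r.mapping_quality == 0 for r in recs if r.is_secondary)
        starts = [(r.reference_id, r.reference_start) for r in recs]
        assert starts == sorted(starts)
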