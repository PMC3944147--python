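"""End-to-end read mapping: seed, cluster, polish, pair, score.

The :class:`ReadAligner` drives the compiled batch kernel over chunks of
reads, producing per-read candidate lists (score-only polish of every
selected region), then resolves pairs against the fragment model,
runs a full traceback only for the placements actually reported, and
finally assigns neural-network mapping qualities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .mapq import MapqNetwork
from .pairing import (STATUS_DISCORDANT, STATUS_NEITHER, STATUS_ONE_END,
                      STATUS_PROPER, STATUS_RESCUED, FragmentModel,
                      ReadCandidates, estimate_fragment_model,
                      observed_fragment, rescue_mate, resolve_pair)
from .refindex import (AlignerConfig, HashIndex, ReferenceSet, build_index,
                       seq_to_idx)
from .swalign import CIGAR_OPS, LocalAlignment, accept_alignment

CHUNK = 2048
FRAG_DEV_CAP = 10.0


@dataclass
class AlnRecord:
    """One reported read placement (or an unaligned read)."""

    name: str
    mate: int | None = None
    seq: str = ""
    quals: np.ndarray | None = None
    mapped: bool = False
    ref_name: str = "*"
    pos: int = 0                  # 0-based, sequence-local
    strand: str = "+"
    cigar: list = field(default_factory=list)
    score: int = 0
    second_score: int = 0
    mismatches: int = 0
    gap_bases: int = 0
    n_loci: int = 0               # accepted candidate loci for this read
    n_hits: int = 0               # seed hash hits (both strands)
    frag_dev: float = 0.0
    pair_tied: bool = False       # several consistent pair combos tied
    mapq: int | None = None
    is_special: bool = False
    special_hit: str = ""         # special-reference name hit, if any
    status: str = STATUS_NEITHER
    read_length: int = 0
    match_reward: int = 10
    entropy: float = 0.0
    # mate bookkeeping for SAM/ZA emission
    mate_ref: str = "*"
    mate_pos: int = 0
    mate_strand: str = "+"
    mate_mapped: bool = False
    tlen: int = 0

    @property
    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.cigar)


def _entropy_from_idx(idx: np.ndarray) -> float:
    counts = np.bincount(idx, minlength=5).astype(float)
    p = counts[counts > 0] / len(idx)
    return float(-(p * np.log2(p)).sum())


class ReadAligner:
    """Hash-cluster aligner over a reference set."""

    def __init__(self, refset: ReferenceSet,
                 config: AlignerConfig | None = None,
                 index: HashIndex | None = None,
                 mapq_net: MapqNetwork | None = None):
        self.refset = refset
        self.config = config or AlignerConfig()
        self.index = index if index is not None else build_index(
            refset, self.config)
        if self.index.k != self.config.hs:
            raise ValueError(
                f"index k={self.index.k} != config hs={self.config.hs}")
        self.mapq_net = mapq_net
        self._bounds = refset.bounds
        self._mask = refset.masks

    # ---------------------------------------------------------- candidates

    def _candidates_batch(self, idx_reads: list[np.ndarray]
                          ) -> tuple[list[ReadCandidates], np.ndarray,
                                     np.ndarray]:
        """Run the batch kernel; returns per-read deduplicated candidate
        lists sorted by score (desc), plus seed-hit and region counts."""
        cfg = self.config
        sc = cfg.scoring
        n = len(idx_reads)
        out_cands: list[ReadCandidates] = [None] * n
        all_hits = np.zeros(n, np.int32)
        all_regs = np.zeros(n, np.int32)
        maxc = cfg.max_loci
        for c0 in range(0, n, CHUNK):
            chunk = idx_reads[c0:c0 + CHUNK]
            R = len(chunk)
            offs = np.zeros(R + 1, np.int64)
            for i, a in enumerate(chunk):
                offs[i + 1] = offs[i] + len(a)
            flat = np.concatenate(chunk) if R else np.zeros(0, np.uint8)
            ncand = np.zeros(R, np.int32)
            nhits = np.zeros(R, np.int32)
            nreg = np.zeros(R, np.int32)
            cp = np.zeros((R, maxc), np.int64)
            ce = np.zeros((R, maxc), np.int64)
            cs = np.zeros((R, maxc), np.int64)
            cst = np.zeros((R, maxc), np.uint8)
            cwlo = np.zeros((R, maxc), np.int64)
            cwhi = np.zeros((R, maxc), np.int64)
            cdlo = np.zeros((R, maxc), np.int64)
            cdhi = np.zeros((R, maxc), np.int64)
            csp = np.zeros((R, maxc), np.uint8)
            _kernels.align_batch(
                flat, offs, self.index.keys, self.index.starts,
                self.index.positions, self._mask, self._bounds,
                self.refset.n_special, self.index.k, self.index.mhp,
                cfg.act, cfg.max_loci, cfg.band, cfg.region_pad,
                sc.match, sc.mismatch, sc.gap_open, sc.gap_extend, cfg.mmp,
                ncand, nhits, nreg, cp, ce, cs, cst, cwlo, cwhi,
                cdlo, cdhi, csp)
            for i in range(R):
                m = int(ncand[i])
                cands = ReadCandidates(
                    pos=cp[i, :m].copy(), end=ce[i, :m].copy(),
                    score=cs[i, :m].copy(), strand=cst[i, :m].copy(),
                    special=csp[i, :m].copy(),
                    seqid=np.searchsorted(self._bounds, cp[i, :m],
                                          side="right") - 1,
                    wlo=cwlo[i, :m].copy(), whi=cwhi[i, :m].copy(),
                    dlo=cdlo[i, :m].copy(), dhi=cdhi[i, :m].copy())
                out_cands[c0 + i] = self._dedup_sort(cands)
                all_hits[c0 + i] = nhits[i]
                all_regs[c0 + i] = nreg[i]
        return out_cands, all_hits, all_regs

    @staticmethod
    def _dedup_sort(c: ReadCandidates) -> ReadCandidates:
        """Merge same-strand candidates with overlapping reference spans
        (adjacent clustered regions can re-discover one locus, e.g. when
        an INDEL splits the seed diagonals by more than one); keep the
        best-scoring representative.  Output sorted by score desc, then
        position asc."""
        m = len(c)
        if m == 0:
            return c
        order = np.lexsort((c.pos, -c.score))
        keep = []
        for i in order:
            dup = False
            for j in keep:
                if (c.strand[i] == c.strand[j]
                        and c.pos[i] < c.end[j] and c.pos[j] < c.end[i]):
                    dup = True
                    break
            if not dup:
                keep.append(int(i))
        k = np.array(keep, int)
        return ReadCandidates(
            pos=c.pos[k], end=c.end[k], score=c.score[k],
            strand=c.strand[k], special=c.special[k], seqid=c.seqid[k],
            wlo=c.wlo[k], whi=c.whi[k], dlo=c.dlo[k], dhi=c.dhi[k])

    # ----------------------------------------------------------- traceback

    def _traceback(self, cands: ReadCandidates, i: int,
                   idx_f: np.ndarray, idx_r: np.ndarray
                   ) -> LocalAlignment | None:
        sc = self.config.scoring
        seq = idx_f if cands.strand[i] == 0 else idx_r
        out = _kernels.sw_traceback(
            seq, self._mask, int(cands.wlo[i]), int(cands.whi[i]),
            int(cands.dlo[i]), int(cands.dhi[i]),
            sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
        score, gstart, ops, lens, n_ops, mism, gaps = out
        aln = LocalAlignment(
            ref_start=int(gstart),
            strand="+" if cands.strand[i] == 0 else "-",
            cigar=[(CIGAR_OPS[int(ops[t])], int(lens[t]))
                   for t in range(n_ops)],
            score=int(score), mismatches=int(mism), gap_bases=int(gaps),
            is_special=bool(cands.special[i]))
        if not accept_alignment(aln, len(idx_f), self.config):
            return None
        return aln

    def _first_accepted(self, cands: ReadCandidates,
                        idx_f: np.ndarray, idx_r: np.ndarray,
                        prefer: int | None = None):
        """Traceback candidates in score order until one passes the
        mismatch ceiling; ``prefer`` tries that index first."""
        order = list(range(len(cands)))
        if prefer is not None and prefer in order:
            order.remove(prefer)
            order.insert(0, prefer)
        for i in order:
            aln = self._traceback(cands, i, idx_f, idx_r)
            if aln is not None:
                return i, aln
        return None, None

    # ------------------------------------------------------------- records

    def _base_record(self, name, mate, seq, quals, idx, cands,
                     n_hits) -> AlnRecord:
        rec = AlnRecord(name=name, mate=mate, seq=seq, quals=quals,
                        read_length=len(idx),
                        match_reward=self.config.scoring.match,
                        n_hits=int(n_hits), n_loci=len(cands),
                        entropy=_entropy_from_idx(idx) if len(idx) else 0.0)
        sp = np.nonzero(cands.special)[0]
        if len(sp):
            rec.special_hit = self.refset.names[int(cands.seqid[sp[0]])]
        return rec

    def _fill_mapped(self, rec: AlnRecord, cands: ReadCandidates,
                     chosen: int | None, aln: LocalAlignment) -> None:
        gpos = aln.ref_start
        ref_name, local = self.refset.global_to_local(gpos)
        rec.mapped = True
        rec.ref_name = ref_name
        rec.pos = local
        rec.strand = aln.strand
        rec.cigar = aln.cigar
        rec.score = aln.score
        rec.mismatches = aln.mismatches
        rec.gap_bases = aln.gap_bases
        rec.is_special = aln.is_special or bool(
            self.refset.is_special[self.refset.names.index(ref_name)])
        if rec.is_special and not rec.special_hit:
            rec.special_hit = ref_name
        others = [int(s) for i2, s in enumerate(cands.score)
                  if chosen is None or i2 != chosen]
        rec.second_score = max(others) if others else 0

    # ------------------------------------------------------------ aligning

    def align_single(self, reads) -> list[AlnRecord]:
        """Align single-end reads: (name, seq) pairs, Read objects or
        plain sequences."""
        names, seqs, quals = _normalise_reads(reads)
        idx = [seq_to_idx(s) for s in seqs]
        cands, nhits, _ = self._candidates_batch(idx)
        records = []
        for i, name in enumerate(names):
            idx_f = idx[i]
            idx_r = _revcomp_idx(idx_f)
            rec = self._base_record(name, None, seqs[i], quals[i], idx_f,
                                    cands[i], nhits[i])
            if len(cands[i]):
                ci, aln = self._first_accepted(cands[i], idx_f, idx_r)
                if aln is not None:
                    self._fill_mapped(rec, cands[i], ci, aln)
                    rec.status = STATUS_ONE_END
            records.append(rec)
        self._assign_mapq(records)
        return records

    def align_pairs(self, reads1, reads2,
                    fragment_model: FragmentModel | None = None,
                    fallback_model: FragmentModel | None = None
                    ) -> list[tuple[AlnRecord, AlnRecord]]:
        """Align mate pairs with fragment-model resolution and rescue.

        When ``fragment_model`` is None it is estimated from uniquely
        both-mapped pairs (median / scaled MAD of observed fragments),
        falling back to ``fallback_model``.
        """
        cfg = self.config
        names1, seqs1, quals1 = _normalise_reads(reads1)
        names2, seqs2, quals2 = _normalise_reads(reads2)
        if len(names1) != len(names2):
            raise ValueError("mate lists differ in length")
        n = len(names1)
        idx1 = [seq_to_idx(s) for s in seqs1]
        idx2 = [seq_to_idx(s) for s in seqs2]
        cands1, hits1, _ = self._candidates_batch(idx1)
        cands2, hits2, _ = self._candidates_batch(idx2)

        model = fragment_model
        if model is None:
            frags = []
            for i in range(n):
                c1, c2 = cands1[i], cands2[i]
                if len(c1) == 1 and len(c2) == 1 and \
                        c1.strand[0] != c2.strand[0] and \
                        c1.seqid[0] == c2.seqid[0]:
                    if c1.strand[0] == 0:
                        f = observed_fragment(c1.pos[0], c1.end[0],
                                              c2.pos[0], c2.end[0])
                        ok = c2.pos[0] >= c1.pos[0]
                    else:
                        f = observed_fragment(c2.pos[0], c2.end[0],
                                              c1.pos[0], c1.end[0])
                        ok = c1.pos[0] >= c2.pos[0]
                    if ok and 0 < f < 100_000:
                        frags.append(f)
            model = estimate_fragment_model(
                frags, fallback=fallback_model,
                multiplier=cfg.rescue_window_sd)

        pairs = []
        for i in range(n):
            pairs.append(self._resolve_one_pair(
                names1[i], seqs1[i], quals1[i], idx1[i], cands1[i], hits1[i],
                names2[i], seqs2[i], quals2[i], idx2[i], cands2[i], hits2[i],
                model))
        self._assign_mapq([r for p in pairs for r in p])
        for r1, r2 in pairs:
            _cross_fill_mates(r1, r2)
        return pairs

    def _resolve_one_pair(self, name1, seq1, q1, idx1, c1, h1,
                          name2, seq2, q2, idx2, c2, h2,
                          model: FragmentModel):
        cfg = self.config
        idx1r = _revcomp_idx(idx1)
        idx2r = _revcomp_idx(idx2)
        rec1 = self._base_record(name1, 0, seq1, q1, idx1, c1, h1)
        rec2 = self._base_record(name2, 1, seq2, q2, idx2, c2, h2)

        combo = resolve_pair(c1, c2, model) if len(c1) and len(c2) else None
        if combo is not None:
            i1, i2, frag, tied = combo
            ci1, aln1 = self._first_accepted(c1, idx1, idx1r, prefer=i1)
            ci2, aln2 = self._first_accepted(c2, idx2, idx2r, prefer=i2)
            if aln1 is not None and aln2 is not None:
                self._fill_mapped(rec1, c1, ci1, aln1)
                self._fill_mapped(rec2, c2, ci2, aln2)
                rec1.status = rec2.status = STATUS_PROPER
                rec1.pair_tied = rec2.pair_tied = bool(tied)
                dev = abs(frag - model.mean) / max(model.spread, 1.0)
                rec1.frag_dev = rec2.frag_dev = min(dev, FRAG_DEV_CAP)
                return rec1, rec2

        # no consistent combination: best individual placements
        ci1 = aln1 = ci2 = aln2 = None
        if len(c1):
            ci1, aln1 = self._first_accepted(c1, idx1, idx1r)
        if len(c2):
            ci2, aln2 = self._first_accepted(c2, idx2, idx2r)

        # rescue: anchor each aligned mate, search for its partner
        best_rescue = None  # (summed score, which_mate_rescued, aln, frag)
        for anchor_aln, anchor_c, anchor_i, mate_idx, mate_idx_r, which in (
                (aln1, c1, ci1, idx2, idx2r, 2),
                (aln2, c2, ci2, idx1, idx1r, 1)):
            if anchor_aln is None:
                continue
            # only unambiguous genome anchors guide a rescue
            if anchor_aln.is_special:
                continue
            gpos = anchor_aln.ref_start
            si = self.refset.seq_index_of(gpos)
            res = rescue_mate(
                (gpos, anchor_aln.ref_end,
                 0 if anchor_aln.strand == "+" else 1),
                mate_idx, mate_idx_r, model, self._mask,
                int(self._bounds[si]), int(self._bounds[si + 1]), cfg)
            if res is None:
                continue
            r_aln, frag = res
            total = anchor_aln.score + r_aln.score
            if best_rescue is None or total > best_rescue[0]:
                best_rescue = (total, which, r_aln, frag)

        if best_rescue is not None:
            _, which, r_aln, frag = best_rescue
            if which == 2:
                if aln1 is not None:
                    self._fill_mapped(rec1, c1, ci1, aln1)
                self._fill_rescued(rec2, c2, r_aln)
            else:
                if aln2 is not None:
                    self._fill_mapped(rec2, c2, ci2, aln2)
                self._fill_rescued(rec1, c1, r_aln)
            rec1.status = rec2.status = STATUS_RESCUED
            anchor_rec = rec1 if which == 2 else rec2
            tied = (anchor_rec.mapped
                    and anchor_rec.second_score >= anchor_rec.score)
            rec1.pair_tied = rec2.pair_tied = bool(tied)
            dev = abs(frag - model.mean) / max(model.spread, 1.0)
            rec1.frag_dev = rec2.frag_dev = min(dev, FRAG_DEV_CAP)
            return rec1, rec2

        if aln1 is not None:
            self._fill_mapped(rec1, c1, ci1, aln1)
        if aln2 is not None:
            self._fill_mapped(rec2, c2, ci2, aln2)
        if aln1 is not None and aln2 is not None:
            rec1.status = rec2.status = STATUS_DISCORDANT
            rec1.frag_dev = rec2.frag_dev = FRAG_DEV_CAP
        elif aln1 is not None or aln2 is not None:
            rec1.status = rec2.status = STATUS_ONE_END
        else:
            rec1.status = rec2.status = STATUS_NEITHER
        return rec1, rec2

    def _fill_rescued(self, rec: AlnRecord, cands: ReadCandidates,
                      aln: LocalAlignment) -> None:
        self._fill_mapped(rec, cands, None, aln)
        # a rescued mate had no accepted candidate of its own; its locus
        # count includes the rescued placement
        rec.n_loci = max(rec.n_loci, 1)

    # --------------------------------------------------------------- mapq

    def _assign_mapq(self, records: list[AlnRecord]) -> None:
        if self.mapq_net is None:
            return
        mapped = [r for r in records if r.mapped]
        if not mapped:
            return
        X = np.zeros((len(mapped), 6), float)
        for t, r in enumerate(mapped):
            denom = r.read_length * r.match_reward
            X[t, 0] = min(max(r.score / denom, 0.0), 1.0)
            X[t, 1] = min(max(r.second_score / denom, 0.0), 1.0)
            X[t, 2] = r.entropy
            X[t, 3] = r.n_loci
            X[t, 4] = r.n_hits
            X[t, 5] = r.frag_dev
        # a fragment-consistent unambiguous pair exempts a read whose own
        # loci tie: the pairing evidence disambiguates the placement
        exempt = np.array([
            r.status in (STATUS_PROPER, STATUS_RESCUED) and not r.pair_tied
            for r in mapped], bool)
        q = self.mapq_net.predict_q(X, tie_exempt=exempt)
        for t, r in enumerate(mapped):
            r.mapq = int(q[t])


def _revcomp_idx(idx: np.ndarray) -> np.ndarray:
    out = idx[::-1].copy()
    sel = out < 4
    out[sel] = 3 - out[sel]
    return out


def _normalise_reads(reads):
    names, seqs, quals = [], [], []
    for i, r in enumerate(reads):
        if isinstance(r, str):
            names.append(f"read{i}")
            seqs.append(r.upper())
            quals.append(None)
        elif isinstance(r, tuple):
            names.append(r[0])
            seqs.append(r[1].upper())
            quals.append(r[2] if len(r) > 2 else None)
        else:  # Read-like object
            names.append(r.name)
            seqs.append(r.seq.upper())
            quals.append(getattr(r, "quals", None))
    return names, seqs, quals


def _cross_fill_mates(r1: AlnRecord, r2: AlnRecord) -> None:
    for a, b in ((r1, r2), (r2, r1)):
        a.mate_mapped = b.mapped
        a.mate_ref = b.ref_name
        a.mate_pos = b.pos
        a.mate_strand = b.strand
    if r1.mapped and r2.mapped and r1.ref_name == r2.ref_name:
        lo = min(r1.pos, r2.pos)
        hi = max(r1.pos + sum(n for op, n in r1.cigar if op in "MD"),
                 r2.pos + sum(n for op, n in r2.cigar if op in "MD"))
        t = hi - lo
        r1.tlen = t if r1.pos <= r2.pos else -t
        r2.tlen = -r1.tlen


def records_to_frame(records) -> pd.DataFrame:
    """Flatten alignment records into a DataFrame for evaluation."""
    flat = []
    for r in records:
        if isinstance(r, tuple):
            flat.extend(r)
        else:
            flat.append(r)
    return pd.DataFrame({
        "name": [r.name for r in flat],
        "mate": [-1 if r.mate is None else r.mate for r in flat],
        "mapped": [r.mapped for r in flat],
        "ref": [r.ref_name for r in flat],
        "pos": [r.pos for r in flat],
        "strand": [r.strand for r in flat],
        "mapq": [-1 if r.mapq is None else r.mapq for r in flat],
        "score": [r.score for r in flat],
        "second_score": [r.second_score for r in flat],
        "n_loci": [r.n_loci for r in flat],
        "status": [r.status for r in flat],
        "special_hit": [r.special_hit for r in flat],
        "cigar": [r.cigar_string for r in flat],
    })
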