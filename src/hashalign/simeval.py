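"""Synthetic data generation and accuracy evaluation.

The generator emulates the study design used to benchmark short-read
mappers: a random genome with planted repeat families, a haplotype
carrying SNPs and 1-14 bp INDELs with full coordinate tracking, paired
Illumina-like reads with a position-dependent substitution-error profile,
and donor genomes with planted mobile-element insertions.  Every read
carries a truth record (reference, 0-based start on *original* genome
coordinates, strand, spanned INDEL events) in a tab-separated sidecar
rather than encoded in read names.

The evaluation half computes the headline statistics of such benchmarks:
positive predictive value by mapping-quality cutoff (20 bp tolerance
window), ROC points, INDEL sensitivity under a strict (position correct
AND variant present in the CIGAR) and a relaxed (position correct)
criterion, mapping-quality calibration, and recovery of planted element
insertions from ZA-tagged anchor pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mapq import CORRECTNESS_TOLERANCE_BP
from .refindex import BASES, ReferenceSet, seq_to_idx

MIN_SPAN_FLANK = 10   # bases required on both sides for a read to "span"
DEFAULT_FRAGMENT_MEAN = 300.0
DEFAULT_FRAGMENT_SD = 30.0
DEFAULT_READ_LEN = 100
#: Illumina-like substitution-error profile: linear ramp along the read
ERROR_RATE_START = 0.001
ERROR_RATE_END = 0.01


def _idx_to_seq(idx: np.ndarray) -> str:
    return "".join("ACGTN"[int(b)] for b in idx)


# --------------------------------------------------------------- genomes

def generate_genome(length: int, seed: int, repeat_spec=None,
                    name: str = "chr1") -> ReferenceSet:
    """Uniform random genome with optional planted repeat families.

    ``repeat_spec`` is a list of dicts with keys ``length``, ``copies``
    and ``divergence`` (per-base substitution rate applied independently
    to each copy).  Copies are interspersed at non-overlapping uniform
    positions.  Deterministic for a fixed seed.
    """
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, 4, size=length).astype(np.uint8)
    if repeat_spec:
        taken: list[tuple[int, int]] = []
        for fam in repeat_spec:
            flen = int(fam["length"])
            copies = int(fam["copies"])
            div = float(fam.get("divergence", 0.0))
            consensus = rng.integers(0, 4, size=flen).astype(np.uint8)
            placed = 0
            attempts = 0
            while placed < copies and attempts < 100 * copies:
                attempts += 1
                p = int(rng.integers(0, length - flen))
                if any(p < e and p + flen > s for s, e in taken):
                    continue
                copy = consensus.copy()
                if div > 0:
                    mut = rng.random(flen) < div
                    copy[mut] = (copy[mut] + rng.integers(
                        1, 4, size=int(mut.sum()))) % 4
                idx[p:p + flen] = copy
                taken.append((p, p + flen))
                placed += 1
    return ReferenceSet.from_sequences([(name, _idx_to_seq(idx))])


@dataclass
class IndelEvent:
    kind: str       # 'ins' or 'del'
    length: int
    orig_pos: int   # original-genome coordinate of the event
    hap_pos: int    # haplotype coordinate (junction / inserted-run start)


@dataclass
class MutationSet:
    """SNPs and INDELs applied to a genome, with the coordinate map."""

    snps: list = field(default_factory=list)      # (orig_pos, ref, alt)
    indels: list = field(default_factory=list)    # IndelEvent
    # piecewise map: haplotype segment starts -> original starts
    hap_starts: np.ndarray = field(
        default_factory=lambda: np.zeros(1, np.int64))
    orig_starts: np.ndarray = field(
        default_factory=lambda: np.zeros(1, np.int64))
    seg_orig_len: np.ndarray = field(
        default_factory=lambda: np.zeros(1, np.int64))

    def to_original(self, hap_pos: int) -> int:
        """Original coordinate of a haplotype position (positions inside
        an inserted run map to the insertion point)."""
        j = int(np.searchsorted(self.hap_starts, hap_pos, "right")) - 1
        off = hap_pos - int(self.hap_starts[j])
        off = min(off, int(self.seg_orig_len[j]))
        return int(self.orig_starts[j]) + off


def mutate_genome(seq: str, snp_rate: float = 0.0, indel_spec=None,
                  seed: int = 0, min_separation: int = 200
                  ) -> tuple[str, MutationSet]:
    """Apply SNPs (Binomial(L, rate) count) and exact INDEL counts.

    ``indel_spec`` maps event length -> count; each length's events are
    split evenly between insertions and deletions.  Events keep at least
    ``min_separation`` bases apart (overlapping draws are re-sampled) so
    no read spans two events.
    """
    rng = np.random.default_rng(seed)
    idx = seq_to_idx(seq).copy()
    L = len(idx)
    ms = MutationSet()
    if snp_rate > 0:
        n_snp = int(rng.binomial(L, snp_rate))
        pos = rng.choice(L, size=min(n_snp, L), replace=False)
        for p in np.sort(pos):
            if idx[p] > 3:
                continue
            alt = (int(idx[p]) + int(rng.integers(1, 4))) % 4
            ms.snps.append((int(p), BASES[int(idx[p])], BASES[alt]))
            idx[p] = alt

    events = []
    if indel_spec:
        occupied: list[int] = []
        for length in sorted(indel_spec):
            count = int(indel_spec[length])
            for e in range(count):
                kind = "ins" if e % 2 == 0 else "del"
                for _ in range(10_000):
                    p = int(rng.integers(min_separation,
                                         L - min_separation - length))
                    if all(abs(p - q) >= min_separation + length
                           for q in occupied):
                        occupied.append(p)
                        events.append((p, int(length), kind))
                        break
                else:
                    raise RuntimeError("could not place INDEL events")
        events.sort()

    # build the haplotype and the piecewise coordinate map
    pieces = []
    hap_starts = [0]
    orig_starts = [0]
    seg_orig_len = []
    cur_orig = 0
    cur_hap = 0
    for p, length, kind in events:
        seg = idx[cur_orig:p]
        pieces.append(seg)
        cur_hap += len(seg)
        seg_orig_len.append(len(seg))
        if kind == "del":
            ms.indels.append(IndelEvent("del", length, p, cur_hap))
            cur_orig = p + length
        else:
            ins = rng.integers(0, 4, size=length).astype(np.uint8)
            pieces.append(ins)
            ms.indels.append(IndelEvent("ins", length, p, cur_hap))
            hap_starts.append(cur_hap)
            orig_starts.append(p)
            seg_orig_len.append(0)   # inserted bases collapse to the point
            cur_hap += length
            hap_starts.append(cur_hap)
            orig_starts.append(p)
            cur_orig = p
            continue
        hap_starts.append(cur_hap)
        orig_starts.append(cur_orig)
    pieces.append(idx[cur_orig:])
    seg_orig_len.append(L - cur_orig)
    ms.hap_starts = np.array(hap_starts, np.int64)
    ms.orig_starts = np.array(orig_starts, np.int64)
    ms.seg_orig_len = np.array(seg_orig_len, np.int64)
    hap = np.concatenate(pieces) if pieces else idx
    return _idx_to_seq(hap), ms


# ----------------------------------------------------------------- reads

def _error_profile(read_len: int) -> tuple[np.ndarray, np.ndarray]:
    rates = np.linspace(ERROR_RATE_START, ERROR_RATE_END, read_len)
    quals = np.round(-10 * np.log10(rates)).astype(np.int16)
    return rates, quals


@dataclass
class SimulatedReads:
    """Paired reads plus the truth sidecar."""

    reads1: list          # (name, seq, quals)
    reads2: list
    truth: pd.DataFrame   # name, mate, ref, start, strand, events


def _spanned_events(mutset: MutationSet | None, s: int, e: int,
                    flank: int = MIN_SPAN_FLANK) -> str:
    if mutset is None or not mutset.indels:
        return ""
    out = []
    for ev in mutset.indels:
        if ev.kind == "del":
            if s + flank <= ev.hap_pos <= e - flank:
                out.append(f"del:{ev.length}:{ev.orig_pos}")
        else:
            if s + flank <= ev.hap_pos and ev.hap_pos + ev.length <= e - flank:
                out.append(f"ins:{ev.length}:{ev.orig_pos}")
    return "|".join(out)


def _apply_errors(read: np.ndarray, rates: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    hit = rng.random(len(read)) < rates
    if hit.any():
        read = read.copy()
        sel = hit & (read < 4)
        read[sel] = (read[sel] + rng.integers(
            1, 4, size=int(sel.sum())).astype(np.uint8)) % 4
    return read


def simulate_reads(hap: str, n_pairs: int, seed: int,
                   read_len: int = DEFAULT_READ_LEN,
                   fragment_mean: float = DEFAULT_FRAGMENT_MEAN,
                   fragment_sd: float = DEFAULT_FRAGMENT_SD,
                   mutset: MutationSet | None = None,
                   ref_name: str = "chr1", error: bool = True,
                   name_prefix: str = "sim") -> SimulatedReads:
    """Paired forward-reverse reads from a haplotype.

    Fragments draw from N(mean, sd) (clipped to the read length); the
    fragment strand is random, so either mate can be the forward read.
    Truth starts are reported on original coordinates via ``mutset``
    (identity when None).  Substitution errors follow the linear
    quality-dependent profile; qualities are the Phred transform of the
    per-position error rate.
    """
    rng = np.random.default_rng(seed)
    hidx = seq_to_idx(hap)
    H = len(hidx)
    rates, quals = _error_profile(read_len)
    no_err = np.zeros(read_len)
    qconst = quals if error else np.full(read_len, 40, np.int16)
    frags = np.maximum(np.round(rng.normal(
        fragment_mean, fragment_sd, n_pairs)).astype(int), read_len)
    frags = np.minimum(frags, H)
    starts = (rng.random(n_pairs) * (H - frags + 1)).astype(np.int64)
    flips = rng.random(n_pairs) < 0.5
    reads1, reads2, rows = [], [], []
    for i in range(n_pairs):
        s, f = int(starts[i]), int(frags[i])
        name = f"{name_prefix}{i}"
        left = (s, s + read_len, "+")
        right = (s + f - read_len, s + f, "-")
        mates = (left, right) if not flips[i] else (right, left)
        for mi, (ms_, me_, strand) in enumerate(mates):
            raw = hidx[ms_:me_]
            if strand == "-":
                raw = raw[::-1].copy()
                sel = raw < 4
                raw[sel] = 3 - raw[sel]
            obs = _apply_errors(raw, rates if error else no_err, rng)
            rec = (name, _idx_to_seq(obs), qconst.copy())
            (reads1 if mi == 0 else reads2).append(rec)
            start = mutset.to_original(ms_) if mutset else ms_
            rows.append((name, mi, ref_name, start, strand,
                         _spanned_events(mutset, ms_, me_)))
    truth = pd.DataFrame(rows, columns=["name", "mate", "ref", "start",
                                        "strand", "events"])
    return SimulatedReads(reads1, reads2, truth)


def simulate_spanning_reads(hap: str, mutset: MutationSet,
                            reads_per_event: int, seed: int,
                            read_len: int = DEFAULT_READ_LEN,
                            fragment_mean: float = DEFAULT_FRAGMENT_MEAN,
                            fragment_sd: float = DEFAULT_FRAGMENT_SD,
                            flank: int = MIN_SPAN_FLANK,
                            ref_name: str = "chr1",
                            name_prefix: str = "span") -> SimulatedReads:
    """Paired reads where one mate spans each INDEL event.

    The spanning mate covers the event with at least ``flank`` bases on
    both sides (a local aligner needs some anchor sequence on each side
    of a gap to place it); its partner sits a fragment away on either
    side at random.
    """
    rng = np.random.default_rng(seed)
    hidx = seq_to_idx(hap)
    H = len(hidx)
    rates, quals = _error_profile(read_len)
    reads1, reads2, rows = [], [], []
    ctr = 0
    for ev in mutset.indels:
        if ev.kind == "del":
            lo = ev.hap_pos - (read_len - flank)
            hi = ev.hap_pos - flank
        else:
            lo = ev.hap_pos + ev.length + flank - read_len
            hi = ev.hap_pos - flank
        lo = max(lo, 0)
        hi = min(hi, H - read_len)
        if hi < lo:
            continue
        for _ in range(reads_per_event):
            s = int(rng.integers(lo, hi + 1))
            frag = max(int(round(rng.normal(fragment_mean, fragment_sd))),
                       read_len)
            span_strand = "+" if rng.random() < 0.5 else "-"
            # partner on the side that keeps FR orientation
            if span_strand == "+":
                ps = min(s + frag - read_len, H - read_len)
                partner = (ps, "-")
            else:
                ps = max(s + read_len - frag, 0)
                partner = (ps, "+")
            span_first = rng.random() < 0.5
            name = f"{name_prefix}{ctr}"
            ctr += 1
            mates = [(s, span_strand), partner]
            if not span_first:
                mates.reverse()
            for mi, (ms_, strand) in enumerate(mates):
                raw = hidx[ms_:ms_ + read_len]
                if strand == "-":
                    raw = raw[::-1].copy()
                    sel = raw < 4
                    raw[sel] = 3 - raw[sel]
                obs = _apply_errors(raw, rates, rng)
                rec = (name, _idx_to_seq(obs), quals.copy())
                (reads1 if mi == 0 else reads2).append(rec)
                rows.append((name, mi, ref_name, mutset.to_original(ms_),
                             strand,
                             _spanned_events(mutset, ms_, ms_ + read_len,
                                             flank)))
    truth = pd.DataFrame(rows, columns=["name", "mate", "ref", "start",
                                        "strand", "events"])
    return SimulatedReads(reads1, reads2, truth)


def insert_elements(seq: str, elements, n_sites: int, seed: int,
                    min_separation: int = 2000):
    """Plant element insertions into a genome.

    ``elements`` is a list of (name, sequence); each site receives one
    randomly chosen element in random orientation.  Returns (donor
    sequence, truth DataFrame with original-coordinate sites).  Site
    draws colliding within ``min_separation`` are re-drawn.
    """
    from .refindex import revcomp
    for name, es in elements:
        if len(es) < 200:
            raise ValueError(f"element {name} shorter than 200 bp")
    rng = np.random.default_rng(seed)
    L = len(seq)
    sites: list[int] = []
    for _ in range(n_sites):
        for _ in range(10_000):
            p = int(rng.integers(min_separation, L - min_separation))
            if all(abs(p - q) >= min_separation for q in sites):
                sites.append(p)
                break
        else:
            raise RuntimeError("could not place element insertions")
    rows = []
    parts = []
    cur = 0
    for p in sorted(sites):
        ei = int(rng.integers(0, len(elements)))
        name, es = elements[ei]
        orient = "+" if rng.random() < 0.5 else "-"
        parts.append(seq[cur:p])
        parts.append(es if orient == "+" else revcomp(es))
        rows.append((p, name, orient))
        cur = p
    parts.append(seq[cur:])
    truth = pd.DataFrame(rows, columns=["site", "element", "orientation"])
    return "".join(parts), truth


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for name, seq, quals in reads:
            q = "".join(chr(int(x) + 33) for x in quals)
            fh.write(f"@{name}\n{seq}\n+\n{q}\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


# ------------------------------------------------------------ evaluation

def attach_truth(results: pd.DataFrame, truth: pd.DataFrame,
                 tolerance: int = CORRECTNESS_TOLERANCE_BP) -> pd.DataFrame:
    """Join alignment results to the truth sidecar and label correctness
    (same reference, same strand, start within the tolerance window)."""
    df = results.merge(truth, on=["name", "mate"], how="left",
                       suffixes=("", "_true"))
    if df["start"].isna().any():
        raise ValueError("alignments without a truth record")
    df["correct"] = (df["mapped"]
                     & (df["ref"] == df["ref_true"])
                     & (df["strand"] == df["strand_true"])
                     & ((df["pos"] - df["start"]).abs() <= tolerance))
    return df


def evaluate_ppv(df: pd.DataFrame, mq_cutoffs=(0, 10, 20, 30)) -> dict:
    """PPV (% correct among mapped) per mapping-quality cutoff.

    A cutoff with no mapped records maps to None (undefined).
    """
    out = {}
    mapped = df[df["mapped"]]
    for c in mq_cutoffs:
        sel = mapped[mapped["mapq"] >= c]
        out[c] = (100.0 * sel["correct"].mean()) if len(sel) else None
    return out


def roc_points(df: pd.DataFrame) -> pd.DataFrame:
    """(total mapped, incorrectly mapped) per descending MQ threshold."""
    mapped = df[df["mapped"]]
    rows = []
    for t in sorted(mapped["mapq"].unique(), reverse=True):
        sel = mapped[mapped["mapq"] >= t]
        rows.append((int(t), len(sel), int((~sel["correct"]).sum())))
    return pd.DataFrame(rows, columns=["mq", "mapped", "incorrect"])


def _cigar_events(cigar: str, ref_start: int):
    """INDEL ops of a CIGAR string as (kind, length, ref_pos)."""
    out = []
    num = ""
    pos = ref_start
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "M=X":
            pos += n
        elif ch == "D":
            out.append(("del", n, pos))
            pos += n
        elif ch == "I":
            out.append(("ins", n, pos))
        elif ch in "NS":
            if ch == "N":
                pos += n
    return out


def indel_sensitivity(df: pd.DataFrame, criterion: str = "strict",
                      tolerance: int = CORRECTNESS_TOLERANCE_BP,
                      event_tolerance: int = 2) -> pd.DataFrame:
    """Per-length INDEL mapping sensitivity over spanning reads.

    ``df`` must come from :func:`attach_truth` with truth ``events``.
    strict: position correct AND the CIGAR places an INDEL of the true
    length and kind within +/- ``event_tolerance`` bp of the true site.
    partial: position correct (entirely or partially mapped there),
    regardless of variant containment.
    """
    if criterion not in ("strict", "partial"):
        raise ValueError(f"unknown criterion {criterion!r}")
    per_len: dict[tuple[str, int], list[int]] = {}
    for row in df.itertuples(index=False):
        ev_str = getattr(row, "events", "")
        if not isinstance(ev_str, str) or not ev_str:
            continue
        cig_events = None
        for ev in ev_str.split("|"):
            kind, ln, opos = ev.split(":")
            ln, opos = int(ln), int(opos)
            ok = bool(row.correct)
            if ok and criterion == "strict":
                if cig_events is None:
                    cig_events = _cigar_events(row.cigar, row.pos)
                ok = any(k == kind and n == ln
                         and abs(p - opos) <= event_tolerance
                         for k, n, p in cig_events)
            per_len.setdefault((kind, ln), []).append(int(ok))
    rows = []
    for (kind, ln), flags in sorted(per_len.items()):
        rows.append((kind, ln, len(flags), int(np.sum(flags)),
                     100.0 * np.mean(flags)))
    return pd.DataFrame(rows, columns=["kind", "length", "n_spanning",
                                       "n_correct", "sensitivity"])


def mei_candidates(bam_path, mapq_min: int = 20, window: int = 500,
                   min_support: int = 2) -> pd.DataFrame:
    """Candidate element-insertion loci from ZA-tagged anchor pairs.

    Anchors are confidently mapped genome reads (MQ >= ``mapq_min``, not
    themselves on a special reference) whose ZA annotation reports a
    special-reference mate.  Anchor positions cluster within ``window``
    bp; clusters with at least ``min_support`` pairs become candidates
    located at the median anchor position.
    """
    import pysam

    from .samio import parse_za
    anchors = []
    with pysam.AlignmentFile(str(bam_path), "rb"
                             if str(bam_path).endswith(".bam") else "r"
                             ) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            if seg.mapping_quality < mapq_min or seg.mapping_quality == 255:
                continue
            if not seg.has_tag("ZA"):
                continue
            ann = parse_za(seg.get_tag("ZA"))
            if not ann.special:
                continue
            anchors.append((seg.reference_name,
                            seg.reference_end if not seg.is_reverse
                            else seg.reference_start))
    rows = []
    by_ref: dict[str, list[int]] = {}
    for ref, p in anchors:
        by_ref.setdefault(ref, []).append(p)
    for ref, ps in by_ref.items():
        ps.sort()
        cluster = [ps[0]]
        for p in ps[1:] + [None]:
            if p is not None and p - cluster[-1] <= window:
                cluster.append(p)
            else:
                if len(cluster) >= min_support:
                    rows.append((ref, int(np.median(cluster)),
                                 len(cluster)))
                cluster = [p] if p is not None else []
    return pd.DataFrame(rows, columns=["ref", "pos", "support"])


def mei_sensitivity(candidates: pd.DataFrame, truth_sites,
                    tolerance: int = 500) -> float:
    """Fraction of planted insertion sites recovered by a candidate."""
    sites = list(truth_sites)
    if not sites:
        return float("nan")
    hit = 0
    pos = candidates["pos"].to_numpy() if len(candidates) else np.zeros(0)
    for s in sites:
        if len(pos) and np.min(np.abs(pos - s)) <= tolerance:
            hit += 1
    return 100.0 * hit / len(sites)
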