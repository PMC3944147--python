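"""Read parsing (FASTQ/FASTA), mate pairing and SOLiD colorspace support.

Colorspace reads encode di-base transitions rather than bases: each color
symbol 0-3 encodes the relation between two adjacent bases, anchored by a
known primer base.  Alignment happens in color space against a
color-encoded reference; afterwards the alignment is decoded back to
basespace against the reference window, and per-base qualities take the
minimum of the two color qualities overlapping each nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import zip_longest

import numpy as np

from .refindex import BASES, BASE_TO_IDX
from .swalign import LocalAlignment

PHRED_OFFSET = 33
MAX_QUAL = 93

# di-base transition matrix: color = _COLOR[base1][base2]
_COLOR = {
    b1: {b2: (BASE_TO_IDX[b1] ^ BASE_TO_IDX[b2]) for b2 in BASES}
    for b1 in BASES
}
# the XOR trick reproduces the standard code: identical pairs -> 0,
# A<->C, G<->T -> 1, A<->G, C<->T -> 2, A<->T, C<->G -> 3
_DECODE = {
    b1: {c: next(b2 for b2 in BASES
                 if (BASE_TO_IDX[b1] ^ BASE_TO_IDX[b2]) == c)
         for c in range(4)}
    for b1 in BASES
}


@dataclass
class Read:
    """A sequencing read in basespace or colorspace."""

    name: str
    seq: str                       # bases, or color symbols '0123'
    quals: np.ndarray              # Phred integers, one per seq symbol
    mate_index: int | None = None  # 0, 1 or None for single-end
    space: str = "basespace"
    primer: str | None = None      # leading base, colorspace only

    def __post_init__(self):
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.quals) != len(self.seq):
            raise ValueError(
                f"read {self.name}: {len(self.seq)} bases but "
                f"{len(self.quals)} quality values")
        if self.quals.size and (self.quals.min() < 0
                                or self.quals.max() > MAX_QUAL):
            raise ValueError(f"read {self.name}: qualities outside [0, 93]")
        if self.space == "colorspace":
            if self.primer is None:
                raise ValueError(f"colorspace read {self.name} lacks primer")
            if set(self.seq) - set("0123"):
                raise ValueError(
                    f"colorspace read {self.name} has non-color symbols")

    def __len__(self) -> int:
        return len(self.seq)


def _decode_quals(qual_line: str, name: str, offset: int = PHRED_OFFSET
                  ) -> np.ndarray:
    q = np.frombuffer(qual_line.encode("ascii"), np.uint8).astype(np.int16)
    q -= offset
    if q.size and (q.min() < 0 or q.max() > MAX_QUAL):
        raise ValueError(f"record {name}: quality characters outside "
                         f"Phred+{offset} range")
    return q


def read_fastq(stream, mate_index=None, phred_offset=PHRED_OFFSET):
    """Iterate Read records from a FASTQ stream or path.

    Malformed records (truncated, or seq/qual length mismatch) raise a
    ValueError naming the record rather than being skipped.
    """
    close = False
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        stream = open(stream)
        close = True
    try:
        it = iter(stream)
        for header in it:
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise ValueError(f"expected @header, got {header[:30]!r}")
            name = header[1:].split()[0] if len(header) > 1 else ""
            try:
                seq = next(it).rstrip("\n")
                plus = next(it).rstrip("\n")
                qual = next(it).rstrip("\n")
            except StopIteration:
                raise ValueError(f"truncated FASTQ record {name!r}")
            if not plus.startswith("+"):
                raise ValueError(f"record {name!r}: missing '+' line")
            if len(seq) != len(qual):
                raise ValueError(
                    f"record {name!r}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}")
            yield Read(name, seq.upper(),
                       _decode_quals(qual, name, phred_offset),
                       mate_index=mate_index)
    finally:
        if close:
            stream.close()


def read_fasta(stream, default_qual=30, mate_index=None):
    """Iterate Read records from FASTA (constant placeholder qualities)."""
    from Bio import SeqIO
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq).upper()
        yield Read(rec.id, seq, np.full(len(seq), default_qual, np.int16),
                   mate_index=mate_index)


def read_paired_fastq(stream1, stream2, phred_offset=PHRED_OFFSET):
    """Pair mates from two FASTQ files by record rank."""
    it1 = read_fastq(stream1, mate_index=0, phred_offset=phred_offset)
    it2 = read_fastq(stream2, mate_index=1, phred_offset=phred_offset)
    for r1, r2 in zip_longest(it1, it2):
        if r1 is None or r2 is None:
            raise ValueError("paired FASTQ files have unequal record counts")
        yield r1, r2


def base_to_color(primer: str, seq: str) -> str:
    """Encode bases as di-base colors anchored on the primer base."""
    prev = primer.upper()
    if prev not in BASES:
        raise ValueError(f"invalid primer base {primer!r}")
    out = []
    for b in seq.upper():
        if b not in BASES:
            raise ValueError(f"ambiguity code {b!r} cannot be color-encoded")
        out.append(str(_COLOR[prev][b]))
        prev = b
    return "".join(out)


def color_to_base(primer: str, colors: str) -> str:
    """Decode a color chain back to bases given the primer."""
    prev = primer.upper()
    out = []
    for c in colors:
        prev = _DECODE[prev][int(c)]
        out.append(prev)
    return "".join(out)


def color_qual_to_base_qual(q_left: int, q_right: int) -> int:
    """A base is supported by its two flanking colors: take the minimum."""
    return min(int(q_left), int(q_right))


def colorspace_alignment_to_basespace(aln: LocalAlignment, ref_window: str,
                                      read: Read) -> tuple[LocalAlignment,
                                                           str, np.ndarray]:
    """Decode a colorspace alignment into basespace.

    Reference-anchored maximum-agreement decoding: within each aligned
    (M) segment the base at every position is taken from the reference
    when the local color chain is consistent with it; an isolated color
    mismatch decodes as agreement with the reference downstream (a
    sequencing error in one color), while two adjacent complementary
    color mismatches decode as a real substitution carried through.

    Returns the basespace alignment plus the decoded bases and their
    qualities (min of the two adjacent color qualities; the first base
    inherits the first color quality).
    """
    if aln.cigar and sum(n for op, n in aln.cigar if op in "MIS") != len(read):
        raise ValueError("CIGAR inconsistent with colorspace read length")
    ref_window = ref_window.upper()
    colors = read.seq
    n = len(colors)
    raw = color_to_base(read.primer, colors)
    decoded = list(raw)
    # within each aligned (M) segment, compare observed colors with the
    # colors the reference implies; a lone discrepancy is a sequencing
    # error (decode as reference), a run of >= 2 discrepancies encodes a
    # real substitution carried through the chain
    ci = 0          # color/read index
    rpos = aln.ref_start
    prev_decoded = read.primer
    for op, ln in aln.cigar:
        if op == "M":
            seg_ref = ref_window[rpos:rpos + ln]
            if all(b in BASES for b in seg_ref):
                anchor = prev_decoded if ci == 0 else None
                diffs = []
                pb = anchor if anchor is not None else None
                for t in range(ln):
                    if t == 0 and pb is not None:
                        expected = _COLOR[pb][seg_ref[0]]
                    elif t == 0:
                        expected = int(colors[ci])  # no anchor: trust read
                    else:
                        expected = _COLOR[seg_ref[t - 1]][seg_ref[t]]
                    diffs.append(int(colors[ci + t]) != expected)
                t = 0
                while t < ln:
                    if not diffs[t]:
                        decoded[ci + t] = seg_ref[t]
                        t += 1
                        continue
                    run = t
                    while run < ln and diffs[run]:
                        run += 1
                    if run - t == 1:
                        decoded[ci + t] = seg_ref[t]   # lone color error
                    else:
                        prev = seg_ref[t - 1] if t > 0 else (
                            anchor if anchor is not None else seg_ref[t])
                        for u in range(t, run):
                            prev = _DECODE[prev][int(colors[ci + u])]
                            decoded[ci + u] = prev
                    t = run
            if ln:
                prev_decoded = decoded[ci + ln - 1]
            ci += ln
            rpos += ln
        elif op in "IS":
            if ln:
                prev_decoded = decoded[ci + ln - 1]
            ci += ln
        elif op == "D":
            rpos += ln
    bases = "".join(decoded)
    # base i is covered by colors i and i+1; ends inherit the single color
    cq = read.quals
    bq = np.empty(n, np.int16)
    for i in range(n):
        if i + 1 < n:
            bq[i] = color_qual_to_base_qual(cq[i], cq[i + 1])
        else:
            bq[i] = cq[i]
    base_aln = LocalAlignment(
        ref_name=aln.ref_name, ref_start=aln.ref_start, strand=aln.strand,
        cigar=list(aln.cigar), score=aln.score, is_special=aln.is_special)
    # recount mismatches in basespace
    mism = 0
    ci = 0
    rpos = base_aln.ref_start
    for op, ln in base_aln.cigar:
        if op == "M":
            for t in range(ln):
                if rpos + t < len(ref_window) and \
                        bases[ci + t] != ref_window[rpos + t]:
                    mism += 1
            ci += ln
            rpos += ln
        elif op in "IS":
            ci += ln
        else:
            rpos += ln
    base_aln.mismatches = mism
    base_aln.gap_bases = aln.gap_bases
    return base_aln, bases, bq


def entropy_bits_per_base(seq: str) -> float:
    """Shannon entropy of mononucleotide frequencies, in bits per base."""
    if not seq:
        raise ValueError("empty sequence")
    counts = np.array([seq.count(b) for b in "ACGT"], float)
    other = len(seq) - counts.sum()
    if other:
        counts = np.append(counts, other)
    p = counts[counts > 0] / len(seq)
    return float(-(p * np.log2(p)).sum())
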