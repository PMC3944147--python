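"""SAM/BAM emission: primary records with ZA mate annotation, and an
optional stripped multi-mapping stream.

The ZA auxiliary tag carries, for each mate of a pair, the information a
structural-variant caller would otherwise have to fish out of the file
with extra lookups: the mate's reference, position, mapping quality and
mapping-location count, plus the name of any special (insertion-sequence)
reference the mate hit.  Text grammar:

    ZA:Z:<ref>;<pos>;<mq>;<nloci>;<special>

with an empty trailing field when there is no special hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pysam

from .pairing import STATUS_PROPER, STATUS_RESCUED
from .refindex import ReferenceSet, revcomp


@dataclass
class ZaAnnotation:
    mate_ref: str
    mate_pos: int          # 1-based; 0 when unmapped
    mate_mq: int
    mate_nloci: int
    special: str = ""

    def __post_init__(self):
        if self.mate_ref != "*" and self.mate_pos < 1:
            raise ValueError("mapped mate annotation needs position >= 1")


def format_za(ann: ZaAnnotation) -> str:
    return (f"ZA:Z:{ann.mate_ref};{ann.mate_pos};{ann.mate_mq};"
            f"{ann.mate_nloci};{ann.special}")


def parse_za(text: str) -> ZaAnnotation:
    if text.startswith("ZA:Z:"):
        text = text[5:]
    parts = text.split(";")
    if len(parts) != 5:
        raise ValueError(f"malformed ZA tag: {text!r}")
    return ZaAnnotation(parts[0], int(parts[1]), int(parts[2]),
                        int(parts[3]), parts[4])


def _header(refset: ReferenceSet) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": len(s)}
               for n, s in zip(refset.names, refset.seqs)],
        "PG": [{"ID": "hashalign", "PN": "hashalign", "VN": "0.1.0"}],
    }


def _mode(path) -> str:
    return "wb" if str(path).endswith(".bam") else "w"


def _make_segment(rec, header: pysam.AlignmentHeader,
                  za: str | None = None) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = rec.name
    flag = 0
    paired = rec.mate is not None
    if paired:
        flag |= 0x1
        flag |= 0x40 if rec.mate == 0 else 0x80
        if rec.status in (STATUS_PROPER, STATUS_RESCUED):
            flag |= 0x2
        if not rec.mate_mapped:
            flag |= 0x8
        elif rec.mate_strand == "-":
            flag |= 0x20
    if not rec.mapped:
        flag |= 0x4
        seg.flag = flag
        seg.query_sequence = rec.seq or None
        if rec.quals is not None:
            seg.query_qualities = [int(q) for q in rec.quals]
        seg.reference_id = -1
        seg.reference_start = -1
        seg.mapping_quality = 0
        _set_mate(seg, rec, header)
        if za:
            seg.set_tag("ZA", za, "Z")
        return seg
    if rec.strand == "-":
        flag |= 0x10
        seq = revcomp(rec.seq) if rec.seq else None
        quals = rec.quals[::-1] if rec.quals is not None else None
    else:
        seq = rec.seq or None
        quals = rec.quals
    seg.flag = flag
    tid = header.get_tid(rec.ref_name)
    if tid < 0:
        raise ValueError(f"alignment references unknown sequence "
                         f"{rec.ref_name!r}")
    seg.reference_id = tid
    seg.reference_start = rec.pos
    seg.mapping_quality = 255 if rec.mapq is None else int(rec.mapq)
    seg.cigarstring = rec.cigar_string
    seg.query_sequence = seq
    if quals is not None:
        seg.query_qualities = [int(q) for q in quals]
    seg.template_length = rec.tlen
    _set_mate(seg, rec, header)
    seg.set_tag("AS", int(rec.score), "i")
    seg.set_tag("NM", int(rec.mismatches + rec.gap_bases), "i")
    if za:
        seg.set_tag("ZA", za, "Z")
    return seg


def _set_mate(seg, rec, header) -> None:
    if rec.mate is not None and rec.mate_mapped:
        seg.next_reference_id = header.get_tid(rec.mate_ref)
        seg.next_reference_start = rec.mate_pos
    else:
        seg.next_reference_id = -1
        seg.next_reference_start = -1


def write_primary(records, refset: ReferenceSet, path) -> None:
    """Write pair-resolved records to SAM/BAM (mode chosen by suffix).

    Paired records carry the ZA annotation of their mate; special-
    reference hits are reported there as well.
    """
    header = pysam.AlignmentHeader.from_dict(_header(refset))
    pairs = []
    for r in records:
        pairs.append(r if isinstance(r, tuple) else (r,))
    with pysam.AlignmentFile(str(path), _mode(path), header=header) as out:
        for group in pairs:
            if len(group) == 2:
                r1, r2 = group
                za1 = format_za(_mate_annotation(r2))[5:]
                za2 = format_za(_mate_annotation(r1))[5:]
                out.write(_make_segment(r1, header, za1))
                out.write(_make_segment(r2, header, za2))
            else:
                (r,) = group
                za = (f"*;0;0;0;{r.special_hit}" if r.special_hit else None)
                out.write(_make_segment(r, header, za))


def _mate_annotation(mate_rec) -> ZaAnnotation:
    if not mate_rec.mapped:
        return ZaAnnotation("*", 0, 0, 0, mate_rec.special_hit)
    return ZaAnnotation(
        mate_rec.ref_name, mate_rec.pos + 1,
        0 if mate_rec.mapq is None else int(mate_rec.mapq),
        max(int(mate_rec.n_loci), 1), mate_rec.special_hit)


def write_multimap(per_read_alignments, refset: ReferenceSet, path) -> None:
    """Stripped multi-mapping stream: one record per accepted locus.

    ``per_read_alignments`` yields (ordinal, [LocalAlignment-like with
    global or local coordinates resolved to (ref_name, pos, strand,
    cigar, score)]).  Read-specific payload (name, sequence, qualities)
    is omitted: names become per-read ordinals, SEQ/QUAL are '*'.  One
    designated representative (the first) keeps the primary flag; the
    rest are flagged secondary with MAPQ 0.  Records are emitted
    position-sorted.
    """
    header = pysam.AlignmentHeader.from_dict(_header(refset))
    staged = []
    for ordinal, alns in per_read_alignments:
        for j, (ref_name, pos, strand, cigar_str, score) in enumerate(alns):
            tid = header.get_tid(ref_name)
            if tid < 0:
                raise ValueError(f"unknown sequence {ref_name!r}")
            staged.append((tid, pos, ordinal, j, strand, cigar_str, score))
    staged.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    with pysam.AlignmentFile(str(path), _mode(path), header=header) as out:
        for tid, pos, ordinal, j, strand, cigar_str, score in staged:
            seg = pysam.AlignedSegment(header)
            seg.query_name = str(ordinal)
            seg.flag = (0x10 if strand == "-" else 0) | (0x100 if j else 0)
            seg.reference_id = tid
            seg.reference_start = pos
            seg.mapping_quality = 0 if j else 255
            seg.cigarstring = cigar_str
            seg.query_sequence = None
            seg.set_tag("AS", int(score), "i")
            out.write(seg)
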