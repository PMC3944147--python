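"""Seed collection and diagonal clustering into candidate regions.

A read is split into every overlapping k-mer; each k-mer's reference
positions become seed hits characterised by their diagonal
(``ref_pos - read_offset``).  Hits on the same strand whose diagonals
differ by at most one and whose positions lie within a read length of
each other are consolidated (transitively) into one alignment candidate
region, which tolerates sequencing errors, SNPs and single-base INDELs
inside the read.  Regions are ranked by the number of distinct read bases
their seeds cover and capped at a configurable number of loci.

These functions give the reference semantics on explicit hit lists; the
batch aligner runs the same rule inside a compiled kernel
(:func:`hashalign._kernels.align_batch`), and the two are cross-checked
against each other in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .refindex import AlignerConfig, HashIndex, revcomp


@dataclass(frozen=True)
class SeedHit:
    read_offset: int
    ref_pos: int
    strand: str  # '+' or '-'

    @property
    def diagonal(self) -> int:
        return self.ref_pos - self.read_offset


@dataclass
class CandidateRegion:
    start: int            # padded global window start
    end: int              # padded global window end (half-open)
    strand: str
    support: int          # contributing seed hits
    covered: int          # distinct read bases covered by seeds
    diag_min: int
    diag_max: int
    is_special: bool = False

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("region start must precede end")


def hash_read(read: str, k: int) -> list[tuple[int, str]]:
    """All overlapping k-mer windows of a read, skipping non-ACGT windows.

    A read shorter than k yields no hashes (it stays unaligned at the
    seeding stage).
    """
    read = read.upper()
    L = len(read)
    out = []
    for o in range(L - k + 1):
        kmer = read[o:o + k]
        if set(kmer) <= set("ACGT"):
            out.append((o, kmer))
    return out


def collect_hits(index: HashIndex, read: str) -> list[SeedHit]:
    """Seed hits for both strands; reverse strand hits come from the
    reverse complement of the read."""
    hits = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for o, kmer in hash_read(seq, index.k):
            for p in index.lookup(kmer):
                hits.append(SeedHit(o, int(p), strand))
    return hits


def cluster_hits(hits: list[SeedHit], read_len: int, k: int,
                 pad: int = 20) -> list[CandidateRegion]:
    """Transitive-closure grouping of seed hits into candidate regions.

    Two same-strand hits join when their diagonals differ by <= 1 and
    their reference positions lie within one read length.  This is the
    naive all-pairs rule; it is deliberately simple and serves as the
    oracle for the compiled batch kernel.
    """
    regions: list[CandidateRegion] = []
    for strand in "+-":
        sh = sorted((h for h in hits if h.strand == strand),
                    key=lambda h: (h.diagonal, h.ref_pos))
        n = len(sh)
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if sh[j].diagonal - sh[i].diagonal > 1:
                    break
                if abs(sh[j].ref_pos - sh[i].ref_pos) <= read_len:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
        groups: dict[int, list[SeedHit]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(sh[i])
        for members in groups.values():
            dmin = min(h.diagonal for h in members)
            dmax = max(h.diagonal for h in members)
            covered_bases = set()
            for h in members:
                covered_bases.update(range(h.read_offset, h.read_offset + k))
            regions.append(CandidateRegion(
                start=dmin - pad, end=dmax + read_len + pad, strand=strand,
                support=len(members), covered=len(covered_bases),
                diag_min=dmin, diag_max=dmax))
    regions.sort(key=lambda r: (-r.covered, -r.support, r.start))
    return regions


def select_regions(regions: list[CandidateRegion], cfg: AlignerConfig
                   ) -> list[CandidateRegion]:
    """Drop regions below the candidate threshold and cap the locus count.

    Ranking: covered bases desc, support desc, special references ahead
    of equally-ranked genome regions, then leftmost position (stable and
    deterministic).  Returns at most ``cfg.max_loci`` regions; an empty
    result means the read is unaligned at the seeding stage.
    """
    kept = [r for r in regions if r.covered >= cfg.act]
    kept.sort(key=lambda r: (-r.covered, -r.support,
                             not r.is_special, r.start))
    return kept[:cfg.max_loci]
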