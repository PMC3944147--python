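"""Hashed reference index with IUPAC ambiguity expansion.

The reference is held as one concatenated coordinate space.  Special
(insertion-sequence) references occupy the *lowest* global coordinates, so
the ascending position order that the index stores naturally reports
special-reference hits before genome hits -- that is how lookup priority is
implemented.

Every overlapping k-mer window of the reference that contains no N/X is
hashed; windows containing other IUPAC ambiguity codes are expanded into
all compatible A/C/G/T k-mers (capped at 64 combinations per window) so
that reads carrying either allele of a masked SNP seed the same region.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from . import _kernels

MAX_REFERENCE_LENGTH = 4_000_000_000
MIN_HASH_SIZE = 4
MAX_HASH_SIZE = 32
EXPANSION_CAP = 64  # max A/C/G/T combinations for one ambiguous window

BASES = "ACGT"
BASE_TO_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: IUPAC nucleotide code -> set of compatible bases.  N and X are handled
#: separately (excluded from hashing entirely).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}

# bitmask encoding used by the alignment kernels: A=1 C=2 G=4 T=8, N/X=0
_MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _c, _bases in IUPAC.items():
    _m = 0
    for _b in _bases:
        _m |= 1 << BASE_TO_IDX[_b]
    _MASK_TABLE[ord(_c)] = _m
    _MASK_TABLE[ord(_c.lower())] = _m

# base-index encoding used for reads: A=0 C=1 G=2 T=3, everything else 4
_IDX_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_TO_IDX.items():
    _IDX_TABLE[ord(_b)] = _i
    _IDX_TABLE[ord(_b.lower())] = _i


def seq_to_mask(seq: str) -> np.ndarray:
    """Encode an IUPAC string as the kernel bitmask representation."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _MASK_TABLE[raw]


def seq_to_idx(seq: str) -> np.ndarray:
    """Encode a read as base indices (A=0,C=1,G=2,T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _IDX_TABLE[raw]


def idx_to_seq(idx: np.ndarray) -> str:
    return "".join("ACGTN"[int(i)] for i in idx)


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTRYSWKMBDHVNXacgtryswkmbdhvnx",
                         "TGCAYRSWMKVHDBNXtgcayrswmkvhdbnx")
    return seq.translate(comp)[::-1]


def expand_iupac(kmer: str) -> set[str]:
    """Cartesian expansion of a k-mer's ambiguity codes into A/C/G/T k-mers.

    Windows containing N or X are not hashed at all: returns the empty set.
    """
    choices = []
    for c in kmer.upper():
        if c in ("N", "X") or c not in IUPAC:
            return set()
        choices.append(IUPAC[c])
    out = [""]
    for ch in choices:
        out = [p + b for p in out for b in ch]
    return set(out)


def encode_kmer(kmer: str) -> int:
    """Pack an A/C/G/T k-mer (length <= 32) into a 2-bit-per-base integer."""
    if len(kmer) > MAX_HASH_SIZE:
        raise ValueError(f"k-mer longer than {MAX_HASH_SIZE}: {len(kmer)}")
    code = 0
    for c in kmer.upper():
        if c not in BASE_TO_IDX:
            raise ValueError(f"non-ACGT character in k-mer: {c!r}")
        code = (code << 2) | BASE_TO_IDX[c]
    return code


def decode_kmer(code: int, k: int) -> str:
    return "".join(BASES[(code >> (2 * (k - 1 - i))) & 3] for i in range(k))


@dataclass
class ReferenceSet:
    """An ordered collection of named IUPAC sequences in one coordinate space.

    Special sequences (known insertion elements) are stored first so their
    global coordinates sort ahead of genome coordinates.
    """

    names: list[str]
    seqs: list[str]
    is_special: np.ndarray          # bool per sequence
    offsets: np.ndarray             # int64, global start per sequence
    bounds: np.ndarray              # int64, len S+1, sequence boundaries
    masks: np.ndarray               # uint8 concatenated bitmask encoding

    @classmethod
    def from_sequences(cls, sequences) -> "ReferenceSet":
        """Build from an iterable of (name, seq) or (name, seq, is_special)."""
        entries = []
        for entry in sequences:
            if len(entry) == 2:
                name, seq = entry
                special = False
            else:
                name, seq, special = entry
            entries.append((name, seq.upper(), bool(special)))
        # special sequences first in the coordinate space
        entries.sort(key=lambda e: (not e[2],))
        names = [e[0] for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("reference sequence names must be unique")
        seqs = [e[1] for e in entries]
        total = sum(len(s) for s in seqs)
        if total > MAX_REFERENCE_LENGTH:
            raise ValueError(
                f"aggregate reference length {total} exceeds "
                f"{MAX_REFERENCE_LENGTH} bases")
        for name, s in zip(names, seqs):
            bad = set(s) - set(IUPAC) - {"N", "X"}
            if bad:
                raise ValueError(f"invalid characters {bad} in {name}")
        special = np.array([e[2] for e in entries], dtype=bool)
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        bounds = np.concatenate([[0], np.cumsum(lengths)])
        masks = (np.concatenate([seq_to_mask(s) for s in seqs])
                 if seqs else np.zeros(0, np.uint8))
        return cls(names, seqs, special, bounds[:-1].copy(), bounds, masks)

    @classmethod
    def from_fasta(cls, path, special_path=None) -> "ReferenceSet":
        entries = []
        for rec in SeqIO.parse(str(path), "fasta"):
            entries.append((rec.id, str(rec.seq), False))
        if special_path is not None:
            for rec in SeqIO.parse(str(special_path), "fasta"):
                entries.append((rec.id, str(rec.seq), True))
        if not entries:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(entries)

    @property
    def n_sequences(self) -> int:
        return len(self.names)

    @property
    def n_special(self) -> int:
        return int(self.is_special.sum())

    @property
    def total_length(self) -> int:
        return int(self.bounds[-1])

    def seq_index_of(self, gpos: int) -> int:
        i = int(np.searchsorted(self.bounds, gpos, side="right")) - 1
        if i < 0 or i >= self.n_sequences:
            raise IndexError(f"global position {gpos} outside reference")
        return i

    def global_to_local(self, gpos: int) -> tuple[str, int]:
        i = self.seq_index_of(gpos)
        return self.names[i], int(gpos - self.offsets[i])

    def local_to_global(self, name: str, pos: int) -> int:
        i = self.names.index(name)
        if not 0 <= pos < len(self.seqs[i]):
            raise IndexError(f"{name}:{pos} outside sequence")
        return int(self.offsets[i] + pos)

    def fetch(self, gstart: int, gend: int) -> str:
        i = self.seq_index_of(gstart)
        lo, hi = int(self.offsets[i]), int(self.bounds[i + 1])
        if gend > hi:
            raise IndexError("fetch crosses a sequence boundary")
        return self.seqs[i][gstart - lo:gend - lo]

    def digest(self) -> str:
        h = hashlib.sha256()
        for name, seq, sp in zip(self.names, self.seqs, self.is_special):
            h.update(f">{name}\t{int(sp)}\n".encode())
            h.update(seq.encode())
        return h.hexdigest()


@dataclass
class ScoringScheme:
    """Affine-gap local alignment scores (all magnitudes, non-negative).

    A gap of length g costs ``gap_open + (g - 1) * gap_extend``.  Defaults
    make one substitution (19 relative to a match) cheaper than a 1 bp gap
    (25), balancing mismatch against gap calls.
    """

    match: int = 10
    mismatch: int = 9
    gap_open: int = 15
    gap_extend: int = 4

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.match <= 0:
            raise ValueError("match reward must be positive")


@dataclass
class AlignerConfig:
    """Tunable alignment parameters (defaults: hs 15, mmp 0.15, act 55)."""

    hs: int = 15                 # hash (k-mer) size
    mmp: float = 0.15            # max mismatch proportion of read length
    act: int = 55                # alignment candidate threshold (seed bases)
    max_loci: int = 200          # cap on candidate loci polished per read
    mhp: int = 100               # positions retained per k-mer at lookup
    band: int = 19               # band half-width around seed diagonals
    region_pad: int = 20         # window padding beyond the seed span
    rescue_window_sd: float = 4.0  # fragment window multiplier for rescue
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self):
        if not MIN_HASH_SIZE <= self.hs <= MAX_HASH_SIZE:
            raise ValueError(
                f"The available hash sizes are {MIN_HASH_SIZE}-{MAX_HASH_SIZE}"
                f" (got {self.hs})")
        if not 0.0 <= self.mmp <= 1.0:
            raise ValueError("mmp must be in [0, 1]")
        if self.act <= 0:
            raise ValueError("act must be positive")
        if self.max_loci < 1:
            raise ValueError("max_loci must be >= 1")

    @classmethod
    def pacbio(cls, **kw) -> "AlignerConfig":
        """High-error long-read preset: hs 10, mmp 0.5, act 15."""
        kw.setdefault("hs", 10)
        kw.setdefault("mmp", 0.5)
        kw.setdefault("act", 15)
        return cls(**kw)


@dataclass
class HashIndex:
    """Packed k-mer -> sorted global reference positions (CSR layout)."""

    k: int
    mhp: int
    keys: np.ndarray        # uint64, sorted distinct k-mer codes
    starts: np.ndarray      # int64, len(keys)+1
    positions: np.ndarray   # int64, ascending within each key
    ref_digest: str

    FORMAT_VERSION = 1

    def lookup(self, kmer) -> np.ndarray:
        """Positions of a k-mer, special-reference positions first.

        Accepts a string or a packed code.  At most ``mhp`` positions are
        returned, keeping the first in global (special-first) order.
        Absent k-mers give an empty array.
        """
        if isinstance(kmer, str):
            if len(kmer) != self.k:
                raise ValueError(f"k-mer length {len(kmer)} != index k {self.k}")
            if set(kmer.upper()) - set(BASES):
                return np.zeros(0, dtype=np.int64)  # never hashed
            code = encode_kmer(kmer)
        else:
            code = int(kmer)
        i = int(np.searchsorted(self.keys, np.uint64(code)))
        if i >= len(self.keys) or self.keys[i] != np.uint64(code):
            return np.zeros(0, dtype=np.int64)
        lo, hi = int(self.starts[i]), int(self.starts[i + 1])
        hi = min(hi, lo + self.mhp)
        return self.positions[lo:hi].copy()

    def save(self, path) -> None:
        """Versioned binary serialization (deterministic byte layout)."""
        header = {
            "format_version": self.FORMAT_VERSION,
            "k": self.k,
            "mhp": self.mhp,
            "ref_digest": self.ref_digest,
            "n_keys": int(len(self.keys)),
            "n_positions": int(len(self.positions)),
        }
        blob = json.dumps(header, sort_keys=True).encode()
        with open(path, "wb") as fh:
            fh.write(b"HAIDX1\n")
            fh.write(len(blob).to_bytes(8, "little"))
            fh.write(blob)
            fh.write(np.ascontiguousarray(self.keys, np.uint64).tobytes())
            fh.write(np.ascontiguousarray(self.starts, np.int64).tobytes())
            fh.write(np.ascontiguousarray(self.positions, np.int64).tobytes())

    @classmethod
    def load(cls, path) -> "HashIndex":
        with open(path, "rb") as fh:
            magic = fh.read(7)
            if magic != b"HAIDX1\n":
                raise ValueError(f"{path} is not a hashalign index")
            n = int.from_bytes(fh.read(8), "little")
            header = json.loads(fh.read(n))
            nk, npos = header["n_keys"], header["n_positions"]
            keys = np.frombuffer(fh.read(8 * nk), dtype=np.uint64)
            starts = np.frombuffer(fh.read(8 * (nk + 1)), dtype=np.int64)
            positions = np.frombuffer(fh.read(8 * npos), dtype=np.int64)
        return cls(header["k"], header["mhp"], keys.copy(), starts.copy(),
                   positions.copy(), header["ref_digest"])


def build_index(refset: ReferenceSet, cfg: AlignerConfig | int,
                mhp: int | None = None) -> HashIndex:
    """Hash every valid k-mer window of the reference.

    Pure A/C/G/T windows go through a rolling-code kernel; windows with
    ambiguity codes (other than N/X) are expanded into all compatible
    k-mers, capped at 64 combinations per window.
    """
    if isinstance(cfg, AlignerConfig):
        k, cap = cfg.hs, cfg.mhp
    else:
        k = int(cfg)
        cap = mhp if mhp is not None else 100
    if not MIN_HASH_SIZE <= k <= MAX_HASH_SIZE:
        raise ValueError(
            f"The available hash sizes are {MIN_HASH_SIZE}-{MAX_HASH_SIZE}"
            f" (got {k})")

    code_chunks: list[np.ndarray] = []
    pos_chunks: list[np.ndarray] = []
    for si, seq in enumerate(refset.seqs):
        if len(seq) < k:
            continue
        offset = int(refset.offsets[si])
        idx = seq_to_idx(seq)
        codes, valid = _kernels.rolling_codes(idx, k)
        # plain windows: only unambiguous bases
        mask = refset.masks[refset.bounds[si]:refset.bounds[si + 1]]
        plain = _kernels.window_all_unambiguous(mask, k)
        ok = valid & plain
        code_chunks.append(codes[ok])
        pos_chunks.append(np.nonzero(ok)[0].astype(np.int64) + offset)
        # ambiguous (non-N/X) windows: Python-side expansion
        amb = (~plain) & _kernels.window_no_nx(mask, k)
        for o in np.nonzero(amb)[0]:
            kmers = expand_iupac(seq[o:o + k])
            if not kmers or len(kmers) > EXPANSION_CAP:
                continue
            exp = np.array(sorted(encode_kmer(x) for x in kmers),
                           dtype=np.uint64)
            code_chunks.append(exp)
            pos_chunks.append(np.full(len(exp), offset + o, dtype=np.int64))

    if code_chunks:
        all_codes = np.concatenate(code_chunks)
        all_pos = np.concatenate(pos_chunks)
    else:
        all_codes = np.zeros(0, np.uint64)
        all_pos = np.zeros(0, np.int64)
    order = np.lexsort((all_pos, all_codes))
    all_codes = all_codes[order]
    all_pos = all_pos[order]
    keys, starts_idx = np.unique(all_codes, return_index=True)
    starts = np.concatenate([starts_idx, [len(all_codes)]]).astype(np.int64)
    return HashIndex(k, cap, keys, starts, all_pos, refset.digest())
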