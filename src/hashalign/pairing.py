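"""Paired-end resolution: fragment model, pair consistency, mate rescue.

Mates are aligned independently first.  A pair is *proper* when the two
placements sit on the same reference sequence in forward-reverse
orientation with an implied fragment length inside the expected window
(mean +/- multiplier * spread).  When no consistent combination exists,
the better-aligned mate anchors a bounded Smith-Waterman search for its
partner over the window the fragment model implies; a hit consistent in
strand, orientation and length counts as rescued.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .refindex import AlignerConfig
from .swalign import _from_kernel, accept_alignment

# pair status values, ordered from worst to best
STATUS_NEITHER = "neither"
STATUS_ONE_END = "one-end"
STATUS_DISCORDANT = "discordant"   # both aligned, fragment inconsistent
STATUS_RESCUED = "rescued"
STATUS_PROPER = "both-proper"


@dataclass
class FragmentModel:
    """Expected fragment-length distribution for forward-reverse pairs."""

    mean: float
    spread: float
    orientation: str = "FR"
    multiplier: float = 4.0

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("fragment mean must be positive")
        if self.spread < 0:
            raise ValueError("fragment spread must be non-negative")

    @property
    def window(self) -> float:
        return self.mean + self.multiplier * max(self.spread, 1.0)

    def consistent(self, fragment: float) -> bool:
        half = self.multiplier * max(self.spread, 1.0)
        return abs(fragment - self.mean) <= half


def estimate_fragment_model(fragment_lengths, fallback: FragmentModel = None,
                            min_pairs: int = 100,
                            multiplier: float = 4.0) -> FragmentModel:
    """Robust location/scale fit: median and 1.4826 * MAD.

    Falls back to ``fallback`` when fewer than ``min_pairs`` uniquely
    both-mapped pairs are available; with neither, raises.
    """
    frags = np.asarray(fragment_lengths, dtype=float)
    frags = frags[np.isfinite(frags) & (frags > 0)]
    if len(frags) < min_pairs:
        if fallback is not None:
            return fallback
        raise ValueError(
            f"only {len(frags)} usable pairs (< {min_pairs}) and no "
            f"fallback fragment model configured")
    med = float(np.median(frags))
    mad = float(np.median(np.abs(frags - med)))
    return FragmentModel(mean=med, spread=1.4826 * mad,
                         multiplier=multiplier)


@dataclass
class ReadCandidates:
    """Accepted candidate placements of one read, sorted by score desc."""

    pos: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    end: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    score: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    strand: np.ndarray = field(default_factory=lambda: np.zeros(0, np.uint8))
    special: np.ndarray = field(default_factory=lambda: np.zeros(0, np.uint8))
    seqid: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    wlo: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    whi: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    dlo: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    dhi: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))

    def __len__(self) -> int:
        return len(self.pos)


def observed_fragment(pos_f, end_f, pos_r, end_r) -> int:
    """Fragment implied by a forward placement and a reverse placement."""
    return int(max(end_f, end_r) - min(pos_f, pos_r))


def resolve_pair(c1: ReadCandidates, c2: ReadCandidates,
                 model: FragmentModel, max_combos: int = 50):
    """Pick the fragment-consistent combination with maximal summed score.

    Returns ``(i1, i2, fragment, tied)`` or ``None`` when no combination
    is consistent; ``tied`` flags that several consistent combinations
    share the maximal summed score (the pair is ambiguous even though it
    is proper).  Combinations must be on the same reference sequence
    with opposite strands in forward-reverse orientation.  Ties break
    toward the leftmost forward placement, then lowest candidate indices
    (deterministic).
    """
    n1 = min(len(c1), max_combos)
    n2 = min(len(c2), max_combos)
    best = None
    best_key = None
    best_total = None
    n_at_best = 0
    for i in range(n1):
        for j in range(n2):
            if c1.seqid[i] != c2.seqid[j]:
                continue
            if c1.strand[i] == c2.strand[j]:
                continue
            if c1.strand[i] == 0:
                pos_f, end_f = c1.pos[i], c1.end[i]
                pos_r, end_r = c2.pos[j], c2.end[j]
            else:
                pos_f, end_f = c2.pos[j], c2.end[j]
                pos_r, end_r = c1.pos[i], c1.end[i]
            if pos_r < pos_f:  # not forward-reverse
                continue
            frag = observed_fragment(pos_f, end_f, pos_r, end_r)
            if not model.consistent(frag):
                continue
            total = int(c1.score[i]) + int(c2.score[j])
            if best_total is None or total > best_total:
                best_total = total
                n_at_best = 1
            elif total == best_total:
                n_at_best += 1
            key = (-total, int(pos_f), i, j)
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j, frag)
    if best is None:
        return None
    return best + (n_at_best > 1,)


def rescue_window(anchor_pos: int, anchor_end: int, anchor_strand: int,
                  model: FragmentModel, read_len: int,
                  seq_lo: int, seq_hi: int) -> tuple[int, int]:
    """Reference window implied by an anchored mate for rescue search."""
    reach = int(np.ceil(model.window)) + read_len
    if anchor_strand == 0:
        lo, hi = anchor_pos, anchor_pos + reach
    else:
        lo, hi = anchor_end - reach, anchor_end
    return max(lo, seq_lo), min(hi, seq_hi)


def rescue_mate(anchor, mate_idx: np.ndarray, mate_idx_rev: np.ndarray,
                model: FragmentModel, refmask: np.ndarray,
                seq_lo: int, seq_hi: int, cfg: AlignerConfig):
    """Bounded local-alignment search for the unanchored mate.

    ``anchor`` is a (pos, end, strand) triple on the global coordinate
    space.  The mate is aligned on the strand opposite the anchor over
    the fragment-model window; the placement is returned only when it
    passes the mismatch ceiling and yields a consistent fragment.

    Returns ``(LocalAlignment with global ref_start, fragment)`` or None.
    """
    a_pos, a_end, a_strand = anchor
    L = len(mate_idx)
    wlo, whi = rescue_window(a_pos, a_end, a_strand, model, L,
                             seq_lo, seq_hi)
    if whi - wlo < L // 2:
        return None
    sc = cfg.scoring
    seq = mate_idx_rev if a_strand == 0 else mate_idx
    W = whi - wlo
    out = _kernels.sw_traceback(seq, refmask, wlo, whi,
                                -(L + W + 2), L + W + 2,
                                sc.match, sc.mismatch, sc.gap_open,
                                sc.gap_extend)
    aln = _from_kernel(*out, strand="-" if a_strand == 0 else "+")
    if aln.score <= 0 or not accept_alignment(aln, L, cfg):
        return None
    # fragment-consistency of the rescued placement
    if a_strand == 0:
        frag = observed_fragment(a_pos, a_end, aln.ref_start, aln.ref_end)
        ok_orient = aln.ref_start >= a_pos
    else:
        frag = observed_fragment(aln.ref_start, aln.ref_end, a_pos, a_end)
        ok_orient = aln.ref_start <= a_pos
    if not ok_orient or not model.consistent(frag):
        return None
    return aln, frag
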