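"""Local affine-gap (Smith-Waterman-Gotoh) polishing of candidate regions.

The DP distinguishes gap-open from gap-extend costs so that one long gap
is cheaper than many short ones.  A banded variant restricts cells to a
diagonal corridor; it is exact whenever the optimal path stays inside the
band and otherwise returns the best within-band alignment.  Read ends not
covered by the local path become soft clips, so M+I+S lengths always sum
to the read length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .refindex import AlignerConfig, ScoringScheme, seq_to_idx, seq_to_mask

CIGAR_OPS = "MIDNSHP=X"


@dataclass
class LocalAlignment:
    """One polished local placement of a read."""

    ref_name: str = ""
    ref_start: int = 0            # 0-based, window- or sequence-local
    strand: str = "+"
    cigar: list = field(default_factory=list)   # [(op_char, length), ...]
    score: int = 0
    mismatches: int = 0
    gap_bases: int = 0
    is_special: bool = False

    @property
    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.cigar)

    @property
    def read_length(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS")

    @property
    def ref_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span

    @property
    def aligned_read_span(self) -> int:
        return sum(n for op, n in self.cigar if op in "MI")

    @property
    def clipped_bases(self) -> int:
        return sum(n for op, n in self.cigar if op == "S")


def _as_idx(read) -> np.ndarray:
    if isinstance(read, str):
        return seq_to_idx(read)
    return np.asarray(read, dtype=np.uint8)


def _as_mask(window) -> np.ndarray:
    if isinstance(window, str):
        return seq_to_mask(window)
    return np.asarray(window, dtype=np.uint8)


def _from_kernel(score, gstart, ops, lens, n_ops, mism, gaps,
                 strand="+") -> LocalAlignment:
    cigar = [(CIGAR_OPS[int(ops[i])], int(lens[i])) for i in range(n_ops)]
    return LocalAlignment(ref_start=int(gstart), strand=strand, cigar=cigar,
                          score=int(score), mismatches=int(mism),
                          gap_bases=int(gaps))


def sw_gotoh(read, window, scoring: ScoringScheme | None = None
             ) -> LocalAlignment:
    """Unrestricted local affine-gap alignment of a read to a window.

    ``read`` and ``window`` may be strings or pre-encoded arrays (base
    indices and IUPAC bitmasks respectively).  A read base aligned against
    an ambiguity code that includes it scores as a match.
    """
    scoring = scoring or ScoringScheme()
    ridx = _as_idx(read)
    wmask = _as_mask(window)
    if len(ridx) == 0 or len(wmask) == 0:
        raise ValueError("empty read or window")
    W = len(wmask)
    out = _kernels.sw_traceback(
        ridx, wmask, 0, W, -(len(ridx) + W + 2), len(ridx) + W + 2,
        scoring.match, scoring.mismatch, scoring.gap_open,
        scoring.gap_extend)
    return _from_kernel(*out)


def banded_sw_gotoh(read, window, scoring: ScoringScheme | None = None,
                    band: int = 19, center: int | None = None
                    ) -> LocalAlignment:
    """Banded variant: diagonals restricted to ``center +/- band``.

    ``center`` is the expected reference offset of the read start within
    the window (the dominant seed diagonal); defaults to 0.  With a band
    at least as wide as the window this is identical to :func:`sw_gotoh`.
    """
    if band < 1:
        raise ValueError("band must be >= 1")
    scoring = scoring or ScoringScheme()
    ridx = _as_idx(read)
    wmask = _as_mask(window)
    if len(ridx) == 0 or len(wmask) == 0:
        raise ValueError("empty read or window")
    c = 0 if center is None else int(center)
    out = _kernels.sw_traceback(
        ridx, wmask, 0, len(wmask), c - band, c + band,
        scoring.match, scoring.mismatch, scoring.gap_open,
        scoring.gap_extend)
    return _from_kernel(*out)


def accept_alignment(aln: LocalAlignment, read, cfg: AlignerConfig) -> bool:
    """Mismatch-proportion ceiling: mismatches plus gap bases <= mmp * L."""
    L = len(read) if not isinstance(read, int) else read
    return (aln.mismatches + aln.gap_bases) <= cfg.mmp * L
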