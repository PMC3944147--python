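"""Numba kernels for the hot alignment path.

Conventions:
 - reference: one concatenated ``uint8`` array of IUPAC bitmasks
   (A=1, C=2, G=4, T=8; N/X=0), special sequences occupying the lowest
   global coordinates;
 - reads: ``uint8`` arrays of base indices (A=0, C=1, G=2, T=3, other=4);
 - all alignment scores are integers; a substitution scores ``match`` when
   the read base bit is set in the reference mask, else ``-mismatch``;
 - a gap of length g costs ``gap_open + (g-1) * gap_extend``.
"""

import numpy as np
from numba import njit

NEG = -(10 ** 9)

# CIGAR op codes (SAM numeric convention)
OP_M = 0
OP_I = 1
OP_D = 2
OP_S = 4

MAX_HITS = 4096          # per-strand seed-hit buffer cap
MAX_READ = 4096          # coverage scratch size (max read length)


@njit(cache=True)
def rolling_codes(idx, k):
    """2-bit rolling codes over a base-index array.

    Returns (codes, valid) of length ``len(idx)-k+1``; a window is valid
    when it contains only A/C/G/T indices.
    """
    n = idx.shape[0]
    m = n - k + 1
    if m <= 0:
        return np.zeros(0, np.uint64), np.zeros(0, np.bool_)
    codes = np.zeros(m, np.uint64)
    valid = np.zeros(m, np.bool_)
    if k < 32:
        mask_bits = np.uint64((np.uint64(1) << np.uint64(2 * k)) - np.uint64(1))
    else:
        mask_bits = np.uint64(0xFFFFFFFFFFFFFFFF)
    code = np.uint64(0)
    last_bad = -1
    for i in range(n):
        b = idx[i]
        if b > 3:
            last_bad = i
            code = (code << np.uint64(2)) & mask_bits
        else:
            code = ((code << np.uint64(2)) | np.uint64(b)) & mask_bits
        if i >= k - 1:
            o = i - k + 1
            codes[o] = code
            valid[o] = last_bad < o
    return codes, valid


@njit(cache=True)
def window_all_unambiguous(mask, k):
    """Boolean per window: every base mask is a single-base power of two."""
    n = mask.shape[0]
    m = n - k + 1
    out = np.zeros(max(m, 0), np.bool_)
    if m <= 0:
        return out
    last_bad = -1
    for i in range(n):
        v = mask[i]
        single = v == 1 or v == 2 or v == 4 or v == 8
        if not single:
            last_bad = i
        if i >= k - 1:
            out[i - k + 1] = last_bad < i - k + 1
    return out


@njit(cache=True)
def window_no_nx(mask, k):
    """Boolean per window: no N/X (zero-mask) base inside."""
    n = mask.shape[0]
    m = n - k + 1
    out = np.zeros(max(m, 0), np.bool_)
    if m <= 0:
        return out
    last_bad = -1
    for i in range(n):
        if mask[i] == 0:
            last_bad = i
        if i >= k - 1:
            out[i - k + 1] = last_bad < i - k + 1
    return out


@njit(cache=True, inline="always")
def _find_key(keys, code):
    lo = 0
    hi = keys.shape[0]
    while lo < hi:
        mid = (lo + hi) >> 1
        if keys[mid] < code:
            lo = mid + 1
        else:
            hi = mid
    if lo < keys.shape[0] and keys[lo] == code:
        return lo
    return -1


@njit(cache=True, inline="always")
def _uf_find(parent, x):
    r = x
    while parent[r] != r:
        r = parent[r]
    while parent[x] != r:
        nxt = parent[x]
        parent[x] = r
        x = nxt
    return r


@njit(cache=True, inline="always")
def _uf_union(parent, a, b):
    ra = _uf_find(parent, a)
    rb = _uf_find(parent, b)
    if ra != rb:
        if ra < rb:
            parent[rb] = ra
        else:
            parent[ra] = rb


@njit(cache=True)
def sw_score(read, refmask, wlo, whi, dlo, dhi, match, mismatch, gopen, gext):
    """Score-only banded local affine-gap alignment with origin tracking.

    Aligns ``read`` (base indices) against ``refmask[wlo:whi]``; cells are
    restricted to diagonals ``j - i`` in ``[dlo, dhi]`` (DP coordinates,
    diagonal 0 = read start matching window start).

    Returns (score, gstart, gend): global reference coordinates of the
    best local alignment span (half-open).
    """
    L = read.shape[0]
    W = whi - wlo
    if L == 0 or W <= 0:
        return 0, wlo, wlo
    H = np.zeros(W + 1, np.int64)
    O = np.zeros(W + 1, np.int64)
    I = np.full(W + 1, NEG, np.int64)
    OI = np.zeros(W + 1, np.int64)
    best = 0
    borigin = 0
    bend = 0
    for i in range(1, L + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > W:
            jhi = W
        if jlo > jhi:
            continue
        Hdiag = H[jlo - 1]
        Odiag = O[jlo - 1]
        if jlo - 1 - (i - 1) > dhi or jlo - 1 - (i - 1) < dlo:
            # (i-1, jlo-1) outside the band: treat as a fresh start
            Hdiag = 0
            Odiag = jlo - 1
        D = NEG
        OD = 0
        hleft = NEG
        oleft = 0
        rb = read[i - 1]
        for j in range(jlo, jhi + 1):
            m = refmask[wlo + j - 1]
            if rb < 4 and (m >> rb) & 1:
                s = match
            else:
                s = -mismatch
            # vertical (insertion in read): from row i-1, same column
            up_in_band = (j - (i - 1)) <= dhi
            if up_in_band:
                iu_ext = I[j] - gext
                iu_open = H[j] - gopen
            else:
                iu_ext = NEG
                iu_open = NEG
            if iu_ext >= iu_open:
                Iu = iu_ext
                OIu = OI[j]
            else:
                Iu = iu_open
                OIu = O[j]
            # horizontal (deletion: consumes reference)
            d_ext = D - gext
            d_open = hleft - gopen
            if d_ext >= d_open:
                D = d_ext
            else:
                D = d_open
                OD = oleft
            # diagonal
            if Hdiag > 0:
                diag = Hdiag + s
                odg = Odiag
            else:
                diag = s
                odg = j - 1
            # combine: prefer diagonal, then deletion, then insertion
            h = diag
            oh = odg
            if D > h:
                h = D
                oh = OD
            if Iu > h:
                h = Iu
                oh = OIu
            if h < 0:
                h = 0
                oh = j
            Hdiag = H[j]
            Odiag = O[j]
            H[j] = h
            O[j] = oh
            I[j] = Iu
            OI[j] = OIu
            hleft = h
            oleft = oh
            if h > best:
                best = h
                borigin = oh
                bend = j
        # invalidate the column just past the band top for the next row
        if jhi + 1 <= W:
            H[jhi + 1] = 0
            O[jhi + 1] = jhi + 1
            I[jhi + 1] = NEG
        if jlo - 1 >= 1:
            # cells to the left of the band are out of play for later rows
            H[jlo - 1] = 0
            O[jlo - 1] = jlo - 1
            I[jlo - 1] = NEG
    return best, wlo + borigin, wlo + bend


@njit(cache=True)
def sw_traceback(read, refmask, wlo, whi, dlo, dhi,
                 match, mismatch, gopen, gext):
    """Banded local affine-gap alignment with full traceback.

    Returns (score, gstart, ops, lens, n_ops, mismatches, gap_bases).
    ``ops`` uses SAM codes (M=0, I=1, D=2, S=4); the op list covers the
    whole read (M+I+S lengths sum to the read length).  Ties prefer
    diagonal over deletion over insertion.
    """
    L = read.shape[0]
    W = whi - wlo
    max_ops = 2 * L + 4
    ops = np.zeros(max_ops, np.int8)
    lens = np.zeros(max_ops, np.int32)
    if L == 0 or W <= 0:
        ops[0] = OP_S
        lens[0] = L
        n = 1 if L > 0 else 0
        return 0, wlo, ops, lens, n, 0, 0
    H = np.zeros((L + 1, W + 1), np.int64)
    I = np.full((L + 1, W + 1), NEG, np.int64)
    D = np.full((L + 1, W + 1), NEG, np.int64)
    # ptr bits: 0-1 H source (0 stop, 1 diag, 2 del, 3 ins);
    # bit 2: D was an extension; bit 3: I was an extension
    ptr = np.zeros((L + 1, W + 1), np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, L + 1):
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dhi
        if jhi > W:
            jhi = W
        rb = read[i - 1]
        for j in range(jlo, jhi + 1):
            m = refmask[wlo + j - 1]
            if rb < 4 and (m >> rb) & 1:
                s = match
            else:
                s = -mismatch
            p = np.uint8(0)
            iu_ext = I[i - 1, j] - gext
            iu_open = H[i - 1, j] - gopen
            if (j - (i - 1)) > dhi:
                iu_ext = NEG
                iu_open = NEG
            if iu_ext >= iu_open:
                I[i, j] = iu_ext
                p |= np.uint8(8)
            else:
                I[i, j] = iu_open
            d_ext = D[i, j - 1] - gext
            d_open = H[i, j - 1] - gopen
            if (j - 1 - i) < dlo:
                d_ext = NEG
                d_open = NEG
            if d_ext >= d_open:
                D[i, j] = d_ext
                p |= np.uint8(4)
            else:
                D[i, j] = d_open
            hd = H[i - 1, j - 1]
            if (j - 1 - (i - 1)) > dhi or (j - 1 - (i - 1)) < dlo:
                hd = 0
            diag = hd + s if hd > 0 else s
            h = 0
            src = np.uint8(0)
            if diag > h:
                h = diag
                src = np.uint8(1)
            if D[i, j] > h:
                h = D[i, j]
                src = np.uint8(2)
            if I[i, j] > h:
                h = I[i, j]
                src = np.uint8(3)
            H[i, j] = h
            ptr[i, j] = p | src
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    n = 0
    mismatches = 0
    gap_bases = 0
    if best <= 0:
        ops[0] = OP_S
        lens[0] = L
        return 0, wlo, ops, lens, 1, 0, 0
    tail_clip = L - bi
    rops = np.zeros(max_ops, np.int8)
    rlens = np.zeros(max_ops, np.int32)
    rn = 0
    i = bi
    j = bj
    state = 0  # 0 in H, 2 in D, 3 in I
    while True:
        if state == 0:
            src = ptr[i, j] & np.uint8(3)
            if src == 0:
                break
            if src == 1:
                rb = read[i - 1]
                m = refmask[wlo + j - 1]
                if not (rb < 4 and (m >> rb) & 1):
                    mismatches += 1
                if rn > 0 and rops[rn - 1] == OP_M:
                    rlens[rn - 1] += 1
                else:
                    rops[rn] = OP_M
                    rlens[rn] = 1
                    rn += 1
                i -= 1
                j -= 1
                if H[i, j] <= 0:
                    break
            elif src == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            # deletion: consume reference
            if rn > 0 and rops[rn - 1] == OP_D:
                rlens[rn - 1] += 1
            else:
                rops[rn] = OP_D
                rlens[rn] = 1
                rn += 1
            gap_bases += 1
            ext = (ptr[i, j] & np.uint8(4)) != 0
            j -= 1
            state = 2 if ext else 0
        else:
            if rn > 0 and rops[rn - 1] == OP_I:
                rlens[rn - 1] += 1
            else:
                rops[rn] = OP_I
                rlens[rn] = 1
                rn += 1
            gap_bases += 1
            ext = (ptr[i, j] & np.uint8(8)) != 0
            i -= 1
            state = 3 if ext else 0
    head_clip = i
    gstart = wlo + j
    if head_clip > 0:
        ops[n] = OP_S
        lens[n] = head_clip
        n += 1
    for t in range(rn - 1, -1, -1):
        ops[n] = rops[t]
        lens[n] = rlens[t]
        n += 1
    if tail_clip > 0:
        ops[n] = OP_S
        lens[n] = tail_clip
        n += 1
    return best, gstart, ops, lens, n, mismatches, gap_bases


@njit(cache=True)
def align_batch(reads_flat, read_offs, keys, kstarts, kpos,
                refmask, seq_bounds, n_special,
                k, mhp, act, max_loci, band, pad,
                match, mismatch, gopen, gext, mmp,
                out_ncand, out_nhits, out_nreg,
                cand_pos, cand_end, cand_score, cand_strand,
                cand_wlo, cand_whi, cand_dlo, cand_dhi, cand_special):
    """Seed, cluster, select and score-polish a batch of reads.

    For each read: collect seed hits on both strands, group hits whose
    diagonals differ by <= 1 and whose positions lie within a read length
    (transitive closure), keep regions covering >= ``act`` read bases,
    rank by (covered, support, special, position) capped at ``max_loci``,
    then run a banded score-only polish per region.  Candidates must reach
    ``L*match - mmp*L*(match+mismatch)`` (the best score attainable at the
    mismatch-proportion ceiling) to be reported.
    """
    R = read_offs.shape[0] - 1
    maxc = cand_pos.shape[1]

    rev = np.zeros(MAX_READ, np.uint8)
    hpos = np.zeros(MAX_HITS, np.int64)
    hoff = np.zeros(MAX_HITS, np.int64)
    sd = np.zeros(MAX_HITS, np.int64)
    sp = np.zeros(MAX_HITS, np.int64)
    so = np.zeros(MAX_HITS, np.int64)
    tmp = np.zeros(MAX_HITS, np.int64)
    parent = np.zeros(MAX_HITS, np.int64)
    regid = np.full(MAX_HITS, -1, np.int64)
    cov_stamp = np.full(MAX_READ, -1, np.int64)
    stamp_base = 0

    MAXREG = 2 * MAX_HITS
    rg_strand = np.zeros(MAXREG, np.uint8)
    rg_dmin = np.zeros(MAXREG, np.int64)
    rg_dmax = np.zeros(MAXREG, np.int64)
    rg_support = np.zeros(MAXREG, np.int64)
    rg_cov = np.zeros(MAXREG, np.int64)
    rg_key = np.zeros(MAXREG, np.int64)
    rg_gid = np.zeros(MAXREG, np.int64)

    n_seqs = seq_bounds.shape[0] - 1

    for r in range(R):
        s0 = read_offs[r]
        s1 = read_offs[r + 1]
        L = int(s1 - s0)
        out_ncand[r] = 0
        out_nhits[r] = 0
        out_nreg[r] = 0
        if L < k or L > MAX_READ:
            continue
        fwd = reads_flat[s0:s1]
        for t in range(L):
            b = fwd[L - 1 - t]
            rev[t] = 3 - b if b < 4 else 4

        total_hits = 0
        nregions = 0

        for strand in range(2):
            if strand == 0:
                seq = fwd
            else:
                seq = rev[:L]
            codes, valid = rolling_codes(seq, k)
            nh = 0
            for o in range(L - k + 1):
                if not valid[o]:
                    continue
                ki = _find_key(keys, codes[o])
                if ki < 0:
                    continue
                lo = kstarts[ki]
                hi = kstarts[ki + 1]
                cnt = hi - lo
                if cnt > mhp:
                    cnt = mhp
                for c in range(cnt):
                    if nh >= MAX_HITS:
                        break
                    hpos[nh] = kpos[lo + c]
                    hoff[nh] = o
                    nh += 1
            total_hits += nh
            if nh == 0:
                continue
            # lexsort hits by (diagonal, position): stable pos pass first
            order1 = np.argsort(hpos[:nh], kind="mergesort")
            for t in range(nh):
                u = order1[t]
                sp[t] = hpos[u]
                so[t] = hoff[u]
                sd[t] = hpos[u] - hoff[u]
            order2 = np.argsort(sd[:nh], kind="mergesort")
            for t in range(nh):
                tmp[t] = sp[order2[t]]
            for t in range(nh):
                hpos[t] = tmp[t]
            for t in range(nh):
                tmp[t] = so[order2[t]]
            for t in range(nh):
                hoff[t] = tmp[t]
            for t in range(nh):
                tmp[t] = sd[order2[t]]
            for t in range(nh):
                sd[t] = tmp[t]
                sp[t] = hpos[t]
                so[t] = hoff[t]
                parent[t] = t
            # union hits with |d1-d2| <= 1 and |p1-p2| <= L
            cbs = 0        # current diagonal block start
            pbs = -1       # previous-adjacent diagonal block range
            pbe = -1
            for t in range(nh):
                if t > 0 and sd[t] != sd[t - 1]:
                    if sd[t] == sd[t - 1] + 1:
                        # find start of the block that just ended
                        pbs = cbs
                        pbe = t
                    else:
                        pbs = -1
                        pbe = -1
                    cbs = t
                u = t - 1
                while u >= cbs and sp[t] - sp[u] <= L:
                    _uf_union(parent, t, u)
                    u -= 1
                if pbs >= 0:
                    lo2 = pbs
                    hi2 = pbe
                    tgt = sp[t] - L
                    while lo2 < hi2:
                        mid = (lo2 + hi2) >> 1
                        if sp[mid] < tgt:
                            lo2 = mid + 1
                        else:
                            hi2 = mid
                    u = lo2
                    while u < pbe and sp[u] <= sp[t] + L:
                        _uf_union(parent, t, u)
                        u += 1
            # compact components into regions
            first_reg = nregions
            for t in range(nh):
                root = _uf_find(parent, t)
                if regid[root] < 0:
                    if nregions >= MAXREG:
                        continue
                    regid[root] = nregions
                    rg_strand[nregions] = strand
                    rg_dmin[nregions] = sd[t]
                    rg_dmax[nregions] = sd[t]
                    rg_support[nregions] = 0
                    rg_cov[nregions] = 0
                    nregions += 1
                g = regid[root]
                if g < 0:
                    continue
                if sd[t] < rg_dmin[g]:
                    rg_dmin[g] = sd[t]
                if sd[t] > rg_dmax[g]:
                    rg_dmax[g] = sd[t]
                rg_support[g] += 1
                tag = stamp_base + g
                for q in range(so[t], so[t] + k):
                    if cov_stamp[q] != tag:
                        cov_stamp[q] = tag
                        rg_cov[g] += 1
            stamp_base += nregions
            for t in range(nh):
                root = _uf_find(parent, t)
                regid[root] = -1

        out_nhits[r] = total_hits
        if nregions == 0:
            continue

        # rank regions: covered desc, support desc, special first, pos asc;
        # stable sort keeps discovery order on full ties (deterministic)
        nkeep = 0
        for g in range(nregions):
            if rg_cov[g] < act:
                continue
            dmin = rg_dmin[g]
            if dmin < 0:
                dmin = 0
            # special iff start lies before the first genome sequence
            sp_flag = 1 if dmin < seq_bounds[n_special] else 0
            cov = rg_cov[g]
            if cov > 4095:
                cov = 4095
            supp = rg_support[g]
            if supp > 2047:
                supp = 2047
            key = ((np.int64(4096 - cov) << 44)
                   | (np.int64(2048 - supp) << 33)
                   | (np.int64(1 - sp_flag) << 32)
                   | (dmin & np.int64(0xFFFFFFFF)))
            rg_key[nkeep] = key
            rg_gid[nkeep] = g
            nkeep += 1
        if nkeep == 0:
            continue
        rorder = np.argsort(rg_key[:nkeep], kind="mergesort")
        nsel = nkeep if nkeep < max_loci else max_loci
        out_nreg[r] = nsel

        smin = np.int64(np.ceil(L * match - mmp * L * (match + mismatch)
                                - 1e-9))
        nc = 0
        for t in range(nsel):
            g = int(rg_gid[rorder[t]])
            dmin = rg_dmin[g]
            dmax = rg_dmax[g]
            wlo = dmin - pad
            whi = dmax + L + pad
            # clip to the containing sequence
            mid = (dmin + dmax + L) // 2
            if mid < 0:
                mid = 0
            si = np.searchsorted(seq_bounds, mid, side="right") - 1
            if si < 0:
                si = 0
            if si >= n_seqs:
                si = n_seqs - 1
            if wlo < seq_bounds[si]:
                wlo = seq_bounds[si]
            if whi > seq_bounds[si + 1]:
                whi = seq_bounds[si + 1]
            if whi - wlo < k:
                continue
            dlo_rel = int(dmin - wlo - band)
            dhi_rel = int(dmax - wlo + band)
            if rg_strand[g] == 0:
                seq = fwd
            else:
                seq = rev[:L]
            score, gs, ge = sw_score(seq, refmask, wlo, whi,
                                     dlo_rel, dhi_rel,
                                     match, mismatch, gopen, gext)
            if score < smin:
                continue
            if nc >= maxc:
                break
            cand_pos[r, nc] = gs
            cand_end[r, nc] = ge
            cand_score[r, nc] = score
            cand_strand[r, nc] = rg_strand[g]
            cand_wlo[r, nc] = wlo
            cand_whi[r, nc] = whi
            cand_dlo[r, nc] = dlo_rel
            cand_dhi[r, nc] = dhi_rel
            cand_special[r, nc] = 1 if si < n_special else 0
            nc += 1
        out_ncand[r] = nc
    return 0
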