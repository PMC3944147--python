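"""Independent reference implementations used as test oracles.

These deliberately share no code with the package: a textbook
three-matrix local affine-gap DP (score only), a naive k-mer scan, and a
naive all-pairs seed grouping.
"""

NEG = float("-inf")

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
}


def gotoh_local_score(read: str, ref: str, match: int, mismatch: int,
                      gap_open: int, gap_extend: int) -> int:
    """Textbook Smith-Waterman-Gotoh, full matrices, score only.

    Gap of length g costs gap_open + (g-1)*gap_extend.  Reference may
    contain IUPAC codes; a read base contained in the code is a match.
    """
    n, m = len(read), len(ref)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (del)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (ins)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            allowed = IUPAC_SETS.get(ref[j - 1], "")
            s = match if read[i - 1] in allowed else -mismatch
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          H[i][j - 1] - gap_open)
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def naive_kmer_positions(seq: str, kmer: str) -> list[int]:
    """All exact occurrences of a k-mer by string scan."""
    out = []
    start = 0
    while True:
        i = seq.find(kmer, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def naive_group_hits(hits, read_len: int):
    """All-pairs transitive grouping of (diag, pos) hits: two hits join
    when |d1-d2| <= 1 and |p1-p2| <= read_len.  Returns a list of sets
    of hit indices."""
    n = len(hits)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(hits[i][0] - hits[j][0]) <= 1 and \
                    abs(hits[i][1] - hits[j][1]) <= read_len:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
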