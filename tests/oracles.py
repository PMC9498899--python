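"""Independent brute-force oracles used by the test suite.

Each oracle re-implements a scanning or numeric rule from first principles
(enumeration, sliding windows, dense grids, textbook DP) without touching
the package's own matching machinery, so agreement is a genuine
cross-check and not a tautology.
"""

from __future__ import annotations

_NES_C1 = set("LV")
_NES_C2 = set("LIVFM")
_NES_C3 = set("LIMTKD")


def enumerate_ccch(seq, bounds=((4, 15), (4, 7), (3, 4)), greedy=True):
    """Left-to-right non-overlapping CCCH matching by exhaustive enumeration.

    At each scan position, every (c1, c2, c3, h) quadruple within the
    spacing bounds is enumerated; the leftmost eligible c1 wins and the
    lexicographically largest (smallest, if lazy) feasible (d1, d2, d3)
    is chosen there. Returns (start, end, d1, d2, d3) tuples.
    """
    (lo1, hi1), (lo2, hi2), (lo3, hi3) = bounds
    out = []
    pos, n = 0, len(seq)
    while pos < n:
        chosen = None
        for c1 in range(pos, n):
            if seq[c1] != "C":
                continue
            feasible = []
            for d1 in range(lo1, hi1 + 1):
                c2 = c1 + 1 + d1
                if c2 >= n or seq[c2] != "C":
                    continue
                for d2 in range(lo2, hi2 + 1):
                    c3 = c2 + 1 + d2
                    if c3 >= n or seq[c3] != "C":
                        continue
                    for d3 in range(lo3, hi3 + 1):
                        h = c3 + 1 + d3
                        if h < n and seq[h] == "H":
                            feasible.append((d1, d2, d3))
            if feasible:
                chosen = (c1, max(feasible) if greedy else min(feasible))
                break
        if chosen is None:
            break
        c1, (d1, d2, d3) = chosen
        end = c1 + d1 + d2 + d3 + 4
        out.append((c1, end, d1, d2, d3))
        pos = end
    return out


def sliding_window_nes(seq):
    """Non-overlapping greedy NES matching by testing every 9/10/11-mer.

    At each start, spacer pairs are tried in the backtracking order a
    greedy regex uses: (3,3), (3,2), (2,3), (2,2); the leftmost matching
    start wins and scanning resumes at the match end. Returns (start, end).
    """
    hits = []
    pos, n = 0, len(seq)
    while pos <= n - 9:
        found = None
        for start in range(pos, n - 8):
            if seq[start] not in _NES_C1:
                continue
            for s1 in (3, 2):
                for s2 in (3, 2):
                    i2 = start + 1 + s1        # [LIVFM]
                    il = i2 + 1 + s2           # mandatory L
                    i3 = il + 2                # [LIMTKD]
                    if i3 >= n:
                        continue
                    if (
                        seq[i2] in _NES_C2
                        and seq[il] == "L"
                        and seq[i3] in _NES_C3
                    ):
                        found = (start, i3 + 1)
                        break
                if found:
                    break
            if found:
                break
        if found is None:
            break
        hits.append(found)
        pos = found[1]
    return hits


def gotoh_score(a, b, match=1.0, mismatch=0.0, gap_open=-10.0, gap_extend=-0.5):
    """Optimal global affine-gap alignment score (textbook three-matrix DP).

    gap_open is the score of a gap's first residue, gap_extend of each
    subsequent one.
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    return max(M[n][m], X[n][m], Y[n][m])


def grid_search_pi(charge_fn, step=1e-4):
    """Brute-force pI: the pH on a dense grid where |charge| is smallest."""
    best_ph, best_abs = 0.0, float("inf")
    ph = 0.0
    while ph <= 14.0:
        c = abs(charge_fn(ph))
        if c < best_abs:
            best_ph, best_abs = ph, c
        ph += step
    return best_ph
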