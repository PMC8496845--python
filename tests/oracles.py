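"""Independent oracles used by the test suite.

These deliberately do not share code with the package:

* ``enumerate_local_score`` — exhaustive enumeration of every local
  alignment (all substring pairs x all monotone alignment paths) with
  affine gap costs; exponential, usable only for tiny sequences.
* ``gotoh_local_score`` — an affine-gap local DP written independently
  (numba-jitted), validated against the enumerator on tiny pairs and then
  used as the oracle for larger exhaustive sweeps.
* ``enumerate_max_pairs`` — exhaustive enumeration of all nested RNA
  secondary structures of a short sequence (min hairpin loop 3, WC+GU),
  the oracle for the Nussinov engine.
"""

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# alignment oracles


def _global_affine_paths(a, b, match, mismatch, gap_open, gap_extend):
    """Best global alignment score of a vs b by exhaustive path recursion.

    State: (i, j, last) where last in {M, A-gap, B-gap} for affine costs.
    Deliberately unmemoized: the recursion enumerates every alignment path,
    so this stays independent of any DP implementation.  Tiny inputs only.
    """

    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            sub = match if a[i] == b[j] else mismatch
            best = max(best, sub + rec(i + 1, j + 1, 0))
        if i < len(a):  # gap in b
            cost = gap_extend if last == 1 else gap_open
            best = max(best, -cost + rec(i + 1, j, 1))
        if j < len(b):  # gap in a
            cost = gap_extend if last == 2 else gap_open
            best = max(best, -cost + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


def enumerate_local_score(a, b, match=5.0, mismatch=-4.0, gap_open=8.0, gap_extend=8.0):
    """Max over all substring pairs of the best global affine alignment
    score; the empty alignment scores 0."""
    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    s = _global_affine_paths(
                        a[i:j], b[k:l], match, mismatch, gap_open, gap_extend
                    )
                    best = max(best, s)
    return best


@njit(cache=False)
def _gotoh(a, b, match, mismatch, gap_open, gap_extend):
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (b consumed)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (a consumed)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            h = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            H[i, j] = h
            if h > best:
                best = h
    return best


def gotoh_local_score(a, b, match=5.0, mismatch=-4.0, gap_open=8.0, gap_extend=8.0):
    """Independent affine local alignment DP (gap of length n costs
    gap_open + (n-1)*gap_extend)."""
    if not a or not b:
        return 0.0
    ca = np.frombuffer(a.encode(), dtype=np.uint8)
    cb = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(_gotoh(ca, cb, match, mismatch, gap_open, gap_extend))


# ---------------------------------------------------------------------------
# structure oracle

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


def enumerate_max_pairs(seq, min_loop=3):
    """Maximum pair count over ALL nested structures, by unmemoized
    recursion over 'first base unpaired or paired with k' (every nested
    structure is visited; usable for ~12-mers)."""
    s = seq.upper().replace("T", "U")

    def rec(i, j):
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in _PAIRS:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1) if s else 0
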