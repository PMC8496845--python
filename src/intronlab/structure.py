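"""RNA secondary-structure scoring.

The default engine is a Nussinov maximum base-pairing dynamic program
(Watson-Crick plus G:U wobble pairs, minimum hairpin loop of 3 unpaired
bases).  Its score, minus the number of pairs in the optimal structure, is
used as a folding-energy (dG) proxy throughout the package: more pairing =
more negative = more structured.  An external minimum-free-energy engine
(ViennaRNA's ``RNAfold`` executable, when available on PATH) can be plugged
in for true dG values; all package defaults and tests use the
dependency-free Nussinov engine.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass

import numpy as np

__all__ = ["StructureScore", "nussinov", "fold_window", "rnafold_window"]

_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}
MIN_LOOP = 3


def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    if any(c not in "ACGUN" for c in s):
        raise ValueError(f"non-IUPAC symbol in sequence: {seq!r}")
    return s


@dataclass
class StructureScore:
    """Predicted structure of a short window.

    ``score`` is -(number of base pairs) for the Nussinov engine (a dG
    proxy, <= 0 whenever at least one pair is possible) or the MFE in
    kcal/mol for an external engine.  ``pairing_mask[i]`` is True when
    position i is base-paired in the predicted structure.
    """

    window: str
    score: float
    pairing_mask: np.ndarray
    pairs: list

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _PAIRS


def nussinov(seq: str, min_loop: int = MIN_LOOP):
    """Maximum base-pairing DP; returns (n_pairs, pairs list, mask)."""
    s = _to_rna(seq)
    n = len(s)
    if n == 0:
        return 0, [], np.zeros(0, dtype=bool)
    M = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = M[i + 1, j]  # i unpaired
            # i paired with some k in (i+min_loop, j]
            for k in range(i + min_loop + 1, j + 1):
                if _can_pair(s[i], s[k]):
                    left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                    right = M[k + 1, j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            M[i, j] = best
    # traceback
    pairs = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        if M[i, j] == M[i + 1, j]:
            stack.append((i + 1, j))
            continue
        for k in range(i + min_loop + 1, j + 1):
            if _can_pair(s[i], s[k]):
                left = M[i + 1, k - 1] if k - 1 >= i + 1 else 0
                right = M[k + 1, j] if k + 1 <= j else 0
                if M[i, j] == 1 + left + right:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    break
    mask = np.zeros(n, dtype=bool)
    for i, j in pairs:
        mask[i] = mask[j] = True
    return int(M[0, n - 1]), pairs, mask


def fold_window(seq: str, engine: str = "nussinov") -> StructureScore:
    """Fold a short window (<= ~60 nt) and return its structure score.

    ``engine`` is ``"nussinov"`` (default, dependency-free) or
    ``"rnafold"`` (requires the ViennaRNA executable).
    """
    if engine == "rnafold":
        return rnafold_window(seq)
    if engine != "nussinov":
        raise ValueError(f"unknown fold engine: {engine}")
    n_pairs, pairs, mask = nussinov(seq)
    return StructureScore(window=seq, score=-float(n_pairs), pairing_mask=mask, pairs=pairs)


def rnafold_window(seq: str) -> StructureScore:
    """Minimum-free-energy fold via the external ``RNAfold`` executable."""
    s = _to_rna(seq)
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=s + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    structure, mfe = out[1].rsplit(" ", 1)
    structure = structure.strip()
    mfe = float(mfe.strip("() "))
    stack, pairs = [], []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    mask = np.zeros(len(s), dtype=bool)
    for i, j in pairs:
        mask[i] = mask[j] = True
    return StructureScore(window=seq, score=mfe, pairing_mask=mask, pairs=pairs)
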