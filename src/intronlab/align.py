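"""Local-alignment kernel and junction scoring.

All read classification in this package rests on two primitives:

* a normalized junction score — a Smith-Waterman local alignment of a short
  (nominally 40 nt) splice-junction reference against a read, divided by the
  junction's self-alignment score.  A junction is "positively aligned" when
  the normalized score exceeds a threshold (default 0.8).
* a gapped design alignment — an end-to-end alignment of a read against the
  full unspliced design under a high gap-open / low gap-extend penalty, so
  that a spliced-out intron shows up as one long uninterrupted gap on the
  reference.  A read is called as a cryptic spliced isoform when the
  normalized score and mismatch count pass the configured call rule.

The pairwise engine is Biopython's :class:`Bio.Align.PairwiseAligner`
(affine gaps, C implementation).  ``N`` bases match nothing: they score as a
mismatch against every base including ``N``.

Note on the gapped mode: under the default cryptic parameters (gap open
100, extend 1) a purely *local* alignment of a spliced read never bridges
the excised intron when one flanking exon is short — dropping the short
exon is cheaper than paying the gap.  The amplicons this package deals with
always cover the entire design (barcode + variable region) minus any
spliced intron, so the gapped mode aligns the read end-to-end (global with
affine internal gaps), under which the excised intron is necessarily the
single maximal reference gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignParams",
    "JunctionAlignment",
    "GapAlignment",
    "smith_waterman",
    "junction_score",
    "gapped_design_alignment",
    "DEFAULT_PARAMS",
    "CRYPTIC_PARAMS",
]

_ALPHABET = "ACGTN"


def _substitution_matrix(match: float, mismatch: float):
    n = len(_ALPHABET)
    m = np.full((n, n), float(mismatch))
    for i, c in enumerate(_ALPHABET):
        if c != "N":
            m[i, i] = float(match)
    return substitution_matrices.Array(alphabet=_ALPHABET, dims=2, data=m)


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring parameters.

    ``gap_open`` and ``gap_extend`` are positive costs; a gap of length n
    costs ``gap_open + (n - 1) * gap_extend``.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 8.0
    gap_extend: float = 8.0

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are positive costs")


#: Matlab swalign nucleotide defaults (NUC44-like), used for junction scoring.
DEFAULT_PARAMS = AlignParams(match=5.0, mismatch=-4.0, gap_open=8.0, gap_extend=8.0)

#: Long-gap parameters for cryptic-isoform discovery.
CRYPTIC_PARAMS = AlignParams(match=5.0, mismatch=-4.0, gap_open=100.0, gap_extend=1.0)


@lru_cache(maxsize=32)
def _local_aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = _substitution_matrix(params.match, params.mismatch)
    a.open_gap_score = -params.gap_open
    a.extend_gap_score = -params.gap_extend
    return a


@lru_cache(maxsize=32)
def _global_aligner(params: AlignParams) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = _substitution_matrix(params.match, params.mismatch)
    a.open_gap_score = -params.gap_open
    a.extend_gap_score = -params.gap_extend
    return a


@dataclass
class JunctionAlignment:
    raw: float
    self_score: float
    normalized: float
    positive: bool


@dataclass
class GapAlignment:
    """Result of a gapped design alignment.

    ``gaps`` are reference (design) intervals, 1-based closed, ordered;
    ``intron`` is the single longest gap (ties broken toward 5').
    """

    normalized: float
    mismatches: int
    gaps: list = field(default_factory=list)

    @property
    def intron(self):
        if not self.gaps:
            return None
        return max(self.gaps, key=lambda g: (g[1] - g[0], -g[0]))


def sw_score(a: str, b: str, params: AlignParams = DEFAULT_PARAMS) -> float:
    """Smith-Waterman local alignment score (score only, fast path)."""
    if not a or not b:
        return 0.0
    return float(_local_aligner(params).score(a, b))


def _alignment_stats(alignment):
    """Aligned reference intervals, mismatch count and reference gap
    intervals (1-based closed) of a Biopython alignment."""
    target_blocks, query_blocks = alignment.aligned
    seq_t = str(alignment.target)
    seq_q = str(alignment.query)
    mismatches = 0
    intervals = []
    for (ts, te), (qs, qe) in zip(target_blocks, query_blocks):
        intervals.append((int(ts) + 1, int(te)))
        for x, y in zip(seq_t[ts:te], seq_q[qs:qe]):
            if x != y or x == "N" or y == "N":
                mismatches += 1
    gaps = []
    for k in range(len(target_blocks) - 1):
        te = int(target_blocks[k][1])
        ts = int(target_blocks[k + 1][0])
        if ts > te:  # reference advances with no query: a deletion gap
            gaps.append((te + 1, ts))
    return intervals, mismatches, gaps


def smith_waterman(a: str, b: str, params: AlignParams = DEFAULT_PARAMS):
    """Maximal local alignment of ``a`` vs ``b`` under affine gaps.

    Returns ``(score, aligned_intervals_on_a, mismatch_count)``; empty
    inputs score 0.
    """
    if not a or not b:
        return 0.0, [], 0
    aligner = _local_aligner(params)
    alignment = aligner.align(a, b)[0]
    intervals, mismatches, _ = _alignment_stats(alignment)
    return float(alignment.score), intervals, mismatches


def junction_score(
    junction: str,
    read: str,
    params: AlignParams = DEFAULT_PARAMS,
    threshold: float = 0.8,
) -> JunctionAlignment:
    """Normalized junction alignment score.

    normalized = SW(junction, read) / SW(junction, junction); the junction
    is positively aligned when normalized > threshold.  Junctions shorter
    than the nominal 40 nt (truncated at oligo ends) are used at their
    natural length — the self-score denominator renormalizes them.
    """
    if not junction:
        raise ValueError("junction must be nonempty")
    self_score = params.match * len(junction)
    if junction in read:  # exact containment short-circuits the DP
        return JunctionAlignment(self_score, self_score, 1.0, True)
    raw = sw_score(junction, read, params)
    normalized = raw / self_score
    return JunctionAlignment(raw, self_score, normalized, normalized > threshold)


def canonical_gap(reference: str, gap: tuple) -> tuple:
    """Shift a deletion interval maximally 5' among its equivalents.

    Removing (a, b) and (a-1, b-1) from the reference yields the same
    sequence whenever reference[a-2] == reference[b-1] (splice-junction
    coordinate wobble); reads cannot distinguish equivalent intervals, so
    all interval reporting uses the 5'-most representative.
    """
    a, b = gap
    while a > 1 and reference[a - 2] == reference[b - 1]:
        a -= 1
        b -= 1
    return (a, b)


def gapped_design_alignment(
    read: str,
    design: str,
    params: AlignParams = CRYPTIC_PARAMS,
    score_threshold: float = 0.7,
    max_mismatch: int = 6,
    score_cmp: str = "lt",
    min_gap: int = 4,
    allow_end_gaps: bool = False,
):
    """Align a read end-to-end against the full unspliced design and call a
    cryptic spliced isoform.

    The candidate intron is the single longest uninterrupted reference gap
    (ties toward 5').  The call requires the normalized score to pass the
    configured comparison against ``score_threshold`` (``score_cmp`` is
    ``"lt"`` by default, or ``"gt"``) and strictly
    fewer than ``max_mismatch`` mismatches.  Returns a :class:`GapAlignment`
    or ``None`` (no-call).

    The normalization denominator is the design self-score.
    """
    if not read or not design:
        return None
    aligner = _global_aligner(params)
    alignment = aligner.align(design, read)[0]
    _, mismatches, gaps = _alignment_stats(alignment)
    # end gaps (read shorter than the design at an edge) are not introns
    target_blocks = alignment.aligned[0]
    if len(target_blocks):
        first_t = int(target_blocks[0][0])
        last_t = int(target_blocks[-1][1])
        edge_gaps = []
        if first_t > 0:
            edge_gaps.append((1, first_t))
        if last_t < len(design):
            edge_gaps.append((last_t + 1, len(design)))
        if allow_end_gaps:
            gaps = edge_gaps[:1] + gaps + edge_gaps[1:]
    gaps = [canonical_gap(design, g) for g in gaps if g[1] - g[0] + 1 >= min_gap]
    if not gaps:
        return None
    self_score = params.match * len(design)
    normalized = max(float(alignment.score), 0.0) / self_score
    ok = normalized < score_threshold if score_cmp == "lt" else normalized > score_threshold
    if not ok or mismatches >= max_mismatch:
        return None
    return GapAlignment(normalized=normalized, mismatches=mismatches, gaps=gaps)
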