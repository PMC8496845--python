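"""Resampling and summary statistics for intron architecture.

The centrepiece is the 3'SS-motif avoidance test: in a genome, the
frequency of the acceptor-site motif ({C,T}AG by default) is profiled
around intron 3' ends (position 0 = last intron base, negative offsets
intronic, motif anchored at its first base), and the observed window mean
is compared with control sets of N random coding-region positions.  The
resampling p-value for a window W is

    p = #{control sets with mean motif frequency over W below the intron
          set's mean} / n_controls

computed for an upstream window (offsets -32..-3) and a downstream window
(+1..+30).  A low p flags significant *depletion* (avoidance) of the motif
near real intron ends.

Also here: feature-binned splicing-efficiency summaries with a bin-trend
correlation, the orthologous-intron delta-SE comparison, Cramer's V on a
3x3 SE-category contingency table, and the two randomization controls
(multiple-barcode variance; mock SE-vs-abundance correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AvoidanceResult",
    "motif_indicator",
    "motif_profile",
    "avoidance_test",
    "binned_se",
    "delta_se",
    "cramers_v",
    "barcode_variance_control",
    "randomized_abundance_control",
]

DEFAULT_MOTIFS = ("CAG", "TAG")
UPSTREAM_WINDOW = (-32, -3)
DOWNSTREAM_WINDOW = (1, 30)

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class AvoidanceResult:
    offsets: np.ndarray
    intron_profile: np.ndarray
    control_profile: np.ndarray
    p_upstream: float
    p_downstream: float
    n_controls: int
    n_introns: int
    log: list = field(default_factory=list)


def motif_indicator(seq: str, motifs=DEFAULT_MOTIFS) -> np.ndarray:
    """Boolean array: position i is True when a motif starts at i."""
    n = len(seq)
    k = len(motifs[0])
    ind = np.zeros(n, dtype=bool)
    arr = np.frombuffer(seq.encode(), dtype="S1")
    for m in motifs:
        if len(m) != k:
            raise ValueError("all motifs must share a length")
        hit = np.ones(max(n - k + 1, 0), dtype=bool)
        for j, c in enumerate(m):
            hit &= arr[j : n - k + 1 + j] == c.encode()
        ind[: len(hit)] |= hit
    return ind


class _OrientedGenome:
    """Per-(contig, strand) motif indicators with prefix sums, so a window
    sum around any anchor is O(1)."""

    def __init__(self, contigs: dict, motifs=DEFAULT_MOTIFS):
        self.motifs = motifs
        self.ind = {}
        self.cum = {}
        self.length = {}
        for name, seq in contigs.items():
            seq = str(seq).upper()
            self.length[name] = len(seq)
            for strand, s in (("+", seq), ("-", _revcomp(seq))):
                ind = motif_indicator(s, motifs)
                self.ind[(name, strand)] = ind
                self.cum[(name, strand)] = np.concatenate([[0], np.cumsum(ind)])

    def oriented_pos(self, chrom: str, pos0: int, strand: str) -> int:
        """Map a 0-based genomic position to the oriented coordinate
        (position along the strand's 5'->3' sequence)."""
        if strand == "+":
            return pos0
        return self.length[chrom] - 1 - pos0

    def window_counts(self, keys, anchors, lo: int, hi: int) -> np.ndarray:
        """Number of motif starts at offsets lo..hi (inclusive) from each
        anchor (anchors are oriented coordinates of offset 0).  Anchors are
        processed per unique (contig, strand) group, vectorized."""
        anchors = np.asarray(anchors, dtype=np.int64)
        out = np.empty(len(anchors), dtype=np.int64)
        order = {}
        for i, key in enumerate(keys):
            order.setdefault(key, []).append(i)
        for key, idxs in order.items():
            cum = self.cum[key]
            n = len(cum) - 1
            ii = np.array(idxs, dtype=np.int64)
            a = anchors[ii]
            s = np.clip(a + lo, 0, n)
            e = np.clip(a + hi + 1, 0, n)
            out[ii] = cum[e] - cum[s]
        return out


def _intron_anchors(genome: _OrientedGenome, introns: pd.DataFrame, margin: int):
    """Oriented anchor (offset-0 position = last intron base) per intron;
    introns too close to a contig edge are excluded with a log entry."""
    keys, anchors, log = [], [], []
    for r in introns.itertuples():
        strand = r.strand
        end0 = (r.end - 1) if strand == "+" else r.start  # 0-based last intron base
        a = genome.oriented_pos(r.chrom, end0, strand)
        n = genome.length[r.chrom]
        if a - margin < 0 or a + margin >= n:
            log.append(f"excluded intron {getattr(r, 'name', r.Index)}: near contig edge")
            continue
        keys.append((r.chrom, strand))
        anchors.append(a)
    return keys, np.array(anchors, dtype=np.int64), log


def motif_profile(
    contigs: dict,
    introns: pd.DataFrame,
    motifs=DEFAULT_MOTIFS,
    window=(-50, 30),
) -> tuple:
    """Positional motif frequency f(i) around intron 3' ends.

    ``introns`` is BED-like (0-based half-open ``start``/``end``, with
    ``chrom`` and ``strand``).  f(i) = fraction of introns with a motif
    whose first base sits at offset i from the last intron base.
    Returns (offsets, frequencies, exclusion log).
    """
    genome = _OrientedGenome(contigs, motifs)
    lo, hi = window
    margin = max(abs(lo), abs(hi)) + len(motifs[0])
    keys, anchors, log = _intron_anchors(genome, introns, margin)
    if len(anchors) == 0:
        raise ValueError("no usable introns")
    offsets = np.arange(lo, hi + 1)
    freqs = np.zeros(len(offsets))
    for j, off in enumerate(offsets):
        freqs[j] = genome.window_counts(keys, anchors, off, off).mean()
    return offsets, freqs, log


def avoidance_test(
    contigs: dict,
    introns: pd.DataFrame,
    coding_regions: pd.DataFrame,
    motifs=DEFAULT_MOTIFS,
    n_controls: int = 100_000,
    seed=None,
    upstream_window=UPSTREAM_WINDOW,
    downstream_window=DOWNSTREAM_WINDOW,
    profile_window=(-50, 30),
) -> AvoidanceResult:
    """Motif-avoidance resampling test around intron 3' ends.

    Each control set re-anchors the N introns at N random coding-region
    positions (same strand orientation as the sampled CDS) and measures the
    same window means.  p-values are the fraction of control sets whose
    window mean falls below the introns' window mean; resolution is
    1/n_controls.
    """
    if len(coding_regions) == 0:
        raise ValueError("coding_regions must be nonempty")
    log = []
    if n_controls < 100:
        log.append("warning: n_controls < 100 gives a very coarse p-value")
    rng = np.random.default_rng(seed)
    genome = _OrientedGenome(contigs, motifs)
    lo_p, hi_p = profile_window
    margin = max(abs(lo_p), abs(hi_p), 33) + len(motifs[0])
    keys, anchors, exc = _intron_anchors(genome, introns, margin)
    log.extend(exc)
    n_introns = len(anchors)
    if n_introns == 0:
        raise ValueError("no usable introns")

    # candidate coding anchors (oriented), away from contig edges
    cand_keys, cand_chunks = [], []
    for r in coding_regions.itertuples():
        n = genome.length[r.chrom]
        pos0 = np.arange(r.start, r.end, dtype=np.int64)
        a = pos0 if r.strand == "+" else n - 1 - pos0
        a = a[(a >= margin) & (a < n - margin)]
        cand_keys.extend([(r.chrom, r.strand)] * len(a))
        cand_chunks.append(a)
    cand_pos = (
        np.concatenate(cand_chunks) if cand_chunks else np.empty(0, dtype=np.int64)
    )
    n_cand = len(cand_pos)
    if n_cand == 0:
        raise ValueError("no usable coding positions")
    replace = n_cand < n_introns
    if replace:
        log.append("fewer coding positions than introns: sampling with replacement")

    # precompute per-candidate window counts once; a control set is then a
    # mean over a random index subset
    def window_sum(keys_, anchors_, win):
        return genome.window_counts(keys_, anchors_, win[0], win[1])

    cand_up = window_sum(cand_keys, cand_pos, upstream_window)
    cand_down = window_sum(cand_keys, cand_pos, downstream_window)
    intron_up = window_sum(keys, anchors, upstream_window).mean()
    intron_down = window_sum(keys, anchors, downstream_window).mean()

    idx = rng.integers(0, n_cand, size=(n_controls, n_introns))
    ctrl_up = cand_up[idx].mean(axis=1)
    ctrl_down = cand_down[idx].mean(axis=1)
    p_up = float(np.count_nonzero(ctrl_up < intron_up)) / n_controls
    p_down = float(np.count_nonzero(ctrl_down < intron_down)) / n_controls

    offsets = np.arange(lo_p, hi_p + 1)
    intron_profile = np.array(
        [window_sum(keys, anchors, (o, o)).mean() for o in offsets]
    )
    ctrl_sub = idx[: min(1000, n_controls)]
    control_profile = np.array(
        [
            window_sum(cand_keys, cand_pos, (o, o))[ctrl_sub.ravel()].mean()
            for o in offsets
        ]
    )
    return AvoidanceResult(
        offsets=offsets,
        intron_profile=intron_profile,
        control_profile=control_profile,
        p_upstream=p_up,
        p_downstream=p_down,
        n_controls=n_controls,
        n_introns=n_introns,
        log=log,
    )


# ---------------------------------------------------------------------------
# binned feature analyses


def binned_se(
    values: pd.Series | np.ndarray,
    se: pd.Series | np.ndarray,
    bin_edges,
) -> dict:
    """Bin SE values by a feature; report per-bin distributions and the
    Pearson correlation of bin centers vs bin mean SE.

    Empty bins are reported (count 0), not dropped.  A constant-SE input
    yields an undefined correlation, flagged with ``trend_defined=False``.
    """
    values = np.asarray(values, dtype=float)
    se = np.asarray(se, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(values, edges[1:-1])
    centers = 0.5 * (edges[:-1] + edges[1:])
    bins = []
    for b in range(len(centers)):
        vals = se[which == b]
        bins.append(
            {
                "center": float(centers[b]),
                "count": int(vals.size),
                "mean_se": float(vals.mean()) if vals.size else np.nan,
                "median_se": float(np.median(vals)) if vals.size else np.nan,
                "values": vals,
            }
        )
    filled = [b for b in bins if b["count"] > 0]
    xs = np.array([b["center"] for b in filled])
    ys = np.array([b["mean_se"] for b in filled])
    if len(filled) < 3 or np.allclose(ys, ys[0]):
        trend = {"r": np.nan, "p": np.nan, "trend_defined": False}
    else:
        r, p = sps.pearsonr(xs, ys)
        trend = {"r": float(r), "p": float(p), "trend_defined": True}
    return {"bins": bins, **trend}


def u_content(seq: str) -> float:
    return seq.count("T") / len(seq) if seq else np.nan


def y_content(seq: str) -> float:
    return (seq.count("T") + seq.count("C")) / len(seq) if seq else np.nan


def c_fraction_of_y(seq: str) -> float:
    y = seq.count("T") + seq.count("C")
    return seq.count("C") / y if y else 0.0


def three_ss_upstream_window(variant, width: int = 20) -> str:
    """The window immediately upstream of the designed 3'SS (U/Y-tract)."""
    start, end = variant.introns[0]
    seq = variant.sequence
    return seq[max(0, end - 3 - width) : end - 3]


# ---------------------------------------------------------------------------
# ortholog comparison, Cramer's V, controls


def delta_se(se_table: pd.DataFrame, orthology: pd.DataFrame):
    """Per-gene SE difference of each ortholog intron vs its S. cerevisiae
    counterpart, with a per-species percent-better summary.

    ``se_table``: variant_id, se.  ``orthology``: variant_id, gene, species
    (the reference species rows carry ``species == 'S.cerevisiae'``).
    """
    se = se_table.set_index("variant_id")["se"]
    merged = orthology.copy()
    merged["se"] = merged["variant_id"].map(se)
    ref = (
        merged[merged["species"] == "S.cerevisiae"]
        .dropna(subset=["se"])
        .set_index("gene")["se"]
    )
    rows, skipped = [], []
    for r in merged[merged["species"] != "S.cerevisiae"].itertuples():
        if r.gene not in ref.index or pd.isna(r.se):
            skipped.append(r.variant_id)
            continue
        rows.append((r.gene, r.species, float(r.se - ref[r.gene])))
    pairs = pd.DataFrame(rows, columns=["gene", "species", "delta_se"])
    summary = (
        pairs.groupby("species")["delta_se"]
        .agg(n="size", percent_better=lambda d: 100.0 * float((d > 0).mean()))
        .reset_index()
    )
    return pairs, summary, skipped


def categorize_se(se, edges=(0.0, 0.5)) -> np.ndarray:
    """Three SE classes: unspliced (SE == low edge), intermediate
    (low < SE <= mid), high (SE > mid)."""
    se = np.asarray(se, dtype=float)
    out = np.where(se <= edges[0], 0, np.where(se <= edges[1], 1, 2))
    return out


def cramers_v(values_a, values_b, edges=(0.0, 0.5)):
    """Cramer's V from the 3x3 contingency table of SE categories.

    phi_C = sqrt(chi2 / (n * (k - 1))), k = 3.  A table with an all-zero
    row AND column margin for the same missing class is reduced; if fewer
    than 2 classes remain on either side phi_C is undefined (NaN, flagged).
    """
    a = categorize_se(values_a, edges)
    b = categorize_se(values_b, edges)
    if len(a) != len(b):
        raise ValueError("inputs must have equal length")
    table = np.zeros((3, 3), dtype=np.int64)
    for i, j in zip(a, b):
        table[i, j] += 1
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    sub = table[np.ix_(rows, cols)]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        return {"phi_c": np.nan, "table": table, "defined": False}
    chi2 = sps.chi2_contingency(sub, correction=False)[0]
    n = table.sum()
    k = min(3, min(sub.shape))
    phi = float(np.sqrt(chi2 / (n * (k - 1))))
    return {"phi_c": phi, "table": table, "defined": True}


def barcode_variance_control(
    se: pd.Series | np.ndarray,
    group_ids: pd.Series | np.ndarray,
    n_shuffles: int = 10_000,
    seed=None,
):
    """Within-group SE variance of multi-barcode design groups vs shuffled
    groups.

    Groups are designs synthesized under several barcodes; only groups
    whose SE values are not all zero contribute.  The null re-forms groups
    of the same sizes from the pooled variants; the empirical p is the
    fraction of shuffles with mean variance <= observed.
    """
    df = pd.DataFrame({"se": np.asarray(se, dtype=float), "g": np.asarray(group_ids)})
    df = df.dropna()
    sizes = df.groupby("g").size()
    multi = sizes[sizes >= 2]
    if multi.empty:
        raise ValueError("no multi-barcode groups")
    df = df[df["g"].isin(multi.index)]

    def mean_var(frame):
        out = []
        for _, g in frame.groupby("g"):
            if (g["se"] != 0).any():
                out.append(g["se"].var(ddof=1))
        return float(np.mean(out)) if out else np.nan

    observed = mean_var(df)
    rng = np.random.default_rng(seed)
    vals = df["se"].to_numpy()
    labels = df["g"].to_numpy()
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(len(vals))
        null[s] = mean_var(pd.DataFrame({"se": vals[perm], "g": labels}))
    p = float(np.count_nonzero(null <= observed) + 1) / (n_shuffles + 1)
    if observed == 0 and np.all(null > 0):
        p = 0.0
    return {"observed": observed, "null": null, "p": p}


def randomized_abundance_control(
    n: int = 5000,
    mu: float = 0.0,
    sigma: float = 1.0,
    seed=None,
):
    """Mock-variant control: SE vs abundance under the null.

    Unspliced and spliced RNA levels are drawn independently from a
    log-normal; SE = spliced / (spliced + unspliced) and total RNA
    abundance = log10(spliced + unspliced) (uniform DNA frequency).  By
    symmetry the true correlation is zero; the reported Pearson r and p
    quantify the sampling noise of one draw.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    unspliced = rng.lognormal(mu, sigma, size=n)
    spliced = rng.lognormal(mu, sigma, size=n)
    se = spliced / (spliced + unspliced)
    abundance = np.log10(spliced + unspliced)
    r, p = sps.pearsonr(se, abundance)
    return {"r": float(r), "p": float(p), "se": se, "abundance": abundance}
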