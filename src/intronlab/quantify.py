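"""Read-to-splicing-efficiency quantification.

Pipeline per sample: barcode decoding (nearest-neighbour, Levenshtein
distance < 3, unique hit required) -> exact-sequence dereplication ->
per-read isoform classification by normalized junction alignment ->
cryptic-isoform discovery by gapped design alignment for undetermined
reads -> per-(index, repeat) splicing efficiencies -> aggregation
(read-count-weighted mean between repeats within each index, then median
between indexes) -> filters (read floor of 10; DNA-sample artifact filter
at SE > 0.05; cryptic reporting floor at SE > 0.01).

Splicing efficiency of an isoform is its read count divided by the
variant's total read count in that group (undetermined reads included in
the denominator by default).  Total RNA abundance of a variant is
log10(RNA frequency / DNA frequency) of its within-sample relative read
frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from . import align
from .design import BARCODE_LEN, OligoVariant

__all__ = [
    "QuantifyConfig",
    "BarcodeIndex",
    "IsoformCall",
    "decode_barcodes",
    "dereplicate",
    "classify_single",
    "classify_two_intron",
    "find_cryptic",
    "classify_reads",
    "splicing_efficiency",
    "rna_abundance",
    "dna_artifact_filter",
    "quantify_sample",
    "quantify_experiment",
]

SINGLE_CLASSES = ("unspliced", "designed_spliced", "cryptic", "undetermined")


@dataclass(frozen=True)
class QuantifyConfig:
    junction_params: align.AlignParams = align.DEFAULT_PARAMS
    junction_threshold: float = 0.8
    cryptic_params: align.AlignParams = align.CRYPTIC_PARAMS
    cryptic_score_threshold: float = 0.7
    cryptic_score_cmp: str = "lt"
    max_mismatch: int = 6
    barcode_max_dist: int = 2
    read_floor: int = 10
    dna_se_threshold: float = 0.05
    cryptic_se_floor: float = 0.01
    include_undetermined_in_total: bool = True


DEFAULT_CONFIG = QuantifyConfig()


@dataclass
class IsoformCall:
    variant_id: str
    isoform: str
    intron: tuple | None = None


# ---------------------------------------------------------------------------
# barcode decoding


class BarcodeIndex:
    """Barcode -> variant decoder.

    Exact 12-nt prefix match first; otherwise the read's first 11-13 nt are
    scanned against all barcodes (semi-global edit distance, so a single
    indel shifts tolerated) and the read is assigned iff exactly one
    barcode attains the minimal distance and that distance is < 3.
    """

    def __init__(self, variants, max_dist: int = 2):
        self.max_dist = max_dist
        self._exact = {}
        for v in variants:
            vid = v.variant_id if isinstance(v, OligoVariant) else v[1]
            bc = v.barcode if isinstance(v, OligoVariant) else v[0]
            if bc in self._exact:
                raise ValueError(f"duplicate barcode {bc}")
            self._exact[bc] = vid
        self._barcodes = list(self._exact)

    def decode(self, read_prefix: str):
        """Return (variant_id, distance) or (None, reason)."""
        exact = self._exact.get(read_prefix[:BARCODE_LEN])
        if exact is not None:
            return exact, 0
        window = read_prefix[: BARCODE_LEN + self.max_dist]
        best_d, best, ties = self.max_dist + 1, None, 0
        for bc in self._barcodes:
            # barcode global / window-prefix free-end: tolerates indels
            d = edlib.align(bc, window, mode="SHW", k=self.max_dist)["editDistance"]
            if d == -1:
                continue
            if d < best_d:
                best_d, best, ties = d, bc, 1
            elif d == best_d:
                ties += 1
        if best is None:
            return None, "over_distance"
        if ties > 1:
            return None, "ambiguous"
        return self._exact[best], best_d


def decode_barcodes(reads: pd.DataFrame, index: BarcodeIndex):
    """Assign a variant to every read; returns (assigned reads, drop log)."""
    prefixes = reads["sequence"].str[: BARCODE_LEN + index.max_dist]
    cache: dict = {}
    assigned = []
    reasons = []
    for p in prefixes:
        hit = cache.get(p)
        if hit is None:
            hit = index.decode(p)
            cache[p] = hit
        assigned.append(hit[0])
        reasons.append(hit[1] if hit[0] is None else None)
    out = reads.copy()
    out["variant_id"] = assigned
    dropped = out[out["variant_id"].isna()].copy()
    dropped["reason"] = [r for r, a in zip(reasons, assigned) if a is None]
    return out[out["variant_id"].notna()].copy(), dropped


def dereplicate(reads: pd.DataFrame, keys=("sequence",)) -> pd.DataFrame:
    """Exact-sequence grouping with multiplicities (counts conserved)."""
    cols = [c for c in reads.columns if c in ("variant_id", "sample", "repeat", "index")]
    group = list(keys) + cols
    return reads.groupby(group, sort=False, dropna=False).size().reset_index(name="count")


# ---------------------------------------------------------------------------
# classification


def classify_single(read: str, variant: OligoVariant, config=DEFAULT_CONFIG) -> IsoformCall:
    """Three-rule junction classification of a single-intron read.

    unspliced: both exon-intron junctions positive, exon-exon negative.
    designed_spliced: exon-exon positive, both exon-intron negative.
    Everything else: undetermined (candidate for cryptic search).
    """
    j = variant.junctions
    p = config.junction_params
    t = config.junction_threshold
    ei5 = align.junction_score(j["exon_intron_5"], read, p, t).positive
    ei3 = align.junction_score(j["intron_exon_3"], read, p, t).positive
    ee = align.junction_score(j["exon_exon"], read, p, t).positive
    if ei5 and ei3 and not ee:
        return IsoformCall(variant.variant_id, "unspliced")
    if ee and not ei5 and not ei3:
        return IsoformCall(variant.variant_id, "designed_spliced", tuple(variant.introns[0]))
    return IsoformCall(variant.variant_id, "undetermined")


#: two-intron rule sets: isoform -> (positive junctions, negative junctions).
#: Checked in an order that makes the five rule sets mutually consistent
#: (a doubly-spliced read also satisfies the single-intron rules).
TWO_INTRON_RULES = (
    ("both", ("exon1_exon2_exon3",),
     ("exon1_intron1", "intron1_exon2", "exon2_intron2", "intron2_exon3")),
    ("exon_skipping", ("exon1_exon3",), ("exon1_intron1", "intron2_exon3")),
    ("intron1", ("exon1_exon2",), ("exon1_intron1", "intron1_exon2")),
    ("intron2", ("exon2_exon3",), ("exon2_intron2", "intron2_exon3")),
    ("unspliced",
     ("exon1_intron1", "intron1_exon2", "exon2_intron2", "intron2_exon3"),
     ("exon1_exon2", "exon2_exon3")),
)


def classify_two_intron(read: str, variant: OligoVariant, config=DEFAULT_CONFIG) -> IsoformCall:
    """Five-way junction classification of a two-intron read."""
    j = variant.junctions
    p = config.junction_params
    t = config.junction_threshold
    cache: dict = {}

    def pos(name):
        if name not in cache:
            cache[name] = align.junction_score(j[name], read, p, t).positive
        return cache[name]

    for label, positives, negatives in TWO_INTRON_RULES:
        if all(pos(n) for n in positives) and not any(pos(n) for n in negatives):
            return IsoformCall(variant.variant_id, label)
    return IsoformCall(variant.variant_id, "unclassified")


def find_cryptic(read: str, variant: OligoVariant, config=DEFAULT_CONFIG) -> IsoformCall:
    """Gapped design alignment of an undetermined read.

    The longest uninterrupted reference gap is the candidate intron; a
    cluster whose ends both equal the designed ends is reassigned to the
    designed isoform downstream.
    """
    gap = align.gapped_design_alignment(
        read,
        variant.sequence,
        params=config.cryptic_params,
        score_threshold=config.cryptic_score_threshold,
        max_mismatch=config.max_mismatch,
        score_cmp=config.cryptic_score_cmp,
    )
    if gap is None or gap.intron is None:
        return IsoformCall(variant.variant_id, "undetermined")
    designed = (
        align.canonical_gap(variant.sequence, tuple(variant.introns[0]))
        if variant.introns else None
    )
    if designed is not None and tuple(gap.intron) == designed:
        return IsoformCall(variant.variant_id, "designed_spliced", tuple(gap.intron))
    return IsoformCall(variant.variant_id, "cryptic", tuple(gap.intron))


def classify_reads(assigned: pd.DataFrame, variants, config=DEFAULT_CONFIG) -> pd.DataFrame:
    """Classify every assigned read; returns per-group isoform counts.

    Input must carry ``variant_id``; classification is memoized per unique
    (variant, sequence) pair, so the cost scales with dereplicated reads.
    """
    by_id = {v.variant_id: v for v in variants}
    derep = dereplicate(assigned)
    calls = []
    memo: dict = {}
    for r in derep.itertuples():
        key = (r.variant_id, r.sequence)
        call = memo.get(key)
        if call is None:
            variant = by_id[r.variant_id]
            if variant.subset_label == "two_intron":
                call = classify_two_intron(r.sequence, variant, config)
            else:
                call = classify_single(r.sequence, variant, config)
                if call.isoform == "undetermined":
                    call = find_cryptic(r.sequence, variant, config)
            memo[key] = call
        if call.isoform == "cryptic":
            iso = f"cryptic:{call.intron[0]}:{call.intron[1]}"
        elif call.isoform == "designed_spliced":
            iso = "designed"
        else:
            iso = call.isoform
        calls.append(iso)
    out = derep.copy()
    out["isoform"] = calls
    group_cols = [c for c in ("variant_id", "isoform", "sample", "repeat", "index") if c in out]
    return out.groupby(group_cols, sort=False)["count"].sum().reset_index()


# ---------------------------------------------------------------------------
# splicing efficiency and filters


def splicing_efficiency(counts: pd.DataFrame, config=DEFAULT_CONFIG) -> pd.DataFrame:
    """Aggregate per-(index, repeat) isoform counts into per-variant SE.

    Per group, SE = isoform count / total variant reads in the group
    (undetermined included by default).  Aggregation: read-count-weighted
    mean between repeats within each index, then median between indexes
    with data.  Variants with fewer than ``read_floor`` reads in the
    sample are flagged ``low_reads`` and their SE is NaN.
    """
    rows = []
    for vid, g in counts.groupby("variant_id", sort=False):
        pivot = g.pivot_table(
            index=["index", "repeat"], columns="isoform", values="count",
            aggfunc="sum", fill_value=0,
        )
        totals = pivot.sum(axis=1)
        n_total = int(totals.sum())
        isoforms = [c for c in pivot.columns if c not in ("undetermined", "unclassified")]
        if not config.include_undetermined_in_total:
            totals = pivot[isoforms].sum(axis=1)
        low = n_total < config.read_floor
        for iso in isoforms:
            if iso == "unspliced":
                continue
            if low:
                rows.append((vid, iso, np.nan, n_total, True))
                continue
            per_index = []
            for idx, gi in pivot.groupby(level="index"):
                tot = totals.loc[idx]
                valid = tot[tot > 0]
                if valid.empty:
                    continue
                se_rep = gi.loc[idx].loc[valid.index, iso] / valid
                per_index.append(float(np.average(se_rep, weights=valid)))
            se = float(np.median(per_index)) if per_index else np.nan
            rows.append((vid, iso, se, n_total, False))
    return pd.DataFrame(rows, columns=["variant_id", "isoform", "se", "n_reads", "low_reads"])


def rna_abundance(rna_counts: pd.Series, dna_counts: pd.Series) -> pd.Series:
    """Total RNA abundance: log10 of the ratio of within-sample relative
    frequencies.  Variants with zero DNA frequency get NaN."""
    rna_freq = rna_counts / rna_counts.sum()
    dna_freq = dna_counts / dna_counts.sum()
    joined = pd.concat({"rna": rna_freq, "dna": dna_freq}, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.log10(joined["rna"] / joined["dna"])
    return ab.replace([np.inf, -np.inf], np.nan)


def dna_artifact_filter(
    rna_se: pd.DataFrame, dna_se: pd.DataFrame, config=DEFAULT_CONFIG
) -> pd.DataFrame:
    """Zero out RNA isoform SEs that the DNA sample also 'detects'.

    Any isoform with SE > threshold (strict) in the DNA sample is a
    synthesis/alignment artifact: its RNA SE is set to 0 and flagged.
    """
    artifacts = {
        (r.variant_id, r.isoform)
        for r in dna_se.itertuples()
        if not np.isnan(r.se) and r.se > config.dna_se_threshold
    }
    out = rna_se.copy()
    flag = [
        (r.variant_id, r.isoform) in artifacts for r in out.itertuples()
    ]
    out["dna_artifact"] = flag
    out.loc[out["dna_artifact"], "se"] = 0.0
    return out


def _suppress_low_cryptic(se_table: pd.DataFrame, config=DEFAULT_CONFIG) -> pd.DataFrame:
    """Report cryptic clusters only above the SE floor (strict >)."""
    keep = ~(
        se_table["isoform"].str.startswith("cryptic:")
        & ~(se_table["se"] > config.cryptic_se_floor)
    )
    return se_table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# sample- and experiment-level drivers


def quantify_sample(reads: pd.DataFrame, variants, config=DEFAULT_CONFIG):
    """Reads of one sample -> (SE table, per-variant read totals, drop log)."""
    index = BarcodeIndex(variants, max_dist=config.barcode_max_dist)
    assigned, dropped = decode_barcodes(reads, index)
    counts = classify_reads(assigned, variants, config)
    se = splicing_efficiency(counts, config)
    totals = counts.groupby("variant_id")["count"].sum()
    return se, totals, dropped


def quantify_experiment(
    rna_reads: pd.DataFrame,
    dna_reads: pd.DataFrame | None,
    variants,
    config=DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Full RNA(+DNA) quantification: SE per isoform with abundance and
    filter flags; mirrors the per-variant splicing-efficiency tables of the
    assay."""
    rna_se, rna_totals, _ = quantify_sample(rna_reads, variants, config)
    if dna_reads is not None and len(dna_reads):
        dna_se, dna_totals, _ = quantify_sample(dna_reads, variants, config)
        rna_se = dna_artifact_filter(rna_se, dna_se, config)
        abundance = rna_abundance(rna_totals, dna_totals)
        rna_se["abundance"] = rna_se["variant_id"].map(abundance)
    else:
        rna_se["dna_artifact"] = False
        rna_se["abundance"] = np.nan
    return _suppress_low_cryptic(rna_se, config)
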