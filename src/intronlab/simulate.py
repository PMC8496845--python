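"""Synthetic targeted-amplicon read simulator with known ground truth.

Reads emulate the merged, adapter-trimmed amplicons of the assay: each read
covers the 12-nt barcode plus the (possibly spliced) 158-nt variable
region.  The generator draws, per variant, a copy number from a log-normal
distribution, an isoform mixture (unspliced / designed spliced / cryptic
isoforms at alternative 3' ends; for two-intron designs the five isoform
classes), and then samples reads multinomially, excising introns at the
truth coordinates and applying i.i.d. substitution errors.  DNA-sample
reads are always unspliced.  Every read carries a sample label (RNA/DNA),
one of two biological repeats and one of four control indexes.

The truth table records the realized (multinomial) counts, so downstream
estimates can be compared against exact per-draw truth rather than the
asymptotic mixture fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import OligoVariant

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "isoform_introns",
    "isoform_sequence",
    "inject_cryptic",
    "simulate_sample",
    "write_fastq",
    "read_fastq",
]

TWO_INTRON_CLASSES = ("unspliced", "intron1", "intron2", "exon_skipping", "both")

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GroundTruth:
    """Per-variant copy numbers and isoform mixtures.

    ``fractions[variant_id]`` maps isoform keys to fractions summing to 1.
    Single-intron keys: ``unspliced``, ``designed``, ``cryptic:START:END``
    (1-based closed intron interval on the oligo).  Two-intron keys:
    ``unspliced``, ``intron1``, ``intron2``, ``exon_skipping``, ``both``.
    """

    copy_number: dict = field(default_factory=dict)
    fractions: dict = field(default_factory=dict)

    def validate(self):
        for vid, fr in self.fractions.items():
            vals = np.array(list(fr.values()), dtype=float)
            if (vals < 0).any():
                raise ValueError(f"negative isoform fraction for {vid}")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(f"isoform fractions for {vid} do not sum to 1")
            if self.copy_number.get(vid, 0) <= 0:
                raise ValueError(f"nonpositive copy number for {vid}")
        return self

    def true_se(self, variant_id: str) -> dict:
        """Spliced-isoform fractions (the asymptotic SE of each isoform)."""
        return {k: v for k, v in self.fractions[variant_id].items() if k != "unspliced"}


def default_ground_truth(
    variants,
    seed=None,
    lognormal_mu: float = 0.0,
    lognormal_sigma: float = 1.0,
    p_functional: float = 0.4,
    functional_beta=(2.0, 1.8),
    nonfunctional_eps: float = 0.0,
) -> GroundTruth:
    """Study-condition ground truth.

    Copy numbers are log-normal (natural-log mu/sigma).  Single-intron
    variants are bimodal: a fraction ``p_functional`` of designs splice
    with a Beta-distributed efficiency, the rest are fully unspliced —
    emulating the observed mostly-on / mostly-off behaviour of intron
    designs.  Negative controls never splice.  Two-intron variants draw a
    Dirichlet mixture over the five isoform classes.
    """
    rng = np.random.default_rng(seed)
    gt = GroundTruth()
    for v in variants:
        gt.copy_number[v.variant_id] = float(
            rng.lognormal(mean=lognormal_mu, sigma=lognormal_sigma)
        )
        if v.subset_label == "two_intron":
            w = rng.dirichlet([2.0, 1.0, 1.0, 0.5, 1.0])
            gt.fractions[v.variant_id] = dict(zip(TWO_INTRON_CLASSES, w.tolist()))
        elif v.subset_label == "negative_control":
            gt.fractions[v.variant_id] = {"unspliced": 1.0, "designed": 0.0}
        else:
            if rng.random() < p_functional:
                se = float(rng.beta(*functional_beta))
            else:
                se = float(nonfunctional_eps)
            gt.fractions[v.variant_id] = {"unspliced": 1.0 - se, "designed": se}
    return gt.validate()


def isoform_introns(variant: OligoVariant, isoform: str):
    """Intron intervals excised by the given isoform key."""
    if isoform == "unspliced":
        return []
    if isoform == "designed":
        return list(variant.introns)
    if isoform.startswith("cryptic:"):
        _, s, e = isoform.split(":")
        return [(int(s), int(e))]
    if variant.subset_label == "two_intron":
        a, b = variant.introns
        if isoform == "intron1":
            return [a]
        if isoform == "intron2":
            return [b]
        if isoform == "both":
            return [a, b]
        if isoform == "exon_skipping":
            return [(a[0], b[1])]  # introns plus middle exon removed
    raise ValueError(f"unknown isoform key {isoform!r} for {variant.variant_id}")


def isoform_sequence(variant: OligoVariant, isoform: str) -> str:
    return variant.spliced_sequence(isoform_introns(variant, isoform))


def inject_cryptic(
    truth: GroundTruth,
    variant: OligoVariant,
    alt_3ss_offset: int,
    fraction: float,
    require_hag: bool = True,
    min_downstream: int = 10,
) -> GroundTruth:
    """Add a cryptic isoform using the designed 5' end and a shifted 3' end.

    The shifted end must land on a HAG motif (last three intron bases
    [ACT]AG) unless ``require_hag`` is False, and must leave at least
    ``min_downstream`` exonic nt before the amplicon end (an isoform that
    splices away the entire 3' exon leaves nothing to amplify or align).
    Existing fractions are rescaled by (1 - fraction).
    """
    if fraction < 0 or fraction >= 1:
        raise ValueError("fraction must be in [0, 1)")
    start, end = variant.introns[0]
    new_end = end + alt_3ss_offset
    seq = variant.sequence
    if new_end <= start + 9 or new_end + min_downstream > len(seq):
        raise ValueError(
            "alternative 3' end outside the usable variable region "
            f"(need {min_downstream} nt of downstream exon)"
        )
    tail = seq[new_end - 3 : new_end]
    if require_hag and not (tail.endswith("AG") and tail[0] in "ACT"):
        raise ValueError(f"no HAG motif at offset {alt_3ss_offset} (found {tail})")
    if fraction == 0:
        return truth
    fr = truth.fractions[variant.variant_id]
    # reads cannot distinguish coordinate-equivalent intervals; key the
    # isoform by its 5'-most representative (junction wobble)
    from .align import canonical_gap

    start, new_end = canonical_gap(seq, (start, new_end))
    key = f"cryptic:{start}:{new_end}"
    scaled = {k: v * (1 - fraction) for k, v in fr.items()}
    scaled[key] = scaled.get(key, 0.0) + fraction
    truth.fractions[variant.variant_id] = scaled
    return truth


def _apply_errors(seqs: list, rate: float, rng) -> list:
    """I.i.d. substitution errors; exact per-read binomial error counts."""
    if rate <= 0:
        return seqs
    lens = np.fromiter((len(s) for s in seqs), dtype=np.int64)
    n_err = rng.binomial(lens, rate)
    out = seqs
    for i in np.nonzero(n_err)[0]:
        b = bytearray(seqs[i], "ascii")
        pos = rng.choice(lens[i], size=n_err[i], replace=False)
        for p in pos:
            cur = chr(b[p])
            alt = [c for c in "ACGT" if c != cur]
            b[p] = ord(alt[rng.integers(3)])
        out[i] = b.decode()
    return out


def simulate_sample(
    variants,
    truth: GroundTruth,
    n_reads: int,
    seed=None,
    sample: str = "RNA",
    error_rate: float = 0.001,
    n_indexes: int = 4,
    n_repeats: int = 2,
):
    """Draw a read sample; returns (reads DataFrame, realized-count table).

    Reads are drawn multinomially across variants by copy number, then
    across isoforms by the truth fractions (DNA samples are always
    unspliced), then uniformly across (repeat, index) read groups.
    Substitution errors are applied i.i.d. per base.  The returned truth
    table has one row per (variant, isoform, repeat, index) with the
    realized count.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if sample not in ("RNA", "DNA"):
        raise ValueError("sample must be RNA or DNA")
    truth.validate()
    by_id = {v.variant_id: v for v in variants}
    missing = set(truth.fractions) - set(by_id)
    if missing:
        raise ValueError(f"truth covers unknown variants: {sorted(missing)[:3]}...")
    rng = np.random.default_rng(seed)
    vids = list(truth.fractions)
    weights = np.array([truth.copy_number[v] for v in vids], dtype=float)
    weights /= weights.sum()
    per_variant = rng.multinomial(n_reads, weights)

    rows = []
    truth_rows = []
    n_groups = n_repeats * n_indexes
    for vid, n_v in zip(vids, per_variant):
        if n_v == 0:
            continue
        variant = by_id[vid]
        fr = truth.fractions[vid]
        if sample == "DNA":
            iso_keys, iso_p = ["unspliced"], np.array([1.0])
        else:
            iso_keys = list(fr)
            iso_p = np.array([fr[k] for k in iso_keys], dtype=float)
        per_iso = rng.multinomial(n_v, iso_p)
        for key, n_i in zip(iso_keys, per_iso):
            if n_i == 0:
                continue
            base = isoform_sequence(variant, key)
            groups = rng.multinomial(n_i, np.full(n_groups, 1.0 / n_groups))
            for g, n_g in enumerate(groups):
                if n_g == 0:
                    continue
                rep, idx = divmod(g, n_indexes)
                seqs = _apply_errors([base] * n_g, error_rate, rng)
                rows.extend(
                    (s, sample, rep + 1, idx + 1, vid, key) for s in seqs
                )
                truth_rows.append((vid, key, rep + 1, idx + 1, int(n_g)))
    reads = pd.DataFrame(
        rows, columns=["sequence", "sample", "repeat", "index", "true_variant", "true_isoform"]
    )
    truth_table = pd.DataFrame(
        truth_rows, columns=["variant_id", "isoform", "repeat", "index", "count"]
    )
    return reads, truth_table


def write_fastq(reads: pd.DataFrame, path, emit_index_prefix: bool = False, index_tags=None):
    """Phred-33 FASTQ with constant quality; read-group labels in headers.

    With ``emit_index_prefix`` an 8-nt index sequence is prepended to each
    read (the literal amplicon layout) instead of only tagging the header.
    """
    if index_tags is None:
        pats = ["AAAAAAAA", "CCCCCCCC", "GGGGGGGG", "TTTTTTTT",
                "ACACACAC", "AGAGAGAG", "ATATATAT", "CGCGCGCG"]
        index_tags = {i + 1: pats[i] for i in range(len(pats))}
    with open(path, "w") as fh:
        for i, r in enumerate(reads.itertuples()):
            seq = r.sequence
            if emit_index_prefix:
                seq = index_tags[r.index] + seq
            fh.write(
                f"@read{i} sample={r.sample} repeat={r.repeat} index={r.index}\n"
                f"{seq}\n+\n{'I' * len(seq)}\n"
            )


def read_fastq(path) -> pd.DataFrame:
    """Parse a FASTQ written by :func:`write_fastq` back into a reads table."""
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fastq"):
        tags = dict(kv.split("=") for kv in rec.description.split()[1:] if "=" in kv)
        rows.append(
            (str(rec.seq), tags.get("sample", "RNA"), int(tags.get("repeat", 1)),
             int(tags.get("index", 1)))
        )
    return pd.DataFrame(rows, columns=["sequence", "sample", "repeat", "index"])
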