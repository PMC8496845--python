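"""Synthetic genomes with annotated introns and coding regions.

These generators exist so the motif-avoidance statistics can be exercised
(and calibrated) without any genome download: a genome is a set of random
contigs carrying coding genes on both strands, a subset of which contain
one intron each.  Three construction modes mirror the hypotheses the
avoidance test distinguishes:

* ``null`` — intron 3' ends are ordinary coding positions; motif frequency
  around intron ends matches the coding background, so avoidance p-values
  are calibrated Uniform(0, 1).
* ``depleted`` — acceptor-site motifs are hard-masked inside a window
  around every intron 3' end (planted avoidance; p should be ~0).
* ``enriched`` — a motif is planted at a fixed offset in a fraction of
  introns (for profile tests).

Annotations are BED-like DataFrames (0-based half-open, stranded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import DEFAULT_MOTIFS, motif_indicator, _revcomp

__all__ = ["synthetic_genome", "write_fasta", "read_fasta", "write_bed6", "read_bed6"]

BASES = list("ACGT")


def _mask_motifs(seq: list, lo: int, hi: int, motifs, rng):
    """Destroy motif occurrences starting in [lo, hi] (0-based, clipped)."""
    k = len(motifs[0])
    lo = max(0, lo)
    hi = min(len(seq) - k, hi)
    for i in range(lo, hi + 1):
        if "".join(seq[i : i + k]) in motifs:
            # break the motif's AG core with a non-G substitution
            seq[i + k - 1] = rng.choice([b for b in BASES if b != seq[i + k - 1] and b != "G"])


def synthetic_genome(
    n_genes: int = 60,
    gene_len: int = 900,
    n_introns: int = 100,
    intron_len: int = 80,
    seed=None,
    motifs=DEFAULT_MOTIFS,
    mode: str = "null",
    depletion_window=(-40, 30),
    enrich_offset: int = 5,
    enrich_fraction: float = 0.0,
    spacer: int = 120,
):
    """Build one contig of ``n_genes`` coding genes, ``n_introns`` of which
    carry an intron; returns (contigs dict, introns BED, cds BED).

    ``n_introns`` may exceed ``n_genes``: genes then host several introns
    spaced along the gene (each intron keeps a margin from its
    neighbours).  Strands alternate.
    """
    if n_introns > n_genes * 3:
        raise ValueError("too many introns for this gene count")
    rng = np.random.default_rng(seed)
    total = n_genes * (gene_len + spacer) + spacer
    contig = list(rng.choice(BASES, size=total))
    name = "chr1"
    genes = []
    for g in range(n_genes):
        start = spacer + g * (gene_len + spacer)
        strand = "+" if g % 2 == 0 else "-"
        genes.append((start, start + gene_len, strand))

    intron_rows = []
    margin = 80
    host = [g % n_genes for g in range(n_introns)]
    per_gene: dict = {}
    for i, g in enumerate(host):
        per_gene.setdefault(g, []).append(i)
    made = 0
    for g, idxs in per_gene.items():
        gstart, gend, strand = genes[g]
        slots = len(idxs)
        usable = gene_len - 2 * margin - slots * intron_len
        if usable <= slots:
            raise ValueError("gene too short for requested introns")
        offs = np.sort(rng.choice(usable, size=slots, replace=False))
        cursor = gstart + margin
        for s, off in enumerate(offs):
            istart = cursor + int(off) + s * intron_len
            iend = istart + intron_len
            intron_rows.append(
                {
                    "chrom": name,
                    "start": istart,
                    "end": iend,
                    "name": f"intron{made}",
                    "score": 0,
                    "strand": strand,
                }
            )
            made += 1

    if mode == "depleted":
        lo, hi = depletion_window
        k = len(motifs[0])
        for r in intron_rows:
            if r["strand"] == "+":
                anchor = r["end"] - 1
                _mask_motifs(contig, anchor + lo, anchor + hi, motifs, rng)
            else:
                # oriented offsets run against the genome axis; mask the
                # corresponding reverse-complement window
                anchor = r["start"]
                rc_motifs = tuple(_revcomp(m) for m in motifs)
                _mask_motifs(contig, anchor - hi - (k - 1), anchor - lo, rc_motifs, rng)
    elif mode == "enriched" and enrich_fraction > 0:
        k = len(motifs[0])
        chosen = rng.random(len(intron_rows)) < enrich_fraction
        for r, c in zip(intron_rows, chosen):
            if not c:
                continue
            m = list(motifs[int(rng.integers(len(motifs)))])
            if r["strand"] == "+":
                p = r["end"] - 1 + enrich_offset
                contig[p : p + k] = m
            else:
                p = r["start"] - enrich_offset - (k - 1)
                contig[p : p + k] = list(_revcomp("".join(m)))
    elif mode not in ("null", "enriched"):
        raise ValueError(f"unknown mode {mode!r}")

    contigs = {name: "".join(contig)}
    introns = pd.DataFrame(intron_rows)
    cds = pd.DataFrame(
        [
            {
                "chrom": name,
                "start": s,
                "end": e,
                "name": f"gene{g}",
                "score": 0,
                "strand": st,
            }
            for g, (s, e, st) in enumerate(genes)
        ]
    )
    return contigs, introns, cds


# ---------------------------------------------------------------------------
# plain-text interchange


def write_fasta(contigs: dict, path):
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def write_bed6(df: pd.DataFrame, path):
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed6(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BED6_COLUMNS)
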