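"""Design the synthetic-intron library.

Builds a desk-scale library with every subset of the assay — combinatorial
splice-site designs, negative controls, natural-style intron insertions,
splice-site mutants and two-intron designs — and writes the manifest.
The manifest (with full sequences) goes to scratch/; a small per-subset
summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from intronlab import design

SEED = 42
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main():
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
    cfg = design.LibraryConfig(
        n_combinatorial=150,
        n_negative_controls=30,
        n_natural=40,
        n_mutated=40,
        n_structure=6,
        two_intron_pool=5,
        n_backgrounds=4,
    )
    variants = design.design_library(cfg, seed=SEED)
    design.write_manifest(variants, SCRATCH / "manifest.tsv", SCRATCH / "oligos.fasta")

    summary = (
        pd.Series([v.subset_label for v in variants])
        .value_counts()
        .rename_axis("subset")
        .rename("n_variants")
        .reset_index()
    )
    summary.to_csv(RESULTS / "01_library_summary.tsv", sep="\t", index=False)
    print(f"designed {len(variants)} variants (seed {SEED})")
    print(summary.to_string(index=False))
    print(f"manifest: {SCRATCH / 'manifest.tsv'}")


if __name__ == "__main__":
    main()
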