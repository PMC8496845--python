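"""Simulate the sequencing experiment.

Draws per-variant copy numbers and isoform mixtures (with cryptic
alternative-3'SS isoforms injected into a quarter of the spliced designs),
then emits merged amplicon reads for two RNA repeats x four indexes plus a
matched unspliced DNA control.  Reads and the ground-truth table go to
scratch/ for the downstream scripts.
"""

from pathlib import Path

from intronlab import design, simulate

SEED = 43
N_RNA = 400_000
N_DNA = 100_000
ERROR_RATE = 0.001
ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"


def main():
    variants = design.read_manifest(SCRATCH / "manifest.tsv")
    truth = simulate.default_ground_truth(variants, seed=SEED)

    injected = 0
    for v in variants:
        if v.subset_label == "two_intron":
            continue
        if truth.fractions[v.variant_id].get("designed", 0) < 0.2:
            continue
        s, e = v.introns[0]
        seq = v.sequence
        offs = [
            off for off in range(6, 45)
            if e + off + 10 <= len(seq)
            and seq[e + off - 3 : e + off].endswith("AG")
            and seq[e + off - 3] in "ACT"
        ]
        if injected % 2 == 0:  # every other eligible variant
            if offs:
                simulate.inject_cryptic(truth, v, offs[0], 0.1)
            elif e + 22 <= len(seq):  # non-HAG cryptic ends also occur
                simulate.inject_cryptic(truth, v, 12, 0.1, require_hag=False)
            else:
                continue
        injected += 1

    rna, truth_table = simulate.simulate_sample(
        variants, truth, N_RNA, seed=SEED + 1, sample="RNA", error_rate=ERROR_RATE
    )
    dna, _ = simulate.simulate_sample(
        variants, truth, N_DNA, seed=SEED + 2, sample="DNA", error_rate=ERROR_RATE
    )
    simulate.write_fastq(rna, SCRATCH / "rna.fastq")
    simulate.write_fastq(dna, SCRATCH / "dna.fastq")
    truth_table.to_csv(SCRATCH / "truth.tsv", sep="\t", index=False)
    print(f"simulated {len(rna)} RNA and {len(dna)} DNA reads "
          f"({injected} variants eligible for cryptic injection)")


if __name__ == "__main__":
    main()
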