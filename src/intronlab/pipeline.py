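"""End-to-end pipeline driver: design -> simulate -> quantify -> stats -> model.

A single global seed fans out to per-stage sub-seeds through
``numpy.random.SeedSequence.spawn`` in a fixed stage order, so every stage
is independently reproducible.  All thresholds in force are echoed into
the run summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import design, features, model, quantify, simulate, stats

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]

STAGES = ("design", "truth", "rna_reads", "dna_reads", "stats", "model")


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage sub-seeds from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        name: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for name, c in zip(STAGES, children)
    }


@dataclass
class PipelineConfig:
    seed: int = 0
    library: design.LibraryConfig = field(default_factory=design.LibraryConfig)
    quantify: quantify.QuantifyConfig = field(default_factory=quantify.QuantifyConfig)
    model: model.ModelConfig = field(default_factory=model.ModelConfig)
    n_rna_reads: int = 100_000
    n_dna_reads: int = 30_000
    error_rate: float = 0.001
    run_model: bool = True

    def thresholds(self) -> dict:
        q = self.quantify
        return {
            "junction_threshold": q.junction_threshold,
            "cryptic_score_threshold": q.cryptic_score_threshold,
            "cryptic_score_cmp": q.cryptic_score_cmp,
            "max_mismatch": q.max_mismatch,
            "read_floor": q.read_floor,
            "dna_se_threshold": q.dna_se_threshold,
            "cryptic_se_floor": q.cryptic_se_floor,
        }


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run all stages, writing tables and a machine-readable summary.

    Returns the summary dict; every number in it is recomputed from the
    stage tables written alongside it.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    marker = out / "INCOMPLETE"
    marker.write_text("pipeline running")

    variants = design.design_library(config.library, seed=seeds["design"])
    manifest_path = out / "manifest.tsv"
    design.write_manifest(variants, manifest_path, out / "oligos.fasta")

    truth = simulate.default_ground_truth(variants, seed=seeds["truth"])
    rna_reads, truth_table = simulate.simulate_sample(
        variants, truth, config.n_rna_reads, seed=seeds["rna_reads"],
        sample="RNA", error_rate=config.error_rate,
    )
    dna_reads, _ = simulate.simulate_sample(
        variants, truth, config.n_dna_reads, seed=seeds["dna_reads"],
        sample="DNA", error_rate=config.error_rate,
    )
    truth_table.to_csv(out / "truth.tsv", sep="\t", index=False)

    se_table = quantify.quantify_experiment(rna_reads, dna_reads, variants, config.quantify)
    se_table.to_csv(out / "splicing_efficiency.tsv", sep="\t", index=False)

    single = [v for v in variants if v.subset_label not in ("two_intron",)]
    designed = se_table[se_table["isoform"] == "designed"].set_index("variant_id")
    detected = designed[designed["se"] > 0]
    cryptic = se_table[se_table["isoform"].str.startswith("cryptic:")]

    truth_se = pd.Series(
        {v.variant_id: truth.fractions[v.variant_id].get("designed", np.nan)
         for v in single}
    )
    est = designed["se"].reindex(truth_se.index)
    both = pd.concat({"truth": truth_se, "est": est}, axis=1).dropna()
    se_recovery_r = (
        float(sps.pearsonr(both["truth"], both["est"])[0]) if len(both) > 2 else np.nan
    )

    ctrl = stats.randomized_abundance_control(seed=seeds["stats"])

    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": config.thresholds(),
        "n_variants": len(variants),
        "n_rna_reads": int(len(rna_reads)),
        "fraction_designed_isoform_detected": float(
            len(detected) / max(len(single), 1)
        ),
        "median_se_detected": float(detected["se"].median()) if len(detected) else np.nan,
        "cryptic_isoform_count": int(len(cryptic)),
        "se_recovery_pearson_r": se_recovery_r,
        "mock_abundance_control_p": ctrl["p"],
        "tables": {
            p.name: _sha(p)
            for p in (manifest_path, out / "splicing_efficiency.tsv", out / "truth.tsv")
        },
    }

    if config.run_model:
        feats = features.feature_table(single)
        est_target = designed["se"].reindex(feats.index).fillna(0.0)
        cv = model.train_cv(feats, est_target.to_numpy(), config.model, seed=seeds["model"])
        summary["model_test_pearson_r"] = cv.test_r
        summary["model_test_n"] = int(len(cv.test_index))

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    marker.unlink()
    return summary
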