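"""Gradient-boosting splicing model on the quantified library.

Extracts the 39-feature vectors for single-intron variants, trains the
LightGBM model with 5-fold averaging cross-validation on the measured SE
values, and reports the test-set correlation, the 3-class Cramer's V
between predictions and measurements, and the Shapley importance ranking.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from intronlab import design, features, model, stats

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"
SEED = 53


def main():
    variants = design.read_manifest(SCRATCH / "manifest.tsv")
    se = pd.read_csv(SCRATCH / "splicing_efficiency.tsv", sep="\t")
    designed = se[se.isoform == "designed"].set_index("variant_id").se

    singles = [v for v in variants
               if v.subset_label not in ("two_intron", "negative_control")]
    X = features.feature_table(singles)
    y = designed.reindex(X.index).fillna(0.0).to_numpy()

    cv = model.train_cv(X, y, seed=SEED)
    sh = model.shapley_importance(cv, X, seed=SEED + 1, n_bootstrap=500)
    v = stats.cramers_v(y[cv.test_index], cv.test_prediction)

    sh["ranking"].head(15).to_csv(RESULTS / "06_shap_ranking.tsv", sep="\t",
                                  index=False)
    summary = {
        "n_train": int(len(cv.train_index)),
        "n_test": int(len(cv.test_index)),
        "test_pearson_r": cv.test_r,
        "test_r_ci95": list(cv.test_r_ci),
        "cramers_v_pred_vs_measured": float(v["phi_c"]) if v["defined"] else None,
        "top5_features": sh["ranking"].feature.head(5).tolist(),
    }
    (RESULTS / "06_model_summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    print("NB: with the default generator the targets carry no sequence "
          "signal beyond sampling noise, so the test r quantifies the "
          "leak-free baseline of the pipeline; planted-effect recovery is "
          "exercised in the test suite and acceptance script.")


if __name__ == "__main__":
    main()
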