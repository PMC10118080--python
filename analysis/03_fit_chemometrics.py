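#!/usr/bin/env python
"""Fit the class models: PCA overview and the 3+2+0 OPLS-DA.

Pareto-scales the oil-sample abundance matrix, confirms the unsupervised
class structure (PCA), fits OPLS-DA with 3 predictive + 2 X-orthogonal
components, cross-validates Q2 with 7-fold venetian blinds and calibrates
it with a label-permutation test.
"""

import json
import sys
from pathlib import Path

import numpy as np

from oilmark.chemometrics import fit_pca, pareto_scale, permutation_test
from oilmark.marker_discovery import fit_class_model
from oilmark.pipeline import RunConfig, build_matrix
from oilmark.synthetic_data import SimulationDesign, simulate_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1]


def main():
    design = SimulationDesign(seed=SEED)
    samples, _ = simulate_study(design)
    matrix = build_matrix(samples, RunConfig(seed=SEED, design=design))

    cols = np.flatnonzero(matrix.roles == "oil")
    X = matrix.abundance[:, cols].T
    pca = fit_pca(pareto_scale(X).X, 3)

    model, _ = fit_class_model(matrix, cv_folds=7)
    perm = permutation_test(
        X, matrix.classes[cols], 3, 2, n_perm=199, seed=SEED, cv_folds=7
    )

    stats = {
        "pca_r2x_per_component": [round(v, 4) for v in pca.r2x_per_component],
        "oplsda": {
            "components": "3+2+0",
            "r2x_cum": round(model.r2x_cum, 4),
            "r2x_predictive": [round(v, 4) for v in model.r2x_per_component],
            "r2x_orthogonal": [round(v, 4) for v in model.r2x_orth_per_component],
            "r2y": round(model.r2y, 4),
            "q2": round(model.q2, 4),
            "s2y": round(model.s2y, 5),
            "see": round(model.see, 4),
        },
        "permutation": {
            "n_perm": perm["n_perm"],
            "p_q2": perm["p_q2"],
            "p_r2y": perm["p_r2y"],
            "mean_permuted_q2": round(float(perm["permuted"][:, 1].mean()), 4),
        },
    }
    ROOT.joinpath("results").mkdir(exist_ok=True)
    (ROOT / "results" / "03_model_stats.json").write_text(
        json.dumps(stats, indent=1) + "\n"
    )
    o = stats["oplsda"]
    print(f"OPLS-DA (3+2+0): R2X={o['r2x_cum']} R2Y={o['r2y']} Q2={o['q2']} "
          f"SEE={o['see']}")
    print(f"permutation p(Q2)={perm['p_q2']:.4g} "
          f"(mean permuted Q2 {stats['permutation']['mean_permuted_q2']})")
    print("stats -> results/03_model_stats.json")


if __name__ == "__main__":
    main()
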