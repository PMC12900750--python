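#!/usr/bin/env python
"""Tri-algorithm diagnostic-panel selection and validation.

LASSO stability selection (100 stratified bootstraps), SVM-RFE with
LOOCV, and random-forest Gini importance (2000 trees) over the hub
markers; the consensus panel is their intersection.  The panel's
logistic model is summarized by the Mann-Whitney AUC and a 1000-
iteration label-permutation test.  Writes results/ml/ and prints the
selection summary.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mddpanel.cohort import read_cohort
from mddpanel.de import cpm
from mddpanel.ml import (
    consensus_panel,
    fit_logistic_roc,
    lasso_stability_selection,
    permutation_test_auc,
    rf_importance,
    svm_rfe_loocv,
)
from mddpanel.pipeline import derive_seeds


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17, help="master seed")
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--hubs", type=Path, default=Path("results/network/hubs.txt"))
    ap.add_argument("--out", type=Path, default=Path("results/ml"))
    args = ap.parse_args()

    seeds = derive_seeds(args.seed)
    cohort = read_cohort(args.cohort)
    hubs = [h for h in args.hubs.read_text().split() if h in cohort.counts.counts.index]

    X = np.log2(cpm(cohort.counts).loc[hubs] + 1.0).T
    y = (cohort.groups.reindex(X.index) == "MDD").astype(int).to_numpy()

    stab = lasso_stability_selection(X, y, B=100, seed=seeds["stability"])
    rfe = svm_rfe_loocv(X, y)
    imp = rf_importance(X, y, ntree=2000, seed=seeds["forest"])
    panel = consensus_panel(stab.stable_set, rfe.optimal_set, imp.selected_set,
                            universe=hubs)

    args.out.mkdir(parents=True, exist_ok=True)
    stab.selection_probability.to_csv(args.out / "stability.tsv", sep="\t")
    pd.Series(rfe.accuracy_curve, name="loocv_accuracy").rename_axis("n_features").to_csv(
        args.out / "rfe_curve.tsv", sep="\t"
    )
    pd.DataFrame({"mean_decrease_gini": imp.mean_decrease_gini, "rank": imp.rank}).to_csv(
        args.out / "importance.tsv", sep="\t", index_label="feature"
    )
    (args.out / "panel.txt").write_text("\n".join(panel) + ("\n" if panel else ""))

    print(f"LASSO stable set (prob > {stab.threshold}, lambda={stab.lambda_used:.4g}): "
          f"{', '.join(stab.stable_set) or '(none)'}")
    print(f"SVM-RFE optimal subset (LOOCV acc "
          f"{rfe.accuracy_curve[rfe.optimal_size]:.3f} at {rfe.optimal_size} features): "
          f"{', '.join(rfe.optimal_set)}")
    print(f"RF selected (Gini importance > 0): {', '.join(imp.selected_set)}")
    print(f"consensus panel: {', '.join(panel) or '(empty)'}")

    summary = {
        "panel": panel,
        "lasso_set": stab.stable_set,
        "svm_set": rfe.optimal_set,
        "rf_set": imp.selected_set,
        "seeds": seeds,
    }
    if panel:
        Xp = X[panel]
        coef, auc, roc = fit_logistic_roc(Xp, y)
        roc.to_csv(args.out / "roc_points.tsv", sep="\t", index=False)
        auc_obs, perm_p = permutation_test_auc(Xp, y, B=1000, seed=seeds["permutation"])
        summary.update(auc=auc, permutation_p=perm_p,
                       coefficients={k: float(v) for k, v in coef.items()})
        print(f"logistic panel model: AUC={auc:.3f}, permutation p={perm_p:.4g} "
              f"(B=1000, floor {1/1001:.4g})")
    (args.out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


if __name__ == "__main__":
    main()
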