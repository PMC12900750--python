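#!/usr/bin/env python
"""Clinical statistics for the hub markers.

Normality-gated group comparisons (mRNA and protein layers), 2^-ddCt
qPCR fold changes, and partial Spearman correlations between marker
levels and HAMD-17 severity adjusted for age and sex.  Writes
results/clinical/ and prints the severity correlations.
"""

import argparse
from pathlib import Path

import numpy as np

from mddpanel.clinstats import (
    group_tests_table,
    marker_severity_correlations,
    qpcr_fold_changes,
)
from mddpanel.cohort import REFERENCE_GENE, read_cohort
from mddpanel.de import cpm


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--hubs", type=Path, default=Path("results/network/hubs.txt"))
    ap.add_argument("--out", type=Path, default=Path("results/clinical"))
    args = ap.parse_args()

    cohort = read_cohort(args.cohort)
    hubs = [h for h in args.hubs.read_text().split() if h]
    markers = [h for h in hubs if h in cohort.counts.counts.index]

    layers = {"mRNA": np.log2(cpm(cohort.counts).loc[markers] + 1.0)}
    present = [m for m in markers if m in cohort.protein_levels.index]
    if present:
        layers["protein"] = cohort.protein_levels.loc[present]

    args.out.mkdir(parents=True, exist_ok=True)
    corr = marker_severity_correlations(layers, cohort.samples)
    corr.to_csv(args.out / "correlations.tsv", sep="\t", index=False)
    group_tests_table(layers, cohort.samples).to_csv(
        args.out / "group_tests.tsv", sep="\t", index=False
    )
    fold = qpcr_fold_changes(cohort.ct_values, REFERENCE_GENE, cohort.groups)
    fold.to_csv(args.out / "qpcr_fold_changes.tsv", sep="\t", index_label="gene")

    print("marker-severity partial Spearman (adjusted for age and sex):")
    for _, row in corr.sort_values(["layer", "adj_p"]).iterrows():
        flag = "*" if row.adj_p < 0.05 else " "
        print(f"  {row.layer:8s} {row.marker:10s} adj_r={row.adj_r:+.2f} "
              f"adj_p={row.adj_p:.4f} {flag}")
    mdd_cols = cohort.groups[cohort.groups == "MDD"].index
    print("mean qPCR fold change (MDD vs HC) per hub gene:")
    print(fold[mdd_cols].mean(axis=1).round(2).to_string())


if __name__ == "__main__":
    main()
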