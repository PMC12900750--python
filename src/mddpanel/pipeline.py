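"""End-to-end pipeline: cohort -> DE -> network hubs -> clinical stats
-> ML consensus, with one master seed, a flat config, and a JSON report.

Each stage writes its tables under the output directory so the stages
are independently inspectable; ``report.json`` collects every headline
quantity (DEG counts, hub list, panel, AUC, permutation p) together with
the parameters and derived per-stage seeds, and reruns bit-identically
for the same config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinstats import group_tests_table, marker_severity_correlations, qpcr_fold_changes
from .cohort import (
    REFERENCE_GENE,
    CohortParams,
    SyntheticCohort,
    generate_cohort,
    planted_hub_network,
    read_cohort,
)
from .de import cpm, deg_sets, differential_expression
from .ml import (
    consensus_panel,
    fit_logistic_roc,
    lasso_stability_selection,
    permutation_test_auc,
    rf_importance,
    svm_rfe_loocv,
)
from .network import (
    consensus_hubs,
    mcode_find_modules,
    read_edge_list,
    subgraph_centrality,
    top_k_nodes,
    write_network_outputs,
)

log = logging.getLogger("mddpanel")

_STAGES = ("cohort", "network", "stability", "forest", "permutation")


@dataclass
class PipelineConfig:
    """Flat, human-editable pipeline configuration with full defaults."""

    # inputs: either a cohort directory (counts.tsv etc.) or synthetic params
    cohort_dir: str | None = None
    network_file: str | None = None
    network_dialect: str = "tsv2col"
    # synthetic cohort
    n_case: int = 15
    n_control: int = 15
    n_genes: int = 2000
    nb_dispersion: float = 0.1
    # differential expression
    p_thresh: float = 0.05
    fc_thresh: float = 1.0
    prior: float = 0.5
    # network
    top_k: int = 25
    mcode_vwp: float = 0.2
    mcode_haircut: bool = True
    mcode_fluff: bool = False
    # ML consensus
    candidate_genes: list[str] = field(default_factory=list)  # empty -> use hubs
    B_stability: int = 100
    stability_threshold: float = 0.6
    ntree: int = 2000
    svm_cost: float = 1.0
    B_permutation: int = 1000
    # run
    master_seed: int = 17
    out_dir: str = "results/pipeline"

    def validate(self) -> list[str]:
        errors = []
        if not (0 < self.p_thresh <= 1):
            errors.append("p_thresh: must be in (0, 1]")
        if self.fc_thresh < 0:
            errors.append("fc_thresh: must be >= 0")
        if self.prior < 0:
            errors.append("prior: must be >= 0")
        if self.top_k < 1:
            errors.append("top_k: must be >= 1")
        if not (0 <= self.mcode_vwp < 1):
            errors.append("mcode_vwp: must be in [0, 1)")
        if not (0 < self.stability_threshold < 1):
            errors.append("stability_threshold: must be in (0, 1)")
        for name in ("B_stability", "B_permutation", "ntree"):
            if getattr(self, name) < 1:
                errors.append(f"{name}: must be >= 1")
        if self.nb_dispersion < 0:
            errors.append("nb_dispersion: must be >= 0")
        if self.n_case < 2 or self.n_control < 2:
            errors.append("n_case/n_control: must be >= 2")
        if self.svm_cost <= 0:
            errors.append("svm_cost: must be > 0")
        if self.cohort_dir is not None and not Path(self.cohort_dir).is_dir():
            errors.append(f"cohort_dir: directory not found: {self.cohort_dir}")
        if self.network_file is not None and not Path(self.network_file).is_file():
            errors.append(f"network_file: file not found: {self.network_file}")
        return errors


def validate_config(path: str | Path | None) -> PipelineConfig:
    """Load + validate a YAML config; raises ValueError listing all violations."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError("unknown config field(s): " + ", ".join(unknown))
    cfg = PipelineConfig(**raw)
    errors = cfg.validate()
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Stable per-stage integer seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


def _log2_cpm(counts_matrix, genes: list[str]) -> pd.DataFrame:
    return np.log2(cpm(counts_matrix).loc[genes] + 1.0)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the report dict (also written to disk)."""
    errors = config.validate()
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.master_seed)
    stage = "setup"
    try:
        # ------------------------------------------------------- cohort
        stage = "cohort"
        log.info("stage cohort: seed=%d", seeds["cohort"])
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
        else:
            params = CohortParams(
                n_case=config.n_case,
                n_control=config.n_control,
                n_genes=config.n_genes,
                nb_dispersion=config.nb_dispersion,
                seed=seeds["cohort"],
            )
            cohort = generate_cohort(params)
        groups = cohort.groups

        # ---------------------------------------------- differential expression
        stage = "differential_expression"
        de = differential_expression(
            cohort.counts,
            groups,
            case_label="MDD",
            p_thresh=config.p_thresh,
            fc_thresh=config.fc_thresh,
            prior=config.prior,
        )
        de.to_csv(out / "de_table.tsv", sep="\t", index_label="gene")
        degs = deg_sets(de)
        log.info("DE: %d DEGs (%d up, %d down)", len(degs["all"]), len(degs["up"]), len(degs["down"]))

        # ------------------------------------------------------ network hubs
        stage = "network_hubs"
        if config.network_file is not None:
            graph = read_edge_list(config.network_file, config.network_dialect)
        else:
            # synthetic interaction network over the DE screen's gene space:
            # planted module = the genes the config declares as candidates,
            # else the cohort's planted hubs recorded at generation time
            planted = config.candidate_genes or sorted(
                cohort.truth.get("planted_log2fc", {})
            )
            background = [g for g in degs["all"] if g not in planted]
            if len(background) < 20:  # ensure a non-trivial noise background
                extra = [
                    g
                    for g in de.sort_values("p_value").index
                    if g not in planted and g not in background
                ]
                background += extra[: 50 - len(background)]
            edges = planted_hub_network(planted, background, seed=seeds["network"])
            graph = nx.Graph(edges)
        ranking = subgraph_centrality(graph)
        topk = top_k_nodes(ranking, config.top_k)
        modules = mcode_find_modules(
            graph,
            vwp=config.mcode_vwp,
            haircut=config.mcode_haircut,
            fluff=config.mcode_fluff,
        )
        hubs = consensus_hubs(topk, modules, ranking)
        write_network_outputs(out, ranking, modules, hubs)
        hub_direction = {
            g: (de.loc[g, "direction"] if g in de.index else "none") for g in hubs
        }
        log.info("network: %d modules, %d consensus hubs", len(modules), len(hubs))

        # ---------------------------------------------------- clinical stats
        stage = "clinical_stats"
        markers = hubs if hubs else degs["all"][:8]
        layers: dict[str, pd.DataFrame] = {}
        if markers:
            layers["mRNA"] = _log2_cpm(cohort.counts, [g for g in markers if g in de.index])
        protein_markers = [g for g in markers if g in cohort.protein_levels.index]
        if protein_markers:
            layers["protein"] = cohort.protein_levels.loc[protein_markers]
        correlations = marker_severity_correlations(layers, cohort.samples)
        correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        gtests = group_tests_table(layers, cohort.samples)
        gtests.to_csv(out / "group_tests.tsv", sep="\t", index=False)
        if REFERENCE_GENE in cohort.ct_values.index:
            fold = qpcr_fold_changes(cohort.ct_values, REFERENCE_GENE, groups)
            fold.to_csv(out / "qpcr_fold_changes.tsv", sep="\t", index_label="gene")

        # ------------------------------------------------------ ML consensus
        stage = "ml_consensus"
        candidates = config.candidate_genes or hubs
        candidates = [g for g in candidates if g in de.index]
        report_ml: dict = {}
        if len(candidates) >= 2:
            X = _log2_cpm(cohort.counts, candidates).T
            y = (groups.reindex(X.index) == "MDD").astype(int).to_numpy()
            stab = lasso_stability_selection(
                X,
                y,
                B=config.B_stability,
                threshold=config.stability_threshold,
                seed=seeds["stability"],
            )
            stab.selection_probability.to_csv(out / "stability.tsv", sep="\t")
            rfe = svm_rfe_loocv(X, y, C=config.svm_cost)
            pd.Series(rfe.accuracy_curve, name="loocv_accuracy").rename_axis(
                "n_features"
            ).to_csv(out / "rfe_curve.tsv", sep="\t")
            imp = rf_importance(X, y, ntree=config.ntree, seed=seeds["forest"])
            pd.DataFrame(
                {"mean_decrease_gini": imp.mean_decrease_gini, "rank": imp.rank}
            ).to_csv(out / "importance.tsv", sep="\t", index_label="feature")
            panel = consensus_panel(
                stab.stable_set, rfe.optimal_set, imp.selected_set, universe=candidates
            )
            (out / "panel.txt").write_text("\n".join(panel) + ("\n" if panel else ""))
            report_ml = {
                "candidates": candidates,
                "lasso_set": stab.stable_set,
                "lambda_used": stab.lambda_used,
                "svm_set": rfe.optimal_set,
                "svm_optimal_size": rfe.optimal_size,
                "rf_set": imp.selected_set,
                "panel": panel,
            }
            if panel:
                Xp = X[panel]
                coef, auc, roc = fit_logistic_roc(Xp, y)
                roc.to_csv(out / "roc_points.tsv", sep="\t", index=False)
                auc_obs, perm_p = permutation_test_auc(
                    Xp, y, B=config.B_permutation, seed=seeds["permutation"]
                )
                report_ml.update(
                    {
                        "auc": auc,
                        "permutation_p": perm_p,
                        "coefficients": {k: float(v) for k, v in coef.items()},
                    }
                )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = {
        "mddpanel_version": __version__,
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "deg_count": len(degs["all"]),
        "deg_up": len(degs["up"]),
        "deg_down": len(degs["down"]),
        "hub_genes": hubs,
        "hub_direction": hub_direction,
        "n_modules": len(modules),
        "ml": report_ml,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
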