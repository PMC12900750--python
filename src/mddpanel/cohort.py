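"""Synthetic adolescent-depression cohort generator.

Emulates the statistical structure of a small case/control PBMC
RNA-seq study so every downstream stage (differential expression,
network hub calling, clinical statistics, machine-learning consensus)
can be exercised end to end without any external data:

* 15 cases vs 15 age/sex-matched controls by default;
* negative-binomial counts with a log-normal baseline and a shared
  dispersion (variance mu + phi*mu^2);
* a dichotomous planted hub signature — erythroid/inflammatory genes
  up (SLC4A1, HBB, GYPA, IL6), neurotrophic/remodeling genes down
  (IGF1, CSF2, MMP9, CXCR1);
* integer HAMD-17 severity scores drawn uniformly on 19-33 (cases)
  and 0-6 (controls);
* gene-to-HAMD rank correlations planted through a Gaussian copula
  (latent normals correlated, counts produced by NB quantile transform
  so marginal means are untouched);
* ELISA-like protein levels (affine in the latent log2 signal, with a
  per-gene sign so transcript/protein discordance can be planted) and
  qPCR-like Ct values built so planted fold changes are recoverable by
  the 2^-ddCt method.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import nbinom, norm, poisson

from .de import CountMatrix

UP_HUBS = ("SLC4A1", "HBB", "GYPA", "IL6")
DOWN_HUBS = ("IGF1", "CSF2", "MMP9", "CXCR1")

#: planted hub signature: (symbol, direction, planted log2 fold change)
DEFAULT_HUB_SPEC: tuple[tuple[str, str, float], ...] = tuple(
    [(g, "up", 2.0) for g in UP_HUBS] + [(g, "down", -2.0) for g in DOWN_HUBS]
)

#: planted gene-to-severity rank correlations (mRNA level)
DEFAULT_GENE_HAMD_RHO: dict[str, float] = {"IL6": 0.70, "MMP9": -0.52}

REFERENCE_GENE = "GAPDH"


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: 15/15 cohort, dispersion
    0.1, the 8-gene dichotomous hub plant at |log2FC| = 2, HAMD-17 on
    19-33 / 0-6, ages 12-17, sex split 8/7 vs 7/8.
    """

    n_case: int = 15
    n_control: int = 15
    n_genes: int = 2000
    hub_spec: tuple[tuple[str, str, float], ...] = DEFAULT_HUB_SPEC
    nb_dispersion: float = 0.1
    mean_log_expression: tuple[float, float] = (float(np.log(100.0)), 1.0)
    hamd_case_range: tuple[int, int] = (19, 33)
    hamd_control_range: tuple[int, int] = (0, 6)
    age_range: tuple[int, int] = (12, 17)
    gene_hamd_rho: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GENE_HAMD_RHO)
    )
    protein_sign: dict[str, float] = field(default_factory=lambda: {"IL6": -1.0})
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control", "n_genes"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise ValueError(f"{name} must be an integer, got {v!r}")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("n_case and n_control must be >= 2")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        hub_names = [g for g, _, _ in self.hub_spec]
        if len(hub_names) > self.n_genes:
            raise ValueError("more hub genes than genes in the universe")
        for g, direction, fc in self.hub_spec:
            if direction not in ("up", "down"):
                raise ValueError(f"hub {g}: direction must be 'up' or 'down'")
            if not np.isfinite(fc):
                raise ValueError(f"hub {g}: planted_log2FC must be finite")
            if direction == "up" and fc < 0 or direction == "down" and fc > 0:
                raise ValueError(f"hub {g}: direction inconsistent with log2FC sign {fc}")
        universe = set(self.gene_universe())
        for g, rho in self.gene_hamd_rho.items():
            if abs(rho) > 1:
                raise ValueError(f"gene_hamd_rho[{g}] must be in [-1, 1]")
            if g not in universe:
                raise ValueError(f"gene_hamd_rho gene {g} not in universe")

    def gene_universe(self) -> list[str]:
        hubs = [g for g, _, _ in self.hub_spec]
        n_bg = self.n_genes - len(hubs)
        width = max(4, len(str(max(n_bg, 1))))
        return hubs + [f"GENE{str(i + 1).zfill(width)}" for i in range(n_bg)]


@dataclass
class SyntheticCohort:
    """A generated cohort: counts, sample metadata, protein/Ct analogues, truth."""

    counts: CountMatrix
    samples: pd.DataFrame
    protein_levels: pd.DataFrame
    ct_values: pd.DataFrame
    truth: dict

    @property
    def groups(self) -> pd.Series:
        return self.samples.set_index("sample_id")["group"]


def _nb_ppf(u: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB (or Poisson at phi=0) quantile transform, mean-preserving."""
    if phi <= 0:
        return poisson.ppf(u, mu).astype(np.int64)
    r = 1.0 / phi
    return nbinom.ppf(u, r, r / (r + mu)).astype(np.int64)


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Draw one synthetic cohort; bit-identical for identical params + seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = params.gene_universe()
    n_genes = len(genes)
    n = params.n_case + params.n_control
    case_ids = [f"MDD{i + 1:02d}" for i in range(params.n_case)]
    ctrl_ids = [f"HC{i + 1:02d}" for i in range(params.n_control)]
    sample_ids = case_ids + ctrl_ids
    is_case = np.array([True] * params.n_case + [False] * params.n_control)

    # --- sample metadata -------------------------------------------------
    age = rng.integers(params.age_range[0], params.age_range[1] + 1, size=n)
    # sex split emulating the matched design: 8/7 males in cases, 7/8 in controls
    n_male_case = (params.n_case + 1) // 2
    n_male_ctrl = params.n_control // 2
    sex = np.array(
        ["M"] * n_male_case
        + ["F"] * (params.n_case - n_male_case)
        + ["M"] * n_male_ctrl
        + ["F"] * (params.n_control - n_male_ctrl)
    )

    # HAMD via a latent normal so the copula can couple genes to severity
    z_hamd = rng.standard_normal(n)
    hamd = np.empty(n, dtype=np.int64)
    for grp_mask, (lo, hi) in (
        (is_case, params.hamd_case_range),
        (~is_case, params.hamd_control_range),
    ):
        u = norm.cdf(z_hamd[grp_mask])
        hamd[grp_mask] = np.minimum(lo + np.floor(u * (hi - lo + 1)).astype(np.int64), hi)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": np.where(is_case, "MDD", "HC"),
            "age": age,
            "sex": sex,
            "hamd": hamd,
        }
    )

    # --- counts ----------------------------------------------------------
    loc, scale = params.mean_log_expression
    baseline = np.exp(rng.normal(loc, scale, size=n_genes))
    log2fc = np.zeros(n_genes)
    hub_idx = {g: i for i, g in enumerate(genes)}
    for g, _, fc in params.hub_spec:
        log2fc[hub_idx[g]] = fc
    mu = np.tile(baseline[:, None], (1, n))
    mu[:, is_case] *= 2.0 ** log2fc[:, None]

    # copula-coupled genes use a latent normal shared with HAMD; all other
    # genes use independent uniforms.  Both paths go through the same NB
    # quantile transform, so marginal group means are exact by construction.
    u = rng.random((n_genes, n))
    eps = rng.standard_normal((n_genes, n))  # drawn for all genes: keeps the
    # stream layout (and thus every gene's counts) stable when rho genes change
    for g, rho in params.gene_hamd_rho.items():
        i = hub_idx[g]
        rho_lat = 2.0 * np.sin(np.pi * rho / 6.0)  # Spearman -> latent Pearson
        z = rho_lat * z_hamd + np.sqrt(1.0 - rho_lat**2) * eps[i]
        u[i] = norm.cdf(z)
    counts = _nb_ppf(u, mu, params.nb_dispersion)

    gene_index = pd.Index(genes, name="gene")
    counts_df = pd.DataFrame(counts, index=gene_index, columns=sample_ids)
    gene_lengths = pd.Series(
        rng.integers(300, 10_001, size=n_genes), index=gene_index, name="length"
    )

    # --- protein (ELISA analogue) over the hub panel ---------------------
    hub_genes = [g for g, _, _ in params.hub_spec]
    latent = np.log2(counts_df.loc[hub_genes].to_numpy() + 1.0)
    signs = np.array([params.protein_sign.get(g, 1.0) for g in hub_genes])
    protein = 10.0 + signs[:, None] * (latent - latent.mean(axis=1, keepdims=True))
    protein += rng.normal(0.0, 0.5, size=protein.shape)
    protein_df = pd.DataFrame(
        protein, index=pd.Index(hub_genes, name="gene"), columns=sample_ids
    )

    # --- Ct (qPCR analogue): target Ct = 30 - log2 expression + noise ----
    ct_ref = 20.0 + rng.normal(0.0, 0.1, size=n)
    ct_target = 30.0 - latent + rng.normal(0.0, 0.1, size=latent.shape)
    ct_df = pd.DataFrame(
        ct_target, index=pd.Index(hub_genes, name="gene"), columns=sample_ids
    )
    ct_df.loc[REFERENCE_GENE] = ct_ref

    truth = {
        "seed": int(params.seed),
        "planted_log2fc": {g: float(fc) for g, _, fc in params.hub_spec},
        "planted_direction": {g: d for g, d, _ in params.hub_spec},
        "gene_hamd_rho": {g: float(r) for g, r in params.gene_hamd_rho.items()},
        "protein_sign": {g: float(s) for g, s in params.protein_sign.items()},
        "nb_dispersion": float(params.nb_dispersion),
        "n_case": int(params.n_case),
        "n_control": int(params.n_control),
        "n_genes": int(params.n_genes),
    }

    return SyntheticCohort(
        counts=CountMatrix(counts_df, gene_lengths=gene_lengths),
        samples=samples,
        protein_levels=protein_df,
        ct_values=ct_df,
        truth=truth,
    )


def planted_hub_network(
    hub_genes: list[str],
    background_genes: list[str],
    mean_degree: float = 3.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Synthetic interaction edge list: a hub clique inside sparse noise.

    The hub genes form a clique (one dense module, as a real interaction
    network's core complex would); background genes get Erdos-Renyi noise
    edges at the requested mean degree, plus one random attachment from
    each hub into the background so the graph is not trivially separable.
    """
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []
    for i, a in enumerate(hub_genes):
        for b in hub_genes[i + 1 :]:
            edges.append((a, b))
    m = len(background_genes)
    if m > 1:
        p = min(1.0, mean_degree / max(m - 1, 1))
        upper = rng.random((m, m)) < p
        for i in range(m):
            for j in range(i + 1, m):
                if upper[i, j]:
                    edges.append((background_genes[i], background_genes[j]))
    if m:
        for a in hub_genes:
            edges.append((a, background_genes[int(rng.integers(m))]))
    return edges


# ---------------------------------------------------------------------------
# on-disk round trip


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write counts.tsv, samples.tsv, proteins.tsv, ct.tsv, truth.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": d / "counts.tsv",
        "gene_lengths": d / "gene_lengths.tsv",
        "samples": d / "samples.tsv",
        "proteins": d / "proteins.tsv",
        "ct": d / "ct.tsv",
        "truth": d / "truth.json",
    }
    try:
        cohort.counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
        if cohort.counts.gene_lengths is not None:
            cohort.counts.gene_lengths.rename("length").to_csv(
                paths["gene_lengths"], sep="\t", index_label="gene"
            )
        cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
        cohort.protein_levels.to_csv(paths["proteins"], sep="\t", index_label="gene")
        cohort.ct_values.to_csv(paths["ct"], sep="\t", index_label="gene")
        paths["truth"].write_text(json.dumps(cohort.truth, indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing cohort file {exc.filename}: {exc}") from exc
    return paths


def read_counts(path: str | Path, lengths_path: str | Path | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    lengths = None
    if lengths_path is not None and Path(lengths_path).exists():
        lengths = pd.read_csv(lengths_path, sep="\t", index_col="gene")["length"]
    return CountMatrix(df.astype(np.int64) if df.size else df, gene_lengths=lengths)


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_by_sample(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    d = Path(directory)
    counts = read_counts(d / "counts.tsv", d / "gene_lengths.tsv")
    samples = read_samples(d / "samples.tsv")
    proteins = read_gene_by_sample(d / "proteins.tsv")
    ct = read_gene_by_sample(d / "ct.tsv")
    truth = json.loads((d / "truth.json").read_text())
    return SyntheticCohort(counts, samples, proteins, ct, truth)
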