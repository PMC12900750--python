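"""Normalization and two-group negative-binomial differential expression.

The screen mirrors the classical exact-test workflow for small two-group
RNA-seq designs: counts are scaled to a common (geometric-mean) library
size, a per-gene dispersion is estimated by the method of moments, and
each gene is tested by conditioning on its total count and summing the
probabilities of all case/control splits no more probable than the one
observed.  At dispersion zero the conditional law is exactly binomial
(the Poisson split test); with dispersion it is the ratio of NB products.

Genes are called differentially expressed when both the nominal p-value
and the absolute log2 fold change pass their (strict) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import binom, nbinom, false_discovery_control


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix with optional gene lengths.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integers, genes as rows, samples as columns.
    gene_lengths : pandas.Series, optional
        Transcript lengths in bp, indexed by gene; required for FPKM.
    library_sizes : pandas.Series, optional
        Per-sample totals; defaults to the column sums.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series | None = None
    library_sizes: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be non-negative")
        if vals.size and not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
            present = self.gene_lengths.dropna()
            if (present <= 0).any():
                raise ValueError("gene lengths must be positive")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = self.library_sizes.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def cpm(matrix: CountMatrix) -> pd.DataFrame:
    """Counts per million: ``count / library_size * 1e6``."""
    libs = matrix.library_sizes
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(map(str, zero.index))}")
    return matrix.counts / libs * 1e6


def fpkm(matrix: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase per million: ``count / (len/1e3) / (lib/1e6)``."""
    if matrix.gene_lengths is None:
        raise ValueError("gene lengths required for FPKM")
    missing = matrix.gene_lengths[matrix.gene_lengths.isna()]
    if len(missing):
        raise ValueError(f"missing gene length for: {', '.join(map(str, missing.index))}")
    libs = matrix.library_sizes
    zero = libs[libs <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {', '.join(map(str, zero.index))}")
    kb = matrix.gene_lengths / 1e3
    return matrix.counts.div(kb, axis=0) / (libs / 1e6)


def _check_two_groups(matrix: CountMatrix, groups: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.Series(groups).reindex(matrix.sample_ids)
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    # convention: the *second* level sorted is usually HC/MDD alphabetical;
    # callers pass case label explicitly via differential_expression
    return groups.to_numpy(), np.asarray(levels, dtype=object)


def _scaled_counts(matrix: CountMatrix) -> np.ndarray:
    """Counts rescaled to the geometric-mean library size (pseudo-counts)."""
    libs = matrix.library_sizes.to_numpy(dtype=float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    geo = np.exp(np.mean(np.log(libs)))
    return matrix.counts.to_numpy(dtype=float) * (geo / libs)


def estimate_dispersion(matrix: CountMatrix, groups: pd.Series) -> pd.Series:
    """Method-of-moments NB dispersion, pooled across the two groups.

    phi-hat = max(0, (s2 - m) / m^2) where m is the mean of the group means
    and s2 the df-weighted pooled within-group variance, both computed on
    counts scaled to the geometric-mean library size.
    """
    g, levels = _check_two_groups(matrix, groups)
    scaled = _scaled_counts(matrix)
    means, ss, dfs = [], [], []
    for lev in levels:
        cols = scaled[:, g == lev]
        if cols.shape[1] < 2:
            raise ValueError(f"group {lev!r} has fewer than 2 samples")
        means.append(cols.mean(axis=1))
        ss.append(cols.var(axis=1, ddof=1) * (cols.shape[1] - 1))
        dfs.append(cols.shape[1] - 1)
    m = np.mean(means, axis=0)
    s2 = (ss[0] + ss[1]) / (dfs[0] + dfs[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(m > 0, (s2 - m) / np.square(m), 0.0)
    return pd.Series(np.maximum(phi, 0.0), index=matrix.counts.index, name="dispersion")


def _exact_split_pvalue(s1: int, total: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact test of an observed split of `total`.

    Conditions on the gene total; under equal effective per-sample sizes
    the group sums are NB(n_g*mu, n_g/phi) and the conditional probability
    of each split s is proportional to f1(s) * f2(total-s).  The p-value
    sums the conditional probabilities of every split no more probable
    than the observed one.  phi = 0 degenerates to the binomial split.
    """
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if phi <= 0.0:
        logp = binom.logpmf(s, total, n1 / (n1 + n2))
    else:
        mu = total / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        lp = nbinom.logpmf(s, r1, r1 / (r1 + n1 * mu)) + nbinom.logpmf(
            total - s, r2, r2 / (r2 + n2 * mu)
        )
        logp = lp - logsumexp(lp)
    obs = logp[s1]
    # small slack so exactly-equal probabilities on the far tail are kept
    keep = logp <= obs + 1e-10
    if keep.all():  # observed split at the mode: every split is as probable
        return 1.0
    return float(min(1.0, np.exp(logsumexp(logp[keep]))))


def nb_exact_test(
    matrix: CountMatrix,
    groups: pd.Series,
    dispersions: pd.Series | float,
) -> pd.Series:
    """Per-gene two-sided NB exact split p-values (library-size equalized).

    Unequal library sizes are handled by scaling every sample to the
    geometric-mean library size and rounding, after which the conditional
    test treats effective sizes as equal; exactness is then approximate.
    """
    g, levels = _check_two_groups(matrix, groups)
    if matrix.counts.isna().to_numpy().any():
        raise ValueError("NaN counts")
    if np.isscalar(dispersions):
        disp = np.full(len(matrix.gene_ids), float(dispersions))
    else:
        disp = dispersions.reindex(matrix.counts.index).to_numpy(dtype=float)
    if (disp < 0).any():
        raise ValueError("dispersions must be >= 0")
    scaled = np.rint(_scaled_counts(matrix)).astype(np.int64)
    in1 = g == levels[0]
    n1, n2 = int(in1.sum()), int((~in1).sum())
    s1 = scaled[:, in1].sum(axis=1)
    tot = scaled.sum(axis=1)
    pvals = np.array(
        [_exact_split_pvalue(int(a), int(t), n1, n2, float(d)) for a, t, d in zip(s1, tot, disp)]
    )
    return pd.Series(pvals, index=matrix.counts.index, name="p_value")


def log2_fold_change(
    matrix: CountMatrix,
    groups: pd.Series,
    case_label: str,
    prior: float = 0.5,
) -> pd.Series:
    """log2((mean case CPM + prior) / (mean control CPM + prior))."""
    if prior < 0:
        raise ValueError("prior must be >= 0")
    g, levels = _check_two_groups(matrix, groups)
    if case_label not in levels:
        raise ValueError(f"case label {case_label!r} not among groups {list(levels)}")
    c = cpm(matrix).to_numpy()
    case = c[:, g == case_label].mean(axis=1)
    ctrl = c[:, g != case_label].mean(axis=1)
    return pd.Series(
        np.log2((case + prior) / (ctrl + prior)), index=matrix.counts.index, name="log2fc"
    )


def differential_expression(
    matrix: CountMatrix,
    groups: pd.Series,
    case_label: str = "MDD",
    p_thresh: float = 0.05,
    fc_thresh: float = 1.0,
    prior: float = 0.5,
    dispersions: pd.Series | float | None = None,
    bh: bool = False,
) -> pd.DataFrame:
    """Full DE table: means, log2FC, dispersion, p, DEG flag and direction.

    ``bh=True`` adds a Benjamini-Hochberg ``fdr`` column; the DEG flag
    always uses the nominal p-value (the screen is a discovery filter).
    """
    g, _ = _check_two_groups(matrix, groups)
    c = cpm(matrix)
    if dispersions is None:
        dispersions = estimate_dispersion(matrix, groups)
    table = pd.DataFrame(index=matrix.counts.index)
    table["mean_cpm_case"] = c.loc[:, g == case_label].mean(axis=1)
    table["mean_cpm_control"] = c.loc[:, g != case_label].mean(axis=1)
    table["log2fc"] = log2_fold_change(matrix, groups, case_label, prior)
    table["dispersion"] = (
        dispersions if not np.isscalar(dispersions) else float(dispersions)
    )
    table["p_value"] = nb_exact_test(matrix, groups, dispersions)
    if bh:
        table["fdr"] = false_discovery_control(table["p_value"].to_numpy(), method="bh")
    flags = filter_degs(table, p_thresh, fc_thresh)
    table["is_deg"] = flags["is_deg"]
    table["direction"] = flags["direction"]
    return table


def filter_degs(de: pd.DataFrame, p_thresh: float, fc_thresh: float) -> pd.DataFrame:
    """Strict-threshold DEG call: p < p_thresh and |log2fc| > fc_thresh."""
    if not (0 < p_thresh <= 1):
        raise ValueError("p_thresh must be in (0, 1]")
    if fc_thresh < 0:
        raise ValueError("fc_thresh must be >= 0")
    is_deg = (de["p_value"] < p_thresh) & (de["log2fc"].abs() > fc_thresh)
    direction = np.where(~is_deg, "none", np.where(de["log2fc"] > 0, "up", "down"))
    return pd.DataFrame({"is_deg": is_deg, "direction": direction}, index=de.index)


def deg_sets(de: pd.DataFrame) -> dict[str, list[str]]:
    """Up/down/all DEG gene lists from a flagged DE table."""
    up = list(de.index[(de["is_deg"]) & (de["direction"] == "up")])
    down = list(de.index[(de["is_deg"]) & (de["direction"] == "down")])
    return {"up": up, "down": down, "all": up + down}
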