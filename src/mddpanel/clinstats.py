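"""Clinical statistics: group comparisons, qPCR fold changes, and
covariate-adjusted rank correlations with symptom severity.

Group comparisons follow the normality-gated convention: Shapiro-Wilk in
each group, Welch's t-test when both pass, otherwise a two-sided
Mann-Whitney U (normal approximation with tie and continuity correction;
an exact variant is available).  Categorical 2x2 tables use the
Yates-corrected chi-square.  Marker-severity associations use partial
Spearman correlation: every variable (including covariates such as age
and 0/1-coded sex) is rank-transformed, the ranks are residualized on
the covariate ranks, and the Pearson correlation of the residuals is
tested with a t approximation on n - 2 - #covariates degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class TestResult:
    statistic_name: str  # "t", "U", "chi2_yates"
    statistic: float
    p_value: float
    method_chosen: str


@dataclass
class PartialCorrelation:
    adj_r: float
    adj_p: float
    n: int
    covariates: tuple[str, ...]


def yates_chi_square(table) -> TestResult:
    """Continuity-corrected chi-square on a 2x2 contingency table.

    chi2 = sum (max(|O - E| - 0.5, 0))^2 / E with p from chi-square(df=1).
    The clamp means a table like [[8, 7], [7, 8]] (|O-E| = 0.5 in every
    cell) yields chi2 = 0, p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("cells must be non-negative integers")
    rows, cols, total = t.sum(axis=1), t.sum(axis=0), t.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / total
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    chi2 = float((adj**2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return TestResult("chi2_yates", chi2, p, "chi-square with Yates continuity correction")


def group_compare(
    values,
    groups,
    alpha_normality: float = 0.05,
    exact_mw: bool = False,
) -> TestResult:
    """Normality-gated two-group comparison (Welch t or Mann-Whitney U)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need >= 3 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        warnings.warn("constant input in both groups; returning p = 1")
        return TestResult("t", 0.0, 1.0, "degenerate (constant input)")
    normal = True
    for x in (a, b):
        if np.ptp(x) == 0:
            normal = False  # Shapiro undefined on constants; treat as non-normal
            break
        if stats.shapiro(x).pvalue < alpha_normality:
            normal = False
            break
    if normal:
        res = stats.ttest_ind(a, b, equal_var=False)
        return TestResult("t", float(res.statistic), float(res.pvalue), "welch_t")
    method = "exact" if exact_mw else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult("U", float(res.statistic), float(res.pvalue), "mann_whitney")


def ddct_fold_change(ct_target, ct_ref, mean_dct_control):
    """Relative quantification by 2^-ddCt.

    dCt = ct_target - ct_ref; ddCt = dCt - mean_dct_control; returns
    2^-ddCt (elementwise on arrays).
    """
    dct = np.asarray(ct_target, dtype=float) - np.asarray(ct_ref, dtype=float)
    ddct = dct - np.asarray(mean_dct_control, dtype=float)
    out = 2.0 ** (-ddct)
    return float(out) if np.ndim(out) == 0 else out


def qpcr_fold_changes(
    ct: pd.DataFrame,
    reference_gene: str,
    groups: pd.Series,
    control_label: str = "HC",
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes referenced to the control-group mean dCt.

    ``ct`` is genes x samples and must contain the reference gene row.
    """
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} missing from Ct table")
    groups = pd.Series(groups).reindex(ct.columns)
    ref = ct.loc[reference_gene]
    targets = ct.drop(index=reference_gene)
    dct = targets.sub(ref, axis=1)
    mean_dct_control = dct.loc[:, groups == control_label].mean(axis=1)
    return 2.0 ** (-dct.sub(mean_dct_control, axis=0))


def partial_spearman(x, y, covariates=None) -> PartialCorrelation:
    """Partial Spearman rank correlation of x and y given covariates.

    All variables are rank-transformed (average ranks on ties); x and y
    ranks are residualized on the covariate ranks (with intercept) and
    the Pearson correlation of the residuals is returned.  With no
    covariates this reduces exactly to Spearman's rho.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((len(x), 0))
        cov_names: tuple[str, ...] = ()
    elif isinstance(covariates, pd.DataFrame):
        cov = covariates.to_numpy(dtype=float)
        cov_names = tuple(map(str, covariates.columns))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_names = tuple(f"c{i}" for i in range(cov.shape[1]))
    n, k = len(x), cov.shape[1]
    if len(y) != n or cov.shape[0] != n:
        raise ValueError("x, y and covariates must have the same length")
    if np.isnan(x).any() or np.isnan(y).any() or np.isnan(cov).any():
        raise ValueError("missing values not allowed")
    if n <= k + 2:
        raise ValueError(f"need n > #covariates + 2 (n={n}, covariates={k})")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("constant variable after ranking: correlation undefined")
    rc = np.column_stack([np.ones(n)] + [stats.rankdata(cov[:, j]) for j in range(k)])
    beta_x, *_ = np.linalg.lstsq(rc, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(rc, ry, rcond=None)
    ex = rx - rc @ beta_x
    ey = ry - rc @ beta_y
    denom = np.sqrt((ex**2).sum() * (ey**2).sum())
    if denom == 0:
        raise ValueError("residual variance is zero: correlation undefined")
    r = float(np.clip((ex * ey).sum() / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        tstat = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(tstat), df))
    return PartialCorrelation(adj_r=r, adj_p=p, n=n, covariates=cov_names)


def marker_severity_correlations(
    layers: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
    covariate_cols: tuple[str, ...] = ("age", "sex"),
) -> pd.DataFrame:
    """Partial Spearman of every marker (rows) vs HAMD, per data layer.

    ``layers`` maps a layer name (e.g. "mRNA", "protein") to a
    genes x samples value table.  Sex is coded 0/1 before ranking.
    """
    meta = samples.set_index("sample_id")
    rows = []
    for layer, table in layers.items():
        cov = meta.loc[table.columns, list(covariate_cols)].copy()
        if "sex" in cov:
            cov["sex"] = (cov["sex"] == "M").astype(float)
        hamd = meta.loc[table.columns, "hamd"].to_numpy(dtype=float)
        for marker in table.index:
            pc = partial_spearman(table.loc[marker].to_numpy(dtype=float), hamd, cov)
            rows.append(
                {
                    "marker": marker,
                    "layer": layer,
                    "adj_r": pc.adj_r,
                    "adj_p": pc.adj_p,
                    "n": pc.n,
                }
            )
    return pd.DataFrame(rows, columns=["marker", "layer", "adj_r", "adj_p", "n"])


def group_tests_table(
    layers: dict[str, pd.DataFrame],
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Normality-gated group comparison for every marker in every layer."""
    meta = samples.set_index("sample_id")
    rows = []
    for layer, table in layers.items():
        grp = meta.loc[table.columns, "group"].to_numpy()
        for marker in table.index:
            res = group_compare(table.loc[marker].to_numpy(dtype=float), grp)
            rows.append(
                {
                    "marker": marker,
                    "layer": layer,
                    "statistic_name": res.statistic_name,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method_chosen,
                }
            )
    return pd.DataFrame(
        rows, columns=["marker", "layer", "statistic_name", "statistic", "p_value", "method"]
    )
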