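"""Tri-algorithm feature-selection consensus and diagnostic model.

Three independent selectors are run over the candidate markers
(by default the eight network hubs):

1. **LASSO stability selection** — the L1 penalty is tuned once on the
   full data by leave-one-out cross-validated deviance, then held fixed
   while the cohort is bootstrapped B times *within each class* (so
   every resample keeps the case/control balance); a feature is stable
   when its selection frequency exceeds the threshold (strictly).
2. **SVM-RFE with LOOCV** — a linear soft-margin SVM repeatedly drops
   the feature with the smallest squared weight; classification
   accuracy at every panel size is estimated by leave-one-out
   cross-validation with the ranking recomputed inside each fold (no
   information leaks from the held-out sample into the ranking).
3. **Random-forest Gini importance** — mean decrease in Gini impurity
   accumulated over the trees (unnormalized, randomForest-style).

The diagnostic panel is the exact three-way intersection.  A logistic
model on the panel is summarized by the Mann-Whitney AUC, and the risk
of small-sample optimism is quantified by a label-permutation test with
p = (1 + #{AUC_perm >= AUC_obs}) / (1 + B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC


@dataclass
class StabilityResult:
    selection_probability: pd.Series
    stable_set: list[str]
    B: int
    threshold: float
    lambda_used: float


@dataclass
class RfeResult:
    elimination_order: list[str]  # first eliminated first; survivor last
    accuracy_curve: dict[int, float]
    optimal_size: int
    optimal_set: list[str]


@dataclass
class ImportanceRanking:
    mean_decrease_gini: pd.Series
    rank: pd.Series
    selected_set: list[str]


def _as_xy(X: pd.DataFrame, y) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(y)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("missing values not allowed")
    return vals, labels.astype(int)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def _l1_logistic(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """L1-penalized logistic fit; returns the coefficient vector.

    The penalty uses the (1/n) * loss + lam * ||w||_1 convention, so the
    liblinear cost parameter is C = 1 / (n * lam).
    """
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / (len(y) * lam), solver="liblinear", tol=1e-7, max_iter=2000
    )
    model.fit(x, y)
    return model.coef_.ravel()


def _lambda_path(x: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(x.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambda)


def loocv_lambda(
    x: np.ndarray, y: np.ndarray, n_lambda: int = 40, rule: str = "1se"
) -> float:
    """L1 penalty by LOOCV binomial deviance over a log-spaced path.

    ``rule="min"`` takes the deviance minimizer (ties -> sparser);
    ``rule="1se"`` (default) takes the largest penalty whose mean deviance
    is within one standard error of the minimum — the usual parsimony
    rule for cross-validated lasso paths.
    """
    if rule not in ("min", "1se"):
        raise ValueError(f"unknown lambda rule {rule!r}")
    path = _lambda_path(x, y, n_lambda)
    n = len(y)
    dev = np.zeros((n, len(path)))
    eps = 1e-12
    for i in range(n):
        tr = np.arange(n) != i
        xt, yt = x[tr], y[tr]
        for j, lam in enumerate(path):
            model = LogisticRegression(
                l1_ratio=1.0,
                C=1.0 / (tr.sum() * lam),
                solver="liblinear",
                tol=1e-7,
                max_iter=2000,
            )
            model.fit(xt, yt)
            p = model.predict_proba(x[i : i + 1])[0, 1]
            p = np.clip(p, eps, 1 - eps)
            dev[i, j] = -2.0 * (y[i] * np.log(p) + (1 - y[i]) * np.log(1 - p))
    mean = dev.mean(axis=0)
    jmin = int(np.flatnonzero(mean == mean.min())[0])  # path descends: first = sparsest
    if rule == "min":
        return float(path[jmin])
    se = dev[:, jmin].std(ddof=1) / np.sqrt(n)
    j1se = int(np.flatnonzero(mean <= mean[jmin] + se)[0])
    return float(path[j1se])


def lasso_stability_selection(
    X: pd.DataFrame,
    y,
    B: int = 100,
    threshold: float = 0.6,
    seed: int = 0,
    lam: float | None = None,
    lambda_rule: str = "1se",
    per_iteration_lambda: bool = False,
) -> StabilityResult:
    """Stratified-bootstrap stability selection around an L1 logistic model.

    Features are z-scored internally.  ``lam=None`` triggers the LOOCV
    tuning on the full data (``lambda_rule`` picks min-deviance or the
    one-standard-error point); ``per_iteration_lambda=True`` re-tunes
    inside every bootstrap instead (slower, offered for comparison).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x, labels = _as_xy(X, y)
    x = _zscore(x)
    if lam is None and not per_iteration_lambda:
        lam = loocv_lambda(x, labels, rule=lambda_rule)
    rng = np.random.default_rng(seed)
    idx_case = np.flatnonzero(labels == 1)
    idx_ctrl = np.flatnonzero(labels == 0)
    hits = np.zeros(x.shape[1])
    for _ in range(B):
        boot = np.concatenate(
            [
                rng.choice(idx_case, size=len(idx_case), replace=True),
                rng.choice(idx_ctrl, size=len(idx_ctrl), replace=True),
            ]
        )
        xb, yb = x[boot], labels[boot]
        lam_b = loocv_lambda(xb, yb, rule=lambda_rule) if per_iteration_lambda else lam
        coef = _l1_logistic(xb, yb, lam_b)
        hits += np.abs(coef) > 1e-10
    prob = pd.Series(hits / B, index=X.columns, name="selection_probability")
    stable = [f for f in X.columns if prob[f] > threshold]
    return StabilityResult(prob, stable, B, threshold, float(lam if lam is not None else np.nan))


def _rfe_ranking(x: np.ndarray, y: np.ndarray, features: list[int], C: float) -> list[int]:
    """Backward elimination order (first eliminated first) on given data."""
    order: list[int] = []
    current = list(features)
    while len(current) > 1:
        svm = SVC(kernel="linear", C=C)
        svm.fit(x[:, current], y)
        w2 = svm.coef_.ravel() ** 2
        drop = int(np.argmin(w2))  # ties: lowest index (deterministic)
        order.append(current.pop(drop))
    order.append(current[0])
    return order


def svm_rfe_loocv(
    X: pd.DataFrame,
    y,
    C: float = 1.0,
    nested: bool = True,
) -> RfeResult:
    """SVM recursive feature elimination with leave-one-out accuracy.

    ``nested=True`` (default) recomputes the elimination ranking inside
    each LOOCV fold; ``nested=False`` reuses the full-data ranking (the
    optimistic variant, for comparison only).
    """
    x, labels = _as_xy(X, y)
    if x.shape[1] < 2:
        raise ValueError("need >= 2 features")
    x = _zscore(x)
    n, p = x.shape
    feats = list(range(p))
    full_order = _rfe_ranking(x, labels, feats, C)
    errors = np.zeros(p)  # errors[s-1] = LOOCV misclassifications with s features
    for i in range(n):
        tr = np.arange(n) != i
        order = _rfe_ranking(x[tr], labels[tr], feats, C) if nested else full_order
        for s in range(1, p + 1):
            keep = order[-s:]
            svm = SVC(kernel="linear", C=C)
            svm.fit(x[tr][:, keep], labels[tr])
            pred = svm.predict(x[i : i + 1, keep])[0]
            errors[s - 1] += pred != labels[i]
    acc = {s: float(1.0 - errors[s - 1] / n) for s in range(1, p + 1)}
    best = max(acc.values())
    optimal_size = min(s for s, a in acc.items() if a == best)
    optimal_set = [X.columns[j] for j in full_order[-optimal_size:]]
    return RfeResult(
        elimination_order=[X.columns[j] for j in full_order],
        accuracy_curve=acc,
        optimal_size=optimal_size,
        optimal_set=sorted(optimal_set, key=list(X.columns).index),
    )


def rf_importance(
    X: pd.DataFrame,
    y,
    ntree: int = 2000,
    seed: int = 0,
    rule: str = "positive",
    top_k: int | None = None,
) -> ImportanceRanking:
    """Random-forest mean-decrease-Gini importance ranking.

    ``rule="positive"`` selects every feature with importance > 0 (the
    permissive default); ``rule="top_k"`` keeps the top_k by rank.
    """
    if ntree < 1:
        raise ValueError("ntree must be >= 1")
    x, labels = _as_xy(X, y)
    forest = RandomForestClassifier(
        n_estimators=ntree,
        criterion="gini",
        max_features="sqrt",
        bootstrap=True,
        random_state=int(seed) % (2**31),
    )
    forest.fit(x, labels)
    # unnormalized mean decrease in impurity, averaged over trees
    imp = np.mean(
        [t.tree_.compute_feature_importances(normalize=False) for t in forest.estimators_],
        axis=0,
    )
    mdg = pd.Series(imp, index=X.columns, name="mean_decrease_gini")
    order = sorted(X.columns, key=lambda f: (-mdg[f], f))
    rank = pd.Series({f: i + 1 for i, f in enumerate(order)}, name="rank")
    if rule == "positive":
        selected = [f for f in X.columns if mdg[f] > 0]
    elif rule == "top_k":
        if top_k is None:
            raise ValueError("top_k required for rule='top_k'")
        selected = order[:top_k]
        selected = sorted(selected, key=list(X.columns).index)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return ImportanceRanking(mdg, rank.reindex(X.columns), selected)


def consensus_panel(
    lasso_set,
    svm_set,
    rf_set,
    universe: list[str] | None = None,
) -> list[str]:
    """Exact three-way intersection, in stable (universe or sorted) order."""
    inter = set(lasso_set) & set(svm_set) & set(rf_set)
    if not inter:
        warnings.warn("consensus panel is empty: the three selectors do not agree")
    if universe is not None:
        return [f for f in universe if f in inter]
    return sorted(inter)


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney probability that a case outscores a control.

    Ties between a case and a control count one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def fit_logistic_roc(X: pd.DataFrame, y, l2: float = 1e-4):
    """Logistic model on the panel with a small ridge stabilizer.

    Returns (coefficients including intercept, in-sample AUC, ROC points
    as a DataFrame of (fpr, tpr) over all score thresholds).
    """
    x, labels = _as_xy(X, y)
    model = LogisticRegression(
        l1_ratio=0.0, C=1.0 / (len(labels) * l2), solver="lbfgs", max_iter=5000
    )
    model.fit(x, labels)
    scores = model.decision_function(x)
    auc = auc_mann_whitney(scores, labels)
    order = np.argsort(-scores, kind="mergesort")
    tp = np.concatenate([[0], np.cumsum(labels[order] == 1)])
    fp = np.concatenate([[0], np.cumsum(labels[order] == 0)])
    roc = pd.DataFrame(
        {"fpr": fp / max(fp[-1], 1), "tpr": tp / max(tp[-1], 1)}
    ).drop_duplicates()
    coef = pd.Series(
        np.concatenate([model.intercept_, model.coef_.ravel()]),
        index=["intercept"] + list(X.columns),
        name="coefficient",
    )
    return coef, auc, roc


def permutation_test_auc(
    X: pd.DataFrame,
    y,
    B: int = 1000,
    seed: int = 0,
    l2: float = 1e-4,
) -> tuple[float, float]:
    """Label-permutation calibration of the in-sample panel AUC.

    The logistic model is refit on each permuted label vector; the
    p-value (1 + #{AUC_perm >= AUC_obs}) / (1 + B) has floor 1/(B+1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    x, labels = _as_xy(X, y)
    _, auc_obs, _ = fit_logistic_roc(X, y, l2)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(B):
        perm = rng.permutation(labels)
        if len(np.unique(perm)) < 2:  # cannot happen for fixed label counts
            continue
        _, auc_b, _ = fit_logistic_roc(X, perm, l2)
        exceed += auc_b >= auc_obs
    return float(auc_obs), float((1 + exceed) / (1 + B))
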