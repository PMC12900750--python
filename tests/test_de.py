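"""Normalization formulas and the NB exact split test against brute force."""

import math

import numpy as np
import pandas as pd
import pytest

from mddpanel.cohort import CohortParams, generate_cohort
from mddpanel.de import (
    CountMatrix,
    cpm,
    differential_expression,
    estimate_dispersion,
    filter_degs,
    fpkm,
    log2_fold_change,
    nb_exact_test,
)


def binomial_split_pvalue(s1: int, total: int, n1: int, n2: int) -> float:
    """Independent oracle: enumerate all splits of `total` between groups
    under the symmetric conditional (binomial) law; sum the probabilities
    of every split no more probable than the observed one."""
    if total == 0:
        return 1.0
    q = n1 / (n1 + n2)
    probs = [math.comb(total, s) * q**s * (1 - q) ** (total - s) for s in range(total + 1)]
    obs = probs[s1]
    return min(1.0, sum(p for p in probs if p <= obs * (1 + 1e-9)))


def _matrix(rows: dict[str, list[int]], lib: float = 1e6) -> CountMatrix:
    df = pd.DataFrame(rows).T
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return CountMatrix(df, library_sizes=pd.Series(lib, index=df.columns))


class TestNormalization:
    def test_cpm_formula(self, toy_counts):
        out = cpm(toy_counts)
        assert out.loc["gA", "s1"] == pytest.approx(500_000.0)
        assert (out.loc["gB"] == 0).all()

    def test_cpm_derived_value(self):
        cm = _matrix({"g": [123]}, lib=4_567_890)
        assert cpm(cm).iloc[0, 0] == pytest.approx(123 / 4_567_890 * 1e6)

    def test_cpm_zero_library_names_sample(self, toy_counts):
        toy_counts.library_sizes["s2"] = 0
        with pytest.raises(ValueError, match="s2"):
            cpm(toy_counts)

    def test_fpkm_formula(self):
        cm = _matrix({"g": [100]}, lib=1e7)
        cm.gene_lengths = pd.Series([2000], index=["g"])
        assert fpkm(cm).iloc[0, 0] == pytest.approx(5.0)

    def test_fpkm_derived_value_and_zero(self):
        cm = _matrix({"g": [250], "z": [0]}, lib=2e6)
        cm.gene_lengths = pd.Series([1500, 1000], index=["g", "z"])
        out = fpkm(cm)
        assert out.loc["g"].iloc[0] == pytest.approx(250 / 1.5 / 2)
        assert out.loc["z"].iloc[0] == 0

    def test_fpkm_missing_lengths_listed(self, toy_counts):
        toy_counts.gene_lengths = pd.Series([2000, np.nan, 1000], index=toy_counts.gene_ids)
        with pytest.raises(ValueError, match="gB"):
            fpkm(toy_counts)


class TestDispersion:
    def test_constant_counts_give_zero(self):
        cm = _matrix({"g": [10, 10, 10, 10]})
        groups = pd.Series(["A", "A", "B", "B"], index=cm.sample_ids)
        assert estimate_dispersion(cm, groups).iloc[0] == 0.0

    def test_method_of_moments_value(self):
        # both groups mean 100, within-group variance 300 -> phi = 0.02
        a = [80, 100, 120]  # mean 100 var 400
        b = [90, 100, 110]  # mean 100 var 100
        cm = _matrix({"g": a + b})
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=cm.sample_ids)
        # pooled variance (400+100)/2 = 250 -> (250-100)/1e4
        assert estimate_dispersion(cm, groups).iloc[0] == pytest.approx((250 - 100) / 100**2)

    def test_poisson_like_gene_clamps_at_zero(self, rng):
        cm = _matrix({"g": list(rng.poisson(50, size=8))})
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cm.sample_ids)
        assert estimate_dispersion(cm, groups).iloc[0] >= 0.0

    def test_single_sample_group_rejected(self):
        cm = _matrix({"g": [1, 2, 3]})
        groups = pd.Series(["A", "A", "B"], index=cm.sample_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(cm, groups)


class TestExactTest:
    def test_matches_binomial_enumeration_at_zero_dispersion(self, rng):
        """phi=0 agrees with the independent split enumeration to 1e-12."""
        for _ in range(60):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            total = int(rng.integers(0, 51))
            s1 = int(rng.integers(0, total + 1))
            counts = _split_counts(s1, total, n1, n2)
            cm = _matrix({"g": counts})
            groups = pd.Series(["A"] * n1 + ["B"] * n2, index=cm.sample_ids)
            p = nb_exact_test(cm, groups, 0.0).iloc[0]
            assert p == pytest.approx(binomial_split_pvalue(s1, total, n1, n2), abs=1e-12)

    def test_zero_total_gives_p_one(self):
        cm = _matrix({"g": [0, 0, 0, 0]})
        groups = pd.Series(["A", "A", "B", "B"], index=cm.sample_ids)
        assert nb_exact_test(cm, groups, 0.3).iloc[0] == 1.0

    def test_balanced_split_at_mode_gives_p_one(self):
        cm = _matrix({"g": [5, 5, 5, 5]})
        groups = pd.Series(["A", "A", "B", "B"], index=cm.sample_ids)
        assert nb_exact_test(cm, groups, 0.0).iloc[0] == 1.0

    def test_extreme_split_matches_symmetric_binomial_tail(self):
        total = 20
        cm = _matrix({"g": [total, 0, 0, 0]})  # all counts in group A (n1=n2=2)
        groups = pd.Series(["A", "A", "B", "B"], index=cm.sample_ids)
        p = nb_exact_test(cm, groups, 0.0).iloc[0]
        assert p == pytest.approx(2 * 0.5**total, abs=1e-12)
        assert p == pytest.approx(binomial_split_pvalue(total, total, 2, 2), abs=1e-12)

    def test_pvalues_in_unit_interval_with_dispersion(self, rng):
        counts = {f"g{i}": list(rng.poisson(30, 8)) for i in range(20)}
        cm = _matrix(counts)
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=cm.sample_ids)
        p = nb_exact_test(cm, groups, 0.2)
        assert ((p > 0) & (p <= 1)).all()

    def test_more_than_two_groups_rejected(self):
        cm = _matrix({"g": [1, 2, 3]})
        groups = pd.Series(["A", "B", "C"], index=cm.sample_ids)
        with pytest.raises(ValueError, match="two groups"):
            nb_exact_test(cm, groups, 0.0)


def _split_counts(s1: int, total: int, n1: int, n2: int) -> list[int]:
    """Distribute s1 over n1 samples and total-s1 over n2 samples."""
    a = [s1 // n1] * n1
    a[0] += s1 - sum(a)
    b = [(total - s1) // n2] * n2
    b[0] += (total - s1) - sum(b)
    return a + b


class TestFoldChangeAndFilter:
    def test_identical_means_give_zero(self, toy_counts):
        groups = pd.Series(["A", "A", "B", "B"], index=toy_counts.sample_ids)
        assert (log2_fold_change(toy_counts, groups, "A", prior=0.5).abs() < 1e-12).all()

    def test_formula_forced_value(self):
        cm = _matrix({"g": [40, 40, 10, 10]})
        groups = pd.Series(["case", "case", "ctrl", "ctrl"], index=cm.sample_ids)
        assert log2_fold_change(cm, groups, "case", prior=0.0).iloc[0] == pytest.approx(2.0)

    def test_prior_cancels_on_all_zero_gene(self):
        cm = _matrix({"g": [0, 0, 0, 0]})
        groups = pd.Series(["A", "A", "B", "B"], index=cm.sample_ids)
        assert log2_fold_change(cm, groups, "A", prior=0.5).iloc[0] == 0.0

    def test_filter_is_strict_at_both_boundaries(self):
        de = pd.DataFrame(
            {"p_value": [0.05, 0.01, 0.01, 0.2], "log2fc": [3.0, 1.5, 0.5, 3.0]},
            index=list("abcd"),
        )
        out = filter_degs(de, 0.05, 1.0)
        assert list(out.index[out.is_deg]) == ["b"]
        assert out.loc["b", "direction"] == "up"
        wide = filter_degs(de, 1.0, 0.0)
        assert wide.is_deg.all()  # every gene has p < 1 and |fc| > 0

    def test_group_swap_negates_fc_and_keeps_p(self, small_cohort):
        cm, groups = small_cohort.counts, small_cohort.groups
        de1 = differential_expression(cm, groups, case_label="MDD")
        de2 = differential_expression(cm, groups, case_label="HC")
        np.testing.assert_allclose(de1["log2fc"], -de2["log2fc"], atol=1e-10)
        np.testing.assert_allclose(de1["p_value"], de2["p_value"], atol=1e-12)

    def test_bh_column_is_monotone_adjustment(self, small_cohort):
        de = differential_expression(small_cohort.counts, small_cohort.groups, bh=True)
        assert (de["fdr"] >= de["p_value"] - 1e-12).all()
        assert de["fdr"].max() <= 1.0


def test_planted_degs_recovered_with_high_power():
    """|log2FC|=2 plants at dispersion 0.1 and ample baseline are flagged
    as DEGs in >=90% of seeded replicates."""
    hits = trials = 0
    for seed in range(20):
        params = CohortParams(
            n_genes=40,
            mean_log_expression=(np.log(200.0), 0.4),
            seed=seed,
        )
        c = generate_cohort(params)
        de = differential_expression(c.counts, c.groups)
        ctrl_mean = c.counts.counts.loc[:, c.groups[c.groups == "HC"].index].mean(axis=1)
        for g in c.truth["planted_log2fc"]:
            if ctrl_mean[g] >= 50:
                trials += 1
                hits += bool(de.loc[g, "is_deg"])
    assert trials > 100
    assert hits / trials >= 0.90
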