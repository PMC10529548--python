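"""Univariate tests and PCA against hand-computed and enumerated oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from museomics.morphstats import (
    chisq_2x2,
    contingency,
    fisher_exact_2x2,
    fisher_exact_rxc,
    pca_standardized,
    two_way_ancova,
    two_way_anova,
)
from museomics.simulate import simulate_morphology


# ---------------------------------------------------------------------------
# chi-squared


def test_chisq_perfect_association():
    res = chisq_2x2([[10, 0], [0, 10]])
    assert res.statistic == pytest.approx(20.0)
    assert res.df == 1


def test_chisq_perfect_independence():
    res = chisq_2x2([[5, 5], [5, 5]])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chisq_hand_computed():
    res = chisq_2x2([[8, 2], [4, 6]])
    assert res.statistic == pytest.approx(10 / 3, abs=1e-9)


def test_chisq_yates_matches_scipy():
    table = [[8, 2], [4, 6]]
    ours = chisq_2x2(table, continuity_correction=True)
    ref = stats.chi2_contingency(np.array(table), correction=True)
    assert ours.statistic == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)


def test_chisq_invariance_under_transposition():
    t = np.array([[8, 2], [4, 6]])
    s0 = chisq_2x2(t).statistic
    assert chisq_2x2(t.T).statistic == pytest.approx(s0)
    assert chisq_2x2(t[::-1]).statistic == pytest.approx(s0)
    assert chisq_2x2(t[:, ::-1]).statistic == pytest.approx(s0)


def test_chisq_zero_margin_suggests_fisher():
    with pytest.raises(ValueError, match="[Ff]isher"):
        chisq_2x2([[0, 0], [3, 4]])


# ---------------------------------------------------------------------------
# Fisher


def exact_fisher_oracle(table):
    """Exact-arithmetic enumeration over the hypergeometric family."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    weights = {
        k: math.comb(r1, k) * math.comb(r2, c1 - k)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    w_obs = weights[a]
    total = sum(weights.values())
    return sum(w for w in weights.values() if w <= w_obs) / total


def test_fisher_diagonal_table():
    res = fisher_exact_2x2([[3, 0], [0, 3]])
    assert res.p_value == pytest.approx(0.1)


def test_fisher_uniform_table():
    assert fisher_exact_2x2([[1, 1], [1, 1]]).p_value == pytest.approx(1.0)


def test_fisher_matches_exact_oracle_sampled(rng):
    for _ in range(200):
        t = rng.integers(0, 9, size=(2, 2))
        if t.sum() == 0:
            continue
        ours = fisher_exact_2x2(t).p_value
        want = exact_fisher_oracle(t.tolist())
        assert ours == pytest.approx(want, abs=1e-9)


def test_fisher_rxc_reduces_to_2x2():
    t = [[5, 1], [2, 6]]
    assert fisher_exact_rxc(t).p_value == pytest.approx(
        fisher_exact_2x2(t).p_value, abs=1e-9
    )


def test_fisher_rxc_2x3():
    t = [[4, 1, 0], [1, 3, 3]]
    ours = fisher_exact_rxc(t).p_value
    # frozen oracle from R: fisher.test(matrix(c(4,1,1,3,0,3), nrow=2))
    assert ours == pytest.approx(0.116161616162, abs=1e-9)


# ---------------------------------------------------------------------------
# ANOVA / ANCOVA


def balanced_table():
    rows = []
    vals = {
        ("SA", "M"): [40, 41, 42, 43],
        ("SA", "F"): [38, 39, 40, 41],
        ("ZW", "M"): [36, 37, 38, 39],
        ("ZW", "F"): [34, 35, 36, 37],
    }
    i = 0
    for (pop, sex), ys in vals.items():
        for y in ys:
            rows.append({"specimen_id": f"s{i}", "population": pop, "sex": sex, "subcaudals": y})
            i += 1
    return pd.DataFrame(rows)


def test_anova_hand_computed_balanced():
    """Balanced 2x2 with means 41.5/39.5/37.5/35.5: SS_pop = 64, SS_sex = 16,
    SS_inter = 0, MS_resid = 5/3."""
    res = {r.effect: r for r in two_way_anova(balanced_table(), "subcaudals")}
    ms_resid = 20 / 12  # SS_resid 20 on 12 df
    assert res["population"].statistic == pytest.approx(64 / ms_resid)
    assert res["sex"].statistic == pytest.approx(16 / ms_resid)
    assert res["population:sex"].statistic == pytest.approx(0.0, abs=1e-10)


def test_anova_equal_means_gives_zero_f():
    df = balanced_table()
    # identical values in every cell: all group means equal, within-cell
    # variance nonzero
    df["subcaudals"] = np.tile([38.0, 39.0, 41.0, 42.0], 4)
    res = two_way_anova(df, "subcaudals")
    for r in res:
        assert abs(r.statistic) < 1e-10


def test_anova_reduces_to_one_way():
    df = balanced_table()
    df["sex"] = "M"  # factor B constant -> one-way on A
    (res,) = two_way_anova(df, "subcaudals")
    groups = [g["subcaudals"].to_numpy() for _, g in df.groupby("population", observed=True)]
    oracle = stats.f_oneway(*groups)
    assert res.statistic == pytest.approx(oracle.statistic)
    assert res.p_value == pytest.approx(oracle.pvalue)


def test_ancova_no_group_structure():
    rng_ = np.random.default_rng(3)
    n = 80
    svl = rng_.uniform(400, 900, n)
    df = pd.DataFrame(
        {
            "TL": 0.2 * svl,  # exactly linear, no sex/population signal
            "SVL": svl,
            "population": np.where(np.arange(n) % 2 == 0, "SA", "ZW"),
            "sex": np.where(np.arange(n) % 4 < 2, "M", "F"),
        }
    )
    res = {r.effect: r for r in two_way_ancova(df)}
    assert abs(res["population"].statistic) < 1e-10
    assert abs(res["sex"].statistic) < 1e-10


def test_ancova_degenerate_covariate_errors():
    df = balanced_table()
    df["SVL"] = 500.0
    df["TL"] = 100.0
    with pytest.raises(ValueError):
        two_way_ancova(df)


def test_ancova_detects_sex_effect():
    """Known sex effect on TL residuals is detected at alpha 0.01 in most
    replicates (power check at n=200, large effect)."""
    hits = 0
    n_rep = 25
    for rep in range(n_rep):
        df = simulate_morphology(n_per_group=50, seed=900 + rep)
        res = {r.effect: r for r in two_way_ancova(df)}
        hits += res["sex"].p_value < 0.01
    assert hits >= int(0.9 * n_rep)


# ---------------------------------------------------------------------------
# PCA


def test_pca_two_perfectly_correlated_characters():
    df = pd.DataFrame(
        {
            "specimen_id": [f"s{i}" for i in range(6)],
            "x": [1.0, 2, 3, 4, 5, 6],
            "y": [2.0, 4, 6, 8, 10, 12],
        }
    )
    res = pca_standardized(df, ["x", "y"])
    assert res.eigenvalues[0] == pytest.approx(2.0)
    assert res.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
    assert res.percent_variance[0] == pytest.approx(100.0)


def test_pca_eigenvalue_sum_is_character_count():
    table = simulate_morphology(n_per_group=12, seed=44)
    res = pca_standardized(table)
    assert res.eigenvalues.sum() == pytest.approx(4.0, abs=1e-9)
    assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)


def test_pca_scores_and_orthonormality():
    table = simulate_morphology(n_per_group=15, seed=45)
    res = pca_standardized(table)
    assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(res.scores.var(axis=0, ddof=1), res.eigenvalues, atol=1e-9)
    assert np.allclose(res.eigenvectors.T @ res.eigenvectors, np.eye(4), atol=1e-9)
    # sign convention: dominant loading positive
    for j in range(4):
        col = res.eigenvectors[:, j]
        assert col[np.argmax(np.abs(col))] > 0


def test_pca_complete_case_exclusion():
    table = simulate_morphology(n_per_group=8, seed=46)
    table.loc[table.index[:3], "ventrals"] = np.nan
    res = pca_standardized(table)
    assert len(res.specimen_ids) == len(table) - 3


def test_pca_zero_variance_errors():
    df = pd.DataFrame(
        {"specimen_id": list("abc"), "x": [1.0, 1, 1], "y": [1.0, 2, 3]}
    )
    with pytest.raises(ValueError, match="zero-variance"):
        pca_standardized(df, ["x", "y"])


def test_contingency_dichotomisation():
    table = simulate_morphology(n_per_group=30, seed=47)
    tab = contingency(table, "midbody_rows", cut=18.5)
    assert tab.shape[0] == 2
    assert tab.sum() == table["midbody_rows"].notna().sum()
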