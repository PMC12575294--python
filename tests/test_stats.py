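"""Rank/distribution tests, two-way ANOVA, discrimination ratio."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import mfquant as m


# --- Mann-Whitney ----------------------------------------------------------


def brute_force_mw_p(a, b):
    """Exact two-sided permutation p for U by enumerating all labelings."""
    vals = list(a) + list(b)
    na, nb = len(a), len(b)
    # rank the fixed pooled values once; relabel which belong to sample a
    ranks = sps.rankdata(vals)
    mu = na * nb / 2
    obs = sum(ranks[:na]) - na * (na + 1) / 2
    count = total = 0
    for comb in itertools.combinations(range(na + nb), na):
        u = sum(ranks[i] for i in comb) - na * (na + 1) / 2
        total += 1
        if abs(u - mu) >= abs(obs - mu) - 1e-12:
            count += 1
    return count / total


def test_mw_complete_separation():
    res = m.mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 20)  # 2 of C(6,3) labelings


def test_mw_identical_samples():
    res = m.mann_whitney([1, 2, 3], [1, 2, 3])
    assert res.p_value > 0.9


def test_mw_exact_matches_enumeration_with_ties():
    a, b = [1, 2, 3, 4], [3, 4, 5, 6]
    res = m.mann_whitney(a, b)
    assert res.p_value == pytest.approx(brute_force_mw_p(a, b))
    assert "exact" in res.details["method"]


def test_mw_large_samples_use_asymptotic():
    rng = np.random.default_rng(0)
    res = m.mann_whitney(rng.normal(size=50), rng.normal(0.5, size=50))
    assert res.details["method"].startswith("asymptotic")
    assert 0 < res.p_value < 1


def test_mw_empty_sample_rejected():
    with pytest.raises(m.ParameterError):
        m.mann_whitney([], [1.0])


# --- Kolmogorov-Smirnov ----------------------------------------------------


def ecdf_sweep_d(a, b):
    """Direct ECDF supremum (oracle)."""
    pts = np.unique(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), pts, side="right") / len(a)
    fb = np.searchsorted(np.sort(b), pts, side="right") / len(b)
    return np.abs(fa - fb).max()


def test_ks_identical_zero():
    assert m.ks_two_sample([1, 2, 3], [1, 2, 3]).statistic == 0.0


def test_ks_disjoint_supports_one():
    assert m.ks_two_sample([1, 2, 3], [10, 11, 12]).statistic == 1.0


@pytest.mark.parametrize("seed", range(5))
def test_ks_matches_ecdf_oracle(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=37)
    b = rng.normal(0.3, 1.2, size=53)
    res = m.ks_two_sample(a, b)
    assert res.statistic == pytest.approx(ecdf_sweep_d(a, b), abs=1e-12)


def test_ks_simple_case():
    res = m.ks_two_sample([1, 2, 3], [2, 3, 4])
    assert res.statistic == pytest.approx(1 / 3)


# --- type-I calibration ----------------------------------------------------


def test_mw_ks_type1_error_calibrated():
    """Under the null both tests reject at ~5%: empirical rate within
    [0.03, 0.07] over 2,000 seeded simulations."""
    n_sim = 2000
    rej_mw = rej_ks = 0
    rng = np.random.default_rng(12345)
    for _ in range(n_sim):
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        rej_mw += m.mann_whitney(a, b).p_value <= 0.05
        rej_ks += m.ks_two_sample(a, b).p_value <= 0.05
    assert 0.03 <= rej_mw / n_sim <= 0.07
    assert 0.03 <= rej_ks / n_sim <= 0.07


# --- two-way ANOVA ---------------------------------------------------------


def unbalanced_cohort_frame(delta, seed, sd=0.4):
    """2M/3F vs 3M/4F cells (n=5 vs 7 mice)."""
    rng = np.random.default_rng(seed)
    rows = []
    for g, base, n_sex in (("ET", 5.0, (2, 3)), ("CT", 5.0 + delta, (3, 4))):
        for sex, k in zip(("M", "F"), n_sex):
            for _ in range(k):
                rows.append(
                    {"value": rng.normal(base, sd), "group": g, "sex": sex}
                )
    return pd.DataFrame(rows)


def test_anova_df_matches_5v7_design():
    """5 vs 7 mice in 4 cells: Group df = 1, residual df = 8."""
    res = m.anova_two_way(unbalanced_cohort_frame(1.5, 0))
    assert res.details["terms"]["group"]["df"] == 1.0
    assert res.details["residual_df"] == 8.0
    assert res.n_a + res.n_b == 12


def test_anova_power_on_pure_group_effect():
    """delta = 2 sigma, 6/cell balanced: Group term significant in >= 80%
    of 100 seeded replicates."""
    hits = 0
    n_rep = 100
    for s in range(n_rep):
        rng = np.random.default_rng(5000 + s)
        rows = []
        for g, mu in (("A", 0.0), ("B", 2.0)):
            for sex in ("M", "F"):
                for _ in range(6):
                    rows.append(
                        {"value": rng.normal(mu, 1.0), "group": g, "sex": sex}
                    )
        res = m.anova_two_way(pd.DataFrame(rows))
        hits += res.p_value <= 0.05
    assert hits / n_rep >= 0.80


def test_anova_constant_data_degenerate():
    df = pd.DataFrame(
        {
            "value": [2.0] * 8,
            "group": ["A"] * 4 + ["B"] * 4,
            "sex": ["M", "F"] * 4,
        }
    )
    res = m.anova_two_way(df)
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_anova_type3_equals_sequential_when_balanced():
    rng = np.random.default_rng(2)
    rows = []
    for g in ("A", "B"):
        for sex in ("M", "F"):
            for _ in range(6):
                rows.append(
                    {
                        "value": rng.normal(1.0 if g == "B" else 0.0, 1.0),
                        "group": g,
                        "sex": sex,
                    }
                )
    df = pd.DataFrame(rows)
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    fit = smf.ols("value ~ C(group, Sum) * C(sex, Sum)", data=df).fit()
    seq = anova_lm(fit, typ=1)
    res = m.anova_two_way(df)
    terms = res.details["terms"]
    assert terms["group"]["sum_sq"] == pytest.approx(
        float(seq.loc["C(group, Sum)", "sum_sq"])
    )
    assert terms["sex"]["sum_sq"] == pytest.approx(
        float(seq.loc["C(sex, Sum)", "sum_sq"])
    )


def test_anova_empty_cell_drops_interaction():
    df = pd.DataFrame(
        {
            "value": np.arange(9, dtype=float),
            "group": ["A"] * 4 + ["B"] * 5,
            "sex": ["M", "M", "F", "F", "M", "M", "M", "M", "M"],  # B has no F
        }
    )
    with pytest.warns(UserWarning, match="interaction"):
        res = m.anova_two_way(df)
    assert not res.details["interaction_included"]
    assert "group x sex" not in res.details["terms"]


def test_anova_single_group_rejected():
    df = pd.DataFrame(
        {"value": [1.0, 2.0], "group": ["A", "A"], "sex": ["M", "F"]}
    )
    with pytest.raises(m.ParameterError):
        m.anova_two_way(df)


# --- discrimination ratio --------------------------------------------------


@pytest.mark.parametrize(
    "novel,familiar,expected",
    [(30.0, 30.0, 1.0), (60.0, 30.0, 2.0), (0.0, 30.0, 0.0)],
)
def test_discrimination_ratio(novel, familiar, expected):
    rec = m.BehaviorRecord("m1", "OLM", novel, familiar)
    assert m.discrimination_ratio(rec) == pytest.approx(expected)
    assert m.discrimination_ratio(
        time_novel=novel, time_familiar=familiar
    ) == pytest.approx(expected)


def test_discrimination_ratio_zero_familiar_flagged():
    with pytest.raises(m.ParameterError):
        m.discrimination_ratio(time_novel=10.0, time_familiar=0.0)
    with pytest.raises(m.ParameterError):
        m.BehaviorRecord("m", "NOR", -1.0, 5.0)
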