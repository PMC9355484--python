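"""RCBD ANOVA against a projection oracle, protected LSD, Shapiro–Wilk,
Pearson matrix, pooled SEM."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from leafphys import (anova_factorial_rcbd, fisher_protected_lsd,
                      pearson_matrix, pooled_sem, shapiro_wilk)
from leafphys.stats import DesignError


def make_table(values, cultivars=("A", "B"), treatments=("c", "w"), blocks=4,
               trait="x"):
    """values: array indexed [cultivar, treatment, block]."""
    rows = []
    for i, cv in enumerate(cultivars):
        for j, tr in enumerate(treatments):
            for b in range(blocks):
                rows.append({"cultivar": cv, "treatment": tr, "block": b + 1,
                             "plant": 1, "trait": trait,
                             "value": float(values[i, j, b])})
    return pd.DataFrame(rows)


def oracle_ss(values):
    """Independent balanced-decomposition oracle from marginal means."""
    a, t, b = values.shape
    g = values.mean()
    ss_cv = t * b * ((values.mean(axis=(1, 2)) - g) ** 2).sum()
    ss_tr = a * b * ((values.mean(axis=(0, 2)) - g) ** 2).sum()
    ss_bl = a * t * ((values.mean(axis=(0, 1)) - g) ** 2).sum()
    cell = values.mean(axis=2)
    ss_int = b * ((cell - values.mean(axis=(1, 2))[:, None]
                   - values.mean(axis=(0, 2))[None, :] + g) ** 2).sum()
    ss_tot = ((values - g) ** 2).sum()
    ss_err = ss_tot - ss_cv - ss_tr - ss_bl - ss_int
    return {"cultivar": ss_cv, "treatment": ss_tr, "cultivar:treatment": ss_int,
            "block": ss_bl, "error": ss_err, "total": ss_tot}


def test_all_equal_gives_zero_f():
    tab = anova_factorial_rcbd(make_table(np.full((2, 2, 4), 3.7)), "x")
    for src in ("cultivar", "treatment", "cultivar:treatment", "block"):
        assert tab.row(src)["f"] == 0.0
        assert tab.row(src)["p"] == 1.0


def test_additive_effects_give_zero_interaction():
    vals = np.zeros((2, 2, 4))
    vals += np.array([0.0, 2.0])[:, None, None]       # cultivar effect
    vals += np.array([0.0, -1.0])[None, :, None]      # treatment effect
    vals += np.arange(4)[None, None, :] * 0.5         # block effect
    tab = anova_factorial_rcbd(make_table(vals), "x")
    assert tab.row("cultivar:treatment")["ss"] == pytest.approx(0.0, abs=1e-10)


def test_ss_decomposition_matches_projection_oracle():
    rng = np.random.default_rng(12)
    for _ in range(20):
        vals = rng.normal(10, 3, size=(2, 2, 4))
        tab = anova_factorial_rcbd(make_table(vals), "x")
        exp = oracle_ss(vals)
        for src in ("cultivar", "treatment", "cultivar:treatment", "block", "error"):
            assert tab.row(src)["ss"] == pytest.approx(exp[src], rel=1e-8, abs=1e-10)
        assert tab.table["df"].sum() == vals.size - 1
        assert tab.table["ss"].sum() == pytest.approx(exp["total"], rel=1e-8)


def test_plant_aggregation_and_balance_errors():
    vals = np.random.default_rng(0).normal(size=(2, 2, 4))
    df = make_table(vals)
    # plants within plots must be averaged, df_error stays 9
    df2 = pd.concat([df.assign(plant=1), df.assign(plant=2, value=df.value + 0.1)],
                    ignore_index=True)
    tab = anova_factorial_rcbd(df2, "x")
    assert tab.df_error == 9
    with pytest.raises(DesignError, match="cell"):
        anova_factorial_rcbd(df[~((df.cultivar == "A") & (df.treatment == "c")
                                  & (df.block == 1))], "x")
    with pytest.raises(DesignError):
        anova_factorial_rcbd(df[df.block == 1], "x")


def test_lsd_separates_known_difference():
    rng = np.random.default_rng(1)
    vals = rng.normal(0, 0.1, size=(2, 2, 4))
    vals[1] += 5.0  # large cultivar effect
    tab = anova_factorial_rcbd(make_table(vals), "x")
    means = {("A", "c"): 0.0, ("A", "w"): 0.05, ("B", "c"): 5.0, ("B", "w"): 5.02}
    res = fisher_protected_lsd(tab, means, 4)
    assert res.groups[("A", "c")] == res.groups[("A", "w")]
    assert res.groups[("B", "c")] == res.groups[("B", "w")]
    assert not set(res.groups[("A", "c")]) & set(res.groups[("B", "c")])
    # letter rule: means further apart than the LSD never share a letter
    for k1, m1 in means.items():
        for k2, m2 in means.items():
            if abs(m1 - m2) > res.lsd_value:
                assert not set(res.groups[k1]) & set(res.groups[k2])


def test_lsd_protection_gate_collapses_letters():
    rng = np.random.default_rng(2)
    vals = rng.normal(10, 1.0, size=(2, 2, 4))  # pure noise: omnibus n.s.
    tab = anova_factorial_rcbd(make_table(vals), "x")
    means = {(cv, tr): float(vals[i, j].mean())
             for i, cv in enumerate("AB") for j, tr in enumerate("cw")}
    res = fisher_protected_lsd(tab, means, 4)
    if res.gate_p > 0.05:
        assert set(res.groups.values()) == {"a"}


def test_lsd_identical_means_share_letter_and_order_invariance():
    vals = np.random.default_rng(3).normal(size=(2, 2, 4))
    tab = anova_factorial_rcbd(make_table(vals), "x")
    means = {("A", "c"): 1.0, ("A", "w"): 1.0, ("B", "c"): 9.0, ("B", "w"): 4.0}
    res1 = fisher_protected_lsd(tab, means, 4)
    assert res1.groups[("A", "c")] == res1.groups[("A", "w")]
    shuffled = dict(reversed(list(means.items())))
    res2 = fisher_protected_lsd(tab, shuffled, 4)
    assert res1.groups == res2.groups
    with pytest.raises(DesignError):
        fisher_protected_lsd(tab, means, 1)


def test_lsd_formula_value():
    vals = np.random.default_rng(4).normal(size=(2, 2, 4))
    tab = anova_factorial_rcbd(make_table(vals), "x")
    expected = scipy.stats.t.ppf(0.975, tab.df_error) * np.sqrt(2 * tab.mse / 4)
    res = fisher_protected_lsd(tab, {("A", "c"): 1, ("A", "w"): 2,
                                     ("B", "c"): 3, ("B", "w"): 4}, 4)
    assert res.lsd_value == pytest.approx(expected, rel=1e-12)


def test_shapiro_wilk_contract():
    n = 50
    quantiles = scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    w, p = shapiro_wilk(quantiles)
    assert w > 0.99
    bimodal = np.concatenate([np.random.default_rng(0).normal(-8, 0.3, 25),
                              np.random.default_rng(1).normal(8, 0.3, 25)])
    _, p_bi = shapiro_wilk(bimodal)
    assert p_bi < 0.01
    with pytest.raises(DesignError):
        shapiro_wilk([1.0, 2.0])
    with pytest.raises(DesignError):
        shapiro_wilk([3.0] * 10)


def _trait_table(arrs):
    rows = []
    for trait, vals in arrs.items():
        for k, v in enumerate(vals):
            rows.append({"cultivar": "A", "treatment": "c", "block": k + 1,
                         "plant": 1, "trait": trait, "value": float(v)})
    return pd.DataFrame(rows)


def test_pearson_exact_and_affine_invariance():
    x = np.arange(1, 17, dtype=float)
    tab = _trait_table({"x": x, "y2": 2 * x, "yneg": -x, "z": x ** 2})
    mat = pearson_matrix(tab, ["x", "y2", "yneg"])
    assert mat.r.loc["x", "y2"] == pytest.approx(1.0)
    assert mat.r.loc["x", "yneg"] == pytest.approx(-1.0)
    assert np.allclose(mat.r.values, mat.r.values.T)
    assert np.allclose(np.diag(mat.r.values), 1.0)
    m1 = pearson_matrix(_trait_table({"x": x, "z": x ** 2}), ["x", "z"])
    m2 = pearson_matrix(_trait_table({"x": 3 * x + 7, "z": x ** 2}), ["x", "z"])
    assert m1.r.loc["x", "z"] == pytest.approx(m2.r.loc["x", "z"], abs=1e-12)


def test_pearson_null_mean_r_near_zero():
    rng = np.random.default_rng(7)
    rs = []
    for _ in range(300):
        tab = _trait_table({"u": rng.normal(size=16), "v": rng.normal(size=16)})
        rs.append(pearson_matrix(tab, ["u", "v"]).r.loc["u", "v"])
    assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.02


def test_pearson_zero_variance_names_trait():
    x = np.arange(16, dtype=float)
    tab = _trait_table({"x": x, "flat": np.ones(16)})
    with pytest.raises(DesignError, match="flat"):
        pearson_matrix(tab, ["x", "flat"])


def test_pooled_sem_back_solves_printed_value():
    vals = np.random.default_rng(5).normal(size=(2, 2, 4))
    tab = anova_factorial_rcbd(make_table(vals), "x")
    tab.table.loc[tab.table.source == "error", "ms"] = 0.0740
    assert pooled_sem(tab, 4) == pytest.approx(0.136, abs=5e-4)
    tab.table.loc[tab.table.source == "error", "ms"] = 0.0
    assert pooled_sem(tab, 4) == 0.0
    tab.table.loc[tab.table.source == "error", "ms"] = 1.0
    assert pooled_sem(tab, 16) == pytest.approx(pooled_sem(tab, 4) / 2)
    with pytest.raises(DesignError):
        pooled_sem(tab, 1)
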