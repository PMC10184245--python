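"""Allometry PGLS, penalized GLS, MANOVA and state-specific rates."""

import numpy as np
import pytest

import morphorates as mr
from conftest import bm_data, star_tree


@pytest.fixture(scope="module")
def ecology(tree64):
    traits = mr.simulate_ecology(tree64, seed=9)
    return traits


def test_pgls_star_tree_equals_ols(tree64):
    rng = np.random.default_rng(0)
    star = star_tree(48)
    sp = list(star.tip_labels)
    x = rng.standard_normal(48)
    Y = np.outer(x, rng.standard_normal(5)) + rng.standard_normal((48, 5))
    res = mr.procrustes_pgls(Y, x, star, n_perm=99, seed=0)
    # direct OLS F for comparison
    X1 = np.column_stack([np.ones(48), x])
    B, *_ = np.linalg.lstsq(X1, Y, rcond=None)
    ss_res = float(((Y - X1 @ B) ** 2).sum())
    dev = Y - Y.mean(axis=0)
    ss_tot = float((dev ** 2).sum())
    F = ((ss_tot - ss_res) / 1) / (ss_res / 46)
    assert res.F == pytest.approx(F, rel=1e-10)
    assert res.p_perm < 0.05
    assert res.Z > 2


def test_pgls_exact_linear_r2_one(tree64):
    sp = list(tree64.tip_labels)
    x = bm_data(tree64, 1, 1.0, seed=5).ravel()
    Y = np.outer(x, [1.0, -2.0, 0.5])
    res = mr.procrustes_pgls(Y, x, tree64, n_perm=49, seed=0)
    assert res.r_squared == pytest.approx(1.0, abs=1e-10)


def test_pgls_null_uniform_p(tree64):
    sp = list(tree64.tip_labels)
    ps = []
    for s in range(40):
        x = bm_data(tree64, 1, 1.0, seed=100 + s).ravel()
        Y = bm_data(tree64, 4, 1.0, seed=200 + s)
        ps.append(mr.procrustes_pgls(Y, x, tree64,
                                     n_perm=99, seed=s).p_perm)
    assert 0.01 < np.mean(ps) < 0.99  # not degenerate
    assert np.mean(np.array(ps) <= 0.05) < 0.25


def test_build_design_terms(ecology, tree64):
    sp = list(tree64.tip_labels)
    log_cs = dict(zip(sp, np.linspace(-1, 1, len(sp))))
    diet = {s: ecology.table.loc[s, "diet"] for s in sp}
    loco = {s: ecology.table.loc[s, "locomotion"] for s in sp}
    d = mr.build_design(sp, log_cs=log_cs, diet=diet, locomotion=loco,
                        interactions=[("log_cs", "diet")])
    assert set(d.terms) == {"log_cs", "diet", "locomotion", "log_cs:diet"}
    assert d.X.shape[1] == 1 + sum(len(v) for v in d.terms.values())
    assert d.contains["log_cs"] == {"log_cs:diet"}
    assert d.contains["log_cs:diet"] == set()


def test_mvgls_lambda_recovery_univariate(tree64):
    sp = list(tree64.tip_labels)
    design = mr.build_design(sp)
    lams = []
    for s in range(15):
        C = mr.transform_covariance(
            tree64, mr.TreeTransform(kind="lambda", lam=0.5)).C
        rng = np.random.default_rng(s)
        y = np.linalg.cholesky(C) @ rng.standard_normal((len(sp), 1))
        fit = mr.mvgls_fit(y, design, tree64)
        lams.append(fit.lam)
    assert np.mean(lams) == pytest.approx(0.5, abs=0.15)


def test_mvgls_high_dimensional_defined(tree64):
    sp = list(tree64.tip_labels)
    design = mr.build_design(sp)
    rng = np.random.default_rng(1)
    Y = bm_data(tree64, 100, 1.0, seed=2) + rng.standard_normal((64, 100))
    fit = mr.mvgls_fit(Y, design, tree64)  # d > N must stay defined
    assert np.isfinite(fit.loglik)
    assert 0 < fit.gamma <= 1
    w = np.linalg.eigvalsh(fit.residual_cov)
    assert w.min() > 0


def test_manova_detects_true_effect(tree64, ecology):
    sp = list(tree64.tip_labels)
    rng = np.random.default_rng(4)
    diet = {s: ecology.table.loc[s, "diet"] for s in sp}
    codes = {d: i for i, d in enumerate(sorted(set(diet.values())))}
    effect = np.array([codes[diet[s]] for s in sp], dtype=float)
    Y = bm_data(tree64, 6, 0.05, seed=3)
    Y[:, 0] += 2.0 * effect
    design = mr.build_design(sp, diet=diet)
    fit = mr.mvgls_fit(Y, design, tree64)
    res = mr.manova_type2(fit, n_perm=199, seed=0)
    assert res.p_perm["diet"] < 0.05
    assert res.pillai["diet"] > 0


def test_manova_reproducible(tree64, ecology):
    sp = list(tree64.tip_labels)
    diet = {s: ecology.table.loc[s, "diet"] for s in sp}
    Y = bm_data(tree64, 5, 1.0, seed=8)
    design = mr.build_design(sp, diet=diet)
    fit = mr.mvgls_fit(Y, design, tree64)
    a = mr.manova_type2(fit, n_perm=99, seed=5)
    b = mr.manova_type2(fit, n_perm=99, seed=5)
    assert a.pillai == b.pillai
    assert a.p_perm == b.p_perm


def test_state_rates_single_state_collapses(tree64):
    Y = bm_data(tree64, 8, 2.0, seed=6)
    Q = np.zeros((1, 1))
    sm = mr.simulate_mk_history(tree64, Q, seed=0, states=("only",))
    res = mr.state_specific_rates(Y, [sm], tree=tree64,
                                  fix_nugget_zero=True)
    direct = mr.sigma2_mult(Y, tree64, species=list(tree64.tip_labels),
                            per="coordinate")
    assert res.sigma2["only"] == pytest.approx(direct, rel=1e-6)


def test_state_rates_recover_ratio(tree64):
    # plant state-dependent rates along a simulated history
    Q = mr.default_q(("slow", "fast"), rate=0.05)
    sm = mr.simulate_mk_history(tree64, Q, seed=3, states=("slow", "fast"))
    Cs = sm.state_covariances(order=list(tree64.tip_labels))
    V = 1.0 * Cs[0] + 4.0 * Cs[1]
    rng = np.random.default_rng(7)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(len(V)))
    Y = L @ rng.standard_normal((tree64.n_tips, 40))
    res = mr.state_specific_rates(Y, [sm], tree=tree64,
                                  fix_nugget_zero=True)
    ratio = res.sigma2["fast"] / res.sigma2["slow"]
    assert ratio == pytest.approx(4.0, rel=0.4)
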