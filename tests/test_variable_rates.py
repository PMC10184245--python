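"""RJ-MCMC machinery: likelihood, transforms, evidence, summaries."""

import numpy as np
import pytest

import morphorates as mr
from conftest import bm_data
from morphorates._pruning import contrasts_reml, tree_arrays
from morphorates.variable_rates import _transformed_bl


def reml_matrix(tree, Y):
    """Matrix-form REML log-likelihood pieces for validation."""
    C = tree.vcv()
    N = len(C)
    Cinv = np.linalg.inv(C)
    one = np.ones(N)
    s1 = one @ Cinv @ one
    mu = (Cinv @ one) / s1
    logdet = np.linalg.slogdet(C)[1] + np.log(s1)
    R = Y - np.outer(one, mu @ Y)
    Q = np.einsum("id,ij,jd->d", R, Cinv, R)
    return logdet, Q


def test_contrasts_equal_matrix_reml(tree64):
    Y = bm_data(tree64, 5, 1.3, seed=0)
    ld, Q = contrasts_reml(tree64.branch_lengths, np.ascontiguousarray(Y),
                           *tree_arrays(tree64))
    ld2, Q2 = reml_matrix(tree64, Y)
    assert ld == pytest.approx(ld2, abs=1e-9)
    np.testing.assert_allclose(Q, Q2, rtol=1e-9)


@pytest.mark.parametrize("kind,param", [("lambda", 0.6), ("kappa", 0.7),
                                        ("delta", 1.8), ("ou", 0.03)])
def test_branch_length_transforms_match_covariance(tree64, kind, param):
    bl = _transformed_bl(tree64, kind, param)
    work = mr.PhyloTree(tree64.parent, bl, tree64.tip_labels,
                        tree64.postorder)
    kw = {"lambda": "lam", "kappa": "kappa", "delta": "delta",
          "ou": "alpha"}[kind]
    C = mr.transform_covariance(tree64,
                                mr.TreeTransform(kind=kind,
                                                 **{kw: param})).C
    np.testing.assert_allclose(work.vcv(), C, atol=1e-10)


def test_ou_requires_ultrametric():
    from morphorates.variable_rates import _check_tree_for_kind
    tr = mr.PhyloTree.from_newick("((a:1,b:2):0.5,c:3);")
    with pytest.raises(ValueError, match="ultrametric"):
        _check_tree_for_kind(tr, "ou")


def test_chain_deterministic(tree64):
    Y = bm_data(tree64, 3, 1.0, seed=1)
    kw = dict(n_iter=2000, seed=42, species=list(tree64.tip_labels))
    a = mr.rjmcmc_variable_rates(Y, tree64, **kw)
    b = mr.rjmcmc_variable_rates(Y, tree64, **kw)
    np.testing.assert_array_equal(a.loglik, b.loglik)
    np.testing.assert_array_equal(a.n_shifts, b.n_shifts)
    assert a.placements == b.placements


def test_prior_only_matches_placement_prior(tree64):
    Y = bm_data(tree64, 2, 1.0, seed=2)
    chain = mr.rjmcmc_variable_rates(Y, tree64, n_iter=60_000, seed=3,
                                     species=list(tree64.tip_labels),
                                     prior_only=True)
    from scipy.stats import poisson
    kmax = chain.n_shifts.max()
    mean = chain.n_shifts.mean()
    assert mean == pytest.approx(2.0, abs=0.35)
    ks = np.arange(0, 51)
    prior_pmf = poisson.pmf(ks, 2.0)
    prior_pmf /= prior_pmf.sum()
    emp = np.bincount(chain.n_shifts, minlength=51)[:51] / len(chain.n_shifts)
    tv = 0.5 * np.abs(emp - prior_pmf).sum()
    assert tv < 0.1
    assert kmax <= 50


def test_stepping_stone_matches_conjugate_toy():
    # N(theta, 1) likelihood with N(0, 1) prior: analytic evidence
    rng = np.random.default_rng(0)
    x = rng.normal(0.7, 1.0, size=12)
    n = len(x)

    def loglik(theta):
        th = np.asarray(theta).item()
        return float(-0.5 * n * np.log(2 * np.pi)
                     - 0.5 * np.sum((x - th) ** 2))

    def log_prior(theta):
        th = np.asarray(theta).item()
        return float(-0.5 * np.log(2 * np.pi) - 0.5 * th ** 2)

    # analytic: x_i ~ N(0, I + 11')
    C = np.eye(n) + 1.0
    sign, ld = np.linalg.slogdet(C)
    exact = float(-0.5 * n * np.log(2 * np.pi) - 0.5 * ld
                  - 0.5 * x @ np.linalg.solve(C, x))
    est = mr.power_posterior_evidence(loglik, log_prior,
                                      lambda r: float(r.normal()),
                                      n_stones=12, iters_per_stone=4000,
                                      seed=1)
    assert est.logml == pytest.approx(exact, abs=0.1)


def test_stepping_stone_matches_exact_bm(tree64):
    Y = bm_data(tree64, 2, 1.0, seed=4)
    sp = list(tree64.tip_labels)
    exact = mr.bm_single_logml_exact(Y, tree64, species=sp)
    est = mr.stepping_stone_logml(Y, tree64, variable=False, n_stones=10,
                                  iters_per_stone=3000, seed=5, species=sp)
    assert est.logml == pytest.approx(exact, abs=max(0.15, 3 * est.mc_error))


def test_compare_models_bf_semantics():
    cmp = mr.compare_models({"a": -10.0, "b": -15.0, "c": -11.65})
    assert cmp.best == "a"
    ids = cmp.model_ids
    ia, ib, ic = ids.index("a"), ids.index("b"), ids.index("c")
    assert cmp.log_bf[ia, ib] == pytest.approx(10.0)   # strong support
    assert cmp.log_bf[ia, ic] == pytest.approx(3.3)    # weaker support
    assert cmp.margin == pytest.approx(3.3)
    assert not cmp.tie


def test_model_registry_complete():
    reg = mr.model_registry()
    ids = {m["model_id"] for m in reg}
    assert len(reg) == 10
    for base in ("BM", "OU", "BM+lambda", "BM+kappa", "BM+delta"):
        assert f"{base}_single" in ids
        assert f"{base}_variable" in ids


def test_gelman_rubin_flags_divergent(tree64):
    Y = bm_data(tree64, 2, 1.0, seed=6)
    sp = list(tree64.tip_labels)
    chains = [mr.rjmcmc_variable_rates(Y, tree64, n_iter=4000, seed=s,
                                       species=sp) for s in (1, 2)]
    rep = mr.gelman_rubin(chains)
    assert all(v >= 1.0 for v in rep.psrf.values())
    assert all(v > 0 for v in rep.ess.values())


def test_branch_rates_hand_oracle(tree4):
    sp = list(tree4.tip_labels)
    chain = mr.rjmcmc_variable_rates(bm_data(tree4, 1, 1.0, seed=0), tree4,
                                     n_iter=400, seed=0, species=sp)
    # overwrite with two hand-made samples: no shifts / one local shift
    chain.placements = [[], [(0, np.log(3.0))]]
    chain.sigma2 = np.array([[2.0], [4.0]])
    chain.loglik = np.zeros(2)
    rates = mr.branch_rates(chain, tree4)
    assert rates.relative[0] == pytest.approx((1.0 + 3.0) / 2)
    assert rates.relative[1] == pytest.approx(1.0)
    assert rates.mean_base_rate == pytest.approx(3.0)


def test_rate_through_time_flat_chain(tree64):
    sp = list(tree64.tip_labels)
    chain = mr.rjmcmc_variable_rates(bm_data(tree64, 1, 1.0, seed=7),
                                     tree64, n_iter=400, seed=0, species=sp)
    chain.placements = [[]]
    chain.sigma2 = np.array([[1.0]])
    chain.loglik = np.zeros(1)
    rates = mr.branch_rates(chain, tree64)
    rtt = mr.bin_rates_through_time(rates, tree64, width=5.0)
    occupied = ~rtt.empty
    assert occupied.any()
    np.testing.assert_allclose(rtt.mean_rate[occupied], 1.0, atol=1e-12)
    assert rtt.n_lineages[-1] >= tree64.n_tips


def test_terminal_rates_by_clade(tree4):
    sp = list(tree4.tip_labels)
    chain = mr.rjmcmc_variable_rates(bm_data(tree4, 1, 1.0, seed=0), tree4,
                                     n_iter=400, seed=0, species=sp)
    chain.placements = [[]]
    chain.sigma2 = np.array([[1.0]])
    chain.loglik = np.zeros(1)
    rates = mr.branch_rates(chain, tree4)
    table = mr.terminal_rates_by_clade(
        rates, {s: ("left" if s in ("a", "b") else "right") for s in sp})
    assert set(table["clade"]) == {"left", "right"}
    assert table["n"].sum() == 4
    np.testing.assert_allclose(table["mean"], 1.0)
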