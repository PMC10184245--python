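"""Phylogenetic signal, rates, rate comparison and group tests."""

import numpy as np
import pytest

import morphorates as mr
from conftest import bm_data, star_tree


def test_kmult_star_tree_is_one():
    star = star_tree(32)
    Y = bm_data(star, 6, 1.0, seed=0)
    res = mr.kmult(Y, star, n_perm=19, seed=0,
                   species=list(star.tip_labels))
    assert res.k_mult == pytest.approx(1.0, abs=1e-10)


def test_kmult_bm_near_one(tree64):
    ks = [mr.kmult(bm_data(tree64, 10, 1.0, seed=s), tree64, n_perm=19,
                   seed=s, species=list(tree64.tip_labels)).k_mult
          for s in range(20)]
    assert 0.85 < float(np.mean(ks)) < 1.15


def test_kmult_detects_signal(tree64):
    rng = np.random.default_rng(3)
    noise = rng.standard_normal((tree64.n_tips, 10))
    res_noise = mr.kmult(noise, tree64, n_perm=199, seed=1,
                         species=list(tree64.tip_labels))
    res_bm = mr.kmult(bm_data(tree64, 10, 1.0, seed=4), tree64, n_perm=199,
                      seed=1, species=list(tree64.tip_labels))
    assert res_bm.k_mult > res_noise.k_mult
    assert res_bm.p_perm < 0.05  # BM data carry signal


def test_sigma2_mult_recovers_rate(tree64):
    rates = [mr.sigma2_mult(bm_data(tree64, 30, 2.5, seed=s), tree64,
                            species=list(tree64.tip_labels),
                            per="coordinate")
             for s in range(30)]
    assert np.mean(rates) == pytest.approx(2.5, rel=0.1)


def test_sigma2_mult_per_point_vs_coordinate(regions_small, tree64):
    r = regions_small[0]
    per_pt = mr.sigma2_mult(r, tree64)
    per_co = mr.sigma2_mult(r, tree64, per="coordinate")
    assert per_pt == pytest.approx(3 * per_co)


def test_rate_ratio_test_detects(tree64):
    sp = list(tree64.tip_labels)
    fast = mr.RegionData("fast", "CNC", bm_data(tree64, 9, 5.0, seed=1),
                         [f"p{i}" for i in range(3)], sp)
    slow = mr.RegionData("slow", "PM", bm_data(tree64, 9, 1.0, seed=2),
                         [f"q{i}" for i in range(3)], sp)
    res = mr.rate_ratio_test([fast, slow], tree64, n_sim=199, seed=0)
    assert res.observed_ratio > 2.0
    assert res.p_sim < 0.05
    assert res.rates["fast"] > res.rates["slow"]
    assert res.pairwise_p.shape == (2, 2)


def test_transform_identity_parameters(tree64):
    C = tree64.vcv()
    for kind, kw in [("lambda", {"lam": 1.0}), ("kappa", {"kappa": 1.0}),
                     ("delta", {"delta": 1.0})]:
        tr = mr.TreeTransform(kind=kind, **kw)
        Ct = mr.transform_covariance(tree64, tr).C
        np.testing.assert_allclose(Ct, C, atol=1e-12)


def test_lambda_zero_is_diagonal(tree64):
    tr = mr.TreeTransform(kind="lambda", lam=0.0)
    Ct = mr.transform_covariance(tree64, tr).C
    off = Ct - np.diag(np.diag(Ct))
    assert np.abs(off).max() == 0.0
    np.testing.assert_allclose(np.diag(Ct), np.diag(tree64.vcv()))


def test_ou_converges_to_bm(tree64):
    C = tree64.vcv()
    Ct = mr.transform_covariance(
        tree64, mr.TreeTransform(kind="ou", alpha=1e-8)).C
    np.testing.assert_allclose(Ct, C, rtol=1e-5)


def test_mann_whitney_matches_reference_columns():
    df = mr.load_region_summary()
    labels = df["origin"].tolist()
    res = mr.mann_whitney_groups(df["rate"], labels)
    assert res.p == pytest.approx(0.0232, abs=0.001)
    res2 = mr.mann_whitney_groups(df["disparity"], labels)
    assert res2.p == pytest.approx(0.246, abs=0.001)


def test_mann_whitney_rejects_bad_groups():
    with pytest.raises(ValueError):
        mr.mann_whitney_groups([1, 2, 3], ["a", "a", "a"])
    with pytest.raises(ValueError):
        mr.mann_whitney_groups([1, 2, 3], ["a", "b", "c"])
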