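"""Self-validation experiments: calibration, recovery and determinism.

Each function runs a seeded simulation experiment against a known truth
and returns plain floats, so the same code backs both the test suite
and the standalone acceptance script.  All randomness is derived from
the ``seed`` argument; nothing here reads external data.
"""

from __future__ import annotations

import math

import numpy as np

from .ecology_models import build_design, mvgls_fit
from .phylo_models import (TreeTransform, kmult, mann_whitney_groups,
                           rate_ratio_test, sigma2_mult,
                           transform_covariance)
from .reference import load_region_summary
from .superimposition import RegionData
from .synthetic_data import simulate_tree
from .tree import PhyloTree
from .variable_rates import (Priors, bm_single_logml_exact, branch_rates,
                             power_posterior_evidence,
                             rjmcmc_variable_rates, stepping_stone_logml)

__all__ = [
    "mw_reference_pvalues", "kmult_calibration", "kmult_star_error",
    "sigma2_recovery", "rate_ratio_calibration", "lambda_recovery",
    "transform_identity_error", "rj_planted_shift", "rj_null_fraction",
    "rj_prior_recovery", "toy_evidence_error",
]


def _bm(tree: PhyloTree, d: int, rate: float, rng, L=None) -> np.ndarray:
    if L is None:
        L = np.linalg.cholesky(tree.vcv())
    return L @ rng.standard_normal((tree.n_tips, d)) * math.sqrt(rate)


def _star(n: int) -> PhyloTree:
    tips = ",".join(f"s{i}:1" for i in range(n))
    return PhyloTree.from_newick(f"({tips});")


# --------------------------------------------------------------------------
# printed statistics recomputable from the packaged per-region table
# --------------------------------------------------------------------------

def mw_reference_pvalues() -> dict[str, float]:
    """CNC-vs-PM Mann-Whitney p-values from the packaged region table."""
    df = load_region_summary()
    labels = df["origin"].tolist()
    rates = mann_whitney_groups(df["rate"], labels).p
    disp = mann_whitney_groups(df["disparity"], labels).p
    sub = df[df["region"] != "pterygoid"]
    disp_sub = mann_whitney_groups(sub["disparity"],
                                   sub["origin"].tolist()).p
    return {"rates": rates, "disparity": disp,
            "disparity_excl_pterygoid": disp_sub}


# --------------------------------------------------------------------------
# K_mult calibration
# --------------------------------------------------------------------------

def kmult_calibration(n_tips: int = 128, d: int = 20, reps: int = 200,
                      n_perm: int = 199, seed: int = 0) -> dict[str, float]:
    """Mean K_mult under BM and permutation type-I error under the null.

    The mean is taken over BM replicates (expected near 1).  The type-I
    error is the rejection rate on exchangeable (signal-free) data, the
    null hypothesis of the permutation test; BM data are expected to be
    rejected nearly always and do not measure the test level.
    """
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    sp = list(tree.tip_labels)
    L = np.linalg.cholesky(tree.vcv())
    rng = np.random.default_rng(seed + 1)
    ks, rej = [], 0
    for r in range(reps):
        Y = _bm(tree, d, 1.0, rng, L)
        ks.append(kmult(Y, tree, n_perm=9, seed=seed + 2 + r,
                        species=sp).k_mult)
        Y0 = rng.standard_normal((n_tips, d))
        res0 = kmult(Y0, tree, n_perm=n_perm, seed=seed + 2 + r,
                     species=sp)
        if res0.p_perm <= 0.05:
            rej += 1
    return {"mean_k": float(np.mean(ks)), "type1": rej / reps,
            "reps": reps}


def kmult_star_error(n_tips: int = 64, d: int = 10, seed: int = 0) -> float:
    """|K_mult - 1| for arbitrary data on a star tree (exactly 0)."""
    star = _star(n_tips)
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((n_tips, d))
    res = kmult(Y, star, n_perm=9, seed=seed, species=list(star.tip_labels))
    return abs(res.k_mult - 1.0)


# --------------------------------------------------------------------------
# rate estimation and comparison
# --------------------------------------------------------------------------

def sigma2_recovery(n_tips: int = 128, d: int = 30, rate: float = 2.5,
                    reps: int = 100, seed: int = 0) -> dict[str, float]:
    """Relative error of the mean sigma^2_mult under a known rate."""
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    sp = list(tree.tip_labels)
    L = np.linalg.cholesky(tree.vcv())
    rng = np.random.default_rng(seed + 1)
    est = [sigma2_mult(_bm(tree, d, rate, rng, L), tree, species=sp,
                       per="coordinate") for _ in range(reps)]
    mean = float(np.mean(est))
    return {"mean_rate": mean, "true_rate": rate,
            "rel_error": abs(mean - rate) / rate, "reps": reps}


def rate_ratio_calibration(ratio: float = 1.0, reps: int = 500,
                           n_tips: int = 64, n_points: int = 2,
                           n_sim: int = 199, seed: int = 0,
                           ) -> dict[str, float]:
    """Rejection rate of the rate-ratio test at a planted ratio.

    ``ratio=1`` estimates the type-I error; larger ratios estimate
    power.  Two regions with ``n_points`` landmarks each.
    """
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    sp = list(tree.tip_labels)
    L = np.linalg.cholesky(tree.vcv())
    rng = np.random.default_rng(seed + 1)
    d = 3 * n_points
    rej = 0
    for r in range(reps):
        a = RegionData("a", "CNC", _bm(tree, d, 1.0, rng, L),
                       [f"p{i}" for i in range(n_points)], sp)
        b = RegionData("b", "PM", _bm(tree, d, ratio, rng, L),
                       [f"q{i}" for i in range(n_points)], sp)
        res = rate_ratio_test([a, b], tree, n_sim=n_sim,
                              seed=seed + 2 + r)
        if res.p_sim <= 0.05:
            rej += 1
    return {"rejection_rate": rej / reps, "reps": reps, "ratio": ratio}


# --------------------------------------------------------------------------
# transform recovery
# --------------------------------------------------------------------------

def lambda_recovery(lam_true: float, reps: int = 100, n_tips: int = 128,
                    seed: int = 0) -> dict[str, float]:
    """Mean absolute error of the ML lambda estimate (univariate)."""
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    sp = list(tree.tip_labels)
    design = build_design(sp)
    C = transform_covariance(tree,
                             TreeTransform(kind="lambda", lam=lam_true)).C
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    rng = np.random.default_rng(seed + 1)
    errs = []
    for _ in range(reps):
        y = L @ rng.standard_normal((n_tips, 1))
        errs.append(abs(mvgls_fit(y, design, tree).lam - lam_true))
    return {"mae": float(np.mean(errs)), "lam_true": lam_true,
            "reps": reps}


def transform_identity_error(n_tips: int = 64, seed: int = 0) -> float:
    """Max deviation of lambda=kappa=delta=1 covariances from plain BM."""
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    C = tree.vcv()
    worst = 0.0
    for kind, kw in (("lambda", {"lam": 1.0}), ("kappa", {"kappa": 1.0}),
                     ("delta", {"delta": 1.0})):
        Ct = transform_covariance(tree, TreeTransform(kind=kind, **kw)).C
        worst = max(worst, float(np.abs(Ct - C).max()))
    return worst


# --------------------------------------------------------------------------
# reversible-jump MCMC
# --------------------------------------------------------------------------

def _planted_tree_and_data(n_tips: int, clade_size: int, magnitude: float,
                           d: int, seed: int):
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    # pick a clade of roughly the requested size
    best, best_err = None, 10 ** 9
    for node in range(tree.n_tips, tree.n_nodes):
        sz = len(tree.clade_tips(node))
        if abs(sz - clade_size) < best_err:
            best, best_err = node, abs(sz - clade_size)
    clade_tips = list(tree.clade_tips(best))
    in_clade = np.zeros(tree.n_nodes, dtype=bool)
    stack = [best]
    while stack:
        nd = stack.pop()
        in_clade[nd] = True
        stack.extend(np.where(tree.parent == nd)[0].tolist())
    bl = tree.branch_lengths.copy()
    bl[in_clade] *= magnitude
    scaled = PhyloTree(tree.parent, bl, tree.tip_labels, tree.postorder)
    rng = np.random.default_rng(seed + 1)
    Y = _bm(scaled, d, 1.0, rng)
    return tree, Y, clade_tips, in_clade


def rj_planted_shift(n_tips: int = 100, clade_size: int = 20,
                     magnitude: float = 5.0, d: int = 2,
                     n_iter: int = 150_000, n_stones: int = 8,
                     iters_per_stone: int = 5000, seed: int = 0,
                     ) -> dict[str, float]:
    """Recovery of a planted clade rate scalar and its Bayes factor."""
    tree, Y, clade_tips, in_clade = _planted_tree_and_data(
        n_tips, clade_size, magnitude, d, seed)
    sp = list(tree.tip_labels)
    chain = rjmcmc_variable_rates(Y, tree, n_iter=n_iter, seed=seed + 2,
                                  species=sp)
    rates = branch_rates(chain, tree)
    shifted = in_clade.copy()
    shifted[tree.root] = False
    clade_mean = float(rates.relative[shifted].mean())
    background = float(np.median(rates.relative[~shifted]))
    ss = stepping_stone_logml(Y, tree, variable=True, n_stones=n_stones,
                              iters_per_stone=iters_per_stone,
                              seed=seed + 3, species=sp)
    single = bm_single_logml_exact(Y, tree, species=sp)
    return {"clade_mean_rate": clade_mean,
            "background_median": background,
            "rate_ratio": clade_mean / background,
            "log_bf_variable_vs_single": 2.0 * (ss.logml - single),
            "n_clade_tips": len(clade_tips)}


def rj_null_fraction(reps: int = 20, n_tips: int = 100, d: int = 2,
                     n_stones: int = 8, iters_per_stone: int = 2500,
                     seed: int = 0) -> dict[str, float]:
    """Fraction of no-shift replicates with log-BF < 2 for shifts."""
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    sp = list(tree.tip_labels)
    L = np.linalg.cholesky(tree.vcv())
    rng = np.random.default_rng(seed + 1)
    ok = 0
    bfs = []
    for r in range(reps):
        Y = _bm(tree, d, 1.0, rng, L)
        ss = stepping_stone_logml(Y, tree, variable=True,
                                  n_stones=n_stones,
                                  iters_per_stone=iters_per_stone,
                                  seed=seed + 2 + r, species=sp)
        single = bm_single_logml_exact(Y, tree, species=sp)
        bf = 2.0 * (ss.logml - single)
        bfs.append(bf)
        if bf < 2.0:
            ok += 1
    return {"fraction_not_rejected": ok / reps, "reps": reps,
            "mean_log_bf": float(np.mean(bfs))}


def rj_prior_recovery(n_tips: int = 64, n_iter: int = 60_000,
                      seed: int = 0) -> dict[str, float]:
    """Prior-only chain vs the truncated-Poisson placement-count prior."""
    from scipy.stats import poisson
    tree = simulate_tree(n_tips=n_tips, seed=seed)
    sp = list(tree.tip_labels)
    rng = np.random.default_rng(seed + 1)
    Y = _bm(tree, 2, 1.0, rng)
    priors = Priors()
    chain = rjmcmc_variable_rates(Y, tree, n_iter=n_iter, seed=seed + 2,
                                  species=sp, prior_only=True)
    kmax = priors.max_shifts
    pmf = poisson.pmf(np.arange(kmax + 1), priors.shift_mean)
    pmf /= pmf.sum()
    emp = (np.bincount(chain.n_shifts, minlength=kmax + 1)[:kmax + 1]
           / len(chain.n_shifts))
    tv = 0.5 * float(np.abs(emp - pmf).sum())
    return {"tv_distance": tv, "mean_shifts": float(chain.n_shifts.mean()),
            "prior_mean": float(pmf @ np.arange(kmax + 1))}


# --------------------------------------------------------------------------
# evidence estimator
# --------------------------------------------------------------------------

def toy_evidence_error(n_obs: int = 12, n_stones: int = 12,
                       iters_per_stone: int = 4000, seed: int = 0,
                       ) -> dict[str, float]:
    """Stepping-stone error on a conjugate normal-normal toy model."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.7, 1.0, size=n_obs)

    def loglik(theta):
        th = float(np.asarray(theta).item())
        return float(-0.5 * n_obs * math.log(2 * math.pi)
                     - 0.5 * np.sum((x - th) ** 2))

    def log_prior(theta):
        th = float(np.asarray(theta).item())
        return float(-0.5 * math.log(2 * math.pi) - 0.5 * th ** 2)

    C = np.eye(n_obs) + 1.0
    exact = float(-0.5 * n_obs * math.log(2 * math.pi)
                  - 0.5 * np.linalg.slogdet(C)[1]
                  - 0.5 * x @ np.linalg.solve(C, x))
    est = power_posterior_evidence(loglik, log_prior,
                                   lambda r: float(r.normal()),
                                   n_stones=n_stones,
                                   iters_per_stone=iters_per_stone,
                                   seed=seed + 1)
    return {"error": abs(est.logml - exact), "exact": exact,
            "estimate": est.logml, "mc_error": est.mc_error}
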