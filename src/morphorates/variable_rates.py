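"""Branch-specific rate inference by reversible-jump MCMC.

The model places multiplicative rate scalars on single branches or on
whole clades (stem branch plus all descendants) of a dated tree.  Score
dimensions are independent Brownian motions with per-dimension base
rates sigma2_j on a shared structure: the base tree is first bent by an
optional lambda/kappa/delta/OU transformation and the scalars then
multiply the transformed branch lengths.  The likelihood is the
restricted (contrasts/REML) likelihood computed by pruning, so the
unknown root state never enters the sampler.

Priors: the number of placements is truncated Poisson (mean 2, max 50),
log-magnitudes are standard normal, base rates are inverse-gamma (which
makes their update a Gibbs draw), lambda is uniform on [0, 1] and the
logs of kappa, delta and the OU attraction are standard normal.

Marginal likelihoods come from stepping-stone sampling along the power
posterior ladder beta_k = (k/K)^(1/0.3), and models are compared with
the factor-2 log Bayes factor convention, 2 (logML_i - logML_j), so the
conventional "BF > 10" strong-support threshold applies directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from ._pruning import contrasts_reml, tree_arrays
from .tree import PhyloTree

__all__ = [
    "Priors",
    "RJChain",
    "ModelComparison",
    "BranchRates",
    "RateThroughTime",
    "ConvergenceReport",
    "SteppingStoneResult",
    "model_registry",
    "rjmcmc_variable_rates",
    "stepping_stone_logml",
    "power_posterior_evidence",
    "bm_single_logml_exact",
    "compare_models",
    "gelman_rubin",
    "branch_rates",
    "bin_rates_through_time",
    "terminal_rates_by_clade",
]


# --------------------------------------------------------------------------
# configuration and results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    shift_mean: float = 2.0        # truncated-Poisson mean of placement count
    max_shifts: int = 50
    mag_sd: float = 1.0            # sd of the log-magnitude prior
    rate_a: float = 2.0            # inverse-gamma shape for base rates
    rate_b: float = 1.0            # inverse-gamma scale for base rates
    mag_step: float = 0.4          # random-walk sd for log magnitudes
    theta_step: float = 0.3        # random-walk sd for transform parameters
    lambda_step: float = 0.1


@dataclass
class RJChain:
    transform_kind: str
    variable: bool
    n_iter: int
    burnin: int
    thinning: int
    seed: int | None
    beta: float
    score_scale: np.ndarray            # (d,) standardization factors
    loglik: np.ndarray                 # (S,) REML loglik, standardized units
    logpost: np.ndarray                # (S,)
    n_shifts: np.ndarray               # (S,)
    theta: np.ndarray                  # (S,) transform parameter (nan if none)
    sigma2: np.ndarray                 # (S, d) base rates, original units
    placements: list[list[tuple[int, float]]]   # per sample: (scope, log mag)
    acceptance: dict[str, tuple[int, int]]
    n_edges: int
    species: list[str]

    @property
    def n_samples(self) -> int:
        return len(self.loglik)


@dataclass
class SteppingStoneResult:
    logml: float
    mc_error: float
    betas: np.ndarray
    per_stone: np.ndarray
    n_stones: int
    iters_per_stone: int
    seed: int | None


@dataclass
class ModelComparison:
    logml: dict[str, float]
    mc_error: dict[str, float]
    model_ids: list[str]
    log_bf: np.ndarray                 # 2 (logml_i - logml_j)
    best: str
    margin: float                      # log-BF of best over runner-up
    tie: bool


@dataclass
class BranchRates:
    relative: np.ndarray               # (n_nodes,) posterior mean scalar
    absolute: np.ndarray               # relative x mean base rate
    mean_base_rate: float
    tree: PhyloTree


@dataclass
class RateThroughTime:
    bin_edges: np.ndarray              # (nb + 1,) ages, root -> present
    mean_rate: np.ndarray              # (nb,)
    n_lineages: np.ndarray             # (nb,)
    empty: np.ndarray                  # (nb,) bool


@dataclass
class ConvergenceReport:
    psrf: dict[str, float]
    ess: dict[str, float]
    warnings: list[str] = field(default_factory=list)


_REGISTRY_KINDS = [("BM", "none"), ("OU", "ou"), ("BM+lambda", "lambda"),
                   ("BM+kappa", "kappa"), ("BM+delta", "delta")]


def model_registry() -> list[dict]:
    """The ten-model set: five structures x {single, variable} rates."""
    out = []
    for label, kind in _REGISTRY_KINDS:
        for variable in (False, True):
            out.append({
                "model_id": f"{label}_{'variable' if variable else 'single'}",
                "transform_kind": kind,
                "variable": variable,
            })
    return out


# --------------------------------------------------------------------------
# tree transformations as branch-length maps
# --------------------------------------------------------------------------

def _transformed_bl(tree: PhyloTree, kind: str, param: float) -> np.ndarray:
    bl = tree.branch_lengths.copy()
    if kind == "none":
        return bl
    depths = tree.depths
    T = depths[:tree.n_tips].max()
    if kind == "lambda":
        lam = param
        bl = bl * lam
        tips = np.arange(tree.n_tips)
        bl[tips] += (1.0 - lam) * depths[tips]
        bl[tree.root] = 0.0
        return bl
    if kind == "kappa":
        out = np.where(bl > 0, bl, 0.0) ** param
        out[tree.root] = 0.0
        return out
    if kind == "delta":
        g = T * (np.maximum(depths, 0.0) / T) ** param
    elif kind == "ou":
        a = param
        g = (np.exp(-2.0 * a * (T - depths)) - np.exp(-2.0 * a * T)) / (2 * a)
    else:
        raise ValueError(f"unknown transform kind {kind!r}")
    out = np.zeros_like(bl)
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p >= 0:
            out[i] = max(g[i] - g[p], 0.0)
    return out


def _check_tree_for_kind(tree: PhyloTree, kind: str) -> None:
    if kind == "ou" and not tree.is_ultrametric(rel_tol=1e-3):
        raise ValueError("the OU branch-length transform used by the sampler "
                         "requires an ultrametric tree")


# --------------------------------------------------------------------------
# scopes: branch-local or clade-wide scalars
# --------------------------------------------------------------------------

def _scope_tables(tree: PhyloTree):
    edges = np.array([i for i in range(tree.n_nodes) if i != tree.root],
                     dtype=np.int64)
    desc: dict[int, list[int]] = {i: [i] for i in range(tree.n_nodes)}
    for i in tree.postorder:
        p = tree.parent[i]
        if p >= 0:
            desc[p].extend(desc[i])
    clade_nodes = [np.array([j for j in desc[e] ], dtype=np.int64)
                   for e in edges]
    return edges, clade_nodes


def _align_scores(scores, tree: PhyloTree, species):
    from .superimposition import RegionData
    if isinstance(scores, RegionData):
        Y, species = scores.matrix, scores.species
    else:
        Y = np.asarray(scores, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if species is not None:
        idx = tree.tip_index(species)
        out = np.empty_like(Y)
        out[idx] = Y
        Y = out
    elif len(Y) != tree.n_tips:
        raise ValueError("scores do not match tree tips")
    return np.ascontiguousarray(Y)


# --------------------------------------------------------------------------
# the sampler
# --------------------------------------------------------------------------

_LOG2PI = math.log(2.0 * math.pi)


class _Sampler:
    def __init__(self, Y: np.ndarray, tree: PhyloTree, kind: str,
                 variable: bool, priors: Priors, rng: np.random.Generator,
                 beta: float = 1.0, fix_transform: float | None = None):
        _check_tree_for_kind(tree, kind)
        self.tree = tree
        self.Y = Y
        self.N, self.d = Y.shape
        self.kind = kind
        self.variable = variable
        self.pri = priors
        self.rng = rng
        self.beta = beta
        self.fix_transform = fix_transform
        self.arrays = tree_arrays(tree)
        self.edges, self.clades = _scope_tables(tree)
        self.n_edges = len(self.edges)
        self.n_scopes = 2 * self.n_edges
        self.edge_pos = {int(e): k for k, e in enumerate(self.edges)}

        # state
        self.placements: list[tuple[int, float]] = []
        if kind == "none":
            self.theta = math.nan
        elif fix_transform is not None:
            self.theta = float(fix_transform)
        else:
            self.theta = 0.5 if kind == "lambda" else 1.0
        self.sigma2 = np.ones(self.d)
        self.bl_t = _transformed_bl(tree, kind, self.theta)
        self.logdet, self.Q = self._kernel(self._effective_bl())
        self.acc: dict[str, list[int]] = {m: [0, 0] for m in
                                          ("birth", "death", "scope", "mag",
                                           "theta")}
        self.moves = []
        if variable:
            self.moves += ["birth", "death", "scope", "mag"]
        if kind != "none" and fix_transform is None:
            self.moves += ["theta"]

    # ---- likelihood machinery ------------------------------------------
    def _kernel(self, bl):
        return contrasts_reml(bl, self.Y, *self.arrays)

    def _effective_bl(self, placements=None, bl_t=None):
        bl = (self.bl_t if bl_t is None else bl_t).copy()
        mult = np.ones(self.tree.n_nodes)
        for s, logm in (self.placements if placements is None else placements):
            m = math.exp(logm)
            if s < self.n_edges:
                mult[self.edges[s]] *= m
            else:
                mult[self.clades[s - self.n_edges]] *= m
        bl *= mult
        return bl

    def loglik(self, logdet=None, Q=None) -> float:
        logdet = self.logdet if logdet is None else logdet
        Q = self.Q if Q is None else Q
        return float(-0.5 * ((self.N - 1) * (self.d * _LOG2PI
                                             + np.sum(np.log(self.sigma2)))
                             + self.d * logdet + np.sum(Q / self.sigma2)))

    def _log_k_prior(self, k: int) -> float:
        if k > self.pri.max_shifts:
            return -np.inf
        lam = self.pri.shift_mean
        return k * math.log(lam) - gammaln(k + 1)

    def _log_theta_prior(self, theta: float) -> float:
        if self.kind in ("none",) or math.isnan(theta):
            return 0.0
        if self.kind == "lambda":
            return 0.0 if 0.0 <= theta <= 1.0 else -np.inf
        lt = math.log(theta)
        return -0.5 * (lt * lt / (self.pri.mag_sd ** 2)) - 0.5 * _LOG2PI - lt

    def log_prior(self) -> float:
        lp = self._log_k_prior(len(self.placements))
        s = self.pri.mag_sd
        for _, logm in self.placements:
            lp += -0.5 * (logm / s) ** 2 - math.log(s) - 0.5 * _LOG2PI
        lp += self._log_theta_prior(self.theta)
        a, b = self.pri.rate_a, self.pri.rate_b
        lp += float(np.sum(a * math.log(b) - gammaln(a)
                           - (a + 1) * np.log(self.sigma2)
                           - b / self.sigma2))
        return lp

    # ---- moves ----------------------------------------------------------
    def _try_state(self, placements=None, theta=None):
        bl_t = (self.bl_t if theta is None
                else _transformed_bl(self.tree, self.kind, theta))
        bl = self._effective_bl(placements=placements, bl_t=bl_t)
        logdet, Q = self._kernel(bl)
        return bl_t, logdet, Q

    def _accept(self, log_alpha: float) -> bool:
        return math.log(self.rng.random() + 1e-300) < log_alpha

    def _delta_ll(self, logdet, Q) -> float:
        if self.beta == 0.0:
            return 0.0
        return self.beta * (self.loglik(logdet, Q) - self.loglik())

    def step(self) -> None:
        if self.moves:
            move = self.moves[self.rng.integers(len(self.moves))]
            self.acc[move][1] += 1
            getattr(self, "_move_" + move)()
        # Gibbs update of the base rates under the tempered posterior
        a = self.pri.rate_a + self.beta * (self.N - 1) / 2.0
        b = self.pri.rate_b + self.beta * self.Q / 2.0
        self.sigma2 = b / self.rng.gamma(a, 1.0, size=self.d)

    def _occupied(self) -> set[int]:
        return {s for s, _ in self.placements}

    def _move_birth(self) -> None:
        k = len(self.placements)
        if k >= min(self.pri.max_shifts, self.n_scopes):
            return
        occ = self._occupied()
        while True:
            s = int(self.rng.integers(self.n_scopes))
            if s not in occ:
                break
        logm = float(self.rng.normal(0.0, self.pri.mag_sd))
        new = self.placements + [(s, logm)]
        _, logdet, Q = self._try_state(placements=new)
        la = (self._delta_ll(logdet, Q)
              + self._log_k_prior(k + 1) - self._log_k_prior(k))
        if self._accept(la):
            self.placements, self.logdet, self.Q = new, logdet, Q
            self.acc["birth"][0] += 1

    def _move_death(self) -> None:
        k = len(self.placements)
        if k == 0:
            return
        i = int(self.rng.integers(k))
        new = self.placements[:i] + self.placements[i + 1:]
        _, logdet, Q = self._try_state(placements=new)
        la = (self._delta_ll(logdet, Q)
              + self._log_k_prior(k - 1) - self._log_k_prior(k))
        if self._accept(la):
            self.placements, self.logdet, self.Q = new, logdet, Q
            self.acc["death"][0] += 1

    def _move_scope(self) -> None:
        k = len(self.placements)
        if k == 0:
            return
        i = int(self.rng.integers(k))
        occ = self._occupied() - {self.placements[i][0]}
        while True:
            s = int(self.rng.integers(self.n_scopes))
            if s not in occ and s != self.placements[i][0]:
                break
        new = list(self.placements)
        new[i] = (s, new[i][1])
        _, logdet, Q = self._try_state(placements=new)
        if self._accept(self._delta_ll(logdet, Q)):
            self.placements, self.logdet, self.Q = new, logdet, Q
            self.acc["scope"][0] += 1

    def _move_mag(self) -> None:
        k = len(self.placements)
        if k == 0:
            return
        i = int(self.rng.integers(k))
        s, logm = self.placements[i]
        logm2 = logm + float(self.rng.normal(0.0, self.pri.mag_step))
        new = list(self.placements)
        new[i] = (s, logm2)
        _, logdet, Q = self._try_state(placements=new)
        sd2 = self.pri.mag_sd ** 2
        la = (self._delta_ll(logdet, Q)
              + 0.5 * (logm * logm - logm2 * logm2) / sd2)
        if self._accept(la):
            self.placements, self.logdet, self.Q = new, logdet, Q
            self.acc["mag"][0] += 1

    def _move_theta(self) -> None:
        if self.kind == "lambda":
            t2 = self.theta + float(self.rng.normal(0.0, self.pri.lambda_step))
            # reflect into [0, 1]
            t2 = abs(t2)
            if t2 > 1.0:
                t2 = 2.0 - t2
            t2 = min(max(t2, 0.0), 1.0)
            dprior = 0.0
        else:
            lt = math.log(self.theta)
            lt2 = lt + float(self.rng.normal(0.0, self.pri.theta_step))
            t2 = math.exp(lt2)
            dprior = 0.5 * (lt * lt - lt2 * lt2)  # N(0,1) prior on log theta
        bl_t, logdet, Q = self._try_state(theta=t2)
        la = self._delta_ll(logdet, Q) + dprior
        if self._accept(la):
            self.theta, self.bl_t = t2, bl_t
            self.logdet, self.Q = logdet, Q
            self.acc["theta"][0] += 1


def rjmcmc_variable_rates(scores, tree: PhyloTree,
                          transform_kind: str = "none",
                          variable: bool = True,
                          n_iter: int = 500_000,
                          burnin: int | None = None,
                          thinning: int | None = None,
                          seed: int | None = None,
                          priors: Priors = Priors(),
                          species: list[str] | None = None,
                          beta: float = 1.0,
                          prior_only: bool = False,
                          fix_transform: float | None = None,
                          standardize: bool = True) -> RJChain:
    """Sample the posterior over rate-scalar placements and base rates.

    Scores are internally standardized by the root-tree contrast
    variance of each dimension (the same deterministic rescaling under
    every model, so Bayes factors are unaffected); reported base rates
    are mapped back to the original scale.  ``prior_only=True`` sets the
    likelihood power to zero, which leaves the chain sampling the prior
    (the standard validity check for reversible-jump moves).
    """
    if burnin is None:
        burnin = n_iter // 4
    if burnin >= n_iter:
        raise ValueError("burn-in must be smaller than n_iter")
    if thinning is None:
        thinning = max(1, (n_iter - burnin) // 1000)
    Y = _align_scores(scores, tree, species)
    scale = np.ones(Y.shape[1])
    if standardize:
        _, Q0 = contrasts_reml(tree.branch_lengths, np.ascontiguousarray(Y),
                               *tree_arrays(tree))
        scale = np.sqrt(Q0 / (tree.n_tips - 1))
        if np.any(scale <= 0):
            raise ValueError("zero-variance score dimension")
        Y = Y / scale
    rng = np.random.default_rng(seed)
    smp = _Sampler(Y, tree, transform_kind, variable, priors, rng,
                   beta=0.0 if prior_only else beta,
                   fix_transform=fix_transform)
    S = (n_iter - burnin) // thinning
    loglik = np.empty(S)
    logpost = np.empty(S)
    kk = np.empty(S, dtype=np.int64)
    theta = np.empty(S)
    sig = np.empty((S, Y.shape[1]))
    plc: list[list[tuple[int, float]]] = []
    si = 0
    for it in range(n_iter):
        smp.step()
        if it >= burnin and (it - burnin) % thinning == 0 and si < S:
            ll = smp.loglik()
            loglik[si] = ll
            logpost[si] = smp.beta * ll + smp.log_prior()
            kk[si] = len(smp.placements)
            theta[si] = smp.theta
            sig[si] = smp.sigma2 * scale ** 2
            plc.append(list(smp.placements))
            si += 1
    sp = (species if species is not None
          else (scores.species if hasattr(scores, "species")
                else tree.tip_labels))
    return RJChain(
        transform_kind=transform_kind, variable=variable, n_iter=n_iter,
        burnin=burnin, thinning=thinning, seed=seed,
        beta=0.0 if prior_only else beta, score_scale=scale,
        loglik=loglik[:si], logpost=logpost[:si], n_shifts=kk[:si],
        theta=theta[:si], sigma2=sig[:si], placements=plc,
        acceptance={m: tuple(v) for m, v in smp.acc.items()},
        n_edges=smp.n_edges, species=list(sp))


# --------------------------------------------------------------------------
# stepping-stone marginal likelihoods
# --------------------------------------------------------------------------

def _ladder(n_stones: int, power: float = 0.3) -> np.ndarray:
    k = np.arange(n_stones + 1, dtype=float)
    return (k / n_stones) ** (1.0 / power)


def _stone_sum(draws: list[np.ndarray], betas: np.ndarray,
               n_blocks: int = 10) -> tuple[float, float, np.ndarray]:
    per_stone = np.empty(len(draws))
    block_tot = np.zeros(n_blocks)
    for kidx, ll in enumerate(draws):
        dbeta = betas[kidx + 1] - betas[kidx]
        w = dbeta * ll
        per_stone[kidx] = logsumexp(w) - math.log(len(w))
        blocks = np.array_split(w, n_blocks)
        block_tot += np.array([logsumexp(b) - math.log(len(b))
                               for b in blocks])
    mc = float(block_tot.std(ddof=1) / math.sqrt(n_blocks))
    return float(per_stone.sum()), mc, per_stone


def stepping_stone_logml(scores, tree: PhyloTree,
                         transform_kind: str = "none",
                         variable: bool = False,
                         n_stones: int = 16,
                         iters_per_stone: int = 10_000,
                         seed: int | None = None,
                         priors: Priors = Priors(),
                         species: list[str] | None = None,
                         burn_frac: float = 0.2,
                         fix_transform: float | None = None,
                         standardize: bool = True) -> SteppingStoneResult:
    """Stepping-stone marginal likelihood of one registry model.

    One tempered chain per rung of the power-posterior ladder, warm
    started from the previous rung; the evidence accumulates the
    logsumexp estimate of each ratio and the MC error comes from ten
    within-stone blocks.  The reported value is in standardized-score
    units; the standardization is identical across models fitted to the
    same scores, so Bayes factors are unaffected.
    """
    Y = _align_scores(scores, tree, species)
    scale = np.ones(Y.shape[1])
    if standardize:
        _, Q0 = contrasts_reml(tree.branch_lengths, np.ascontiguousarray(Y),
                               *tree_arrays(tree))
        scale = np.sqrt(Q0 / (tree.n_tips - 1))
        Y = Y / scale
    rng = np.random.default_rng(seed)
    betas = _ladder(n_stones)
    smp = _Sampler(Y, tree, transform_kind, variable, priors, rng,
                   beta=0.0, fix_transform=fix_transform)
    burn = int(burn_frac * iters_per_stone)
    draws: list[np.ndarray] = []
    for kidx in range(n_stones):
        smp.beta = float(betas[kidx])
        ll = np.empty(iters_per_stone - burn)
        for it in range(iters_per_stone):
            smp.step()
            if it >= burn:
                ll[it - burn] = smp.loglik()
        if not np.all(np.isfinite(ll)):
            raise FloatingPointError("non-finite likelihood draw in stone "
                                     f"{kidx}")
        draws.append(ll)
    logml, mc, per_stone = _stone_sum(draws, betas)
    return SteppingStoneResult(logml=logml, mc_error=mc, betas=betas,
                               per_stone=per_stone, n_stones=n_stones,
                               iters_per_stone=iters_per_stone, seed=seed)


def power_posterior_evidence(loglik_fn, log_prior_fn, sample_prior,
                             n_stones: int = 16,
                             iters_per_stone: int = 10_000,
                             proposal_sd: float = 0.5,
                             seed: int | None = None,
                             burn_frac: float = 0.2) -> SteppingStoneResult:
    """Generic stepping-stone evidence for a continuous-parameter model.

    A plain random-walk Metropolis chain targets prior x likelihood^beta
    along the same ladder used by the tree models; useful for validating
    the estimator against models with closed-form evidence.
    """
    rng = np.random.default_rng(seed)
    betas = _ladder(n_stones)
    x = np.atleast_1d(np.asarray(sample_prior(rng), dtype=float))
    lx, px = float(loglik_fn(x)), float(log_prior_fn(x))
    burn = int(burn_frac * iters_per_stone)
    draws: list[np.ndarray] = []
    for kidx in range(n_stones):
        beta = betas[kidx]
        ll = np.empty(iters_per_stone - burn)
        for it in range(iters_per_stone):
            prop = x + rng.normal(0.0, proposal_sd, size=x.shape)
            lp, pp = float(loglik_fn(prop)), float(log_prior_fn(prop))
            if math.log(rng.random() + 1e-300) < beta * (lp - lx) + pp - px:
                x, lx, px = prop, lp, pp
            if it >= burn:
                ll[it - burn] = lx
        draws.append(ll)
    logml, mc, per_stone = _stone_sum(draws, betas)
    return SteppingStoneResult(logml=logml, mc_error=mc, betas=betas,
                               per_stone=per_stone, n_stones=n_stones,
                               iters_per_stone=iters_per_stone, seed=seed)


def bm_single_logml_exact(scores, tree: PhyloTree,
                          priors: Priors = Priors(),
                          species: list[str] | None = None,
                          standardize: bool = True) -> float:
    """Closed-form evidence of the single-rate BM model.

    The inverse-gamma base-rate prior is conjugate to the REML Brownian
    likelihood, so the evidence integrates analytically dimension by
    dimension; used to validate the stepping-stone estimator.
    """
    Y = _align_scores(scores, tree, species)
    arrays = tree_arrays(tree)
    logdet, Q = contrasts_reml(tree.branch_lengths,
                               np.ascontiguousarray(Y), *arrays)
    if standardize:
        scale2 = Q / (tree.n_tips - 1)
        Y = Y / np.sqrt(scale2)
        logdet, Q = contrasts_reml(tree.branch_lengths,
                                   np.ascontiguousarray(Y), *arrays)
    N = tree.n_tips
    a, b = priors.rate_a, priors.rate_b
    half = (N - 1) / 2.0
    out = 0.0
    for j in range(Y.shape[1]):
        out += (-half * _LOG2PI - 0.5 * logdet
                + a * math.log(b) - gammaln(a)
                + gammaln(a + half) - (a + half) * math.log(b + Q[j] / 2.0))
    return float(out)


def compare_models(logmls: dict) -> ModelComparison:
    """Pairwise log Bayes factors (factor-2 convention) and best model."""
    if len(logmls) < 2:
        raise ValueError("need at least two models")
    ids = list(logmls)
    vals, errs = {}, {}
    for mid, v in logmls.items():
        if isinstance(v, SteppingStoneResult):
            vals[mid], errs[mid] = v.logml, v.mc_error
        elif isinstance(v, (tuple, list)):
            vals[mid], errs[mid] = float(v[0]), float(v[1])
        else:
            vals[mid], errs[mid] = float(v), 0.0
        if not np.isfinite(vals[mid]):
            raise ValueError(f"missing or non-finite logML for {mid!r}")
    arr = np.array([vals[i] for i in ids])
    log_bf = 2.0 * (arr[:, None] - arr[None, :])
    order = np.argsort(arr)[::-1]
    best = ids[order[0]]
    margin = 2.0 * (arr[order[0]] - arr[order[1]])
    return ModelComparison(logml=vals, mc_error=errs, model_ids=ids,
                           log_bf=log_bf, best=best, margin=float(margin),
                           tie=bool(margin == 0.0))


# --------------------------------------------------------------------------
# diagnostics
# --------------------------------------------------------------------------

def _chain_series(chain) -> dict[str, np.ndarray]:
    if isinstance(chain, RJChain):
        out = {"loglik": chain.loglik,
               "n_shifts": chain.n_shifts.astype(float),
               "mean_log_rate": np.log(chain.sigma2).mean(axis=1)}
        if not np.all(np.isnan(chain.theta)):
            out["theta"] = chain.theta
        return out
    return {k: np.asarray(v, dtype=float) for k, v in chain.items()}


def _ess(chains: list[np.ndarray]) -> float:
    n = min(len(c) for c in chains)
    taus = []
    for c in chains:
        x = c[:n] - c[:n].mean()
        v = float(x @ x) / n
        if v == 0:
            continue
        rho = [float(x[:-lag] @ x[lag:]) / (n * v)
               for lag in range(1, n // 2)]
        tau = 1.0
        # Geyer initial positive sequence: add lag pairs while their sum
        # stays positive
        for t in range(0, len(rho) - 1, 2):
            pair = rho[t] + rho[t + 1]
            if pair <= 0:
                break
            tau += 2.0 * pair
        taus.append(tau)
    if not taus:
        return float(len(chains) * n)
    return float(len(chains) * n / float(np.mean(taus)))


def gelman_rubin(chains: list) -> ConvergenceReport:
    """Potential scale reduction factor and ESS per tracked parameter."""
    if len(chains) < 2:
        raise ValueError("need at least two chains")
    series = [_chain_series(c) for c in chains]
    params = sorted(set.intersection(*(set(s) for s in series)))
    n = min(len(s[p]) for s in series for p in params)
    psrf: dict[str, float] = {}
    ess: dict[str, float] = {}
    warn: list[str] = []
    m = len(series)
    for p in params:
        X = np.stack([s[p][:n] for s in series])
        W = float(X.var(axis=1, ddof=1).mean())
        Bn = float(X.mean(axis=1).var(ddof=1))
        if W == 0:
            psrf[p] = 1.0
            warn.append(f"parameter {p!r} has zero within-chain variance")
        else:
            var_plus = (n - 1) / n * W + Bn
            # clamp at 1: the finite-sample estimator can dip just below
            psrf[p] = max(float(math.sqrt(var_plus / W)), 1.0)
        ess[p] = _ess([X[i] for i in range(m)])
    return ConvergenceReport(psrf=psrf, ess=ess, warnings=warn)


# --------------------------------------------------------------------------
# rate summaries
# --------------------------------------------------------------------------

def branch_rates(chain: RJChain, tree: PhyloTree) -> BranchRates:
    """Posterior mean relative scalar per branch and absolute rates."""
    if chain.n_samples == 0:
        raise ValueError("chain holds no samples")
    edges, clades = _scope_tables(tree)
    n_edges = len(edges)
    acc = np.zeros(tree.n_nodes)
    for plc in chain.placements:
        mult = np.ones(tree.n_nodes)
        for s, logm in plc:
            m = math.exp(logm)
            if s < n_edges:
                mult[edges[s]] *= m
            else:
                mult[clades[s - n_edges]] *= m
        acc += mult
    rel = acc / chain.n_samples
    rel[tree.root] = 1.0
    base = float(chain.sigma2.mean())
    return BranchRates(relative=rel, absolute=rel * base,
                       mean_base_rate=base, tree=tree)


def bin_rates_through_time(rates: BranchRates, tree: PhyloTree | None = None,
                           width: float = 1.0) -> RateThroughTime:
    """Average branch rates across coexisting lineages in time bins."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    tree = tree if tree is not None else rates.tree
    A = tree.root_age
    nb = int(math.ceil(A / width))
    edges_hi = A - width * np.arange(nb + 1)
    edges_hi[-1] = max(edges_hi[-1], 0.0)
    depths = tree.depths
    mean_rate = np.full(nb, np.nan)
    n_lin = np.zeros(nb, dtype=int)
    spans = []
    for i in range(tree.n_nodes):
        p = tree.parent[i]
        if p < 0:
            continue
        spans.append((A - depths[i], A - depths[p], rates.relative[i]))
    for b in range(nb):
        hi, lo = edges_hi[b], max(edges_hi[b + 1], 0.0)
        vals = [r for (alo, ahi, r) in spans if alo < hi and ahi > lo]
        if vals:
            mean_rate[b] = float(np.mean(vals))
            n_lin[b] = len(vals)
    return RateThroughTime(bin_edges=edges_hi, mean_rate=mean_rate,
                           n_lineages=n_lin, empty=n_lin == 0)


def terminal_rates_by_clade(rates: BranchRates,
                            clade_map: dict[str, str]) -> pd.DataFrame:
    """Per-clade summary of terminal-branch relative rates."""
    tree = rates.tree
    missing = [t for t in tree.tip_labels if t not in clade_map]
    if missing:
        raise ValueError(f"tips missing from clade_map: {missing[:5]}")
    rows: dict[str, list[float]] = {}
    for i, lab in enumerate(tree.tip_labels):
        rows.setdefault(clade_map[lab], []).append(float(rates.relative[i]))
    recs = []
    for clade in sorted(rows):
        v = np.array(rows[clade])
        recs.append({"clade": clade, "n": len(v), "mean": v.mean(),
                     "median": float(np.median(v)),
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0})
    return pd.DataFrame.from_records(recs)
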