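"""Mk models for discrete characters: ML fitting, stochastic maps, simulation.

The all-rates-different (ARD) continuous-time Markov model gives every
ordered state pair its own transition rate.  Likelihoods use Felsenstein
pruning; stochastic character maps sample full histories (per-branch
state segments) conditional on the tip data via node-state posteriors
and uniformization of the within-branch path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .tree import PhyloTree

__all__ = ["QMatrixFit", "SimmapTree", "mk_loglik", "fit_mk_ard",
           "sample_stochastic_maps", "simulate_mk"]


@dataclass
class QMatrixFit:
    Q: np.ndarray
    states: tuple[str, ...]
    loglik: float
    root_prior: np.ndarray
    tree: PhyloTree
    tip_states: np.ndarray            # int codes aligned with tree tips
    trace: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.states)


@dataclass
class SimmapTree:
    """Per-branch ordered (state, duration) histories on a fixed tree."""
    tree: PhyloTree
    states: tuple[str, ...]
    segments: dict[int, list[tuple[int, float]]]  # node index -> history
    node_states: np.ndarray                       # state at each node

    def validate(self) -> None:
        for i, segs in self.segments.items():
            total = sum(d for _, d in segs)
            if abs(total - self.tree.branch_lengths[i]) > 1e-9 * max(
                    1.0, self.tree.branch_lengths[i]):
                raise AssertionError(f"branch {i} durations do not sum to length")
            for (s1, _), (s2, _) in zip(segs, segs[1:]):
                if s1 == s2:
                    raise AssertionError("adjacent segments share a state")

    def state_branch_times(self) -> np.ndarray:
        """(n_nodes, k) time each branch spends in each state."""
        out = np.zeros((self.tree.n_nodes, len(self.states)))
        for i, segs in self.segments.items():
            for s, d in segs:
                out[i, s] += d
        return out

    def total_state_times(self) -> np.ndarray:
        return self.state_branch_times().sum(axis=0)

    def n_changes(self) -> int:
        return sum(len(segs) - 1 for segs in self.segments.values())

    def state_covariances(self, order: list[str] | None = None) -> np.ndarray:
        """(k, N, N) shared root-to-MRCA path time spent in each state."""
        tree = self.tree
        ntip, k = tree.n_tips, len(self.states)
        times = self.state_branch_times()
        below = np.zeros((tree.n_nodes, ntip), dtype=bool)
        Cs = np.zeros((k, ntip, ntip))
        for i in tree.postorder:
            if i < ntip:
                below[i, i] = True
            else:
                for c in np.where(tree.parent == i)[0]:
                    below[i] |= below[c]
        for i in range(tree.n_nodes):
            if tree.parent[i] < 0:
                continue
            mask = below[i]
            block = np.ix_(np.where(mask)[0], np.where(mask)[0])
            for s in range(k):
                if times[i, s]:
                    Cs[s][block] += times[i, s]
        if order is not None:
            idx = tree.tip_index(order)
            Cs = Cs[:, idx][:, :, idx]
        return Cs


# --------------------------------------------------------------------------
# likelihood
# --------------------------------------------------------------------------

def _transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) for every branch, via eigendecomposition with expm fallback."""
    k = len(Q)
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.real(np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(lengths, w)), Vinv))
    except np.linalg.LinAlgError:
        P = np.stack([expm(Q * t) for t in lengths])
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


def _tip_codes(states, tree: PhyloTree, alphabet: tuple[str, ...] | None):
    if hasattr(states, "items"):
        mapping = dict(states.items())
    else:
        mapping = dict(zip(tree.tip_labels, states))
    if alphabet is None:
        alphabet = tuple(sorted({str(v) for v in mapping.values()}))
    code = {s: i for i, s in enumerate(alphabet)}
    try:
        tips = np.array([code[str(mapping[l])] for l in tree.tip_labels])
    except KeyError as e:
        raise ValueError(f"state or species missing: {e.args[0]!r}") from None
    return tips, alphabet


def _partials(tree: PhyloTree, tips: np.ndarray, P: np.ndarray, k: int):
    """Conditional likelihoods of the data below each node."""
    n = tree.n_nodes
    L = np.zeros((n, k))
    scale = 0.0
    for i in tree.postorder:
        if i < tree.n_tips:
            L[i, tips[i]] = 1.0
        else:
            prod = np.ones(k)
            for c in np.where(tree.parent == i)[0]:
                prod *= P[c] @ L[c]
            m = prod.max()
            if m <= 0:
                return L, -np.inf
            L[i] = prod / m
            scale += np.log(m)
    return L, scale


def mk_loglik(tree: PhyloTree, tips: np.ndarray, Q: np.ndarray,
              root_prior: np.ndarray) -> float:
    """Pruning log-likelihood of tip states under the Mk model."""
    P = _transition_matrices(Q, tree.branch_lengths)
    L, scale = _partials(tree, tips, P, len(Q))
    if not np.isfinite(scale):
        return -np.inf
    lik = float(root_prior @ L[tree.root])
    return np.log(lik) + scale if lik > 0 else -np.inf


def _ard_q(log_rates: np.ndarray, k: int) -> np.ndarray:
    Q = np.zeros((k, k))
    off = np.exp(log_rates)
    idx = 0
    for i in range(k):
        for j in range(k):
            if i != j:
                Q[i, j] = off[idx]
                idx += 1
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_mk_ard(states, tree: PhyloTree, root_prior: str = "flat",
               alphabet: tuple[str, ...] | None = None,
               n_restarts: int = 5, seed: int = 0) -> QMatrixFit:
    """Maximum-likelihood ARD transition matrix by bounded quasi-Newton.

    Optimizes the k(k-1) log-rates with multiple random restarts; the
    root prior is flat by default.  All tips sharing one state drives the
    rates toward zero (a warning-worthy but valid boundary fit).
    """
    tips, alphabet = _tip_codes(states, tree, alphabet)
    k = len(alphabet)
    if k < 2:
        raise ValueError("need >= 2 states in the alphabet")
    prior = np.full(k, 1.0 / k)
    nrate = k * (k - 1)
    scale0 = max(np.log(max(k - 1, 1)) * tree.n_tips / tree.total_length, 1e-8)

    def nll(lr):
        ll = mk_loglik(tree, tips, _ard_q(lr, k), prior)
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    best, trace = None, []
    for r in range(n_restarts):
        x0 = np.full(nrate, np.log(scale0))
        if r > 0:
            x0 = x0 + rng.normal(0, 1.5, nrate)
        res = minimize(nll, x0, method="L-BFGS-B",
                       bounds=[(-25.0, 12.0)] * nrate,
                       options={"ftol": 1e-10, "gtol": 1e-8})
        trace.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    # L-BFGS-B can stall on the flat log-rate surface; polish simplex-wise
    polish = minimize(nll, best.x, method="Nelder-Mead",
                      options={"xatol": 1e-8, "fatol": 1e-10,
                               "maxiter": 4000})
    if polish.fun < best.fun:
        best = polish
        trace.append(-polish.fun)
    Q = _ard_q(best.x, k)
    if root_prior == "stationary":
        w, V = np.linalg.eig(Q.T)
        pi = np.real(V[:, np.argmin(np.abs(w))])
        prior = np.abs(pi) / np.abs(pi).sum()
    return QMatrixFit(Q, alphabet, float(-best.fun), prior, tree, tips,
                      trace)


# --------------------------------------------------------------------------
# stochastic character mapping
# --------------------------------------------------------------------------

def node_state_posteriors(fit: QMatrixFit) -> np.ndarray:
    """Marginal posterior state probabilities at every node (pruning-based)."""
    tree = fit.tree
    k = fit.k
    P = _transition_matrices(fit.Q, tree.branch_lengths)
    L, _ = _partials(tree, fit.tip_states, P, k)
    up = np.zeros((tree.n_nodes, k))   # outside partials
    post = np.zeros((tree.n_nodes, k))
    order = tree.postorder[::-1]       # preorder
    up[tree.root] = fit.root_prior
    for i in order:
        if i == tree.root:
            continue
        p = tree.parent[i]
        sib_prod = np.ones(k)
        for c in np.where(tree.parent == p)[0]:
            if c != i:
                sib_prod *= P[c] @ L[c]
        msg = up[p] * sib_prod
        up[i] = msg @ P[i]
        up[i] /= max(up[i].max(), 1e-300)
    for i in range(tree.n_nodes):
        q = up[i] * L[i]
        post[i] = q / q.sum()
    return post


def _sample_path(Q, P, R, mu, a, b, t, rng, max_jumps=10000):
    """State history on one branch conditional on endpoints (uniformization)."""
    if t <= 0:
        return [(b, 0.0)] if a == b else [(a, 0.0), (b, 0.0)]
    pab = P[a, b]
    if pab <= 0:
        raise ValueError("endpoint pair with zero transition probability")
    # sample number of uniformized jumps
    mut = mu * t
    Rpow = [np.eye(len(Q))]
    u = rng.random()
    logpois = -mut
    cum = 0.0
    n = 0
    term = np.exp(logpois) * Rpow[0][a, b] / pab
    cum += term
    while cum < u and n < max_jumps:
        n += 1
        Rpow.append(Rpow[-1] @ R)
        logpois += np.log(mut) - np.log(n)
        cum += np.exp(logpois) * Rpow[n][a, b] / pab
    # sample chain states given n jumps
    states = [a]
    for i in range(1, n):
        prev = states[-1]
        probs = R[prev] * Rpow[n - i][:, b]
        probs = probs / probs.sum()
        states.append(int(rng.choice(len(Q), p=probs)))
    if n >= 1:
        states.append(b)
    times = np.sort(rng.random(n)) * t if n else np.array([])
    # build segments, dropping virtual (self) jumps
    segs = []
    cur, start = a, 0.0
    for s, tau in zip(states[1:], times):
        if s != cur:
            segs.append((cur, float(tau - start)))
            cur, start = s, float(tau)
    segs.append((cur, float(t - start)))
    return segs


def sample_stochastic_maps(fit: QMatrixFit, n: int = 100,
                           seed: int | None = None) -> list[SimmapTree]:
    """Sample full character histories consistent with tips and the Mk fit.

    Interior node states come from their conditional posteriors (pruning
    partials with the root prior applied); each branch's history is drawn
    conditional on its endpoint states by uniformization.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    tree, k = fit.tree, fit.k
    rng = np.random.default_rng(seed)
    P = _transition_matrices(fit.Q, tree.branch_lengths)
    L, _ = _partials(tree, fit.tip_states, P, k)
    qdiag = np.abs(np.diag(fit.Q)).max()
    mu = 1.05 * qdiag if qdiag > 0 else 1.0
    R = np.eye(k) + fit.Q / mu
    order = tree.postorder[::-1]
    maps = []
    for _ in range(n):
        node_state = np.full(tree.n_nodes, -1)
        probs = fit.root_prior * L[tree.root]
        node_state[tree.root] = rng.choice(k, p=probs / probs.sum())
        for i in order:
            if i == tree.root:
                continue
            a = node_state[tree.parent[i]]
            pr = P[i][a] * L[i]
            node_state[i] = rng.choice(k, p=pr / pr.sum())
        segments = {}
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p < 0:
                continue
            segments[i] = _sample_path(fit.Q, P[i], R, mu, node_state[p],
                                       node_state[i], tree.branch_lengths[i],
                                       rng)
        maps.append(SimmapTree(tree, fit.states, segments, node_state))
    return maps


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate_mk_history(tree: PhyloTree, Q: np.ndarray,
                        seed: int | None = None,
                        states: tuple[str, ...] | None = None,
                        root_prior: np.ndarray | None = None) -> SimmapTree:
    """Simulate a full character history under a CTMC.

    The root state is drawn from the root prior (flat by default) and
    states evolve along branches with exponential waiting times; the
    returned map records every dwell segment on every branch.
    """
    Q = np.asarray(Q, dtype=float)
    k = len(Q)
    if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-10):
        raise ValueError("Q row sums must be 0")
    if np.any(Q - np.diag(np.diag(Q)) < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    if states is None:
        states = tuple(f"s{i}" for i in range(k))
    if root_prior is None:
        root_prior = np.full(k, 1.0 / k)
    rng = np.random.default_rng(seed)
    node_state = np.full(tree.n_nodes, -1)
    node_state[tree.root] = rng.choice(k, p=root_prior)
    segments: dict[int, list[tuple[int, float]]] = {}
    for i in tree.postorder[::-1]:
        p = tree.parent[i]
        if p < 0:
            continue
        s = node_state[p]
        t = tree.branch_lengths[i]
        segs: list[tuple[int, float]] = []
        elapsed = 0.0
        last = 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            elapsed += rng.exponential(1.0 / rate)
            if elapsed >= t:
                break
            segs.append((s, elapsed - last))
            last = elapsed
            probs = Q[s].copy()
            probs[s] = 0.0
            probs /= probs.sum()
            s = int(rng.choice(k, p=probs))
        segs.append((s, t - last))
        segments[i] = segs
        node_state[i] = s
    return SimmapTree(tree=tree, states=tuple(states), segments=segments,
                      node_states=node_state)


def simulate_mk(tree: PhyloTree, Q: np.ndarray,
                seed: int | None = None,
                states: tuple[str, ...] | None = None,
                root_prior: np.ndarray | None = None) -> dict[str, str]:
    """Simulate tip states under a continuous-time Markov chain."""
    sm = simulate_mk_history(tree, Q, seed=seed, states=states,
                             root_prior=root_prior)
    return {lab: sm.states[sm.node_states[i]]
            for i, lab in enumerate(tree.tip_labels)}
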