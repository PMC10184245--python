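"""Ecological models of cranial shape evolution.

Three analyses relating shape to size and ecology on a phylogeny:

* evolutionary allometry by phylogenetic Procrustes ANOVA of the
  Procrustes coordinates against log centroid size, with significance
  from residual-randomization permutations (RRPP) and an effect size
  expressed as a standard-normal Z score of log F;
* type-II phylogenetic MANOVA under a Pagel's-lambda row covariance
  fitted by penalized likelihood, with linear shrinkage of the residual
  (column) covariance toward its diagonal so that high-dimensional
  blocks (d comparable to or larger than N) remain estimable, and
  Pillai's trace assessed by permutation;
* state-specific Brownian rates: given stochastic character maps of a
  discrete ecology, the tip covariance becomes a mixture of per-state
  shared-path times plus an iid nugget, and one rate scalar per state
  is estimated by maximum likelihood with per-dimension variances
  profiled out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .phylo_models import _ordered_C, _region_matrix, inv_sqrt

__all__ = [
    "AnovaResult",
    "GLSFit",
    "ManovaResult",
    "StateRates",
    "Design",
    "build_design",
    "procrustes_pgls",
    "mvgls_fit",
    "manova_type2",
    "state_specific_rates",
]


# --------------------------------------------------------------------------
# result records
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    F: float
    r_squared: float
    Z: float
    p_perm: float
    n_perm: int
    df_model: int
    df_resid: int
    seed: int | None = None


@dataclass
class Design:
    """A model matrix with named column blocks (terms).

    ``terms`` maps a term name to the column indices it occupies in
    ``X`` (the intercept column 0 is not a term).  ``contains`` maps a
    term to the set of terms containing it (e.g. an interaction contains
    its main effects); type-II tests exclude containing terms from both
    the full and the reduced model of a tested term.
    """
    X: np.ndarray
    terms: dict[str, np.ndarray]
    contains: dict[str, set[str]]
    species: list[str]

    def columns_for(self, names: list[str]) -> np.ndarray:
        cols = [np.array([0])] + [self.terms[n] for n in names]
        return np.concatenate(cols)


@dataclass
class GLSFit:
    B: np.ndarray                # (q, d) coefficient matrix
    lam: float                   # Pagel's lambda in [0, 1]
    gamma: float                 # shrinkage intensity in [0, 1]
    residual_cov: np.ndarray     # (d, d) shrunk residual covariance
    loglik: float                # penalized log-likelihood at the optimum
    design: Design
    Y: np.ndarray                # (N, d) response, tree order of design
    C: np.ndarray                # (N, N) lambda-transformed covariance


@dataclass
class ManovaResult:
    pillai: dict[str, float]
    p_perm: dict[str, float]
    n_perm: int
    seed: int | None = None


@dataclass
class StateRates:
    states: list[str]
    sigma2: dict[str, float]           # across-map mean rate per state
    sigma2_sd: dict[str, float]
    sigma2_e: float                    # across-map mean nugget variance
    sigma2_e_sd: float
    loglik: float                      # across-map mean log-likelihood
    per_map: list[dict] = field(default_factory=list)


# --------------------------------------------------------------------------
# phylogenetic Procrustes ANOVA (allometry)
# --------------------------------------------------------------------------

def _as_response(region) -> tuple[np.ndarray, list[str] | None]:
    Y, sp = _region_matrix(region)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y, sp


def _align_predictor(x, species):
    if isinstance(x, dict):
        return np.array([x[s] for s in species], dtype=float)
    return np.asarray(x, dtype=float)


def procrustes_pgls(region, log_cs, tree, n_perm: int = 999,
                    seed: int | None = None) -> AnovaResult:
    """Phylogenetic regression of a shape block on log centroid size.

    Rows of the response and predictor are whitened by the symmetric
    inverse square root of the BM covariance; sums of squares are
    squared residual norms; the null distribution permutes the
    reduced-model (intercept-only) whitened residual rows (RRPP).  The
    effect size Z standardizes log F against the permuted log F values
    and the p-value uses the +1 convention.
    """
    Y, sp = _as_response(region)
    species = sp if sp is not None else list(range(len(Y)))
    x = _align_predictor(log_cs, species)
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    C = _ordered_C(tree, sp)
    W = inv_sqrt(C)
    Yw = W @ Y
    N = len(Yw)
    X0 = W @ np.ones((N, 1))
    X1 = W @ np.column_stack([np.ones(N), x])

    def _resid(Xw, Yw):
        B, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        return Yw - Xw @ B

    R0 = _resid(X0, Yw)
    df1, df2 = 1, N - 2

    def f_stat(Yw_):
        R1 = _resid(X1, Yw_)
        ss_tot = float(np.sum(_resid(X0, Yw_) ** 2))
        ss_res = float(np.sum(R1 ** 2))
        ss_mod = ss_tot - ss_res
        return (ss_mod / df1) / (ss_res / df2), ss_mod, ss_res, ss_tot

    F_obs, ss_mod, ss_res, ss_tot = f_stat(Yw)
    fitted0 = Yw - R0
    rng = np.random.default_rng(seed)
    log_fs = np.empty(n_perm)
    n_ge = 0
    for b in range(n_perm):
        Yb = fitted0 + R0[rng.permutation(N)]
        Fb, *_ = f_stat(Yb)
        log_fs[b] = np.log(Fb)
        if Fb >= F_obs - 1e-12:
            n_ge += 1
    sd = log_fs.std(ddof=1)
    Z = (np.log(F_obs) - log_fs.mean()) / sd if sd > 0 else np.inf
    p = (n_ge + 1) / (n_perm + 1)
    return AnovaResult(F=F_obs, r_squared=ss_mod / ss_tot, Z=Z, p_perm=p,
                       n_perm=n_perm, df_model=df1, df_resid=df2, seed=seed)


# --------------------------------------------------------------------------
# penalized multivariate GLS (Pagel's lambda + shrinkage)
# --------------------------------------------------------------------------

def build_design(species: list[str], log_cs=None, diet=None,
                 locomotion=None,
                 interactions: list[tuple[str, str]] = ()) -> Design:
    """Model matrix with intercept, optional size, factors, interactions.

    Factors are dummy-coded dropping the first (sorted) level.
    Interaction terms are products of the participating columns and are
    recorded as containing their main effects for type-II testing.
    """
    cols: list[np.ndarray] = [np.ones((len(species), 1))]
    terms: dict[str, np.ndarray] = {}
    blocks: dict[str, np.ndarray] = {}
    start = 1

    def add(name, mat):
        nonlocal start
        mat = np.atleast_2d(mat.T).T
        cols.append(mat)
        terms[name] = np.arange(start, start + mat.shape[1])
        blocks[name] = mat
        start += mat.shape[1]

    if log_cs is not None:
        add("log_cs", _align_predictor(log_cs, species)[:, None])
    for name, values in (("diet", diet), ("locomotion", locomotion)):
        if values is None:
            continue
        v = (np.array([values[s] for s in species])
             if isinstance(values, dict) else np.asarray(values))
        levels = sorted(set(v.tolist()))
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} has fewer than two levels")
        add(name, np.column_stack([(v == lv).astype(float)
                                   for lv in levels[1:]]))
    contains: dict[str, set[str]] = {t: set() for t in terms}
    for a, b in interactions:
        mat = np.concatenate(
            [blocks[a][:, [i]] * blocks[b] for i in range(blocks[a].shape[1])],
            axis=1)
        name = f"{a}:{b}"
        add(name, mat)
        contains[name] = set()
        contains[a].add(name)
        contains[b].add(name)
    X = np.concatenate(cols, axis=1)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return Design(X=X, terms=terms, contains=contains, species=list(species))


def _lambda_C(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def _shrunk(S: np.ndarray, gamma: float) -> np.ndarray:
    out = (1.0 - gamma) * S
    out[np.diag_indices_from(out)] += gamma * np.diag(S)
    return out


def _gauss_logpdf_rows(R: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    d = Sigma.shape[0]
    w, V = np.linalg.eigh(Sigma)
    w = np.maximum(w, 1e-300)
    Z = R @ V
    quad = np.sum(Z * Z / w, axis=1)
    return -0.5 * (d * np.log(2 * np.pi) + np.sum(np.log(w)) + quad)


def _loo_score(R: np.ndarray, gamma: float) -> float:
    """Leave-one-out Gaussian log-score of whitened residual rows.

    The held-out covariance is (1-gamma) S_(-i) + gamma D with D the
    full-data diagonal target; since the held-out matrix is then a
    rank-one downdate of a common matrix, every fold is scored exactly
    from one eigendecomposition via the Sherman-Morrison identity.
    """
    n, d = R.shape
    S = R.T @ R
    M = (1.0 - gamma) * S
    M[np.diag_indices_from(M)] += gamma * np.diag(S)
    M /= (n - 1)
    w, V = np.linalg.eigh(M)
    if w[0] <= 1e-12 * max(w[-1], 1e-300):
        return -np.inf
    Z = R @ V
    a = np.sum(Z * Z / w, axis=1)
    c = (1.0 - gamma) / (n - 1)
    t = 1.0 - c * a
    if np.any(t <= 1e-10):
        return -np.inf
    logdet = float(np.sum(np.log(w))) + np.log(t)
    quad = a / t
    return float(np.sum(-0.5 * (d * np.log(2 * np.pi) + logdet + quad)))


def _golden(fun, lo, hi, tol=1e-4, iters=40):
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc, fd = fun(c), fun(d)
    for _ in range(iters):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = fun(d)
    return (a + b) / 2.0


def mvgls_fit(region, design: Design, tree,
              lambda_grid: int = 21, gamma_grid: int = 21) -> GLSFit:
    """Multivariate GLS with estimated lambda and shrunk residual cov.

    For each candidate lambda the rows are whitened by the inverse
    square root of the lambda-transformed covariance, B is ordinary
    least squares in the whitened space, and the shrinkage intensity
    gamma is chosen to maximize the leave-one-out Gaussian log-score of
    the whitened residual rows (gamma has no effect when d = 1).  The
    reported objective is the penalized log-likelihood of the
    row-correlated model with the shrunk covariance plugged in; lambda
    maximizes it over a grid refined by golden-section search.  With
    gamma > 0 the fit remains defined for d >= N.
    """
    Y, sp = _as_response(region)
    species = sp if sp is not None else design.species
    if list(design.species) != list(species):
        raise ValueError("design species do not match response species")
    C = _ordered_C(tree, sp)
    X = design.X
    N, d = Y.shape
    q = X.shape[1]
    if N < q + 2:
        raise ValueError("too few species for the design")

    def fit_at(lam):
        Cl = _lambda_C(C, lam)
        W = inv_sqrt(Cl)
        Xw, Yw = W @ X, W @ Y
        B, *_ = np.linalg.lstsq(Xw, Yw, rcond=None)
        R = Yw - Xw @ B
        if d == 1:
            gamma = 0.0
        else:
            gam_of = lambda g: _loo_score(R, g)
            grid = np.linspace(0.0, 1.0, gamma_grid)
            scores = [gam_of(g) for g in grid]
            k = int(np.argmax(scores))
            lo = grid[max(k - 1, 0)]
            hi = grid[min(k + 1, len(grid) - 1)]
            gamma = _golden(gam_of, lo, hi) if hi > lo else grid[k]
        Sigma = _shrunk(R.T @ R / N, gamma)
        sign, logdet_C = np.linalg.slogdet(Cl)
        w = np.linalg.eigvalsh(Sigma)
        w = np.maximum(w, 1e-300)
        quad = float(np.trace(np.linalg.solve(Sigma, R.T @ R)))
        ll = -0.5 * (N * d * np.log(2 * np.pi) + d * logdet_C
                     + N * float(np.sum(np.log(w))) + quad)
        return ll, gamma, B, Sigma, Cl

    grid = np.linspace(0.0, 1.0, lambda_grid)
    lls = [fit_at(l)[0] for l in grid]
    k = int(np.argmax(lls))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    lam = _golden(lambda l: fit_at(l)[0], lo, hi) if hi > lo else grid[k]
    ll, gamma, B, Sigma, Cl = fit_at(lam)
    return GLSFit(B=B, lam=float(lam), gamma=float(gamma), residual_cov=Sigma,
                  loglik=float(ll), design=design, Y=Y, C=Cl)


# --------------------------------------------------------------------------
# type-II phylogenetic MANOVA
# --------------------------------------------------------------------------

def manova_type2(fit: GLSFit, n_perm: int = 1000,
                 seed: int | None = None) -> ManovaResult:
    """Per-term Pillai traces with RRPP permutation p-values.

    Each term is tested entered last among the terms that do not contain
    it (type II): the reduced model drops the term and any interaction
    containing it, the full model adds the term back.  Pillai's trace is
    tr(H (H + E_reg)^-1) with the error cross-product shrunk toward its
    diagonal by the fitted gamma; the null permutes the reduced-model
    whitened residual rows.
    """
    design = fit.design
    if not design.terms:
        raise ValueError("the design has no terms to test")
    W = inv_sqrt(fit.C)
    Yw = W @ fit.Y
    Xw_all = W @ design.X
    N = len(Yw)
    rng = np.random.default_rng(seed)
    pillai: dict[str, float] = {}
    p_perm: dict[str, float] = {}
    for term in design.terms:
        others = [t for t in design.terms
                  if t != term and term not in design.contains.get(t, set())
                  and t not in design.contains.get(term, set())]
        red_cols = design.columns_for(sorted(others))
        full_cols = np.sort(np.concatenate([red_cols, design.terms[term]]))
        X_red, X_full = Xw_all[:, red_cols], Xw_all[:, full_cols]

        def stat(Yw_):
            Br, *_ = np.linalg.lstsq(X_red, Yw_, rcond=None)
            Rr = Yw_ - X_red @ Br
            Bf, *_ = np.linalg.lstsq(X_full, Yw_, rcond=None)
            Rf = Yw_ - X_full @ Bf
            E = Rf.T @ Rf
            H = Rr.T @ Rr - E
            E_reg = _shrunk(E, fit.gamma)
            return float(np.trace(np.linalg.solve((H + E_reg).T, H.T).T)), Rr

        obs, Rr = stat(Yw)
        fitted_red = Yw - Rr
        n_ge = 0
        for _ in range(n_perm):
            Yb = fitted_red + Rr[rng.permutation(N)]
            sb, _ = stat(Yb)
            if sb >= obs - 1e-12:
                n_ge += 1
        pillai[term] = obs
        p_perm[term] = (n_ge + 1) / (n_perm + 1)
    return ManovaResult(pillai=pillai, p_perm=p_perm, n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------
# state-specific Brownian rates on stochastic maps
# --------------------------------------------------------------------------

def _fit_one_map(Y: np.ndarray, Cs: np.ndarray, states: list[str],
                 fix_nugget_zero: bool) -> dict:
    k, N, _ = Cs.shape
    d = Y.shape[1]
    ones = np.ones(N)

    def neg_ll(x):
        g = np.ones(k)
        g[1:] = np.exp(x[:k - 1])
        e = 0.0 if fix_nugget_zero else np.exp(x[k - 1])
        V = np.tensordot(g, Cs, axes=1)
        V[np.diag_indices_from(V)] += e
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        Zy = np.linalg.solve(L, Y)
        z1 = np.linalg.solve(L, ones)
        denom = float(z1 @ z1)
        mu = (z1 @ Zy) / denom
        R = Zy - np.outer(z1, mu)
        Q = np.sum(R * R, axis=0)
        sig = np.maximum(Q / N, 1e-300)
        ll = -0.5 * np.sum(N * np.log(2 * np.pi) + N * np.log(sig)
                           + logdet + N)
        return -float(ll)

    n_par = (k - 1) + (0 if fix_nugget_zero else 1)
    if n_par == 0:
        nll = neg_ll(np.zeros(0))
        x = np.zeros(0)
    else:
        best = None
        for x0 in (np.zeros(n_par), np.full(n_par, -2.0),
                   np.full(n_par, 1.0)):
            res = minimize(neg_ll, x0, method="L-BFGS-B",
                           bounds=[(-20.0, 12.0)] * n_par)
            if best is None or res.fun < best.fun:
                best = res
        x, nll = best.x, best.fun
    g = np.ones(k)
    g[1:] = np.exp(x[:k - 1])
    e = 0.0 if fix_nugget_zero else float(np.exp(x[k - 1]))
    V = np.tensordot(g, Cs, axes=1)
    V[np.diag_indices_from(V)] += e
    L = np.linalg.cholesky(V)
    Zy = np.linalg.solve(L, Y)
    z1 = np.linalg.solve(L, ones)
    mu = (z1 @ Zy) / float(z1 @ z1)
    R = Zy - np.outer(z1, mu)
    scale = float(np.mean(np.sum(R * R, axis=0)) / N)
    return {
        "sigma2": {s: g[i] * scale for i, s in enumerate(states)},
        "sigma2_e": e * scale,
        "loglik": -nll,
    }


def state_specific_rates(region_scores, simmaps, tree=None,
                         fix_nugget_zero: bool = False) -> StateRates:
    """State-specific BM rates plus an iid nugget, averaged over maps.

    For each stochastic map the tip covariance is sum_s sigma^2_s C_s +
    sigma^2_e I, where C_s is the shared path time spent in state s.
    The first state's scalar is fixed to 1 during optimization and
    per-dimension variances are profiled out; the common scale is the
    mean profiled variance, so with a single state and the nugget fixed
    at zero the estimate collapses to the net multivariate BM rate per
    coordinate.
    """
    maps = simmaps if isinstance(simmaps, (list, tuple)) else [simmaps]
    if not maps:
        raise ValueError("need at least one stochastic map")
    Y, sp = _as_response(region_scores)
    states = list(maps[0].states)
    per_map = []
    for m in maps:
        times = m.total_state_times()
        zero = [states[i] for i in range(len(states)) if times[i] <= 0]
        if zero:
            raise ValueError(f"states with zero total time: {zero}")
        order = sp if sp is not None else m.tree.tip_labels
        Cs = m.state_covariances(order=order)
        per_map.append(_fit_one_map(Y, Cs, states, fix_nugget_zero))
    sig = {s: np.array([pm["sigma2"][s] for pm in per_map]) for s in states}
    es = np.array([pm["sigma2_e"] for pm in per_map])
    lls = np.array([pm["loglik"] for pm in per_map])
    sd = lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0
    return StateRates(
        states=states,
        sigma2={s: float(v.mean()) for s, v in sig.items()},
        sigma2_sd={s: sd(v) for s, v in sig.items()},
        sigma2_e=float(es.mean()), sigma2_e_sd=sd(es),
        loglik=float(lls.mean()), per_map=per_map)
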