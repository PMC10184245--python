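"""Generalized Procrustes Analysis and shape-space decomposition.

GPA removes translation, scale and rotation by iterative superimposition
onto a consensus; semilandmarks may slide along their curve tangents to
minimize thin-plate-spline bending energy against the consensus.  After
alignment the mirrored (right-side) points are dropped and the
configuration is partitioned into named regions for all downstream
region-wise analyses.  Disparity is Procrustes variance (mean squared
distance from the mean shape, /N convention); ordinary and phylogenetic
PCA summarize each region's shape space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_store import SpecimenSet, Template, centroid_size
from .tree import PhyloTree

__all__ = [
    "AlignedSet", "RegionData", "PCASpace",
    "gpa", "slide_semilandmarks", "split_regions",
    "procrustes_variance", "pca", "phylo_pca",
    "bending_energy_matrix", "total_bending_energy",
]


@dataclass
class AlignedSet:
    """Procrustes-aligned configurations (dimensionless shape space)."""
    coords: np.ndarray           # (N, P, 3)
    centroid_sizes: np.ndarray   # (N,) pre-scaling sizes, scan units
    consensus: np.ndarray        # (P, 3), unit centroid size
    point_ids: list[str]
    species: list[str]
    tangent_projected: bool = False
    converged: bool = True

    def copy(self) -> "AlignedSet":
        return AlignedSet(self.coords.copy(), self.centroid_sizes.copy(),
                          self.consensus.copy(), list(self.point_ids),
                          list(self.species), self.tangent_projected,
                          self.converged)


@dataclass
class RegionData:
    """One region's aligned coordinates, flattened to N x (3 p_r)."""
    name: str
    origin: str                  # CNC or PM
    matrix: np.ndarray           # (N, 3 * p_r)
    point_ids: list[str]
    species: list[str]

    @property
    def n_points(self) -> int:
        return len(self.point_ids)


@dataclass
class PCASpace:
    eigenvectors: np.ndarray     # (d, k) orthonormal columns
    eigenvalues: np.ndarray      # (k,) descending
    scores: np.ndarray           # (N, k)
    cumulative_variance: np.ndarray
    n_components_95: int
    center: np.ndarray = field(default=None)  # type: ignore[assignment]


# --------------------------------------------------------------------------
# GPA
# --------------------------------------------------------------------------

def _optimal_rotation(X: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R minimizing ||X R - target||_F."""
    U, _, Vt = np.linalg.svd(X.T @ target)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(U @ Vt))
    return U @ D @ Vt


def _superimpose(coords: np.ndarray, consensus: np.ndarray,
                 tol: float = 1e-10, max_iter: int = 100,
                 ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Iteratively rotate unit-size centered configs onto the consensus."""
    coords = coords.copy()
    converged = False
    for _ in range(max_iter):
        for i in range(len(coords)):
            coords[i] = coords[i] @ _optimal_rotation(coords[i], consensus)
        new = coords.mean(axis=0)
        new /= np.linalg.norm(new)
        if np.linalg.norm(new - consensus) < tol:
            consensus = new
            converged = True
            break
        consensus = new
    return coords, consensus, converged


def gpa(sset: SpecimenSet, template: Template | None = None,
        slide: bool = True, project_to_tangent: bool = True,
        slide_passes: int = 3, tol: float = 1e-10, max_iter: int = 100,
        ) -> AlignedSet:
    """Generalized Procrustes Analysis with optional semilandmark sliding.

    Each configuration is centered, scaled to unit centroid size and
    rotated onto the evolving consensus until the consensus stabilizes.
    With ``slide=True`` (requires a template with curves) semilandmarks
    are slid along their tangents to minimize bending energy against the
    consensus, interleaved with re-superimposition.  Original centroid
    sizes are retained; an orthogonal projection into the tangent space
    at the consensus is applied by default.
    """
    if len(sset) < 2:
        raise ValueError("need >= 2 configurations")
    status = sset.status_array()
    if np.any(status == 1):  # MISSING
        raise ValueError("missing points present; run estimate_missing first")
    raw = sset.coords_array().astype(float)
    sizes = np.empty(len(raw))
    coords = np.empty_like(raw)
    for i, X in enumerate(raw):
        c = X - X.mean(axis=0)
        cs = np.linalg.norm(c)
        if cs <= 0:
            raise ValueError(f"zero centroid size for specimen {i}")
        sizes[i] = cs
        coords[i] = c / cs
    consensus = coords[0].copy()
    consensus /= np.linalg.norm(consensus)
    coords, consensus, converged = _superimpose(coords, consensus, tol, max_iter)
    aligned = AlignedSet(coords, sizes, consensus, list(sset.point_ids),
                         sset.species, converged=converged)
    if slide and template is not None and template.curves:
        aligned = slide_semilandmarks(aligned, template, passes=slide_passes)
    aligned = _canonicalize(aligned)
    if project_to_tangent:
        aligned = _project_tangent(aligned)
    return aligned


def _canonicalize(aligned: AlignedSet) -> AlignedSet:
    """Rotate the whole solution into a canonical pose.

    GPA only fixes shapes up to one global rotation; aligning the
    consensus to its principal axes (largest-|coordinate| positive, det
    +1) makes the output a deterministic function of the input shapes.
    """
    c = aligned.consensus
    w, V = np.linalg.eigh(c.T @ c)
    order = np.argsort(w)[::-1]
    R = V[:, order]
    proj = c @ R
    for j in range(3):
        col = np.abs(proj[:, j])
        # bilateral configurations have mirror-twin points of (near-)equal
        # magnitude and opposite sign; taking the first qualifying point in
        # the fixed point order breaks the tie deterministically
        cands = np.where(col >= 0.5 * col.max())[0]
        if proj[cands[0], j] < 0:
            R[:, j] *= -1
    if np.linalg.det(R) < 0:
        # preserve chirality by flipping the most symmetric axis, whose
        # sign carries the least information
        proj = c @ R
        asym = np.abs((proj ** 3).sum(axis=0))
        R[:, int(np.argmin(asym))] *= -1
    out = aligned.copy()
    out.consensus = c @ R
    out.coords = aligned.coords @ R
    return out


def _project_tangent(aligned: AlignedSet) -> AlignedSet:
    c = aligned.consensus.ravel()
    c = c / np.linalg.norm(c)
    X = aligned.coords.reshape(len(aligned.coords), -1)
    X = X - np.outer(X @ c - 1.0, c)
    out = aligned.copy()
    out.coords = X.reshape(aligned.coords.shape)
    out.tangent_projected = True
    return out


# --------------------------------------------------------------------------
# semilandmark sliding
# --------------------------------------------------------------------------

def bending_energy_matrix(reference: np.ndarray, ridge: float = 1e-12) -> np.ndarray:
    """Thin-plate-spline bending energy matrix of a 3-D reference shape.

    Kernel U(r) = -r (the 3-D polyharmonic kernel; -r is conditionally
    positive definite in odd dimension, so the resulting B is PSD on the
    non-affine subspace).  The affine subspace carries zero energy.
    Energy of a displacement field D (P x 3) from the reference is
    sum_d D[:, d]' B D[:, d].
    """
    P = len(reference)
    r = np.linalg.norm(reference[:, None] - reference[None, :], axis=2)
    K = -r + ridge * np.eye(P)
    Q = np.hstack([np.ones((P, 1)), reference])
    L = np.zeros((P + 4, P + 4))
    L[:P, :P] = K
    L[:P, P:] = Q
    L[P:, :P] = Q.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular bending-energy kernel (coincident points)") from e
    B = Linv[:P, :P]
    return 0.5 * (B + B.T)


def total_bending_energy(coords: np.ndarray, consensus: np.ndarray,
                         B: np.ndarray | None = None) -> float:
    """Summed TPS bending energy of all specimens against the consensus."""
    if B is None:
        B = bending_energy_matrix(consensus)
    D = coords - consensus  # (N, P, 3)
    return float(np.einsum("npd,pq,nqd->", D, B, D))


def _slider_structure(template: Template, point_ids: list[str]):
    """(index, prev index, next index) for every semilandmark present."""
    pos = {p: i for i, p in enumerate(point_ids)}
    sliders = []
    for curve in template.curves:
        m = curve.n_semilandmarks
        chain = [curve.point_ids[0]] + [f"{curve.curve_id}:{k}"
                                        for k in range(1, m - 1)] + [curve.point_ids[-1]]
        # left-side chain
        for k in range(1, m - 1):
            if chain[k] in pos:
                sliders.append((pos[chain[k]], pos[chain[k - 1]], pos[chain[k + 1]]))
        # mirrored chain (only if the mirrored semilandmarks exist)
        mchain = [template.mirror_id(p) for p in chain]
        if mchain[1] in pos and mchain[1] != chain[1]:
            for k in range(1, m - 1):
                sliders.append((pos[mchain[k]], pos[mchain[k - 1]], pos[mchain[k + 1]]))
    # deduplicate, keep order
    seen, out = set(), []
    for s in sliders:
        if s[0] not in seen:
            seen.add(s[0])
            out.append(s)
    return out


def slide_semilandmarks(aligned: AlignedSet, template: Template,
                        passes: int = 3, resuperimpose: bool = True,
                        ) -> AlignedSet:
    """Slide semilandmarks along curve tangents to minimize bending energy.

    Tangent directions are central differences of each semilandmark's
    curve neighbours on the specimen itself.  Per pass and specimen the
    optimal tangential displacements solve a closed-form quadratic
    (normal equations in the bending-energy metric of the consensus);
    a specimen's update is kept only if its energy does not increase.
    Fixed landmarks never move.
    """
    out = aligned.copy()
    sliders = _slider_structure(template, out.point_ids)
    if not sliders:
        return out
    idx = np.array([s[0] for s in sliders])
    iprev = np.array([s[1] for s in sliders])
    inext = np.array([s[2] for s in sliders])
    for _ in range(passes):
        B = bending_energy_matrix(out.consensus)
        Bsub = B[np.ix_(idx, idx)]
        for n in range(len(out.coords)):
            Y = out.coords[n]
            D = Y - out.consensus
            e_old = float(np.einsum("pd,pq,qd->", D, B, D))
            tang = Y[inext] - Y[iprev]
            norms = np.linalg.norm(tang, axis=1)
            ok = norms > 1e-12
            tang[ok] /= norms[ok, None]
            tang[~ok] = 0.0
            A = Bsub * (tang @ tang.T)
            b = -np.einsum("sd,sd->s", tang, (B @ D)[idx])
            try:
                t = np.linalg.solve(A + 1e-10 * np.eye(len(A)), b)
            except np.linalg.LinAlgError:
                continue
            Ynew = Y.copy()
            Ynew[idx] += t[:, None] * tang
            Dn = Ynew - out.consensus
            e_new = float(np.einsum("pd,pq,qd->", Dn, B, Dn))
            if e_new <= e_old + 1e-12:
                out.coords[n] = Ynew
        if resuperimpose:
            # recenter/rescale/rotate and refresh the consensus
            for n in range(len(out.coords)):
                c = out.coords[n] - out.coords[n].mean(axis=0)
                out.coords[n] = c / np.linalg.norm(c)
            out.coords, out.consensus, _ = _superimpose(
                out.coords, out.consensus)
    return out


# --------------------------------------------------------------------------
# regions, disparity, PCA
# --------------------------------------------------------------------------

def split_regions(aligned: AlignedSet, template: Template) -> list[RegionData]:
    """Drop the mirrored side and partition the points by region.

    Returns one :class:`RegionData` per template region (CNC regions
    first).  The right-side points (non-self images under the bilateral
    pairing) are removed to reduce dimensionality.
    """
    left = template.left_point_ids_set()
    keep = [i for i, p in enumerate(aligned.point_ids) if p in left]
    kept_ids = [aligned.point_ids[i] for i in keep]
    X = aligned.coords[:, keep, :]
    out = []
    for region in template.regions():
        cols = [j for j, p in enumerate(kept_ids)
                if template.region_of.get(p) == region]
        if not cols:
            raise ValueError(f"region {region!r} has zero points")
        mat = X[:, cols, :].reshape(len(X), -1)
        out.append(RegionData(region, template.origin_of[region], mat,
                              [kept_ids[j] for j in cols], aligned.species))
    return out


def procrustes_variance(region: RegionData | np.ndarray) -> float:
    """Disparity: mean squared distance from the mean shape (/N)."""
    Y = region.matrix if isinstance(region, RegionData) else np.asarray(region)
    if len(Y) < 2:
        raise ValueError("need >= 2 specimens")
    dev = Y - Y.mean(axis=0)
    return float((dev ** 2).sum() / len(Y))


def _deterministic_signs(V: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so the largest-magnitude loading is positive."""
    j = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[j, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def _finish_pca(dev: np.ndarray, V: np.ndarray, lam: np.ndarray,
                center: np.ndarray) -> PCASpace:
    lam = np.maximum(lam, 0.0)
    keep = lam > max(lam.max(), 0.0) * 1e-12 if lam.size else lam > 0
    if keep.sum() == 0:
        keep = np.zeros(len(lam), dtype=bool)
        keep[0] = True
    V, lam = V[:, keep], lam[keep]
    V = _deterministic_signs(V)
    scores = dev @ V
    total = lam.sum()
    cum = np.cumsum(lam) / total if total > 0 else np.ones_like(lam)
    n95 = int(np.searchsorted(cum, 0.95 - 1e-12) + 1)
    return PCASpace(V, lam, scores, cum, n95, center)


def pca(region: RegionData | np.ndarray) -> PCASpace:
    """Ordinary PCA of the sample covariance (divisor N-1) of the rows."""
    Y = region.matrix if isinstance(region, RegionData) else np.asarray(region)
    if len(Y) < 3:
        raise ValueError("need >= 3 specimens")
    center = Y.mean(axis=0)
    dev = Y - center
    U, s, Vt = np.linalg.svd(dev, full_matrices=False)
    lam = s ** 2 / (len(Y) - 1)
    return _finish_pca(dev, Vt.T, lam, center)


def phylo_pca(region: RegionData, tree: PhyloTree,
              C: np.ndarray | None = None) -> PCASpace:
    """Phylogenetic PCA: eigen-axes of the GLS evolutionary covariance.

    The evolutionary covariance is the residual cross-product from the
    phylogenetic (GLS) mean, weighted by the inverse BM covariance,
    divisor N-1; scores are the projections of the rows centered on the
    phylogenetic mean.  On a star tree with equal branch lengths this
    reduces exactly to ordinary PCA.
    """
    Y = region.matrix
    if C is None:
        C = tree.vcv(order=region.species)
    N = len(Y)
    Cinv = np.linalg.inv(C)
    one = np.ones(N)
    w = Cinv @ one / (one @ Cinv @ one)
    a_hat = w @ Y
    dev = Y - a_hat
    R = dev.T @ Cinv @ dev / (N - 1)
    lam, V = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    k = min(N - 1, Y.shape[1])
    return _finish_pca(dev, V[:, :k], lam[:k], a_hat)
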