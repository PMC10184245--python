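"""GPA, sliding, tangent projection, regions, disparity and PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import morphorates as mr
from morphorates.landmark_store import OBSERVED


def _as_set(coords, point_ids=None):
    ids = (point_ids if point_ids is not None
           else [f"p{i}" for i in range(coords.shape[1])])
    configs = [mr.LandmarkConfiguration(
        f"s{i}", f"s{i}", coords[i].copy(),
        np.full(coords.shape[1], OBSERVED, dtype=np.int8))
        for i in range(len(coords))]
    return mr.SpecimenSet(configs, list(ids))


def test_gpa_similarity_invariance(small_dataset, small_template):
    sset, _ = small_dataset
    base = mr.gpa(sset, small_template, slide=False)
    rng = np.random.default_rng(1)
    coords = sset.coords_array().copy()
    for i in range(len(coords)):
        R = Rotation.random(random_state=np.random.RandomState(i)).as_matrix()
        s = float(rng.uniform(0.5, 2.0))
        t = rng.normal(size=3) * 10
        coords[i] = s * coords[i] @ R + t
    moved = _as_set(coords, sset.point_ids)
    again = mr.gpa(moved, small_template, slide=False)
    assert np.abs(again.coords - base.coords).max() < 1e-8


def test_gpa_unit_size_and_centered(small_dataset, small_template):
    sset, _ = small_dataset
    al = mr.gpa(sset, small_template, slide=False, project_to_tangent=False)
    for X in al.coords:
        assert np.linalg.norm(X) == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-8)


def test_sliding_reduces_bending_energy(small_dataset, small_template):
    sset, _ = small_dataset
    rigid = mr.gpa(sset, small_template, slide=False,
                   project_to_tangent=False)
    slid = mr.slide_semilandmarks(rigid, small_template, passes=1,
                                  resuperimpose=False)
    for n in range(len(rigid.coords)):
        e0 = mr.total_bending_energy(rigid.coords[n][None], rigid.consensus)
        e1 = mr.total_bending_energy(slid.coords[n][None], slid.consensus)
        assert e1 <= e0 + 1e-12


def test_bending_energy_zero_for_affine():
    rng = np.random.default_rng(0)
    ref = rng.standard_normal((12, 3))
    A = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    affine = ref @ A + rng.standard_normal(3)
    assert mr.total_bending_energy(affine[None], ref) == pytest.approx(0.0, abs=1e-8)
    bent = affine + 0.1 * rng.standard_normal(affine.shape)
    assert mr.total_bending_energy(bent[None], ref) > 1e-6


def test_split_regions_drops_right_side(regions_small, small_template,
                                        aligned_small):
    names = [r.name for r in regions_small]
    assert names == ["front", "side", "back"]  # CNC regions first
    left = small_template.left_point_ids_set()
    total_pts = sum(r.n_points for r in regions_small)
    assert total_pts == len(left)
    for r in regions_small:
        assert all(p in left for p in r.point_ids)
        assert r.matrix.shape == (len(aligned_small.species), 3 * r.n_points)


def test_procrustes_variance_matches_pairwise():
    rng = np.random.default_rng(2)
    Y = rng.standard_normal((20, 9))
    pv = mr.procrustes_variance(Y)
    dev = Y - Y.mean(axis=0)
    assert pv == pytest.approx(float((dev ** 2).sum() / len(Y)))


def test_pca_orthonormal_and_variance(regions_small):
    r = regions_small[0]
    space = mr.pca(r)
    V = space.eigenvectors
    np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-10)
    np.testing.assert_allclose(space.scores.var(axis=0, ddof=1),
                               space.eigenvalues, rtol=1e-10)
    assert space.cumulative_variance[-1] == pytest.approx(1.0)
    assert 1 <= space.n_components_95 <= V.shape[1]


def test_phylo_pca_star_tree_equals_pca(regions_small):
    from conftest import star_tree
    r = regions_small[0]
    star = star_tree(len(r.species))
    r2 = mr.RegionData(r.name, r.origin, r.matrix, r.point_ids,
                       [f"s{i}" for i in range(len(r.species))])
    ordinary = mr.pca(r2)
    phylo = mr.phylo_pca(r2, star)
    np.testing.assert_allclose(np.abs(phylo.scores[:, :3]),
                               np.abs(ordinary.scores[:, :3]), atol=1e-8)


def test_gpa_requires_complete_data(small_dataset, small_template):
    sset, _ = small_dataset
    broken = sset.copy()
    broken.configurations[0].status[0] = 1  # MISSING
    with pytest.raises(ValueError, match="missing"):
        mr.gpa(broken, small_template)
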