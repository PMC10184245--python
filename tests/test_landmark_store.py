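"""Landmark I/O, templates, mirroring, missing estimation, collapsing."""

import json

import numpy as np
import pytest

import morphorates as mr
from morphorates.landmark_store import ESTIMATED, MISSING, OBSERVED


def test_template_roundtrip_yaml(small_template, tmp_path):
    p = tmp_path / "t.yaml"
    small_template.to_yaml(p)
    back = mr.Template.from_yaml(p)
    assert back.left_point_ids() == small_template.left_point_ids()
    assert back.full_point_ids() == small_template.full_point_ids()
    assert back.regions() == small_template.regions()
    assert back.midline_ids == small_template.midline_ids


def test_left_ids_order_fixed_then_semis(small_template):
    ids = small_template.left_point_ids()
    n_fixed = len(small_template.fixed_ids)
    assert ids[:n_fixed] == list(small_template.fixed_ids)
    assert all(":" in p for p in ids[n_fixed:])


def test_csv_roundtrip_exact(small_dataset, tmp_path):
    sset, _ = small_dataset
    p = tmp_path / "lm.csv"
    mr.write_landmarks(sset, p)
    back = mr.read_landmarks(p, point_ids=sset.point_ids)
    assert back.point_ids == sset.point_ids
    a = sset.coords_array()
    b = back.coords_array()
    np.testing.assert_array_equal(sset.status_array(), back.status_array())
    ok = sset.status_array() != MISSING
    np.testing.assert_array_equal(a[ok], b[ok])


def test_read_accepts_left_or_full_layout(small_dataset, small_template,
                                          tmp_path):
    sset, _ = small_dataset  # full bilateral layout
    p = tmp_path / "full.csv"
    mr.write_landmarks(sset, p)
    back = mr.read_landmarks(p, template=small_template)
    assert back.point_ids == small_template.full_point_ids()


def test_read_rejects_unknown_ids(small_dataset, small_template, tmp_path):
    import pandas as pd
    sset, _ = small_dataset
    p = tmp_path / "bad.csv"
    mr.write_landmarks(sset, p)
    df = pd.read_csv(p)
    df.loc[0, "point_id"] = "nonexistent_point"
    df.to_csv(p, index=False)
    with pytest.raises(ValueError, match="unknown point ids"):
        mr.read_landmarks(p, template=small_template)


def test_centroid_size():
    pts = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 2.0, 0], [0, -2.0, 0]])
    assert mr.centroid_size(pts) == pytest.approx(np.sqrt(1 + 1 + 4 + 4))


def test_resample_curve_arc_length():
    t = np.linspace(0, 1, 50)
    pts = np.column_stack([t, t ** 2, np.zeros_like(t)])
    out = mr.resample_curve(pts, 7)
    assert out.shape == (7, 3)
    np.testing.assert_allclose(out[0], pts[0], atol=1e-12)
    np.testing.assert_allclose(out[-1], pts[-1], atol=1e-12)
    seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert seg.std() / seg.mean() < 0.05  # near-equal arc spacing


def test_mirror_set_symmetric(small_template):
    rng = np.random.default_rng(0)
    left_ids = small_template.left_point_ids()
    from morphorates.synthetic_data import template_base_matrix
    base = template_base_matrix(small_template)
    configs = []
    for i in range(3):
        pts = base + 0.01 * rng.standard_normal(base.shape)
        pts[[j for j, p in enumerate(left_ids)
             if p in small_template.midline_ids], 0] = 0.0
        status = np.full(len(pts), OBSERVED, dtype=np.int8)
        configs.append(mr.LandmarkConfiguration(f"s{i}", f"s{i}",
                                                pts, status))
    sset = mr.SpecimenSet(configs, left_ids)
    plane = (np.zeros(3), np.array([1.0, 0.0, 0.0]))
    full = mr.mirror_set(sset, small_template, plane=plane)
    assert full.point_ids == small_template.full_point_ids()
    # mirrored copies are reflections: same |x|, same (y, z)
    n_left = len(left_ids)
    lateral = [j for j, p in enumerate(left_ids)
               if p not in small_template.midline_ids]
    for c in full.configurations:
        L = c.points[lateral]
        R = c.points[n_left:]
        np.testing.assert_allclose(np.abs(L[:, 0]), np.abs(R[:, 0]),
                                   atol=1e-8)
        np.testing.assert_allclose(L[:, 1:], R[:, 1:], atol=1e-8)


def test_estimate_missing_recovers_points(small_dataset, small_template):
    sset, _ = small_dataset
    rng = np.random.default_rng(5)
    broken = sset.copy()
    truth = {}
    for c in broken.configurations[:8]:
        kill = rng.choice(len(broken.point_ids), size=3, replace=False)
        truth[c.specimen_id] = (kill, c.points[kill].copy())
        c.points[kill] = np.nan
        c.status[kill] = MISSING
    est = mr.estimate_missing(broken)
    for c in est.configurations:
        assert not np.any(c.status == MISSING)
        if c.specimen_id in truth:
            kill, pts = truth[c.specimen_id]
            assert np.all(c.status[kill] == ESTIMATED)
            err = np.linalg.norm(c.points[kill] - pts, axis=1)
            cs = mr.centroid_size(pts if len(pts) > 3 else c.points)
            assert np.mean(err) < 0.05 * cs


def test_estimate_missing_deterministic(small_dataset):
    sset, _ = small_dataset
    broken = sset.copy()
    c = broken.configurations[0]
    c.points[:4] = np.nan
    c.status[:4] = MISSING
    a = mr.estimate_missing(broken)
    b = mr.estimate_missing(broken)
    np.testing.assert_array_equal(a.coords_array(), b.coords_array())


def test_collapse_absent_idempotent(small_dataset, small_template):
    sset, _ = small_dataset
    c = sset.configurations[0]
    out1 = mr.collapse_absent(c, "side", small_template, sset.point_ids)
    out2 = mr.collapse_absent(out1, "side", small_template, sset.point_ids)
    np.testing.assert_array_equal(out1.points, out2.points)
    np.testing.assert_array_equal(out1.status, out2.status)
    anchor = small_template.absent_anchor["side"]
    ai = sset.point_ids.index(anchor)
    for i, p in enumerate(sset.point_ids):
        if small_template.region_of.get(p) == "side" and i != ai:
            np.testing.assert_array_equal(out1.points[i], c.points[ai])


def test_read_traits(tmp_path):
    p = tmp_path / "traits.csv"
    p.write_text("species,diet,locomotion\n"
                 "a,herbivore,terrestrial\n"
                 "b,carnivore,arboreal\n")
    tt = mr.read_traits(p)
    assert tt.table.loc["a", "diet"] == "herbivore"
    assert set(tt.table.columns) == {"diet", "locomotion"}
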