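"""Synthetic generator: trees, templates, shapes, missingness, truth."""

import numpy as np
import pytest

import morphorates as mr
from conftest import SMALL_SPEC


def test_simulate_tree_defaults_are_study_scale():
    tree = mr.simulate_tree(seed=1)
    assert tree.n_tips == 322
    assert tree.root_age == pytest.approx(80.3, rel=1e-9)
    depths = tree.depths[:tree.n_tips]
    np.testing.assert_allclose(depths, 80.3, rtol=1e-9)  # ultrametric


def test_simulate_tree_reproducible():
    a = mr.simulate_tree(n_tips=20, seed=5)
    b = mr.simulate_tree(n_tips=20, seed=5)
    assert a.to_newick() == b.to_newick()


def test_default_template_layout():
    tmpl = mr.build_template()
    regions = tmpl.regions()
    assert len(regions) == 17
    origins = [tmpl.origin_of[r] for r in regions]
    assert origins.count("CNC") == 12
    assert origins.count("PM") == 5
    assert origins[:12] == ["CNC"] * 12  # CNC regions first
    for m in tmpl.midline_ids:
        assert tmpl.base_geometry[m][0] == 0.0


def test_region_rates_ordering():
    rates = mr.default_region_rates()
    assert len(rates) == 17
    assert rates["premaxilla_v"] > rates["basioccipital"]
    assert all(v > 0 for v in rates.values())


def test_simulate_shapes_truth_roundtrip(tree64, small_template, tmp_path):
    sset, truth = mr.simulate_shapes(tree64, small_template, seed=3)
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = mr.SyntheticTruth.from_json(p)
    assert back.seed == truth.seed
    assert back.tree_newick == truth.tree_newick
    assert back.region_rates == truth.region_rates
    sset2, _ = mr.simulate_shapes(tree64, small_template, seed=3)
    np.testing.assert_array_equal(sset.coords_array(), sset2.coords_array())


def test_simulate_shapes_rate_recovery(tree64, small_template):
    rates = {"front": 4e-4, "side": 1e-4, "back": 1e-4}
    sset, _ = mr.simulate_shapes(tree64, small_template, region_rates=rates,
                                 allometry_slope=0.0, log_cs_rate=0.01,
                                 seed=8)
    al = mr.gpa(sset, small_template, slide=False)
    regions = mr.split_regions(al, small_template)
    est = {r.name: mr.sigma2_mult(r, tree64) for r in regions}
    assert est["front"] > 2.0 * est["side"]


def test_inject_missing_fractions(tree64, small_template):
    sset, _ = mr.simulate_shapes(tree64, small_template, seed=2)
    out, absent = mr.inject_missing(
        sset, small_template,
        element_fractions={"side": 0.5}, absent_fractions={"side": 0.2},
        seed=0)
    cols = small_template.region_points("side", out.point_ids)
    status = out.status_array()
    n_missing = int((status[:, cols] == 1).any(axis=1).sum())
    assert 0.3 * len(out) < n_missing < 0.7 * len(out)
    assert set(absent) == {"side"}
    assert all(a in {c.specimen_id for c in out.configurations}
               for a in absent["side"])
    # untouched regions stay complete
    other = small_template.region_points("front", out.point_ids)
    assert not (status[:, other] == 1).any()


def test_simulate_ecology_states(tree64):
    traits = mr.simulate_ecology(tree64, seed=4)
    assert list(traits.table.index) == list(tree64.tip_labels)
    assert set(traits.table["diet"]) <= {"herbivore", "carnivore",
                                         "omnivore", "insectivore"}
    assert set(traits.table["locomotion"]) <= {"terrestrial", "arboreal",
                                               "aquatic", "fossorial"}


def test_shift_clade_raises_rates(tree64, small_template):
    tips = mr.simulate_tree(n_tips=64, seed=7).tip_labels  # same tree seed
    clade = tree64.clade_tips(tree64.mrca(list(tips[:6])))
    sh = [{"tips": list(clade), "magnitude": 8.0}]
    rates = {"front": 1e-4, "side": 1e-4, "back": 1e-4}
    sset, truth = mr.simulate_shapes(tree64, small_template,
                                     region_rates=rates, shift_clades=sh,
                                     allometry_slope=0.0, seed=1)
    assert truth.shift_clades[0]["magnitude"] == 8.0
    al = mr.gpa(sset, small_template, slide=False)
    regions = mr.split_regions(al, small_template)
    Y = regions[0].matrix
    idx_in = [regions[0].species.index(s) for s in clade]
    idx_out = [i for i in range(len(Y)) if i not in idx_in]
    v_in = np.var(Y[idx_in], axis=0).mean()
    v_out = np.var(Y[idx_out], axis=0).mean()
    assert v_in > v_out  # the shifted clade is more disparate
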