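"""Shared fixtures: small trees, templates and simulated datasets."""

import numpy as np
import pytest

import morphorates as mr

SMALL_SPEC = [
    {"name": "front", "origin": "CNC", "n_fixed_lateral": 2,
     "n_fixed_midline": 1, "curve_semilandmarks": 5},
    {"name": "side", "origin": "CNC", "n_fixed_lateral": 2,
     "n_fixed_midline": 0, "curve_semilandmarks": 4},
    {"name": "back", "origin": "PM", "n_fixed_lateral": 2,
     "n_fixed_midline": 1, "curve_semilandmarks": 0},
]


@pytest.fixture(scope="session")
def tree16() -> mr.PhyloTree:
    """Balanced ultrametric 16-tip tree of depth 4."""
    nw = ("((((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,(g:1,h:1):1):1):1,"
          "(((i:1,j:1):1,(k:1,l:1):1):1,((m:1,n:1):1,(o:1,p:1):1):1):1);")
    return mr.PhyloTree.from_newick(nw)


@pytest.fixture(scope="session")
def tree4() -> mr.PhyloTree:
    return mr.PhyloTree.from_newick("((a:1,b:1):0.5,(c:0.8,d:0.8):0.7);")


@pytest.fixture(scope="session")
def tree64() -> mr.PhyloTree:
    return mr.simulate_tree(n_tips=64, root_age=80.3, seed=7)


@pytest.fixture(scope="session")
def small_template() -> mr.Template:
    return mr.build_template(SMALL_SPEC, seed=3)


@pytest.fixture(scope="session")
def small_dataset(tree64, small_template):
    """Raw bilateral specimen set simulated on the 64-tip tree."""
    rates = {"front": 2e-4, "side": 1e-4, "back": 5e-5}
    sset, truth = mr.simulate_shapes(tree64, small_template,
                                     region_rates=rates, seed=11)
    return sset, truth


@pytest.fixture(scope="session")
def aligned_small(small_dataset, small_template):
    sset, _ = small_dataset
    return mr.gpa(sset, small_template, slide=True)


@pytest.fixture(scope="session")
def regions_small(aligned_small, small_template):
    return mr.split_regions(aligned_small, small_template)


def star_tree(n: int, depth: float = 1.0) -> mr.PhyloTree:
    tips = ",".join(f"s{i}:{depth}" for i in range(n))
    return mr.PhyloTree.from_newick(f"({tips});")


def bm_data(tree: mr.PhyloTree, d: int, rate: float, seed: int) -> np.ndarray:
    """Tip data under iid-per-dimension BM with the given rate."""
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(tree.vcv())
    return L @ rng.standard_normal((tree.n_tips, d)) * np.sqrt(rate)
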