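"""Synthetic study generator: trees, templates, shapes, traits, missingness.

Emulates the structure of a large comparative cranial dataset: a dated
(ultrametric) phylogeny of a few hundred species, a bilateral landmark
template partitioned into 17 named regions labelled by embryonic origin
(12 cranial-neural-crest, 5 paraxial-mesoderm), region-wise Brownian
shape evolution with optional clade rate shifts and tree transformations,
Brownian log centroid size driving a per-region allometric component,
Mk-evolving diet and locomotion categories, and element-wise missingness
with biologically absent elements.  Every generator is a pure function of
(config, seed) and records the complete generating truth.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .landmark_store import (LandmarkConfiguration, MISSING, OBSERVED,
                             SpecimenSet, Template, TraitTable, centroid_size)
from .discrete_traits import simulate_mk
from .phylo_models import TreeTransform, transform_covariance
from .tree import PhyloTree

__all__ = ["SyntheticTruth", "simulate_tree", "build_template",
           "simulate_shapes", "inject_missing", "simulate_ecology",
           "DEFAULT_REGION_SPEC", "default_region_rates", "default_q",
           "TABLE_REGIONS"]

# The 17 cranial regions with their embryonic origin labels, CNC first.
TABLE_REGIONS: tuple[tuple[str, str], ...] = (
    ("nasal", "CNC"), ("premaxilla_d", "CNC"), ("premaxilla_v", "CNC"),
    ("maxilla_d", "CNC"), ("maxilla_v", "CNC"), ("palatine", "CNC"),
    ("jugal", "CNC"), ("frontal", "CNC"), ("squamosal_v", "CNC"),
    ("squamosal_z", "CNC"), ("glenoid_fossa", "CNC"), ("pterygoid", "CNC"),
    ("parietal", "PM"), ("supraoccipital", "PM"), ("occipital_condyle", "PM"),
    ("basioccipital", "PM"), ("basisphenoid", "PM"),
)

DEFAULT_REGION_SPEC = [
    {"name": name, "origin": origin, "n_fixed_lateral": 2,
     "n_fixed_midline": 1, "curve_semilandmarks": 5}
    for name, origin in TABLE_REGIONS
]

# Default per-region BM rates (squared shape units per Myr).  Relative
# magnitudes follow the observed spread of per-region cranial rates
# (faster anterior-face CNC elements, slower basicranium), scaled so that
# tip-level Procrustes variance lands in a realistic range.
_RELATIVE_RATES = {
    "nasal": 5.810, "premaxilla_d": 6.285, "premaxilla_v": 8.588,
    "maxilla_d": 5.416, "maxilla_v": 4.905, "palatine": 3.883,
    "jugal": 7.021, "frontal": 6.362, "squamosal_v": 4.202,
    "squamosal_z": 5.624, "glenoid_fossa": 4.219, "pterygoid": 3.877,
    "parietal": 5.499, "supraoccipital": 4.005, "occipital_condyle": 3.812,
    "basioccipital": 2.269, "basisphenoid": 2.549,
}


def default_region_rates(scale: float = 1e-5) -> dict[str, float]:
    """Per-region BM rates: relative cranial-rate profile times ``scale``."""
    return {r: v * scale for r, v in _RELATIVE_RATES.items()}


def default_q(states: tuple[str, ...], rate: float = 0.02) -> np.ndarray:
    """Symmetric Mk matrix with the given per-pair transition rate."""
    k = len(states)
    Q = np.full((k, k), rate)
    np.fill_diagonal(Q, -(k - 1) * rate)
    return Q


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate a dataset bit-identically."""
    tree_newick: str
    region_rates: dict[str, float]
    shift_clades: list[dict] = field(default_factory=list)
    transform_kind: str = "none"
    transform_parameter: float = 1.0
    allometry_slope: dict[str, float] = field(default_factory=dict)
    allometry_direction: dict[str, list[float]] = field(default_factory=dict)
    log_cs_rate: float = 0.05
    log_cs_root: float = 0.0
    nugget: float = 0.0
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# --------------------------------------------------------------------------
# tree
# --------------------------------------------------------------------------

def simulate_tree(n_tips: int = 322, birth: float = 1.0, death: float = 0.5,
                  root_age: float = 80.3, seed: int = 0) -> PhyloTree:
    """Ultrametric birth-death tree conditioned on n_tips, rescaled in age.

    The birth-death process runs until n_tips extant lineages exist; the
    terminal branches are extended by one exponential waiting time (so no
    zero-length cherries remain) and the tree is rescaled so the root
    depth equals ``root_age`` (Myr).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = _random.Random(seed)
    if n_tips == 2:
        return PhyloTree.from_newick(f"(t1:{root_age},t2:{root_age});")
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_tips, rng=rng,
        repeat_until_success=True)
    grace = rng.expovariate(n_tips * birth)
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + grace
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        if leaf.taxon is None:
            leaf.taxon = dtree.taxon_namespace.new_taxon(f"t{i}")
    tree = PhyloTree.from_dendropy(dtree)
    depth = tree.root_age
    tree = PhyloTree(tree.parent, tree.branch_lengths * (root_age / depth),
                     tree.tip_labels, tree.postorder)
    return tree


# --------------------------------------------------------------------------
# template
# --------------------------------------------------------------------------

def build_template(region_spec: list[dict] | None = None,
                   seed: int = 0) -> Template:
    """Bilateral template with midline, paired lateral points and curves.

    The default specification is the 17-region cranial layout (12 CNC and
    5 PM regions).  Region base geometry is laid out deterministically
    from the seed on the left half (x >= 0) of a unit-scale dome, with
    midline points exactly on the x = 0 plane.
    """
    spec = region_spec if region_spec is not None else DEFAULT_REGION_SPEC
    rng = np.random.default_rng(seed)
    fixed, midline, pairs, regions, curves, curve_regions = [], [], {}, {}, [], {}
    base: dict[str, np.ndarray] = {}
    n_r = len(spec)
    for ri, r in enumerate(spec):
        name = r["name"]
        if r.get("n_fixed_lateral", 0) + r.get("n_fixed_midline", 0) == 0:
            raise ValueError(f"region {name!r} has zero points")
        # region center along an anterior-posterior arc
        theta = np.pi * (ri + 0.5) / n_r
        center = np.array([0.45, np.cos(theta), 0.6 * np.sin(theta)])
        pts = []
        for j in range(r.get("n_fixed_midline", 0)):
            pid = f"{name}_m{j}"
            base[pid] = np.array([0.0, center[1] + 0.12 * rng.normal(),
                                  center[2] + 0.12 * rng.normal()])
            fixed.append(pid)
            midline.append(pid)
            pts.append(pid)
        lat = []
        for j in range(r.get("n_fixed_lateral", 0)):
            pid = f"{name}_l{j}"
            base[pid] = center + 0.12 * rng.normal(size=3)
            base[pid][0] = abs(base[pid][0]) + 0.1
            fixed.append(pid)
            pairs[pid] = f"{name}_l{j}_R"
            lat.append(pid)
            pts.append(pid)
        m = int(r.get("curve_semilandmarks", 0))
        if m >= 3 and len(lat) >= 2:
            cid = f"{name}_c"
            curves.append({"id": cid, "points": [lat[0], lat[1]],
                           "n_semilandmarks": m})
            curve_regions[cid] = name
            a, b = base[lat[0]], base[lat[1]]
            bulge = 0.08 * rng.normal(size=3)
            for k in range(1, m - 1):
                t = k / (m - 1)
                p = (1 - t) * a + t * b + np.sin(np.pi * t) * bulge
                p[0] = abs(p[0]) + 0.05
                base[f"{cid}:{k}"] = p
        regions[name] = {"origin": r["origin"], "points": pts}
    # absent-element anchors: the nearest fixed landmark outside the region
    tmpl_dict = {"fixed": fixed, "curves": curves, "curve_regions": curve_regions,
                 "midline": midline, "pairs": pairs, "regions": regions}
    for ri, r in enumerate(spec):
        name = r["name"]
        own = set(regions[name]["points"])
        others = [p for p in fixed if p not in own]
        cen = np.mean([base[p] for p in regions[name]["points"]], axis=0)
        anchor = min(others, key=lambda p: float(np.linalg.norm(base[p] - cen)))
        regions[name]["absent_anchor"] = anchor
    tmpl = Template.from_dict(tmpl_dict)
    tmpl.base_geometry = {p: base[p].tolist() for p in tmpl.left_point_ids()}
    return tmpl


def template_base_matrix(template: Template) -> np.ndarray:
    """(L, 3) base coordinates of the left+midline points."""
    if not hasattr(template, "base_geometry"):
        raise ValueError("template has no base geometry (not synthetic)")
    return np.array([template.base_geometry[p]
                     for p in template.left_point_ids()])


# --------------------------------------------------------------------------
# shapes
# --------------------------------------------------------------------------

def simulate_shapes(tree: PhyloTree, template: Template,
                    region_rates: dict[str, float] | None = None,
                    shift_clades: list[dict] | None = None,
                    transform: TreeTransform | None = None,
                    allometry_slope: float | dict[str, float] = 0.02,
                    log_cs_rate: float = 0.05, log_cs_root: float = 0.0,
                    nugget: float = 0.0, seed: int = 0,
                    rigid_motion: bool = True, bilateral: bool = True,
                    ) -> tuple[SpecimenSet, SyntheticTruth]:
    """Simulate landmark configurations evolving on the tree.

    Per region, coordinate deviations from the template base follow BM
    (iid across coordinates) with rate sigma^2_r on the (optionally
    transformed, optionally clade-rescaled) tree; log centroid size
    follows BM and adds an allometric component along a fixed seeded unit
    direction per region; optional iid nugget noise.  Left-side points
    are mirrored across x=0 into symmetric full configurations
    (``bilateral=True``) and each specimen receives a random rigid motion
    and its centroid-size scale, emulating raw scan coordinates.
    """
    rng = np.random.default_rng(seed)
    rates = dict(region_rates if region_rates is not None
                 else default_region_rates())
    for r, v in rates.items():
        if v < 0:
            raise ValueError(f"negative rate for region {r!r}")
    shift_clades = list(shift_clades or [])
    transform = transform or TreeTransform()
    left_ids = template.left_point_ids()
    base = template_base_matrix(template)
    N = tree.n_tips
    species = tree.tip_labels

    # optionally rescale clade branches before building the covariance
    work = PhyloTree(tree.parent, tree.branch_lengths.copy(),
                     tree.tip_labels, tree.postorder)
    for sh in shift_clades:
        node = tree.mrca(sh["tips"]) if "tips" in sh else int(sh["node"])
        mag = float(sh["magnitude"])
        stack = [node]
        while stack:
            i = stack.pop()
            if tree.parent[i] >= 0:
                work.branch_lengths[i] *= mag
            stack.extend(np.where(tree.parent == i)[0].tolist())
    C = transform_covariance(work, transform).C
    L = np.linalg.cholesky(C + 1e-12 * np.trace(C) / N * np.eye(N))

    log_cs = log_cs_root + np.sqrt(log_cs_rate) * (L @ rng.standard_normal(N))
    centered_lcs = log_cs - log_cs.mean()

    slopes = ({r: float(allometry_slope) for r, _ in _iter_regions(template)}
              if np.isscalar(allometry_slope) else dict(allometry_slope))
    directions: dict[str, np.ndarray] = {}
    dev = np.zeros((N, len(left_ids) * 3))
    for region, cols in _iter_regions(template):
        d = 3 * len(cols)
        flat = np.repeat(np.array(cols) * 3, 3) + np.tile([0, 1, 2], len(cols))
        sigma2 = rates.get(region, 0.0)
        if sigma2 > 0:
            dev[:, flat] += np.sqrt(sigma2) * (L @ rng.standard_normal((N, d)))
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        directions[region] = u
        beta = slopes.get(region, 0.0)
        if beta:
            dev[:, flat] += beta * np.outer(centered_lcs, u)
    if nugget > 0:
        dev += np.sqrt(nugget) * rng.standard_normal(dev.shape)

    shapes = base[None, :, :] + dev.reshape(N, len(left_ids), 3)
    mid_mask = np.array([p in template.midline_ids for p in left_ids])
    # keep midline points exactly on the symmetry plane
    shapes[:, mid_mask, 0] = 0.0

    cs0 = centroid_size(base)
    configs = []
    point_ids = list(left_ids)
    if bilateral:
        point_ids = template.full_point_ids()
    for i, sp in enumerate(species):
        pts = shapes[i]
        if bilateral:
            refl = pts[~mid_mask].copy()
            refl[:, 0] *= -1.0
            pts = np.vstack([pts, refl])
        scale = np.exp(log_cs[i]) / cs0
        pts = pts * scale
        if rigid_motion:
            A = rng.standard_normal((3, 3))
            Qr, _ = np.linalg.qr(A)
            if np.linalg.det(Qr) < 0:
                Qr[:, 0] *= -1
            pts = pts @ Qr + rng.normal(0, 5.0, 3)
        status = np.zeros(len(pts), dtype=np.int8)
        configs.append(LandmarkConfiguration(sp, sp, pts, status))
    sset = SpecimenSet(configs, point_ids,
                       {sp: True for sp in species})
    truth = SyntheticTruth(
        tree_newick=tree.to_newick(), region_rates=rates,
        shift_clades=[{k: (list(v) if isinstance(v, (list, tuple)) else v)
                       for k, v in sh.items()} for sh in shift_clades],
        transform_kind=transform.kind,
        transform_parameter=transform.parameter,
        allometry_slope=slopes,
        allometry_direction={r: d.tolist() for r, d in directions.items()},
        log_cs_rate=log_cs_rate, log_cs_root=log_cs_root, nugget=nugget,
        seed=seed, extra={"log_cs": log_cs.tolist()})
    return sset, truth


def _iter_regions(template: Template):
    left = template.left_point_ids()
    for region in template.regions():
        cols = [i for i, p in enumerate(left)
                if template.region_of.get(p) == region]
        yield region, cols


# --------------------------------------------------------------------------
# missingness and traits
# --------------------------------------------------------------------------

DEFAULT_MISSING_FRACTIONS = {
    # observed element-wise missingness proportions out of 322 specimens
    "pterygoid": 102 / 322,
    "jugal": 49 / 322,
    "basisphenoid": 33 / 322,
    "squamosal_z": 22 / 322,
}
DEFAULT_ABSENT_FRACTIONS = {"jugal": 8 / 322}


def inject_missing(sset: SpecimenSet, template: Template,
                   element_fractions: dict[str, float] | None = None,
                   absent_fractions: dict[str, float] | None = None,
                   seed: int = 0,
                   ) -> tuple[SpecimenSet, dict[str, list[str]]]:
    """Flag whole elements missing (and a subset biologically absent).

    Per element, specimens are sampled independently with the element's
    missingness fraction; of those, a sub-fraction is flagged
    biologically absent (to be collapsed rather than estimated).  Returns
    the modified set and a map region -> specimen ids flagged absent.
    """
    fr = dict(DEFAULT_MISSING_FRACTIONS if element_fractions is None
              else element_fractions)
    ab = dict(DEFAULT_ABSENT_FRACTIONS if absent_fractions is None
              else absent_fractions)
    for d in (fr, ab):
        for r, f in d.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction for {r!r} out of [0, 1]")
    rng = np.random.default_rng(seed)
    out = sset.copy()
    absent: dict[str, list[str]] = {r: [] for r in ab}
    for region, frac in fr.items():
        cols = template.region_points(region, out.point_ids)
        if not cols:
            continue
        hit = rng.random(len(out)) < frac
        frac_abs = ab.get(region, 0.0)
        for i, c in enumerate(out.configurations):
            if hit[i]:
                c.points[cols] = np.nan
                c.status[cols] = MISSING
                if frac_abs and rng.random() < frac_abs / max(frac, 1e-12):
                    absent[region].append(c.specimen_id)
    return out, absent


def simulate_ecology(tree: PhyloTree,
                     Q_diet: np.ndarray | None = None,
                     Q_locomotion: np.ndarray | None = None,
                     diet_states: tuple[str, ...] = ("herbivore", "carnivore",
                                                     "omnivore", "insectivore"),
                     locomotion_states: tuple[str, ...] = ("terrestrial",
                                                           "arboreal",
                                                           "aquatic",
                                                           "fossorial"),
                     seed: int = 0) -> TraitTable:
    """Two independent Mk characters (diet, locomotion) on the tree."""
    import pandas as pd
    if Q_diet is None:
        Q_diet = default_q(diet_states)
    if Q_locomotion is None:
        Q_locomotion = default_q(locomotion_states)
    diet = simulate_mk(tree, Q_diet, seed=seed, states=diet_states)
    loco = simulate_mk(tree, Q_locomotion, seed=seed + 1,
                       states=locomotion_states)
    df = pd.DataFrame({"species": tree.tip_labels,
                       "diet": [diet[s] for s in tree.tip_labels],
                       "locomotion": [loco[s] for s in tree.tip_labels]})
    return TraitTable(df.set_index("species")[["diet", "locomotion"]])
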