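"""Landmark data model, file I/O and preprocessing.

Holds the template (landmark scheme: fixed points, semilandmark curves,
midline, bilateral pairing, region membership, embryonic origin labels),
raw specimen configurations, and the preprocessing chain applied before
superimposition: curve resampling to a common semilandmark count,
bilateral mirroring across the sagittal plane, estimation of missing
landmarks from the most similar complete specimens, and collapsing of
biologically absent elements to a single anchor position.

Supported formats: TPS (``LM3=`` blocks) and long-form CSV
(``specimen,point_id,x,y,z``) for landmarks, CSV for species traits.
Coordinates equal to the missing sentinel (9999 by default) or empty CSV
fields are flagged ``MISSING``.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import RBFInterpolator

log = logging.getLogger(__name__)

__all__ = [
    "OBSERVED", "MISSING", "ESTIMATED", "ABSENT_COLLAPSED",
    "Curve", "Template", "LandmarkConfiguration", "SpecimenSet", "TraitTable",
    "read_landmarks", "write_landmarks", "read_traits",
    "resample_curve", "mirror_bilateral", "estimate_missing", "collapse_absent",
    "centroid_size",
]

# per-point status codes
OBSERVED = 0
MISSING = 1
ESTIMATED = 2
ABSENT_COLLAPSED = 3

MISSING_SENTINEL = 9999.0

DIET_VOCABULARY = (
    "herbivore", "carnivore", "omnivore", "insectivore",
    "piscivore", "bulk_invertivore", "frugivore",
)
LOCOMOTION_VOCABULARY = (
    "terrestrial", "arboreal", "aquatic", "semi_aquatic",
    "fossorial", "semi_fossorial", "volant",
)


@dataclass(frozen=True)
class Curve:
    """An ordered semilandmark curve anchored on two fixed landmarks."""
    curve_id: str
    point_ids: tuple[str, ...]   # ordered, endpoints are the anchors
    n_semilandmarks: int         # target count after resampling (incl. anchors)

    @property
    def anchors(self) -> tuple[str, str]:
        return self.point_ids[0], self.point_ids[-1]


@dataclass
class Template:
    """Landmark scheme: what every point is and where it belongs.

    ``pair_map`` is an involution mapping left and right point ids onto
    each other; midline ids map to themselves.  ``region_of`` assigns
    every point id (left, midline and right) to exactly one region;
    ``origin_of`` labels each region CNC (cranial neural crest) or PM
    (paraxial mesoderm).
    """

    fixed_ids: tuple[str, ...]
    curves: tuple[Curve, ...]
    midline_ids: frozenset[str]
    pair_map: dict[str, str]
    region_of: dict[str, str]
    origin_of: dict[str, str]
    absent_anchor: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # ---------------------------------------------------------------- checks
    def validate(self) -> None:
        for a, b in self.pair_map.items():
            if self.pair_map.get(b) != a:
                raise ValueError(f"pair_map is not an involution at {a!r}")
        for m in self.midline_ids:
            if self.pair_map.get(m, m) != m:
                raise ValueError(f"midline id {m!r} is not a fixed point of pair_map")
        for c in self.curves:
            for a in c.anchors:
                if a not in self.fixed_ids:
                    raise ValueError(f"curve {c.curve_id!r} endpoint {a!r} is not a fixed landmark")
            if c.n_semilandmarks < 2:
                raise ValueError(f"curve {c.curve_id!r} needs >= 2 semilandmarks")
        for pid in self.left_point_ids():
            if pid not in self.region_of:
                raise ValueError(f"point {pid!r} has no region")
        for r in set(self.region_of.values()):
            if r not in self.origin_of:
                raise ValueError(f"region {r!r} has no origin label")

    # ------------------------------------------------------------- id layout
    def left_point_ids(self) -> list[str]:
        """Digitized point ids (left side + midline) in canonical order:
        fixed landmarks first, then each curve's resampled semilandmarks."""
        ids = list(self.fixed_ids)
        for c in self.curves:
            for k in range(1, c.n_semilandmarks - 1):
                ids.append(f"{c.curve_id}:{k}")
        return ids

    def full_point_ids(self) -> list[str]:
        """Point ids after bilateral mirroring (left + midline + right)."""
        ids = self.left_point_ids()
        return ids + [self.mirror_id(p) for p in ids if p not in self.midline_ids]

    def mirror_id(self, pid: str) -> str:
        if pid in self.midline_ids:
            return pid
        return self.pair_map.get(pid, pid + "__R")

    def regions(self) -> list[str]:
        """Region names, CNC regions first, in declaration order."""
        seen: list[str] = []
        for r in self.region_of.values():
            if r not in seen:
                seen.append(r)
        return sorted(seen, key=lambda r: (self.origin_of[r] != "CNC", seen.index(r)))

    def region_points(self, region: str, ids: list[str]) -> list[int]:
        return [i for i, p in enumerate(ids) if self.region_of.get(p) == region]

    # ----------------------------------------------------------------- (de)serialization
    @classmethod
    def from_dict(cls, spec: dict) -> "Template":
        curves = tuple(
            Curve(c["id"], tuple(c["points"]), int(c["n_semilandmarks"]))
            for c in spec.get("curves", [])
        )
        pairs = dict(spec.get("pairs", {}))
        pair_map = {}
        for a, b in pairs.items():
            pair_map[a] = b
            pair_map[b] = a
        midline = frozenset(spec.get("midline", []))
        for m in midline:
            pair_map[m] = m
        region_of, origin_of, anchors = {}, {}, {}
        for rname, r in spec["regions"].items():
            origin_of[rname] = r["origin"]
            if "absent_anchor" in r:
                anchors[rname] = r["absent_anchor"]
            for pid in r["points"]:
                if pid in region_of:
                    raise ValueError(f"point {pid!r} assigned to two regions")
                region_of[pid] = rname
        # semilandmarks inherit their curve's declared region; right-side
        # points inherit their partner's region
        for c in curves:
            creg = spec.get("curve_regions", {}).get(c.curve_id)
            if creg is None:
                creg = region_of[c.point_ids[0]]
            for k in range(1, c.n_semilandmarks - 1):
                region_of.setdefault(f"{c.curve_id}:{k}", creg)
        for pid in list(region_of):
            mirrored = pair_map.get(pid, pid + "__R") if pid not in midline else pid
            region_of.setdefault(mirrored, region_of[pid])
        tmpl = cls(
            fixed_ids=tuple(spec["fixed"]), curves=curves, midline_ids=midline,
            pair_map=pair_map, region_of=region_of, origin_of=origin_of,
            absent_anchor=anchors,
        )
        if "base_geometry" in spec:  # synthetic templates carry a mean shape
            tmpl.base_geometry = {k: [float(x) for x in v]
                                  for k, v in spec["base_geometry"].items()}
        return tmpl

    @classmethod
    def from_yaml(cls, path) -> "Template":
        if hasattr(path, "read"):
            spec = yaml.safe_load(path)
        else:
            with open(path) as fh:
                spec = yaml.safe_load(fh)
        return cls.from_dict(spec)

    def to_dict(self) -> dict:
        regions: dict[str, dict] = {}
        for pid, r in self.region_of.items():
            is_semi = ":" in pid
            is_right = pid not in self.left_point_ids_set()
            if is_semi or is_right:
                continue
            entry = regions.setdefault(
                r, {"origin": self.origin_of[r], "points": []})
            entry["points"].append(pid)
        for r, anchor in self.absent_anchor.items():
            regions[r]["absent_anchor"] = anchor
        pairs = {}
        for a, b in self.pair_map.items():
            if a != b and b not in pairs and a in self.left_point_ids_set():
                pairs[a] = b
        out = {
            "fixed": list(self.fixed_ids),
            "curves": [
                {"id": c.curve_id, "points": list(c.point_ids),
                 "n_semilandmarks": c.n_semilandmarks}
                for c in self.curves
            ],
            "curve_regions": {c.curve_id: self.region_of[f"{c.curve_id}:1"]
                              for c in self.curves if c.n_semilandmarks > 2},
            "midline": sorted(self.midline_ids),
            "pairs": pairs,
            "regions": regions,
        }
        if hasattr(self, "base_geometry"):
            out["base_geometry"] = self.base_geometry
        return out

    def left_point_ids_set(self) -> set[str]:
        return set(self.left_point_ids())

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class LandmarkConfiguration:
    """One specimen's 3-D points with per-point status."""
    specimen_id: str
    species: str
    points: np.ndarray   # (P, 3)
    status: np.ndarray   # (P,) int8

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (P, 3)")
        if len(self.status) != len(self.points):
            raise ValueError("status length must equal point count")
        obs = self.status == OBSERVED
        if not np.all(np.isfinite(self.points[obs])):
            raise ValueError("observed coordinates must be finite")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(self.specimen_id, self.species,
                                     self.points.copy(), self.status.copy())


@dataclass
class SpecimenSet:
    """A collection of configurations sharing one point layout."""
    configurations: list[LandmarkConfiguration]
    point_ids: list[str]
    extant: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        P = len(self.point_ids)
        for c in self.configurations:
            if c.n_points != P:
                raise ValueError(
                    f"specimen {c.specimen_id!r} has {c.n_points} points, expected {P}")
        species = [c.species for c in self.configurations]
        if len(set(species)) != len(species):
            dup = [s for s, n in Counter(species).items() if n > 1]
            raise ValueError(f"duplicate species labels: {dup}")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def species(self) -> list[str]:
        return [c.species for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        return np.stack([c.points for c in self.configurations])

    def status_array(self) -> np.ndarray:
        return np.stack([c.status for c in self.configurations])

    def centroid_sizes(self) -> np.ndarray:
        return np.array([centroid_size(c.points) for c in self.configurations])

    def copy(self) -> "SpecimenSet":
        return SpecimenSet([c.copy() for c in self.configurations],
                           list(self.point_ids), dict(self.extant))


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances from the centroid."""
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))


@dataclass
class TraitTable:
    """Species-level diet and locomotion categories."""
    table: pd.DataFrame  # index species, columns diet, locomotion

    def diet(self, species: list[str]) -> np.ndarray:
        return self.table.loc[species, "diet"].to_numpy()

    def locomotion(self, species: list[str]) -> np.ndarray:
        return self.table.loc[species, "locomotion"].to_numpy()


# --------------------------------------------------------------------------
# readers / writers
# --------------------------------------------------------------------------

def read_landmarks(path, template: Template | None = None,
                   point_ids: list[str] | None = None,
                   sentinel: float = MISSING_SENTINEL) -> SpecimenSet:
    """Read landmark configurations from TPS or long-form CSV.

    The expected point layout is the template's digitized (left+midline)
    ids or, if the file holds a mirrored bilateral set, the template's
    full left+midline+right ids; ``point_ids`` overrides both.  Rows
    equal to the sentinel in all coordinates (or empty CSV fields) are
    flagged MISSING.
    """
    if point_ids is not None:
        layouts = [list(point_ids)]
    elif template is None:
        raise ValueError("either template or point_ids is required")
    else:
        layouts = [template.left_point_ids(), template.full_point_ids()]
    text_path = str(path)
    if text_path.lower().endswith(".tps"):
        sset = _read_tps(path, layouts, sentinel)
    else:
        sset = _read_csv(path, layouts, sentinel)
    _log_missingness(sset, template)
    return sset


def _log_missingness(sset: SpecimenSet, template: Template | None) -> None:
    if template is None:
        return
    status = sset.status_array()
    for region in template.regions():
        cols = template.region_points(region, sset.point_ids)
        if cols:
            n_missing = int((status[:, cols] == MISSING).any(axis=1).sum())
            log.info("region %s: %d/%d specimens with missing points",
                     region, n_missing, len(sset))


def _read_tps(path, layouts, sentinel) -> SpecimenSet:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    configs, i, ids_seen = [], 0, set()
    point_ids = layouts[0]
    while i < len(lines):
        if not lines[i].upper().startswith("LM3="):
            raise ValueError(f"expected LM3= record at line {i + 1}")
        n = int(lines[i].split("=", 1)[1])
        if not configs:
            matches = [ids for ids in layouts if len(ids) == n]
            if matches:
                point_ids = matches[0]
        coords = np.array([[float(x) for x in lines[i + 1 + j].split()]
                           for j in range(n)])
        if coords.shape != (n, 3):
            raise ValueError("wrong dimensionality in TPS record")
        i += 1 + n
        spec_id = f"specimen{len(configs)}"
        while i < len(lines) and "=" in lines[i] and not lines[i].upper().startswith("LM3="):
            key, val = lines[i].split("=", 1)
            if key.upper() == "ID":
                spec_id = val.strip()
            i += 1
        if n != len(point_ids):
            raise ValueError(
                f"record {spec_id!r} has {n} points, template defines {len(point_ids)}")
        if spec_id in ids_seen:
            raise ValueError(f"duplicate specimen id {spec_id!r}")
        ids_seen.add(spec_id)
        status = np.where(np.all(coords == sentinel, axis=1), MISSING, OBSERVED)
        coords = coords.copy()
        coords[status == MISSING] = np.nan
        configs.append(LandmarkConfiguration(spec_id, spec_id, coords, status))
    log.info("read %d TPS records from %s", len(configs), path)
    return SpecimenSet(configs, list(point_ids))


def _read_csv(path, layouts, sentinel) -> SpecimenSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen", "point_id", "x", "y", "z"}
    if not required <= set(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    seen = set(df["point_id"])
    matches = [ids for ids in layouts if seen <= set(ids)]
    if not matches:
        unknown = seen - set(layouts[-1])
        raise ValueError(f"unknown point ids: {sorted(unknown)[:5]}")
    point_ids = matches[0]
    order = {p: i for i, p in enumerate(point_ids)}
    configs, ids_seen = [], set()
    for spec_id, grp in df.groupby("specimen", sort=False):
        if spec_id in ids_seen:
            raise ValueError(f"duplicate specimen id {spec_id!r}")
        ids_seen.add(spec_id)
        coords = np.full((len(point_ids), 3), np.nan)
        status = np.full(len(point_ids), MISSING, dtype=np.int8)
        for _, row in grp.iterrows():
            i = order[row["point_id"]]
            xyz = np.array([row["x"], row["y"], row["z"]], dtype=float)
            if np.all(xyz == sentinel) or np.any(pd.isna(xyz)):
                continue
            coords[i], status[i] = xyz, OBSERVED
        species = str(grp["species"].iloc[0]) if "species" in grp else str(spec_id)
        configs.append(LandmarkConfiguration(str(spec_id), species, coords, status))
    log.info("read %d specimens (%d rows) from %s", len(configs), len(df), path)
    return SpecimenSet(configs, list(point_ids))


def write_landmarks(sset: SpecimenSet, path,
                    sentinel: float = MISSING_SENTINEL) -> None:
    """Write a SpecimenSet to long-form CSV (full printed precision)."""
    rows = []
    for c in sset.configurations:
        for i, pid in enumerate(sset.point_ids):
            if c.status[i] == MISSING:
                x = y = z = sentinel
            else:
                x, y, z = c.points[i]
            rows.append((c.specimen_id, c.species, pid,
                         repr(float(x)), repr(float(y)), repr(float(z))))
    pd.DataFrame(rows, columns=["specimen", "species", "point_id",
                                "x", "y", "z"]).to_csv(path, index=False)


def read_traits(path, diet_vocabulary=DIET_VOCABULARY,
                locomotion_vocabulary=LOCOMOTION_VOCABULARY) -> TraitTable:
    """Read a species trait CSV (species, diet, locomotion columns).

    Pass ``None`` for a vocabulary to accept any category (open vocabulary).
    """
    df = pd.read_csv(path)
    for col in ("species", "diet", "locomotion"):
        if col not in df.columns:
            raise ValueError(f"trait CSV missing column {col!r}")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicated species rows: {dup}")
    for col, vocab in (("diet", diet_vocabulary),
                       ("locomotion", locomotion_vocabulary)):
        if vocab is not None:
            bad = sorted(set(df[col]) - set(vocab))
            if bad:
                raise ValueError(f"unknown {col} categories: {bad}")
    log.info("read %d trait rows from %s", len(df), path)
    return TraitTable(df.set_index("species")[["diet", "locomotion"]])


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def resample_curve(points: np.ndarray, m: int) -> np.ndarray:
    """Resample an ordered polyline to m points equally spaced by arc length.

    The first and last input points are preserved exactly.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need >= 2 input points")
    if m < 2:
        raise ValueError("m must be >= 2")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total == 0:
        raise ValueError("zero-length polyline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, m)
    out = np.empty((m, 3))
    out[0], out[-1] = pts[0], pts[-1]
    for k in range(1, m - 1):
        j = np.searchsorted(s, targets[k], side="right") - 1
        j = min(j, len(seg) - 1)
        t = (targets[k] - s[j]) / seg[j] if seg[j] > 0 else 0.0
        out[k] = (1 - t) * pts[j] + t * pts[j + 1]
    return out


def resample_set(sset: SpecimenSet, template: Template,
                 raw_curve_points: dict[str, list[str]] | None = None) -> SpecimenSet:
    """Resample every curve of every specimen to the template's target counts.

    ``raw_curve_points`` maps curve id to the ordered raw point ids as
    digitized; by default the template's declared curve points are used
    (identity layout).  Curves containing any missing point yield missing
    semilandmarks, to be filled by :func:`estimate_missing`.
    """
    out_ids = template.left_point_ids()
    configs = []
    raw_order = {p: i for i, p in enumerate(sset.point_ids)}
    for c in sset.configurations:
        coords = np.full((len(out_ids), 3), np.nan)
        status = np.full(len(out_ids), MISSING, dtype=np.int8)
        pos = {p: i for i, p in enumerate(out_ids)}
        for pid in template.fixed_ids:
            i = raw_order.get(pid)
            if i is not None and c.status[i] == OBSERVED:
                coords[pos[pid]] = c.points[i]
                status[pos[pid]] = OBSERVED
        for curve in template.curves:
            src_ids = (raw_curve_points or {}).get(curve.curve_id, list(curve.point_ids))
            idx = [raw_order[p] for p in src_ids if p in raw_order]
            if idx and np.all(c.status[idx] == OBSERVED) and len(idx) >= 2:
                res = resample_curve(c.points[idx], curve.n_semilandmarks)
                for k in range(1, curve.n_semilandmarks - 1):
                    j = pos[f"{curve.curve_id}:{k}"]
                    coords[j], status[j] = res[k], OBSERVED
        configs.append(LandmarkConfiguration(c.specimen_id, c.species, coords, status))
    return SpecimenSet(configs, out_ids, dict(sset.extant))


def _fit_midline_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through >=3 non-collinear points.

    Returns (point on plane, unit normal)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need >= 3 midline points to fit the plane")
    center = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - center)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("midline points are collinear")
    return center, vt[2]


def reflect_points(points: np.ndarray, plane_point: np.ndarray,
                   normal: np.ndarray) -> np.ndarray:
    """Exact reflection of points through the plane (point, normal)."""
    n = normal / np.linalg.norm(normal)
    d = (points - plane_point) @ n
    return points - 2.0 * np.outer(d, n)


def mirror_bilateral(config: LandmarkConfiguration, template: Template,
                     point_ids: list[str],
                     plane: tuple[np.ndarray, np.ndarray] | None = None,
                     ) -> LandmarkConfiguration:
    """Reflect non-midline points through the sagittal plane.

    Output holds the original L points followed by reflections of the
    L - m non-midline points (count 2L - m).  The plane is fitted to the
    observed midline landmarks by total least squares unless given.
    """
    mid_idx = [i for i, p in enumerate(point_ids) if p in template.midline_ids]
    if plane is None:
        obs_mid = [i for i in mid_idx if config.status[i] != MISSING]
        plane = _fit_midline_plane(config.points[obs_mid])
    plane_point, normal = plane
    side_idx = [i for i, p in enumerate(point_ids) if p not in template.midline_ids]
    refl = np.full((len(side_idx), 3), np.nan)
    ok = config.status[side_idx] != MISSING
    pts = config.points[side_idx]
    refl[ok] = reflect_points(pts[ok], plane_point, normal)
    coords = np.vstack([config.points, refl])
    status = np.concatenate([config.status, config.status[side_idx]])
    return LandmarkConfiguration(config.specimen_id, config.species, coords, status)


def mirror_set(sset: SpecimenSet, template: Template,
               plane: tuple[np.ndarray, np.ndarray] | None = None) -> SpecimenSet:
    full_ids = list(sset.point_ids) + [
        template.mirror_id(p) for p in sset.point_ids
        if p not in template.midline_ids]
    configs = [mirror_bilateral(c, template, sset.point_ids, plane)
               for c in sset.configurations]
    return SpecimenSet(configs, full_ids, dict(sset.extant))


def _partial_procrustes_align(source: np.ndarray, target: np.ndarray,
                              ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Similarity transform (R, translation, scale) aligning source onto
    target, and the resulting Procrustes distance.  Returns the transform
    as (R, t, s, dist) such that aligned = s * source @ R + t."""
    mu_s, mu_t = source.mean(axis=0), target.mean(axis=0)
    A, B = source - mu_s, target - mu_t
    na = np.linalg.norm(A)
    if na == 0:
        raise ValueError("degenerate source configuration")
    U, sv, Vt = np.linalg.svd(A.T @ B)
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(U @ Vt))
    R = U @ D @ Vt
    s = (sv * np.diag(D)).sum() / (na ** 2)
    t = mu_t - s * mu_s @ R
    dist = float(np.linalg.norm(s * A @ R - B))
    return R, t, s, dist


def estimate_missing(sset: SpecimenSet, k: int = 3,
                     min_shared_for_warp: int = 10,
                     weight_floor: float = 1e-9) -> SpecimenSet:
    """Estimate missing landmarks from the k most similar complete specimens.

    For each incomplete specimen, the k complete configurations with the
    smallest partial Procrustes distance over the shared observed points
    are each similarity-aligned onto the target and warped by a 3-D
    thin-plate spline fitted on the shared points; the missing positions
    are the 1/distance-weighted mean of the warped predictions.  With
    fewer than ``min_shared_for_warp`` shared points the spline is skipped
    and the aligned donor coordinates are averaged directly.
    Deterministic; donor ties are broken by specimen id.
    """
    complete = [c for c in sset.configurations
                if np.all(c.status != MISSING)]
    incomplete = [c for c in sset.configurations if np.any(c.status == MISSING)]
    if incomplete and len(complete) < k:
        raise ValueError(f"need >= {k} complete donor specimens, have {len(complete)}")
    out = []
    for c in sset.configurations:
        if not np.any(c.status == MISSING):
            out.append(c.copy())
            continue
        obs = np.where(c.status != MISSING)[0]
        miss = np.where(c.status == MISSING)[0]
        scored = []
        for donor in complete:
            try:
                _, _, _, dist = _partial_procrustes_align(
                    donor.points[obs], c.points[obs])
            except ValueError:
                continue
            # normalize by target centroid size over shared points for
            # scale-free ranking
            cs = centroid_size(c.points[obs])
            scored.append((dist / max(cs, 1e-300), donor.specimen_id, donor))
        scored.sort(key=lambda t: (t[0], t[1]))
        donors = scored[:k]
        if not donors:
            raise ValueError(f"no usable donor for specimen {c.specimen_id!r}")
        weights = np.array([1.0 / max(d, weight_floor) for d, _, _ in donors])
        weights /= weights.sum()
        preds = np.zeros((len(donors), len(miss), 3))
        for j, (_, _, donor) in enumerate(donors):
            R, t, s, _ = _partial_procrustes_align(donor.points[obs], c.points[obs])
            aligned = s * donor.points @ R + t
            if len(obs) >= min_shared_for_warp:
                # exact-interpolation TPS (3-D polyharmonic, kernel r)
                warp = RBFInterpolator(aligned[obs], c.points[obs],
                                       kernel="linear", degree=1)
                preds[j] = warp(aligned[miss])
            else:
                preds[j] = aligned[miss]
        filled = np.tensordot(weights, preds, axes=(0, 0))
        new = c.copy()
        new.points[miss] = filled
        new.status[miss] = ESTIMATED
        out.append(new)
    return SpecimenSet(out, list(sset.point_ids), dict(sset.extant))


def collapse_absent(config: LandmarkConfiguration, region: str,
                    template: Template, point_ids: list[str],
                    ) -> LandmarkConfiguration:
    """Collapse a biologically absent element onto its anchor landmark.

    Every point of the region is moved to the coordinates of the region's
    configured anchor landmark and flagged ABSENT_COLLAPSED; the point
    count is unchanged.  Idempotent.
    """
    if region not in template.origin_of:
        raise KeyError(f"unknown region {region!r}")
    anchor_id = template.absent_anchor.get(region)
    if anchor_id is None:
        raise KeyError(f"region {region!r} has no absent_anchor configured")
    pos = {p: i for i, p in enumerate(point_ids)}
    ai = pos[anchor_id]
    if config.status[ai] == MISSING:
        raise ValueError(
            f"anchor {anchor_id!r} of region {region!r} is missing; estimate first")
    new = config.copy()
    for i, p in enumerate(point_ids):
        if template.region_of.get(p) == region and i != ai:
            new.points[i] = config.points[ai]
            new.status[i] = ABSENT_COLLAPSED
    return new
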