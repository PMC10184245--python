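"""End-to-end orchestration: ingest to publication-style tables.

The pipeline chains the library stages — ingest (files or synthetic
generation), preprocessing (resampling, mirroring, missing-landmark
estimation, collapsing absent elements, specimen filters), Procrustes
superimposition with semilandmark sliding, region decomposition,
per-region signal/disparity/rate/allometry statistics, group
comparisons, phylogenetic MANOVA, ecology-state rates on stochastic
maps, the variable-rates model comparison, and report writing.

Each stage's output is cached on disk keyed by a content hash of its
own configuration plus the upstream stage hashes, so re-running with
one changed parameter recomputes only the affected downstream stages.
All randomness is derived deterministically from the single top-level
seed; rerunning an identical configuration yields byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import landmark_store as ls
from . import synthetic_data as syn
from .discrete_traits import fit_mk_ard, sample_stochastic_maps
from .ecology_models import (build_design, manova_type2, mvgls_fit,
                             procrustes_pgls, state_specific_rates)
from .phylo_models import (kmult, mann_whitney_groups, rate_ratio_test,
                           sigma2_mult)
from .superimposition import (gpa, phylo_pca, procrustes_variance,
                              split_regions)
from .tree import read_tree
from . import variable_rates as vr

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "PipelineStageError",
           "ConfigError", "run_pipeline", "report_table1", "STAGES"]

STAGES = ("ingest", "preprocess", "align", "regions", "ecology",
          "varrates", "report")

_FILTERS = ("none", "drop-estimated", "drop-any-missing")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    # either a synthetic-generation block or explicit input paths
    synthetic: dict | None = field(default_factory=lambda: {"n_tips": 64})
    inputs: dict | None = None
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    specimen_filter: str = "none"
    n_perm: int = 999
    n_perm_manova: int = 1000
    n_simmaps: int = 10
    pca_variance: float = 0.95
    varrates: dict = field(default_factory=dict)
    use_cache: bool = True

    def validate(self) -> None:
        if self.specimen_filter not in _FILTERS:
            raise ConfigError(f"filter must be one of {_FILTERS}")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if self.synthetic is None and self.inputs is None:
            raise ConfigError("either a synthetic block or input paths "
                              "must be given")
        if self.inputs is not None:
            need = {"landmarks", "template", "tree", "traits"}
            missing = need - set(self.inputs)
            if missing:
                raise ConfigError(f"inputs missing keys: {sorted(missing)}")
        if not (0 < self.pca_variance <= 1):
            raise ConfigError("pca_variance must be in (0, 1]")
        for key in ("n_perm", "n_perm_manova", "n_simmaps"):
            if getattr(self, key) < 1:
                raise ConfigError(f"{key} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return _hash_obj(self.to_dict())


@dataclass
class ReportBundle:
    table1: pd.DataFrame
    group_comparisons: pd.DataFrame
    rate_comparison: object
    manova: pd.DataFrame | None
    state_rates: pd.DataFrame | None
    model_comparison: pd.DataFrame | None
    branch_rates: pd.DataFrame | None
    rate_through_time: pd.DataFrame | None
    clade_rates: pd.DataFrame | None
    run_log: dict


# --------------------------------------------------------------------------
# hashing / caching
# --------------------------------------------------------------------------

def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Cache:
    def __init__(self, outdir: Path, enabled: bool):
        self.dir = outdir / "cache"
        self.enabled = enabled
        if enabled:
            self.dir.mkdir(parents=True, exist_ok=True)

    def get_or_run(self, stage: str, key: str, fn):
        path = self.dir / f"{stage}-{key}.pkl"
        if self.enabled and path.exists():
            with open(path, "rb") as fh:
                log.info("stage %s: cache hit (%s)", stage, key)
                return pickle.load(fh)
        t0 = time.perf_counter()
        out = fn()
        if self.enabled:
            with open(path, "wb") as fh:
                pickle.dump(out, fh)
        log.info("stage %s: computed in %.2fs", stage, time.perf_counter() - t0)
        return out


def _seed(base: int, offset: int) -> int:
    return int((base * 1_000_003 + offset) % (2 ** 31))


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_ingest(cfg: PipelineConfig):
    if cfg.inputs is not None:
        template = ls.Template.from_yaml(cfg.inputs["template"])
        sset = ls.read_landmarks(cfg.inputs["landmarks"], template)
        tree = read_tree(cfg.inputs["tree"])
        traits = ls.read_traits(cfg.inputs["traits"],
                                diet_vocabulary=None,
                                locomotion_vocabulary=None)
        absent = {}
        truth = None
        if "absent" in cfg.inputs:
            with open(cfg.inputs["absent"]) as fh:
                absent = json.load(fh)
    else:
        blk = dict(cfg.synthetic)
        n_tips = int(blk.pop("n_tips", 64))
        root_age = float(blk.pop("root_age", 80.3))
        missing = bool(blk.pop("missing", True))
        template = syn.build_template(seed=_seed(cfg.seed, 1))
        tree = syn.simulate_tree(n_tips=n_tips, root_age=root_age,
                                 birth=float(blk.pop("birth", 1.0)),
                                 death=float(blk.pop("death", 0.5)),
                                 seed=_seed(cfg.seed, 2))
        sset, truth = syn.simulate_shapes(tree, template,
                                          seed=_seed(cfg.seed, 3), **blk)
        absent = {}
        if missing:
            sset, absent = syn.inject_missing(sset, template,
                                              seed=_seed(cfg.seed, 4))
        traits = syn.simulate_ecology(tree, seed=_seed(cfg.seed, 5))
    return {"sset": sset, "template": template, "tree": tree,
            "traits": traits, "absent": absent, "truth": truth}


def _stage_preprocess(cfg: PipelineConfig, ing):
    sset, template = ing["sset"], ing["template"]
    if len(sset.point_ids) == len(template.left_point_ids()):
        sset = ls.mirror_set(sset, template)
    status = sset.status_array()
    had_missing = (status == ls.MISSING).any(axis=1)
    if had_missing.any():
        sset = ls.estimate_missing(sset)
    for region, specimens in ing["absent"].items():
        wanted = set(specimens)
        for c in sset.configurations:
            if c.specimen_id in wanted:
                c2 = ls.collapse_absent(c, region, template, sset.point_ids)
                c.points, c.status = c2.points, c2.status
    if cfg.specimen_filter != "none":
        status = sset.status_array()
        if cfg.specimen_filter == "drop-estimated":
            bad = (status == ls.ESTIMATED).any(axis=1)
        else:  # drop-any-missing
            bad = ((status == ls.ESTIMATED)
                   | (status == ls.ABSENT_COLLAPSED)).any(axis=1)
        keep = [c for c, b in zip(sset.configurations, bad) if not b]
        if len(keep) < 4:
            raise ValueError("specimen filter removed nearly all specimens")
        sset = ls.SpecimenSet(keep, list(sset.point_ids), dict(sset.extant))
        log.info("filter %s kept %d specimens", cfg.specimen_filter,
                 len(keep))
    return sset


def _stage_align(cfg: PipelineConfig, sset, template, tree):
    aligned = gpa(sset, template, slide=True)
    regions = split_regions(aligned, template)
    species = aligned.species
    tree_use = (tree.restrict_to(species)
                if set(species) != set(tree.tip_labels) else tree)
    log_cs = np.log(aligned.centroid_sizes)
    return {"aligned": aligned, "regions": regions, "tree": tree_use,
            "log_cs": log_cs}


def _stage_regions(cfg: PipelineConfig, al):
    regions, tree, log_cs = al["regions"], al["tree"], al["log_cs"]
    C = tree.vcv(order=regions[0].species)
    rows = []
    for i, reg in enumerate(regions):
        sig = kmult(reg, tree, n_perm=cfg.n_perm,
                    seed=_seed(cfg.seed, 10 + i))
        anova = procrustes_pgls(reg, log_cs, tree, n_perm=cfg.n_perm,
                                seed=_seed(cfg.seed, 40 + i))
        rows.append({
            "region": reg.name, "origin": reg.origin,
            "K_mult": sig.k_mult, "K_p": sig.p_perm,
            "allometry_Z": anova.Z, "allometry_p": anova.p_perm,
            "disparity": procrustes_variance(reg),
            "rate": sigma2_mult(reg, tree),
        })
    results = pd.DataFrame(rows)
    ratio = rate_ratio_test(regions, tree, n_sim=cfg.n_perm,
                            seed=_seed(cfg.seed, 70))
    origins = results["origin"].to_numpy()
    comps = []
    for col in ("rate", "disparity"):
        g = mann_whitney_groups(results[col].to_numpy(), origins)
        comps.append({"comparison": f"CNC_vs_PM_{col}", "U": g.U,
                      "z": g.z, "p": g.p, "n1": g.n1, "n2": g.n2})
    mask = results["region"] != "pterygoid"
    g = mann_whitney_groups(results.loc[mask, "disparity"].to_numpy(),
                            origins[mask.to_numpy()])
    comps.append({"comparison": "CNC_vs_PM_disparity_excl_pterygoid",
                  "U": g.U, "z": g.z, "p": g.p, "n1": g.n1, "n2": g.n2})
    return {"results": results, "rate_comparison": ratio,
            "group_comparisons": pd.DataFrame(comps)}


def _stage_ecology(cfg: PipelineConfig, al, traits):
    regions, tree, log_cs = al["regions"], al["tree"], al["log_cs"]
    species = regions[0].species
    diet = traits.diet(species)
    loco = traits.locomotion(species)
    manova_rows, state_rows = [], []
    fits = {}
    for trait_name, values in (("diet", diet), ("locomotion", loco)):
        fit = fit_mk_ard(dict(zip(species, values)), tree,
                         seed=_seed(cfg.seed, 80))
        fits[trait_name] = fit
        maps = sample_stochastic_maps(fit, n=cfg.n_simmaps,
                                      seed=_seed(cfg.seed, 81))
        fits[trait_name + "_maps"] = maps
    for i, reg in enumerate(regions):
        space = phylo_pca(reg, tree)
        k = int(np.searchsorted(space.cumulative_variance,
                                cfg.pca_variance) + 1)
        scores = space.scores[:, :k]
        from .superimposition import RegionData
        sreg = RegionData(reg.name, reg.origin, scores,
                          [f"pc{j+1}" for j in range(k)], species)
        kwargs = {"log_cs": log_cs}
        if len(set(diet)) > 1:
            kwargs["diet"] = diet
        if len(set(loco)) > 1:
            kwargs["locomotion"] = loco
        design = build_design(species, **kwargs)
        gfit = mvgls_fit(sreg, design, tree)
        mv = manova_type2(gfit, n_perm=cfg.n_perm_manova,
                          seed=_seed(cfg.seed, 110 + i))
        for term in mv.pillai:
            manova_rows.append({"region": reg.name, "origin": reg.origin,
                                "term": term, "pillai": mv.pillai[term],
                                "p": mv.p_perm[term],
                                "lambda": gfit.lam, "gamma": gfit.gamma})
        for trait_name in ("diet", "locomotion"):
            sr = state_specific_rates(sreg, fits[trait_name + "_maps"])
            for st in sr.states:
                state_rows.append({
                    "region": reg.name, "origin": reg.origin,
                    "trait": trait_name, "state": st,
                    "sigma2": sr.sigma2[st], "sigma2_sd": sr.sigma2_sd[st],
                    "sigma2_e": sr.sigma2_e})
    return {"manova": pd.DataFrame(manova_rows),
            "state_rates": pd.DataFrame(state_rows)}


_VR_DEFAULTS = {
    "regions": None,            # None -> first region only (desk scale)
    "models": None,             # None -> full 10-model registry
    "n_stones": 8,
    "iters_per_stone": 2000,
    "n_iter": 20_000,
    "n_chains": 2,
    "max_dims": 10,
}


def _stage_varrates(cfg: PipelineConfig, al):
    opts = {**_VR_DEFAULTS, **cfg.varrates}
    regions, tree = al["regions"], al["tree"]
    wanted = opts["regions"] or [regions[0].name]
    registry = vr.model_registry()
    if opts["models"] is not None:
        registry = [m for m in registry if m["model_id"] in opts["models"]]
    species = regions[0].species
    clade_map = _default_clades(tree)
    comp_rows, br_rows, rtt_rows, clade_rows = [], [], [], []
    for reg in regions:
        if reg.name not in wanted:
            continue
        space = phylo_pca(reg, tree)
        k = min(int(np.searchsorted(space.cumulative_variance,
                                    cfg.pca_variance) + 1),
                int(opts["max_dims"]))
        scores = space.scores[:, :k]
        logmls = {}
        for j, model in enumerate(registry):
            ss = vr.stepping_stone_logml(
                scores, tree, transform_kind=model["transform_kind"],
                variable=model["variable"], n_stones=int(opts["n_stones"]),
                iters_per_stone=int(opts["iters_per_stone"]),
                seed=_seed(cfg.seed, 200 + j), species=species)
            logmls[model["model_id"]] = ss
        comp = vr.compare_models(logmls)
        best = next(m for m in registry if m["model_id"] == comp.best)
        for mid in comp.model_ids:
            comp_rows.append({"region": reg.name, "model": mid,
                              "logml": comp.logml[mid],
                              "mc_error": comp.mc_error[mid],
                              "best": mid == comp.best,
                              "log_bf_vs_best":
                                  2 * (comp.logml[mid]
                                       - comp.logml[comp.best])})
        chains = [vr.rjmcmc_variable_rates(
            scores, tree, transform_kind=best["transform_kind"],
            variable=best["variable"], n_iter=int(opts["n_iter"]),
            seed=_seed(cfg.seed, 300 + c), species=species)
            for c in range(int(opts["n_chains"]))]
        conv = vr.gelman_rubin(chains) if len(chains) > 1 else None
        br = vr.branch_rates(chains[0], tree)
        for i in range(tree.n_nodes):
            if i == tree.root:
                continue
            br_rows.append({"region": reg.name, "node": i,
                            "is_tip": i < tree.n_tips,
                            "label": (tree.tip_labels[i]
                                      if i < tree.n_tips else ""),
                            "relative_rate": br.relative[i],
                            "absolute_rate": br.absolute[i]})
        rtt = vr.bin_rates_through_time(br, tree)
        for b in range(len(rtt.mean_rate)):
            rtt_rows.append({"region": reg.name,
                             "bin_start_Ma": rtt.bin_edges[b],
                             "mean_rate": rtt.mean_rate[b],
                             "n_lineages": int(rtt.n_lineages[b]),
                             "empty": bool(rtt.empty[b])})
        tcl = vr.terminal_rates_by_clade(br, clade_map)
        tcl.insert(0, "region", reg.name)
        clade_rows.append(tcl)
        if conv is not None:
            log.info("region %s PSRF: %s", reg.name,
                     {k_: round(v, 3) for k_, v in conv.psrf.items()})
    return {"model_comparison": pd.DataFrame(comp_rows),
            "branch_rates": pd.DataFrame(br_rows),
            "rate_through_time": pd.DataFrame(rtt_rows),
            "clade_rates": (pd.concat(clade_rows, ignore_index=True)
                            if clade_rows else pd.DataFrame())}


def _default_clades(tree) -> dict[str, str]:
    """Label tips by the subtree below each grandchild of the root."""
    kids = [i for i in range(tree.n_nodes) if tree.parent[i] == tree.root]
    groups = []
    for kid in kids:
        sub = [i for i in range(tree.n_nodes) if tree.parent[i] == kid]
        groups.extend(sub if sub else [kid])
    out = {}
    for g, node in enumerate(sorted(groups)):
        for lab in tree.clade_tips(node):
            out[lab] = f"clade_{g + 1}"
    return out


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------

def report_table1(results: pd.DataFrame) -> pd.DataFrame:
    """Per-region summary table, CNC rows first, asterisk at p < 0.01."""
    need = {"region", "origin", "K_mult", "K_p", "allometry_Z",
            "allometry_p", "disparity", "rate"}
    missing = need - set(results.columns)
    if missing:
        raise ValueError(f"missing result columns: {sorted(missing)}")
    df = results.copy()
    order = {"CNC": 0, "PM": 1}
    df = df.sort_values(["origin", "region"],
                        key=lambda s: (s.map(order) if s.name == "origin"
                                       else s)).reset_index(drop=True)
    df["K_sig"] = np.where(df["K_p"] < 0.01, "*", "")
    df["allometry_sig"] = np.where(df["allometry_p"] < 0.01, "*", "")
    return df[["region", "origin", "K_mult", "K_p", "K_sig", "allometry_Z",
               "allometry_p", "allometry_sig", "disparity", "rate"]]


def _write_tables(outdir: Path, bundle: ReportBundle) -> None:
    tables = outdir / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    bundle.table1.to_csv(tables / "table1.csv", index=False)
    bundle.group_comparisons.to_csv(tables / "group_comparisons.csv",
                                    index=False)
    rc = bundle.rate_comparison
    pd.DataFrame({
        "statistic": ["max_min_ratio", "p_sim"],
        "value": [rc.observed_ratio, rc.p_sim],
    }).to_csv(tables / "rate_comparison.csv", index=False)
    pair = pd.DataFrame(rc.pairwise_p, index=rc.region_names,
                        columns=rc.region_names)
    pair.to_csv(tables / "rate_pairwise_p.csv")
    for name, df in (("manova", bundle.manova),
                     ("state_rates", bundle.state_rates),
                     ("model_comparison", bundle.model_comparison),
                     ("branch_rates", bundle.branch_rates),
                     ("rate_through_time", bundle.rate_through_time),
                     ("clade_terminal_rates", bundle.clade_rates)):
        if df is not None and len(df):
            df.to_csv(tables / f"{name}.csv", index=False)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(bundle.run_log, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# driver
# --------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cache = _Cache(outdir, cfg.use_cache)
    run_log: dict = {"config": cfg.to_dict(),
                     "config_hash": cfg.config_hash(),
                     "stage_seconds": {}, "seed": cfg.seed}
    state: dict = {}
    hashes: dict[str, str] = {}

    def run_stage(name, deps, fn, params):
        key = _hash_obj({"params": params,
                         "up": [hashes[d] for d in deps]})
        hashes[name] = key
        t0 = time.perf_counter()
        try:
            out = cache.get_or_run(name, key, fn)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        run_log["stage_seconds"][name] = round(time.perf_counter() - t0, 3)
        return out

    base_params = {"seed": cfg.seed, "synthetic": cfg.synthetic,
                   "inputs": cfg.inputs}
    state["ingest"] = run_stage("ingest", [], lambda: _stage_ingest(cfg),
                                base_params)
    ing = state["ingest"]
    want = set(cfg.stages)

    sset = run_stage("preprocess", ["ingest"],
                     lambda: _stage_preprocess(cfg, ing),
                     {"filter": cfg.specimen_filter})
    al = run_stage("align", ["preprocess"],
                   lambda: _stage_align(cfg, sset, ing["template"],
                                        ing["tree"]), {})
    run_log["n_specimens"] = len(al["aligned"].species)
    reg = run_stage("regions", ["align"], lambda: _stage_regions(cfg, al),
                    {"n_perm": cfg.n_perm})
    eco = (run_stage("ecology", ["align"],
                     lambda: _stage_ecology(cfg, al, ing["traits"]),
                     {"n_perm_manova": cfg.n_perm_manova,
                      "n_simmaps": cfg.n_simmaps,
                      "pca_variance": cfg.pca_variance})
           if "ecology" in want else None)
    vrr = (run_stage("varrates", ["align"],
                     lambda: _stage_varrates(cfg, al),
                     {"varrates": cfg.varrates,
                      "pca_variance": cfg.pca_variance})
           if "varrates" in want else None)

    bundle = ReportBundle(
        table1=report_table1(reg["results"]),
        group_comparisons=reg["group_comparisons"],
        rate_comparison=reg["rate_comparison"],
        manova=eco["manova"] if eco else None,
        state_rates=eco["state_rates"] if eco else None,
        model_comparison=vrr["model_comparison"] if vrr else None,
        branch_rates=vrr["branch_rates"] if vrr else None,
        rate_through_time=vrr["rate_through_time"] if vrr else None,
        clade_rates=vrr["clade_rates"] if vrr else None,
        run_log=run_log)
    if "report" in want:
        _write_tables(outdir, bundle)
    return bundle
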