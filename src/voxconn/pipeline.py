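"""End-to-end orchestration: simulate -> preprocess -> graphs -> metrics ->
maps -> group statistics, driven by one serializable config.

A single master seed fans out deterministically (numpy SeedSequence) to the
study simulation, every per-dataset null ensemble and every permutation
test, so identical configs produce byte-identical JSON reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import maps as maps_mod
from . import stats as stats_mod
from .metrics import compute_nodal_metrics
from .netbuild import (correlation_matrix, group_common_threshold,
                       restrict_to_largest, scan_tmax, threshold_graph)
from .nulls import null_ensemble
from .preprocess import preprocess_session
from .roi import make_roi, select_subregion
from .simulate import StudyDesign, EffectSpec, simulate_study

__all__ = ["RunConfig", "run_pipeline", "analyze_study"]


@dataclass
class RunConfig:
    """All stage parameters of a synthetic end-to-end run."""

    seed: int = 0
    # study
    n_subjects: int = 14
    sessions: tuple = ("anodal", "cathodal", "sham")
    roi_n_voxels: int = 470
    roi_shape: str = "slab"
    target_n_voxels: int = 40
    coupling_delta: float = 0.15
    anodal_coupling_delta: float = 0.25
    n_shortcut_partners: int = 3
    n_timepoints: int = 175
    tr_seconds: float = 1.8
    noise_sd: float = 1.0
    subject_heterogeneity: float = 0.3
    effect_heterogeneity: float = 0.0
    baseline_effect_rho: float = 0.0
    cathodal_effect: str = "local_coupling"
    anodal_effect: str = "long_range"
    # preprocess
    n_discard: int = 2
    ar_order: int = 1
    band_hz: tuple = (0.01, 0.09)
    preprocess_order: str = "regress-prewhiten-bandpass"
    # netbuild
    scan_t0: float = 0.1
    scan_step: float = 0.002
    scan_criterion: float = 0.95
    # nulls
    n_null_replicates: int = 1000
    swap_factor: float = 10.0
    # maps
    smoothing_fwhm_mm: float = 6.0
    hub_fraction: float = 0.15
    # stats
    n_permutations: int = 5000
    adjacency: int = 26
    cluster_forming_p: float = 0.05
    cluster_alpha: float = 0.05
    gate_posthoc_on_interaction: bool = True

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("sessions", "band_hz"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _build_design(cfg: RunConfig, target) -> StudyDesign:
    effects = {}
    if "cathodal" in cfg.sessions and cfg.cathodal_effect != "none":
        effects[("cathodal", "after")] = EffectSpec(
            kind=cfg.cathodal_effect, target_voxels=tuple(target),
            coupling_delta=cfg.coupling_delta,
            n_shortcut_partners=cfg.n_shortcut_partners)
    if "anodal" in cfg.sessions and cfg.anodal_effect != "none":
        effects[("anodal", "after")] = EffectSpec(
            kind=cfg.anodal_effect, target_voxels=tuple(target),
            coupling_delta=cfg.anodal_coupling_delta,
            n_shortcut_partners=cfg.n_shortcut_partners)
    return StudyDesign(n_subjects=cfg.n_subjects, sessions=tuple(cfg.sessions),
                       effect_by_cell=effects, seed=cfg.seed,
                       subject_heterogeneity=cfg.subject_heterogeneity,
                       effect_heterogeneity=cfg.effect_heterogeneity,
                       baseline_effect_rho=cfg.baseline_effect_rho)


@dataclass
class DatasetResult:
    subject: int
    session: str
    time: str
    T_max: float
    n_nodes: int
    global_metrics: dict
    maps: dict = field(repr=False, default_factory=dict)


def analyze_study(study, cfg: RunConfig, seed_seq=None, progress=False):
    """Run preprocessing, threshold scan, metrics and maps for every dataset
    of a simulated (or loaded) study.  Returns (results, T_group)."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed).spawn(1)[0]
    null_seeds = seed_seq.spawn(len(study.records))

    cleans, syncs, tmaxes = [], [], []
    for rec in study.records:
        clean = preprocess_session(
            rec.bold, rec.nuisance, n_discard=cfg.n_discard,
            ar_order=cfg.ar_order, low_hz=cfg.band_hz[0],
            high_hz=cfg.band_hz[1], order=cfg.preprocess_order)
        M = correlation_matrix(clean)
        scan = scan_tmax(M, T0=cfg.scan_t0, step=cfg.scan_step,
                         criterion=cfg.scan_criterion)
        cleans.append(clean)
        syncs.append(M)
        tmaxes.append(scan.T_max)
    T_group = group_common_threshold(tmaxes)

    results = []
    for i, rec in enumerate(study.records):
        G = threshold_graph(syncs[i], T_group)
        Gl = restrict_to_largest(G)
        seed = int(null_seeds[i].generate_state(1)[0] % 2**31)
        null = null_ensemble(Gl, n_replicates=cfg.n_null_replicates,
                             seed=seed, swap_factor=cfg.swap_factor)
        nm = compute_nodal_metrics(Gl)
        gm = {"K": float(nm.K.mean()), "C": float(nm.C.mean()),
              "L": float(nm.L.mean()), "C_rand": null.C_rand,
              "L_rand": null.L_rand}
        gm["gamma"] = gm["C"] / gm["C_rand"] if gm["C_rand"] else float("nan")
        gm["lambda"] = gm["L"] / gm["L_rand"] if gm["L_rand"] else float("nan")
        gm["sigma"] = (gm["gamma"] / gm["lambda"]
                       if gm["lambda"] not in (0.0,) else float("nan"))
        kmap = maps_mod.normalize_degree_map(
            maps_mod.metric_map_from_nodal(nm.K.astype(float), nm.node_ids,
                                           study.roi, "K"))
        cmap = maps_mod.normalize_clustering_map(
            maps_mod.metric_map_from_nodal(nm.C, nm.node_ids, study.roi, "C"),
            null.C_rand)
        lmap = maps_mod.normalize_pathlength_map(
            maps_mod.metric_map_from_nodal(nm.L, nm.node_ids, study.roi, "L"),
            null.L_rand)
        mm = {}
        for name, m in (("K", kmap), ("C", cmap), ("L", lmap)):
            mm[name] = maps_mod.smooth_map(m, cfg.smoothing_fwhm_mm)
        results.append(DatasetResult(
            subject=rec.subject, session=rec.session, time=rec.time,
            T_max=float(tmaxes[i]), n_nodes=Gl.n_nodes,
            global_metrics=gm, maps=mm))
    return results, float(T_group)


def _map_array(results, roi, metric, subjects, sessions, times):
    arr = np.full((len(subjects), len(sessions), len(times), roi.n_voxels),
                  np.nan)
    for r in results:
        arr[subjects.index(r.subject), sessions.index(r.session),
            times.index(r.time)] = r.maps[metric].values
    return arr


def _cluster_to_dict(c):
    return {"n_voxels": int(c.size), "size_mm3": float(c.size_mm3),
            "peak_stat": round(float(c.peak_stat), 6),
            "peak_voxel": int(c.peak_voxel),
            "p_corrected": round(float(c.p_corrected), 6),
            "sign": int(c.sign),
            "voxels": [int(v) for v in c.voxels]}


def run_pipeline(config: RunConfig, out_dir=None) -> dict:
    """Execute the full synthetic pipeline and return the run report.

    The report carries per-dataset T_max and global metrics, the group
    threshold, cluster tables for the interaction and post-hoc contrasts of
    every metric map, baseline-dependence regressions for significant
    post-hoc clusters, the hub map, and the config hash.  Identical config
    (incl. seed) => identical report.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    ss_analysis, ss_stats = ss.spawn(2)

    roi = make_roi(cfg.roi_n_voxels, cfg.roi_shape, seed=cfg.seed)
    target = select_subregion(roi, cfg.target_n_voxels, seed=cfg.seed)
    design = _build_design(cfg, target)
    study = simulate_study(
        design, roi_params={"n_voxels": cfg.roi_n_voxels,
                            "shape": cfg.roi_shape, "seed": cfg.seed},
        session_params={"target_voxels": target,
                        "n_timepoints": cfg.n_timepoints,
                        "tr_seconds": cfg.tr_seconds,
                        "noise_sd": cfg.noise_sd})
    results, T_group = analyze_study(study, cfg, seed_seq=ss_analysis)

    report = {
        "config": asdict(cfg),
        "config_digest": cfg.digest(),
        "group_threshold_T": round(T_group, 6),
        "n_datasets": len(results),
        "datasets": [{
            "subject": r.subject, "session": r.session, "time": r.time,
            "T_max": round(r.T_max, 6), "n_nodes": r.n_nodes,
            "global_metrics": {k: round(v, 6)
                               for k, v in r.global_metrics.items()},
        } for r in results],
        "ground_truth": study.ground_truth(),
    }

    subjects = list(range(cfg.n_subjects))
    sessions = list(cfg.sessions)
    times = ["before", "after"]
    can_do_stats = cfg.n_subjects >= 3 and len(sessions) >= 2
    report["stats"] = {}
    if not can_do_stats:
        report["stats"]["skipped"] = "insufficient design for group statistics"
    else:
        stat_seeds = ss_stats.spawn(64)
        seed_i = 0

        def next_seed():
            nonlocal seed_i
            s = int(stat_seeds[seed_i].generate_state(1)[0] % 2**31)
            seed_i += 1
            return s

        for metric in ("K", "C", "L"):
            arr = _map_array(results, study.roi, metric, subjects, sessions,
                             times)
            entry = {}
            fmap = stats_mod.interaction_map(arr, roi=study.roi,
                                             contrast=f"{metric}: stim x time")
            fres = stats_mod.cluster_correct(
                fmap, arr, study.roi, adjacency=cfg.adjacency,
                cluster_forming_p=cfg.cluster_forming_p,
                n_permutations=cfg.n_permutations, seed=next_seed())
            entry["interaction"] = {
                "clusters": [_cluster_to_dict(c) for c in fres.clusters],
                "n_significant": len(fres.significant(cfg.cluster_alpha)),
            }
            gate_open = (not cfg.gate_posthoc_on_interaction
                         or entry["interaction"]["n_significant"] > 0)
            entry["posthoc_gate_open"] = gate_open
            entry["posthoc"] = {}
            if gate_open:
                ib, ia = times.index("before"), times.index("after")
                contrasts = {}
                for sess in sessions:
                    js = sessions.index(sess)
                    contrasts[f"after_{sess}-before_{sess}"] = (
                        arr[:, js, ia], arr[:, js, ib], sess)
                if "sham" in sessions:
                    jsham = sessions.index("sham")
                    for sess in sessions:
                        if sess == "sham":
                            continue
                        js = sessions.index(sess)
                        contrasts[f"after_{sess}-after_sham"] = (
                            arr[:, js, ia], arr[:, jsham, ia], sess)
                for cname, (A, B, sess) in contrasts.items():
                    tmap = stats_mod.posthoc_paired_map(
                        A, B, roi=study.roi, contrast=f"{metric}: {cname}")
                    tres = stats_mod.cluster_correct(
                        tmap, A - B, study.roi, adjacency=cfg.adjacency,
                        cluster_forming_p=cfg.cluster_forming_p,
                        n_permutations=cfg.n_permutations, seed=next_seed())
                    centry = {
                        "clusters": [_cluster_to_dict(c)
                                     for c in tres.clusters],
                        "n_significant": len(tres.significant(cfg.cluster_alpha)),
                    }
                    sig = tres.significant(cfg.cluster_alpha)
                    if sig and cname.startswith("after_") and "-before_" in cname:
                        js = sessions.index(sess)
                        reg = stats_mod.baseline_dependence(
                            sig[0].voxels, arr[:, js, ib], arr[:, js, ia])
                        centry["baseline_dependence"] = {
                            k: round(float(reg[k]), 6)
                            for k in ("slope", "intercept", "r2", "p")}
                    entry["posthoc"][cname] = centry
            report["stats"][metric] = entry

        before_L = [r.maps["L"] for r in results if r.time == "before"]
        hub = maps_mod.hub_map(before_L, fraction=cfg.hub_fraction)
        report["hubs"] = {
            "fraction": cfg.hub_fraction,
            "realized_fraction": round(float(hub.realized_fraction), 6),
            "n_hub_voxels": int(len(hub.hub_voxels)),
            "hub_voxels": [int(v) for v in hub.hub_voxels],
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=1))
        cfg.to_yaml(out / "config.yaml")
    return report
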