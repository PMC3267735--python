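"""Group-level inference for metric maps and global network metrics.

Implements the study-style analysis ladder:

* paired t-tests on global metrics per threshold (before vs after, per
  session);
* a voxelwise two-way repeated-measures ANOVA (stimulation x time) whose
  interaction F map is the gatekeeper for post-hoc contrasts;
* post-hoc paired t maps for stated contrasts;
* Monte-Carlo cluster correction: supra-threshold voxels (parametric
  forming threshold, p < 0.05 by default) are grouped into lattice-adjacency
  clusters and compared against the permutation null distribution of the
  maximum cluster extent -- sign-flipping of per-subject difference maps for
  paired t, within-subject session-label permutation for the interaction;
* baseline-dependence regression: per-subject cluster-mean effect
  (after - before) against the cluster-mean baseline value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sst

from .maps import MetricMap
from .roi import RoiMask

__all__ = [
    "GroupDesignTable", "StatMap", "Cluster", "ClusterResult",
    "global_metric_tests", "interaction_map", "posthoc_paired_map",
    "cluster_correct", "baseline_dependence",
]


@dataclass
class GroupDesignTable:
    """Long-format table of one record per (subject, session, time) cell.

    ``table`` needs columns subject, session, time plus whatever payload
    (map reference or metric value) the analysis uses; the design must be
    fully crossed.
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = {"subject", "session", "time"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"table must have columns {sorted(req)}")
        counts = self.table.groupby(["subject", "session", "time"]).size()
        if (counts != 1).any():
            raise ValueError("design must be fully crossed, one entry per cell")
        n_cells = (self.table["session"].nunique() * self.table["time"].nunique())
        per_subj = self.table.groupby("subject").size()
        if (per_subj != n_cells).any():
            raise ValueError("every subject needs all session x time cells")

    @property
    def subjects(self):
        return sorted(self.table["subject"].unique())

    @property
    def sessions(self):
        return list(dict.fromkeys(self.table["session"]))

    @property
    def times(self):
        return list(dict.fromkeys(self.table["time"]))


@dataclass
class StatMap:
    stat: np.ndarray              # per-voxel statistic, NaN where missing
    p: np.ndarray                 # per-voxel uncorrected p
    kind: str                     # "t" or "F"
    contrast: str
    df: tuple
    roi: RoiMask | None = None


@dataclass
class Cluster:
    voxels: np.ndarray            # ROI voxel indices
    size: int
    size_mm3: float
    peak_stat: float
    peak_voxel: int
    p_corrected: float
    sign: int = 1


@dataclass
class ClusterResult:
    clusters: list
    n_permutations: int
    cluster_forming_p: float
    null_max_sizes: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if c.p_corrected < alpha]


# --------------------------------------------------------------------------
# global metric tests


def _paired_t(before: np.ndarray, after: np.ndarray) -> tuple[float, float]:
    d = np.asarray(after, float) - np.asarray(before, float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if np.all(d == 0):
        return 0.0, 1.0
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance nonzero differences: t undefined")
        return np.nan, np.nan
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * sst.t.sf(abs(t), n - 1)
    return float(t), float(p)


def global_metric_tests(design: GroupDesignTable, metric: str,
                        threshold_col: str = "threshold") -> pd.DataFrame:
    """Two-tailed paired t (after vs before) per session and threshold.

    ``design.table`` must carry the metric values in column ``metric`` and a
    threshold column; no multiplicity correction is applied at this stage.
    """
    tab = design.table
    rows = []
    for (session, thr), sub in tab.groupby(["session", threshold_col]):
        piv = sub.pivot(index="subject", columns="time", values=metric)
        t, p = _paired_t(piv["before"].to_numpy(), piv["after"].to_numpy())
        rows.append({"session": session, threshold_col: thr, "metric": metric,
                     "t": t, "p": p, "n": len(piv)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# voxelwise repeated-measures ANOVA interaction


def _interaction_f(data: np.ndarray) -> tuple[np.ndarray, tuple]:
    """Vectorized two-way within-subject interaction F.

    ``data`` is (n_subjects, n_sessions, n_times, n_voxels).  Returns the
    per-voxel F and the (df1, df2) pair.
    """
    n, a, b, _ = data.shape
    r = (data
         - data.mean(axis=2, keepdims=True)
         - data.mean(axis=1, keepdims=True)
         + data.mean(axis=(1, 2), keepdims=True))
    rbar = r.mean(axis=0)                                   # (a, b, V)
    ss_ab = n * (rbar**2).sum(axis=(0, 1))
    ss_tot = (r**2).sum(axis=(0, 1, 2))
    ss_err = ss_tot - ss_ab
    df1 = (a - 1) * (b - 1)
    df2 = (a - 1) * (b - 1) * (n - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ss_ab / df1) / (ss_err / df2)
    f[ss_ab <= 1e-300] = 0.0          # no interaction variance at all
    return f, (df1, df2)


def interaction_map(data: np.ndarray, roi: RoiMask | None = None,
                    contrast: str = "stimulation x time") -> StatMap:
    """Per-voxel stimulation-by-time interaction F map.

    ``data``: (n_subjects, n_sessions, n_times, n_voxels); voxels with any
    missing cell are marked missing in the output.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("data must be (subjects, sessions, times, voxels)")
    valid = ~np.isnan(data).any(axis=(0, 1, 2))
    f = np.full(data.shape[-1], np.nan)
    p = np.full(data.shape[-1], np.nan)
    if valid.any():
        fv, (df1, df2) = _interaction_f(data[..., valid])
        f[valid] = fv
        p[valid] = sst.f.sf(fv, df1, df2)
    else:
        n, a, b, _ = data.shape
        df1, df2 = (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1)
    return StatMap(stat=f, p=p, kind="F", contrast=contrast, df=(df1, df2),
                   roi=roi)


def posthoc_paired_map(maps_a: np.ndarray, maps_b: np.ndarray,
                       roi: RoiMask | None = None,
                       contrast: str = "A - B") -> StatMap:
    """Voxelwise two-tailed paired t for per-subject map pairs (A - B)."""
    a = np.asarray(maps_a, float)
    b = np.asarray(maps_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("maps must be matching (subjects, voxels) arrays")
    d = a - b
    n = d.shape[0]
    valid = ~np.isnan(d).any(axis=0)
    t = np.full(d.shape[1], np.nan)
    p = np.full(d.shape[1], np.nan)
    dv = d[:, valid]
    sd = dv.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tv = dv.mean(axis=0) / (sd / np.sqrt(n))
    tv[np.all(dv == 0, axis=0)] = 0.0
    t[valid] = tv
    p[valid] = 2 * sst.t.sf(np.abs(tv), n - 1)
    return StatMap(stat=t, p=p, kind="t", contrast=contrast, df=(n - 1,), roi=roi)


# --------------------------------------------------------------------------
# cluster-based Monte-Carlo correction


_STRUCTURES = {6: ndimage.generate_binary_structure(3, 1),
               18: ndimage.generate_binary_structure(3, 2),
               26: ndimage.generate_binary_structure(3, 3)}


def _cluster_sizes(mask_1d: np.ndarray, vol_index: tuple, shape: tuple,
                   structure: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Label supra-threshold voxels on the lattice; returns per-voxel cluster
    label (0 = none) and cluster sizes (index label-1)."""
    vol = np.zeros(shape, dtype=bool)
    vol[vol_index] = mask_1d
    lab, n = ndimage.label(vol, structure=structure)
    labels_1d = lab[vol_index]
    sizes = np.bincount(lab.ravel())[1:] if n else np.array([], dtype=int)
    return labels_1d, sizes


def _max_cluster(mask_1d, vol_index, shape, structure) -> int:
    _, sizes = _cluster_sizes(mask_1d, vol_index, shape, structure)
    return int(sizes.max()) if sizes.size else 0


def _lattice_context(roi: RoiMask):
    origin = roi.voxel_coords.min(axis=0)
    shape = tuple(int(s) for s in (roi.voxel_coords.max(axis=0) - origin + 1))
    ijk = (roi.voxel_coords - origin).T
    return (ijk[0], ijk[1], ijk[2]), shape


def _observed_clusters(stat, supra_pos, supra_neg, roi, vol_index, shape,
                       structure, voxel_vol):
    clusters = []
    for supra, sign in ((supra_pos, 1), (supra_neg, -1)):
        if supra is None or not supra.any():
            continue
        labels_1d, sizes = _cluster_sizes(supra, vol_index, shape, structure)
        for lab in range(1, len(sizes) + 1):
            vox = np.flatnonzero(labels_1d == lab)
            if vox.size == 0:
                continue
            peak = vox[np.nanargmax(sign * stat[vox])]
            clusters.append(Cluster(voxels=vox, size=len(vox),
                                    size_mm3=len(vox) * voxel_vol,
                                    peak_stat=float(stat[peak]),
                                    peak_voxel=int(peak), p_corrected=np.nan,
                                    sign=sign))
    return clusters


def cluster_correct(stat_map: StatMap, data: np.ndarray, roi: RoiMask,
                    adjacency: int = 26, cluster_forming_p: float = 0.05,
                    n_permutations: int = 5000, seed: int = 0) -> ClusterResult:
    """Permutation (Monte-Carlo) correction of cluster extents.

    ``data`` supplies the exchangeable units matching ``stat_map.kind``:

    * ``"t"``: per-subject difference maps, (n_subjects, n_voxels); the null
      is built by random sign-flipping of whole subject maps;
    * ``"F"``: the full cell array (n_subjects, n_sessions, n_times,
      n_voxels); the null permutes session labels within subject, keeping
      each (before, after) pair together.

    The corrected p of an observed cluster of extent s is
    (1 + #{permutation max extent >= s}) / (1 + n_permutations).
    """
    if adjacency not in _STRUCTURES:
        raise ValueError("adjacency must be 6, 18 or 26")
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: corrected p is unstable")
    structure = _STRUCTURES[adjacency]
    vol_index, shape = _lattice_context(roi)
    voxel_vol = float(roi.voxel_size_mm**3)
    rng = np.random.default_rng(seed)
    data = np.asarray(data, dtype=float)
    stat = stat_map.stat
    valid = ~np.isnan(stat)

    if stat_map.kind == "t":
        n = data.shape[0]
        df = n - 1
        tcrit = sst.t.ppf(1 - cluster_forming_p / 2, df)
        supra_pos = valid & (stat > tcrit)
        supra_neg = valid & (stat < -tcrit)
        clusters = _observed_clusters(stat, supra_pos, supra_neg, roi,
                                      vol_index, shape, structure, voxel_vol)
        dv = np.where(np.isnan(data), 0.0, data)[:, valid]
        sumsq = (dv**2).sum(axis=0)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
        mean_p = signs @ dv / n                              # (P, Vv)
        var_p = (sumsq / n - mean_p**2) * n / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_p = mean_p / np.sqrt(var_p / n)
        null_max = np.empty(n_permutations, dtype=int)
        for k in range(n_permutations):
            # two-sided: positive and negative clusters compete separately
            mp = np.zeros(len(stat), dtype=bool)
            mn = np.zeros(len(stat), dtype=bool)
            mp[valid] = t_p[k] > tcrit
            mn[valid] = t_p[k] < -tcrit
            null_max[k] = max(_max_cluster(mp, vol_index, shape, structure),
                              _max_cluster(mn, vol_index, shape, structure))
    elif stat_map.kind == "F":
        if data.ndim != 4:
            raise ValueError("interaction correction needs 4-D cell data")
        n, a, b, _ = data.shape
        df1, df2 = stat_map.df
        fcrit = sst.f.ppf(1 - cluster_forming_p, df1, df2)
        supra_pos = valid & (stat > fcrit)
        clusters = _observed_clusters(stat, supra_pos, None, roi, vol_index,
                                      shape, structure, voxel_vol)
        dv = data[..., valid]
        null_max = np.empty(n_permutations, dtype=int)
        for k in range(n_permutations):
            perm = np.empty_like(dv)
            for s in range(n):
                perm[s] = dv[s, rng.permutation(a)]
            f_p, _ = _interaction_f(perm)
            m = np.zeros(len(stat), dtype=bool)
            m[valid] = f_p > fcrit
            null_max[k] = _max_cluster(m, vol_index, shape, structure)
    else:
        raise ValueError(f"unsupported statistic kind {stat_map.kind!r}")

    for c in clusters:
        c.p_corrected = float((1 + np.sum(null_max >= c.size))
                              / (1 + n_permutations))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return ClusterResult(clusters=clusters, n_permutations=n_permutations,
                         cluster_forming_p=cluster_forming_p,
                         null_max_sizes=null_max)


# --------------------------------------------------------------------------
# baseline dependence


def baseline_dependence(cluster_voxels: np.ndarray,
                        before_maps: np.ndarray,
                        after_maps: np.ndarray) -> dict:
    """Regress the per-subject cluster-mean effect on its baseline value.

    ``before_maps`` / ``after_maps`` are (n_subjects, n_voxels) arrays of
    one session's maps.  For each subject the effect is the mean of
    (after - before) over ``cluster_voxels`` and the baseline is the mean of
    the before map over the same voxels; OLS returns slope, R^2 and the
    two-tailed p of the slope.
    """
    before = np.asarray(before_maps, float)
    after = np.asarray(after_maps, float)
    if before.shape != after.shape or before.ndim != 2:
        raise ValueError("maps must be matching (subjects, voxels) arrays")
    if before.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    vox = np.asarray(cluster_voxels, dtype=int)
    baseline = np.nanmean(before[:, vox], axis=1)
    effect = np.nanmean(after[:, vox] - before[:, vox], axis=1)
    res = sst.linregress(baseline, effect)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2), "p": float(res.pvalue),
            "baseline": baseline, "effect": effect}
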