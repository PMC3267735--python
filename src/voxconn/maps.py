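"""Per-voxel metric maps: normalization, mask-restricted smoothing, hubs.

Nodal metrics are carried back onto the ROI lattice as maps with one value
per voxel (voxels outside the graph's largest component are missing).  The
three normalizations follow the conventions of nodal connectomics: degree
maps are scaled to the individual maximum (K_i / max K), clustering maps by
the null scalar (C_i / C_rand), and path-length maps are *inverted* by the
null (L_rand / L_i) so that larger values always mean better-integrated
voxels.  Hub extraction takes the top fraction of the subject-averaged
inverted path-length map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .roi import RoiMask

__all__ = [
    "MetricMap", "HubMap", "metric_map_from_nodal",
    "normalize_degree_map", "normalize_clustering_map",
    "normalize_pathlength_map", "smooth_map", "hub_map", "average_maps",
]


@dataclass
class MetricMap:
    """Per-voxel scalar map aligned to an ROI; NaN marks missing voxels."""

    values: np.ndarray
    roi: RoiMask
    metric: str = "raw"
    smoothing_fwhm_mm: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != self.roi.n_voxels:
            raise ValueError("values must be 1-D with one entry per ROI voxel")
        self.values = v

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class HubMap:
    hub_voxels: np.ndarray          # ROI voxel indices, sorted
    fraction: float                 # requested fraction
    realized_fraction: float        # after ceiling + tie inclusion
    source: MetricMap | None = field(default=None, repr=False)


def metric_map_from_nodal(values: np.ndarray, node_ids: np.ndarray,
                          roi: RoiMask, metric: str = "raw") -> MetricMap:
    """Scatter per-node values onto the full ROI; absent voxels become NaN."""
    full = np.full(roi.n_voxels, np.nan)
    full[np.asarray(node_ids, dtype=int)] = values
    return MetricMap(values=full, roi=roi, metric=metric)


def normalize_degree_map(kmap: MetricMap) -> MetricMap:
    """Scale the degree map to [0, 1] by its own maximum."""
    vmax = np.nanmax(kmap.values)
    if not vmax > 0:
        raise ValueError("degree map maximum must be positive")
    return MetricMap(values=kmap.values / vmax, roi=kmap.roi, metric="K_norm")


def normalize_clustering_map(cmap: MetricMap, C_rand: float) -> MetricMap:
    """C_i / C_rand."""
    if not C_rand > 0:
        raise ValueError("C_rand must be positive")
    return MetricMap(values=cmap.values / C_rand, roi=cmap.roi, metric="C_norm")


def normalize_pathlength_map(lmap: MetricMap, L_rand: float) -> MetricMap:
    """L_rand / L_i -- inverted so higher means better integrated."""
    if np.nanmin(lmap.values) <= 0:
        raise ValueError("all L_i must be positive")
    return MetricMap(values=L_rand / lmap.values, roi=lmap.roi, metric="L_norm")


def smooth_map(m: MetricMap, fwhm_mm: float = 6.0,
               truncate_sd: float = 3.5) -> MetricMap:
    """Mask-restricted Gaussian smoothing.

    Weights are the isotropic Gaussian of the given FWHM evaluated at the
    Euclidean voxel-centre offsets, renormalized over in-mask non-missing
    voxels only -- so a constant map stays constant and nothing bleeds in
    from outside the ROI.  ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return MetricMap(values=m.values.copy(), roi=m.roi, metric=m.metric,
                         smoothing_fwhm_mm=0.0)
    sigma = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    d = m.roi.pairwise_distance_mm()
    w = np.exp(-0.5 * (d / sigma) ** 2)
    w[d > truncate_sd * sigma] = 0.0
    valid = m.valid
    w[:, ~valid] = 0.0
    norm = w.sum(axis=1)
    out = np.full_like(m.values, np.nan)
    vals = np.where(valid, m.values, 0.0)
    ok = valid & (norm > 0)
    out[ok] = (w @ vals)[ok] / norm[ok]
    return MetricMap(values=out, roi=m.roi, metric=m.metric,
                     smoothing_fwhm_mm=float(fwhm_mm))


def average_maps(maps: list[MetricMap]) -> MetricMap:
    """Voxelwise mean over maps sharing one ROI; a voxel is valid only where
    it is valid in every input map (common-support rule)."""
    if not maps:
        raise ValueError("need at least one map")
    roi = maps[0].roi
    stack = np.vstack([m.values for m in maps])
    for m in maps:
        if m.roi is not roi and not np.array_equal(m.roi.voxel_coords,
                                                   roi.voxel_coords):
            raise ValueError("maps must share one RoiMask")
    out = np.where(np.all(~np.isnan(stack), axis=0), stack.mean(axis=0), np.nan)
    return MetricMap(values=out, roi=roi, metric=maps[0].metric)


def hub_map(baseline_maps: list[MetricMap], fraction: float = 0.15) -> HubMap:
    """Hubs: top ``fraction`` of voxels of the averaged inverted-path-length
    map.  The count is the ceiling of fraction x valid voxels; ties at the
    cutoff value are all included and the realized fraction recorded.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    mean_map = average_maps(baseline_maps)
    valid_idx = np.flatnonzero(mean_map.valid)
    vals = mean_map.values[valid_idx]
    n_valid = len(valid_idx)
    if n_valid == 0:
        raise ValueError("no valid voxels to select hubs from")
    n_hub = int(math.ceil(fraction * n_valid))
    order = np.argsort(vals)[::-1]
    cutoff = vals[order[n_hub - 1]]
    chosen = valid_idx[vals >= cutoff]
    return HubMap(hub_voxels=np.sort(chosen), fraction=fraction,
                  realized_fraction=len(chosen) / n_valid, source=mean_map)
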