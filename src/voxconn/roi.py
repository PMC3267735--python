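"""Voxel lattice regions of interest.

An ROI is a set of voxels on an integer 3-D lattice with a physical voxel
size.  The voxels are the nodes of every graph built downstream, so the ROI
must be connected under face (6-neighbour) adjacency: a disconnected mask
would make the percolation threshold scan meaningless.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = ["RoiMask", "make_roi", "select_subregion"]

_FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=np.int64,
)


@dataclass(frozen=True)
class RoiMask:
    """A connected set of voxels on a regular lattice.

    Parameters
    ----------
    voxel_coords
        ``(n, 3)`` integer array of 0-based lattice indices, one row per voxel.
        Row order defines the node ordering of all derived graphs and maps.
    voxel_size_mm
        Isotropic voxel edge length in millimetres (default 3, the in-plane
        and slice resolution of a typical 3 T resting-state EPI acquisition).
    """

    voxel_coords: np.ndarray
    voxel_size_mm: float = 3.0
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        coords = np.asarray(self.voxel_coords, dtype=np.int64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("voxel_coords must be an (n, 3) integer array")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "voxel_coords", coords)
        index = {tuple(c): i for i, c in enumerate(coords.tolist())}
        if len(index) != len(coords):
            raise ValueError("voxel coordinates must be unique")
        object.__setattr__(self, "_index", index)
        if len(coords) > 1 and not self._is_connected():
            raise ValueError("ROI mask is not connected under face adjacency")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_coords)

    def _is_connected(self) -> bool:
        seen = {0}
        stack = [0]
        coords = self.voxel_coords
        while stack:
            i = stack.pop()
            for off in _FACE_OFFSETS:
                j = self._index.get(tuple((coords[i] + off).tolist()))
                if j is not None and j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_voxels

    def contains(self, coord) -> bool:
        return tuple(int(c) for c in coord) in self._index

    def index_of(self, coord) -> int:
        """Node index of a lattice coordinate (KeyError if outside the mask)."""
        return self._index[tuple(int(c) for c in coord)]

    def coords_mm(self) -> np.ndarray:
        """Voxel centre positions in millimetres, ``(n, 3)`` float array."""
        return self.voxel_coords.astype(float) * self.voxel_size_mm

    def pairwise_distance_mm(self) -> np.ndarray:
        """Euclidean distance between all voxel centres, in mm."""
        xyz = self.coords_mm()
        diff = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))

    def bounding_shape(self) -> tuple[int, int, int]:
        """Shape of the tightest 0-anchored grid containing the mask."""
        return tuple(int(m) + 1 for m in self.voxel_coords.max(axis=0))

    def to_volume(self, values: np.ndarray | None = None, fill=0.0) -> np.ndarray:
        """Embed per-voxel values into a dense 3-D array (mask offsets removed)."""
        origin = self.voxel_coords.min(axis=0)
        shape = self.voxel_coords.max(axis=0) - origin + 1
        vol = np.full(tuple(int(s) for s in shape), fill, dtype=float)
        ijk = (self.voxel_coords - origin).T
        vol[ijk[0], ijk[1], ijk[2]] = 1.0 if values is None else values
        return vol


def _grow_blob(n_voxels: int, center: np.ndarray, bound: int, rng: np.random.Generator,
               allowed: set | None = None) -> np.ndarray:
    """Compact seeded region growth: repeatedly add the frontier voxel closest
    to `center`, random tie-break.  Produces ball-like connected masks."""
    start = tuple(np.round(center).astype(int).tolist())
    if allowed is not None and start not in allowed:
        start = min(allowed, key=lambda c: float(np.sum((np.array(c) - center) ** 2)))
    chosen = {start}
    heap: list = []
    counter = 0

    def push(c):
        nonlocal counter
        d = float(np.sum((np.array(c) - center) ** 2))
        heapq.heappush(heap, (d, float(rng.random()), counter, c))
        counter += 1

    for off in _FACE_OFFSETS:
        push(tuple((np.array(start) + off).tolist()))
    while len(chosen) < n_voxels:
        if not heap:
            raise ValueError(f"cannot grow blob to {n_voxels} voxels within bounds")
        _, _, _, c = heapq.heappop(heap)
        if c in chosen or any(x < -bound or x > bound for x in c):
            continue
        if allowed is not None and c not in allowed:
            continue
        chosen.add(c)
        for off in _FACE_OFFSETS:
            nb = tuple((np.array(c) + off).tolist())
            if nb not in chosen:
                push(nb)
    coords = np.array(sorted(chosen), dtype=np.int64)
    return coords - coords.min(axis=0)


def make_roi(n_voxels: int, shape: str = "slab", voxel_size_mm: float = 3.0,
             seed: int = 0) -> RoiMask:
    """Build a connected synthetic ROI of exactly ``n_voxels`` voxels.

    ``shape="slab"`` fills a 3-voxel-thick cortical-ribbon-like cuboid in
    scan-line order (deterministic; the seed only matters for ``blob``).
    ``shape="blob"`` grows a compact ball-like mask from the origin, with
    seeded tie-breaking among equidistant candidates.
    """
    if n_voxels < 8:
        raise ValueError("n_voxels must be at least 8")
    rng = np.random.default_rng(seed)
    if shape == "slab":
        nz = 3
        nx = int(np.ceil(np.sqrt(n_voxels / nz)))
        ny = int(np.ceil(n_voxels / (nz * nx)))
        if nx * ny * nz < n_voxels:
            raise ValueError("slab capacity exceeded")  # pragma: no cover
        coords = [(x, y, z)
                  for y in range(ny) for x in range(nx) for z in range(nz)]
        coords = np.array(coords[:n_voxels], dtype=np.int64)
    elif shape == "blob":
        bound = 64
        if n_voxels > (2 * bound + 1) ** 3:
            raise ValueError(f"blob capacity exceeded ({n_voxels} voxels)")
        coords = _grow_blob(n_voxels, np.array([0.5, 0.5, 0.5]), bound, rng)
    else:
        raise ValueError(f"unknown ROI shape {shape!r}")
    return RoiMask(voxel_coords=coords, voxel_size_mm=voxel_size_mm)


def select_subregion(roi: RoiMask, n_voxels: int, seed: int = 0,
                     around: np.ndarray | None = None) -> np.ndarray:
    """Pick a compact connected subregion of the ROI (node indices).

    Used to place planted connectivity effects: grows a blob of
    ``n_voxels`` mask voxels around ``around`` (default: the mask centroid).
    Returns sorted node indices into ``roi.voxel_coords``.
    """
    if not 0 < n_voxels <= roi.n_voxels:
        raise ValueError("subregion size must be in (0, n_voxels]")
    rng = np.random.default_rng(seed)
    center = np.asarray(around, dtype=float) if around is not None \
        else roi.voxel_coords.mean(axis=0)
    allowed = set(map(tuple, roi.voxel_coords.tolist()))
    # grow within the mask; origin shift of _grow_blob must be undone
    start = min(allowed, key=lambda c: float(np.sum((np.array(c) - center) ** 2)))
    chosen = {start}
    heap: list = []
    counter = 0
    while len(chosen) < n_voxels:
        frontier = set()
        for c in chosen:
            for off in _FACE_OFFSETS:
                nb = tuple((np.array(c) + off).tolist())
                if nb in allowed and nb not in chosen:
                    frontier.add(nb)
        if not frontier:
            raise ValueError("subregion growth exhausted the mask")
        for c in frontier:
            d = float(np.sum((np.array(c) - center) ** 2))
            heapq.heappush(heap, (d, float(rng.random()), counter, c))
            counter += 1
        while heap:
            _, _, _, c = heapq.heappop(heap)
            if c not in chosen:
                chosen.add(c)
                break
        heap = []
    return np.array(sorted(roi.index_of(c) for c in chosen), dtype=np.int64)
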