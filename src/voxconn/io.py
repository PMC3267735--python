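"""File formats: NIfTI volumes, HDF5 study bundles, motion-parameter text,
edge lists and MatrixMarket adjacency.

Real data enters as a 4-D BOLD NIfTI plus a binary ROI mask on the same
grid and an MCFLIRT-style 6-column ``.par`` motion file; synthetic studies
round-trip through a single HDF5 bundle with a JSON ground-truth sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .maps import MetricMap
from .netbuild import FunctionalGraph, SyncMatrix
from .roi import RoiMask
from .simulate import BoldSeries, NuisanceSet, StudyData

__all__ = [
    "write_bold_nifti", "read_bold_nifti", "write_mask_nifti",
    "read_mask_nifti", "write_map_nifti", "read_motion_par",
    "write_motion_par", "write_study_hdf5", "read_study_bold",
    "write_edge_list", "write_adjacency_mtx", "write_sync_hdf5",
    "read_sync_hdf5",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_mask_nifti(roi: RoiMask, path) -> None:
    vol = roi.to_volume().astype(np.uint8)
    nib.save(nib.Nifti1Image(vol, _affine(roi.voxel_size_mm)), str(path))


def read_mask_nifti(path) -> RoiMask:
    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj)
    coords = np.argwhere(vol > 0).astype(np.int64)
    vs = float(np.abs(img.affine[0, 0])) or 3.0
    return RoiMask(voxel_coords=coords, voxel_size_mm=vs)


def write_bold_nifti(bold: BoldSeries, path) -> None:
    """4-D NIfTI of the ROI series embedded in the ROI bounding box."""
    roi = bold.roi
    if roi is None:
        raise ValueError("BoldSeries must carry an ROI to be written as NIfTI")
    origin = roi.voxel_coords.min(axis=0)
    shape = tuple(int(s) for s in roi.voxel_coords.max(axis=0) - origin + 1)
    vol = np.zeros(shape + (bold.n_timepoints,), dtype=np.float32)
    ijk = (roi.voxel_coords - origin).T
    vol[ijk[0], ijk[1], ijk[2], :] = bold.data
    img = nib.Nifti1Image(vol, _affine(roi.voxel_size_mm))
    img.header.set_zooms((roi.voxel_size_mm,) * 3 + (bold.tr_seconds,))
    nib.save(img, str(path))


def read_bold_nifti(bold_path, mask_path) -> BoldSeries:
    roi = read_mask_nifti(mask_path)
    img = nib.load(str(bold_path))
    vol = np.asanyarray(img.dataobj)
    if vol.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    ijk = roi.voxel_coords.T
    data = vol[ijk[0], ijk[1], ijk[2], :].astype(float)
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.8
    return BoldSeries(data=data, tr_seconds=tr or 1.8, roi=roi)


def write_map_nifti(m: MetricMap, path, fill: float = 0.0) -> None:
    vals = np.where(np.isnan(m.values), fill, m.values)
    vol = m.roi.to_volume(vals, fill=fill).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine(m.roi.voxel_size_mm)), str(path))


def read_motion_par(path) -> np.ndarray:
    """MCFLIRT ``.par`` dialect: whitespace-delimited, one row per volume,
    rotations (radians) then translations (mm).  Returned as the package's
    6 x T convention (translations mm first, rotations in degrees)."""
    arr = np.loadtxt(str(path))
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion file must have 6 columns")
    rot_deg = np.degrees(arr[:, :3])
    trans = arr[:, 3:]
    return np.vstack([trans.T, rot_deg.T])


def write_motion_par(motion: np.ndarray, path) -> None:
    motion = np.asarray(motion, float)
    rot_rad = np.radians(motion[3:6])
    arr = np.column_stack([rot_rad.T, motion[:3].T])
    np.savetxt(str(path), arr, fmt="%.10f")


def write_study_hdf5(study: StudyData, path) -> None:
    """One HDF5 bundle per study plus a JSON ground-truth sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["n_subjects"] = study.design.n_subjects
        f.attrs["seed"] = study.design.seed
        f.create_dataset("roi/voxel_coords", data=study.roi.voxel_coords)
        f.attrs["voxel_size_mm"] = study.roi.voxel_size_mm
        for rec in study.records:
            g = f.create_group(f"sub{rec.subject:02d}/{rec.session}/{rec.time}")
            g.create_dataset("bold", data=rec.bold.data,
                             compression="gzip", compression_opts=4)
            g.create_dataset("nuisance", data=rec.nuisance.regressors)
            g.attrs["tr_seconds"] = rec.bold.tr_seconds
            g.attrs["effect_kind"] = rec.effect.kind
            g.attrs["seed"] = rec.seed
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(study.ground_truth(), indent=2))


def read_study_bold(path, subject: int, session: str, time: str
                    ) -> tuple[BoldSeries, NuisanceSet]:
    with h5py.File(str(path), "r") as f:
        roi = RoiMask(voxel_coords=f["roi/voxel_coords"][()],
                      voxel_size_mm=float(f.attrs["voxel_size_mm"]))
        g = f[f"sub{subject:02d}/{session}/{time}"]
        bold = BoldSeries(data=g["bold"][()],
                          tr_seconds=float(g.attrs["tr_seconds"]), roi=roi)
        nuis = NuisanceSet(g["nuisance"][()])
    return bold, nuis


def write_edge_list(G: FunctionalGraph, path) -> None:
    """Plain-text edge list; node ids are 0-based ROI voxel ordinals."""
    edges = G.edge_list()
    ids = G.node_ids
    with open(path, "w") as f:
        f.write(f"# nodes={G.n_nodes} edges={G.n_edges} T={G.threshold_T}\n")
        for i, j in edges:
            f.write(f"{ids[i]} {ids[j]}\n")


def write_adjacency_mtx(G: FunctionalGraph, path) -> None:
    mmwrite(str(path), csr_matrix(G.adjacency.astype(np.int8)))


def write_sync_hdf5(M: SyncMatrix, path) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("sync", data=M.values, compression="gzip")


def read_sync_hdf5(path) -> SyncMatrix:
    with h5py.File(str(path), "r") as f:
        return SyncMatrix(values=f["sync"][()])
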