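"""NIfTI and table I/O plus the run manifest.

Volumes travel as NIfTI-1 with a diagonal affine carrying the voxel size;
masks are coerced to boolean (nonzero = in-mask); series are 4D with time
on the 4th axis. Bin maps are written as a single 4D file (bin as 4th
axis) with a JSON sidecar naming the bin edges.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fcs import BinnedFCSMaps, ConnectivityParams, FCSMap
from .grid import MaskedVolumeGrid
from .preproc import BoldSeries


class IOError_(ValueError):
    pass


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def write_volume(path, data: np.ndarray, voxel_size_mm: float) -> Path:
    """Write a 3D map or 4D series with an isotropic diagonal affine."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, path)
    return path


def read_volume(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI volume; returns (data, isotropic voxel size in mm)."""
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise IOError_(f"{path}: anisotropic voxels {zooms} are not supported")
    return np.asarray(img.dataobj, dtype=float), float(zooms[0])


def read_mask(path) -> MaskedVolumeGrid:
    """Read a mask volume; float {0,1} volumes are coerced to boolean."""
    data, vox = read_volume(path)
    if data.ndim != 3:
        raise IOError_(f"{path}: mask must be 3D, got {data.ndim}D")
    return MaskedVolumeGrid(data != 0, vox, name=Path(path).stem)


def read_series(path, grid: MaskedVolumeGrid,
                repetition_time_s: float | None = None) -> BoldSeries:
    """Read a 4D series and sample it on the grid's mask."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise IOError_(f"{path}: expected a 4D series, got {data.ndim}D")
    if data.shape[3] == 1:
        raise IOError_(
            f"{path}: 4th dimension has length 1 — this is a map, not a series")
    zooms = img.header.get_zooms()
    if data.shape[:3] != grid.shape or not np.isclose(zooms[0], grid.voxel_size_mm):
        raise IOError_(
            f"{path}: series grid {data.shape[:3]} @ {zooms[0]} mm does not "
            f"match mask {grid.shape} @ {grid.voxel_size_mm} mm")
    tr = repetition_time_s if repetition_time_s is not None else float(zooms[3])
    return BoldSeries(data[grid.mask, :], tr, mask_ref=grid.name)


def write_series(path, series: BoldSeries, grid: MaskedVolumeGrid) -> Path:
    vol = np.zeros(grid.shape + (series.n_timepoints,), dtype=np.float32)
    vol[grid.mask, :] = series.data
    path = Path(path)
    img = nib.Nifti1Image(vol, _affine(grid.voxel_size_mm))
    img.header.set_zooms((grid.voxel_size_mm,) * 3 + (series.repetition_time_s,))
    nib.save(img, path)
    return path


def write_fcs_map(path, fcs_map: FCSMap) -> Path:
    return write_volume(path, fcs_map.to_volume(), fcs_map.grid.voxel_size_mm)


def read_fcs_map(path, grid: MaskedVolumeGrid,
                 params: ConnectivityParams | None = None) -> FCSMap:
    data, vox = read_volume(path)
    if data.ndim != 3:
        raise IOError_(f"{path}: expected a 3D map, got {data.ndim}D")
    if data.shape != grid.shape or not np.isclose(vox, grid.voxel_size_mm):
        raise IOError_(f"{path}: map grid does not match mask grid")
    return FCSMap(data[grid.mask], grid, params)


def write_binned_maps(path, binned: BinnedFCSMaps) -> Path:
    """4D bin-map file (bin index on the 4th axis) + JSON edge sidecar."""
    path = Path(path)
    vol = np.zeros(binned.grid.shape + (binned.n_bins,), dtype=np.float32)
    vol[binned.grid.mask, :] = binned.values
    write_volume(path, vol, binned.grid.voxel_size_mm)
    sidecar = path.with_name(path.name.split(".")[0] + "_bins.json")
    sidecar.write_text(json.dumps(
        {"bin_edges_mm": binned.bin_edges_mm.tolist(), "layout": "4d-bin-axis"},
        indent=2))
    return path


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Config snapshot, seeds, parameters and outputs of one pipeline run."""

    config: dict
    seeds: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    preprocessing_order: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    software_version: str = ""
    started: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    finished: str = ""

    def declare_output(self, name: str, path) -> Path:
        self.outputs[name] = str(path)
        return Path(path)

    def write(self, path) -> Path:
        self.finished = datetime.now(timezone.utc).isoformat()
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path

    def reproducible_view(self) -> dict:
        """Manifest minus wall-clock fields, for run-to-run comparison."""
        d = asdict(self)
        d.pop("started"), d.pop("finished")
        return d


def write_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path
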