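"""Time-averaged 3D occupancy grids of selected headgroup atoms.

Hard-sphere (nearest-voxel) binning, no kernel smearing.  Atoms are wrapped
laterally into the box before binning; z (the membrane normal) is never
wrapped, matching the conventions of the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .structio import Trajectory

__all__ = ["DensityGrid", "density_grid", "grid_slab", "threshold_mask",
           "ThresholdMask", "write_opendx"]

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class DensityGrid:
    """Voxelised occupancy of a selection accumulated over frames.

    ``counts`` holds raw per-voxel atom counts summed over frames;
    ``occupancy`` is the fraction of frames in which the voxel held at least
    one selected atom (always in [0, 1]).
    """

    origin: np.ndarray
    voxel_size: float
    counts: np.ndarray
    occupancy: np.ndarray
    n_frames: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def nonzero_to_csv(self, path) -> None:
        idx = np.argwhere(self.counts > 0)
        centers = self.origin + (idx + 0.5) * self.voxel_size
        pd.DataFrame(
            {
                "x": centers[:, 0],
                "y": centers[:, 1],
                "z": centers[:, 2],
                "count": self.counts[idx[:, 0], idx[:, 1], idx[:, 2]],
                "occupancy": self.occupancy[idx[:, 0], idx[:, 1], idx[:, 2]],
            }
        ).to_csv(path, index=False)


def density_grid(
    traj: Trajectory,
    selection: Sequence[int],
    voxel_size: float = 0.1,
) -> DensityGrid:
    """Accumulate selected atoms into voxels over all frames."""
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("selection is empty")
    box = traj.frames[0].box
    if box is None or np.any(box[:2] <= 0):
        raise ValueError("degenerate box: density grid needs a periodic box")

    zs = np.concatenate([f.coordinates[selection, 2] for f in traj.frames])
    z_min = np.floor(zs.min() / voxel_size) * voxel_size
    z_max = np.ceil(zs.max() / voxel_size + 1e-9) * voxel_size
    nx = int(np.ceil(box[0] / voxel_size - 1e-9))
    ny = int(np.ceil(box[1] / voxel_size - 1e-9))
    nz = max(1, int(round((z_max - z_min) / voxel_size)))
    origin = np.array([0.0, 0.0, z_min])

    counts = np.zeros((nx, ny, nz), dtype=int)
    frames_occupied = np.zeros((nx, ny, nz), dtype=int)
    for frame in traj.frames:
        pos = frame.coordinates[selection].copy()
        pos[:, 0] %= box[0]
        pos[:, 1] %= box[1]
        ijk = np.floor((pos - origin) / voxel_size).astype(int)
        ijk[:, 0] = np.clip(ijk[:, 0], 0, nx - 1)
        ijk[:, 1] = np.clip(ijk[:, 1], 0, ny - 1)
        ijk[:, 2] = np.clip(ijk[:, 2], 0, nz - 1)
        frame_counts = np.zeros((nx, ny, nz), dtype=int)
        np.add.at(frame_counts, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1)
        counts += frame_counts
        frames_occupied += frame_counts > 0

    return DensityGrid(
        origin=origin,
        voxel_size=voxel_size,
        counts=counts,
        occupancy=frames_occupied / traj.n_frames,
        n_frames=traj.n_frames,
    )


def grid_slab(
    grid: DensityGrid, axis: str, position: float, width: float
) -> np.ndarray:
    """Sum voxels whose centers fall within position ± width/2 along ``axis``.

    Returns the 2D projection over the remaining two axes.
    """
    ax = _AXIS[axis]
    centers = grid.voxel_centers(ax)
    inside = np.abs(centers - position) <= width / 2.0 + 1e-12
    if not np.any(inside):
        raise ValueError("slab does not intersect the grid")
    return np.take(grid.counts, np.flatnonzero(inside), axis=ax).sum(axis=ax)


class ThresholdMask(NamedTuple):
    mask: np.ndarray
    n_voxels: int


def threshold_mask(grid: DensityGrid, iso_level: float) -> ThresholdMask:
    """Boolean mask of voxels with occupancy >= iso_level."""
    if not (0.0 < iso_level <= 1.0):
        raise ValueError("iso_level must be in (0, 1] for occupancy normalization")
    mask = grid.occupancy >= iso_level
    return ThresholdMask(mask=mask, n_voxels=int(mask.sum()))


def write_opendx(grid: DensityGrid, path, field: str = "occupancy") -> None:
    """Export the grid in OpenDX text format (VMD-compatible)."""
    data = getattr(grid, field).astype(float)
    nx, ny, nz = data.shape
    # OpenDX conventionally carries Å for molecular viewers
    ox, oy, oz = grid.origin * 10.0
    d = grid.voxel_size * 10.0
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {d:.6f} 0 0\ndelta 0 {d:.6f} 0\ndelta 0 0 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {data.size} data follows\n"
        )
        flat = data.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')
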