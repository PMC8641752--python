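"""Protein-conformation metrics: Kabsch superposition, pairwise-RMSD
GROMOS (Daura) clustering and Shrake–Rupley solvent-accessible surface area.

No periodic imaging is applied here — the protein is assumed whole.
Hydrogens are ignored by the default backbone selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .structio import Frame, Trajectory

__all__ = [
    "RmsdMatrix",
    "ClusterResult",
    "SasaResult",
    "BONDI_RADII",
    "BACKBONE_ATOMS",
    "kabsch_superpose",
    "pairwise_rmsd_matrix",
    "gromos_cluster",
    "golden_spiral_points",
    "shrake_rupley_sasa",
]

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Bondi van der Waals radii, nm
BONDI_RADII: Mapping[str, float] = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "F": 0.147,
    "P": 0.180,
    "S": 0.180,
    "CL": 0.175,
}


def kabsch_superpose(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of X onto Y.

    Returns (rotation, translation, rmsd) such that ``X @ rotation.T +
    translation`` best fits Y.  The rotation is proper (determinant +1);
    reflections are excluded by the usual sign correction on the smallest
    singular vector.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X and Y must both have shape (n, 3)")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 points to superpose")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    Xc = X - cx
    Yc = Y - cy
    H = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cy - R @ cx
    diff = Xc @ R.T - Yc
    rmsd = float(np.sqrt((diff**2).sum() / X.shape[0]))
    return R, t, rmsd


@dataclass
class RmsdMatrix:
    """Symmetric pairwise RMSD matrix over trajectory frames (nm)."""

    values: np.ndarray
    selection_label: str

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_rmsd_matrix(
    traj: Trajectory, selection: frozenset | set | None = None
) -> RmsdMatrix:
    """Pairwise Kabsch RMSD between every frame pair on the selected atoms.

    Default selection is the protein backbone {N, CA, C, O}.
    """
    names = BACKBONE_ATOMS if selection is None else frozenset(selection)
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a pairwise RMSD matrix")
    mask = np.array([str(a) in names for a in traj.frames[0].atom_names])
    if not np.any(mask):
        raise ValueError(f"selection {sorted(names)} matches no atoms")
    coords = [f.coordinates[mask] for f in traj.frames]
    n = len(coords)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(coords[i], coords[j])
            values[i, j] = values[j, i] = rmsd
    return RmsdMatrix(values=values, selection_label="+".join(sorted(names)))


@dataclass
class ClusterResult:
    """GROMOS clustering output: one cluster id per frame."""

    assignments: np.ndarray
    centers: list[int]
    prevalence: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centers)


def gromos_cluster(matrix: RmsdMatrix, cutoff: float = 0.1) -> ClusterResult:
    """Daura-style iterative neighbor-count clustering.

    Repeatedly: count, among unassigned frames, each frame's neighbors within
    ``cutoff``; the frame with the most neighbors (ties broken by lowest
    frame index) becomes a cluster center and is removed together with its
    neighbors.  Every frame ends in exactly one cluster.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    values = matrix.values
    n = matrix.n
    remaining = np.ones(n, dtype=bool)
    assignments = np.full(n, -1, dtype=int)
    centers: list[int] = []
    adjacency = values <= cutoff
    np.fill_diagonal(adjacency, True)
    cluster_id = 0
    while np.any(remaining):
        idx = np.flatnonzero(remaining)
        counts = adjacency[np.ix_(idx, idx)].sum(axis=1)
        center = idx[int(np.argmax(counts))]  # argmax takes the lowest index on ties
        members = idx[adjacency[center, idx]]
        assignments[members] = cluster_id
        centers.append(int(center))
        remaining[members] = False
        cluster_id += 1
    prevalence = np.bincount(assignments, minlength=cluster_id) / n
    return ClusterResult(
        assignments=assignments,
        centers=centers,
        prevalence=prevalence,
        cutoff=cutoff,
    )


@dataclass
class SasaResult:
    per_atom_area: np.ndarray  # nm^2
    total_area: float
    probe_radius: float
    n_sphere_points: int


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def shrake_rupley_sasa(
    frame: Frame,
    probe_radius: float = 0.14,
    n_sphere_points: int = 960,
    radii_table: Mapping[str, float] | None = None,
    indices: Sequence[int] | None = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area.

    For each atom, ``n_sphere_points`` test points are placed on the sphere
    of radius (r_vdw + probe); a point is accessible when it lies outside
    every other atom's expanded sphere.  Area = accessible fraction ×
    4π(r_vdw + probe)².
    """
    radii_table = BONDI_RADII if radii_table is None else radii_table
    if indices is None:
        indices = np.arange(frame.n_atoms)
    indices = np.asarray(indices, dtype=int)
    elements = [str(frame.elements[i]).upper() for i in indices]
    unknown = sorted({e for e in elements if e not in radii_table})
    if unknown:
        raise ValueError(f"unknown elements with no vdW radius: {unknown}")
    coords = frame.coordinates[indices]
    radii = np.array([radii_table[e] for e in elements]) + probe_radius
    sphere = golden_spiral_points(n_sphere_points)

    n = len(indices)
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        accessible = np.ones(n_sphere_points, dtype=bool)
        d = np.linalg.norm(coords - coords[i], axis=1)
        neighbors = np.flatnonzero((d < radii + radii[i]) & (np.arange(n) != i))
        for j in neighbors:
            if not accessible.any():
                break
            dist2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= dist2 > radii[j] ** 2
        areas[i] = accessible.mean() * 4.0 * np.pi * radii[i] ** 2
    return SasaResult(
        per_atom_area=areas,
        total_area=float(areas.sum()),
        probe_radius=probe_radius,
        n_sphere_points=n_sphere_points,
    )
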