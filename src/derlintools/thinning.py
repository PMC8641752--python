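"""Per-lipid trans-leaflet thickness, lateral thickness maps and thinning reports.

The central statistic: a lipid's membrane thickness is the average of the
three shortest 3D distances from its headgroup to phosphate-bearing
headgroups of the opposing leaflet, with minimum-image wrapping applied
laterally only.  Cholesterol (no phosphate) is excluded from the thickness
statistic but participates in leaflet assignment.  Maps pool per-lipid
samples over frames onto a lateral grid; reports locate the smoothed
minimum in the protein-proximal zone and contrast it with the bulk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .structio import Frame, Trajectory, HeadgroupSelection, select_headgroups, \
    min_image_displacement
from .synthetic import ProteinStub

__all__ = [
    "LeafletAssignment",
    "ThicknessSample",
    "ThicknessMap",
    "ThinningReport",
    "MapComparison",
    "assign_leaflets",
    "lipid_thickness",
    "thickness_map",
    "bulk_thickness",
    "thinning_report",
    "compare_maps",
]

OUTLIER_BAND = 0.5  # nm from the midplane; flagged but still labeled
DEFAULT_BULK_RADIUS = 2.5  # nm from the nearest helix axis
DEFECT_ZONE_RADIUS = 1.0  # nm around the reported minimum, for leaflet heights


@dataclass
class LeafletAssignment:
    """Upper/lower labels for the selected headgroups of one frame."""

    selection: HeadgroupSelection
    labels: np.ndarray  # "upper"/"lower" per selected headgroup
    midplane_z: float
    flagged_outliers: np.ndarray  # positions into the selection

    @property
    def upper_mask(self) -> np.ndarray:
        return self.labels == "upper"


def assign_leaflets(frame: Frame, selection: HeadgroupSelection) -> LeafletAssignment:
    """Split headgroups into leaflets by sign of z about the global midplane.

    The midplane is the median z of all selected headgroups.  Headgroups
    within 0.5 nm of the midplane are flagged as outliers but still labeled;
    if every headgroup sits inside that band there is no bilayer to analyse.
    """
    if len(selection) < 2:
        raise ValueError("need at least 2 headgroups to assign leaflets")
    z = frame.coordinates[selection.indices, 2]
    midplane = float(np.median(z))
    dz = z - midplane
    if np.all(np.abs(dz) < OUTLIER_BAND):
        raise ValueError("no bilayer structure: all headgroups within 0.5 nm of midplane")
    labels = np.where(dz >= 0, "upper", "lower").astype(object)
    if not (np.any(labels == "upper") and np.any(labels == "lower")):
        raise ValueError("degenerate leaflet assignment: one leaflet is empty")
    outliers = np.nonzero(np.abs(dz) < OUTLIER_BAND)[0]
    return LeafletAssignment(
        selection=selection, labels=labels, midplane_z=midplane,
        flagged_outliers=outliers,
    )


@dataclass(frozen=True)
class ThicknessSample:
    lipid_index: int
    leaflet: str
    lateral_position: tuple[float, float]
    thickness: float
    frame_index: int
    k_used: int


def _thickness_arrays(
    frame: Frame, assignment: LeafletAssignment, k: int
) -> pd.DataFrame:
    """Vectorised core: one row per phosphate-bearing lipid."""
    sel = assignment.selection
    coords = frame.coordinates[sel.indices]
    box = frame.require_periodic_box()
    upper = assignment.upper_mask
    phos = sel.is_phosphate

    rows = []
    for this_mask, that_mask, label in (
        (upper & phos, ~upper & phos, "upper"),
        (~upper & phos, upper & phos, "lower"),
    ):
        n_this, n_that = int(this_mask.sum()), int(that_mask.sum())
        if n_this == 0:
            continue
        if n_that == 0:
            raise ValueError(
                "opposing leaflet has no phosphate-bearing headgroups"
            )
        a = coords[this_mask]
        b = coords[that_mask]
        disp = min_image_displacement(
            a[:, None, :], b[None, :, :], box, wrap_axes=("x", "y")
        )
        dist = np.linalg.norm(disp, axis=-1)
        k_used = min(k, n_that)
        smallest = np.partition(dist, k_used - 1, axis=1)[:, :k_used]
        thick = smallest.mean(axis=1)
        idx = sel.indices[this_mask]
        rows.append(
            pd.DataFrame(
                {
                    "lipid_index": idx,
                    "leaflet": label,
                    "x": a[:, 0] % box[0],
                    "y": a[:, 1] % box[1],
                    "thickness": thick,
                    "frame": frame.frame_index,
                    "k_used": k_used,
                    "height": np.abs(a[:, 2] - assignment.midplane_z),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def lipid_thickness(
    frame: Frame, assignment: LeafletAssignment, k: int = 3
) -> list[ThicknessSample]:
    """Trans-leaflet thickness for every phosphate-bearing lipid of a frame.

    thickness = mean of the ``k`` smallest minimum-image 3D distances to
    phosphate-bearing headgroups of the opposing leaflet; if the opposing
    leaflet holds only m < k such lipids, m is used and recorded as k_used.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = _thickness_arrays(frame, assignment, k)
    return [
        ThicknessSample(
            lipid_index=int(r.lipid_index),
            leaflet=str(r.leaflet),
            lateral_position=(float(r.x), float(r.y)),
            thickness=float(r.thickness),
            frame_index=int(r.frame),
            k_used=int(r.k_used),
        )
        for r in df.itertuples()
    ]


@dataclass
class ThicknessMap:
    """Binned lateral aggregation of pooled thickness samples.

    ``mean_grid`` holds NaN for empty cells (missing, never zero).  The
    ``samples`` frame keeps every sample (both leaflets); the grid is built
    from the samples selected by ``leaflet_scope``.
    """

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    mean_grid: np.ndarray
    count_grid: np.ndarray
    samples: pd.DataFrame
    leaflet_scope: str
    box_xy: tuple[float, float]
    k: int = 3
    display_range: tuple[float, float] = (2.0, 5.0)

    def __post_init__(self) -> None:
        scoped = self.scoped_samples()
        total = self.count_grid.sum()
        if total != len(scoped):
            raise AssertionError("count grid does not conserve samples")
        if total:
            grid_mean = (
                np.nansum(self.mean_grid * self.count_grid) / total
            )
            if abs(grid_mean - scoped["thickness"].mean()) > 1e-9:
                raise AssertionError(
                    "count-weighted grid mean does not match sample mean"
                )

    def scoped_samples(self) -> pd.DataFrame:
        if self.leaflet_scope == "both":
            return self.samples
        return self.samples[self.samples["leaflet"] == self.leaflet_scope]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cx = 0.5 * (self.bin_edges_x[:-1] + self.bin_edges_x[1:])
        cy = 0.5 * (self.bin_edges_y[:-1] + self.bin_edges_y[1:])
        return cx, cy

    def to_csv(self, grid_path=None, samples_path=None) -> None:
        if grid_path is not None:
            pd.DataFrame(
                self.mean_grid,
                index=pd.Index(self.cell_centers()[0], name="x_center"),
                columns=pd.Index(self.cell_centers()[1], name="y_center"),
            ).to_csv(grid_path)
        if samples_path is not None:
            self.samples[
                ["lipid_index", "frame", "leaflet", "x", "y", "thickness"]
            ].to_csv(samples_path, index=False)

    def render(self, path, title: str = "") -> None:
        """Rasterise the map honoring the 2.0–5.0 nm display range."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4.2))
        vmin, vmax = self.display_range
        im = ax.pcolormesh(
            self.bin_edges_x, self.bin_edges_y, self.mean_grid.T,
            vmin=vmin, vmax=vmax, cmap="turbo",
        )
        fig.colorbar(im, ax=ax, label="thickness (nm)")
        ax.set_xlabel("x (nm)")
        ax.set_ylabel("y (nm)")
        ax.set_aspect("equal")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def thickness_map(
    traj: Trajectory,
    stride: int = 1,
    bin_size: float = 0.2,
    k: int = 3,
    leaflet_scope: str = "both",
    rules=None,
) -> ThicknessMap:
    """Pool per-lipid thickness over strided frames onto a lateral grid.

    ``leaflet_scope`` restricts which leaflet's headgroup positions populate
    the grid while the thickness itself remains the trans-leaflet (total)
    statistic.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if leaflet_scope not in ("upper", "lower", "both"):
        raise ValueError("leaflet_scope must be 'upper', 'lower' or 'both'")
    frames = traj.frames[::stride]
    if not frames:
        raise ValueError("no frames remain after striding")

    box = frames[0].require_periodic_box()
    chunks = []
    for frame in frames:
        sel = select_headgroups(frame, rules)
        assignment = assign_leaflets(frame, sel)
        chunks.append(_thickness_arrays(frame, assignment, k))
    samples = pd.concat(chunks, ignore_index=True)

    nx = int(np.ceil(box[0] / bin_size - 1e-9))
    ny = int(np.ceil(box[1] / bin_size - 1e-9))
    edges_x = np.linspace(0.0, nx * bin_size, nx + 1)
    edges_y = np.linspace(0.0, ny * bin_size, ny + 1)

    scoped = samples if leaflet_scope == "both" else samples[
        samples["leaflet"] == leaflet_scope
    ]
    counts, _, _ = np.histogram2d(
        scoped["x"], scoped["y"], bins=[edges_x, edges_y]
    )
    sums, _, _ = np.histogram2d(
        scoped["x"], scoped["y"], bins=[edges_x, edges_y],
        weights=scoped["thickness"],
    )
    with np.errstate(invalid="ignore"):
        mean_grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    return ThicknessMap(
        bin_edges_x=edges_x,
        bin_edges_y=edges_y,
        mean_grid=mean_grid,
        count_grid=counts.astype(int),
        samples=samples,
        leaflet_scope=leaflet_scope,
        box_xy=(float(box[0]), float(box[1])),
        k=k,
    )


def _distance_to_nearest_helix(
    xy: np.ndarray, protein: ProteinStub, box_xy: tuple[float, float]
) -> np.ndarray:
    """Min-image lateral distance from points to the nearest helix axis."""
    xy = np.atleast_2d(xy)
    box = np.array([box_xy[0], box_xy[1], 1.0])
    best = np.full(len(xy), np.inf)
    pts = np.column_stack([xy, np.zeros(len(xy))])
    for axis_xy in protein.axis_positions():
        disp = min_image_displacement(
            pts, np.array([axis_xy[0], axis_xy[1], 0.0]), box
        )
        best = np.minimum(best, np.hypot(disp[:, 0], disp[:, 1]))
    return best


def bulk_thickness(
    map: ThicknessMap,
    protein: ProteinStub | None,
    bulk_radius: float = DEFAULT_BULK_RADIUS,
) -> tuple[float, float]:
    """Mean and SD of thickness over samples far from every helix axis.

    With no protein, every sample is bulk.
    """
    scoped = map.scoped_samples()
    if protein is None:
        bulk = scoped
    else:
        xy = scoped[["x", "y"]].to_numpy()
        dist = _distance_to_nearest_helix(xy, protein, map.box_xy)
        bulk = scoped[dist > bulk_radius]
    if len(bulk) == 0:
        raise ValueError(
            f"no samples beyond bulk_radius={bulk_radius} nm of every helix; "
            "try a smaller radius"
        )
    return float(bulk["thickness"].mean()), float(bulk["thickness"].std(ddof=0))


@dataclass
class ThinningReport:
    """Summary of local thinning relative to the bulk membrane."""

    bulk_mean: float
    bulk_sd: float
    min_thickness: float
    min_location: tuple[float, float]
    nearest_helices: list[tuple[str, float]]
    per_leaflet_heights: dict

    def to_dict(self) -> dict:
        return {
            "bulk_mean_nm": self.bulk_mean,
            "bulk_sd_nm": self.bulk_sd,
            "min_thickness_nm": self.min_thickness,
            "min_location_nm": list(self.min_location),
            "nearest_helices": [
                {"label": lab, "distance_nm": d} for lab, d in self.nearest_helices
            ],
            "per_leaflet_heights_nm": self.per_leaflet_heights,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def smoothed_grid(map: ThicknessMap, smoothing_sigma: float) -> np.ndarray:
    """Count-weighted periodic Gaussian smoothing of the mean grid.

    NaN cells contribute zero weight; cells that remain unsupported after
    smoothing stay NaN.
    """
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    if smoothing_sigma >= min(map.mean_grid.shape):
        raise ValueError("smoothing sigma exceeds grid size")
    if smoothing_sigma == 0:
        return map.mean_grid.copy()
    w = map.count_grid.astype(float)
    v = np.where(np.isnan(map.mean_grid), 0.0, map.mean_grid)
    num = gaussian_filter(v * w, smoothing_sigma, mode="wrap")
    den = gaussian_filter(w, smoothing_sigma, mode="wrap")
    with np.errstate(invalid="ignore"):
        out = np.where(den > 1e-12, num / np.maximum(den, 1e-300), np.nan)
    return out


def thinning_report(
    map: ThicknessMap,
    protein: ProteinStub | None,
    smoothing_sigma: float = 1.0,
    bulk_radius: float = DEFAULT_BULK_RADIUS,
) -> ThinningReport:
    """Locate the smoothed thickness minimum in the protein-proximal zone.

    The proximal zone is the set of grid cells within ``bulk_radius`` of any
    helix axis (the whole grid when no protein is given).  Leaflet heights
    |z - midplane| are reported for the defect zone (within 1 nm of the
    minimum) and for the bulk.
    """
    if map.count_grid.sum() == 0:
        raise ValueError("empty thickness map")
    grid = smoothed_grid(map, smoothing_sigma)
    cx, cy = map.cell_centers()
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    centers = np.column_stack([gx.ravel(), gy.ravel()])

    if protein is None:
        zone = np.ones(len(centers), dtype=bool)
    else:
        zone = _distance_to_nearest_helix(centers, protein, map.box_xy) <= bulk_radius
    flat = grid.ravel()
    candidate = zone & ~np.isnan(flat)
    if not np.any(candidate):
        raise ValueError("no mapped cells inside the protein-proximal zone")
    best = np.flatnonzero(candidate)[np.argmin(flat[np.flatnonzero(candidate)])]
    min_thickness = float(flat[best])
    min_location = (float(centers[best, 0]), float(centers[best, 1]))

    nearest: list[tuple[str, float]] = []
    if protein is not None:
        box = np.array([map.box_xy[0], map.box_xy[1], 1.0])
        loc = np.array([min_location[0], min_location[1], 0.0])
        for label, (hx, hy) in protein.helix_axes:
            disp = min_image_displacement(loc, np.array([hx, hy, 0.0]), box)
            nearest.append((label, float(np.hypot(disp[0], disp[1]))))
        nearest.sort(key=lambda t: (t[1], t[0]))

    bulk_mean, bulk_sd = bulk_thickness(map, protein, bulk_radius)

    samples = map.samples
    xy = samples[["x", "y"]].to_numpy()
    box = np.array([map.box_xy[0], map.box_xy[1], 1.0])
    disp = min_image_displacement(
        np.column_stack([xy, np.zeros(len(xy))]),
        np.array([min_location[0], min_location[1], 0.0]),
        box,
    )
    in_zone = np.hypot(disp[:, 0], disp[:, 1]) <= DEFECT_ZONE_RADIUS
    if protein is None:
        in_bulk = np.ones(len(samples), dtype=bool)
    else:
        in_bulk = _distance_to_nearest_helix(xy, protein, map.box_xy) > bulk_radius
    heights: dict[str, dict[str, float | None]] = {}
    for leaflet in ("upper", "lower"):
        m = (samples["leaflet"] == leaflet).to_numpy()
        zone_vals = samples["height"].to_numpy()[m & in_zone]
        bulk_vals = samples["height"].to_numpy()[m & in_bulk]
        heights[leaflet] = {
            "defect_zone": float(zone_vals.mean()) if zone_vals.size else None,
            "bulk": float(bulk_vals.mean()) if bulk_vals.size else None,
        }

    return ThinningReport(
        bulk_mean=bulk_mean,
        bulk_sd=bulk_sd,
        min_thickness=min_thickness,
        min_location=min_location,
        nearest_helices=nearest,
        per_leaflet_heights=heights,
    )


@dataclass
class MapComparison:
    """Cellwise difference of two identically binned maps (a - b)."""

    delta_grid: np.ndarray
    delta_min: float
    delta_bulk_mean: float
    max_abs_cell: tuple[int, int]
    max_abs_value: float


def compare_maps(a: ThicknessMap, b: ThicknessMap) -> MapComparison:
    if not (
        np.array_equal(a.bin_edges_x, b.bin_edges_x)
        and np.array_equal(a.bin_edges_y, b.bin_edges_y)
    ):
        raise ValueError("incompatible bin edges")
    both = ~np.isnan(a.mean_grid) & ~np.isnan(b.mean_grid)
    delta = np.where(both, a.mean_grid - b.mean_grid, np.nan)
    delta_min = float(np.nanmin(a.mean_grid) - np.nanmin(b.mean_grid))
    delta_bulk = float(
        a.scoped_samples()["thickness"].mean() - b.scoped_samples()["thickness"].mean()
    )
    if np.any(both):
        flat = np.where(both, np.abs(delta), -np.inf)
        ij = np.unravel_index(int(np.argmax(flat)), delta.shape)
        max_val = float(delta[ij])
    else:
        ij, max_val = (0, 0), float("nan")
    return MapComparison(
        delta_grid=delta,
        delta_min=delta_min,
        delta_bulk_mean=delta_bulk,
        max_abs_cell=(int(ij[0]), int(ij[1])),
        max_abs_value=max_val,
    )
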