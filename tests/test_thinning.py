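"""Leaflet assignment, the 3-nearest trans-leaflet statistic, maps, reports."""

import math
from dataclasses import replace

import numpy as np
import pytest

from derlintools.structio import Frame, select_headgroups
from derlintools.synthetic import build_bilayer_spec, generate_trajectory
from derlintools.thinning import (
    assign_leaflets,
    bulk_thickness,
    compare_maps,
    lipid_thickness,
    thickness_map,
    thinning_report,
)
from conftest import make_two_leaflet_frame

# closed-form 3-NN thickness on aligned square lattices, spacing 0.8 nm,
# separation 4.2 nm: the direct opposite plus two first-shell neighbors
LATTICE_VALUE = (4.2 + 2.0 * math.sqrt(4.2**2 + 0.8**2)) / 3.0


def _headgroup_frame(zs, box=(10, 10, 10)):
    n = len(zs)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.linspace(0.5, 9.5, n)
    coords[:, 2] = zs
    return Frame(
        atom_names=["P"] * n,
        residue_names=["POPC"] * n,
        residue_ids=list(range(1, n + 1)),
        chains=[""] * n,
        elements=["P"] * n,
        coordinates=coords,
        box=box,
    )


def flat_lattice_spec(**overrides):
    """9.6 nm box tiled exactly by the 0.8 nm lattice, pure POPC, no jitter."""
    base = dict(
        box_x=9.6, box_y=9.6, area_per_lipid=0.64,
        composition={"POPC": 1.0},
        lateral_jitter_sd=0.0, vertical_jitter_sd=0.0, n_frames=1,
    )
    base.update(overrides)
    return build_bilayer_spec("ER_BULK", base)


class TestAssignLeaflets:
    def test_symmetric_bilayer_splits_at_zero(self):
        frame = _headgroup_frame([2.1] * 10 + [-2.1] * 10)
        sel = select_headgroups(frame)
        assignment = assign_leaflets(frame, sel)
        assert assignment.midplane_z == pytest.approx(0.0)
        assert (assignment.labels == "upper").sum() == 10
        assert (assignment.labels == "lower").sum() == 10
        assert len(assignment.flagged_outliers) == 0

    def test_particle_near_midplane_is_labeled_but_flagged(self):
        frame = _headgroup_frame([2.1] * 10 + [-2.1] * 10 + [0.2])
        assignment = assign_leaflets(frame, select_headgroups(frame))
        assert assignment.labels[-1] == "upper"
        assert 20 in assignment.flagged_outliers

    def test_labels_invariant_under_permutation(self):
        rng = np.random.default_rng(0)
        zs = np.concatenate([rng.normal(2.1, 0.1, 12), rng.normal(-2.1, 0.1, 12)])
        frame = _headgroup_frame(zs)
        assignment = assign_leaflets(frame, select_headgroups(frame))
        perm = rng.permutation(len(zs))
        frame_p = _headgroup_frame(zs[perm])
        assignment_p = assign_leaflets(frame_p, select_headgroups(frame_p))
        assert list(assignment_p.labels) == list(assignment.labels[perm])

    def test_collapsed_bilayer_rejected(self):
        frame = _headgroup_frame(np.linspace(-0.2, 0.2, 12))
        with pytest.raises(ValueError, match="no bilayer"):
            assign_leaflets(frame, select_headgroups(frame))


class TestLipidThickness:
    def test_flat_lattice_matches_closed_form(self):
        traj = generate_trajectory(flat_lattice_spec(), seed=0)
        frame = traj.frames[0]
        assignment = assign_leaflets(frame, select_headgroups(frame))
        samples = lipid_thickness(frame, assignment, k=3)
        values = np.array([s.thickness for s in samples])
        np.testing.assert_allclose(values, LATTICE_VALUE, atol=1e-9)

    def test_opposing_leaflet_of_exactly_three_equidistant_lipids(self):
        d = 4.5
        lat = math.sqrt(d**2 - 4.2**2)
        # two far-away decoys balance the leaflets so the median midplane
        # falls between the planes
        upper = np.array([[5.0, 5.0], [0.5, 0.5], [9.0, 1.0]])
        lower = np.array(
            [[5.0 + lat, 5.0], [5.0 - lat, 5.0], [5.0, 5.0 + lat]]
        )
        frame = make_two_leaflet_frame(upper, lower)
        assignment = assign_leaflets(frame, select_headgroups(frame))
        samples = lipid_thickness(frame, assignment, k=3)
        sample = next(s for s in samples if s.lipid_index == 0)
        assert sample.thickness == pytest.approx(d, abs=1e-12)
        assert sample.k_used == 3

    def test_k1_uses_directly_opposing_lipid(self):
        frame = make_two_leaflet_frame(np.array([[5.0, 5.0]]),
                                       np.array([[5.0, 5.0]]))
        assignment = assign_leaflets(frame, select_headgroups(frame))
        samples = lipid_thickness(frame, assignment, k=1)
        assert all(s.thickness == pytest.approx(4.2) for s in samples)
        assert all(s.k_used == 1 for s in samples)

    def test_k_used_recorded_when_opposing_leaflet_small(self):
        frame = make_two_leaflet_frame(
            np.array([[5.0, 5.0], [0.5, 0.5]]),
            np.array([[5.0, 5.0], [5.8, 5.0]]),
        )
        assignment = assign_leaflets(frame, select_headgroups(frame))
        samples = lipid_thickness(frame, assignment, k=3)
        # both leaflets hold only 2 phosphate lipids, so k falls back to 2
        assert all(s.k_used == 2 for s in samples)

    def test_bias_nonnegative_on_flat_lattice(self):
        traj = generate_trajectory(flat_lattice_spec(), seed=0)
        frame = traj.frames[0]
        assignment = assign_leaflets(frame, select_headgroups(frame))
        for s in lipid_thickness(frame, assignment, k=3):
            assert s.thickness >= 4.2 - 1e-12

    def test_bruteforce_oracle_equivalence_small(self):
        """Vectorised statistic equals pure-python all-pairs enumeration."""
        rng = np.random.default_rng(11)
        box = (8.0, 8.0, 10.0)
        for _ in range(30):
            n_u = n_l = int(rng.integers(4, 25))
            upper = rng.uniform(0, 8, (n_u, 2))
            lower = rng.uniform(0, 8, (n_l, 2))
            frame = make_two_leaflet_frame(upper, lower, box=box)
            frame.coordinates[:, 2] += rng.normal(0, 0.2, len(frame.coordinates))
            assignment = assign_leaflets(frame, select_headgroups(frame))
            samples = lipid_thickness(frame, assignment, k=3)
            for s in samples:
                mine = frame.coordinates[s.lipid_index]
                opposite = [
                    i for i in range(frame.n_atoms)
                    if assignment.labels[i] != s.leaflet
                ]
                dists = []
                for j in opposite:
                    dx = mine[0] - frame.coordinates[j, 0]
                    dy = mine[1] - frame.coordinates[j, 1]
                    dx -= box[0] * round(dx / box[0])
                    dy -= box[1] * round(dy / box[1])
                    dz = mine[2] - frame.coordinates[j, 2]
                    dists.append(math.sqrt(dx * dx + dy * dy + dz * dz))
                expected = sum(sorted(dists)[: s.k_used]) / s.k_used
                assert s.thickness == pytest.approx(expected, abs=1e-12)


class TestThicknessMap:
    def test_flat_trajectory_fills_cells_with_lattice_value(self):
        traj = generate_trajectory(flat_lattice_spec(n_frames=2), seed=0)
        tmap = thickness_map(traj, bin_size=0.2)
        filled = tmap.mean_grid[~np.isnan(tmap.mean_grid)]
        np.testing.assert_allclose(filled, LATTICE_VALUE, atol=1e-9)

    def test_single_sample_occupies_single_cell(self):
        frame = make_two_leaflet_frame(np.array([[1.0, 1.0]]),
                                       np.array([[1.0, 1.0]]))
        from derlintools.structio import Trajectory

        tmap = thickness_map(Trajectory([frame]), bin_size=0.2,
                             leaflet_scope="upper")
        filled = ~np.isnan(tmap.mean_grid)
        assert filled.sum() == 1
        assert tmap.mean_grid[filled][0] == pytest.approx(4.2)

    def test_count_weighted_grid_mean_matches_sample_mean(self):
        spec = build_bilayer_spec("DFM1_WT", {"n_frames": 4})
        tmap = thickness_map(generate_trajectory(spec, 3))
        total = tmap.count_grid.sum()
        grid_mean = np.nansum(tmap.mean_grid * tmap.count_grid) / total
        assert grid_mean == pytest.approx(
            tmap.scoped_samples()["thickness"].mean(), abs=1e-9
        )

    def test_leaflet_scope_restricts_mapped_positions(self):
        spec = build_bilayer_spec("DFM1_F107S", {"n_frames": 2})
        traj = generate_trajectory(spec, 3)
        upper = thickness_map(traj, leaflet_scope="upper")
        both = thickness_map(traj, leaflet_scope="both")
        assert len(upper.scoped_samples()) < len(both.scoped_samples())
        assert set(upper.scoped_samples()["leaflet"]) == {"upper"}

    def test_stride_and_empty_errors(self):
        spec = build_bilayer_spec("ER_BULK", {"n_frames": 2})
        traj = generate_trajectory(spec, 0)
        with pytest.raises(ValueError):
            thickness_map(traj, stride=0)
        with pytest.raises(ValueError):
            thickness_map(traj, bin_size=-0.1)


class TestBulkAndReport:
    def test_defect_free_lattice_bulk_statistics(self):
        traj = generate_trajectory(flat_lattice_spec(), seed=0)
        tmap = thickness_map(traj, bin_size=0.2)
        mean, sd = bulk_thickness(tmap, None)
        assert mean == pytest.approx(LATTICE_VALUE, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_bulk_mean_invariant_under_rigid_translation(self):
        spec = build_bilayer_spec("ER_BULK", {"n_frames": 2})
        traj = generate_trajectory(spec, 9)
        mean_a, _ = bulk_thickness(thickness_map(traj), None)
        for frame in traj.frames:
            frame.coordinates[:, 0] += 1.7
            frame.coordinates[:, 1] -= 0.9
        mean_b, _ = bulk_thickness(thickness_map(traj), None)
        assert mean_b == pytest.approx(mean_a, abs=1e-9)

    def test_defect_free_min_is_near_bulk(self):
        spec = build_bilayer_spec("ER_BULK", {"n_frames": 10})
        tmap = thickness_map(generate_trajectory(spec, 4))
        report = thinning_report(tmap, None)
        assert report.min_thickness >= report.bulk_mean - 3 * max(report.bulk_sd, 1e-6)

    def test_wt_minimum_sits_at_the_gate(self):
        spec = build_bilayer_spec("DFM1_WT")
        tmap = thickness_map(generate_trajectory(spec, 11))
        report = thinning_report(tmap, spec.protein)
        defect = spec.defects[0]
        dist = math.hypot(
            report.min_location[0] - defect.center_xy[0],
            report.min_location[1] - defect.center_xy[1],
        )
        assert dist <= defect.sigma
        assert {report.nearest_helices[0][0], report.nearest_helices[1][0]} == {
            "TM2", "TM5",
        }
        assert report.min_thickness <= report.bulk_mean

    def test_deeper_defect_reports_smaller_minimum(self):
        base = build_bilayer_spec("DFM1_WT", {"n_frames": 10})
        mins = []
        for floor in (2.8, 2.2):
            spec = replace(
                base, defects=(replace(base.defects[0], floor_thickness=floor),)
            )
            tmap = thickness_map(generate_trajectory(spec, 5))
            mins.append(thinning_report(tmap, spec.protein).min_thickness)
        assert mins[1] < mins[0]

    def test_f107s_spares_the_luminal_leaflet(self):
        spec = build_bilayer_spec("DFM1_F107S", {"n_frames": 10})
        tmap = thickness_map(generate_trajectory(spec, 8))
        report = thinning_report(tmap, spec.protein)
        heights = report.per_leaflet_heights
        # cytosolic (upper) headgroups dip toward the midplane in the defect
        # zone; luminal (lower) stay at their bulk height
        upper_drop = heights["upper"]["bulk"] - heights["upper"]["defect_zone"]
        lower_drop = heights["lower"]["bulk"] - heights["lower"]["defect_zone"]
        assert upper_drop > 0.3
        assert abs(lower_drop) < 0.1

    def test_oversized_smoothing_rejected(self):
        spec = build_bilayer_spec("ER_BULK", {"n_frames": 1})
        tmap = thickness_map(generate_trajectory(spec, 0))
        with pytest.raises(ValueError, match="smoothing"):
            thinning_report(tmap, None, smoothing_sigma=100)


class TestCompareMaps:
    def test_self_difference_is_zero(self):
        spec = build_bilayer_spec("DFM1_WT", {"n_frames": 3})
        tmap = thickness_map(generate_trajectory(spec, 2))
        diff = compare_maps(tmap, tmap)
        assert diff.delta_min == 0.0
        assert diff.delta_bulk_mean == 0.0
        assert np.nanmax(np.abs(diff.delta_grid)) == 0.0

    def test_wt_is_thinner_than_quad(self):
        wt = build_bilayer_spec("DFM1_WT", {"n_frames": 10})
        quad = build_bilayer_spec("DFM1_QUAD", {"n_frames": 10})
        map_wt = thickness_map(generate_trajectory(wt, 6))
        map_quad = thickness_map(generate_trajectory(quad, 6))
        diff = compare_maps(map_wt, map_quad)
        assert diff.delta_min < 0

    def test_antisymmetry(self):
        a = thickness_map(
            generate_trajectory(build_bilayer_spec("DFM1_WT", {"n_frames": 3}), 1)
        )
        b = thickness_map(
            generate_trajectory(build_bilayer_spec("DFM1_QUAD", {"n_frames": 3}), 2)
        )
        ab, ba = compare_maps(a, b), compare_maps(b, a)
        assert ab.delta_min == pytest.approx(-ba.delta_min)
        assert ab.delta_bulk_mean == pytest.approx(-ba.delta_bulk_mean)
        np.testing.assert_allclose(ab.delta_grid, -ba.delta_grid)

    def test_incompatible_binning_rejected(self):
        traj = generate_trajectory(build_bilayer_spec("ER_BULK", {"n_frames": 1}), 0)
        with pytest.raises(ValueError, match="bin edges"):
            compare_maps(thickness_map(traj, bin_size=0.2),
                         thickness_map(traj, bin_size=0.4))
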