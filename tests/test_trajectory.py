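"""Two-helix trajectory analysis: geometry, kinetics, interface, membrane."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from tmdimer import trajectory as ta
from tmdimer.helices import (P75_SEQUENCE, P75_START, TRKA_SEQUENCE,
                             TRKA_START, build_ideal_helix)
from tmdimer.synthetic import TrajectorySimSpec, gen_trajectory
from tmdimer.trajio import TwoHelixTrajectory, minimum_image

from conftest import make_interface_fixture, make_two_helix_frame
from oracles import kabsch_rmsd, min_image_27


def _single_bead_traj(pos_a, pos_b, box):
    """Trajectories whose helices are one labelled bead each."""
    pos_a = np.asarray(pos_a, dtype=float).reshape(-1, 1, 3)
    pos_b = np.asarray(pos_b, dtype=float).reshape(-1, 1, 3)
    n = pos_a.shape[0]
    return TwoHelixTrajectory(
        pos_a, pos_b, np.array([276]), np.array([441]),
        np.array(["BB"]), np.array(["BB"]),
        box=np.tile(np.asarray(box, dtype=float), (n, 1)))


class TestInterhelixDistance:
    def test_coincident_reference_beads_give_zero(self):
        traj = _single_bead_traj([[5, 5, 5]], [[5, 5, 5]], [60, 60, 60])
        assert ta.interhelix_distance(traj)[0] == 0.0

    def test_minimum_image_across_the_boundary(self):
        traj = _single_bead_traj([[0, 0, 0]], [[59, 0, 0]], [60, 60, 60])
        assert ta.interhelix_distance(traj)[0] == pytest.approx(1.0)

    def test_rigid_translation_leaves_series_unchanged(self):
        rng = np.random.default_rng(0)
        pa = rng.uniform(0, 60, (20, 3))
        pb = rng.uniform(0, 60, (20, 3))
        t1 = _single_bead_traj(pa, pb, [60, 60, 60])
        shift = np.array([13.0, -7.0, 4.0])
        t2 = _single_bead_traj(pa + shift, pb + shift, [60, 60, 60])
        np.testing.assert_allclose(ta.interhelix_distance(t1),
                                   ta.interhelix_distance(t2), atol=1e-9)

    def test_absent_residue_rejected(self):
        traj = _single_bead_traj([[0, 0, 0]], [[1, 0, 0]], [60, 60, 60])
        with pytest.raises(ValueError, match="not present"):
            ta.interhelix_distance(traj, residue_a=999)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_minimum_image_matches_27_image_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        box = rng.uniform(10, 80, 3)
        # points inside the central box, so +/-1 images suffice for the oracle
        p1 = rng.uniform(0, 1, 3) * box
        p2 = rng.uniform(0, 1, 3) * box
        d = np.linalg.norm(minimum_image(p2 - p1, box))
        assert d == pytest.approx(min_image_27(p1, p2, box), abs=1e-9)


class TestDetectDimerization:
    def test_never_below_cutoff_returns_none(self):
        assert ta.detect_dimerization(np.full(500, 30.0), 10.0, 50) is None

    def test_step_association_detected_at_step_frame(self):
        series = np.concatenate([np.full(100, 55.0), np.full(200, 8.0)])
        assert ta.detect_dimerization(series, 10.0, 50) == 100

    def test_transient_dip_ignored_until_sustained(self):
        series = np.full(600, 55.0)
        series[100:110] = 8.0  # 10-frame dip, shorter than the dwell
        series[300:450] = 8.0  # sustained
        assert ta.detect_dimerization(series, 10.0, 50) == 300

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ta.detect_dimerization(np.array([]), 10.0, 50)


class TestContactMap:
    def test_distant_helices_give_all_zero_map(self):
        traj = make_two_helix_frame(offset=(80.0, 0.0, 0.0))
        cmap = ta.contact_occupancy(traj, cutoff=5.5)
        assert cmap.occupancy.max() == 0.0

    def test_single_touching_pair_has_unit_occupancy(self):
        traj = make_interface_fixture(iface_a=(266,), iface_b=(422,))
        cmap = ta.contact_occupancy(traj, cutoff=5.5)
        ia = np.flatnonzero(cmap.resids_a == 266)[0]
        ib = np.flatnonzero(cmap.resids_b == 422)[0]
        assert cmap.occupancy[ia, ib] == 1.0
        assert cmap.occupancy.sum() == 1.0

    def test_occupancy_monotone_in_cutoff(self):
        spec = TrajectorySimSpec(n_frames=60, seed=4, with_lipids=False,
                                 start_separation=12.0)
        traj = gen_trajectory(spec)
        occ_small = ta.contact_occupancy(traj, cutoff=4.0).occupancy
        occ_large = ta.contact_occupancy(traj, cutoff=8.0).occupancy
        assert (occ_large >= occ_small - 1e-12).all()

    def test_empty_frame_range_rejected(self):
        traj = make_two_helix_frame()
        with pytest.raises(ValueError):
            ta.contact_occupancy(traj, frame_range=(1, 1))


class TestInterfaceProfile:
    def test_p75_motif_on_constructed_dimer(self, interface_fixture):
        cmap = ta.contact_occupancy(interface_fixture, cutoff=5.5)
        prof = ta.interface_profile(cmap, helix="a")
        assert prof.motif == "C257 S258 xx A261 A262 xx V265 G266 xx A269"

    def test_trka_motif_on_constructed_dimer(self, interface_fixture):
        cmap = ta.contact_occupancy(interface_fixture, cutoff=5.5)
        prof = ta.interface_profile(cmap, helix="b")
        assert prof.motif == "V418 xxx V422 xxx V426 F427 xx L430"

    def test_interface_residues_subset_of_construct(self, interface_fixture):
        cmap = ta.contact_occupancy(interface_fixture, cutoff=5.5)
        prof = ta.interface_profile(cmap, helix="a")
        assert set(prof.interface_resids) <= set(
            range(P75_START, P75_START + len(P75_SEQUENCE)))

    def test_all_zero_map_gives_empty_motif(self):
        traj = make_two_helix_frame(offset=(80.0, 0.0, 0.0))
        cmap = ta.contact_occupancy(traj, cutoff=5.5)
        prof = ta.interface_profile(cmap, helix="a")
        assert prof.motif == ""
        assert prof.interface_resids.size == 0


class TestCrossingAngle:
    def test_identical_parallel_helices_are_at_zero(self):
        la, ra, na = build_ideal_helix(P75_SEQUENCE, P75_START)
        traj = TwoHelixTrajectory(
            la[None], (la + np.array([10.0, 0, 0]))[None], ra, ra, na, na,
            box=np.array([[200.0, 200.0, 200.0]]),
            seq_b=P75_SEQUENCE, start_b=P75_START)
        assert ta.crossing_angle(traj) == pytest.approx(0.0, abs=1e-4)

    def test_twenty_degree_tilt_recovered(self):
        rot = Rotation.from_euler("x", 20, degrees=True)
        traj = make_two_helix_frame(rotate_b=rot)
        assert abs(ta.crossing_angle(traj)) == pytest.approx(20.0, abs=0.5)

    def test_antiparallel_helices_near_180(self):
        rot = Rotation.from_euler("x", 180, degrees=True)
        traj = make_two_helix_frame(rotate_b=rot)
        assert abs(ta.crossing_angle(traj)) == pytest.approx(180.0, abs=1.0)

    def test_degenerate_axis_rejected(self):
        coords = np.zeros((1, 4, 3))  # all beads coincide
        traj = TwoHelixTrajectory(
            coords, coords + 5.0, np.arange(245, 249), np.arange(410, 414),
            np.array(["BB"] * 4), np.array(["BB"] * 4),
            box=np.array([[50.0, 50.0, 50.0]]))
        with pytest.raises(ValueError, match="degenerate"):
            ta.crossing_angle(traj)


class TestEndpointAzimuth:
    def _place_partner(self, azimuth_deg: float) -> TwoHelixTrajectory:
        """Partner centred along the given azimuth from A's first residue."""
        la, ra, na = build_ideal_helix(P75_SEQUENCE, P75_START)
        lb, rb, nb = build_ideal_helix(TRKA_SEQUENCE, TRKA_START)
        # A's first residue (phase 0) points along +x
        ang = np.deg2rad(azimuth_deg)
        offset = 12.0 * np.array([np.cos(ang), np.sin(ang), 0.0])
        return TwoHelixTrajectory(la[None], (lb + offset)[None], ra, rb,
                                  na, nb, box=np.array([[200.0] * 3]))

    def test_partner_along_reference_direction_is_zero(self):
        # finite-helix centroids sit ~0.1 A off the geometric axis, so the
        # azimuth carries a sub-degree systematic offset
        traj = self._place_partner(0.0)
        pose = ta.endpoint_azimuth(traj, target="a", partner="b",
                                   reference_residue=245)
        assert pose.azimuth == pytest.approx(0.0, abs=1.0) or \
            pose.azimuth == pytest.approx(360.0, abs=1.0)

    def test_quarter_turn_measured(self):
        pose = ta.endpoint_azimuth(self._place_partner(90.0), target="a",
                                   partner="b", reference_residue=245)
        assert pose.azimuth == pytest.approx(90.0, abs=1.0)

    def test_sector_assignment(self):
        sectors = [("s1", (0.0, 120.0)), ("s2", (120.0, 240.0)),
                   ("s3", (240.0, 360.0))]
        pose = ta.endpoint_azimuth(self._place_partner(200.0), target="a",
                                   partner="b", reference_residue=245,
                                   sectors=sectors)
        assert pose.sector == "s2"

    def test_uniform_placements_spread_evenly_over_sectors(self):
        sectors = [("s1", (0.0, 120.0)), ("s2", (120.0, 240.0)),
                   ("s3", (240.0, 360.0))]
        rng = np.random.default_rng(11)
        counts = {"s1": 0, "s2": 0, "s3": 0}
        n_rounds, n_place = 100, 12
        for _ in range(n_rounds):
            for az in rng.uniform(0, 360, n_place):
                pose = ta.endpoint_azimuth(self._place_partner(az),
                                           target="a", partner="b",
                                           reference_residue=245,
                                           sectors=sectors)
                counts[pose.sector] += 1
        means = {k: v / n_rounds for k, v in counts.items()}
        for v in means.values():
            assert v == pytest.approx(4.0, abs=0.5)

    def test_single_patch_endpoints_restricted_patchless_distributed(self):
        # a single attractive patch funnels final poses into one azimuthal
        # sector; an isotropic (patchless) well leaves them spread out
        def sector_counts(patch):
            counts = np.zeros(3, dtype=int)
            for seed in range(12):
                traj = gen_trajectory(TrajectorySimSpec(
                    n_frames=5000, seed=seed, with_lipids=False,
                    patch_halfwidth=patch))
                pose = ta.endpoint_azimuth(traj, target="a", partner="b",
                                           reference_residue=245)
                counts[int(pose.azimuth // 120.0) % 3] += 1
            return counts

        assert sector_counts(40.0).max() >= 9
        assert sector_counts(None).max() <= 7

    def test_partner_on_axis_rejected(self):
        la, ra, na = build_ideal_helix(P75_SEQUENCE, P75_START)
        traj = TwoHelixTrajectory(la[None], la[None].copy(), ra, ra, na, na,
                                  box=np.array([[200.0] * 3]),
                                  seq_b=P75_SEQUENCE, start_b=P75_START)
        with pytest.raises(ValueError, match="centred"):
            ta.endpoint_azimuth(traj, target="a", partner="b",
                                reference_residue=245)


class TestClusterEndpoints:
    def test_identical_models_form_one_zero_rmsd_cluster(self):
        la, _, _ = build_ideal_helix(P75_SEQUENCE, P75_START)
        res = ta.cluster_endpoints([la, la.copy(), la.copy()], cut=1.0)
        assert len(res.cluster_sizes) == 1
        assert res.cluster_avg_rmsd[res.largest] == 0.0

    def test_two_conformations_split_at_cut(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 3, (30, 3))
        other = base + np.array([0.0, 0.0, 0.0])
        other = base + rng.normal(0, 4, (30, 3))  # a genuinely different shape
        models = [base, base.copy(), base.copy(), other, other.copy(),
                  other.copy()]
        d = ta.pairwise_rmsd(base, other)
        res = ta.cluster_endpoints(models, cut=d / 2)
        assert sorted(res.cluster_sizes.values()) == [3, 3]

    def test_rmsd_matches_independent_kabsch(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            a = rng.normal(0, 5, (25, 3))
            b = a + rng.normal(0, 0.8, (25, 3))
            rot = Rotation.random(random_state=int(rng.integers(2 ** 16)))
            b = rot.apply(b) + rng.normal(0, 10, 3)
            assert ta.pairwise_rmsd(a, b) == pytest.approx(
                kabsch_rmsd(a, b), rel=1e-9, abs=1e-12)

    def test_superposition_removes_rigid_motion(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0, 5, (40, 3))
        rot = Rotation.from_euler("zyx", [40, 10, -25], degrees=True)
        b = rot.apply(a) + np.array([3.0, -8.0, 1.0])
        assert ta.pairwise_rmsd(a, b) == pytest.approx(0.0, abs=1e-9)

    def test_jittered_models_average_rmsd_matches_expectation(self):
        # two clouds jittered with iid Gaussian sigma per coordinate:
        # empirical mean pairwise RMSD vs the independent Kabsch oracle
        rng = np.random.default_rng(31)
        base = rng.normal(0, 5, (50, 3))
        sigma = 0.6
        ours, oracle = [], []
        for _ in range(200):
            m1 = base + sigma * rng.standard_normal(base.shape)
            m2 = base + sigma * rng.standard_normal(base.shape)
            ours.append(ta.pairwise_rmsd(m1, m2))
            oracle.append(kabsch_rmsd(m1, m2))
        assert np.mean(ours) == pytest.approx(np.mean(oracle), rel=0.05)

    def test_selection_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ta.pairwise_rmsd(np.zeros((5, 3)), np.zeros((6, 3)))


class TestMembraneDescriptors:
    @staticmethod
    def _membrane_traj(jitter=0.0, seed=0, apl=63.2):
        return gen_trajectory(TrajectorySimSpec(
            n_frames=2, seed=seed, jitter_sd=jitter, lipid_apl=apl))

    def test_hexagonal_lattice_area_is_exact(self):
        traj = self._membrane_traj()
        a = np.sqrt(63.2 / (np.sqrt(3) / 2))
        assert ta.area_per_lipid(traj, frame=0) == pytest.approx(
            np.sqrt(3) / 2 * a * a, rel=1e-9)

    def test_square_lattice_area_is_exact(self):
        n, a = 8, 8.0
        xy = np.stack(np.meshgrid(np.arange(n) * a, np.arange(n) * a),
                      axis=-1).reshape(-1, 2)
        areas = ta.voronoi_cell_areas(xy, np.array([n * a, n * a]))
        np.testing.assert_allclose(areas, a * a, rtol=1e-9)

    def test_cell_areas_tile_the_box(self):
        rng = np.random.default_rng(3)
        box = np.array([70.0, 55.0])
        pts = rng.uniform(0, 1, (40, 2)) * box
        areas = ta.voronoi_cell_areas(pts, box)
        assert areas.sum() == pytest.approx(box.prod(), rel=1e-6)

    def test_degenerate_colinear_lipids_rejected(self):
        pts = np.column_stack([np.linspace(1, 9, 5), np.full(5, 2.0)])
        with pytest.raises(ValueError):
            ta.voronoi_cell_areas(pts, np.array([10.0, 10.0]))

    def test_thickness_between_reference_planes(self):
        traj = self._membrane_traj()
        assert ta.bilayer_thickness(traj, 0, "glycerol") == pytest.approx(34.8)
        assert ta.bilayer_thickness(traj, 0, "phosphate") == pytest.approx(38.4)

    def test_thickness_invariant_under_z_shift(self):
        traj = self._membrane_traj(jitter=0.3, seed=9)
        t1 = ta.bilayer_thickness(traj, 0, "glycerol")
        traj.lipids = traj.lipids + np.array([0.0, 0.0, 5.0])
        assert ta.bilayer_thickness(traj, 0, "glycerol") == pytest.approx(t1)

    def test_density_profile_conserves_total_electrons(self):
        traj = self._membrane_traj(jitter=0.4, seed=2)
        prof = ta.electron_density_profile(traj, bins=64)
        integral = prof.density.sum() * prof.bin_width * prof.area
        assert integral == pytest.approx(traj.electron_weight.sum(), rel=1e-9)

    def test_density_profile_peaks_at_reference_planes(self):
        traj = self._membrane_traj()
        prof = ta.electron_density_profile(traj, bins=90)
        occupied = prof.z_centers[prof.density > 0]
        for plane in (-19.2, -17.4, 17.4, 19.2):
            assert np.min(np.abs(occupied - plane)) < prof.bin_width

    def test_zero_bins_rejected(self):
        traj = self._membrane_traj()
        with pytest.raises(ValueError):
            ta.electron_density_profile(traj, bins=0)


class TestRigidMotionInvariance:
    def test_geometry_invariant_under_global_z_rotation_and_translation(self):
        spec = TrajectorySimSpec(n_frames=5, seed=8, with_lipids=False,
                                 start_separation=12.0)
        traj = gen_trajectory(spec)
        angle0 = ta.crossing_angle(traj, frame=0)
        d0 = ta.interhelix_distance(traj)
        rot = Rotation.from_euler("z", 35, degrees=True)
        center = traj.box[0] / 2
        for arr in (traj.coords_a, traj.coords_b):
            arr[:] = rot.apply((arr - center).reshape(-1, 3)).reshape(arr.shape) + center
        assert ta.crossing_angle(traj, frame=0) == pytest.approx(angle0, abs=1e-6)
        np.testing.assert_allclose(ta.interhelix_distance(traj), d0, atol=1e-6)
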