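"""Base-pair frames, helical axis and curvilinear helicoidal mapping."""

import numpy as np
import pytest

import groovetherm as gt
from groovetherm.helix import RegionSpec


class TestBasePairFrames:
    def test_triads_orthonormal_right_handed(self, seq1_frames):
        T = seq1_frames.triads
        eye = np.einsum("fkij,fkil->fkjl", T, T)
        assert np.allclose(eye, np.eye(3), atol=1e-6)
        assert np.allclose(np.linalg.det(T), 1.0, atol=1e-6)

    def test_successive_origins_separated_by_rise(self, seq1_frames):
        d = np.linalg.norm(np.diff(seq1_frames.origins[0], axis=0), axis=1)
        assert np.allclose(d, 3.38, atol=1e-9)

    def test_missing_c1_reports_residue(self, seq1_traj):
        names = list(seq1_traj.names)
        idx = seq1_traj.atom_index(5, "C1'")
        names[idx] = "XX"
        broken = gt.Trajectory(seq1_traj.coords, names, seq1_traj.resids,
                               seq1_traj.resnames, seq1_traj.segids)
        with pytest.raises(ValueError, match="residue 5"):
            gt.compute_bp_frames(broken, seq1_traj.meta["pairing"])


class TestHelicalAxis:
    def test_straight_duplex_axis_on_z_line(self, seq1_frames):
        axis = gt.fit_helical_axis(seq1_frames)
        assert np.abs(axis.points[:, :2]).max() < 1e-3
        assert np.all(np.diff(axis.arclength) > 0)
        assert np.allclose(np.linalg.norm(axis.tangents, axis=1), 1.0)

    def test_bent_duplex_recovers_arc_curvature(self, seq1_traj):
        """Bend the fixture origins onto a circular arc of radius 100 Å and
        check the discrete curvature of the fitted axis."""
        radius = 100.0
        traj = seq1_traj
        coords = traj.coords.copy()
        # map z -> arc of given radius in the x-z plane, preserving arclength
        z = coords[..., 2].copy()
        phi = z / radius
        coords[..., 0] += radius * (1 - np.cos(phi))
        coords[..., 2] = radius * np.sin(phi)
        bent = gt.Trajectory(coords, traj.names, traj.resids, traj.resnames,
                             traj.segids)
        frames = gt.compute_bp_frames(bent, traj.meta["pairing"])
        axis = gt.fit_helical_axis(frames)
        # three-point circumradius at interior points
        p = axis.points
        curv = []
        for i in range(1, len(p) - 1):
            a, b, c = p[i - 1], p[i], p[i + 1]
            ab, bc, ca = b - a, c - b, a - c
            area2 = np.linalg.norm(np.cross(ab, bc))
            curv.append(area2 / (np.linalg.norm(ab) * np.linalg.norm(bc)
                                 * np.linalg.norm(ca)))
        curvature = 2 * np.median(curv)
        assert curvature == pytest.approx(1.0 / radius, rel=0.10)

    def test_too_few_bp_rejected(self, seq1_frames):
        from groovetherm.helix import BasePairFrameSeries
        small = BasePairFrameSeries(seq1_frames.origins[:, :3],
                                    seq1_frames.triads[:, :3])
        with pytest.raises(ValueError):
            gt.fit_helical_axis(small)


class TestHelicoidalMapping:
    def test_round_trip_on_straight_axis(self):
        axis = gt.straight_axis(21, 3.38)
        D = np.array([10.0, 3.0, 55.0])
        R = np.array([8.0, 2.0, 15.0])
        A = np.array([90.0, 200.0, 359.0])
        pos = gt.helicoidal_to_cartesian(axis, D, R, A)
        hc = gt.to_helicoidal(axis, pos)
        assert np.allclose(hc.D, D, atol=1e-6)
        assert np.allclose(hc.R, R, atol=1e-6)
        assert np.allclose(hc.A, A, atol=1e-6)

    def test_particle_on_axis_gets_sentinel(self):
        axis = gt.straight_axis(10, 3.38)
        hc = gt.to_helicoidal(axis, np.array([[0.0, 0.0, 10.0]]))
        assert hc.R[0] == 0.0 and hc.A[0] == 0.0

    def test_round_trip_on_gently_curved_axis(self):
        radius = 200.0
        s = np.arange(21) * 3.38
        phi = s / radius
        pts = np.column_stack([radius * (1 - np.cos(phi)), np.zeros_like(s),
                               radius * np.sin(phi)])
        tan = np.column_stack([np.sin(phi), np.zeros_like(s), np.cos(phi)])
        ref = np.column_stack([np.cos(phi), np.zeros_like(s), -np.sin(phi)])
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(pts, axis=0), axis=1))])
        axis = gt.HelicalAxis(pts, tan, ref, arc)
        D = np.array([20.0, 40.0])
        R = np.array([5.0, 9.0])
        A = np.array([60.0, 250.0])
        hc = gt.to_helicoidal(axis, gt.helicoidal_to_cartesian(axis, D, R, A))
        assert np.allclose(hc.D, D, atol=0.1)
        assert np.allclose(hc.R, R, atol=0.1)
        assert np.allclose(hc.A, A, atol=1.0)

    def test_groove_markers_calibrated(self, seq1_traj, seq1_frames):
        """Minor-groove probes map inside [33, 147) and major-groove probes
        outside, at every bp level."""
        axis = gt.fit_helical_axis(seq1_frames)
        minor = seq1_traj.coords[0][seq1_traj.select(name="MIN")]
        major = seq1_traj.coords[0][seq1_traj.select(name="MAJ")]
        a_min = gt.to_helicoidal(axis, minor).A
        a_maj = gt.to_helicoidal(axis, major).A
        assert np.all((a_min >= 33.0) & (a_min < 147.0))
        assert np.all((a_maj < 33.0) | (a_maj >= 147.0))


class TestRegions:
    @pytest.mark.parametrize("R,A,expected", [
        (8.0, 90.0, "minor_inner"),
        (15.0, 200.0, "major_outer"),
        (25.0, 90.0, "bulk"),
        (10.25, 33.0, "minor_inner"),    # half-open boundary joins minor
        (10.25, 147.0, "major_inner"),   # upper edge belongs to major
        (10.26, 146.9, "minor_outer"),
        (20.5, 200.0, "major_outer"),
        (20.51, 200.0, "bulk"),
    ])
    def test_boundary_assignments(self, R, A, expected):
        hc = gt.HelicoidalCoords(np.array([5.0]), np.array([R]),
                                 np.array([A]))
        assert gt.assign_region(hc, RegionSpec(), (0.0, 10.0))[0] == expected

    def test_outside_duplex_span_is_bulk(self):
        hc = gt.HelicoidalCoords(np.array([-1.0, 11.0]), np.array([5.0, 5.0]),
                                 np.array([90.0, 90.0]))
        assert list(gt.assign_region(hc, RegionSpec(), (0.0, 10.0))) \
            == ["bulk", "bulk"]

    def test_labels_partition_space(self, rng):
        hc = gt.HelicoidalCoords(rng.uniform(-5, 70, 3000),
                                 rng.uniform(0, 40, 3000),
                                 rng.uniform(0, 360, 3000))
        labels = gt.assign_region(hc, RegionSpec(), (0.0, 64.0))
        counts = {r: int(np.sum(labels == r)) for r in
                  ("minor_inner", "major_inner", "minor_outer",
                   "major_outer", "bulk")}
        assert sum(counts.values()) == 3000


class TestDensityMap:
    def _frames_single_ion(self, n=25):
        # one ion pinned in a 10x10x10 Å curvilinear cell, every frame
        hc = gt.HelicoidalCoords(np.array([5.0]), np.array([5.0]),
                                 np.array([90.0]))
        return [hc] * n

    def test_one_ion_per_cubic_nm_is_1p661_molar(self):
        # cell: D in [0,10], R in [0, 10], A spanning 114.59...deg so that
        # the curvilinear volume R_mid*dR*dA*dD equals 1000 A^3
        da = np.degrees(1000.0 / (10.0 * 5.0 * 10.0))
        dmap = gt.density_map(self._frames_single_ion(),
                              np.array([0.0, 10.0]),
                              np.array([80.0, 80.0 + da]),
                              (0.0, 10.0))
        assert dmap.molarity[0, 0] == pytest.approx(1.661, abs=5e-3)

    def test_count_volume_conservation(self, rng):
        """Sum over cells of molarity*volume*N_A equals the mean particle
        count inside the grid."""
        frames = [gt.HelicoidalCoords(rng.uniform(0, 60, 200),
                                      rng.uniform(0, 20, 200),
                                      rng.uniform(0, 360, 200))
                  for _ in range(10)]
        r_edges = np.linspace(0, 20.5, 6)
        a_edges = np.linspace(0, 360, 13)
        dmap = gt.density_map(frames, r_edges, a_edges, (0.0, 60.0))
        r_mid = 0.5 * (r_edges[:-1] + r_edges[1:])
        vol = 60.0 * r_mid[:, None] * np.diff(r_edges)[:, None] \
            * np.radians(np.diff(a_edges))[None, :]
        total = np.sum(dmap.molarity * vol) * gt.N_AVOGADRO * 1e-27
        mean_inside = np.mean([
            np.sum((f.D >= 0) & (f.D <= 60) & (f.R <= 20.5)) for f in frames])
        assert total == pytest.approx(mean_inside, rel=1e-6)

    def test_empty_region_zero(self):
        dmap = gt.density_map(self._frames_single_ion(),
                              np.array([15.0, 20.0]), np.array([0.0, 30.0]),
                              (0.0, 10.0))
        assert dmap.molarity[0, 0] == 0.0

    def test_bulk_ratio_requires_bulk(self):
        dmap = gt.density_map(self._frames_single_ion(),
                              np.array([0.0, 10.0]), np.array([0.0, 180.0]),
                              (0.0, 10.0))
        with pytest.raises(ValueError):
            gt.bulk_ratio(dmap)

    def test_uniform_cloud_ratio_near_one(self):
        spec = gt.IonCloudSpec(
            region_molarity={r: 0.5 for r in ("minor_inner", "major_inner",
                                              "minor_outer", "major_outer")},
            bulk_molarity=0.5, n_frames=300, seed=12)
        cloud = gt.gen_ion_cloud(spec)
        frames = [gt.to_helicoidal(cloud.axis, f) for f in cloud.frames]
        rspec = spec.region_spec
        dmap = gt.density_map(frames, np.array([0.0, rspec.inner_R,
                                                rspec.cutoff_R]),
                              np.linspace(33.0, 393.0, 4),
                              (0.0, cloud.axis.length),
                              float(np.prod(cloud.box)), rspec)
        _, max_ratio = gt.bulk_ratio(dmap)
        assert max_ratio == pytest.approx(1.0, abs=0.1)


class TestConvergence:
    def _frames_poisson(self, lam, n, seed):
        rng = np.random.default_rng(seed)
        frames = []
        for _ in range(n):
            k = rng.poisson(lam)
            frames.append(gt.HelicoidalCoords(
                rng.uniform(0, 60, k), rng.uniform(0, 8, k),
                rng.uniform(33, 147, k)))
        return frames

    def test_stationary_occupancy_converges(self):
        frames = self._frames_poisson(5.0, 400, 13)
        res = gt.convergence_series(frames, "minor_inner",
                                    d_span=(0.0, 60.0))
        se = 3 * np.sqrt(5.0 / 400)
        assert res.running_mean[-1] == pytest.approx(5.0, abs=se)
        assert not res.drift_flag

    def test_constant_occupancy_flat(self):
        hc = gt.HelicoidalCoords(np.array([5.0, 6.0]), np.array([4.0, 4.0]),
                                 np.array([90.0, 100.0]))
        res = gt.convergence_series([hc] * 50, "minor_inner",
                                    d_span=(0.0, 60.0))
        assert np.allclose(res.running_mean, 2.0)
        assert res.block_se == 0.0

    def test_drift_is_flagged(self):
        rng = np.random.default_rng(14)
        frames = []
        for i in range(200):
            k = rng.poisson(2.0 + 0.05 * i)
            frames.append(gt.HelicoidalCoords(
                rng.uniform(0, 60, k), rng.uniform(0, 8, k),
                rng.uniform(33, 147, k)))
        res = gt.convergence_series(frames, "minor_inner",
                                    d_span=(0.0, 60.0))
        assert res.drift_flag

    def test_too_few_frames_rejected(self):
        hc = gt.HelicoidalCoords(np.array([1.0]), np.array([1.0]),
                                 np.array([90.0]))
        with pytest.raises(ValueError):
            gt.convergence_series([hc] * 5, "minor_inner")


class TestRadialDistribution:
    def test_ring_of_ions_peaks_at_its_radius(self):
        hc = gt.HelicoidalCoords(np.linspace(1, 59, 50), np.full(50, 8.0),
                                 np.full(50, 90.0))
        prof = gt.radial_distribution([hc] * 5, 1.0, (0.0, 60.0))
        peak = prof["r_mid"][np.argmax(prof["minor"])]
        assert peak == pytest.approx(8.5, abs=0.51)
        assert prof["major"].max() == 0.0

    def test_no_ions_all_zero(self):
        hc = gt.HelicoidalCoords(np.empty(0), np.empty(0), np.empty(0))
        prof = gt.radial_distribution([hc], 1.0, (0.0, 60.0))
        assert np.all(prof["all"] == 0.0)

    def test_invalid_dr_rejected(self):
        hc = gt.HelicoidalCoords(np.array([1.0]), np.array([1.0]),
                                 np.array([90.0]))
        with pytest.raises(ValueError):
            gt.radial_distribution([hc], 0.0, (0.0, 60.0))
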