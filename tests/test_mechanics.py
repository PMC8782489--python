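"""Helical-parameter mechanics: extraction, KL, stiffness, grooves, ED."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import groovetherm as gt


def _rigid(traj, seed=0):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
    t = rng.uniform(-50, 50, 3)
    return traj.transformed(R, t)


class TestHelParExtract:
    def test_ideal_fixture_exact(self, seq1_frames):
        hp = gt.helpar_extract(seq1_frames)
        assert np.allclose(hp.get("twist"), 36.0, atol=1e-6)
        assert np.allclose(hp.get("rise"), 3.38, atol=1e-6)
        for name in ("shift", "slide", "tilt", "roll"):
            assert np.abs(hp.get(name)).max() < 1e-6
        for name in ("shear", "stretch", "stagger", "buckle", "propeller",
                     "opening"):
            assert np.abs(hp.get(name)).max() < 1e-6

    def test_rigid_motion_invariance(self, seq1_traj, seq1_pairing,
                                     seq1_frames):
        moved = _rigid(seq1_traj, seed=21)
        hp0 = gt.helpar_extract(seq1_frames)
        hp1 = gt.helpar_extract(gt.compute_bp_frames(moved, seq1_pairing))
        assert np.abs(hp1.step_values - hp0.step_values).max() < 1e-8
        assert np.abs(hp1.bp_values - hp0.bp_values).max() < 1e-8

    def test_jittered_means_recover_ideal(self):
        traj = gt.gen_ideal_duplex_traj("ACGTACGTAC", n_frames=2000,
                                        jitter_sd=0.05, seed=22)
        frames = gt.compute_bp_frames(traj, traj.meta["pairing"])
        hp = gt.helpar_extract(frames)
        tw = hp.get("twist")
        se = tw.std(axis=0) / np.sqrt(len(tw))
        assert np.all(np.abs(tw.mean(axis=0) - 36.0) < 4 * se + 1e-3)

    def test_single_bp_rejected(self, seq1_frames):
        from groovetherm.helix import BasePairFrameSeries
        one = BasePairFrameSeries(seq1_frames.origins[:, :1],
                                  seq1_frames.triads[:, :1])
        with pytest.raises(ValueError):
            gt.helpar_extract(one)


class TestKLDivergence:
    def test_self_divergence_zero(self, rng):
        a = rng.normal(0, 1, 5000)
        assert gt.kl_divergence(a, a) < 1e-12

    def test_shifted_gaussians_match_closed_form(self):
        r = np.random.default_rng(23)
        a = r.normal(0, 1, 100_000)
        b = r.normal(1, 1, 100_000)
        assert gt.kl_divergence(a, b) == pytest.approx(0.5, abs=0.05)

    def test_disjoint_supports_finite(self):
        a = np.linspace(0, 1, 500)
        b = np.linspace(10, 11, 500)
        d = gt.kl_divergence(a, b)
        assert np.isfinite(d) and d > 5.0

    def test_non_negative(self, rng):
        for _ in range(10):
            a = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), 500)
            b = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), 500)
            assert gt.kl_divergence(a, b) >= 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gt.kl_divergence([], [1.0])


class TestStiffness:
    def test_one_dimensional_kT_over_variance(self):
        r = np.random.default_rng(24)
        vals = r.normal(0.0, 0.5, (50_000, 1))  # variance 0.25 A^2
        mat = gt.stiffness_from_covariance(vals, 300.0)
        assert mat.K[0, 0] == pytest.approx(9.977, rel=0.02)

    def test_recovery_of_generating_matrix(self):
        rng = np.random.default_rng(25)
        A = rng.standard_normal((6, 6))
        K = A @ A.T + 6 * np.eye(6)
        spec = gt.StiffnessSpec(K=K, means=np.zeros(6), n_frames=100_000,
                                seed=26)
        mats = gt.stiffness_from_covariance(gt.gen_helpar_traj(spec), 300.0)
        err = np.linalg.norm(mats[0].K - K) / np.linalg.norm(K)
        assert err < 0.05

    def test_temperature_linearity(self):
        r = np.random.default_rng(27)
        vals = r.normal(0.0, 1.0, (20_000, 2))
        a = gt.stiffness_from_covariance(vals, 300.0)
        b = gt.stiffness_from_covariance(vals, 600.0)
        assert np.allclose(b.K, 2 * a.K)

    def test_singular_covariance_flagged(self):
        base = np.random.default_rng(28).normal(0, 1, (500, 1))
        vals = np.hstack([base, 2 * base])  # perfectly collinear
        with pytest.warns(UserWarning):
            mat = gt.stiffness_from_covariance(vals, 300.0)
        assert mat.pseudo_inverse

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            gt.stiffness_from_covariance(np.zeros((30, 6)), 300.0)


class TestOverallStiffness:
    def _mats(self, diags):
        return [gt.StiffnessMatrix(np.diag(d), f"s{i}")
                for i, d in enumerate(diags)]

    def test_identity_diagonals(self):
        res = gt.overall_stiffness(self._mats([np.ones(6)] * 3))
        assert np.allclose(res.per_step_combined, 1.0)
        assert res.molecule_combined == 1.0

    def test_molecule_mean_of_steps(self):
        res = gt.overall_stiffness(self._mats([np.full(6, 2.0),
                                               np.full(6, 4.0)]))
        assert res.molecule_combined == pytest.approx(3.0)

    def test_scaling_linearity(self):
        diags = [np.arange(1.0, 7.0), np.arange(2.0, 8.0)]
        a = gt.overall_stiffness(self._mats(diags))
        b = gt.overall_stiffness(self._mats([2 * d for d in diags]))
        assert b.molecule_combined == pytest.approx(2 * a.molecule_combined)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gt.overall_stiffness([])


class TestGrooveWidths:
    def test_noiseless_fixture_deterministic(self):
        traj = gt.gen_ideal_duplex_traj(gt.SEQ1_AT_RICH, n_frames=3)
        gw = gt.groove_widths(traj, traj.meta["pairing"])
        assert np.nanmax(np.abs(gw["minor"] - gw["minor"][0])) < 1e-6
        assert np.isfinite(gw["minor_mean"]) and np.isfinite(gw["major_mean"])
        assert gw["major_mean"] > gw["minor_mean"]

    def test_radial_compression_scales_uncorrected_distance(self, seq1_traj,
                                                            seq1_pairing):
        a = gt.groove_widths(seq1_traj, seq1_pairing)
        squeezed = gt.Trajectory(seq1_traj.coords * 0.95, seq1_traj.names,
                                 seq1_traj.resids, seq1_traj.resnames,
                                 seq1_traj.segids)
        b = gt.groove_widths(squeezed, seq1_pairing)
        assert b["minor_mean"] + 5.8 == pytest.approx(
            0.95 * (a["minor_mean"] + 5.8), rel=1e-9)

    def test_rigid_rotation_invariance(self, seq1_traj, seq1_pairing):
        a = gt.groove_widths(seq1_traj, seq1_pairing)
        b = gt.groove_widths(_rigid(seq1_traj, seed=29), seq1_pairing)
        assert b["minor_mean"] == pytest.approx(a["minor_mean"], abs=1e-9)
        assert b["major_mean"] == pytest.approx(a["major_mean"], abs=1e-9)


class TestHBonds:
    def test_separated_strands_have_none(self, seq1_traj, seq1_pairing):
        coords = seq1_traj.coords.copy()
        crick = np.array([s == "C" for s in seq1_traj.segids])
        coords[:, crick, :] += np.array([20.0, 0.0, 0.0])
        apart = gt.Trajectory(coords, seq1_traj.names, seq1_traj.resids,
                              seq1_traj.resnames, seq1_traj.segids)
        assert gt.count_hbonds(apart, seq1_pairing)["mean"] == 0.0

    def test_tail_window_frame_count(self):
        traj = gt.gen_ideal_duplex_traj("ACGTACGT", n_frames=1000,
                                        jitter_sd=0.01, seed=30)
        hb = gt.count_hbonds(traj, traj.meta["pairing"], tail_window=0.4)
        assert hb["n_frames_used"] == 400
        assert len(hb["per_frame"]) == 400

    def test_unknown_residue_rejected(self, seq1_traj, seq1_pairing):
        resnames = ["XYZ"] * seq1_traj.n_atoms
        bad = gt.Trajectory(seq1_traj.coords, seq1_traj.names,
                            seq1_traj.resids, resnames, seq1_traj.segids)
        with pytest.raises(ValueError, match="unknown residue"):
            gt.count_hbonds(bad, seq1_pairing)


class TestEssentialDynamics:
    def test_direct_covariance_spectrum(self):
        C = np.diag([4.0, 1.0, 0.0, 0.0])
        res = gt.ed_from_covariance(C, k=10)
        assert np.allclose(res.eigenvalues, [4.0, 1.0, 0.0, 0.0])
        assert res.sum_first_k == pytest.approx(5.0)
        assert res.trace == pytest.approx(np.trace(C))

    def test_identical_trajectories_zero_sum_difference(self):
        traj = gt.gen_ideal_duplex_traj("ACGTACGT", n_frames=50,
                                        jitter_sd=0.1, seed=31)
        a = gt.ed_eigen(traj.coords, traj.coords[0])
        b = gt.ed_eigen(traj.coords.copy(), traj.coords[0])
        assert gt.ed_sum_difference(a, b) == 0.0

    def test_known_covariance_partial_trace(self):
        """Gaussian displacements with a known spectrum: the sum of the
        first 10 eigenvalues approaches the analytic partial trace."""
        r = np.random.default_rng(32)
        n_atoms = 10
        evals = np.concatenate([np.linspace(5.0, 1.0, 10),
                                np.full(3 * n_atoms - 10, 0.05)])
        Q = np.linalg.qr(r.standard_normal((3 * n_atoms,) * 2))[0]
        L = Q @ np.diag(np.sqrt(evals))
        disp = r.standard_normal((100_000, 3 * n_atoms)) @ L.T
        coords = disp.reshape(-1, n_atoms, 3)
        res = gt.ed_eigen(coords, np.zeros((n_atoms, 3)), k=10, align=False)
        assert res.sum_first_k == pytest.approx(evals[:10].sum(), rel=0.05)

    def test_eigenvalue_sum_equals_trace(self):
        traj = gt.gen_ideal_duplex_traj("ACGTACGT", n_frames=60,
                                        jitter_sd=0.2, seed=33)
        res = gt.ed_eigen(traj.coords, traj.coords[0])
        from groovetherm.mechanics import kabsch_superpose
        x = kabsch_superpose(traj.coords, traj.coords[0])
        C = np.cov(x.reshape(x.shape[0], -1), rowvar=False)
        assert res.trace == pytest.approx(np.trace(C), abs=1e-8)

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError):
            gt.ed_eigen(np.zeros((5, 4, 3)), np.zeros((4, 3)), k=10)


class TestCovarianceOverlap:
    def test_identical_subspaces(self):
        C = np.diag([5.0, 4.0, 3.0, 2.0, 1.0])
        assert gt.covariance_overlap(C, C, k=3) == pytest.approx(1.0)

    def test_orthogonal_subspaces(self):
        a = np.diag([5.0, 4.0, 0.0, 0.0])
        b = np.diag([0.0, 0.0, 5.0, 4.0])
        assert gt.covariance_overlap(a, b, k=2) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(34)
        for _ in range(5):
            d, k = 12, 4
            spectrum = np.sort(rng.uniform(0.1, 5.0, d))[::-1]
            Qa = np.linalg.qr(rng.standard_normal((d, d)))[0]
            Qb = np.linalg.qr(rng.standard_normal((d, d)))[0]
            Ca = Qa @ np.diag(spectrum) @ Qa.T
            Cb = Qb @ np.diag(spectrum) @ Qb.T
            va = np.linalg.eigh(Ca)[1][:, ::-1][:, :k]
            vb = np.linalg.eigh(Cb)[1][:, ::-1][:, :k]
            brute = sum((va[:, i] @ vb[:, j]) ** 2
                        for i in range(k) for j in range(k)) / k
            assert gt.covariance_overlap(Ca, Cb, k=k) == pytest.approx(
                brute, abs=1e-12)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(35)
        A = rng.standard_normal((8, 8))
        B = rng.standard_normal((8, 8))
        Ca, Cb = A @ A.T, B @ B.T
        assert gt.covariance_overlap(Ca, Cb, 4) == pytest.approx(
            gt.covariance_overlap(Cb, Ca, 4), abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            gt.covariance_overlap(np.eye(4), np.eye(5), 2)
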