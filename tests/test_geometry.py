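"""Geometry engine: superposition, series observables, plane fits.

Independent oracles: a quaternion eigenvalue superposition for Kabsch
RMSD, a direct SVD fit for ring planes, and hand-computed examples.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aptadyn.geometry import (GeometrySeries, detect_hbonds, fit_ring_plane,
                              hbond_geometry, hbond_series, kabsch_superpose,
                              rmsd_series, rmsf_per_residue, stacking_geometry,
                              stacking_series)
from aptadyn.model import Frame, HBondDefinition, RingDefinition, Trajectory

from conftest import random_rigid_motion, transform_trajectory


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Independent minimal-RMSD oracle via the 4×4 quaternion key matrix."""
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    m = p.T @ q
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz]])
    lam = np.linalg.eigvalsh(key).max()
    ga = np.sum(p ** 2) + np.sum(q ** 2)
    n = mobile.shape[0]
    return float(np.sqrt(max(ga - 2.0 * lam, 0.0) / n))


class TestKabsch:
    def test_identical_sets_zero_rmsd_identity_rotation(self):
        pts = np.random.default_rng(0).uniform(0, 10, (6, 3))
        rot, t, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 10, (8, 3))
        rot0 = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        moved = pts @ rot0.T + np.array([3.0, -2.0, 7.0])
        rot, t, rmsd = kabsch_superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-5, 5, (10, 3))
        b = rng.uniform(-5, 5, (10, 3))
        _, _, rmsd = kabsch_superpose(a, b)
        assert rmsd == pytest.approx(quaternion_rmsd(a, b), abs=1e-8)

    def test_rotation_always_proper(self):
        # a reflection-like correspondence must still yield det(R) = +1
        rng = np.random.default_rng(3)
        a = rng.uniform(-5, 5, (10, 3))
        b = a.copy()
        b[:, 2] *= -1.0
        rot, _, _ = kabsch_superpose(a, b)
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="degenerate|collinear"):
            kabsch_superpose(line, line)

    def test_superposed_rmsd_never_exceeds_raw(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.uniform(-5, 5, (12, 3))
            b = a + rng.normal(0, 1.0, (12, 3))
            _, _, fitted = kabsch_superpose(a, b)
            raw = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
            assert fitted <= raw + 1e-12


class TestRmsdRmsf:
    def _toy_traj(self):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        return base

    def test_static_trajectory_zero_series(self, water_topology):
        frame = np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        traj = Trajectory(water_topology, [Frame(frame, i) for i in range(4)])
        series = rmsd_series(traj, [0, 1, 2])
        assert np.allclose(series.values, 0.0, atol=1e-10)

    def test_translated_frame_zero_rmsd(self, water_topology):
        frame = np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        traj = Trajectory(water_topology, [Frame(frame, 0), Frame(frame + 5.0, 1)])
        series = rmsd_series(traj, [0, 1, 2])
        assert series.values[1] == pytest.approx(0.0, abs=1e-10)

    def test_post_fit_displacement_matches_direct_formula(self):
        """One atom displaced after fitting on the other three: RMSD = sqrt(d²/N)."""
        from aptadyn.model import AtomRecord, Topology
        atoms = [AtomRecord(i + 1, f"C{i+1}", "C", "TOY", 1) for i in range(4)]
        top = Topology(atoms)
        base = self._toy_traj()
        moved = base.copy()
        moved[3] += np.array([0.0, 0.0, 1.0])   # 1 Å shift of atom 4
        traj = Trajectory(top, [Frame(base, 0), Frame(moved, 1)])
        series = rmsd_series(traj, [0, 1, 2, 3], fit_selection=[0, 1, 2])
        assert series.values[1] == pytest.approx(np.sqrt(1.0 / 4.0), abs=1e-12)

    def test_rmsf_static_zero_and_single_frame_rejected(self, water_topology):
        frame = np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]])
        traj = Trajectory(water_topology, [Frame(frame, i) for i in range(3)])
        assert all(v == pytest.approx(0.0, abs=1e-10)
                   for v in rmsf_per_residue(traj).values())
        with pytest.raises(ValueError):
            rmsf_per_residue(Trajectory(water_topology, [Frame(frame, 0)]))

    def test_oscillating_atom_rmsf_closed_form(self):
        """±a oscillation along x over 2 frames gives RMSF exactly a."""
        from aptadyn.model import AtomRecord, Topology
        atoms = [AtomRecord(i + 1, f"C{i+1}", "C", "TOY", rid)
                 for i, rid in enumerate([1, 1, 1, 1, 2])]
        top = Topology(atoms)
        a = 0.4
        # anchor cloud is asymmetric so superposition is well conditioned
        base = np.array([[0.0, 0, 0], [4, 0, 0], [0, 5, 0], [0, 0, 6], [10, 10, 10]])
        f1, f2 = base.copy(), base.copy()
        f1[4, 0] += a
        f2[4, 0] -= a
        traj = Trajectory(top, [Frame(f1, 0), Frame(f2, 1)])
        rmsf = rmsf_per_residue(traj, selection=[4], fit_selection=[0, 1, 2, 3])
        assert rmsf[2] == pytest.approx(a, rel=1e-6)

    def test_site_rmsf_below_terminal_rmsf(self, wt_small):
        """Site residues fluctuate only with the posed-observable spread;
        terminal residues carry the generator's large rigid jitter."""
        rmsf = rmsf_per_residue(wt_small.trajectory)
        site = np.mean([rmsf[r] for r in (5, 21, 22)])
        terminal = np.mean([rmsf[1], rmsf[27]])
        assert site < terminal / 2.0
        loop = np.mean([rmsf[r] for r in (13, 14, 15)])
        assert site < loop


class TestHbonds:
    def test_collinear_geometry(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]])
        frame = Frame(xyz)
        hb = HBondDefinition(0, 1, 2)
        length, angle = hbond_geometry(frame, hb)
        assert length == pytest.approx(2.0)
        assert angle == pytest.approx(180.0)

    def test_right_angle_geometry(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 2.0, 0]])
        _, angle = hbond_geometry(Frame(xyz), HBondDefinition(0, 1, 2))
        assert angle == pytest.approx(90.0)

    def test_coincident_atoms_rejected(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError):
            hbond_geometry(Frame(xyz), HBondDefinition(0, 1, 2))

    def test_series_mean_matches_generator_mean(self, wt_small):
        length, angle = hbond_series(wt_small.trajectory, wt_small.h1)
        n = wt_small.trajectory.n_frames
        assert abs(length.mean - 2.07) <= 4 * 0.16 / np.sqrt(n)
        assert abs(angle.mean - 162.0) <= 4 * 9.5 / np.sqrt(n)

    def test_detection_empty_when_nothing_close(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0], [50.0, 0, 0]])
        hits = detect_hbonds(Frame(xyz), [(0, 1)], [2])
        assert hits == []

    def test_detection_single_ideal_pair(self):
        xyz = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.9, 0.05, 0]])
        hits = detect_hbonds(Frame(xyz), [(0, 1)], [2], d_max=2.5, angle_min=120.0)
        assert len(hits) == 1
        assert hits[0].acceptor_index == 2

    def test_planted_noncanonical_pairs_recovered(self, wt_small):
        """The fixture plants base6→G21 and base23→G5 hydrogen bonds."""
        for frame in wt_small.trajectory.frames[:10]:
            hits = detect_hbonds(frame, wt_small.nonwc_donors,
                                 wt_small.nonwc_acceptors)
            found = {(h.donor_index, h.acceptor_index) for h in hits}
            expected = {(d, a) for (d, _), a in
                        zip(wt_small.nonwc_donors, wt_small.nonwc_acceptors)}
            assert expected <= found


class TestRingPlanes:
    def _hexagon(self):
        ang = np.radians(np.arange(6) * 60.0)
        return np.c_[1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)]

    def test_flat_hexagon_normal_is_z(self):
        fit = fit_ring_plane(Frame(self._hexagon()), RingDefinition(range(6)))
        assert abs(fit.normal[2]) == pytest.approx(1.0)
        assert fit.rms_deviation == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(fit.centroid, 0.0, atol=1e-12)

    def test_rotated_hexagon_normal_equivariant(self):
        rng = np.random.default_rng(4)
        rot, _ = random_rigid_motion(rng)
        fit = fit_ring_plane(Frame(self._hexagon() @ rot.T), RingDefinition(range(6)))
        expected = rot @ np.array([0.0, 0.0, 1.0])
        assert abs(np.dot(fit.normal, expected)) == pytest.approx(1.0, abs=1e-10)

    def test_puckered_ring_matches_svd_oracle(self):
        rng = np.random.default_rng(5)
        pts = self._hexagon()[:5]
        extra = pts[:4] + np.array([0.3, 0.9, 0.0])
        ring = np.vstack([pts, extra])
        ring[:, 2] += rng.normal(0, 0.15, len(ring))   # pucker
        fit = fit_ring_plane(Frame(ring), RingDefinition(range(len(ring))))
        centered = ring - ring.mean(axis=0)
        _, _, vt = np.linalg.svd(centered)
        assert abs(np.dot(fit.normal, vt[2])) == pytest.approx(1.0, abs=1e-10)

    def test_collinear_ring_rejected(self):
        line = np.outer(np.arange(4.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            fit_ring_plane(Frame(line), RingDefinition(range(4)))


class TestStacking:
    def _two_rings(self, separation, tilt_deg):
        ang = np.radians(np.arange(6) * 60.0)
        ring = np.c_[1.39 * np.cos(ang), 1.39 * np.sin(ang), np.zeros(6)]
        c, s = np.cos(np.radians(tilt_deg)), np.sin(np.radians(tilt_deg))
        rot = np.array([[1.0, 0, 0], [0, c, -s], [0, s, c]])
        upper = ring @ rot.T + np.array([0.0, 0.0, separation])
        return np.vstack([ring, upper])

    @pytest.mark.parametrize("sep,tilt", [(3.4, 0.0), (3.4, 90.0), (4.1, 13.4)])
    def test_constructed_geometry_recovered(self, sep, tilt):
        xyz = self._two_rings(sep, tilt)
        dist, angle = stacking_geometry(Frame(xyz), RingDefinition(range(6)),
                                        RingDefinition(range(6, 12)))
        assert dist == pytest.approx(sep, abs=1e-10)
        assert angle == pytest.approx(tilt, abs=1e-8)

    def test_series_recovers_fixture_means(self, wt_small):
        dist, angle = stacking_series(wt_small.trajectory, wt_small.ring6,
                                      wt_small.ring_ligand)
        n = wt_small.trajectory.n_frames
        assert abs(dist.mean - 4.09) <= 4 * 0.22 / np.sqrt(n)
        assert abs(angle.mean - 13.4) <= 4 * 6.9 / np.sqrt(n)


class TestRigidMotionInvariance:
    """All observables must be invariant under global rigid motion."""

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_observables_invariant(self, seed, wt_frozen):
        rng = np.random.default_rng(seed)
        rot, t = random_rigid_motion(rng)
        moved = transform_trajectory(wt_frozen.trajectory, rot, t)
        l0, a0 = hbond_series(wt_frozen.trajectory, wt_frozen.h1)
        l1, a1 = hbond_series(moved, wt_frozen.h1)
        np.testing.assert_allclose(l1.values, l0.values, atol=1e-8)
        np.testing.assert_allclose(a1.values, a0.values, atol=1e-8)
        d0, s0 = stacking_series(wt_frozen.trajectory, wt_frozen.ring6,
                                 wt_frozen.ring_ligand)
        d1, s1 = stacking_series(moved, wt_frozen.ring6, wt_frozen.ring_ligand)
        np.testing.assert_allclose(d1.values, d0.values, atol=1e-8)
        np.testing.assert_allclose(s1.values, s0.values, atol=1e-7)
        sel = wt_frozen.topology.groups["site"]
        r0 = rmsd_series(wt_frozen.trajectory, sel)
        r1 = rmsd_series(moved, sel)
        np.testing.assert_allclose(r1.values, r0.values, atol=1e-8)


def test_series_statistics_consistent(wt_small):
    length, angle = hbond_series(wt_small.trajectory, wt_small.h2)
    for s in (length, angle):
        assert s.mean == pytest.approx(float(np.mean(s.values)))
        assert s.std == pytest.approx(float(np.std(s.values)))
        assert len(s) == wt_small.trajectory.n_frames
    assert np.all(angle.values >= 0.0) and np.all(angle.values <= 180.0)
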