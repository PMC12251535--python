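"""RDFs, coordination numbers, structural distributions, hydrogen bonds,
and closest-water selection on droplet fixtures."""

import numpy as np
import pytest

import trajvib as tv
from trajvib.structure import (
    StructureError,
    bond_angles,
    dihedral_angles,
    find_waters,
)
from trajvib.trajio import SelectionError


def _static_traj(positions, elements):
    atoms = tv.AtomTable(list(elements), np.array(
        [tv.ATOMIC_MASSES[e] for e in elements]))
    return tv.Trajectory(atoms, np.asarray(positions, float)[None], None, 1.0)


class TestRDF:
    def test_frozen_pair_single_occupied_bin(self):
        d = 2.05
        traj = _static_traj([[0, 0, 0], [d, 0, 0]], ["O", "H"])
        rdf = tv.radial_distribution(
            traj, [0], [1], bin_width=0.05, r_max=4.0,
            normalization="bulk", cavity_radius=4.0,
        )
        occ = np.nonzero(rdf.g)[0]
        assert occ.size == 1
        assert abs(rdf.r[occ[0]] - d) <= 0.05
        beyond = rdf.r > d + 0.05
        np.testing.assert_allclose(rdf.n[beyond], 1.0, rtol=1e-12)

    def test_empty_group_rejected(self):
        traj = _static_traj([[0, 0, 0], [1, 0, 0]], ["O", "H"])
        with pytest.raises(SelectionError):
            tv.radial_distribution(traj, [], [1])

    def test_ideal_gas_droplet_is_flat_under_cavity_mc(self):
        R = 12.0
        traj, _ = tv.droplet_configurations(
            np.zeros((1, 3)), ["C"], [], n_uniform=300,
            cavity_radius=R, n_frames=100, seed=17,
        )
        oxygens = [w[0] for w in find_waters(traj)]
        rdf = tv.radial_distribution(
            traj, [0], oxygens, bin_width=0.25, r_max=R,
            normalization="cavity-mc", cavity_radius=R,
            cavity_center=np.zeros(3), seed=5,
        )
        sel = (rdf.r >= 2.0) & (rdf.r <= R / 2)
        # stochastic bound: ~3.5σ of the per-bin counting noise (~7%)
        assert np.abs(rdf.g[sel] - 1.0).max() < 0.25

    def test_bulk_and_cavity_mc_agree_away_from_wall(self):
        R = 12.0
        traj, _ = tv.droplet_configurations(
            np.zeros((1, 3)), ["C"], [], n_uniform=200,
            cavity_radius=R, n_frames=30, seed=23,
        )
        oxygens = [w[0] for w in find_waters(traj)]
        kwargs = dict(bin_width=1.0, r_max=6.0, cavity_radius=R,
                      cavity_center=np.zeros(3))
        g_bulk = tv.radial_distribution(traj, [0], oxygens,
                                        normalization="bulk", **kwargs)
        g_mc = tv.radial_distribution(traj, [0], oxygens,
                                      normalization="cavity-mc", seed=1,
                                      n_mc=2_000_000, **kwargs)
        sel = g_bulk.r > 2.0
        np.testing.assert_allclose(g_mc.g[sel], g_bulk.g[sel], rtol=0.02)

    def test_first_shell_fixture_peak_and_coordination(self):
        solute = np.array([[0.0, 0.0, 0.0], [1.22, 0.0, 0.0]])  # C, O
        # waters donate an O–H to the carbonyl oxygen: placing O_w at
        # 2.05 + r_OH puts the donated hydrogen at 2.05 Å from the site
        from trajvib.synth import WATER_OH_LENGTH

        traj, _ = tv.droplet_configurations(
            solute, ["C", "O"],
            [tv.ShellSpec(site=1, distance=2.05 + WATER_OH_LENGTH, count=2,
                          jitter=0.03, orientation="toward-site")],
            n_frames=50, seed=31,
        )
        hydrogens = [i for w in find_waters(traj) for i in w[1:]]
        rdf = tv.radial_distribution(
            traj, [1], hydrogens, bin_width=0.05, r_max=6.0,
            normalization="bulk", cavity_radius=8.0,
        )
        peak_r = rdf.r[np.argmax(rdf.g)]
        assert abs(peak_r - 2.05) <= 0.05 + 1e-9
        assert rdf.n_at(rdf.first_minimum()) == pytest.approx(2.0, abs=0.05)

    def test_rdf_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(scale=3.0, size=(5, 6, 3))
        atoms = tv.AtomTable(["O"] * 6, np.full(6, 15.999))
        traj = tv.Trajectory(atoms, pos, None, 1.0)
        # a random rotation + translation applied to every frame
        th = 0.7
        Rm = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        moved = tv.Trajectory(atoms, pos @ Rm.T + np.array([3.0, -1.0, 2.0]), None, 1.0)
        kwargs = dict(bin_width=0.2, r_max=8.0, normalization="bulk", cavity_radius=8.0)
        a = tv.radial_distribution(traj, [0, 1, 2], [3, 4, 5], **kwargs)
        b = tv.radial_distribution(moved, [0, 1, 2], [3, 4, 5], **kwargs)
        np.testing.assert_allclose(a.g, b.g, atol=1e-12)

    def test_coordination_bookkeeping_identity(self):
        """n(r_max) equals mean observed pairs within r_max per a-site (bulk)."""
        rng = np.random.default_rng(3)
        pos = rng.uniform(-4, 4, size=(10, 8, 3))
        atoms = tv.AtomTable(["O"] * 8, np.full(8, 15.999))
        traj = tv.Trajectory(atoms, pos, None, 1.0)
        rdf = tv.radial_distribution(
            traj, [0, 1], [2, 3, 4, 5], bin_width=0.1, r_max=14.0,
            normalization="bulk", cavity_radius=7.0,
        )
        d = np.linalg.norm(
            pos[:, [0, 1], None, :] - pos[:, None, [2, 3, 4, 5], :], axis=3
        )
        mean_pairs = (d < 14.0).sum() / (10 * 2)
        assert rdf.n[-1] == pytest.approx(mean_pairs, rel=1e-10)


class TestRunningCoordination:
    def _rdf(self, g, bin_width, density):
        r = (np.arange(len(g)) + 0.5) * bin_width
        return tv.RDFResult(r, np.asarray(g, float), bin_width, density)

    def test_zero_g_gives_zero_n(self):
        rdf = self._rdf(np.zeros(50), 0.05, 0.03)
        np.testing.assert_array_equal(rdf.n, 0.0)

    def test_unit_g_reproduces_sphere_volume_integral(self):
        rho, dr = 0.0334, 0.05
        rdf = self._rdf(np.ones(200), dr, rho)
        n = rdf.n
        edges = (np.arange(200) + 1) * dr
        exact = (4.0 / 3.0) * np.pi * rho * edges**3
        sel = edges >= 0.5
        np.testing.assert_allclose(n[sel], exact[sel], rtol=0.01)

    def test_monotone_for_nonnegative_g(self):
        rng = np.random.default_rng(0)
        rdf = self._rdf(rng.random(100), 0.1, 0.02)
        assert np.all(np.diff(rdf.n) >= 0)

    def test_missing_density_is_a_state_error(self):
        rdf = self._rdf(np.ones(10), 0.1, 0.0)
        with pytest.raises(StructureError):
            tv.running_coordination(rdf)


class TestStructuralDistributions:
    def test_rigid_geometry_single_bin_zero_std(self):
        traj = _static_traj([[0, 0, 0], [1.1, 0, 0], [1.1, 1.5, 0]], ["O", "C", "N"])
        traj = tv.Trajectory(traj.atoms, np.repeat(traj.positions, 4, axis=0), None, 1.0)
        (bond,) = tv.structural_distributions(traj, [(0, 1)])
        assert bond.std == 0.0
        assert (bond.counts > 0).sum() == 1
        assert bond.mean == pytest.approx(1.1)
        assert bond.bin_width == 0.001

    def test_harmonic_bond_variance_matches_equipartition(self):
        # canonical sampling of δr ~ N(0, k_BT/k): sample variance ≈ k_BT/k
        k = 0.2  # amu Å²/fs² per Å²
        T = 300.0
        rng = np.random.default_rng(42)
        n = 20000
        dr = rng.normal(0.0, np.sqrt(tv.KB * T / k), n)
        pos = np.zeros((n, 2, 3))
        pos[:, 1, 0] = 1.0 + dr
        atoms = tv.AtomTable(["C", "O"], np.array([12.011, 15.999]))
        traj = tv.Trajectory(atoms, pos, None, 1.0)
        (bond,) = tv.structural_distributions(traj, [(0, 1)])
        assert bond.std**2 == pytest.approx(tv.KB * T / k, rel=0.05)

    def test_angle_bin_width_default(self):
        traj = _static_traj([[1, 0, 0], [0, 0, 0], [0, 1, 0]], ["H", "O", "H"])
        (ang,) = tv.structural_distributions(traj, [(0, 1, 2)])
        assert ang.kind == "angle"
        assert ang.bin_width == 0.05
        assert ang.mean == pytest.approx(90.0)

    def test_dihedral_wrap_is_periodic_and_circular_mean(self):
        # two frames at +179.9° and −179.9°: adjacent periodic bins, mean ±180°
        base = np.array(
            [[0.0, 1.0, 0.0], [0, 0, 0], [1.0, 0, 0], [1.0, 0.0, 0.0]]
        )
        pos = np.zeros((2, 4, 3))
        for f, ang in enumerate((179.9, -179.9)):
            a = np.radians(ang)
            pos[f] = base
            pos[f, 3] = [1.0, np.cos(a), np.sin(a)]
        atoms = tv.AtomTable(["C", "C", "C", "C"], np.full(4, 12.011))
        traj = tv.Trajectory(atoms, pos, None, 1.0)
        vals = dihedral_angles(traj, 0, 1, 2, 3)
        assert vals[0] == pytest.approx(179.9, abs=1e-6)
        assert vals[1] == pytest.approx(-179.9, abs=1e-6)
        (dih,) = tv.structural_distributions(traj, [(0, 1, 2, 3)])
        assert abs(abs(dih.mean) - 180.0) < 0.2  # circular mean near ±180
        assert dih.std == pytest.approx(0.1, abs=0.01)

    def test_collinear_angle_samples_dropped_with_count(self):
        pos = np.zeros((3, 3, 3))
        pos[:, 1, 0] = 1.0
        pos[:, 2, 0] = 2.0  # perfectly collinear: angle defined (180°), fine
        pos[2, 2] = pos[2, 1]  # zero-length arm → NaN sample
        atoms = tv.AtomTable(["C", "C", "C"], np.full(3, 12.011))
        traj = tv.Trajectory(atoms, pos, None, 1.0)
        (ang,) = tv.structural_distributions(traj, [(0, 1, 2)])
        assert ang.n_dropped == 1
        assert ang.counts.sum() == 2


class TestHBond:
    def _linear_hbond_traj(self, n_frames, break_at=None):
        # D–H⋯A collinear: D at 0, H at 1.0, A at 2.9 (d(D,A)=2.9 < 3.5, angle 180°)
        pos = np.zeros((n_frames, 3, 3))
        pos[:, 1, 0] = 1.0
        pos[:, 2, 0] = 2.9
        if break_at is not None:
            pos[break_at:, 2, 0] = 6.0
        atoms = tv.AtomTable(["N", "H", "O"], np.array([14.007, 1.008, 15.999]))
        return tv.Trajectory(atoms, pos, None, 2.0)

    def test_frozen_bonded_geometry_survives_entire_trajectory(self):
        traj = self._linear_hbond_traj(10)
        hb = tv.hbond_series(traj, (0, 1), 2)
        assert hb.bonded.all()
        assert hb.longest_interval == (0.0, 20.0)

    def test_bond_broken_at_half_gives_first_half_interval(self):
        n = 40
        traj = self._linear_hbond_traj(n, break_at=n // 2)
        hb = tv.hbond_series(traj, (0, 1), 2)
        assert hb.longest_interval == (0.0, n // 2 * 2.0)
        assert len(hb.intervals) == 1

    def test_zero_cutoff_never_bonds(self):
        traj = self._linear_hbond_traj(5)
        hb = tv.hbond_series(traj, (0, 1), 2, d_cut=0.0)
        assert not hb.bonded.any()
        assert hb.intervals == []
        assert hb.longest_interval is None


class TestClosestWaters:
    def test_inner_shell_selected_every_frame(self):
        solute = np.array([[0.0, 0.0, 0.0]])
        traj, truth = tv.droplet_configurations(
            solute, ["C"],
            [tv.ShellSpec(0, 2.5, 2, jitter=0.02),
             tv.ShellSpec(0, 5.0, 3, jitter=0.02),
             tv.ShellSpec(0, 8.0, 3, jitter=0.02)],
            n_frames=12, seed=13, cavity_radius=10.0,
        )
        sel = tv.select_closest_waters(traj, [0], 2)
        inner = truth["shell_waters"][:2]
        assert sel.fixed == sorted(inner)
        for frame in sel.per_frame:
            assert frame == sorted(inner)
        assert len(sel.fixed_atom_indices()) == 6

    def test_count_equal_to_total_selects_all(self):
        traj, _ = tv.droplet_configurations(
            np.zeros((1, 3)), ["C"], [], n_uniform=4, n_frames=2, seed=7,
            cavity_radius=8.0,
        )
        sel = tv.select_closest_waters(traj, [0], 4)
        assert sel.fixed == [0, 1, 2, 3]

    def test_water_near_two_sites_assigned_once(self):
        # one water equidistant from two sites; with count=1 it appears once
        pos = np.zeros((1, 5, 3))
        pos[0, 1, 0] = 4.0  # second site
        pos[0, 2] = [2.0, 0.5, 0.0]  # water O between the sites
        pos[0, 3] = [2.8, 0.5, 0.6]
        pos[0, 4] = [1.2, 0.5, 0.6]
        atoms = tv.AtomTable(
            ["C", "C", "O", "H", "H"],
            np.array([12.011, 12.011, 15.999, 1.008, 1.008]),
        )
        traj = tv.Trajectory(atoms, pos, None, 1.0)
        sel = tv.select_closest_waters(traj, [0, 1], 1, waters=[(2, 3, 4)])
        assert sel.per_frame[0] == [0]

    def test_too_few_waters_is_an_availability_error(self):
        traj, _ = tv.droplet_configurations(
            np.zeros((1, 3)), ["C"], [], n_uniform=2, seed=3, cavity_radius=8.0,
        )
        with pytest.raises(SelectionError):
            tv.select_closest_waters(traj, [0], 5)
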