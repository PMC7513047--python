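"""Alignment, slab profiles, order parameter, pressure and gyration."""
import math

import numpy as np
import pytest

import activeblend as ab


def _roll_traj(traj, shift):
    """Translate all snapshots along z across the periodic boundary."""
    pos = traj.positions.copy()
    Lz = traj.box.lengths[2]
    pos[:, :, 2] = np.mod(pos[:, :, 2] + shift, Lz)
    return ab.Trajectory(positions=pos, velocities=traj.velocities.copy(),
                         times=traj.times.copy(), species=traj.species,
                         chain_id=traj.chain_id, box=traj.box)


class TestAlignment:
    def test_centered_config_left_in_place(self, two_phase_traj):
        aligned = ab.align_snapshots(two_phase_traj)
        shift = np.abs(aligned.positions[:, :, 2]
                       - two_phase_traj.positions[:, :, 2])
        shift = np.minimum(shift, two_phase_traj.box.lengths[2] - shift)
        assert shift.max() < 0.5  # statistical center-of-mass jitter only

    def test_restores_translation_across_boundary(self, two_phase_traj):
        rolled = _roll_traj(two_phase_traj, 0.4 * two_phase_traj.box.lengths[2])
        a0 = ab.align_snapshots(two_phase_traj)
        a1 = ab.align_snapshots(rolled)
        np.testing.assert_allclose(a0.positions, a1.positions, atol=1e-9)

    def test_mixed_labels_raise(self, two_phase_traj):
        rng = np.random.default_rng(0)
        shuffled = ab.Trajectory(
            positions=two_phase_traj.positions, velocities=two_phase_traj.velocities,
            times=two_phase_traj.times,
            species=rng.permutation(two_phase_traj.species),
            chain_id=two_phase_traj.chain_id, box=two_phase_traj.box)
        with pytest.raises(ab.AlignmentError):
            ab.align_snapshots(shuffled)


class TestDensityProfiles:
    def test_uniform_gas_is_flat(self):
        spec = ab.TwoPhaseSpec(box=(10.0, 10.0, 20.0), rho_hot_phase=0.85,
                               rho_cold_phase=0.85, purity_hot_phase=0.5,
                               purity_cold_phase=0.5)
        traj = ab.Trajectory.from_states(
            [ab.make_two_phase(spec, seed=k) for k in range(4)])
        grid = ab.SlabGrid.for_box(traj.box, n_slabs=20)
        prof = ab.density_profile(traj, grid)
        expected = traj.n_particles / traj.box.volume
        assert np.abs(prof.values - expected).max() < 0.1
        # mass conservation: integral over slabs x area = particle count
        area = traj.box.lengths[0] * traj.box.lengths[1]
        total = prof.values.sum() * area * grid.width
        assert total == pytest.approx(traj.n_particles, rel=1e-12)

    def test_two_phase_plateaus(self, two_phase_traj):
        aligned = ab.align_snapshots(two_phase_traj)
        grid = ab.SlabGrid.for_box(aligned.box, n_slabs=30)
        hot = ab.density_profile(aligned, grid, "hot")
        z = grid.centers
        core_hot = (z > 10.0) & (z < 20.0)
        core_cold = (z < 4.0) | (z > 26.0)
        assert hot.values[core_hot].mean() == pytest.approx(0.78, abs=0.05)
        assert hot.values[core_cold].mean() == pytest.approx(0.0, abs=0.02)
        total = ab.density_profile(aligned, grid, "cold")
        assert total.values[core_cold].mean() == pytest.approx(0.92, abs=0.05)

    def test_empty_trajectory_rejected(self, two_phase_traj):
        grid = ab.SlabGrid(length=10.0, n_slabs=5)
        empty = ab.Trajectory(
            positions=np.empty((0, 1, 3)), velocities=np.empty((0, 1, 3)),
            times=np.empty(0), species=np.array([1], dtype=np.int8),
            chain_id=np.array([0], dtype=np.int32),
            box=ab.SimulationBox((10.0, 10.0, 10.0)))
        with pytest.raises(ValueError):
            ab.density_profile(empty, grid)


class TestVelocityProfiles:
    def test_single_temperature_msv(self):
        spec = ab.TwoPhaseSpec(box=(10.0, 10.0, 20.0), rho_hot_phase=0.85,
                               rho_cold_phase=0.85, purity_hot_phase=0.5,
                               purity_cold_phase=0.5, T_hot_species=2.0,
                               T_cold_species=2.0)
        traj = ab.Trajectory.from_states(
            [ab.make_two_phase(spec, seed=k) for k in range(5)])
        grid = ab.SlabGrid.for_box(traj.box, n_slabs=10)
        prof = ab.msv_profile(traj, grid)
        assert np.abs(prof.values - 2.0).max() < 3.5 * np.nanmax(prof.stderr)

    def test_effective_temperature_recovery(self, two_phase_traj):
        eff = ab.effective_temperatures(two_phase_traj)
        n_hot = (two_phase_traj.species == ab.HOT).sum() * len(two_phase_traj)
        se = 2.6 * math.sqrt(2.0 / (3.0 * n_hot))
        assert abs(eff.hot - 2.6) < 3 * se
        assert abs(eff.cold - 1.2) < 3 * se
        assert eff.chi == pytest.approx((eff.hot - eff.cold) / eff.cold)

    def test_hot_selector_plateau(self, two_phase_traj):
        aligned = ab.align_snapshots(two_phase_traj)
        grid = ab.SlabGrid.for_box(aligned.box, n_slabs=15)
        hot = ab.msv_profile(aligned, grid, "hot")
        core = (grid.centers > 10) & (grid.centers < 20)
        assert np.nanmean(hot.values[core]) == pytest.approx(2.6, abs=0.1)

    @pytest.mark.parametrize("th,tc,expected", [
        (3.0, 1.0, 2.0), (1.7, 1.7, 0.0), (2.6, 1.3, 1.0)])
    def test_chi_formula(self, th, tc, expected):
        assert ab.chi_asymmetry(th, tc) == pytest.approx(expected)

    def test_chi_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            ab.chi_asymmetry(2.0, 0.0)


class TestMsvDecomposition:
    def test_weighted_profile_is_msv_identically(self, two_phase_traj):
        grid = ab.SlabGrid.for_box(two_phase_traj.box, n_slabs=25)
        weighted, _, _ = ab.msv_decomposition(two_phase_traj, grid)
        msv = ab.msv_profile(two_phase_traj, grid)
        np.testing.assert_allclose(weighted.values, msv.values,
                                   rtol=1e-12, equal_nan=True)

    def test_uncorrelated_mixture_has_zero_difference(self):
        spec = ab.TwoPhaseSpec(box=(10.0, 10.0, 20.0), rho_hot_phase=0.85,
                               rho_cold_phase=0.85, purity_hot_phase=0.5,
                               purity_cold_phase=0.5, T_hot_species=2.6,
                               T_cold_species=1.2)
        traj = ab.Trajectory.from_states(
            [ab.make_two_phase(spec, seed=k) for k in range(8)])
        grid = ab.SlabGrid.for_box(traj.box, n_slabs=8)
        _, _, diff = ab.msv_decomposition(traj, grid)
        assert np.nanmax(np.abs(diff.values)) < 0.05

    def test_bulk_flux_relation(self, two_phase_traj):
        # with species temperatures set to the reservoirs, the msv profile
        # follows Th*phi_h + Tc*(1 - phi_h)
        grid = ab.SlabGrid.for_box(two_phase_traj.box, n_slabs=15)
        msv = ab.msv_profile(two_phase_traj, grid)
        phi = ab.number_fraction_profile(two_phase_traj, grid)
        predicted = 2.6 * phi.values + 1.2 * (1.0 - phi.values)
        assert np.nanmax(np.abs(msv.values - predicted)) < 0.15


class TestOrderParameter:
    def test_fully_separated_is_one(self):
        # two distant pure-species blobs: no cross-species contacts at all
        rng = np.random.default_rng(4)
        n = 200
        pos = np.vstack([rng.random((n, 3)) * 4.0 + [1, 1, 1],
                         rng.random((n, 3)) * 4.0 + [1, 1, 11]])
        state = ab.SystemState(
            positions=pos, velocities=np.zeros((2 * n, 3)),
            species=np.repeat([ab.HOT, ab.COLD], n).astype(np.int8),
            chain_id=(np.arange(2 * n) // 40).astype(np.int32),
            box=ab.SimulationBox((20.0, 20.0, 20.0)))
        assert ab.order_parameter_phi(state) == 1.0

    def test_shuffled_labels_average_zero(self, small_melt):
        # monomer-level label permutation: like and unlike inter-chain
        # contacts equally likely, so Phi vanishes on average
        rng = np.random.default_rng(11)
        phis = []
        for _ in range(20):
            s = small_melt.copy()
            s.species = rng.permutation(small_melt.species)
            phis.append(ab.order_parameter_phi(s))
        assert abs(np.mean(phis)) < 3 * np.std(phis) / math.sqrt(len(phis)) + 0.02

    def test_dilute_input_raises(self):
        state = ab.SystemState(
            positions=np.array([[1.0, 1, 1], [5.0, 5, 5]]),
            velocities=np.zeros((2, 3)),
            species=np.array([1, 0], dtype=np.int8),
            chain_id=np.array([0, 1], dtype=np.int32),
            box=ab.SimulationBox((12.0, 12.0, 12.0)))
        with pytest.raises(ValueError):
            ab.order_parameter_phi(state)


def _lattice_gas(T=1.7, nx=6, spacing=2.0, seed=0):
    """Noninteracting uniform gas: lattice positions, Maxwell velocities."""
    rng = np.random.default_rng(seed)
    g = (np.mgrid[0:nx, 0:nx, 0:nx].reshape(3, -1).T + 0.5) * spacing
    n = g.shape[0]
    return ab.SystemState(
        positions=g, velocities=rng.standard_normal((n, 3)) * math.sqrt(T),
        species=rng.integers(0, 2, n).astype(np.int8),
        chain_id=np.arange(n, dtype=np.int32),
        box=ab.SimulationBox(np.full(3, nx * spacing)))


class TestPressure:
    def test_ideal_gas_limit(self):
        states = [_lattice_gas(seed=k) for k in range(20)]
        traj = ab.Trajectory.from_states(states)
        grid = ab.SlabGrid.for_box(traj.box, n_slabs=6)
        pp = ab.pressure_profiles(traj, grid)
        rho = traj.n_particles / traj.box.volume
        assert np.all(pp.virial == 0.0)  # lattice spacing beyond the cutoff
        diag = np.array([pp.kinetic[:, k, k] for k in range(3)])
        assert np.abs(diag - rho * 1.7).max() < 0.25
        off = pp.kinetic[:, 0, 1]
        assert np.abs(off).max() < 0.15
        assert np.abs(pp.anisotropy).max() < 0.3
        gamma, _ = ab.tension_integral(pp)
        assert abs(gamma) < 0.5

    def test_kinetic_trace_matches_msv(self):
        traj = ab.Trajectory.from_states([_lattice_gas(seed=k) for k in range(6)])
        grid = ab.SlabGrid.for_box(traj.box, n_slabs=4)
        pp = ab.pressure_profiles(traj, grid, include_virial=False)
        msv = ab.msv_profile(traj, grid)
        dens = ab.density_profile(traj, grid)
        trace = (pp.kinetic[:, 0, 0] + pp.kinetic[:, 1, 1]
                 + pp.kinetic[:, 2, 2]) / 3.0
        np.testing.assert_allclose(trace, dens.values * msv.values, rtol=1e-9)

    def test_bonded_pair_virial_oracle(self, ff):
        d = np.array([0.3, 0.2, 1.2])  # beyond rc, inside rmax: FENE only
        box = ab.SimulationBox((8.0, 8.0, 8.0))
        z0 = 1.4  # segment 1.4 -> 2.6 straddles the slab-0 mid-plane at z = 2
        pos = np.array([[4.0, 4.0, z0 + d[2]], [4.0 - d[0], 4.0 - d[1], z0]])
        state = ab.SystemState(
            positions=pos, velocities=np.zeros((2, 3)),
            species=np.array([1, 1], dtype=np.int8),
            chain_id=np.array([0, 0], dtype=np.int32), box=box)
        traj = ab.Trajectory.from_states([state])
        grid = ab.SlabGrid.for_box(box, n_slabs=2)  # single mid-plane at z=4
        pp = ab.pressure_profiles(traj, grid, ff)
        r = np.linalg.norm(d)
        fac = -ff.K / (1.0 - (r / ff.rmax) ** 2)
        expected = np.outer(d, fac * d) / (2.0 * 64.0)
        slab = int(np.argmax(np.abs(pp.virial[:, 2, 2])))
        np.testing.assert_allclose(pp.virial[slab], expected, rtol=1e-10)
        other = [s for s in range(2) if s != slab]
        assert np.all(pp.virial[other] == 0.0)

    def test_tension_quadrature(self):
        # synthetic profile with a known closed-form integral
        grid = ab.SlabGrid(length=10.0, n_slabs=200)
        z = grid.centers
        kin = np.zeros((200, 3, 3))
        kin[:, 0, 0] = kin[:, 1, 1] = 1.0
        kin[:, 2, 2] = 1.0 + np.sin(2 * np.pi * z / 10.0) ** 2  # mean 1/2
        pp = ab.PressureProfile(grid=grid, kinetic=kin,
                                virial=np.zeros_like(kin),
                                anisotropy=np.zeros(200),
                                anisotropy_stderr=np.zeros(200),
                                counts=np.ones(200))
        gamma, _ = ab.tension_integral(pp)
        assert gamma == pytest.approx(0.5 * 5.0, rel=1e-6)
        pp.kinetic[:, 2, 2] = 1.0  # isotropic tensor: zero tension
        gamma, _ = ab.tension_integral(pp)
        assert gamma == pytest.approx(0.0, abs=1e-12)


class TestGyration:
    def test_rigid_rod_closed_form(self):
        n, b = 40, 0.97
        rod = np.zeros((n, 3))
        rod[:, 2] = np.arange(n) * b
        rg2 = ab.squared_gyration(rod)
        assert rg2 == pytest.approx(b ** 2 * (n ** 2 - 1) / 12.0, rel=1e-12)
        assert ab.squared_gyration(np.ones((5, 3))) == 0.0

    def test_ideal_chain_ensemble(self):
        rng = np.random.default_rng(8)
        n, b, chains = 40, 1.0, 400
        rg2 = []
        for _ in range(chains):
            steps = rng.standard_normal((n - 1, 3))
            steps *= b / np.linalg.norm(steps, axis=1)[:, None]
            walk = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
            rg2.append(ab.squared_gyration(walk))
        expected = (n ** 2 - 1) * b ** 2 / (6.0 * n)
        assert np.mean(rg2) == pytest.approx(expected, rel=0.1)

    def test_region_assignment(self):
        # three compact chains at known z with interfaces at 10 and 20
        box = ab.SimulationBox((30.0, 30.0, 30.0))
        rng = np.random.default_rng(2)
        blobs = {15.0: ab.HOT, 5.0: ab.COLD, 10.5: ab.HOT}
        pos, species, chain_id = [], [], []
        for c, (zc, sp) in enumerate(blobs.items()):
            p = rng.standard_normal((10, 3)) * 0.3 + [15.0, 15.0, zc]
            pos.append(p)
            species += [sp] * 10
            chain_id += [c] * 10
        state = ab.SystemState(
            positions=np.vstack(pos), velocities=np.zeros((30, 3)),
            species=np.array(species, dtype=np.int8),
            chain_id=np.array(chain_id, dtype=np.int32), box=box)
        traj = ab.Trajectory.from_states([state])
        stats = ab.gyration_by_region(traj, (10.0, 20.0), width=1.5)
        cells = {(s.region, s.species): s for s in stats}
        assert cells[("hot", "hot")].n_chains == 1
        assert cells[("cold", "cold")].n_chains == 1
        assert cells[("transition", "hot")].n_chains == 1
        assert all(s.mean_rg2 < 1.0 for s in stats)
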