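"""MD engine tests: integration, constraints, thermostats, walls, annealing."""

import numpy as np
import pytest

from pdmslab import units
from pdmslab.errors import ParameterError, StabilityError
from pdmslab.md import (
    AnnealSchedule,
    IntegratorConfig,
    maxwell_velocities,
    minimize,
    rattle_project,
    run_ensemble,
    shake_project,
    velocity_verlet_step,
    wall_force,
)
from pdmslab.system import Molecule, State, Topology, Wall
from pdmslab.templates import water
from tests.conftest import lj_fluid


class TestVelocityVerlet:
    def test_free_flight_is_exact(self, ff):
        st = lj_fluid(1, spacing=100.0)
        st.velocities[0] = [0.01, 0.0, 0.0]
        cfg = IntegratorConfig(dt=1.0, ensemble="NVE")
        x0 = st.positions[0, 0]
        for _ in range(100):
            st, _ = velocity_verlet_step(st, ff, cfg)
        assert st.positions[0, 0] - x0 == pytest.approx(1.0, rel=1e-12)

    def test_harmonic_oscillator_period(self, ff):
        k, r0 = 300.0, 1.5
        top = Topology(kinds=["CH3", "CH3"], masses=np.array([15.0, 15.0]),
                       charges=np.zeros(2),
                       molecules=[Molecule("d", np.array([0, 1]))],
                       bonds=[(0, 1, "osc")])
        ff_local = ff.with_()
        ff_local.bonded.bonds["osc"] = (k, r0)
        st = State(top, np.array([[0.0, 0, 0], [r0 + 0.1, 0, 0]]),
                   np.zeros((2, 3)), np.array([100.0] * 3),
                   np.array([False] * 3))
        mu = 15.0 / 2
        # E = k dr^2 acts as a spring of stiffness 2k
        period = 2 * np.pi / np.sqrt(2 * k * units.F2A / mu)
        cfg = IntegratorConfig(dt=period / 1000, ensemble="NVE")
        sep, f = [], None
        for _ in range(2500):
            st, f = velocity_verlet_step(st, ff_local, cfg, f)
            sep.append(st.positions[1, 0] - st.positions[0, 0])
        s = np.array(sep) - r0
        crossings = np.flatnonzero((s[:-1] > 0) & (s[1:] <= 0))
        measured = np.diff(crossings).mean() * cfg.dt
        assert measured == pytest.approx(period, rel=1e-3)

    def test_nve_energy_drift_scales_with_dt_squared(self, ff):
        ff_sf = ff.with_(lj_shift="force")
        rng = np.random.default_rng(4)
        fluctuations = []
        for dt in (0.5, 1.0, 2.0):
            st = lj_fluid(3, spacing=4.6)
            maxwell_velocities(st, 120.0, np.random.default_rng(4))
            cfg = IntegratorConfig(dt=dt, ensemble="NVE")
            _, traj = run_ensemble(st, ff_sf, cfg, int(400 / dt), stride=10)
            e_tot = np.array([
                fr.potential_energy
                + 0.5 * fr.temperature * units.KB * (3 * 27 - 3)
                for fr in traj
            ])
            fluctuations.append(e_tot.std())
        # quadrupling dt should grow the energy error by roughly 16x
        assert fluctuations[2] / fluctuations[0] > 4

    def test_zero_steps_returns_input_unchanged(self, ff):
        st = lj_fluid(2)
        final, traj = run_ensemble(st, ff, IntegratorConfig(), 0)
        assert final is st
        assert len(traj) == 0

    def test_nve_frame_energies_match_posthoc_recomputation(self, ff):
        from pdmslab.forcefield import total_potential_energy
        st = lj_fluid(2, spacing=4.8)
        maxwell_velocities(st, 100.0, np.random.default_rng(0))
        _, traj = run_ensemble(st, ff, IntegratorConfig(ensemble="NVE"),
                               200, stride=50)
        for fr in traj:
            st2 = State(st.topology, fr.positions, st.velocities, fr.box,
                        st.periodic)
            assert fr.potential_energy == pytest.approx(
                total_potential_energy(st2, ff), rel=1e-10)

    def test_trajectory_determinism_under_seed(self, ff):
        st = lj_fluid(2, spacing=4.8)
        cfg = IntegratorConfig(ensemble="NVT", T_target=150.0, seed=9,
                               thermostat="langevin")
        _, ta = run_ensemble(st, ff, cfg, 100, stride=20)
        _, tb = run_ensemble(st, ff, cfg, 100, stride=20)
        for fa, fb in zip(ta, tb):
            assert np.array_equal(fa.positions, fb.positions)


class TestShake:
    def test_stretched_water_restored_to_spc_geometry(self):
        w = water()
        pos = w.coords.copy()
        pos[1] = pos[0] + (pos[1] - pos[0]) * 1.05
        out = shake_project(pos, pos, w.constraints, w.masses, tol=1e-10)
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(1.0, rel=1e-8)
        assert np.linalg.norm(out[2] - out[0]) == pytest.approx(1.0, rel=1e-8)
        # H-H target is 2 sin(109.47deg / 2) = 1.6329809
        assert np.linalg.norm(out[2] - out[1]) == pytest.approx(
            1.6329809, rel=1e-6)

    def test_satisfied_constraints_are_fixed_point(self):
        w = water()
        out = shake_project(w.coords, w.coords, w.constraints, w.masses)
        assert np.allclose(out, w.coords, atol=1e-12)

    def test_center_of_mass_preserved(self):
        w = water()
        rng = np.random.default_rng(3)
        pos = w.coords + rng.normal(scale=0.08, size=w.coords.shape)
        out = shake_project(pos, pos, w.constraints, w.masses)
        com_before = np.average(pos, axis=0, weights=w.masses)
        com_after = np.average(out, axis=0, weights=w.masses)
        assert np.allclose(com_before, com_after, atol=1e-12)

    def test_rattle_removes_bond_relative_velocities(self):
        w = water()
        rng = np.random.default_rng(5)
        vel = rng.normal(scale=0.01, size=(3, 3))
        out = rattle_project(vel, w.coords, w.constraints, w.masses)
        for i, j, _ in w.constraints:
            r = w.coords[i] - w.coords[j]
            assert abs(np.dot(r, out[i] - out[j])) < 1e-10
        # momentum conserved
        p0 = (w.masses[:, None] * vel).sum(axis=0)
        p1 = (w.masses[:, None] * out).sum(axis=0)
        assert np.allclose(p0, p1, atol=1e-12)

    def test_constraints_hold_during_dynamics(self, ff, water_box):
        cfg = IntegratorConfig(ensemble="NVT", T_target=298.15, seed=1)
        final, _ = run_ensemble(water_box, ff, cfg, 300, stride=100)
        for i, j, d in final.topology.constraints:
            r = np.linalg.norm(final.positions[i] - final.positions[j])
            assert abs(r - d) / d < 1e-7


class TestThermostat:
    def test_nvt_water_reaches_target_temperature(self, ff, water_box):
        cfg = IntegratorConfig(ensemble="NVT", T_target=298.15, seed=2)
        _, traj = run_ensemble(water_box, ff, cfg, 2500, stride=25)
        temps = [fr.temperature for fr in traj][40:]
        assert 292.0 < np.mean(temps) < 304.0

    def test_langevin_fluid_reaches_target_temperature(self, ff):
        st = lj_fluid(3, spacing=4.6)
        cfg = IntegratorConfig(ensemble="NVT", T_target=200.0, seed=3,
                               thermostat="langevin", langevin_gamma=0.05)
        _, traj = run_ensemble(st, ff, cfg, 2000, stride=20)
        temps = [fr.temperature for fr in traj][30:]
        assert abs(np.mean(temps) - 200.0) / 200.0 < 0.05

    def test_runaway_temperature_raises_stability_error(self, ff):
        st = lj_fluid(2, spacing=4.8)
        maxwell_velocities(st, 120.0, np.random.default_rng(0))
        st.velocities *= 40.0  # inject a huge kinetic spike
        cfg = IntegratorConfig(ensemble="NVT", T_target=100.0, seed=0)
        with pytest.raises(StabilityError):
            run_ensemble(st, ff, cfg, 50, stride=10,
                         initialize_velocities=False)


class TestAnnealSchedule:
    def test_level_sequence_of_the_cooling_protocol(self):
        sched = AnnealSchedule(T_high=408.15, T_low=298.15, step=10.0)
        levels = sched.levels()
        assert len(levels) == 12
        assert levels[0] == pytest.approx(408.15)
        assert levels[-1] == pytest.approx(298.15)

    def test_degenerate_schedule_is_single_level(self):
        sched = AnnealSchedule(T_high=300.0, T_low=300.0, step=10.0)
        assert list(sched.levels()) == [300.0]

    def test_inverted_schedule_rejected(self):
        with pytest.raises(ParameterError):
            AnnealSchedule(T_high=100.0, T_low=300.0)


class TestWallForce:
    def test_zero_beyond_interaction_range(self):
        wall = Wall(x0=0.0, side=+1, sigma=3.0)
        assert np.allclose(wall_force([10.0, 0, 0], wall), 0.0)

    def test_repulsion_points_inward_and_grows_monotonically(self):
        wall = Wall(x0=0.0, side=+1, sigma=3.0)
        f_far = wall_force([3.0, 0, 0], wall)[0]
        f_near = wall_force([2.0, 0, 0], wall)[0]
        assert f_far > 0          # pushes toward larger x
        assert f_near > f_far     # monotone in proximity

    def test_species_filter_exempts_water(self):
        wall = Wall(x0=0.0, side=+1, sigma=3.0,
                    species=frozenset({"pdms-n1"}))
        assert np.allclose(wall_force([1.0, 0, 0], wall, species="water"),
                           0.0)
        assert wall_force([1.0, 0, 0], wall, species="pdms-n1")[0] > 0


class TestMinimize:
    def test_reduces_energy_and_forces(self, ff):
        from pdmslab.forcefield import evaluate
        st = lj_fluid(2, spacing=4.0)
        rng = np.random.default_rng(0)
        st.positions += rng.normal(scale=0.3, size=st.positions.shape)
        u0, _, _ = evaluate(st, ff)
        relaxed = minimize(st, ff, max_steps=200, f_tol=1.0)
        u1, f1, _ = evaluate(relaxed, ff)
        assert u1 < u0
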