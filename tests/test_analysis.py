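"""Analysis tests: profiles, interfaces, partitioning, transport, errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdmslab import analysis as A
from pdmslab.errors import AnalysisError, FitError, ParameterError
from pdmslab.synthetic import (
    PartitionScenario,
    make_brownian_trajectory,
    make_partition_trajectory,
)
from pdmslab.system import Frame, Molecule, Topology, Trajectory


def _single_site_traj(xs, box=(128.0, 40.0, 40.0), species="s", n_frames=1):
    """Trajectory of single-site molecules at fixed x positions."""
    xs = np.asarray(xs, float)
    n = len(xs)
    top = Topology(kinds=["m"] * n, masses=np.full(n, 10.0),
                   charges=np.zeros(n),
                   molecules=[Molecule(species, np.array([i]))
                              for i in range(n)])
    pos = np.zeros((n, 3))
    pos[:, 0] = xs
    pos[:, 1] = 20.0
    pos[:, 2] = 20.0
    frames = [Frame(step=t, time=float(t), positions=pos.copy(),
                    box=np.array(box)) for t in range(n_frames)]
    return Trajectory(topology=top, frames=frames, unwrapped=True)


class TestMoleculeCoordinate:
    def test_single_site_molecule_returns_its_own_x(self):
        assert A.molecule_coordinate(np.array([[3.7, 1, 2]]),
                                     np.array([5.0])) == 3.7

    def test_symmetric_triatomic_returns_central_site(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        m = np.array([1.0, 1.0, 1.0])
        assert A.molecule_coordinate(pos, m) == 1.0

    def test_matches_brute_force_min_distance_scan(self):
        rng = np.random.default_rng(7)
        pos = rng.normal(size=(13, 3)) * 3
        m = rng.uniform(1, 30, size=13)
        com = np.average(pos, axis=0, weights=m)
        d = np.linalg.norm(pos - com, axis=1)
        assert A.molecule_coordinate(pos, m) == pos[np.argmin(d), 0]


class TestDensityProfile:
    def test_point_mass_lands_in_the_right_half_open_bin(self):
        traj = _single_site_traj([10.0] * 5)
        prof = A.density_profile(traj, bin_width=1.5)
        # 10.0 / 1.5 -> bin 6 = [9.0, 10.5)
        assert prof.counts["s"][6] == 5.0
        assert prof.counts["s"].sum() == 5.0

    def test_counts_conserved_per_frame(self):
        sc = PartitionScenario(occupancies={"phenol": (30, 20)}, n_frames=10,
                               seed=2)
        traj = make_partition_trajectory(sc)
        prof = A.density_profile(traj, bin_width=1.5)
        for s, arr in prof.per_frame.items():
            n_mol = sum(1 for m in traj.topology.molecules if m.species == s)
            assert np.all(arr.sum(axis=1) == n_mol)

    def test_step_profile_recovered_within_binning_error(self):
        sc = PartitionScenario(occupancies={}, n_pdms_markers=4000,
                               n_frames=4, seed=3)
        traj = make_partition_trajectory(sc)
        prof = A.density_profile(traj, bin_width=1.5)
        centers = prof.centers
        inside = (centers > 52) & (centers < 76)
        outside = (centers < 47) | (centers > 81)
        dens = prof.counts["pdms"]
        expected = 4000 * 1.5 / 28.0
        assert dens[inside].mean() == pytest.approx(expected, rel=0.05)
        assert dens[outside].max() == 0.0

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ParameterError):
            A.density_profile(_single_site_traj([1.0]), bin_width=0.0)


class TestLocateInterfaces:
    def test_ideal_step_profile_found_within_one_bin(self):
        sc = PartitionScenario(occupancies={}, n_pdms_markers=5000,
                               n_frames=5, seed=4)
        traj = make_partition_trajectory(sc)
        prof = A.density_profile(traj, bin_width=1.5)
        xl, xr = A.locate_interfaces(prof, species="pdms")
        assert xl == pytest.approx(50.0, abs=1.5)
        assert xr == pytest.approx(78.0, abs=1.5)

    def test_interfaces_symmetric_for_symmetric_profile(self):
        sc = PartitionScenario(occupancies={}, n_pdms_markers=5000,
                               n_frames=5, seed=5)
        traj = make_partition_trajectory(sc)
        prof = A.density_profile(traj, bin_width=1.5)
        xl, xr = A.locate_interfaces(prof, species="pdms")
        center = 0.5 * (50.0 + 78.0)
        assert (center - xl) == pytest.approx(xr - center, abs=1.5)

    def test_all_zero_profile_raises_analysis_error(self):
        traj = _single_site_traj([10.0], species="pdms")
        prof = A.density_profile(traj, bin_width=1.5)
        prof.counts["pdms"][:] = 0.0
        with pytest.raises(AnalysisError):
            A.locate_interfaces(prof, species="pdms")

    def test_nominal_positions_bypass_detection(self):
        traj = _single_site_traj([10.0], species="pdms")
        prof = A.density_profile(traj, bin_width=1.5)
        assert A.locate_interfaces(prof, nominal=(50.0, 78.0)) == (50.0, 78.0)


class TestPartitionCounts:
    def test_prescribed_occupancies_recovered_exactly(self):
        sc = PartitionScenario(occupancies={"phenol": (140, 50)}, n_frames=20,
                               seed=6)
        traj = make_partition_trajectory(sc)
        part = A.partition_counts(traj, (50.0, 78.0), margin=3.0)
        assert part.counts["phenol"] == {"pdms": 140.0, "water": 50.0,
                                         "excluded": 0.0}

    def test_boundary_molecule_assigned_to_pdms_side(self):
        # exactly at x_left + margin: closed polymer boundary
        traj = _single_site_traj([53.0])
        part = A.partition_counts(traj, (50.0, 78.0), margin=3.0)
        assert part.counts["s"]["pdms"] == 1.0

    def test_classification_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(8)
        xs = rng.uniform(0, 128, size=1000)
        traj = _single_site_traj(xs)
        part = A.partition_counts(traj, (50.0, 78.0), margin=3.0)
        c = part.counts["s"]
        assert c["pdms"] + c["water"] + c["excluded"] == 1000
        # brute-force re-classification
        n_p = np.sum((xs >= 53.0) & (xs <= 75.0))
        n_w = np.sum((xs < 47.0) | (xs > 81.0))
        assert c["pdms"] == n_p
        assert c["water"] == n_w

    def test_margin_wider_than_half_slab_rejected(self):
        traj = _single_site_traj([10.0])
        with pytest.raises(ParameterError):
            A.partition_counts(traj, (50.0, 78.0), margin=14.0)


class TestLogP:
    def test_phenol_room_temperature_arithmetic(self):
        # printed counts with the nominal 28/48 A geometry
        value = A.log_p(140, 28 * 40 * 40, 50, 2 * 48 * 40 * 40)
        assert value == pytest.approx(0.98, abs=0.005)
        assert abs(value - 1.0) < 0.06  # within the reported uncertainty

    def test_equal_concentrations_give_zero(self):
        assert A.log_p(10, 1000.0, 20, 2000.0) == 0.0

    def test_guaiacol_arithmetic(self):
        value = A.log_p(86, 28 * 40 * 40, 27, 2 * 48 * 40 * 40)
        assert value == pytest.approx(1.04, abs=0.005)
        assert abs(value - 1.03) < 0.05

    def test_empty_phase_flags_undefined(self):
        assert math.isnan(A.log_p(0, 100.0, 5, 100.0))
        assert math.isnan(A.log_p(5, 100.0, 0, 100.0))


class TestMolarSolubility:
    def test_unit_definition_of_the_conversion(self):
        # one molecule in 1660.54 A^3 is 1 mol/L by definition
        assert A.molar_solubility(1, 1660.54) == pytest.approx(1.0, abs=1e-4)

    def test_phenol_solubility_in_the_polymer_slab(self):
        assert A.molar_solubility(140, 28 * 40 * 40) == pytest.approx(
            5.19, abs=0.005)

    def test_zero_count_gives_zero(self):
        assert A.molar_solubility(0, 123.0) == 0.0

    def test_phenethyl_alcohol_at_elevated_temperature(self):
        assert A.molar_solubility(108, 28 * 40 * 40) == pytest.approx(
            4.00, abs=0.005)


class TestMsd:
    def test_stationary_particles_have_zero_msd(self):
        traj = _single_site_traj([5.0, 9.0, 13.0], n_frames=10)
        t, m = A.msd(traj)
        assert np.all(m == 0.0)

    def test_ballistic_motion_is_quadratic(self):
        v = 0.02  # A/fs
        n_frames = 20
        top = Topology(kinds=["m"], masses=np.array([10.0]),
                       charges=np.zeros(1),
                       molecules=[Molecule("s", np.array([0]))])
        frames = [Frame(step=t, time=t * 100.0,
                        positions=np.array([[v * t * 100.0, 0.0, 0.0]]),
                        box=np.array([1e4] * 3)) for t in range(n_frames)]
        traj = Trajectory(topology=top, frames=frames, unwrapped=True)
        t_ps, m = A.msd(traj, origin_stride=1)
        v_ps = v * 1000.0  # A/ps
        assert m[1:] == pytest.approx((v_ps * t_ps[1:]) ** 2, rel=1e-10)

    def test_wrapped_trajectory_rejected(self):
        traj = _single_site_traj([5.0], n_frames=5)
        traj.unwrapped = False
        with pytest.raises(AnalysisError):
            A.msd(traj)

    def test_brownian_ensemble_slope_matches_2nD(self):
        d_true = 1.0e-5
        traj = make_brownian_trajectory({"s": d_true}, n_particles=150,
                                        dt=1000.0, n_steps=400, seed=9)
        t, m = A.msd(traj, species="s")
        est = A.diffusion_coefficient(t, m, dimension=3)
        assert est.D_cm2_s == pytest.approx(d_true, rel=0.05)


class TestDiffusionCoefficient:
    def test_exact_linear_msd_recovers_D(self):
        t = np.linspace(0, 10, 50)
        m = 6.0 * 2.0 * t  # 3-D Einstein with D = 2 A^2/ps
        est = A.diffusion_coefficient(t, m, dimension=3)
        assert est.D_cm2_s == pytest.approx(2.0e-4, rel=1e-12)

    def test_zero_msd_gives_zero_D(self):
        t = np.linspace(0, 10, 30)
        est = A.diffusion_coefficient(t, np.zeros(30))
        assert est.D_cm2_s == 0.0

    def test_short_window_raises_fit_error(self):
        t = np.linspace(0, 10, 30)
        with pytest.raises(FitError):
            A.diffusion_coefficient(t, t, fit_window=(5, 7))

    @pytest.mark.parametrize("d_true", [1e-6, 1e-5, 1e-4])
    def test_recovery_across_three_decades(self, d_true):
        traj = make_brownian_trajectory({"s": d_true}, n_particles=150,
                                        dt=1000.0, n_steps=400, seed=17)
        t, m = A.msd(traj, species="s")
        # fit the well-sampled early-to-middle lags
        est = A.diffusion_coefficient(t, m, fit_window=(2, len(t) // 2))
        assert est.D_cm2_s == pytest.approx(d_true, rel=0.05)


class TestBlockSem:
    def test_constant_series_has_zero_sem(self):
        ba = A.block_sem(np.full(100, 3.3), 10)
        assert ba.sem == 0.0
        assert ba.mean == pytest.approx(3.3)

    def test_alternating_series_blocks_to_zero(self):
        series = np.tile([1.0, -1.0], 50)
        ba = A.block_sem(series, 2)
        assert np.all(ba.block_means == 0.0)
        assert ba.sem == 0.0

    def test_grand_mean_invariant_to_blocking(self):
        rng = np.random.default_rng(2)
        series = rng.normal(size=120)
        for L in (2, 5, 12, 60):
            assert A.block_sem(series, L).mean == pytest.approx(
                series[: (120 // L) * L].mean())

    def test_autocorrelated_series_inflates_block_sem(self):
        # AR(1) with phi = 0.9: naive SEM underestimates the true error
        rng = np.random.default_rng(11)
        n = 20000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = 0.9 * x[i - 1] + eps[i]
        naive = x.std(ddof=1) / math.sqrt(n)
        blocked = A.block_sem(x, 500).sem
        # analytic inflation factor sqrt((1+phi)/(1-phi)) = sqrt(19) = 4.36
        assert blocked / naive > 2.5

    def test_fewer_than_two_blocks_rejected(self):
        with pytest.raises(ParameterError):
            A.block_sem(np.arange(10.0), 10)

    @given(st.integers(2, 10))
    @settings(max_examples=20, deadline=None)
    def test_sem_nonnegative(self, block_length):
        rng = np.random.default_rng(block_length)
        series = rng.normal(size=block_length * 7)
        assert A.block_sem(series, block_length).sem >= 0.0


class TestLogpConvergence:
    def test_stationary_scenario_plateaus_at_static_value(self):
        sc = PartitionScenario(occupancies={"phenol": (140, 50)}, n_frames=60,
                               seed=13)
        traj = make_partition_trajectory(sc)
        res = A.logp_convergence(traj, (50.0, 78.0), "phenol", stride=2,
                                 vol_pdms=28 * 40 * 40,
                                 vol_water=2 * 48 * 40 * 40)
        assert res.plateaued
        assert res.final == pytest.approx(
            A.log_p(140, 28 * 40 * 40, 50, 2 * 48 * 40 * 40), abs=1e-9)

    def test_drifting_counts_do_not_plateau(self):
        # linear drift of molecules from water into the slab
        n, frames = 60, 40
        top = Topology(kinds=["m"] * n, masses=np.full(n, 10.0),
                       charges=np.zeros(n),
                       molecules=[Molecule("phenol", np.array([i]))
                                  for i in range(n)])
        traj_frames = []
        for t in range(frames):
            n_in = 5 + t  # keeps drifting, never settles
            pos = np.zeros((n, 3))
            pos[:n_in, 0] = 60.0
            pos[n_in:, 0] = 20.0
            traj_frames.append(Frame(step=t, time=float(t),
                                     positions=pos,
                                     box=np.array([128.0, 40.0, 40.0])))
        traj = Trajectory(topology=top, frames=traj_frames)
        res = A.logp_convergence(traj, (50.0, 78.0), "phenol", stride=2)
        assert not res.plateaued

    def test_exponential_relaxation_plateaus_near_time_constant(self):
        sc = PartitionScenario(
            occupancies={"phenol": (140, 50)},
            initial_occupancies={"phenol": (0, 190)},
            relaxation_frames=15.0, n_frames=150, seed=21)
        traj = make_partition_trajectory(sc)
        res = A.logp_convergence(traj, (50.0, 78.0), "phenol", stride=5,
                                 vol_pdms=28 * 40 * 40,
                                 vol_water=2 * 48 * 40 * 40)
        assert res.plateaued
        target = A.log_p(140, 28 * 40 * 40, 50, 2 * 48 * 40 * 40)
        assert res.final == pytest.approx(target, abs=0.15)
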