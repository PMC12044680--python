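"""Force-field unit tests: mixing, pair potentials, bonded terms, forces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdmslab import forcefield as F
from pdmslab.errors import (
    ParameterError,
    SingularityError,
    UnknownKindError,
)
from pdmslab.forcefield import (
    CH3_SIGMA_SCALE,
    PairTable,
    SiteKind,
    apply_ch3_sigma_modification,
    coulomb_pair_energy,
    lj_pair_energy,
    mix_pair_params,
)
from pdmslab.system import Molecule, State, Topology
from pdmslab.templates import pdms_oligomer, phenol


# ---------------------------------------------------------------------------
# pair parameter mixing
# ---------------------------------------------------------------------------

class TestMixing:
    def test_explicit_table_row_overrides_mixing(self, ff):
        # tabulated Si-CH3 row, not the Lorentz-Berthelot value
        assert ff.pair_params("Si", "CH3") == (0.1596, 3.83)

    def test_self_pair_without_entry_is_identity(self):
        table = PairTable()
        x = SiteKind("X", 10.0, 0.0, 0.25, 3.1)
        assert mix_pair_params(x, x, table) == (0.25, 3.1)

    def test_scaled_cross_term_matches_hand_arithmetic(self, ff):
        # water-O vs aromatic-C with the 1.20 affinity correction
        ow, ca = ff.kind("OW"), ff.kind("CA")
        eps, sig = ff.pair_params("OW", "CA")
        assert eps == pytest.approx(1.20 * math.sqrt(ow.epsilon * ca.epsilon))
        assert sig == pytest.approx(0.5 * (ow.sigma + ca.sigma))

    def test_unknown_kind_error_names_the_kind(self, ff):
        with pytest.raises(UnknownKindError, match="unobtainium"):
            ff.pair_params("Si", "unobtainium")

    @given(e1=st.floats(0.01, 2.0), e2=st.floats(0.01, 2.0),
           s1=st.floats(2.0, 5.0), s2=st.floats(2.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_mixing_is_symmetric(self, e1, e2, s1, s2):
        table = PairTable()
        a = SiteKind("A", 1.0, 0.0, e1, s1)
        b = SiteKind("B", 1.0, 0.0, e2, s2)
        assert mix_pair_params(a, b, table) == mix_pair_params(b, a, table)


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

class TestPairPotentials:
    def test_lj_zero_at_sigma_and_minimum_at_r_min(self):
        assert lj_pair_energy(3.86, 0.1944, 3.86) == pytest.approx(0.0)
        r_min = 2 ** (1 / 6) * 3.86
        assert lj_pair_energy(r_min, 0.1944, 3.86) == pytest.approx(-0.1944)

    def test_lj_tabulated_ch3_pair_at_5A(self):
        # hand-evaluated 4 eps [(sig/r)^12 - (sig/r)^6]
        assert lj_pair_energy(5.0, 0.1944, 3.86) == pytest.approx(
            -0.1298, abs=5e-5)

    def test_lj_rejects_nonpositive_separation(self):
        with pytest.raises(ParameterError):
            lj_pair_energy(0.0, 0.1, 3.0)

    def test_direct_coulomb_unit_charges_at_1A(self):
        assert coulomb_pair_energy(1.0, 1.0, 1.0, "direct") == pytest.approx(
            332.06, abs=0.01)

    def test_coulomb_zero_charge_is_zero(self):
        for r in (0.5, 3.0, 11.0):
            assert coulomb_pair_energy(r, 0.0, 0.7, "direct") == 0.0

    def test_dsf_energy_vanishes_at_cutoff(self):
        e = coulomb_pair_energy(12.0, 1.0, -1.0, "damped-shifted-force",
                                cutoff=12.0, alpha=0.2)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_reaction_field_energy_vanishes_at_cutoff(self):
        e = coulomb_pair_energy(12.0, 1.0, 1.0, "reaction-field", cutoff=12.0)
        assert e == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["damped-shifted-force",
                                        "reaction-field"])
    def test_closures_reduce_to_direct_coulomb_at_short_range(self, method):
        r = 0.002  # r << cutoff (the O(r/Rc) shift is negligible here)
        direct = coulomb_pair_energy(r, 1.0, 1.0, "direct")
        closed = coulomb_pair_energy(r, 1.0, 1.0, method, cutoff=12.0,
                                     alpha=1e-6)
        assert closed == pytest.approx(direct, rel=1e-3)

    def test_dsf_force_goes_continuously_to_zero_at_cutoff(self):
        rc = 12.0
        _, f = F._coulomb_e_f(np.array([rc - 1e-9]), 332.06,
                              "damped-shifted-force", rc, 0.2, 78.5)
        assert abs(f[0]) < 1e-6


# ---------------------------------------------------------------------------
# CH3 sigma modification
# ---------------------------------------------------------------------------

class TestCh3Sigma:
    def test_forward_application_recovers_tabulated_value(self):
        assert apply_ch3_sigma_modification(3.7298) == pytest.approx(
            3.860, abs=5e-4)

    def test_unit_input_scales_by_factor(self):
        assert apply_ch3_sigma_modification(1.0) == CH3_SIGMA_SCALE

    def test_round_trip_is_identity(self):
        x = apply_ch3_sigma_modification(3.123) / CH3_SIGMA_SCALE
        assert x == pytest.approx(3.123, rel=1e-12)


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _single_bond_topology(k=300.0, r0=1.5):
    top = Topology(kinds=["CH3", "CH3"], masses=np.array([15.0, 15.0]),
                   charges=np.zeros(2),
                   molecules=[Molecule("m", np.array([0, 1]))],
                   bonds=[(0, 1, "test")])
    terms = F.BondedTerms(bonds={"test": (k, r0)})
    return top, terms


class TestBondedEnergy:
    def test_zero_at_equilibrium_geometry(self, ff):
        t = pdms_oligomer(1)
        top = Topology(kinds=t.kinds, masses=t.masses, charges=t.charges,
                       molecules=[Molecule(t.name, np.arange(t.n_sites))],
                       bonds=t.bonds, angles=t.angles, dihedrals=t.dihedrals)
        # idealize geometry onto the term minima: strip dihedrals, relax
        terms = F.BondedTerms(
            bonds={"SiO": (350.0, 1.64), "SiC": (190.0, 1.90)},
            angles={}, dihedrals={},
        )
        pos = t.coords.copy()
        # place each bond exactly at its r0 along its current direction
        for i, j, typ in t.bonds:
            d = pos[j] - pos[i]
            pos[j] = pos[i] + d / np.linalg.norm(d) * terms.bonds[typ][1]
        top2 = Topology(kinds=t.kinds, masses=t.masses, charges=t.charges,
                        molecules=[Molecule(t.name, np.arange(t.n_sites))],
                        bonds=[t.bonds[0]])
        total, _ = F.bonded_energy(top2, pos, terms)
        assert total == pytest.approx(0.0, abs=1e-18)

    def test_stretched_bond_follows_k_dr_squared_convention(self):
        top, terms = _single_bond_topology(k=300.0, r0=1.5)
        pos = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])
        total, breakdown = F.bonded_energy(top, pos, terms)
        assert total == pytest.approx(300.0 * 0.1**2)  # 3.0 kcal/mol
        assert breakdown["bond"] == pytest.approx(total)

    def test_half_harmonic_convention_flag(self):
        top, terms = _single_bond_topology(k=300.0, r0=1.5)
        pos = np.array([[0.0, 0.0, 0.0], [1.6, 0.0, 0.0]])
        total, _ = F.bonded_energy(top, pos, terms, half_harmonic=True)
        assert total == pytest.approx(150.0 * 0.1**2)

    def test_breakdown_sums_to_total(self):
        t = phenol()
        top = Topology(kinds=t.kinds, masses=t.masses, charges=t.charges,
                       molecules=[Molecule(t.name, np.arange(t.n_sites))],
                       bonds=t.bonds, angles=t.angles, dihedrals=t.dihedrals)
        rng = np.random.default_rng(0)
        pos = t.coords + rng.normal(scale=0.05, size=t.coords.shape)
        from pdmslab.parameters import default_forcefield
        terms = default_forcefield().bonded
        total, breakdown = F.bonded_energy(top, pos, terms)
        assert sum(breakdown.values()) == pytest.approx(total, rel=1e-12)

    def test_missing_site_raises_topology_error(self):
        top, terms = _single_bond_topology()
        top.bonds = [(0, 5, "test")]
        with pytest.raises(F.TopologyError):
            F.bonded_energy(top, np.zeros((2, 3)), terms)


# ---------------------------------------------------------------------------
# total energy and forces
# ---------------------------------------------------------------------------

def _random_mixed_state(ff, seed=3, jitter=0.05):
    from pdmslab.builder import assemble_system, pack_nonoverlapping
    from pdmslab.templates import pdms_oligomer, phenol, water
    box = np.array([25.0, 25.0, 25.0])
    placements = pack_nonoverlapping(
        [(phenol(), 1), (pdms_oligomer(1), 1), (water(), 3)],
        (np.zeros(3), box), min_dist=2.2, seed=seed, box=box,
        periodic=np.array([True] * 3))
    state = assemble_system(placements, box, periodic=(True, True, True))
    rng = np.random.default_rng(seed)
    state.positions += rng.normal(scale=jitter, size=state.positions.shape)
    return state


class TestTotalEnergy:
    def test_isolated_lj_dimer_at_minimum_is_minus_epsilon(self, ff):
        r_min = 2 ** (1 / 6) * 3.86
        top = Topology(kinds=["CH3", "CH3"], masses=np.array([15.0, 15.0]),
                       charges=np.zeros(2),
                       molecules=[Molecule("a", np.array([0])),
                                  Molecule("b", np.array([1]))])
        st = State(top, np.array([[0.0, 0, 0], [r_min, 0, 0]]),
                   np.zeros((2, 3)), np.array([100.0] * 3),
                   np.array([False] * 3))
        u = F.total_potential_energy(
            st, ff.with_(lj_shift="none"), apply_cutoff=False)
        assert u == pytest.approx(-0.1944, rel=1e-12)

    def test_energy_invariant_under_box_translation(self, ff):
        st = _random_mixed_state(ff)
        u0 = F.total_potential_energy(st, ff)
        st.positions[:, 1] += st.box[1]
        u1 = F.total_potential_energy(st, ff)
        assert u1 == pytest.approx(u0, rel=1e-10)

    def test_matches_naive_double_loop_oracle(self, ff):
        """Cutoff-free nonbonded energy vs a brute-force O(N^2) loop."""
        rng = np.random.default_rng(11)
        n = 50
        kinds = list(rng.choice(["CH3", "OW", "CA"], size=n))
        charges = rng.uniform(-0.3, 0.3, size=n)
        top = Topology(kinds=kinds, masses=np.full(n, 15.0), charges=charges,
                       molecules=[Molecule("m", np.array([i]))
                                  for i in range(n)])
        box = np.array([60.0] * 3)
        pos = rng.uniform(5, 55, size=(n, 3))
        # enforce no overlaps for numerical comparability
        from scipy.spatial.distance import pdist
        assert pdist(pos).min() > 0.5
        st = State(top, pos, np.zeros((n, 3)), box, np.array([False] * 3))
        ffd = ff.with_(electrostatics="direct", lj_shift="none")
        u_vec = F.total_potential_energy(st, ffd, apply_cutoff=False)
        u_naive = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                eps, sig = ffd.pair_params(kinds[i], kinds[j])
                r = float(np.linalg.norm(pos[i] - pos[j]))
                if eps > 0:
                    u_naive += lj_pair_energy(r, eps, sig)
                u_naive += 332.06371 * charges[i] * charges[j] / r
        assert u_vec == pytest.approx(u_naive, rel=1e-10)

    def test_overlapping_sites_raise_singularity_error(self, ff):
        top = Topology(kinds=["CH3", "CH3"], masses=np.array([15.0, 15.0]),
                       charges=np.zeros(2),
                       molecules=[Molecule("a", np.array([0])),
                                  Molecule("b", np.array([1]))])
        st = State(top, np.array([[1.0, 1, 1], [1.0, 1, 1 + 1e-9]]),
                   np.zeros((2, 3)), np.array([50.0] * 3),
                   np.array([True] * 3))
        with pytest.raises(SingularityError):
            F.total_potential_energy(st, ff)


class TestForces:
    def test_analytic_forces_match_central_differences(self, ff):
        st = _random_mixed_state(ff, seed=5)
        u, f, _ = F.evaluate(st, ff)
        h = 1e-5
        rng = np.random.default_rng(0)
        # probe 20 random site/axis combinations
        scale = np.abs(f).max()
        for _ in range(20):
            i = int(rng.integers(st.topology.n_sites))
            ax = int(rng.integers(3))
            p0 = st.positions[i, ax]
            st.positions[i, ax] = p0 + h
            up = F.total_potential_energy(st, ff)
            st.positions[i, ax] = p0 - h
            um = F.total_potential_energy(st, ff)
            st.positions[i, ax] = p0
            fd = -(up - um) / (2 * h)
            assert abs(fd - f[i, ax]) / scale < 1e-6

    def test_lj_dimer_forces_equal_and_opposite(self, ff):
        top = Topology(kinds=["CH3", "CH3"], masses=np.array([15.0, 15.0]),
                       charges=np.zeros(2),
                       molecules=[Molecule("a", np.array([0])),
                                  Molecule("b", np.array([1]))])
        st = State(top, np.array([[0.0, 0, 0], [4.1, 0, 0]]),
                   np.zeros((2, 3)), np.array([100.0] * 3),
                   np.array([False] * 3))
        f = F.forces(st, ff)
        assert np.allclose(f[0], -f[1])
        assert abs(f[0, 0]) > 0

    def test_force_vanishes_at_potential_minimum(self, ff):
        r_min = 2 ** (1 / 6) * 3.86
        top = Topology(kinds=["CH3", "CH3"], masses=np.array([15.0, 15.0]),
                       charges=np.zeros(2),
                       molecules=[Molecule("a", np.array([0])),
                                  Molecule("b", np.array([1]))])
        st = State(top, np.array([[0.0, 0, 0], [r_min, 0, 0]]),
                   np.zeros((2, 3)), np.array([100.0] * 3),
                   np.array([False] * 3))
        f = F.forces(st, ff.with_(lj_shift="none"), apply_cutoff=False)
        assert np.abs(f).max() < 1e-8

    def test_net_force_on_isolated_system_is_zero(self, ff):
        st = _random_mixed_state(ff, seed=9)
        f = F.forces(st, ff)
        assert np.abs(f.sum(axis=0)).max() < 1e-9


class TestSpecValidation:
    def test_cutoff_must_exceed_largest_sigma(self, ff):
        bad = ff.with_(cutoff=3.0)
        with pytest.raises(ParameterError):
            bad.validate()

    def test_unknown_electrostatics_method_rejected(self, ff):
        with pytest.raises(ParameterError):
            ff.with_(electrostatics="pppm")

    def test_site_kind_invariants(self):
        with pytest.raises(ParameterError):
            SiteKind("bad", -1.0, 0.0, 0.1, 3.0)
        with pytest.raises(ParameterError):
            SiteKind("bad", 1.0, 0.0, 0.1, 0.0)
        # LJ-inactive hydrogen with zero sigma is legitimate
        SiteKind("HO", 1.008, 0.4, 0.0, 0.0)
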