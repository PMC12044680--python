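"""Ground-truth generators and an independent thermodynamic oracle.

Every analysis stage can be exercised without running dynamics:

* :func:`make_partition_trajectory` emits slab trajectories with
  prescribed per-phase occupancies (optionally relaxing toward them via
  a per-molecule two-state Markov jump process),
* :func:`make_brownian_trajectory` emits unwrapped random walks with
  known diffusion coefficients,
* :func:`widom_log_p` estimates a partition coefficient from test-particle
  insertion chemical potentials, independently of any counting analysis,
* :func:`make_toy_two_phase_system` builds a frozen two-bath slab whose
  solute statistics can be sampled by Metropolis Monte Carlo and
  cross-checked against the Widom route.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .analysis import block_sem
from .errors import AnalysisError, ParameterError
from .system import Frame, Molecule, Topology, Trajectory

__all__ = [
    "PartitionScenario",
    "make_partition_trajectory",
    "make_brownian_trajectory",
    "BathEnsemble",
    "WidomResult",
    "widom_mu_excess",
    "widom_log_p",
    "ToyTwoPhaseSystem",
    "make_toy_two_phase_system",
    "mc_solute_partition",
]


# ---------------------------------------------------------------------------
# partition scenarios
# ---------------------------------------------------------------------------

@dataclass
class PartitionScenario:
    """Slab geometry plus prescribed per-phase occupancies.

    ``occupancies`` maps each mobile species to its equilibrium
    (pdms_count, water_count).  With ``relaxation_frames`` set, each
    molecule performs a two-state Markov jump process whose stationary
    distribution matches the occupancy split and whose autocorrelation
    time is the given number of frames, starting from
    ``initial_occupancies``; otherwise the prescribed counts are placed
    exactly in every frame.
    """

    pdms_width: float = 28.0
    water_width: float = 48.0
    edge_gap: float = 2.0
    ly: float = 40.0
    lz: float = 40.0
    occupancies: dict[str, tuple[int, int]] = field(default_factory=dict)
    n_pdms_markers: int = 89
    interface_width: float = 0.0
    exclusion_margin: float = 3.0
    placement_pad: float = 0.25
    relaxation_frames: float | None = None
    initial_occupancies: dict[str, tuple[int, int]] | None = None
    n_frames: int = 100
    frame_interval: float = 1000.0       # fs
    seed: int = 0

    @property
    def box(self) -> np.ndarray:
        lx = 2 * self.edge_gap + 2 * self.water_width + self.pdms_width
        return np.array([lx, self.ly, self.lz])

    @property
    def interfaces(self) -> tuple[float, float]:
        xl = self.edge_gap + self.water_width
        return (xl, xl + self.pdms_width)

    def validate(self) -> None:
        if self.pdms_width <= 0 or self.water_width <= 0:
            raise ParameterError("slab and water widths must be positive")
        pad = self.exclusion_margin + self.placement_pad
        if 2 * pad >= self.pdms_width:
            raise ParameterError(
                "exclusion margin leaves no polymer-phase interior")
        if pad >= self.water_width:
            raise ParameterError(
                "exclusion margin leaves no aqueous-phase interior")
        for sp, (a, b) in self.occupancies.items():
            if a < 0 or b < 0:
                raise ParameterError(f"occupancies for {sp} must be >= 0")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")


_MARKER_MASS = {"pdms": 236.53, "water": 18.015}


def make_partition_trajectory(scenario: PartitionScenario) -> Trajectory:
    """Synthesize a slab trajectory realizing the prescribed occupancies.

    Molecules are single-site markers.  Polymer markers fill the slab
    (edges optionally smeared by ``interface_width``); each mobile
    species is placed inside the phase interiors, strictly clear of the
    exclusion margins, so a margin-aware partition analysis recovers the
    prescribed counts exactly in the static case.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    xl, xr = scenario.interfaces
    box = scenario.box
    pad = scenario.exclusion_margin + scenario.placement_pad

    species_order = ["pdms"] + sorted(scenario.occupancies)
    kinds, masses, molecules = [], [], []
    idx = 0
    counts_total = {"pdms": scenario.n_pdms_markers}
    for sp, (a, b) in scenario.occupancies.items():
        counts_total[sp] = a + b
    for sp in species_order:
        for _ in range(counts_total[sp]):
            kinds.append(sp)
            masses.append(_MARKER_MASS.get(sp, 100.0))
            molecules.append(Molecule(sp, np.array([idx])))
            idx += 1
    top = Topology(kinds=kinds, masses=np.array(masses),
                   charges=np.zeros(idx), molecules=molecules)

    # per-molecule phase trajectories (True = polymer phase)
    n_mobile = {sp: counts_total[sp] for sp in scenario.occupancies}
    phase_series: dict[str, np.ndarray] = {}
    for sp, (a, b) in scenario.occupancies.items():
        total = a + b
        series = np.zeros((scenario.n_frames, total), dtype=bool)
        if total == 0:
            phase_series[sp] = series
            continue
        if scenario.relaxation_frames is None:
            series[:, :a] = True          # exact counts every frame
        else:
            p_eq = a / total
            tau = max(scenario.relaxation_frames, 1e-9)
            # two-state jump process: relaxation rate 1/tau, split by p_eq
            p_wp = (1 - math.exp(-1.0 / tau)) * p_eq        # water->polymer
            p_pw = (1 - math.exp(-1.0 / tau)) * (1 - p_eq)  # polymer->water
            init = scenario.initial_occupancies or {}
            a0, b0 = init.get(sp, (a, b))
            if a0 + b0 != total:
                raise ParameterError(
                    f"initial occupancies for {sp} must total {total}")
            state = np.zeros(total, dtype=bool)
            state[:a0] = True
            for t in range(scenario.n_frames):
                u = rng.random(total)
                flip_to_w = state & (u < p_pw)
                flip_to_p = (~state) & (u < p_wp)
                state = (state & ~flip_to_w) | flip_to_p
                series[t] = state
        phase_series[sp] = series

    # polymer marker x positions: uniform in slab, optionally smeared edges
    def pdms_x(n):
        x = xl + rng.random(n) * (xr - xl)
        if scenario.interface_width > 0:
            x = x + rng.normal(scale=scenario.interface_width, size=n)
        return np.clip(x, 0.0, box[0] - 1e-9)

    def polymer_interior_x(n):
        return xl + pad + rng.random(n) * ((xr - xl) - 2 * pad)

    def water_interior_x(n):
        w_lo = scenario.edge_gap
        left_w = (xl - pad) - w_lo
        right_lo = xr + pad
        right_w = (box[0] - scenario.edge_gap) - right_lo
        pick_left = rng.random(n) < left_w / (left_w + right_w)
        x = np.where(
            pick_left,
            w_lo + rng.random(n) * left_w,
            right_lo + rng.random(n) * right_w,
        )
        return x

    frames = []
    for t in range(scenario.n_frames):
        pos = np.zeros((top.n_sites, 3))
        pos[:, 1] = rng.random(top.n_sites) * box[1]
        pos[:, 2] = rng.random(top.n_sites) * box[2]
        cursor = 0
        pos[cursor:cursor + scenario.n_pdms_markers, 0] = pdms_x(
            scenario.n_pdms_markers)
        cursor += scenario.n_pdms_markers
        for sp in species_order[1:]:
            total = n_mobile[sp]
            in_p = phase_series[sp][t]
            x = np.empty(total)
            x[in_p] = polymer_interior_x(int(in_p.sum()))
            x[~in_p] = water_interior_x(int((~in_p).sum()))
            pos[cursor:cursor + total, 0] = x
            cursor += total
        frames.append(Frame(step=t, time=t * scenario.frame_interval,
                            positions=pos, box=box.copy()))
    return Trajectory(topology=top, frames=frames, unwrapped=False)


# ---------------------------------------------------------------------------
# Brownian trajectories
# ---------------------------------------------------------------------------

def make_brownian_trajectory(
    d_per_species: dict[str, float],
    n_particles: int = 100,
    dt: float = 1000.0,
    n_steps: int = 500,
    seed: int = 0,
    box: np.ndarray | None = None,
) -> Trajectory:
    """Unwrapped Gaussian random walks with prescribed D (cm^2/s).

    Per-axis displacement variance is 2 D dt, the discrete-time
    free-diffusion propagator.
    """
    for sp, d in d_per_species.items():
        if d < 0:
            raise ParameterError(f"D for {sp} must be >= 0")
    rng = np.random.default_rng(seed)
    if box is None:
        box = np.array([1e4, 1e4, 1e4])
    kinds, masses, molecules = [], [], []
    sigmas = []
    idx = 0
    for sp in sorted(d_per_species):
        d_a2fs = d_per_species[sp] / units.A2_PS_TO_CM2_S / units.FS_PER_PS
        sig = math.sqrt(2.0 * d_a2fs * dt)
        for _ in range(n_particles):
            kinds.append(sp)
            masses.append(100.0)
            molecules.append(Molecule(sp, np.array([idx])))
            sigmas.append(sig)
            idx += 1
    top = Topology(kinds=kinds, masses=np.array(masses),
                   charges=np.zeros(idx), molecules=molecules)
    sigmas = np.array(sigmas)[:, None]
    pos = rng.random((idx, 3)) * 20.0
    frames = [Frame(step=0, time=0.0, positions=pos.copy(), box=box.copy())]
    for t in range(1, n_steps + 1):
        pos = pos + rng.normal(size=(idx, 3)) * sigmas
        frames.append(Frame(step=t, time=t * dt, positions=pos.copy(),
                            box=box.copy()))
    return Trajectory(topology=top, frames=frames, unwrapped=True)


# ---------------------------------------------------------------------------
# Widom insertion oracle
# ---------------------------------------------------------------------------

@dataclass
class BathEnsemble:
    """Frozen bath configurations a ghost solute is inserted into."""

    frames: list[np.ndarray]
    box: np.ndarray
    pair_epsilon: float          # solute-bath LJ epsilon, kcal/mol
    pair_sigma: float            # A
    cutoff: float
    insert_lo: np.ndarray
    insert_hi: np.ndarray

    @classmethod
    def ideal_gas(cls, n_bath: int, box, pair_epsilon: float,
                  pair_sigma: float, n_frames: int = 20,
                  seed: int | np.random.Generator = 0,
                  cutoff: float | None = None,
                  region: tuple[np.ndarray, np.ndarray] | None = None):
        """Uncorrelated uniform bath configurations (ideal-gas structure)."""
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        box = np.asarray(box, float)
        frames = [rng.random((n_bath, 3)) * box for _ in range(n_frames)]
        lo, hi = (np.zeros(3), box) if region is None else region
        return cls(frames=frames, box=box, pair_epsilon=pair_epsilon,
                   pair_sigma=pair_sigma,
                   cutoff=cutoff if cutoff is not None else box.min() / 2,
                   insert_lo=np.asarray(lo, float),
                   insert_hi=np.asarray(hi, float))

    def insertion_energy(self, frame_index: int, position: np.ndarray) -> float:
        bath = self.frames[frame_index]
        d = bath - position
        d -= self.box * np.round(d / self.box)
        r2 = np.sum(d * d, axis=1)
        r2 = r2[r2 < self.cutoff**2]
        if r2.size == 0:
            return 0.0
        sr6 = (self.pair_sigma**2 / r2) ** 3
        return float(np.sum(4.0 * self.pair_epsilon * (sr6 * sr6 - sr6)))


@dataclass
class WidomResult:
    """Excess chemical potentials per phase and the implied log P."""

    mu_a: float
    mu_b: float
    se_mu_a: float
    se_mu_b: float
    log_p: float                 # decadic preference of phase A over B
    se_log_p: float
    n_insertions: int
    failed: bool = False


def widom_mu_excess(
    ensemble: BathEnsemble,
    kT: float,
    n_insertions: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Excess chemical potential -kT ln<exp(-dU/kT)> and its standard error."""
    if n_insertions <= 0:
        raise ParameterError("n_insertions must be > 0")
    beta = 1.0 / kT
    n_frames = len(ensemble.frames)
    frame_idx = rng.integers(0, n_frames, size=n_insertions)
    span = ensemble.insert_hi - ensemble.insert_lo
    positions = ensemble.insert_lo + rng.random((n_insertions, 3)) * span
    b = np.empty(n_insertions)
    for k in range(n_insertions):
        b[k] = math.exp(-beta * ensemble.insertion_energy(
            int(frame_idx[k]), positions[k]))
    mean_b = b.mean()
    if mean_b <= 0.0:
        return math.inf, math.inf
    mu = -kT * math.log(mean_b)
    se = kT * b.std(ddof=1) / (mean_b * math.sqrt(n_insertions))
    return mu, se


def widom_log_p(
    phase_a: BathEnsemble,
    phase_b: BathEnsemble,
    kT: float,
    n_insertions: int = 20000,
    seed: int = 0,
) -> WidomResult:
    """Partition coefficient of a ghost solute between two baths.

    log P = (mu_b - mu_a) / (kT ln 10): positive when the solute prefers
    phase A.  Swapping the phases flips the sign exactly.  A phase where
    every insertion overlaps is flagged as failed (infinite SE).
    """
    # fresh identically-seeded streams per phase: each phase's estimate is
    # independent of argument order, so swapping phases flips log P exactly
    mu_a, se_a = widom_mu_excess(phase_a, kT, n_insertions,
                                 np.random.default_rng(seed))
    mu_b, se_b = widom_mu_excess(phase_b, kT, n_insertions,
                                 np.random.default_rng(seed))
    failed = not (math.isfinite(mu_a) and math.isfinite(mu_b))
    ln10kt = kT * math.log(10.0)
    return WidomResult(
        mu_a=mu_a, mu_b=mu_b, se_mu_a=se_a, se_mu_b=se_b,
        log_p=(mu_b - mu_a) / ln10kt if not failed else math.nan,
        se_log_p=(math.sqrt(se_a**2 + se_b**2) / ln10kt
                  if not failed else math.inf),
        n_insertions=n_insertions, failed=failed,
    )


# ---------------------------------------------------------------------------
# toy two-phase system
# ---------------------------------------------------------------------------

@dataclass
class ToyTwoPhaseSystem:
    """Two frozen immiscible LJ baths in a slab, plus one mobile solute.

    Phase A occupies x in [0, Lx/2), phase B the other half (periodic in
    all directions).  The solute's LJ epsilon toward the A bath exceeds
    that toward the B bath by the affinity contrast.  Bath frames have
    ideal-gas structure so that insertion and counting estimates share
    an exactly common reference field.
    """

    box: np.ndarray
    frames_a: list[np.ndarray]
    frames_b: list[np.ndarray]
    eps_a: float
    eps_b: float
    sigma: float
    cutoff: float

    @property
    def half_x(self) -> float:
        return float(self.box[0]) / 2.0

    def solute_energy(self, frame_index: int, position: np.ndarray) -> float:
        e = 0.0
        for bath, eps in ((self.frames_a[frame_index], self.eps_a),
                          (self.frames_b[frame_index], self.eps_b)):
            d = bath - position
            d -= self.box * np.round(d / self.box)
            r2 = np.sum(d * d, axis=1)
            r2 = r2[r2 < self.cutoff**2]
            if r2.size:
                sr6 = (self.sigma**2 / r2) ** 3
                e += float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
        return e

    def phase_ensemble(self, phase: str, margin: float) -> BathEnsemble:
        """Insertion ensemble restricted to one phase interior.

        The ghost particle still interacts with both baths (as the real
        solute does), so the chemical potentials are directly comparable
        with the counting route.
        """
        if phase == "A":
            lo = np.array([margin, 0.0, 0.0])
            hi = np.array([self.half_x - margin, self.box[1], self.box[2]])
            eps_same, eps_other = self.eps_a, self.eps_b
            frames_same, frames_other = self.frames_a, self.frames_b
        elif phase == "B":
            lo = np.array([self.half_x + margin, 0.0, 0.0])
            hi = np.array([self.box[0] - margin, self.box[1], self.box[2]])
            eps_same, eps_other = self.eps_b, self.eps_a
            frames_same, frames_other = self.frames_b, self.frames_a
        else:
            raise ParameterError("phase must be 'A' or 'B'")
        return _TwoBathEnsemble(
            frames=frames_same, frames_other=frames_other,
            box=self.box, pair_epsilon=eps_same, pair_epsilon_other=eps_other,
            pair_sigma=self.sigma, cutoff=self.cutoff,
            insert_lo=lo, insert_hi=hi,
        )


@dataclass
class _TwoBathEnsemble(BathEnsemble):
    """Bath ensemble whose ghost also feels the opposite-phase bath."""

    frames_other: list[np.ndarray] = field(default_factory=list)
    pair_epsilon_other: float = 0.0

    def insertion_energy(self, frame_index: int, position: np.ndarray) -> float:
        e = super().insertion_energy(frame_index, position)
        bath = self.frames_other[frame_index]
        d = bath - position
        d -= self.box * np.round(d / self.box)
        r2 = np.sum(d * d, axis=1)
        r2 = r2[r2 < self.cutoff**2]
        if r2.size:
            sr6 = (self.pair_sigma**2 / r2) ** 3
            e += float(np.sum(4.0 * self.pair_epsilon_other * (sr6 * sr6 - sr6)))
        return e


def make_toy_two_phase_system(
    affinity_contrast: float,
    seed: int = 0,
    n_bath_per_phase: int = 40,
    box=(32.0, 16.0, 16.0),
    eps_base: float = 0.3,
    sigma: float = 3.0,
    n_frames: int = 24,
) -> ToyTwoPhaseSystem:
    """Build the frozen two-bath slab with the given affinity contrast.

    ``affinity_contrast`` multiplies the solute's epsilon toward phase A
    relative to phase B; 1.0 makes the two phases statistically
    equivalent.
    """
    if affinity_contrast <= 0:
        raise ParameterError("affinity contrast must be > 0")
    rng = np.random.default_rng(seed)
    box = np.asarray(box, float)
    half = box[0] / 2.0
    frames_a, frames_b = [], []
    for _ in range(n_frames):
        a = rng.random((n_bath_per_phase, 3)) * box
        a[:, 0] = rng.random(n_bath_per_phase) * half
        b = rng.random((n_bath_per_phase, 3)) * box
        b[:, 0] = half + rng.random(n_bath_per_phase) * half
        frames_a.append(a)
        frames_b.append(b)
    return ToyTwoPhaseSystem(
        box=box, frames_a=frames_a, frames_b=frames_b,
        eps_a=eps_base * affinity_contrast, eps_b=eps_base, sigma=sigma,
        cutoff=float(min(box[1], box[2]) / 2.0),
    )


def mc_solute_partition(
    system: ToyTwoPhaseSystem,
    kT: float,
    n_steps: int = 20000,
    seed: int = 0,
    margin: float = 2.0,
    n_blocks: int = 10,
):
    """Counting-based log P from Metropolis sampling of the solute.

    Proposes a uniform position and bath frame each step (an
    independence sampler, which mixes in one step for this frozen
    field).  Returns ``(log_p, sem_log_p, occupancy_series)`` where the
    series holds +1 for phase-A interior, -1 for phase-B interior, 0 for
    the interfacial margin.
    """
    rng = np.random.default_rng(seed)
    beta = 1.0 / kT
    n_frames = len(system.frames_a)
    pos = np.array([system.box[0] * 0.25, system.box[1] / 2, system.box[2] / 2])
    frame = 0
    u = system.solute_energy(frame, pos)
    occ = np.zeros(n_steps, dtype=np.int8)
    half = system.half_x
    lx = float(system.box[0])
    for step in range(n_steps):
        new_pos = rng.random(3) * system.box
        new_frame = int(rng.integers(0, n_frames))
        u_new = system.solute_energy(new_frame, new_pos)
        if u_new <= u or rng.random() < math.exp(-beta * (u_new - u)):
            pos, frame, u = new_pos, new_frame, u_new
        x = pos[0] % lx
        if margin <= x <= half - margin:
            occ[step] = 1
        elif half + margin <= x <= lx - margin:
            occ[step] = -1
    n_a = int(np.sum(occ == 1))
    n_b = int(np.sum(occ == -1))
    if n_a == 0 or n_b == 0:
        raise AnalysisError("solute never visited one of the phase interiors")
    # equal interior volumes: concentration ratio is the count ratio
    lp = math.log10(n_a / n_b)
    block_len = max(n_steps // n_blocks, 1)
    ba = block_sem((occ == 1).astype(float), block_len)
    bb = block_sem((occ == -1).astype(float), block_len)
    f_a, f_b = n_a / n_steps, n_b / n_steps
    se = math.sqrt((ba.sem / f_a) ** 2 + (bb.sem / f_b) ** 2) / math.log(10.0)
    return lp, se, occ
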