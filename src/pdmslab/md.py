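"""Desk-scale molecular dynamics: velocity-Verlet, SHAKE, NVT/NPT, annealing.

Integration is velocity Verlet at 1 fs by default.  Temperature control
uses a Nose-Hoover chain (length 3) acting on all unfrozen degrees of
freedom; a Langevin thermostat is available for very small systems where
the deterministic chain equilibrates poorly.  Pressure control is a
first-order Berendsen-style volume relaxation applied to the selected
(periodic) axes; it is adequate for driving small boxes to their
equilibrium density, which is all this package asks of it.  Rigid SPC
water is maintained by SHAKE position projection plus RATTLE velocity
projection every step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units
from .errors import (
    ConstraintError,
    IntegrationError,
    ParameterError,
    StabilityError,
)
from .forcefield import ForceFieldSpec, evaluate
from .system import Frame, State, Trajectory, Wall

__all__ = [
    "IntegratorConfig",
    "AnnealSchedule",
    "maxwell_velocities",
    "velocity_verlet_step",
    "shake_project",
    "rattle_project",
    "run_ensemble",
    "anneal",
    "wall_force",
]

#: isothermal compressibility used by the volume relaxation, 1/atm
_BERENDSEN_BETA = 4.5e-5


@dataclass
class IntegratorConfig:
    """Time step, ensemble and coupling settings."""

    dt: float = 1.0                  # fs
    ensemble: str = "NVE"            # NVE | NVT | NPT
    T_target: float | None = None    # K
    P_target: float = 1.0            # atm
    tau_t: float = 100.0             # fs thermostat coupling
    tau_p: float = 1000.0            # fs barostat coupling
    thermostat: str = "nose-hoover"  # | "langevin"
    langevin_gamma: float = 0.01     # 1/fs
    seed: int = 0
    shake_tol: float = 1e-8
    shake_maxiter: int = 500
    barostat_axes: tuple[bool, bool, bool] | None = None  # default: periodic axes

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.ensemble not in ("NVE", "NVT", "NPT"):
            raise ParameterError(f"unknown ensemble {self.ensemble!r}")
        if self.ensemble in ("NVT", "NPT"):
            if self.T_target is None or self.T_target <= 0:
                raise ParameterError("NVT/NPT require T_target > 0")


@dataclass
class AnnealSchedule:
    """Stepwise cooling protocol: dwell at each level from T_high to T_low."""

    T_high: float = 408.15
    T_low: float = 298.15
    step: float = 10.0
    dwell: float = 1000.0            # fs per temperature level

    def __post_init__(self) -> None:
        if self.T_high < self.T_low:
            raise ParameterError("T_high must be >= T_low")
        if self.step <= 0:
            raise ParameterError("step must be > 0")

    def levels(self) -> np.ndarray:
        """Temperatures from T_high down to T_low, T_low always included."""
        ts = list(np.arange(self.T_high, self.T_low, -self.step))
        ts.append(self.T_low)
        return np.array(ts)


def maxwell_velocities(state: State, T: float, rng: np.random.Generator) -> None:
    """Draw Maxwell-Boltzmann velocities in place (net momentum zeroed)."""
    m = state.topology.masses
    sigma = np.sqrt(units.KB * T / (m * units.MVV2E))
    state.velocities = rng.normal(size=(len(m), 3)) * sigma[:, None]
    if len(state.frozen):
        state.velocities[state.frozen] = 0.0
    mask = np.ones(len(m), bool)
    mask[state.frozen] = False
    mom = np.sum(m[mask, None] * state.velocities[mask], axis=0)
    state.velocities[mask] -= mom / m[mask].sum()


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------

class _ConstraintClusters:
    """Constraints grouped into independent molecules (rigid triangles).

    When every cluster has the same number of constraints the SHAKE and
    RATTLE systems are solved exactly per cluster with batched dense
    solves (Newton for positions, a single solve for velocities), which
    converges in a couple of iterations instead of the tens a Jacobi
    sweep needs.
    """

    def __init__(self, constraints, masses):
        self.idx_i = np.array([c[0] for c in constraints])
        self.idx_j = np.array([c[1] for c in constraints])
        self.d2 = np.array([c[2] for c in constraints]) ** 2
        self.inv_mi = 1.0 / masses[self.idx_i]
        self.inv_mj = 1.0 / masses[self.idx_j]
        # connected components over shared atoms
        parent: dict[int, int] = {}

        def find(a):
            while parent.setdefault(a, a) != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j, _ in constraints:
            parent[find(i)] = find(j)
        groups: dict[int, list[int]] = {}
        for c, (i, _, _) in enumerate(constraints):
            groups.setdefault(find(i), []).append(c)
        sizes = {len(g) for g in groups.values()}
        self.uniform = len(sizes) == 1
        if not self.uniform:
            return
        self.k = sizes.pop()
        self.clusters = np.array(sorted(groups.values()))      # (M, k)
        ci = self.idx_i[self.clusters]                          # (M, k)
        cj = self.idx_j[self.clusters]
        # sign of the lambda_b contribution to atoms i_a / j_a of cluster
        self.s_i = ((ci[:, :, None] == ci[:, None, :]).astype(float)
                    - (ci[:, :, None] == cj[:, None, :]))
        self.s_j = ((cj[:, :, None] == ci[:, None, :]).astype(float)
                    - (cj[:, :, None] == cj[:, None, :]))
        self.w_i = self.inv_mi[self.clusters]                   # (M, k)
        self.w_j = self.inv_mj[self.clusters]


_CLUSTER_CACHE: dict[int, _ConstraintClusters] = {}


def _shake_newton(pos, reference, cl: _ConstraintClusters, tol, maxiter):
    r_ref = reference[cl.idx_i] - reference[cl.idx_j]
    rr = r_ref[cl.clusters]                                     # (M, k, 3)
    for _ in range(maxiter):
        r_now = pos[cl.idx_i] - pos[cl.idx_j]
        diff = np.sum(r_now * r_now, axis=1) - cl.d2
        if np.all(np.abs(diff) <= tol * cl.d2):
            return pos, True
        rn = r_now[cl.clusters]
        dot_now = np.einsum("max,mbx->mab", rn, rr)
        m_mat = 2.0 * dot_now * (cl.s_i * cl.w_i[:, :, None]
                                 - cl.s_j * cl.w_j[:, :, None])
        try:
            lam = np.linalg.solve(m_mat, -diff[cl.clusters][..., None])[..., 0]
        except np.linalg.LinAlgError:
            return pos, False
        corr = lam[:, :, None] * rr                             # (M, k, 3)
        flat = cl.clusters.ravel()
        np.add.at(pos, cl.idx_i[flat],
                  (cl.w_i[:, :, None] * corr).reshape(-1, 3))
        np.add.at(pos, cl.idx_j[flat],
                  (-cl.w_j[:, :, None] * corr).reshape(-1, 3))
    return pos, False


def shake_project(
    positions: np.ndarray,
    reference: np.ndarray,
    constraints,
    masses: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 500,
) -> np.ndarray:
    """Project positions onto the constraint manifold (SHAKE iteration).

    ``reference`` supplies the bond directions the corrections act along
    (the pre-drift coordinates during dynamics; pass the positions
    themselves for a standalone projection).  Mass-weighted corrections
    leave the linear momentum/center of mass unchanged.  Raises
    :class:`ConstraintError` if the iteration does not converge.
    """
    pos = positions.copy()
    if not constraints:
        return pos
    cl = _CLUSTER_CACHE.get(id(constraints))
    if cl is None:
        cl = _ConstraintClusters(constraints, masses)
        _CLUSTER_CACHE.clear()
        _CLUSTER_CACHE[id(constraints)] = cl
    if cl.uniform:
        pos, ok = _shake_newton(pos, reference, cl, tol, maxiter)
        if ok:
            return pos
        raise ConstraintError(f"SHAKE did not converge in {maxiter} iterations")
    idx_i = np.array([c[0] for c in constraints])
    idx_j = np.array([c[1] for c in constraints])
    d2 = np.array([c[2] for c in constraints]) ** 2
    inv_mi = 1.0 / masses[idx_i]
    inv_mj = 1.0 / masses[idx_j]
    r_ref = reference[idx_i] - reference[idx_j]
    for _ in range(maxiter):
        r_now = pos[idx_i] - pos[idx_j]
        diff = np.sum(r_now * r_now, axis=1) - d2
        if np.all(np.abs(diff) <= tol * d2):
            return pos
        g = diff / (2.0 * (inv_mi + inv_mj) * np.sum(r_now * r_ref, axis=1))
        corr = g[:, None] * r_ref
        np.add.at(pos, idx_i, -inv_mi[:, None] * corr)
        np.add.at(pos, idx_j, inv_mj[:, None] * corr)
    raise ConstraintError(
        f"SHAKE did not converge in {maxiter} iterations "
        f"(max violation {np.abs(diff).max():.3e})"
    )


def rattle_project(
    velocities: np.ndarray,
    positions: np.ndarray,
    constraints,
    masses: np.ndarray,
    tol: float = 1e-10,
    maxiter: int = 200,
) -> np.ndarray:
    """Remove velocity components along constrained bonds (RATTLE)."""
    vel = velocities.copy()
    if not constraints:
        return vel
    cl = _CLUSTER_CACHE.get(id(constraints))
    if cl is None:
        cl = _ConstraintClusters(constraints, masses)
        _CLUSTER_CACHE.clear()
        _CLUSTER_CACHE[id(constraints)] = cl
    if cl.uniform:
        r = positions[cl.idx_i] - positions[cl.idx_j]
        rc = r[cl.clusters]                                     # (M, k, 3)
        m_mat = np.einsum("max,mbx->mab", rc, rc) * (
            cl.s_i * cl.w_i[:, :, None] - cl.s_j * cl.w_j[:, :, None])
        v_rel = vel[cl.idx_i] - vel[cl.idx_j]
        rv = np.sum(r * v_rel, axis=1)
        lam = np.linalg.solve(m_mat, -rv[cl.clusters][..., None])[..., 0]
        corr = lam[:, :, None] * rc
        flat = cl.clusters.ravel()
        np.add.at(vel, cl.idx_i[flat],
                  (cl.w_i[:, :, None] * corr).reshape(-1, 3))
        np.add.at(vel, cl.idx_j[flat],
                  (-cl.w_j[:, :, None] * corr).reshape(-1, 3))
        return vel
    idx_i = np.array([c[0] for c in constraints])
    idx_j = np.array([c[1] for c in constraints])
    inv_mi = 1.0 / masses[idx_i]
    inv_mj = 1.0 / masses[idx_j]
    r = positions[idx_i] - positions[idx_j]
    r2 = np.sum(r * r, axis=1)
    for _ in range(maxiter):
        v_rel = vel[idx_i] - vel[idx_j]
        rv = np.sum(r * v_rel, axis=1)
        if np.all(np.abs(rv) <= tol * np.sqrt(r2)):
            return vel
        k = rv / ((inv_mi + inv_mj) * r2)
        corr = k[:, None] * r
        np.add.at(vel, idx_i, -inv_mi[:, None] * corr)
        np.add.at(vel, idx_j, inv_mj[:, None] * corr)
    return vel


# ---------------------------------------------------------------------------
# thermostats
# ---------------------------------------------------------------------------

class _NoseHooverChain:
    """Global Nose-Hoover chain (length 3), Martyna-style half-step update."""

    def __init__(self, dof: int, T: float, tau: float, length: int = 3):
        self.dof = dof
        self.T = T
        kt = units.KB * T
        self.q = np.array([dof * kt * tau**2] + [kt * tau**2] * (length - 1))
        self.xi = np.zeros(length)      # thermostat velocities
        self.length = length

    def half_step(self, kinetic2: float, dt_half: float) -> float:
        """Advance the chain by dt_half; return the velocity scale factor.

        ``kinetic2`` is twice the kinetic energy, kcal/mol.
        """
        kt = units.KB * self.T
        n = self.length
        g = np.zeros(n)
        g[0] = (kinetic2 - self.dof * kt) / self.q[0]
        for k in range(1, n):
            g[k] = (self.q[k - 1] * self.xi[k - 1] ** 2 - kt) / self.q[k]
        dt4 = 0.5 * dt_half
        dt8 = 0.5 * dt4
        # update chain from the tail inward
        self.xi[n - 1] += g[n - 1] * dt4
        for k in range(n - 2, -1, -1):
            damp = math.exp(-dt8 * self.xi[k + 1])
            self.xi[k] = damp * (damp * self.xi[k] + g[k] * dt4)
        scale = math.exp(-dt_half * self.xi[0])
        kinetic2 *= scale * scale
        g[0] = (kinetic2 - self.dof * kt) / self.q[0]
        for k in range(n - 1):
            damp = math.exp(-dt8 * self.xi[k + 1])
            self.xi[k] = damp * (damp * self.xi[k] + g[k] * dt4)
            g[k + 1] = (self.q[k] * self.xi[k] ** 2 - kt) / self.q[k + 1]
        self.xi[n - 1] += g[n - 1] * dt4
        return scale


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _check_finite(f: np.ndarray) -> None:
    if not np.all(np.isfinite(f)):
        bad = int(np.flatnonzero(~np.isfinite(f).all(axis=1))[0])
        raise IntegrationError(f"non-finite force on site {bad}")


def velocity_verlet_step(
    state: State,
    ff: ForceFieldSpec,
    config: IntegratorConfig,
    f: np.ndarray | None = None,
):
    """One velocity-Verlet step (no thermostat); returns (state, forces).

    Exact for force-free flight.  ``f`` may carry the forces from the
    previous step to avoid recomputation.
    """
    work = state.copy()
    if f is None:
        _, f, _ = evaluate(work, ff)
        _check_finite(f)
    f_new, _, _ = _vv_inner(work, ff, config, f)
    return work, f_new


def _vv_inner(state: State, ff: ForceFieldSpec, config: IntegratorConfig,
              f: np.ndarray):
    """In-place velocity-Verlet update; returns (forces, energy, virial)."""
    dt = config.dt
    m = state.topology.masses[:, None]
    cons = state.topology.constraints
    inv_m = units.F2A / m
    state.velocities += 0.5 * dt * f * inv_m
    if len(state.frozen):
        state.velocities[state.frozen] = 0.0
    ref = state.positions
    new_pos = ref + dt * state.velocities
    if cons:
        corrected = shake_project(new_pos, ref, cons, state.topology.masses,
                                  config.shake_tol, config.shake_maxiter)
        state.velocities += (corrected - new_pos) / dt
        new_pos = corrected
    state.positions = new_pos
    u_new, f_new, w_new = evaluate(state, ff)
    _check_finite(f_new)
    state.velocities += 0.5 * dt * f_new * inv_m
    if cons:
        state.velocities = rattle_project(
            state.velocities, state.positions, cons, state.topology.masses)
    if len(state.frozen):
        state.velocities[state.frozen] = 0.0
    return f_new, u_new, w_new


def minimize(
    state: State,
    ff: ForceFieldSpec,
    max_steps: int = 500,
    f_tol: float = 1.0,
    max_disp: float = 0.2,
) -> State:
    """Steepest-descent relaxation with a displacement cap.

    Used to take packed initial configurations off their worst overlaps
    before dynamics; stops when the largest force component drops below
    ``f_tol`` (kcal/mol/A).  Constrained geometries are re-projected
    after every move.
    """
    work = state.copy()
    cons = work.topology.constraints
    u, f, _ = evaluate(work, ff)
    step = 0.05
    for _ in range(max_steps):
        fmax = np.abs(f).max()
        if fmax < f_tol:
            break
        disp = np.clip(step * f, -max_disp, max_disp)
        trial = work.positions + disp
        if cons:
            try:
                trial = shake_project(trial, work.positions, cons,
                                      work.topology.masses)
            except ConstraintError:
                step *= 0.5
                if step < 1e-8:
                    break
                continue
        u_new, f_new, _ = evaluate(
            State(work.topology, trial, work.velocities, work.box,
                  work.periodic, walls=work.walls, frozen=work.frozen), ff)
        if u_new < u:
            work.positions = trial
            u, f = u_new, f_new
            step = min(step * 1.2, 1.0)
        else:
            step *= 0.5
            if step < 1e-8:
                break
    return work


def run_ensemble(
    state: State,
    ff: ForceFieldSpec,
    config: IntegratorConfig,
    n_steps: int,
    stride: int = 100,
    initialize_velocities: bool | None = None,
):
    """Integrate ``n_steps`` and record frames every ``stride`` steps.

    Returns ``(final_state, trajectory)``.  ``n_steps = 0`` returns the
    input state unchanged.  Coordinates are never wrapped, so recorded
    frames are continuous in time (usable for MSD analysis).  Raises
    :class:`StabilityError` if the kinetic temperature exceeds ten times
    the target.
    """
    if n_steps == 0:
        return state, Trajectory(topology=state.topology, frames=[], unwrapped=True)
    rng = np.random.default_rng(config.seed)
    work = state.copy()
    m = work.topology.masses
    if initialize_velocities is None:
        initialize_velocities = (
            config.T_target is not None
            and not np.any(work.velocities)
        )
    if initialize_velocities:
        maxwell_velocities(work, config.T_target, rng)
        if work.topology.constraints:
            work.velocities = rattle_project(
                work.velocities, work.positions, work.topology.constraints, m)

    nhc = None
    if config.ensemble in ("NVT", "NPT") and config.thermostat == "nose-hoover":
        nhc = _NoseHooverChain(work.n_dof(), config.T_target, config.tau_t)
    if config.ensemble == "NPT":
        axes = config.barostat_axes
        if axes is None:
            axes = tuple(bool(p) for p in work.periodic)
        if not any(axes):
            raise ParameterError("NPT requires at least one barostat axis")

    u, f, w = evaluate(work, ff)
    _check_finite(f)
    frames: list[Frame] = []
    dt = config.dt
    mask_free = np.ones(len(m), bool)
    mask_free[work.frozen] = False

    def record(step, u):
        frames.append(Frame(
            step=step, time=step * dt, positions=work.positions.copy(),
            box=work.box.copy(), temperature=work.temperature(),
            potential_energy=u,
            extra={"density": work.density()},
        ))

    for step in range(1, n_steps + 1):
        if nhc is not None:
            scale = nhc.half_step(2.0 * work.kinetic_energy(), 0.5 * dt)
            work.velocities[mask_free] *= scale
        f, u, w = _vv_inner(work, ff, config, f)
        if config.ensemble in ("NVT", "NPT") and config.thermostat == "langevin":
            c1 = math.exp(-config.langevin_gamma * dt)
            sig = np.sqrt(
                (1.0 - c1 * c1) * units.KB * config.T_target / (m * units.MVV2E)
            )
            work.velocities[mask_free] = (
                c1 * work.velocities[mask_free]
                + sig[mask_free, None] * rng.normal(
                    size=work.velocities[mask_free].shape)
            )
            if work.topology.constraints:
                work.velocities = rattle_project(
                    work.velocities, work.positions,
                    work.topology.constraints, m)
        if nhc is not None:
            scale = nhc.half_step(2.0 * work.kinetic_energy(), 0.5 * dt)
            work.velocities[mask_free] *= scale
        if config.ensemble == "NPT":
            p_inst = (
                (2.0 * work.kinetic_energy() + w)
                / (3.0 * work.volume)
                * units.P_KCALMOLA3_TO_ATM
            )
            mu3 = 1.0 - _BERENDSEN_BETA * dt / config.tau_p * (
                config.P_target - p_inst)
            mu = np.clip(mu3, 0.95, 1.05) ** (1.0 / 3.0)
            for ax in range(3):
                if axes[ax]:
                    work.box[ax] *= mu
                    work.positions[:, ax] *= mu
        if config.T_target is not None and work.temperature() > 10 * config.T_target:
            raise StabilityError(
                f"temperature {work.temperature():.0f} K exceeds 10x target "
                f"at step {step}"
            )
        if step % stride == 0 or step == n_steps:
            record(step, u)
    return work, Trajectory(topology=work.topology, frames=frames, unwrapped=True)


def anneal(
    state: State,
    ff: ForceFieldSpec,
    schedule: AnnealSchedule,
    config: IntegratorConfig | None = None,
    discard_fraction: float = 0.5,
):
    """Run the stepwise cooling protocol; returns (state, level summaries).

    Each level dwells for ``schedule.dwell`` fs in the configured
    ensemble (NPT by default) and reports the mean density and potential
    energy over the kept tail of the dwell.
    """
    if config is None:
        config = IntegratorConfig(ensemble="NPT", T_target=schedule.T_high)
    work = state
    summaries = []
    n_steps = max(int(round(schedule.dwell / config.dt)), 1)
    for i, T in enumerate(schedule.levels()):
        cfg = IntegratorConfig(**{**config.__dict__, "T_target": float(T),
                                  "seed": config.seed + i})
        work, traj = run_ensemble(work, ff, cfg, n_steps,
                                  stride=max(n_steps // 50, 1),
                                  initialize_velocities=(i == 0))
        keep = [fr for fr in traj if fr.time >= discard_fraction * schedule.dwell]
        summaries.append({
            "T": float(T),
            "mean_density": float(np.mean([fr.extra["density"] for fr in keep])),
            "mean_potential_energy": float(np.mean(
                [fr.potential_energy for fr in keep])),
            "mean_temperature": float(np.mean(
                [fr.temperature for fr in keep])),
        })
    return work, summaries


def wall_force(position, wall: Wall, species: str | None = None) -> np.ndarray:
    """Force from a repulsive wall on a site; zero outside its range
    or for species the wall does not act on."""
    if species is not None and not wall.applies_to(species):
        return np.zeros(3)
    x = float(np.asarray(position, float)[0])
    dist = wall.side * (x - wall.x0)
    rc = 2 ** (1 / 6) * wall.sigma
    if dist >= rc:
        return np.zeros(3)
    dd = max(dist, 0.01)
    sr6 = (wall.sigma / dd) ** 6
    fmag = 24 * wall.epsilon * (2 * sr6**2 - sr6) / dd
    return np.array([wall.side * fmag, 0.0, 0.0])
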