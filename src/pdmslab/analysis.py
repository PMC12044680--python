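"""Trajectory observables: density profiles, phase partitioning, log P,
molar solubilities, mean-squared displacement and diffusion, block errors.

Molecules are located along x by the coordinate of the site nearest the
molecular center of mass.  Profiles use half-open 1.5 A bins anchored at
the box lower edge.  Phase assignment splits the box at the two
polymer-slab interfaces and discards a 3 A margin on either side of
each interface so interfacially adsorbed molecules bias neither phase;
the PDMS-side boundary is closed.  log P is the decadic ratio of molar
concentrations in the polymer and aqueous phases; D follows the
Einstein relation D = slope(MSD)/(2n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import units
from .errors import AnalysisError, FitError, ParameterError
from .system import Topology, Trajectory

__all__ = [
    "DensityProfile",
    "PhasePartition",
    "TransportEstimate",
    "BlockAverage",
    "molecule_coordinate",
    "representative_x",
    "density_profile",
    "locate_interfaces",
    "partition_counts",
    "log_p",
    "molar_solubility",
    "msd",
    "diffusion_coefficient",
    "block_sem",
    "logp_convergence",
]


def molecule_coordinate(positions: np.ndarray, masses: np.ndarray) -> float:
    """x-coordinate of the site nearest the molecular center of mass.

    Ties break to the lowest site index.
    """
    positions = np.asarray(positions, float)
    masses = np.asarray(masses, float)
    com = np.average(positions, axis=0, weights=masses)
    d2 = np.sum((positions - com) ** 2, axis=1)
    return float(positions[int(np.argmin(d2)), 0])


def representative_x(topology: Topology, positions: np.ndarray) -> np.ndarray:
    """Per-molecule representative x for one frame (vectorized helper)."""
    out = np.empty(topology.n_molecules)
    for i, mol in enumerate(topology.molecules):
        pos = positions[mol.sites]
        m = topology.masses[mol.sites]
        com = np.average(pos, axis=0, weights=m)
        d2 = np.sum((pos - com) ** 2, axis=1)
        out[i] = pos[int(np.argmin(d2)), 0]
    return out


@dataclass
class DensityProfile:
    """Per-species molecule counts along x (per frame and time-averaged)."""

    bin_width: float
    edges: np.ndarray                      # len n_bins + 1, half-open [lo, hi)
    species: list[str]
    per_frame: dict[str, np.ndarray]       # species -> (n_frames, n_bins)
    counts: dict[str, np.ndarray] = field(init=False)   # time-averaged

    def __post_init__(self) -> None:
        self.counts = {s: a.mean(axis=0) for s, a in self.per_frame.items()}

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def n_frames(self) -> int:
        return next(iter(self.per_frame.values())).shape[0]


def density_profile(
    trajectory: Trajectory,
    species: list[str] | None = None,
    bin_width: float = 1.5,
) -> DensityProfile:
    """Histogram molecules along x with half-open bins from the box edge."""
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    if len(trajectory) == 0:
        raise AnalysisError("empty trajectory")
    top = trajectory.topology
    all_species = sorted({m.species for m in top.molecules})
    if species is None:
        species = all_species
    lx = float(trajectory[0].box[0])
    n_bins = int(math.ceil(lx / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    mol_species = np.array([m.species for m in top.molecules])
    per_frame = {s: np.zeros((len(trajectory), n_bins)) for s in species}
    for t, frame in enumerate(trajectory):
        x = representative_x(top, frame.positions)
        x = np.mod(x, lx)  # fold into the box along x for binning
        bins = np.minimum((x / bin_width).astype(int), n_bins - 1)
        for s in species:
            sel = bins[mol_species == s]
            per_frame[s][t] = np.bincount(sel, minlength=n_bins)
    return DensityProfile(bin_width=bin_width, edges=edges,
                          species=list(species), per_frame=per_frame)


def locate_interfaces(
    profile: DensityProfile,
    species: str = "pdms",
    threshold_fraction: float = 0.5,
    nominal: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Polymer-slab interface positions from the slab species' profile.

    The interface is where the time-averaged density crosses
    ``threshold_fraction`` of the plateau mean (linearly interpolated
    between bin centers).  Pass ``nominal`` to bypass detection and use
    fixed positions.
    """
    if nominal is not None:
        return nominal
    matches = [s for s in profile.species if s == species or s.startswith(species)]
    if not matches:
        raise AnalysisError(f"species {species!r} not present in profile")
    dens = sum(profile.counts[s] for s in matches)
    peak = dens.max()
    if peak <= 0:
        raise AnalysisError("all-zero profile: no slab to locate")
    plateau_bins = dens >= 0.5 * peak
    plateau = dens[plateau_bins].mean()
    thr = threshold_fraction * plateau
    above = dens >= thr
    if not above.any() or above.all():
        raise AnalysisError("no plateau edges detected")
    centers = profile.centers
    i_lo = int(np.argmax(above))
    i_hi = int(len(above) - 1 - np.argmax(above[::-1]))

    def cross(i_out, i_in):
        if i_out < 0 or i_out >= len(dens):
            return centers[i_in]
        x0, x1 = centers[i_out], centers[i_in]
        y0, y1 = dens[i_out], dens[i_in]
        if y1 == y0:
            return 0.5 * (x0 + x1)
        return x0 + (thr - y0) / (y1 - y0) * (x1 - x0)

    return (cross(i_lo - 1, i_lo), cross(i_hi + 1, i_hi))


@dataclass
class PhasePartition:
    """Time-averaged per-species phase occupancies and derived log P."""

    interfaces: tuple[float, float]
    margin: float
    cross_section: float                   # Ly * Lz, A^2
    counts: dict[str, dict[str, float]]    # species -> {pdms, water, excluded}
    sem: dict[str, dict[str, float]]
    per_frame: dict[str, np.ndarray]       # species -> (n_frames, 3) columns
    water_bounds: tuple[float, float]      # x extent available to water

    @property
    def slab_width(self) -> float:
        return self.interfaces[1] - self.interfaces[0]

    def volume_pdms(self, exclude_margin: bool = False) -> float:
        w = self.slab_width - (2 * self.margin if exclude_margin else 0.0)
        return w * self.cross_section

    def volume_water(self, exclude_margin: bool = True) -> float:
        lo, hi = self.water_bounds
        w = (hi - lo) - self.slab_width
        if exclude_margin:
            w -= 2 * self.margin
        return w * self.cross_section

    def concentration(self, species: str, phase: str = "pdms") -> float:
        vol = self.volume_pdms() if phase == "pdms" else self.volume_water()
        return molar_solubility(self.counts[species][phase], vol)

    def log_p(self, species: str, vol_pdms: float | None = None,
              vol_water: float | None = None) -> float:
        """Decadic PDMS/water partition coefficient for one species.

        Nominal (margin-free) phase volumes are the default; pass
        explicit volumes to override.
        """
        vp = self.volume_pdms() if vol_pdms is None else vol_pdms
        vw = self.volume_water(exclude_margin=False) if vol_water is None else vol_water
        return log_p(self.counts[species]["pdms"], vp,
                     self.counts[species]["water"], vw)

    def log_p_sem(self, species: str) -> float:
        """First-order propagation of the block SEMs of both phase counts."""
        c = self.counts[species]
        s = self.sem[species]
        if c["pdms"] <= 0 or c["water"] <= 0:
            return float("nan")
        rel2 = (s["pdms"] / c["pdms"]) ** 2 + (s["water"] / c["water"]) ** 2
        return math.sqrt(rel2) / math.log(10.0)


def partition_counts(
    trajectory: Trajectory,
    interfaces: tuple[float, float],
    margin: float = 3.0,
    species: list[str] | None = None,
    water_bounds: tuple[float, float] | None = None,
    n_blocks: int = 10,
) -> PhasePartition:
    """Classify every molecule per frame into pdms / water / excluded.

    The polymer phase is the closed slab ``[x_left+margin, x_right-margin]``,
    the aqueous phase everything outside ``[x_left-margin, x_right+margin]``,
    and the interfacial margins are excluded from both.  Counts are
    time-averaged; block averaging supplies their standard errors.
    """
    if len(trajectory) == 0:
        raise AnalysisError("empty trajectory")
    xl, xr = interfaces
    if xr <= xl:
        raise ParameterError("interfaces must satisfy x_left < x_right")
    if margin >= 0.5 * (xr - xl):
        raise ParameterError("margin must be smaller than the half slab width")
    box = trajectory[0].box
    if not (0 <= xl <= box[0] and 0 <= xr <= box[0]):
        raise ParameterError("interfaces must lie inside the box")
    top = trajectory.topology
    mol_species = np.array([m.species for m in top.molecules])
    if species is None:
        species = sorted(set(mol_species))
    per_frame = {s: np.zeros((len(trajectory), 3)) for s in species}
    for t, frame in enumerate(trajectory):
        x = np.mod(representative_x(top, frame.positions), box[0])
        in_pdms = (x >= xl + margin) & (x <= xr - margin)
        in_water = (x < xl - margin) | (x > xr + margin)
        for s in species:
            sel = mol_species == s
            n_p = int(np.sum(in_pdms & sel))
            n_w = int(np.sum(in_water & sel))
            per_frame[s][t] = (n_p, n_w, int(sel.sum()) - n_p - n_w)
    counts = {}
    sems = {}
    for s in species:
        arr = per_frame[s]
        counts[s] = {"pdms": float(arr[:, 0].mean()),
                     "water": float(arr[:, 1].mean()),
                     "excluded": float(arr[:, 2].mean())}
        block_len = max(len(arr) // n_blocks, 1)
        sems[s] = {}
        for col, name in [(0, "pdms"), (1, "water"), (2, "excluded")]:
            if len(arr) >= 2 * block_len and len(arr) // block_len >= 2:
                sems[s][name] = block_sem(arr[:, col], block_len).sem
            else:
                sems[s][name] = float("nan")
    return PhasePartition(
        interfaces=(xl, xr), margin=margin,
        cross_section=float(box[1] * box[2]),
        counts=counts, sem=sems, per_frame=per_frame,
        water_bounds=(0.0, float(box[0])) if water_bounds is None else water_bounds,
    )


def log_p(count_pdms: float, vol_pdms: float,
          count_water: float, vol_water: float) -> float:
    """log10 of the PDMS/water concentration ratio (NaN if a phase is empty)."""
    if vol_pdms <= 0 or vol_water <= 0:
        raise ParameterError("phase volumes must be positive")
    if count_pdms <= 0 or count_water <= 0:
        return float("nan")
    return math.log10((count_pdms / vol_pdms) / (count_water / vol_water))


def molar_solubility(count: float, volume_a3: float) -> float:
    """Molar concentration (mol/L) of ``count`` molecules in ``volume_a3``."""
    if volume_a3 <= 0:
        raise ParameterError("volume must be positive")
    return count / volume_a3 * units.COUNT_A3_TO_MOL_L


# ---------------------------------------------------------------------------
# transport
# ---------------------------------------------------------------------------

@dataclass
class TransportEstimate:
    """MSD series with the Einstein-relation diffusion coefficient."""

    times_ps: np.ndarray
    msd: np.ndarray                 # A^2
    dimension: int
    fit_window: tuple[int, int]
    slope: float                    # A^2/ps
    slope_stderr: float
    D_cm2_s: float
    D_stderr: float


def msd(
    trajectory: Trajectory,
    species: str | None = None,
    origin_stride: int = 1,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-time-origin mean-squared displacement of molecule COMs.

    Returns ``(lag times [ps], MSD [A^2])`` with MSD(0) = 0.  Requires an
    unwrapped trajectory (continuous coordinates).
    """
    if not trajectory.unwrapped:
        raise AnalysisError(
            "MSD needs unwrapped coordinates (or image flags); this "
            "trajectory is wrapped"
        )
    if len(trajectory) < 2:
        raise AnalysisError("need at least two frames")
    top = trajectory.topology
    sel = [i for i, m in enumerate(top.molecules)
           if species is None or m.species == species]
    if not sel:
        raise AnalysisError(f"no molecules of species {species!r}")
    n_frames = len(trajectory)
    if max_lag is None:
        max_lag = n_frames // 2 if n_frames > 3 else n_frames - 1
    max_lag = max(min(max_lag, n_frames - 1), 1)
    # COM per molecule per frame
    coms = np.empty((n_frames, len(sel), 3))
    for t, frame in enumerate(trajectory):
        for a, im in enumerate(sel):
            mol = top.molecules[im]
            coms[t, a] = np.average(frame.positions[mol.sites], axis=0,
                                    weights=top.masses[mol.sites])
    times = trajectory.times
    dt = np.diff(times)
    if not np.allclose(dt, dt[0]):
        raise AnalysisError("MSD requires evenly spaced frames")
    out = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        origins = np.arange(0, n_frames - lag, origin_stride)
        disp = coms[origins + lag] - coms[origins]
        out[lag] = np.mean(np.sum(disp * disp, axis=2))
    lag_times = np.arange(max_lag + 1) * dt[0] / units.FS_PER_PS
    return lag_times, out


def diffusion_coefficient(
    times_ps: np.ndarray,
    msd_a2: np.ndarray,
    dimension: int = 3,
    fit_window: tuple[int, int] | None = None,
) -> TransportEstimate:
    """Einstein-relation D = slope/(2 n) from a linear fit of MSD vs t.

    The default window skips the first 10% of the series (ballistic /
    cage regime) and fits the rest.
    """
    times_ps = np.asarray(times_ps, float)
    msd_a2 = np.asarray(msd_a2, float)
    if fit_window is None:
        fit_window = (max(len(times_ps) // 10, 1), len(times_ps))
    lo, hi = fit_window
    if hi - lo < 3:
        raise FitError("fit window must contain at least 3 points")
    fit = stats.linregress(times_ps[lo:hi], msd_a2[lo:hi])
    slope = float(fit.slope)
    d_a2ps = slope / (2.0 * dimension)
    return TransportEstimate(
        times_ps=times_ps, msd=msd_a2, dimension=dimension,
        fit_window=(lo, hi), slope=slope, slope_stderr=float(fit.stderr),
        D_cm2_s=d_a2ps * units.A2_PS_TO_CM2_S,
        D_stderr=float(fit.stderr) / (2.0 * dimension) * units.A2_PS_TO_CM2_S,
    )


# ---------------------------------------------------------------------------
# uncertainty
# ---------------------------------------------------------------------------

@dataclass
class BlockAverage:
    block_length: int
    block_means: np.ndarray
    mean: float
    sem: float


def block_sem(series, block_length: int) -> BlockAverage:
    """Block-averaged standard error for an autocorrelated series.

    Splits the series into consecutive blocks (dropping the remainder)
    and reports std(block means)/sqrt(n_blocks).  The grand mean over
    whole blocks is independent of the blocking.
    """
    series = np.asarray(series, float)
    if block_length < 1:
        raise ParameterError("block_length must be >= 1")
    n_blocks = len(series) // block_length
    if n_blocks < 2:
        raise ParameterError("need at least 2 blocks")
    trimmed = series[: n_blocks * block_length]
    means = trimmed.reshape(n_blocks, block_length).mean(axis=1)
    sem = float(np.std(means, ddof=1) / math.sqrt(n_blocks))
    return BlockAverage(block_length=block_length, block_means=means,
                        mean=float(trimmed.mean()), sem=sem)


# ---------------------------------------------------------------------------
# convergence
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    times: np.ndarray
    running_log_p: np.ndarray
    plateaued: bool
    final: float


def logp_convergence(
    trajectory: Trajectory,
    interfaces: tuple[float, float],
    species: str,
    margin: float = 3.0,
    stride: int = 1,
    vol_pdms: float | None = None,
    vol_water: float | None = None,
    plateau_tol: float = 0.05,
) -> ConvergenceResult:
    """Running time-average log P and a plateau decision.

    Evaluates the cumulative log P after every ``stride`` frames and
    declares a plateau when the line fitted to the last 20% of the
    series changes by less than ``plateau_tol`` log units across that
    window.
    """
    part = partition_counts(trajectory, interfaces, margin, species=[species])
    arr = part.per_frame[species]
    if len(arr) // stride < 10:
        raise AnalysisError("need at least 10 strided evaluations")
    vp = part.volume_pdms() if vol_pdms is None else vol_pdms
    vw = part.volume_water(exclude_margin=False) if vol_water is None else vol_water
    idx = np.arange(stride, len(arr) + 1, stride)
    cum_p = np.cumsum(arr[:, 0])
    cum_w = np.cumsum(arr[:, 1])
    values = np.array([
        log_p(cum_p[i - 1] / i, vp, cum_w[i - 1] / i, vw) for i in idx
    ])
    times = trajectory.times[idx - 1]
    tail = max(int(0.2 * len(values)), 3)
    t_tail = times[-tail:]
    v_tail = values[-tail:]
    if np.any(~np.isfinite(v_tail)):
        plateaued = False
    else:
        fit = stats.linregress(t_tail, v_tail)
        plateaued = bool(abs(fit.slope) * (t_tail[-1] - t_tail[0]) < plateau_tol)
    return ConvergenceResult(times=times, running_log_p=values,
                             plateaued=plateaued, final=float(values[-1]))
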