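"""Interaction model: united-atom/all-atom sites, pair table, bonded terms.

The potential energy is the usual sum of harmonic bond stretches,
harmonic angle bends, cosine-series dihedrals, and nonbonded 12-6
Lennard-Jones plus Coulomb terms between sites separated by more than
three bonds (1-4 pairs scaled).  Cross LJ interactions follow
Lorentz-Berthelot mixing (geometric epsilon, arithmetic sigma) unless an
explicit tabulated pair overrides them; selected cross pairs carry a
multiplicative epsilon scale factor (the water-organic affinity
correction uses 1.20).

Long-range electrostatics is handled by short-range closures selected in
:class:`ForceFieldSpec`: damped-shifted-force (default), reaction-field,
or plain ``direct`` Coulomb.  Both closures go continuously to zero at
the cutoff and reduce to direct Coulomb at short range.

Harmonic terms use the engine convention ``E = k (x - x0)^2``; set
``half_harmonic=True`` for the ``E = k/2 (x - x0)^2`` convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erfc

from . import units
from .errors import (
    ParameterError,
    SingularityError,
    TopologyError,
    UnknownKindError,
)
from .system import State, Topology

__all__ = [
    "SiteKind",
    "PairTable",
    "BondedTerms",
    "ForceFieldSpec",
    "CH3_SIGMA_SCALE",
    "apply_ch3_sigma_modification",
    "mix_pair_params",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "bonded_energy",
    "total_potential_energy",
    "forces",
    "evaluate",
]

# The CH3 Lennard-Jones diameter of the parent united-atom siloxane model
# is enlarged by 3.49% to reproduce experimental PDMS liquid densities.
CH3_SIGMA_SCALE = 1.0349


def apply_ch3_sigma_modification(base_sigma: float) -> float:
    """Return the density-corrected CH3 sigma (base value x 1.0349)."""
    if base_sigma <= 0:
        raise ParameterError("sigma must be positive")
    return base_sigma * CH3_SIGMA_SCALE


@dataclass(frozen=True)
class SiteKind:
    """One interaction-site type (united atom or atom)."""

    name: str
    mass: float       # amu
    charge: float     # e
    epsilon: float    # kcal/mol
    sigma: float      # A

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ParameterError(f"site kind {self.name}: mass must be > 0")
        if self.epsilon < 0:
            raise ParameterError(f"site kind {self.name}: epsilon must be >= 0")
        if self.epsilon > 0 and self.sigma <= 0:
            raise ParameterError(
                f"site kind {self.name}: sigma must be > 0 for LJ-active sites"
            )


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class PairTable:
    """Explicit LJ pairs plus per-pair cross-interaction scale factors."""

    explicit_pairs: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    cross_scale: dict[tuple[str, str], float] = field(default_factory=dict)

    def set_pair(self, a: str, b: str, epsilon: float, sigma: float) -> None:
        self.explicit_pairs[_key(a, b)] = (float(epsilon), float(sigma))

    def set_scale(self, a: str, b: str, factor: float) -> None:
        if factor <= 0:
            raise ParameterError("cross_scale factor must be > 0")
        self.cross_scale[_key(a, b)] = float(factor)

    def explicit(self, a: str, b: str) -> tuple[float, float] | None:
        return self.explicit_pairs.get(_key(a, b))

    def scale(self, a: str, b: str) -> float:
        return self.cross_scale.get(_key(a, b), 1.0)


def mix_pair_params(
    kind_a: SiteKind, kind_b: SiteKind, table: PairTable
) -> tuple[float, float]:
    """Cross LJ parameters for a pair of site kinds.

    An explicit table entry is returned verbatim; otherwise
    Lorentz-Berthelot mixing applies with the table's scale factor on
    epsilon.  Symmetric in its arguments by construction.
    """
    explicit = table.explicit(kind_a.name, kind_b.name)
    if explicit is not None:
        return explicit
    eps = table.scale(kind_a.name, kind_b.name) * math.sqrt(
        kind_a.epsilon * kind_b.epsilon
    )
    sig = 0.5 * (kind_a.sigma + kind_b.sigma)
    return (eps, sig)


@dataclass
class BondedTerms:
    """Typed tables of bond, angle and dihedral parameters.

    bonds:     type -> (k [kcal/mol/A^2], r0 [A])
    angles:    type -> (k [kcal/mol/rad^2], theta0 [deg])
    dihedrals: type -> OPLS cosine-series coefficients (K1..K4, kcal/mol)
    """

    bonds: dict[str, tuple[float, float]] = field(default_factory=dict)
    angles: dict[str, tuple[float, float]] = field(default_factory=dict)
    dihedrals: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, (_, r0) in self.bonds.items():
            if r0 <= 0:
                raise ParameterError(f"bond type {name}: r0 must be > 0")
        for name, (_, th0) in self.angles.items():
            if not (0.0 < th0 <= 180.0):
                raise ParameterError(
                    f"angle type {name}: theta0 must be in (0, 180] degrees"
                )


@dataclass
class ForceFieldSpec:
    """Complete interaction model: site kinds, pair table, bonded terms."""

    kinds: dict[str, SiteKind] = field(default_factory=dict)
    pair_table: PairTable = field(default_factory=PairTable)
    bonded: BondedTerms = field(default_factory=BondedTerms)
    cutoff: float = 12.0
    electrostatics: str = "damped-shifted-force"  # | "reaction-field" | "direct"
    dsf_alpha: float = 0.2          # 1/A damping of the shifted-force closure
    rf_dielectric: float = 78.5     # reaction-field continuum dielectric
    coulomb_constant: float = units.KE_COULOMB
    half_harmonic: bool = False     # True -> E = (k/2) dx^2 convention
    scale_14: float = 0.5           # 1-4 nonbonded scaling (OPLS convention)
    lj_shift: str = "energy"        # "none" | "energy" | "force"

    _METHODS = ("damped-shifted-force", "reaction-field", "direct")

    def __post_init__(self) -> None:
        if self.electrostatics not in self._METHODS:
            raise ParameterError(
                f"electrostatics must be one of {self._METHODS}, "
                f"got {self.electrostatics!r}"
            )
        if self.lj_shift not in ("none", "energy", "force"):
            raise ParameterError(f"unknown lj_shift {self.lj_shift!r}")

    def add_kind(self, kind: SiteKind) -> None:
        self.kinds[kind.name] = kind

    def kind(self, name: str) -> SiteKind:
        try:
            return self.kinds[name]
        except KeyError:
            raise UnknownKindError(f"unknown site kind {name!r}") from None

    def pair_params(self, name_a: str, name_b: str) -> tuple[float, float]:
        return mix_pair_params(self.kind(name_a), self.kind(name_b), self.pair_table)

    def validate(self) -> None:
        self.bonded.validate()
        max_sigma = max((k.sigma for k in self.kinds.values() if k.epsilon > 0),
                        default=0.0)
        if self.cutoff <= max_sigma:
            raise ParameterError(
                f"cutoff {self.cutoff} A must exceed the largest sigma {max_sigma} A"
            )

    def with_(self, **kw) -> "ForceFieldSpec":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# pair potentials
# ---------------------------------------------------------------------------

def lj_pair_energy(r, epsilon: float, sigma: float):
    """12-6 Lennard-Jones energy 4 eps [(sig/r)^12 - (sig/r)^6], kcal/mol."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("separation r must be > 0")
    sr6 = (sigma / r) ** 6
    out = 4.0 * epsilon * (sr6 * sr6 - sr6)
    return float(out) if out.ndim == 0 else out


def _lj_e_f(r2, eps, sig, cutoff, shift):
    """Vectorized LJ energy and radial force magnitude (F = -dE/dr).

    ``shift`` in {"none", "energy", "force"} controls behaviour at the
    cutoff: plain truncation, energy shift to zero, or shifted-force
    (energy and force both continuous at the cutoff).
    """
    inv_r2 = 1.0 / r2
    sr6 = (sig * sig * inv_r2) ** 3
    sr12 = sr6 * sr6
    e = 4.0 * eps * (sr12 - sr6)
    f = 24.0 * eps * (2.0 * sr12 - sr6) * np.sqrt(inv_r2)
    if shift != "none":
        src6 = (sig / cutoff) ** 6
        src12 = src6 * src6
        e_c = 4.0 * eps * (src12 - src6)
        e = e - e_c
        if shift == "force":
            f_c = 24.0 * eps * (2.0 * src12 - src6) / cutoff
            r = np.sqrt(r2)
            e = e + f_c * (r - cutoff)
            f = f - f_c
    return e, f


def coulomb_pair_energy(
    r,
    q_a: float,
    q_b: float,
    method: str = "direct",
    cutoff: float = 12.0,
    alpha: float = 0.2,
    rf_dielectric: float = 78.5,
    ke: float = units.KE_COULOMB,
):
    """Pairwise electrostatic energy under the configured closure, kcal/mol.

    ``direct`` is k q_a q_b / r.  ``damped-shifted-force`` is the
    erfc-damped, force-shifted closure (zero energy and force at the
    cutoff); ``reaction-field`` embeds the pair in a continuum of the
    given dielectric, energy-shifted to zero at the cutoff.  Both reduce
    to direct Coulomb for r much smaller than the cutoff as the damping
    vanishes.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ParameterError("separation r must be > 0")
    qq = ke * q_a * q_b
    e, _ = _coulomb_e_f(r, qq, method, cutoff, alpha, rf_dielectric)
    return float(e) if e.ndim == 0 else e


def _coulomb_e_f(r, qq, method, cutoff, alpha, rf_dielectric):
    """Vectorized Coulomb energy and radial force magnitude (F = -dE/dr)."""
    r = np.asarray(r, dtype=float)
    if method == "direct":
        e = qq / r
        f = qq / r**2
    elif method == "damped-shifted-force":
        # Fennell-Gezelter damped shifted-force closure
        rc = cutoff
        erfc_rc = erfc(alpha * rc)
        gauss_rc = 2.0 * alpha / math.sqrt(math.pi) * math.exp(-(alpha * rc) ** 2)
        f_shift = erfc_rc / rc**2 + gauss_rc / rc
        e = qq * (erfc(alpha * r) / r - erfc_rc / rc + f_shift * (r - rc))
        gauss_r = 2.0 * alpha / math.sqrt(math.pi) * np.exp(-((alpha * r) ** 2))
        f = qq * (erfc(alpha * r) / r**2 + gauss_r / r - f_shift)
    elif method == "reaction-field":
        rc = cutoff
        eps_rf = rf_dielectric
        b = (2.0 * (eps_rf - 1.0)) / (2.0 * eps_rf + 1.0)
        shift = (1.0 + 0.5 * b) / rc
        e = qq * (1.0 / r + 0.5 * b * r**2 / rc**3 - shift)
        f = qq * (1.0 / r**2 - b * r / rc**3)
    else:  # pragma: no cover - guarded in ForceFieldSpec
        raise ParameterError(f"unknown electrostatics method {method!r}")
    return e, f


# ---------------------------------------------------------------------------
# bonded terms
# ---------------------------------------------------------------------------

def _min_image(d: np.ndarray, box: np.ndarray, periodic: np.ndarray) -> np.ndarray:
    d = d.copy()
    for ax in range(3):
        if periodic[ax]:
            d[..., ax] -= box[ax] * np.round(d[..., ax] / box[ax])
    return d


def bonded_energy(
    topology: Topology,
    positions: np.ndarray,
    terms: BondedTerms,
    box: np.ndarray | None = None,
    periodic: np.ndarray | None = None,
    half_harmonic: bool = False,
) -> tuple[float, dict[str, float]]:
    """Total bonded energy with a per-class breakdown.

    Returns ``(total, {"bond": .., "angle": .., "dihedral": ..})``; the
    breakdown sums to the total.
    """
    e, _, _ = _bonded_e_f(
        topology, np.asarray(positions, float), terms,
        box if box is not None else np.array([1e9, 1e9, 1e9]),
        periodic if periodic is not None else np.zeros(3, bool),
        half_harmonic, need_forces=False,
    )
    total = float(sum(e.values()))
    return total, e


def _bonded_e_f(topology, pos, terms, box, periodic, half_harmonic, need_forces=True):
    n = topology.n_sites
    breakdown = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0}
    f = np.zeros((n, 3)) if need_forces else None
    virial = 0.0
    kfac = 0.5 if half_harmonic else 1.0

    # --- bonds
    if topology.bonds:
        i_idx = np.array([b[0] for b in topology.bonds])
        j_idx = np.array([b[1] for b in topology.bonds])
        if i_idx.max(initial=-1) >= n or j_idx.max(initial=-1) >= n:
            raise TopologyError("bond references missing site")
        try:
            params = np.array([terms.bonds[b[2]] for b in topology.bonds])
        except KeyError as exc:
            raise ParameterError(f"missing bond type {exc}") from None
        k, r0 = params[:, 0], params[:, 1]
        d = _min_image(pos[i_idx] - pos[j_idx], box, periodic)
        r = np.linalg.norm(d, axis=1)
        dr = r - r0
        breakdown["bond"] = float(np.sum(kfac * k * dr**2))
        if need_forces:
            # F_i = -dE/dr * d/r
            coef = -2.0 * kfac * k * dr / r
            fij = coef[:, None] * d
            np.add.at(f, i_idx, fij)
            np.add.at(f, j_idx, -fij)
            virial += float(np.sum(np.sum(fij * d, axis=1)))

    # --- angles (i-j-k, vertex j)
    if topology.angles:
        ai = np.array([a[0] for a in topology.angles])
        aj = np.array([a[1] for a in topology.angles])
        ak = np.array([a[2] for a in topology.angles])
        if max(ai.max(), aj.max(), ak.max()) >= n:
            raise TopologyError("angle references missing site")
        try:
            params = np.array([terms.angles[a[3]] for a in topology.angles])
        except KeyError as exc:
            raise ParameterError(f"missing angle type {exc}") from None
        k, th0 = params[:, 0], np.deg2rad(params[:, 1])
        rij = _min_image(pos[ai] - pos[aj], box, periodic)
        rkj = _min_image(pos[ak] - pos[aj], box, periodic)
        nij = np.linalg.norm(rij, axis=1)
        nkj = np.linalg.norm(rkj, axis=1)
        cos_t = np.clip(np.sum(rij * rkj, axis=1) / (nij * nkj), -1.0, 1.0)
        theta = np.arccos(cos_t)
        dth = theta - th0
        breakdown["angle"] = float(np.sum(kfac * k * dth**2))
        if need_forces:
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
            de_dth = 2.0 * kfac * k * dth
            # dtheta/dri and dtheta/drk
            coef = -1.0 / sin_t
            dcos_dri = (rkj / (nij * nkj)[:, None]
                        - cos_t[:, None] * rij / (nij**2)[:, None])
            dcos_drk = (rij / (nij * nkj)[:, None]
                        - cos_t[:, None] * rkj / (nkj**2)[:, None])
            fi = -de_dth[:, None] * coef[:, None] * dcos_dri
            fk = -de_dth[:, None] * coef[:, None] * dcos_drk
            np.add.at(f, ai, fi)
            np.add.at(f, ak, fk)
            np.add.at(f, aj, -(fi + fk))
            virial += float(np.sum(fi * rij) + np.sum(fk * rkj))

    # --- dihedrals (OPLS cosine series)
    if topology.dihedrals:
        d1 = np.array([d[0] for d in topology.dihedrals])
        d2 = np.array([d[1] for d in topology.dihedrals])
        d3 = np.array([d[2] for d in topology.dihedrals])
        d4 = np.array([d[3] for d in topology.dihedrals])
        if max(d1.max(), d2.max(), d3.max(), d4.max()) >= n:
            raise TopologyError("dihedral references missing site")
        try:
            coeffs = np.array(
                [list(terms.dihedrals[d[4]]) + [0.0] * 4 for d in topology.dihedrals]
            )[:, :4]
        except KeyError as exc:
            raise ParameterError(f"missing dihedral type {exc}") from None
        b1 = _min_image(pos[d2] - pos[d1], box, periodic)
        b2 = _min_image(pos[d3] - pos[d2], box, periodic)
        b3 = _min_image(pos[d4] - pos[d3], box, periodic)
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        x = np.sum(n1 * n2, axis=1)
        y = np.sum(np.cross(n1, n2) * b2, axis=1) / nb2
        phi = np.arctan2(y, x)
        k1, k2, k3, k4 = coeffs.T
        breakdown["dihedral"] = float(np.sum(
            0.5 * k1 * (1 + np.cos(phi))
            + 0.5 * k2 * (1 - np.cos(2 * phi))
            + 0.5 * k3 * (1 + np.cos(3 * phi))
            + 0.5 * k4 * (1 - np.cos(4 * phi))
        ))
        if need_forces:
            de_dphi = (
                -0.5 * k1 * np.sin(phi)
                + k2 * np.sin(2 * phi)
                - 1.5 * k3 * np.sin(3 * phi)
                + 2.0 * k4 * np.sin(4 * phi)
            )
            n1sq = np.sum(n1 * n1, axis=1)
            n2sq = np.sum(n2 * n2, axis=1)
            # guard collinear geometries
            n1sq = np.clip(n1sq, 1e-12, None)
            n2sq = np.clip(n2sq, 1e-12, None)
            # dphi/dr1 = -(|b2|/|n1|^2) n1 ; dphi/dr4 = +(|b2|/|n2|^2) n2 ;
            # transverse atoms carry -(1+t) g1 + s g4 and t g1 - (1+s) g4
            g1 = (-nb2 / n1sq)[:, None] * n1
            g4 = (nb2 / n2sq)[:, None] * n2
            t = (np.sum(b1 * b2, axis=1) / nb2**2)[:, None]
            s = (np.sum(b3 * b2, axis=1) / nb2**2)[:, None]
            a = de_dphi[:, None]
            f1 = -a * g1
            f4 = -a * g4
            f2 = -a * (-(1.0 + t) * g1 + s * g4)
            f3 = -a * (t * g1 - (1.0 + s) * g4)
            np.add.at(f, d1, f1)
            np.add.at(f, d2, f2)
            np.add.at(f, d3, f3)
            np.add.at(f, d4, f4)
            # positions relative to site 2 (consistent local frame)
            p1 = -b1
            p3 = b2
            p4 = b2 + b3
            virial += float(np.sum(f1 * p1) + np.sum(f3 * p3) + np.sum(f4 * p4))

    return breakdown, f, virial


# ---------------------------------------------------------------------------
# nonbonded evaluation
# ---------------------------------------------------------------------------

def _nb_cache(topology: Topology, ff: ForceFieldSpec):
    """Per-topology cache: kind indices, per-pair eps/sigma/qq, scale matrix."""
    key = (
        ff.scale_14,
        tuple(sorted(ff.pair_table.explicit_pairs.items())),
        tuple(sorted(ff.pair_table.cross_scale.items())),
        tuple(
            (k.name, k.epsilon, k.sigma)
            for k in sorted(
                (ff.kinds[n] for n in set(topology.kinds) if n in ff.kinds),
                key=lambda k: k.name,
            )
        ),
    )
    cache = getattr(topology, "_nb_cache", None)
    if cache is not None and cache["key"] == key:
        return cache
    n = topology.n_sites
    kind_names = sorted(set(topology.kinds))
    for name in kind_names:
        ff.kind(name)  # raise on unregistered kinds
    kind_of = {name: i for i, name in enumerate(kind_names)}
    ki = np.array([kind_of[k] for k in topology.kinds])
    nk = len(kind_names)
    eps_k = np.zeros((nk, nk))
    sig_k = np.ones((nk, nk))
    for a in range(nk):
        for b in range(nk):
            eps_k[a, b], sig_k[a, b] = ff.pair_params(kind_names[a], kind_names[b])
    eps = eps_k[ki[:, None], ki[None, :]]
    sig = sig_k[ki[:, None], ki[None, :]]
    q = topology.charges
    qq = q[:, None] * q[None, :]

    # 1-2/1-3 exclusions and 1-4 scaling from the bond graph (+ constraints)
    scale = np.ones((n, n))
    np.fill_diagonal(scale, 0.0)
    adj: list[set[int]] = [set() for _ in range(n)]
    for i, j, _ in topology.bonds:
        adj[i].add(j)
        adj[j].add(i)
    for i, j, _ in topology.constraints:
        adj[i].add(j)
        adj[j].add(i)
    for i in range(n):
        one_two = adj[i]
        one_three = set().union(*(adj[j] for j in one_two)) - {i} if one_two else set()
        one_four = (set().union(*(adj[j] for j in one_three)) - {i}
                    if one_three else set())
        for j in one_four - one_two - one_three:
            scale[i, j] = min(scale[i, j], ff.scale_14)
        for j in one_two | one_three:
            scale[i, j] = 0.0
    iu, ju = np.triu_indices(n, k=1)
    cache = {
        "key": key,
        "iu": iu,
        "ju": ju,
        "eps": eps[iu, ju],
        "sig": sig[iu, ju],
        "qq": qq[iu, ju] * ff.coulomb_constant,
        "scale": scale[iu, ju],
    }
    topology._nb_cache = cache
    return cache


def _nonbonded_e_f(state: State, ff: ForceFieldSpec, need_forces=True,
                   apply_cutoff=True):
    top = state.topology
    n = top.n_sites
    cache = _nb_cache(top, ff)
    iu, ju = cache["iu"], cache["ju"]
    pos = state.positions
    d = _min_image(pos[iu] - pos[ju], state.box, state.periodic)
    r2 = np.sum(d * d, axis=1)
    active = cache["scale"] > 0.0
    if np.any(r2[active] < 1e-12):
        bad = np.flatnonzero(active & (r2 < 1e-12))[0]
        raise SingularityError(
            f"sites {iu[bad]} and {ju[bad]} overlap (r < 1e-6 A)"
        )
    within = active & (r2 < ff.cutoff**2) if apply_cutoff else active
    idx = np.flatnonzero(within)
    r2s = r2[idx]
    eps = cache["eps"][idx]
    sig = cache["sig"][idx]
    qq = cache["qq"][idx] * cache["scale"][idx]
    lj_mask = eps > 0.0
    e_lj = np.zeros(len(idx))
    f_lj = np.zeros(len(idx))
    if np.any(lj_mask):
        e_lj[lj_mask], f_lj[lj_mask] = _lj_e_f(
            r2s[lj_mask], eps[lj_mask], sig[lj_mask], ff.cutoff,
            ff.lj_shift if apply_cutoff else "none",
        )
        e_lj[lj_mask] *= cache["scale"][idx][lj_mask]
        f_lj[lj_mask] *= cache["scale"][idx][lj_mask]
    r = np.sqrt(r2s)
    q_mask = qq != 0.0
    e_c = np.zeros(len(idx))
    f_c = np.zeros(len(idx))
    if np.any(q_mask):
        method = ff.electrostatics if apply_cutoff else "direct"
        e_c[q_mask], f_c[q_mask] = _coulomb_e_f(
            r[q_mask], qq[q_mask], method, ff.cutoff, ff.dsf_alpha,
            ff.rf_dielectric,
        )
    energy = float(np.sum(e_lj) + np.sum(e_c))
    f = None
    virial = 0.0
    if need_forces:
        fmag = f_lj + f_c
        fvec = (fmag / r)[:, None] * d[idx]
        f = np.zeros((n, 3))
        np.add.at(f, iu[idx], fvec)
        np.add.at(f, ju[idx], -fvec)
        virial = float(np.sum(fmag * r))
    return energy, f, virial


def _wall_e_f(state: State, need_forces=True):
    """Purely repulsive (WCA) wall interactions along x."""
    if not state.walls:
        return 0.0, (np.zeros_like(state.positions) if need_forces else None)
    top = state.topology
    species_of_site = np.empty(top.n_sites, dtype=object)
    for mol in top.molecules:
        species_of_site[mol.sites] = mol.species
    energy = 0.0
    f = np.zeros((top.n_sites, 3)) if need_forces else None
    x = state.positions[:, 0]
    for wall in state.walls:
        applies = np.array([wall.applies_to(s) if s is not None else False
                            for s in species_of_site])
        dist = wall.side * (x - wall.x0)
        rc = 2 ** (1 / 6) * wall.sigma
        mask = applies & (dist < rc)
        if not np.any(mask):
            continue
        dd = np.clip(dist[mask], 0.01, None)
        sr6 = (wall.sigma / dd) ** 6
        energy += float(np.sum(4 * wall.epsilon * (sr6**2 - sr6) + wall.epsilon))
        if need_forces:
            fmag = 24 * wall.epsilon * (2 * sr6**2 - sr6) / dd
            f[mask, 0] += wall.side * fmag
    return energy, f


def evaluate(state: State, ff: ForceFieldSpec, apply_cutoff: bool = True):
    """Potential energy, forces, and pair virial of a configuration.

    Returns ``(U [kcal/mol], F [(N,3) kcal/mol/A], W [kcal/mol])`` where
    W is the scalar virial sum r_ij . f_ij over all interactions (used
    for the pressure).  Frozen sites have their forces zeroed.
    """
    e_b, f_b, w_b = _bonded_e_f(
        state.topology, state.positions, ff.bonded, state.box, state.periodic,
        ff.half_harmonic,
    )
    e_nb, f_nb, w_nb = _nonbonded_e_f(state, ff, need_forces=True,
                                      apply_cutoff=apply_cutoff)
    e_w, f_w = _wall_e_f(state)
    u = float(sum(e_b.values())) + e_nb + e_w
    f = f_b + f_nb + f_w
    if len(state.frozen):
        f[state.frozen] = 0.0
    return u, f, w_b + w_nb


def total_potential_energy(state: State, ff: ForceFieldSpec,
                           apply_cutoff: bool = True) -> float:
    """Bonded + LJ + Coulomb energy with exclusions, kcal/mol."""
    e_b, _, _ = _bonded_e_f(
        state.topology, state.positions, ff.bonded, state.box, state.periodic,
        ff.half_harmonic, need_forces=False,
    )
    e_nb, _, _ = _nonbonded_e_f(state, ff, need_forces=False,
                                apply_cutoff=apply_cutoff)
    e_w, _ = _wall_e_f(state, need_forces=False)
    return float(sum(e_b.values())) + e_nb + e_w


def forces(state: State, ff: ForceFieldSpec,
           apply_cutoff: bool = True) -> np.ndarray:
    """Analytic forces, kcal/mol/A (negative gradient of the energy)."""
    _, f, _ = evaluate(state, ff, apply_cutoff=apply_cutoff)
    return f
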