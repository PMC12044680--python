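"""Default force-field parameterisation and literature reference data.

The PDMS united-atom set carries the tabulated 12-6 pairs (self terms
define the site kinds, cross terms are explicit table entries that
override Lorentz-Berthelot mixing), with the CH3 diameter already at its
density-corrected value (3.86 A = 3.7298 A x 1.0349).  Water is SPC,
kept rigid by distance constraints.  The five organics use OPLS-style
all-atom parameters; their hydroxyl hydrogens are LJ-inactive.

The water-organic cross epsilon is scaled by 1.20 (fitted on the
water-phenol pair against aqueous phenol diffusion data and applied to
every organic species by default).

PDMS partial charges and bonded constants are package defaults chosen to
be physically reasonable for a siloxane backbone; every partition /
solubility quantity computed downstream is independent of them.
"""

from __future__ import annotations

import math as _math

from .forcefield import BondedTerms, ForceFieldSpec, PairTable, SiteKind

__all__ = [
    "default_forcefield",
    "apply_water_organic_scaling",
    "WATER_ORGANIC_EPS_SCALE",
    "ORGANIC_KINDS",
    "MOLAR_MASS",
    "WATER_SOLUBILITY_MOL_PCT",
    "SPC_OH", "SPC_HH", "SPC_ANGLE_DEG",
]

WATER_ORGANIC_EPS_SCALE = 1.20

# SPC water geometry (rigid): O-H 1.0 A, H-O-H 109.47 deg
SPC_OH = 1.0
SPC_ANGLE_DEG = 109.47
SPC_HH = 2.0 * SPC_OH * _math.sin(_math.radians(SPC_ANGLE_DEG / 2.0))

#: site kinds used by the organic all-atom templates
ORGANIC_KINDS = ("CA", "HA", "OH", "HO", "CL", "CT", "HC", "OS")

#: molar masses of the studied compounds, g/mol
MOLAR_MASS = {
    "phenol": 94.11,
    "guaiacol": 124.14,
    "chlorophenol": 128.6,
    "benzyl alcohol": 108.14,
    "phenethyl alcohol": 122.16,
    "water": 18.015,
}

#: aqueous solubility limits (mol %) used to size the organic loading
WATER_SOLUBILITY_MOL_PCT = {
    ("phenol", 298.15): 1.6,
    ("phenol", 330.48): 2.7,
    ("phenol", 335.89): 3.5,
    ("guaiacol", 298.15): 0.3,
    ("chlorophenol", 298.15): 0.4,
    ("benzyl alcohol", 298.15): 0.71,
    ("phenethyl alcohol", 298.15): 0.3,
}


def default_forcefield() -> ForceFieldSpec:
    """The package's standard interaction model (PDMS + SPC + organics)."""
    kinds = [
        # PDMS united-atom sites (self LJ terms from the tabulated pairs)
        SiteKind("Si", 28.0855, 0.30, 0.1310, 4.29),
        SiteKind("OSi", 15.999, -0.30, 0.0800, 3.30),
        SiteKind("CH3", 15.035, 0.00, 0.1944, 3.86),
        # SPC water
        SiteKind("OW", 15.999, -0.82, 0.1553, 3.166),
        SiteKind("HW", 1.008, 0.41, 0.0, 0.0),
        # organic all-atom sites (OPLS-style)
        SiteKind("CA", 12.011, -0.115, 0.070, 3.55),
        SiteKind("HA", 1.008, 0.115, 0.030, 2.42),
        SiteKind("OH", 15.999, -0.585, 0.170, 3.12),
        SiteKind("HO", 1.008, 0.435, 0.0, 0.0),
        SiteKind("CL", 35.453, -0.180, 0.300, 3.40),
        SiteKind("CT", 12.011, 0.0, 0.066, 3.50),
        SiteKind("HC", 1.008, 0.060, 0.030, 2.50),
        SiteKind("OS", 15.999, -0.285, 0.140, 2.90),
        # frozen wall decoration (interactions carried by the planar wall)
        SiteKind("WALL", 195.08, 0.0, 0.0, 0.0),
    ]

    pairs = PairTable()
    # tabulated PDMS 12-6 pairs; cross rows override L-B mixing
    pairs.set_pair("Si", "Si", 0.1310, 4.29)
    pairs.set_pair("Si", "OSi", 0.0772, 3.94)
    pairs.set_pair("Si", "CH3", 0.1596, 3.83)
    pairs.set_pair("OSi", "OSi", 0.0800, 3.30)
    pairs.set_pair("OSi", "CH3", 0.1247, 3.38)
    pairs.set_pair("CH3", "CH3", 0.1944, 3.86)

    bonded = BondedTerms(
        bonds={
            "SiO": (350.0, 1.64),
            "SiC": (190.0, 1.90),
            "CA-CA": (469.0, 1.40),
            "CA-HA": (367.0, 1.08),
            "CA-OH": (450.0, 1.364),
            "OH-HO": (553.0, 0.945),
            "CA-CL": (300.0, 1.725),
            "CA-CT": (317.0, 1.51),
            "CT-CT": (268.0, 1.529),
            "CT-HC": (340.0, 1.09),
            "CT-OH": (320.0, 1.41),
            "CA-OS": (450.0, 1.364),
            "CT-OS": (320.0, 1.41),
        },
        angles={
            "OSiO": (95.0, 107.8),
            "SiOSi": (14.0, 146.0),
            "CSiC": (49.0, 109.5),
            "CSiO": (49.5, 110.0),
            "CA-CA-CA": (63.0, 120.0),
            "CA-CA-HA": (35.0, 120.0),
            "CA-CA-OH": (70.0, 120.0),
            "CA-OH-HO": (35.0, 109.0),
            "CA-CA-CL": (75.0, 120.0),
            "CA-CA-CT": (70.0, 120.0),
            "CA-CT-HC": (35.0, 109.5),
            "HC-CT-HC": (33.0, 107.8),
            "CA-CT-CT": (63.0, 114.0),
            "CA-CT-OH": (50.0, 109.5),
            "CT-CT-OH": (50.0, 109.5),
            "CT-CT-HC": (33.0, 110.7),
            "CT-OH-HO": (55.0, 108.5),
            "CA-OS-CT": (75.0, 111.0),
            "CA-CA-OS": (70.0, 120.0),
            "HC-CT-OS": (35.0, 109.5),
            "HC-CT-OH": (35.0, 109.5),
        },
        dihedrals={
            # OPLS cosine-series coefficients K1..K4
            "AROM": (0.0, 7.25, 0.0, 0.0),   # keeps rings planar
            "SIOX": (0.0, 0.0, 0.225, 0.0),  # soft siloxane backbone torsion
            "SOFT": (0.0, 0.0, 0.30, 0.0),   # generic substituent torsion
        },
    )

    ff = ForceFieldSpec(
        kinds={k.name: k for k in kinds},
        pair_table=pairs,
        bonded=bonded,
        cutoff=12.0,
    )
    apply_water_organic_scaling(ff)
    ff.validate()
    return ff


def apply_water_organic_scaling(
    ff: ForceFieldSpec,
    factor: float = WATER_ORGANIC_EPS_SCALE,
    organic_kinds: tuple[str, ...] | None = None,
) -> None:
    """Scale the water-organic cross epsilon.

    By default the correction applies to every organic site kind; pass an
    explicit subset (e.g. only the phenol kinds) to restrict it.
    """
    targets = ORGANIC_KINDS if organic_kinds is None else organic_kinds
    for name in targets:
        ff.pair_table.set_scale("OW", name, factor)
        ff.pair_table.set_scale("HW", name, factor)
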