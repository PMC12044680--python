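"""Unit system and physical constants.

The package works in "real" MD units throughout:

========== =================
quantity   unit
========== =================
length     angstrom (A)
time       femtosecond (fs)
mass       amu (g/mol)
energy     kcal/mol
charge     elementary charge e
velocity   A/fs
force      kcal/mol/A
T          kelvin
P          atm
========== =================

Conversion factors follow CODATA values rounded at the precision
conventional for classical force-field engines.
"""

# Boltzmann constant, kcal/(mol K)
KB = 0.0019872067

# Coulomb prefactor k_e in kcal*A/(mol*e^2):  E = KE_COULOMB * q1*q2 / r
KE_COULOMB = 332.06371

# kinetic energy:  (amu * (A/fs)^2)  ->  kcal/mol
MVV2E = 48.88821291 ** 2  # = 2390.0574...

# force/mass -> acceleration:  (kcal/mol/A) / amu  ->  A/fs^2
F2A = 1.0 / MVV2E

# pressure:  kcal/(mol A^3)  ->  atm
P_KCALMOLA3_TO_ATM = 68568.415

# density:  (amu / A^3)  ->  g/cm^3
AMU_A3_TO_G_CM3 = 1.66053907

AVOGADRO = 6.02214076e23

# molarity: count / A^3 -> mol/L  (1 A^3 = 1e-27 L)
COUNT_A3_TO_MOL_L = 1.0 / (AVOGADRO * 1e-27)

# diffusion: A^2/ps -> cm^2/s
A2_PS_TO_CM2_S = 1.0e-4

FS_PER_PS = 1000.0
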