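"""Package-wide unit system and physical constants.

Everything in the package is expressed in a single coherent unit system
chosen for femtosecond ion dynamics on Ångström length scales:

==========  =======================================
length      Å
time        fs
energy      eV
charge      elementary charge e
mass        eV·fs²/Å² (atomic masses entered in u)
==========  =======================================

In these units the Coulomb constant ``e²/(4πε₀)`` is ``K_E = 14.3996 eV·Å``
and a particle of mass *m* (u) moving at *v* (Å/fs) has kinetic energy
``0.5 * m * MASS_U * v**2`` eV.  1 Å/fs = 10⁵ m/s.
"""

# Coulomb constant e^2 / (4 pi eps0) in eV·Å
K_E = 14.3996

# 1 u in eV·fs²/Å²  (931.494 MeV / c²  with c = 2997.92458 Å/fs)
MASS_U = 931.49410242e6 / 2997.92458**2

# electron mass in eV·fs²/Å²
MASS_E = 510998.95 / 2997.92458**2

# speed of light, Å/fs (occasionally useful in sanity checks)
C_LIGHT = 2997.92458

# conversion: 1 Å/fs in m/s
ANG_PER_FS_TO_M_PER_S = 1.0e5

# conversion: photons per µm² -> photons per Å²  (1 µm² = 1e8 Å²)
PER_UM2_TO_PER_A2 = 1.0e-8

# atomic masses (u) for the elements the generators produce
ATOMIC_MASS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}

# single-bond covalent radii (Å), used for the collision-potential contact
# radii r_e = r_cov(i) + r_cov(j)
COVALENT_RADIUS = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
}

ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "S": 16}
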