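"""Physical constants and unit conventions.

Internal units: length Å, time ps, mass amu (Da), energy kcal/mol,
temperature K.  Velocities are Å/ps; kinetic energy in kcal/mol is
``0.5 * KE_FACTOR * sum(m * v**2)``.
"""

# Boltzmann constant, kcal/(mol K)
KB_KCAL = 0.0019872041

# Converts amu * (Å/ps)^2 to kcal/mol:
#   1 amu Å^2/ps^2 = 1.66053906660e-27 kg * 1e4 m^2/s^2 * N_A / 4184 J/kcal
KE_FACTOR = 0.002390057361376673


def kinetic_energy(masses, velocities) -> float:
    """Kinetic energy (kcal/mol) of per-atom velocities (Å/ps)."""
    import numpy as np

    v2 = np.einsum("ij,ij->i", velocities, velocities)
    return 0.5 * KE_FACTOR * float(np.dot(masses, v2))


def kinetic_temperature(masses, velocities) -> float:
    """Instantaneous kinetic temperature (K), 3N degrees of freedom."""
    ke = kinetic_energy(masses, velocities)
    n = len(masses)
    return 2.0 * ke / (3.0 * n * KB_KCAL)
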