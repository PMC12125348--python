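"""Physical constants and unit conventions.

The package works in GROMACS-style units throughout: lengths in nm, times
in ps (user-facing times in ns), energies in kJ/mol, masses in amu and
charges in elementary charge units.  Velocities are nm/ps, forces
kJ mol^-1 nm^-1.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.00831446261815324

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_COULOMB = 138.935458

#: Avogadro's number, mol^-1
N_AVOGADRO = 6.02214076e23

#: nm^3 per litre
NM3_PER_LITRE = 1.0e24


def kt(temperature: float) -> float:
    """Thermal energy k_B*T in kJ/mol at the given temperature (K)."""
    return KB * temperature
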