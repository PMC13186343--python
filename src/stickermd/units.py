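"""Unit system and physical constants.

The package works in the "real" unit convention common in coarse-grained
biomolecular MD: distances in angstrom (Å), time in femtoseconds (fs),
energies in kcal/mol, masses in g/mol, temperature in kelvin.  In these
units velocities are Å/fs and forces kcal/(mol·Å).
"""

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹
KB = 0.0019872041

#: (g/mol)·(Å/fs)² → kcal/mol (kinetic-energy conversion)
MVV2E = 1.0e7 / 4184.0

#: (kcal/mol/Å) / (g/mol) → Å/fs² (force-to-acceleration conversion)
FTM2V = 4184.0 / 1.0e7


def kT(temperature: float) -> float:
    """Thermal energy kB·T in kcal/mol at the given temperature (K)."""
    return KB * temperature
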