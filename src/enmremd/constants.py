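"""Physical constants and unit conventions.

The package works in a single internal unit system throughout:

========== ==================== =====================================
quantity   unit                 notes
========== ==================== =====================================
length     Å (angstrom)
time       ps (picosecond)
energy     kcal/mol
mass       amu (g/mol)
temperature K
force      kcal mol⁻¹ Å⁻¹
spring k   kcal mol⁻¹ Å⁻²
bias k     kcal mol⁻¹ Å⁻⁴      quartic centroid-distance bias
========== ==================== =====================================

Because kcal/mol is not the natural energy unit of (amu, Å, ps),
accelerations and thermal velocities carry the conversion factor
``AKMA_ENERGY`` = 418.4 amu Å² ps⁻² per kcal/mol.
"""

#: Boltzmann constant / gas constant, kcal mol^-1 K^-1
KB = 1.987204259e-3

#: thermal energy RT at 300 K, kcal/mol (0.5962 to the precision used here)
RT_300 = KB * 300.0

#: 1 kcal/mol expressed in amu Å^2 ps^-2
AKMA_ENERGY = 418.4

#: default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0

#: average amino-acid residue mass, amu, used when per-residue masses are off
DEFAULT_RESIDUE_MASS = 110.0

#: monoisotopic-ish average residue masses (amu) for optional exact weighting
RESIDUE_MASSES = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "PRO": 97.12, "VAL": 99.13,
    "THR": 101.10, "CYS": 103.14, "LEU": 113.16, "ILE": 113.16, "ASN": 114.10,
    "ASP": 115.09, "GLN": 128.13, "LYS": 128.17, "GLU": 129.12, "MET": 131.20,
    "HIS": 137.14, "PHE": 147.18, "ARG": 156.19, "TYR": 163.18, "TRP": 186.21,
}
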