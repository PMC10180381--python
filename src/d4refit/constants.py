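"""Physical constants and unit conversions.

All internal quantities use Å for lengths and kcal/mol for energies.
Parameter files may declare atomic units and are converted once at load time.
"""

HARTREE_TO_KCAL_PER_MOL: float = 627.509474
BOHR_TO_ANGSTROM: float = 0.52917721

#: Standard atomic weights (u) for the elements the package recognizes.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "Be": 9.0122,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Ne": 20.180,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Ar": 39.948,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

RECOGNIZED_ELEMENTS = frozenset(ATOMIC_MASSES)
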