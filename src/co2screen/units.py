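"""Physical constants and unit conversions.

All energies are stored in Hartree internally, all coordinates in
Angstrom.  Conversion to the reporting unit (kcal/mol) happens at the
edges, always through the single constant defined here.
"""

#: 1 Hartree in kcal/mol (CODATA).
HARTREE_TO_KCAL: float = 627.509474

#: Boltzmann constant in Hartree per Kelvin.
KB_HARTREE: float = 3.166811563e-6

#: Default thermochemistry temperature (K).
ROOM_TEMPERATURE: float = 298.15

#: Preset for adduct stability in DMSO at 20 degrees C.
T_20C: float = 293.15


def hartree_to_kcal(value: float) -> float:
    """Convert an energy from Hartree to kcal/mol."""
    return value * HARTREE_TO_KCAL


def kcal_to_hartree(value: float) -> float:
    """Convert an energy from kcal/mol to Hartree."""
    return value / HARTREE_TO_KCAL
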