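"""Published reference values for benchmark carbanion candidates.

Twelve reference nucleophiles from the screening study this workflow
automates, with their reported HOMO energies (Hartree) and CO2
affinities (kcal/mol, negative Gibbs free reaction energy of
carboxylation in DMSO).  The two candidates with HOMO energies below
the -0.140 Hartree screen ("11" and "12") were screened out and did
not form adducts experimentally; the remainder passed.

These numbers are inputs for regression-testing the screening filter
and the affinity sign convention; the package never fits to them.
"""

#: id -> (epsilon_HOMO / Hartree, CO2 affinity / kcal mol^-1)
REFERENCE_CANDIDATES: dict[str, tuple[float, float]] = {
    "1": (-0.137, -1.32),
    "37": (-0.128, 4.72),
    "38": (-0.129, 3.12),
    "48": (-0.132, 2.89),
    "32": (-0.130, 2.63),
    "41": (-0.130, 2.56),
    "92": (-0.137, 2.25),
    "39": (-0.130, 1.85),
    "33": (-0.133, 1.53),
    "73": (-0.137, 1.47),
    "12": (-0.153, -2.7),
    "11": (-0.150, -5.6),
}

#: ids reported as screened out by the HOMO-energy filter
SCREENED_OUT_IDS = frozenset({"11", "12"})
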