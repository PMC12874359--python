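"""Bundled reference data.

A single covalent-radius table (Cordero et al. style consensus values, in
Å) is versioned here so that bond detection is reproducible across runs
and machines.  For carbon the sp3 value is used.
"""

# fmt: off
COVALENT_RADII = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Sc": 1.70, "Ti": 1.60, "V": 1.53, "Cr": 1.39,
    "Mn": 1.39, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32, "Zn": 1.22,
    "Ga": 1.22, "Ge": 1.20, "As": 1.19, "Se": 1.20, "Br": 1.20, "Kr": 1.16,
    "Rb": 2.20, "Sr": 1.95, "I": 1.39, "Xe": 1.40,
    # single-site marker for analytic 2-D surfaces (one pseudo-atom)
    "X": 0.50,
}
# fmt: on

#: Bohr radius in Å; used by the external-calculator adapter to convert
#: Hartree/bohr gradients to Hartree/Å.
BOHR_IN_ANGSTROM = 0.529177210903
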