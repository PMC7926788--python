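"""Shared chemical constants: vdW radii, hydrophobicity scale, residue classes."""

# Element-keyed van der Waals radii (Å). Deliberately coarse: cavity geometry
# at alpha-sphere resolution does not need per-atom-type radii.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}
VDW_DEFAULT = 1.70

# Elements counted as apolar for alpha-sphere apolarity tagging.
APOLAR_ELEMENTS = frozenset({"C", "S"})

# Kyte-Doolittle hydropathy index per 3-letter residue code.
KYTE_DOOLITTLE = {
    "ILE": 4.5, "VAL": 4.2, "LEU": 3.8, "PHE": 2.8, "CYS": 2.5,
    "MET": 1.9, "ALA": 1.8, "GLY": -0.4, "THR": -0.7, "SER": -0.8,
    "TRP": -0.9, "TYR": -1.3, "PRO": -1.6, "HIS": -3.2, "GLU": -3.5,
    "GLN": -3.5, "ASP": -3.5, "ASN": -3.5, "LYS": -3.9, "ARG": -4.5,
}

# Residue-class membership (3-letter codes); one-letter sets in the feature
# contract: polar {S,T,N,Q,Y,C,H}, charged {D,E,K,R}, aromatic {F,W,Y,H}.
POLAR_RESIDUES = frozenset({"SER", "THR", "ASN", "GLN", "TYR", "CYS", "HIS"})
CHARGED_RESIDUES = frozenset({"ASP", "GLU", "LYS", "ARG"})
AROMATIC_RESIDUES = frozenset({"PHE", "TRP", "TYR", "HIS"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})
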