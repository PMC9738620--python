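"""Packaged chemical reference tables.

All geometry modules draw radii, polarity classes and solvation parameters
from this single module so that results are reproducible across tools.
Every table can be overridden by passing an explicit mapping to the
operation that consumes it.
"""

from __future__ import annotations

# Bondi-style van der Waals radii (Angstrom), keyed by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

#: Radius used (with a warning) for elements absent from VDW_RADII.
DEFAULT_VDW_RADIUS: float = 1.70

STANDARD_RESIDUES: frozenset[str] = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
        "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
        "TYR", "VAL",
    }
)

AA_THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

AA_ONE_TO_THREE: dict[str, str] = {v: k for k, v in AA_THREE_TO_ONE.items()}

BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O"})

# Heavy side-chain atoms counted as apolar for hydrophobic-contact typing.
# Carbons bonded to polar/charged groups are deliberately excluded
# (e.g. Ser CB, Arg CD, Lys CE); Met SD is treated as apolar sulfur.
APOLAR_ATOMS: dict[str, frozenset[str]] = {
    "ALA": frozenset({"CB"}),
    "ARG": frozenset({"CB", "CG"}),
    "ASN": frozenset({"CB"}),
    "ASP": frozenset({"CB"}),
    "CYS": frozenset({"CB"}),
    "GLN": frozenset({"CB", "CG"}),
    "GLU": frozenset({"CB", "CG"}),
    "GLY": frozenset(),
    "HIS": frozenset({"CB"}),
    "ILE": frozenset({"CB", "CG1", "CG2", "CD1"}),
    "LEU": frozenset({"CB", "CG", "CD1", "CD2"}),
    "LYS": frozenset({"CB", "CG", "CD"}),
    "MET": frozenset({"CB", "CG", "SD", "CE"}),
    "PHE": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "PRO": frozenset({"CB", "CG", "CD"}),
    "SER": frozenset(),
    "THR": frozenset({"CG2"}),
    "TRP": frozenset({"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CB", "CG", "CD1", "CD2", "CE1", "CE2"}),
    "VAL": frozenset({"CB", "CG1", "CG2"}),
}

# Heavy-atom hydrogen-bond donors per residue, with the antecedent atom
# used for the (antecedent, donor, acceptor) angle test when present.
# The backbone amide N (antecedent CA) is a donor for every residue
# except proline.
SIDECHAIN_DONORS: dict[str, dict[str, str]] = {
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "LYS": {"NZ": "CE"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TRP": {"NE1": "CD1"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
}

# Heavy-atom hydrogen-bond acceptors per residue; backbone carbonyl O is
# an acceptor for every residue.
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLN": frozenset({"OE1"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
}

# Charged-group atoms for salt-bridge detection and positive-ionisable
# pharmacophore centroids.
CATION_ATOMS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "CZ", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

ANION_ATOMS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

# Atomic solvation parameters sigma (kcal/mol/A^2), applied per buried
# area: residue solvation gain = sum sigma(element) * dASA(atom).
# Apolar elements carry negative sigma (burial is favourable); polar
# elements positive.  Magnitudes are a documented surrogate - only the
# sign and the relative ordering of outputs are contractual.
SOLVATION_SIGMA: dict[str, float] = {
    "C": -0.025,
    "S": -0.021,
    "N": 0.012,
    "O": 0.012,
    "P": 0.012,
}

# Approximate distance (Angstrom) from CA to the side-chain centroid,
# used by the synthetic toy-complex builder to place one pseudo-atom
# per residue beyond CB.
SIDECHAIN_REACH: dict[str, float] = {
    "ALA": 1.5, "ARG": 4.1, "ASN": 2.5, "ASP": 2.5, "CYS": 2.1,
    "GLN": 3.1, "GLU": 3.1, "GLY": 0.0, "HIS": 3.2, "ILE": 2.4,
    "LEU": 2.6, "LYS": 3.5, "MET": 2.9, "PHE": 3.4, "PRO": 1.9,
    "SER": 1.9, "THR": 1.9, "TRP": 3.9, "TYR": 3.6, "VAL": 2.0,
}

# Name given to the side-chain centroid pseudo-atom per residue.  The
# name is chosen so that the polarity tables above classify the
# pseudo-atom the way the real side-chain tip would be classified
# (apolar carbon, H-bond donor/acceptor oxygen, charged nitrogen, ...).
SIDECHAIN_PSEUDO_ATOM: dict[str, str] = {
    "ALA": "CB", "ARG": "NH1", "ASN": "OD1", "ASP": "OD1", "CYS": "SG",
    "GLN": "OE1", "GLU": "OE1", "HIS": "NE2", "ILE": "CD1", "LEU": "CG",
    "LYS": "NZ", "MET": "CE", "PHE": "CZ", "PRO": "CG", "SER": "OG",
    "THR": "OG1", "TRP": "CZ2", "TYR": "CE1", "VAL": "CG1",
}


def element_from_atom_name(name: str) -> str:
    """Infer an element symbol from a PDB atom name.

    Digits and whitespace are stripped; a leading digit marks a
    hydrogen variant (e.g. ``1HB``).  Two-letter element names that
    occur in amino acids (SE of selenomethionine) are recognised; the
    general fallback is the first alphabetic character.
    """
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():
        return "H"
    alpha = "".join(ch for ch in stripped if ch.isalpha()).upper()
    if not alpha:
        return ""
    if alpha[:2] in ("SE", "CL", "BR", "FE", "ZN", "MG", "NA", "MN"):
        return alpha[:2]
    return alpha[0]
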