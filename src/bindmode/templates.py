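"""Built-in chemistry templates for standard residues and water.

Atom naming follows PDB v3 conventions. For each standard residue the table
records the heavy-atom bond graph, potential hydrogen-bond donors (heavy atoms
that donate when a hydrogen is attached), acceptors, formally charged side
chain groups, aromatic rings (ordered, cyclic) and apolar carbons used for
hydrophobic-contact detection. Donor status is *potential*: a heavy atom only
acts as a donor if the loaded structure actually carries an attached hydrogen.
"""

from __future__ import annotations

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "H2O", "TIP", "SPC"}

#: hydrogens whose attachment the positional heuristic cannot resolve
EXPLICIT_H_ATTACH = {
    "H": "N", "HN": "N", "H1": "N", "H2": "N", "H3": "N",
    "HA": "CA", "HA2": "CA", "HA3": "CA",
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HN", "HA", "HA2", "HA3",
                  "H1", "H2", "H3"}

BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O")]

# per-residue: side-chain heavy-atom bonds (backbone bonds added separately)
SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "GLY": [],
    "ALA": [("CA", "CB")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "CE1"),
            ("CE1", "CZ"), ("CZ", "CE2"), ("CE2", "CD2"), ("CD2", "CG"),
            ("CZ", "OH")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CD1", "NE1"),
            ("NE1", "CE2"), ("CE2", "CD2"), ("CD2", "CG"), ("CD2", "CE3"),
            ("CE3", "CZ3"), ("CZ3", "CH2"), ("CH2", "CZ2"), ("CZ2", "CE2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("ND1", "CE1"),
            ("CE1", "NE2"), ("NE2", "CD2"), ("CD2", "CG")],
}

# potential donor heavy atoms per residue (side chain; backbone N handled
# generically except PRO)
POTENTIAL_DONORS: dict[str, list[str]] = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"], "CYS": ["SG"],
    "ASN": ["ND2"], "GLN": ["NE2"], "LYS": ["NZ"],
    "ARG": ["NE", "NH1", "NH2"], "HIS": ["ND1", "NE2"], "TRP": ["NE1"],
}

ACCEPTORS: dict[str, list[str]] = {
    "SER": ["OG"], "THR": ["OG1"], "TYR": ["OH"],
    "ASP": ["OD1", "OD2"], "GLU": ["OE1", "OE2"],
    "ASN": ["OD1"], "GLN": ["OE1"], "HIS": ["ND1", "NE2"],
}

CHARGED_GROUPS: dict[str, tuple[list[str], int]] = {
    "ASP": (["CG", "OD1", "OD2"], -1),
    "GLU": (["CD", "OE1", "OE2"], -1),
    "LYS": (["NZ"], +1),
    "ARG": (["CZ", "NE", "NH1", "NH2"], +1),
}

AROMATIC_RINGS: dict[str, list[list[str]]] = {
    "PHE": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "TYR": [["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]],
    "HIS": [["CG", "ND1", "CE1", "NE2", "CD2"]],
    "TRP": [["CG", "CD1", "NE1", "CE2", "CD2"],
            ["CD2", "CE3", "CZ3", "CH2", "CZ2", "CE2"]],
}

HYDROPHOBIC_CARBONS: dict[str, list[str]] = {
    "ALA": ["CB"],
    "VAL": ["CB", "CG1", "CG2"],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "ILE": ["CB", "CG1", "CG2", "CD1"],
    "MET": ["CB", "CG", "CE"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CB", "CG", "CD1", "CD2", "CE1", "CE2"],
    "TRP": ["CB", "CG", "CD2", "CE3", "CZ3", "CH2", "CZ2"],
    "PRO": ["CB", "CG"],
    "LYS": ["CB", "CG", "CD"],
    "ARG": ["CB", "CG"],
    "THR": ["CG2"],
    "GLU": ["CB", "CG"],
    "GLN": ["CB", "CG"],
    "ASP": ["CB"],
    "ASN": ["CB"],
    "HIS": ["CB"],
    "CYS": ["CB"],
}

STANDARD_RESNAMES = set(SIDECHAIN_BONDS) | {"HID", "HIE", "HIP"}


def is_water_resname(resname: str) -> bool:
    return resname.strip().upper() in WATER_RESNAMES


def is_standard_resname(resname: str) -> bool:
    return resname.strip().upper() in STANDARD_RESNAMES


def canonical_resname(resname: str) -> str:
    """Map protonation-variant names onto the template key."""
    r = resname.strip().upper()
    if r in {"HID", "HIE", "HIP"}:
        return "HIS"
    return r


def hydrogen_parent(h_name: str, heavy_names: list[str]) -> str | None:
    """Resolve which heavy atom a hydrogen named per PDB v3 sits on.

    Uses the positional-code heuristic (HB2 -> CB, HG12 -> CG1, HG1 -> OG1 in
    THR) with an explicit table for backbone hydrogens.
    """
    if h_name in EXPLICIT_H_ATTACH and EXPLICIT_H_ATTACH[h_name] in heavy_names:
        return EXPLICIT_H_ATTACH[h_name]
    code = h_name[1:]  # strip leading H
    best, best_len = None, -1
    for heavy in heavy_names:
        hcode = heavy[1:]
        if hcode and code.startswith(hcode) and len(hcode) > best_len:
            best, best_len = heavy, len(hcode)
    return best
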