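"""Residue template table: (residue name, atom name) -> (CHARMM-style atom type, partial charge).

Used to assign atom types and partial charges to static PDB input that has no
accompanying PSF topology. Covers the 20 standard amino acids plus the
histidine protonation variants (HSD/HSE/HSP and the Amber-style HID/HIE/HIP
aliases). Charges follow the CHARMM all-atom protein convention (backbone
amide N -0.47 / HN +0.31, carbonyl C +0.51 / O -0.51, unit-charge side-chain
groups for Arg/Lys/Asp/Glu). Aliphatic hydrogens not listed explicitly fall
back to a generic +0.09 type.

For trajectory input none of this is consulted: types and charges come from
the PSF.
"""

from __future__ import annotations

# Shared backbone atoms (all residues; GLY and PRO override below).
_BACKBONE: dict[str, tuple[str, float]] = {
    "N": ("NH1", -0.47),
    "HN": ("H", 0.31),
    "H": ("H", 0.31),  # PDB v3 name for the amide hydrogen
    "CA": ("CT1", 0.07),
    "HA": ("HB1", 0.09),
    "C": ("C", 0.51),
    "O": ("O", -0.51),
    "OXT": ("OC", -0.67),  # C-terminal carboxylate oxygen
}

# Side chains. Heavy atoms carry the chemically meaningful charges; polar
# hydrogens are listed explicitly, aliphatic/aromatic ones where their type
# differs from the generic fallback.
_SIDECHAINS: dict[str, dict[str, tuple[str, float]]] = {
    "ALA": {"CB": ("CT3", -0.27)},
    "ARG": {
        "CB": ("CT2", -0.18),
        "CG": ("CT2", -0.18),
        "CD": ("CT2", 0.20),
        "NE": ("NC2", -0.70),
        "HE": ("HC", 0.44),
        "CZ": ("C", 0.64),
        "NH1": ("NC2", -0.80),
        "HH11": ("HC", 0.46),
        "HH12": ("HC", 0.46),
        "NH2": ("NC2", -0.80),
        "HH21": ("HC", 0.46),
        "HH22": ("HC", 0.46),
    },
    "ASN": {
        "CB": ("CT2", -0.18),
        "CG": ("CC", 0.55),
        "OD1": ("O", -0.55),
        "ND2": ("NH2", -0.62),
        "HD21": ("H", 0.32),
        "HD22": ("H", 0.30),
    },
    "ASP": {
        "CB": ("CT2A", -0.28),
        "CG": ("CC", 0.62),
        "OD1": ("OC", -0.76),
        "OD2": ("OC", -0.76),
    },
    "CYS": {
        "CB": ("CT2", -0.11),
        "SG": ("S", -0.23),
        "HG1": ("HS", 0.16),
        "HG": ("HS", 0.16),
    },
    "GLN": {
        "CB": ("CT2", -0.18),
        "CG": ("CT2", -0.18),
        "CD": ("CC", 0.55),
        "OE1": ("O", -0.55),
        "NE2": ("NH2", -0.62),
        "HE21": ("H", 0.32),
        "HE22": ("H", 0.30),
    },
    "GLU": {
        "CB": ("CT2A", -0.18),
        "CG": ("CT2", -0.28),
        "CD": ("CC", 0.62),
        "OE1": ("OC", -0.76),
        "OE2": ("OC", -0.76),
    },
    "GLY": {},
    "HSD": {
        "CB": ("CT2", -0.09),
        "CG": ("CPH1", -0.05),
        "ND1": ("NR1", -0.36),
        "HD1": ("H", 0.32),
        "CE1": ("CPH2", 0.25),
        "HE1": ("HR1", 0.13),
        "NE2": ("NR2", -0.70),
        "CD2": ("CPH1", 0.22),
        "HD2": ("HR3", 0.10),
    },
    "HSE": {
        "CB": ("CT2", -0.08),
        "CG": ("CPH1", 0.22),
        "ND1": ("NR2", -0.70),
        "CE1": ("CPH2", 0.25),
        "HE1": ("HR1", 0.13),
        "NE2": ("NR1", -0.36),
        "HE2": ("H", 0.32),
        "CD2": ("CPH1", -0.05),
        "HD2": ("HR3", 0.09),
    },
    "HSP": {
        "CB": ("CT2A", -0.05),
        "CG": ("CPH1", 0.19),
        "ND1": ("NR3", -0.51),
        "HD1": ("H", 0.44),
        "CE1": ("CPH2", 0.32),
        "HE1": ("HR2", 0.18),
        "NE2": ("NR3", -0.51),
        "HE2": ("H", 0.44),
        "CD2": ("CPH1", 0.19),
        "HD2": ("HR1", 0.13),
    },
    "ILE": {
        "CB": ("CT1", -0.09),
        "CG1": ("CT2", -0.18),
        "CG2": ("CT3", -0.27),
        "CD1": ("CT3", -0.27),
        "CD": ("CT3", -0.27),  # CHARMM name for ILE CD1
    },
    "LEU": {
        "CB": ("CT2", -0.18),
        "CG": ("CT1", -0.09),
        "CD1": ("CT3", -0.27),
        "CD2": ("CT3", -0.27),
    },
    "LYS": {
        "CB": ("CT2", -0.18),
        "CG": ("CT2", -0.18),
        "CD": ("CT2", -0.18),
        "CE": ("CT2", 0.21),
        "NZ": ("NH3", -0.30),
        "HZ1": ("HC", 0.33),
        "HZ2": ("HC", 0.33),
        "HZ3": ("HC", 0.33),
    },
    "MET": {
        "CB": ("CT2", -0.18),
        "CG": ("CT2", -0.14),
        "SD": ("S", -0.09),
        "CE": ("CT3", -0.22),
    },
    "PHE": {
        "CB": ("CT2", -0.18),
        "CG": ("CA", 0.00),
        "CD1": ("CA", -0.115),
        "HD1": ("HP", 0.115),
        "CD2": ("CA", -0.115),
        "HD2": ("HP", 0.115),
        "CE1": ("CA", -0.115),
        "HE1": ("HP", 0.115),
        "CE2": ("CA", -0.115),
        "HE2": ("HP", 0.115),
        "CZ": ("CA", -0.115),
        "HZ": ("HP", 0.115),
    },
    "PRO": {
        "CB": ("CP2", -0.18),
        "CG": ("CP2", -0.18),
        "CD": ("CP3", 0.00),
    },
    "SER": {
        "CB": ("CT2", 0.05),
        "OG": ("OH1", -0.66),
        "HG1": ("H", 0.43),
        "HG": ("H", 0.43),
    },
    "THR": {
        "CB": ("CT1", 0.14),
        "OG1": ("OH1", -0.66),
        "HG1": ("H", 0.43),
        "CG2": ("CT3", -0.27),
    },
    "TRP": {
        "CB": ("CT2", -0.18),
        "CG": ("CY", -0.03),
        "CD1": ("CA", 0.035),
        "HD1": ("HP", 0.115),
        "NE1": ("NY", -0.61),
        "HE1": ("H", 0.38),
        "CE2": ("CPT", 0.13),
        "CD2": ("CPT", -0.02),
        "CE3": ("CA", -0.115),
        "HE3": ("HP", 0.115),
        "CZ3": ("CA", -0.115),
        "HZ3": ("HP", 0.115),
        "CZ2": ("CA", -0.115),
        "HZ2": ("HP", 0.115),
        "CH2": ("CA", -0.115),
        "HH2": ("HP", 0.115),
    },
    "TYR": {
        "CB": ("CT2", -0.18),
        "CG": ("CA", 0.00),
        "CD1": ("CA", -0.115),
        "HD1": ("HP", 0.115),
        "CD2": ("CA", -0.115),
        "HD2": ("HP", 0.115),
        "CE1": ("CA", -0.115),
        "HE1": ("HP", 0.115),
        "CE2": ("CA", -0.115),
        "HE2": ("HP", 0.115),
        "CZ": ("CA", 0.11),
        "OH": ("OH1", -0.54),
        "HH": ("H", 0.43),
    },
    "VAL": {
        "CB": ("CT1", -0.09),
        "CG1": ("CT3", -0.27),
        "CG2": ("CT3", -0.27),
    },
}

# Residue-name aliases: common alternatives map onto a canonical template.
RESIDUE_ALIASES: dict[str, str] = {
    "HIS": "HSD",  # plain PDB histidine: treated as the neutral delta tautomer
    "HID": "HSD",
    "HIE": "HSE",
    "HIP": "HSP",
    "CYX": "CYS",
}

_BACKBONE_OVERRIDES: dict[str, dict[str, tuple[str, float]]] = {
    "GLY": {"CA": ("CT2", -0.02), "HA1": ("HB2", 0.09), "HA2": ("HB2", 0.09)},
    "PRO": {"N": ("N", -0.29), "CA": ("CP1", 0.02)},
}

GENERIC_HYDROGEN: tuple[str, float] = ("HA2", 0.09)


def canonical_resname(resname: str) -> str:
    resname = resname.upper()
    return RESIDUE_ALIASES.get(resname, resname)


def lookup(resname: str, atom_name: str) -> tuple[str, float] | None:
    """Return (atom type, charge) for an atom, or None if unknown.

    Hydrogens without an explicit entry map to the generic aliphatic type.
    """
    res = canonical_resname(resname)
    side = _SIDECHAINS.get(res)
    if side is None:
        return None
    name = atom_name.upper()
    if name in side:
        return side[name]
    over = _BACKBONE_OVERRIDES.get(res)
    if over and name in over:
        return over[name]
    if name in _BACKBONE:
        if res == "PRO" and name in ("HN", "H"):
            return None  # proline has no amide hydrogen
        return _BACKBONE[name]
    if name.startswith("H") or (name[:1].isdigit() and name[1:2] == "H"):
        return GENERIC_HYDROGEN
    return None


def template_residue_names() -> frozenset[str]:
    return frozenset(_SIDECHAINS) | frozenset(RESIDUE_ALIASES)
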