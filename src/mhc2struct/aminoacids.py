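"""Amino-acid naming tables and per-element constants shared across modules.

Matrices and structure records use 3-letter residue names; peptide sequences
use 1-letter codes. ``AA_ORDER_3`` is the row order used by the packaged
scoring matrices and all serialized 20xN tables.
"""

from __future__ import annotations

# Row order of the packaged matrices (alphabetical by 3-letter name with
# GLU before GLN, as conventional in these tables).
AA_ORDER_3: tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLU", "GLN", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_AA3: frozenset[str] = frozenset(THREE_TO_ONE)

#: index of each residue type in 20x... arrays (pair-potential tables)
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER_3)}
AA_INDEX.update({THREE_TO_ONE[aa]: i for i, aa in enumerate(AA_ORDER_3)})

BACKBONE_ATOMS: frozenset[str] = frozenset({"N", "CA", "C", "O", "OXT"})

# Bondi van der Waals radii (Angstrom) for the heavy elements found in
# protein crystal structures; used by the vdW contact criterion.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}


def aa_index(aa: str) -> int:
    """Array index of a residue type given as 1- or 3-letter code."""
    try:
        return AA_INDEX[aa.upper()]
    except KeyError:
        raise KeyError(f"unknown amino-acid code: {aa!r}") from None


def to_one(aa: str) -> str:
    """Normalize a 1- or 3-letter code to 1-letter."""
    aa = aa.upper()
    if len(aa) == 1:
        if aa not in ONE_TO_THREE:
            raise KeyError(f"unknown amino-acid code: {aa!r}")
        return aa
    return THREE_TO_ONE[aa]


def to_three(aa: str) -> str:
    """Normalize a 1- or 3-letter code to 3-letter."""
    aa = aa.upper()
    if len(aa) == 3:
        if aa not in THREE_TO_ONE:
            raise KeyError(f"unknown amino-acid code: {aa!r}")
        return aa
    return ONE_TO_THREE[aa]
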