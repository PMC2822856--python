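"""Shared fixtures: tiny hand-written PDB snippets and packaged matrices."""

from __future__ import annotations

import pytest

from mhc2struct import load_matrix


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    x: float,
    y: float,
    z: float,
    occupancy: float = 1.0,
    altloc: str = " ",
    element: str | None = None,
    record: str = "ATOM",
) -> str:
    """One fixed-width PDB coordinate record."""
    elem = element if element is not None else name[0]
    return (
        f"{record:<6s}{serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00"
        f"          {elem:>2s}"
    )


@pytest.fixture(scope="session")
def two_residue_pdb() -> str:
    """ALA + GLY with full backbones in one chain."""
    lines = [
        atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0),
        atom_line(2, "CA", "ALA", "A", 1, 1.458, 0.0, 0.0, element="C"),
        atom_line(3, "C", "ALA", "A", 1, 2.0, 1.42, 0.0, element="C"),
        atom_line(4, "O", "ALA", "A", 1, 1.4, 2.44, 0.0),
        atom_line(5, "CB", "ALA", "A", 1, 2.0, -0.8, -1.2, element="C"),
        atom_line(6, "N", "GLY", "A", 2, 3.32, 1.45, 0.0),
        atom_line(7, "CA", "GLY", "A", 2, 4.0, 2.74, 0.0, element="C"),
        atom_line(8, "C", "GLY", "A", 2, 5.5, 2.6, 0.2, element="C"),
        atom_line(9, "O", "GLY", "A", 2, 6.1, 1.55, 0.4),
    ]
    return "\n".join(lines) + "\nEND\n"


@pytest.fixture(scope="session")
def contact_matrix():
    return load_matrix("contact_dr0101")


@pytest.fixture(scope="session")
def md_matrix():
    return load_matrix("md_dr0101")


#: peptide / crystallographic 9-mer core pairs from solved DRB1*0101
#: complexes; the packaged contact matrix was derived from these complexes,
#: so scanning each peptide with it must recover the crystal core.
DR0101_CRYSTAL_CORES = [
    ("AGFKGEQGPKGEPG", "FKGEQGPKG"),
    ("GELIGILNAAKVPAD", "IGILNAAKV"),
    ("PEVIPMFSALSEGATP", "VIPMFSALS"),
    ("GSDWRFLRGYHQYA", "WRFLRGYHQ"),
    ("AAYSDQATPLLLSPR", "YSDQATPLL"),
    ("PKYVKQNTLKLAT", "YVKQNTLKL"),
]
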