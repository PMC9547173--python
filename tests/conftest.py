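"""Shared fixtures: hand-written toy PDB blocks and builders."""

from __future__ import annotations

import numpy as np
import pytest


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    altloc: str = "",
    element: str | None = None,
    hetatm: bool = False,
) -> str:
    """Format one fixed-width ATOM/HETATM record."""
    record = "HETATM" if hetatm else "ATOM  "
    el = element if element is not None else name[0]
    aname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record}{serial:5d} {aname:<4s}{altloc or ' ':1s}{resname:>3s} "
        f"{chain:1s}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {el:>2s}  "
    )


# standard side-chain heavy-atom names used by the toy residues
SIDECHAINS = {
    "ALA": ["CB"],
    "GLY": [],
    "LEU": ["CB", "CG", "CD1", "CD2"],
    "LYS": ["CB", "CG", "CD", "CE", "NZ"],
    "PHE": ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
}


def make_residue_lines(
    resname: str,
    chain: str,
    resnum: int,
    origin: tuple[float, float, float],
    serial_start: int = 1,
) -> list[str]:
    """Backbone + side-chain records for one residue, spread around origin."""
    ox, oy, oz = origin
    names = ["N", "CA", "C", "O"] + SIDECHAINS[resname]
    lines = []
    for i, name in enumerate(names):
        el = "N" if name.startswith("N") else "O" if name.startswith("O") else "C"
        lines.append(
            pdb_atom_line(
                serial_start + i, name, resname, chain, resnum,
                ox + 1.3 * i, oy + 0.7 * (i % 3), oz + 0.4 * (i % 2), element=el,
            )
        )
    return lines


@pytest.fixture
def ala_pdb() -> str:
    """A single 5-atom alanine residue."""
    return "\n".join(make_residue_lines("ALA", "A", 1, (0, 0, 0))) + "\n"


@pytest.fixture
def ala_with_water_pdb(ala_pdb) -> str:
    hoh = pdb_atom_line(6, "O", "HOH", "A", 101, 12.0, 0.0, 0.0, element="O", hetatm=True)
    return ala_pdb + hoh + "\n"


@pytest.fixture
def altloc_pdb() -> str:
    """ALA whose CB has altlocs A (occ 0.6, x=4) and B (occ 0.4, x=5)."""
    lines = make_residue_lines("ALA", "A", 1, (0, 0, 0))[:4]
    lines.append(pdb_atom_line(5, "CB", "ALA", "A", 1, 4.0, 0.0, 0.0, occ=0.6, altloc="A"))
    lines.append(pdb_atom_line(6, "CB", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.4, altloc="B"))
    return "\n".join(lines) + "\n"


@pytest.fixture
def two_chain_pdb() -> str:
    lines = make_residue_lines("ALA", "A", 1, (0, 0, 0))
    lines += make_residue_lines("GLY", "B", 1, (20, 0, 0), serial_start=10)
    return "\n".join(lines) + "\n"


@pytest.fixture
def messy_pdb() -> str:
    """Chain A with ALA, 3 waters, a zinc ion and one explicit hydrogen."""
    lines = make_residue_lines("ALA", "A", 1, (0, 0, 0))
    lines.append(pdb_atom_line(6, "HB1", "ALA", "A", 1, 2.0, 1.0, 1.0, element="H"))
    for i, num in enumerate((101, 102, 103)):
        lines.append(
            pdb_atom_line(7 + i, "O", "HOH", "A", num, 15.0 + i, 0, 0, element="O", hetatm=True)
        )
    lines.append(pdb_atom_line(10, "ZN", "ZN", "A", 201, 20.0, 5.0, 0, element="ZN", hetatm=True))
    return "\n".join(lines) + "\n"


@pytest.fixture
def lkf_pdb() -> str:
    """Toy Leu-Lys-Phe tripeptide with standard heavy-atom names."""
    lines = make_residue_lines("LEU", "A", 1, (0, 0, 0))
    lines += make_residue_lines("LYS", "A", 2, (8, 0, 0), serial_start=20)
    lines += make_residue_lines("PHE", "A", 3, (16, 0, 0), serial_start=40)
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
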