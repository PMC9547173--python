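"""Typed protein-structure model with PDB I/O, cleaning and atom selection.

The model mirrors the preparation protocol used throughout this package for
hydrophobic-patch analysis of HECT-domain structures: keep a single chain,
drop waters and other heteroatoms, drop hydrogens (heavy-atom convention),
assign van der Waals radii, and select hydrophobic side-chain atoms.

Parsing is delegated to :mod:`gemmi`; this module owns the cleaning policy,
altloc resolution, provenance bookkeeping and the hydrophobicity rules.
"""

from __future__ import annotations

import logging
import math
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "AtomSelection",
    "parse_structure",
    "write_pdb",
    "clean_structure",
    "assign_radii",
    "remove_residue_range",
    "select_hydrophobic_sidechains",
    "fetch_pdb",
    "HYDROPHOBIC_RESIDUES",
    "BACKBONE_ATOMS",
    "RADII_SETS",
    "THREE_TO_ONE",
]

#: Residues counted as hydrophobic (one-letter codes A,G,V,I,L,F,M,Y,W).
#: MSE (selenomethionine) is treated as methionine.
HYDROPHOBIC_RESIDUES = frozenset(
    {"ALA", "GLY", "VAL", "ILE", "LEU", "PHE", "MET", "TYR", "TRP", "MSE"}
)

#: Backbone heavy-atom names excluded from side-chain selections.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

# Heavy-atom vdW radii (Å). "default-heavy" follows the Bondi-style values in
# common SASA use; "pymol-like" is a united-atom style set with an enlarged
# carbon radius absorbing implicit hydrogens, shipped as data/radii_pymol_like.tsv.
RADII_SETS: dict[str, dict[str, float]] = {
    "default-heavy": {
        "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
        "H": 1.20, "SE": 1.90, "default": 1.70,
    },
    "pymol-like": {
        "C": 1.90, "N": 1.65, "O": 1.50, "S": 1.85, "P": 1.90,
        "H": 1.20, "SE": 1.95, "default": 1.90,
    },
}

ALTLOC_POLICIES = ("highest_occupancy", "first")


@dataclass
class Atom:
    """A single atom with coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    vdw_radius: float | None = None
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.name}: vdw_radius must be positive")


@dataclass
class Residue:
    """A residue identified by author number and insertion code."""

    name3: str
    number: int
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.name3 = self.name3.upper()

    @property
    def key(self) -> tuple[int, str]:
        return (self.number, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def is_hydrophobic(self) -> bool:
        return self.name3 in HYDROPHOBIC_RESIDUES

    def sidechain_heavy_atoms(self) -> list[Atom]:
        return [
            a for a in self.atoms
            if a.name not in BACKBONE_ATOMS and a.element.upper() not in ("H", "D")
        ]


@dataclass
class Structure:
    """Chains of residues; `provenance` records parse/cleaning events."""

    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)

    def iter_atoms(self) -> Iterator[tuple[str, Residue, Atom]]:
        for cid, residues in self.chains.items():
            for res in residues:
                for atom in res.atoms:
                    yield cid, res, atom

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def copy(self) -> "Structure":
        out = Structure(self.id, provenance=list(self.provenance))
        for cid, residues in self.chains.items():
            out.chains[cid] = [
                Residue(
                    r.name3, r.number, r.icode,
                    [Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                          a.altloc, a.vdw_radius, a.is_hetero) for a in r.atoms],
                )
                for r in residues
            ]
        return out

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue | None:
        for res in self.chains.get(chain_id, []):
            if res.number == number and res.icode == icode:
                return res
        return None


@dataclass
class AtomSelection:
    """Set of (chain, resnum, icode, atom_name) keys with provenance."""

    members: set[tuple[str, int, str, str]]
    description: str = ""

    def __len__(self) -> int:
        return len(self.members)


class StructureParseError(ValueError):
    pass


def _validate_pdb_records(pdb_text: str) -> int:
    """Pre-validate fixed-width coordinate records; return their count."""
    n = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            if len(line) < 54:
                raise StructureParseError(
                    f"line {lineno}: truncated coordinate record ({len(line)} cols)"
                )
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError as exc:
                raise StructureParseError(
                    f"line {lineno}: unparseable coordinate field"
                ) from exc
            n += 1
    return n


def parse_structure(
    pdb_text: str,
    altloc_policy: str = "highest_occupancy",
    structure_id: str = "structure",
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is kept. Alternate locations are resolved per
    ``altloc_policy``: ``highest_occupancy`` keeps, for each atom name, the
    altloc with the highest occupancy (ties broken by altloc letter order);
    ``first`` keeps the first record seen. Dropped records are counted in
    ``provenance``.
    """
    if altloc_policy not in ALTLOC_POLICIES:
        raise ValueError(f"altloc_policy must be one of {ALTLOC_POLICIES}")
    n_records = _validate_pdb_records(pdb_text)
    if n_records == 0:
        raise StructureParseError("no ATOM or HETATM records found")

    st = gemmi.read_pdb_string(pdb_text)
    out = Structure(structure_id or st.name or "structure")
    if len(st) > 1:
        out.provenance.append(f"discarded {len(st) - 1} extra MODEL(s)")
    model = st[0]

    n_altloc_dropped = 0
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            is_het = res.het_flag == "H"
            # group atoms by name for altloc resolution
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms: list[Atom] = []
            for name, group in by_name.items():
                if len(group) > 1:
                    if altloc_policy == "highest_occupancy":
                        group = sorted(group, key=lambda a: (-a.occ, a.altloc or "~"))
                    n_altloc_dropped += len(group) - 1
                a = group[0]
                atoms.append(
                    Atom(
                        name=name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        occupancy=a.occ,
                        altloc=(a.altloc or ""),
                        is_hetero=is_het,
                    )
                )
            residues.append(
                Residue(res.name, res.seqid.num, (res.seqid.icode or "").strip(), atoms)
            )
        if residues:
            out.chains.setdefault(chain.name, []).extend(residues)
    if n_altloc_dropped:
        out.provenance.append(
            f"dropped {n_altloc_dropped} alternate-location atom(s) "
            f"(policy={altloc_policy})"
        )
    if out.n_atoms == 0:
        raise StructureParseError("structure contains zero atoms after parsing")
    return out


def write_pdb(s: Structure) -> str:
    """Serialize to PDB format (fixed-width ATOM/HETATM records, TER, END)."""
    lines: list[str] = []
    serial = 0
    for cid, residues in s.chains.items():
        for res in residues:
            for a in res.atoms:
                serial += 1
                record = "HETATM" if a.is_hetero else "ATOM  "
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"{record}{serial:5d} {name:<4s}{'':1s}{res.name3:>3s} "
                    f"{cid[:1]:1s}{res.number:4d}{res.icode or ' ':1s}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          "
                    f"{a.element.upper():>2s}  "
                )
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def clean_structure(s: Structure, chain_id: str) -> Structure:
    """Keep one chain, drop waters/heteroatoms and hydrogens.

    This is the preparation step used before area analysis: only the
    requested chain is retained, residues made of HETATM records (waters,
    ions, ligands) are removed — except selenomethionine (MSE), which is a
    modified methionine and is kept — and hydrogen/deuterium atoms are
    stripped (heavy-atom convention).
    """
    if chain_id not in s.chains:
        raise KeyError(
            f"chain {chain_id!r} not found; available: {sorted(s.chains)}"
        )
    out = Structure(s.id, provenance=list(s.provenance))
    n_het_res = 0
    n_h = 0
    residues: list[Residue] = []
    for res in s.chains[chain_id]:
        if any(a.is_hetero for a in res.atoms) and res.name3 != "MSE":
            n_het_res += 1
            continue
        atoms = []
        for a in res.atoms:
            if a.element.upper() in ("H", "D"):
                n_h += 1
                continue
            atoms.append(Atom(a.name, a.element, a.coords.copy(), a.occupancy,
                              a.altloc, a.vdw_radius, False))
        if atoms:
            residues.append(Residue(res.name3, res.number, res.icode, atoms))
    out.chains[chain_id] = residues
    note = (
        f"clean: kept chain {chain_id}, removed {n_het_res} hetero residue(s), "
        f"{n_h} hydrogen(s)"
    )
    if n_het_res or n_h:
        out.provenance.append(note)
    if out.n_atoms == 0:
        raise ValueError(f"chain {chain_id!r} has no atoms after cleaning")
    return out


def assign_radii(s: Structure, radii_set: str = "default-heavy") -> Structure:
    """Return a copy with van der Waals radii assigned from the named set.

    Unknown elements receive the set's default radius and are logged.
    """
    if radii_set not in RADII_SETS:
        raise ValueError(f"unknown radii set {radii_set!r}; choose from {sorted(RADII_SETS)}")
    table = RADII_SETS[radii_set]
    out = s.copy()
    unknown: set[str] = set()
    for _, _, atom in out.iter_atoms():
        el = atom.element.upper()
        if el in table:
            atom.vdw_radius = table[el]
        else:
            atom.vdw_radius = table["default"]
            unknown.add(el)
    if unknown:
        logger.warning(
            "assign_radii(%s): default radius used for unknown element(s) %s",
            radii_set, sorted(unknown),
        )
        out.provenance.append(
            f"radii {radii_set}: default used for {sorted(unknown)}"
        )
    return out


def remove_residue_range(
    s: Structure, chain_id: str, start: int, end: int
) -> tuple[Structure, int]:
    """Delete residues with start ≤ author number ≤ end from one chain.

    Returns (new structure, number of residues removed). A range matching
    zero residues produces a warning, not an error — deletion ranges often
    fall in unmodelled loops.
    """
    if start > end:
        raise ValueError(f"start ({start}) must be ≤ end ({end})")
    if chain_id not in s.chains:
        raise KeyError(f"chain {chain_id!r} not found; available: {sorted(s.chains)}")
    out = s.copy()
    kept = [r for r in out.chains[chain_id] if not (start <= r.number <= end)]
    n_removed = len(out.chains[chain_id]) - len(kept)
    out.chains[chain_id] = kept
    if n_removed == 0:
        logger.warning(
            "remove_residue_range: %s:%d-%d matched no residues", chain_id, start, end
        )
    out.provenance.append(f"removed {n_removed} residue(s) in {chain_id}:{start}-{end}")
    return out, n_removed


def select_hydrophobic_sidechains(s: Structure) -> AtomSelection:
    """Select side-chain heavy atoms of hydrophobic residues.

    Hydrophobic residues are A, G, V, I, L, F, M, Y, W (MSE counts as M).
    Side-chain atoms are all heavy atoms whose name is not a backbone name
    (N, CA, C, O, OXT); glycine therefore contributes no atoms.
    """
    members: set[tuple[str, int, str, str]] = set()
    for cid, residues in s.chains.items():
        for res in residues:
            if not res.is_hydrophobic:
                continue
            for a in res.sidechain_heavy_atoms():
                members.add((cid, res.number, res.icode, a.name))
    return AtomSelection(members, description="hydrophobic side-chain heavy atoms")


def fetch_pdb(
    pdb_id: str,
    cache_dir: str | Path | None = None,
    timeout: float = 15.0,
) -> str:
    """Return PDB-format text for an accession, from cache or RCSB.

    Looks in ``cache_dir`` (default ``~/.cache/exthect/pdb`` plus ``data/pdb``
    relative to the working directory) for ``<id>.pdb`` before attempting a
    download; downloads are cached. Raises ``OSError`` when the file is
    neither cached nor reachable.
    """
    pdb_id = pdb_id.lower()
    candidates = []
    if cache_dir is not None:
        candidates.append(Path(cache_dir))
    candidates += [Path("data/pdb"), Path.home() / ".cache" / "exthect" / "pdb"]
    for d in candidates:
        for name in (f"{pdb_id}.pdb", f"{pdb_id.upper()}.pdb"):
            p = d / name
            if p.is_file():
                return p.read_text()
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode()
    except Exception as exc:  # noqa: BLE001 - report any transport failure
        raise OSError(
            f"PDB entry {pdb_id.upper()} not in cache ({[str(c) for c in candidates]}) "
            f"and download from {url} failed: {exc}"
        ) from exc
    target = candidates[-1] if cache_dir is None else Path(cache_dir)
    try:
        target.mkdir(parents=True, exist_ok=True)
        (target / f"{pdb_id}.pdb").write_text(text)
    except OSError:
        pass
    return text
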