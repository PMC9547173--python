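"""Synthetic inputs with known ground truth for every pipeline stage.

Generators:

* ideal α-helices built from internal coordinates (φ=−57°, ψ=−47°), with a
  CB pseudo side chain placed radially outward — the geometry realizes the
  canonical ~1.5 Å rise, ~100° twist and ~2.3 Å CA radius;
* helix–slab complexes in which an amphipathic helix packs face-on against
  a hydrophobic atom slab, with the buried hydrophobic side-chain area
  recorded by an independent Monte-Carlo SASA estimator (random sampling,
  brute-force occlusion — no code shared with the lattice engine);
* ortholog-style alignments with a conserved amphipathic helix planted a
  known number of residues upstream of a "domain" start;
* single- and two-sphere systems with closed-form accessible areas.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .msa import Alignment
from .structure import Atom, Residue, Structure

__all__ = [
    "SyntheticHelixSpec",
    "HelixLobeSpec",
    "SyntheticMsaSpec",
    "build_ideal_helix",
    "build_helix_lobe_complex",
    "simulate_msa",
    "sphere_fixtures",
    "monte_carlo_sasa",
    "two_sphere_exact_area",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Helical-wheel offsets (period ≈ 3.6 residues) of the hydrophobic face
#: within an 18-residue window: one face of five helical turns.
WHEEL_OFFSETS = (0, 3, 7, 10, 14, 17)

_FACE_HYDROPHOBIC = "LFILWV"   # cycled over wheel positions
_FACE_POLAR = "KEQNRD"         # charged/polar face boosts the moment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_POLAR_POOL = "STNQDEKRHP"


# ---------------------------------------------------------------------------
# geometry: internal-coordinate chain building
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D with bond |CD|, angle B-C-D and torsion A-B-C-D."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        -bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _design_amphipathic(length: int) -> str:
    seq = []
    for i in range(length):
        w = i % 18
        if w in WHEEL_OFFSETS:
            seq.append(_FACE_HYDROPHOBIC[WHEEL_OFFSETS.index(w)])
        else:
            seq.append(_FACE_POLAR[w % len(_FACE_POLAR)])
    return "".join(seq)


@dataclass(frozen=True)
class SyntheticHelixSpec:
    """An ideal α-helix to generate.

    ``sequence=None`` auto-designs an amphipathic sequence (hydrophobic
    residues on one helical face). rise / twist / ca_radius describe the
    geometry realized by the ideal dihedrals and are validated, not dialled:
    the backbone is built from φ=−57°, ψ=−47°.
    """

    length: int = 20
    sequence: str | None = None
    rise: float = 1.5
    twist: float = 100.0
    ca_radius: float = 2.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 4:
            raise ValueError("helix length must be ≥ 4")
        if self.twist <= 0:
            raise ValueError("twist must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError("sequence length must equal spec length")

    def resolved_sequence(self) -> str:
        return (self.sequence or _design_amphipathic(self.length)).upper()


def _helix_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(axis unit vector, centroid) from CA coordinates via PCA."""
    centroid = ca.mean(axis=0)
    u, s, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    # orient N→C
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    return axis, centroid


def build_ideal_helix(spec: SyntheticHelixSpec) -> tuple[Structure, dict]:
    """Build an ideal α-helix Structure (N/CA/C/O + radial CB) and its truth.

    Truth records the helix extent (residue numbers), the designed sequence
    and the realized rise/twist/radius.
    """
    seq = spec.resolved_sequence()
    L = spec.length
    phi, psi, omega = -57.0, -47.0, 180.0
    # seed atoms of residue 0 in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([1.458, 0.0, 0.0])
    t = math.radians(180.0 - 111.2)
    c0 = ca0 + 1.525 * np.array([math.cos(t), math.sin(t), 0.0])
    backbone = [{"N": n0, "CA": ca0, "C": c0}]
    for i in range(1, L):
        prev = backbone[-1]
        n = _place_atom(prev["N"], prev["CA"], prev["C"], 1.329, 116.2, psi)
        ca = _place_atom(prev["CA"], prev["C"], n, 1.458, 121.7, omega)
        c = _place_atom(prev["C"], n, ca, 1.525, 111.2, phi)
        backbone.append({"N": n, "CA": ca, "C": c})
    for i, res in enumerate(backbone):
        # carbonyl O anti to the next N (trans peptide)
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], 1.231, 120.8, psi + 180.0)

    ca_coords = np.array([r["CA"] for r in backbone])
    axis, centroid = _helix_axis(ca_coords)

    residues = []
    for i, (aa, bb) in enumerate(zip(seq, backbone)):
        atoms = [
            Atom("N", "N", bb["N"]),
            Atom("CA", "C", bb["CA"]),
            Atom("C", "C", bb["C"]),
            Atom("O", "O", bb["O"]),
        ]
        if aa != "G":
            radial = bb["CA"] - (centroid + np.dot(bb["CA"] - centroid, axis) * axis)
            radial /= np.linalg.norm(radial)
            atoms.append(Atom("CB", "C", bb["CA"] + 1.53 * radial))
        residues.append(Residue(_ONE_TO_THREE.get(aa, "ALA"), i + 1, "", atoms))
    s = Structure(f"ideal_helix_L{L}", {"A": residues})

    proj = (ca_coords - centroid) @ axis
    rise = float((proj[-1] - proj[0]) / (L - 1))
    radial_vecs = ca_coords - centroid - np.outer(proj, axis)
    radius = float(np.linalg.norm(radial_vecs, axis=1).mean())
    truth = {
        "chain": "A",
        "start": 1,
        "end": L,
        "sequence": seq,
        "rise": rise,
        "ca_radius": radius,
        "axis": axis,
        "centroid": centroid,
        "hydrophobic_positions": [i + 1 for i, aa in enumerate(seq) if aa in "AGVILFMYW"],
    }
    return s, truth


# ---------------------------------------------------------------------------
# Monte-Carlo SASA oracle (independent of the lattice engine)
# ---------------------------------------------------------------------------

def monte_carlo_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_per_atom: int = 20000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-atom SASA by random sphere sampling with brute-force occlusion.

    The standard error of each exposed fraction is ≈ sqrt(f(1−f)/n); the
    default 20 000 samples gives sub-percent accuracy.
    """
    rng = rng or np.random.default_rng(0)
    coords = np.asarray(coords, dtype=float)
    acc = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    areas = np.empty(n)
    d = cdist(coords, coords)
    for i in range(n):
        pts = rng.normal(size=(n_per_atom, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = coords[i] + acc[i] * pts
        neigh = np.flatnonzero((d[i] < acc[i] + acc) & (np.arange(n) != i))
        alive = np.ones(n_per_atom, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            alive &= d2 >= acc[j] * acc[j]
        areas[i] = alive.mean() * 4.0 * math.pi * acc[i] ** 2
    return areas


# ---------------------------------------------------------------------------
# helix–slab complex
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixLobeSpec:
    """An amphipathic helix packed face-on against a hydrophobic slab.

    contact_fraction scales how much of the helix length the slab spans;
    gap is the vertical clearance (Å) between the hydrophobic-face CB atoms
    and the top slab layer.
    """

    helix: SyntheticHelixSpec = field(default_factory=lambda: SyntheticHelixSpec(length=24))
    lobe_atoms: int = 200
    contact_fraction: float = 1.0
    gap: float = 3.6
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_fraction <= 1.0:
            raise ValueError("contact_fraction must be in [0, 1]")


def _canonical_helix_frame(s: Structure, truth: dict) -> Structure:
    """Rotate/translate so the helix axis is +x and the hydrophobic CB face
    points toward −z."""
    axis = truth["axis"]
    centroid = truth["centroid"]
    coords = np.array([a.coords for _, _, a in s.iter_atoms()])
    # build frame: x = axis
    tmp = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    y = np.cross(axis, tmp)
    y /= np.linalg.norm(y)
    z = np.cross(axis, y)
    R = np.vstack([axis, y, z])  # world → frame
    for _, res, atom in s.iter_atoms():
        atom.coords = R @ (atom.coords - centroid)
    # rotate about x so mean hydrophobic CB radial direction → −z
    face = []
    for _, res, atom in s.iter_atoms():
        if atom.name == "CB" and res.is_hydrophobic:
            v = atom.coords.copy()
            v[0] = 0.0
            face.append(v / np.linalg.norm(v))
    mean_face = np.mean(face, axis=0)
    ang = math.atan2(mean_face[1], mean_face[2])  # current angle from +z in zy
    # rotate by (pi - ang) about x to bring face to −z
    theta = math.pi - ang
    c, sn = math.cos(theta), math.sin(theta)
    rot = np.array([[1, 0, 0], [0, c, -sn], [0, sn, c]])
    for _, _, atom in s.iter_atoms():
        atom.coords = rot @ atom.coords
    return s


def build_helix_lobe_complex(
    spec: HelixLobeSpec,
) -> tuple[Structure, tuple[str, int, int], dict]:
    """Build the helix–slab complex; truth holds the Monte-Carlo buried area.

    The structure has the helix as residues 1..L and the slab as
    single-atom LEU residues numbered from 1001 on the same chain. The
    truth record contains ``buried_area``: the summed positive gain in
    hydrophobic side-chain SASA of the slab residues when the helix is
    removed, estimated by :func:`monte_carlo_sasa` with the default
    heavy-atom radii and a 1.4 Å probe.
    """
    helix, htruth = build_ideal_helix(spec.helix)
    helix = _canonical_helix_frame(helix, htruth)
    L = spec.helix.length

    helix_res = helix.chains["A"]
    ca_x = np.array([r.atom("CA").coords[0] for r in helix_res])
    face_cb_z = [
        r.atom("CB").coords[2]
        for r in helix_res
        if r.is_hydrophobic and r.atom("CB") is not None and r.atom("CB").coords[2] < 0
    ]
    z_face = min(face_cb_z)
    z_top = z_face - spec.gap

    x_lo = ca_x.min() - 2.0
    x_hi = x_lo + max(3.0, spec.contact_fraction * (ca_x.max() - ca_x.min() + 4.0))
    y_half = 6.0
    per_layer = max(4, spec.lobe_atoms // 2)
    x_len = x_hi - x_lo
    n_x = max(2, int(round(math.sqrt(per_layer * x_len / (2 * y_half)))))
    n_y = max(2, int(math.ceil(per_layer / n_x)))
    xs = np.linspace(x_lo, x_hi, n_x)
    ys = np.linspace(-y_half, y_half, n_y)

    residues = list(helix_res)
    num = 1001
    for layer, z in enumerate((z_top, z_top - 3.0)):
        for x in xs:
            for y in ys:
                residues.append(
                    Residue("LEU", num, "", [Atom("CB", "C", np.array([x, y, z]))])
                )
                num += 1
    s = Structure(f"helix_lobe_L{L}", {"A": residues})
    ext = ("A", 1, L)

    # --- Monte-Carlo truth: hydrophobic side-chain SASA gain of the slab ---
    from .structure import RADII_SETS  # local import to keep module load light

    table = RADII_SETS["default-heavy"]
    rng = np.random.default_rng(spec.seed)

    def hydro_sidechain(arr_res):
        keys, coords, radii = [], [], []
        for r in arr_res:
            for a in r.atoms:
                coords.append(a.coords)
                radii.append(table.get(a.element.upper(), table["default"]))
                is_sc = (
                    r.is_hydrophobic
                    and a.name not in ("N", "CA", "C", "O", "OXT")
                )
                keys.append((r.number, is_sc))
        return keys, np.array(coords), np.array(radii)

    slab_res = [r for r in residues if r.number >= 1001]
    keys_full, c_full, r_full = hydro_sidechain(residues)
    keys_slab, c_slab, r_slab = hydro_sidechain(slab_res)
    a_full = monte_carlo_sasa(c_full, r_full, rng=rng)
    a_slab = monte_carlo_sasa(c_slab, r_slab, rng=rng)

    def per_res_hydro(keys, areas, only_ge=1001):
        out: dict[int, float] = {}
        for (numr, is_sc), area in zip(keys, areas):
            if is_sc and numr >= only_ge:
                out[numr] = out.get(numr, 0.0) + area
        return out

    full_by = per_res_hydro(keys_full, a_full)
    slab_by = per_res_hydro(keys_slab, a_slab)
    deltas = {n: slab_by[n] - full_by.get(n, 0.0) for n in slab_by}
    buried = float(sum(dv for dv in deltas.values() if dv > 1.0))

    # planted interface contacts at 4.5 Å, by brute-force all-pairs distances
    helix_sc = [
        (r.number, a.coords)
        for r in helix_res if r.is_hydrophobic
        for a in r.sidechain_heavy_atoms()
    ]
    slab_sc = [(r.number, r.atoms[0].coords) for r in slab_res]
    contact_helix: set[int] = set()
    contact_slab: set[int] = set()
    if helix_sc and slab_sc:
        dmat = cdist(np.array([c for _, c in helix_sc]), np.array([c for _, c in slab_sc]))
        hit_h, hit_s = np.nonzero(dmat <= 4.5)
        contact_helix = {helix_sc[i][0] for i in hit_h}
        contact_slab = {slab_sc[j][0] for j in hit_s}
    truth = {
        "buried_area": buried,
        "per_residue_delta": deltas,
        "n_slab_atoms": len(slab_res),
        "helix": htruth,
        "mc_points_per_atom": 20000,
        "contact_helix_residues": sorted(contact_helix),
        "contact_slab_residues": sorted(contact_slab),
        "contact_cutoff": 4.5,
    }
    return s, ext, truth


# ---------------------------------------------------------------------------
# ortholog-style MSA with a planted amphipathic helix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticMsaSpec:
    """Ortholog-style alignment with a conserved amphipathic helix planted
    ``planted_helix_offset`` residues upstream of the domain (core) start.

    conservation_level is the per-position probability that a row keeps the
    consensus residue inside the planted helix; linker positions outside the
    helix are weakly conserved (0.25) and the core strongly (0.9). Indels
    (gaps, plus rare insertion columns) occur at ``indel_rate`` in the
    linker only. ``first_residue_number`` sets the numbering of the first
    row (the "query"); other rows are numbered from 1.
    """

    n_seqs: int = 30
    core_length: int = 120
    ext_length: int = 80
    planted_helix_offset: int = 47
    conservation_level: float = 0.8
    indel_rate: float = 0.02
    seed: int = 0
    first_residue_number: int = 1
    helix_window: int = 18

    def __post_init__(self) -> None:
        if not 0 < self.conservation_level <= 1:
            raise ValueError("conservation_level must be in (0, 1]")
        if self.planted_helix_offset >= self.ext_length:
            raise ValueError("planted_helix_offset must be < ext_length")
        if self.n_seqs < 2:
            raise ValueError("n_seqs must be ≥ 2")


def simulate_msa(spec: SyntheticMsaSpec) -> tuple[Alignment, pd.DataFrame, dict]:
    """Simulate the alignment; returns (alignment, annotations, truth).

    Annotations carry per-row ``first_residue_number`` and ``uniprot_start``
    (the residue number of the core start in that row's own numbering).
    Truth records each row's planted helix start residue number.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = spec.ext_length + spec.core_length
    helix_lo = spec.ext_length - spec.planted_helix_offset
    helix_hi = helix_lo + spec.helix_window  # exclusive
    if helix_lo < 0:
        raise ValueError("planted helix does not fit in the extension region")

    consensus = [AMINO_ACIDS[i] for i in rng.integers(0, 20, size=n_pos)]
    for i in range(spec.ext_length):
        if not helix_lo <= i < helix_hi:
            consensus[i] = _POLAR_POOL[rng.integers(0, len(_POLAR_POOL))]
    helix_seq = _design_amphipathic(spec.helix_window)
    for k, aa in enumerate(helix_seq):
        consensus[helix_lo + k] = aa

    keep_p = np.empty(n_pos)
    keep_p[: spec.ext_length] = 0.25
    keep_p[helix_lo:helix_hi] = spec.conservation_level
    keep_p[spec.ext_length:] = 0.9

    rows_chars: list[list[str]] = []
    for r in range(spec.n_seqs):
        chars = []
        for i in range(n_pos):
            if rng.random() < keep_p[i]:
                chars.append(consensus[i])
            else:
                chars.append(AMINO_ACIDS[rng.integers(0, 20)])
        # deletions in the linker (not the planted helix, not the core);
        # row 0 is the intact query
        if r > 0 and spec.indel_rate > 0:
            for i in range(spec.ext_length):
                if not helix_lo <= i < helix_hi and rng.random() < spec.indel_rate:
                    chars[i] = "-"
        rows_chars.append(chars)

    # rare insertion columns in the linker: one row carries a residue
    columns: list[list[str]] = []
    for i in range(n_pos):
        if (
            i < spec.ext_length
            and not helix_lo <= i < helix_hi
            and spec.indel_rate > 0
            and rng.random() < spec.indel_rate / 2
        ):
            owner = int(rng.integers(1, spec.n_seqs))
            col = ["-"] * spec.n_seqs
            col[owner] = AMINO_ACIDS[rng.integers(0, 20)]
            columns.append(col)
        columns.append([rows_chars[r][i] for r in range(spec.n_seqs)])

    ids = [f"ortho_{r:02d}" for r in range(spec.n_seqs)]
    aligned = ["".join(col[r] for col in columns) for r in range(spec.n_seqs)]
    alignment = Alignment(list(zip(ids, aligned)))

    ann_rows = []
    truth_starts: dict[str, int] = {}
    truth_cores: dict[str, int] = {}
    for r in range(spec.n_seqs):
        first = spec.first_residue_number if r == 0 else 1
        n_before_helix = sum(1 for i in range(helix_lo) if rows_chars[r][i] != "-")
        n_before_core = sum(1 for i in range(spec.ext_length) if rows_chars[r][i] != "-")
        truth_starts[ids[r]] = first + n_before_helix
        truth_cores[ids[r]] = first + n_before_core
        ann_rows.append(
            {
                "seq_id": ids[r],
                "first_residue_number": first,
                "uniprot_start": first + n_before_core,
                "uniprot_end": first + sum(1 for ch in rows_chars[r] if ch != "-") - 1,
            }
        )
    annotations = pd.DataFrame(ann_rows)
    truth = {
        "planted_start": truth_starts,
        "core_start": truth_cores,
        "helix_consensus": helix_seq,
        "helix_cols": None,  # alignment columns shift with insertions; see maps
        "spec": spec,
    }
    return alignment, annotations, truth


# ---------------------------------------------------------------------------
# analytic sphere systems
# ---------------------------------------------------------------------------

def two_sphere_exact_area(
    r1: float, r2: float, d: float, probe: float = 1.4
) -> float:
    """Exact total SASA of two spheres at centre distance d (cap formula)."""
    R1, R2 = r1 + probe, r2 + probe
    full = 4.0 * math.pi * (R1 * R1 + R2 * R2)
    if d >= R1 + R2:
        return full
    if d <= abs(R1 - R2):
        big = max(R1, R2)
        return 4.0 * math.pi * big * big
    x1 = (d * d + R1 * R1 - R2 * R2) / (2.0 * d)
    h1 = R1 - x1
    x2 = d - x1
    h2 = R2 - x2
    return full - 2.0 * math.pi * (R1 * h1 + R2 * h2)


def _sphere_structure(positions: list[np.ndarray], radii: list[float], sid: str) -> Structure:
    residues = []
    for i, (pos, r) in enumerate(zip(positions, radii), start=1):
        residues.append(
            Residue("SPH", i, "", [Atom("C1", "C", pos, vdw_radius=r)])
        )
    return Structure(sid, {"A": residues})


def sphere_fixtures(probe: float = 1.4) -> list[tuple[Structure, float, dict]]:
    """Single- and two-sphere systems with closed-form total SASA.

    Returns (structure, exact total area at the given probe, meta) tuples.
    Radii cover C/O/S-like values; separations span strong overlap to none.
    """
    out: list[tuple[Structure, float, dict]] = []
    radii = (1.52, 1.70, 1.80)
    for r in radii:
        s = _sphere_structure([np.zeros(3)], [r], f"sphere_r{r}")
        area = 4.0 * math.pi * (r + probe) ** 2
        out.append((s, area, {"kind": "single", "radii": (r,), "d": None}))
    for r in radii:
        for d in (2.5, 3.0, 4.0, 10.0):
            s = _sphere_structure(
                [np.zeros(3), np.array([d, 0.0, 0.0])], [r, r], f"two_r{r}_d{d}"
            )
            area = two_sphere_exact_area(r, r, d, probe)
            out.append((s, area, {"kind": "pair", "radii": (r, r), "d": d}))
    return out


def boundary_recovery_experiment(
    spec: SyntheticMsaSpec,
    tol: int = 3,
) -> dict:
    """Run one planted-helix recovery replicate.

    Returns per-row recovery (fraction of rows whose proposed start lands
    within ``tol`` of the planted start), the replicate-level consensus
    error (median over extended rows), and the proposals themselves.
    """
    from .msa import column_conservation, map_columns, propose_extension

    aln, ann, truth = simulate_msa(spec)
    profile = column_conservation(aln)
    maps = {
        r.seq_id: map_columns(aln, r.seq_id, r.first_residue_number)
        for r in ann.itertuples()
    }
    ustarts = {r.seq_id: r.uniprot_start for r in ann.itertuples()}
    proposals = propose_extension(aln, profile, maps, ustarts)
    errs = [
        p.proposed_start - truth["planted_start"][p.seq_id]
        for p in proposals
        if p.status == "extended"
    ]
    row_recovery = float(
        np.mean(
            [
                p.status == "extended"
                and abs(p.proposed_start - truth["planted_start"][p.seq_id]) <= tol
                for p in proposals
            ]
        )
    )
    consensus_err = float(np.median(errs)) if errs else math.inf
    return {
        "row_recovery": row_recovery,
        "consensus_error": consensus_err,
        "recovered": abs(consensus_err) <= tol,
        "n_extended": len(errs),
        "proposals": proposals,
        "truth": truth,
    }
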