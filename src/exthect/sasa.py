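"""Solvent-accessible surface area by deterministic sphere sampling.

Shrake–Rupley style: each atom's accessible sphere (radius = vdW + probe) is
covered with a golden-spiral point lattice; a point is exposed when it lies
outside every neighbouring atom's accessible sphere. The per-atom area is the
exposed fraction times the sphere area.

The lattice is deterministic. To make areas invariant under rigid-body
motion of the whole structure (to floating-point precision, not just lattice
noise), the lattice is expressed in a canonical frame derived from the
structure's principal axes, so the sampling co-rotates with the molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomSelection, Structure

__all__ = [
    "SasaParams",
    "SasaResult",
    "generate_sphere_points",
    "compute_sasa",
    "sasa_of_selection",
    "sasa_table",
]


@dataclass(frozen=True)
class SasaParams:
    """Parameters of a SASA computation.

    probe_radius : solvent probe radius in Å (water ≈ 1.4).
    n_points : lattice points per atom sphere (≥ 12).
    radii_set : name of the vdW radii set that was assigned.
    include_hetero : include HETATM-flagged atoms.
    """

    probe_radius: float = 1.4
    n_points: int = 960
    radii_set: str = "default-heavy"
    include_hetero: bool = False

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be ≥ 0")
        if self.n_points < 12:
            raise ValueError("n_points must be ≥ 12")


AtomKey = tuple[str, int, str, str]
ResidueKey = tuple[str, int, str]


@dataclass
class SasaResult:
    """Per-atom and per-residue accessible areas (Å²)."""

    per_atom: dict[AtomKey, float]
    per_residue: dict[ResidueKey, float]
    total: float
    params_echo: SasaParams
    structure_id: str = ""
    resnames: dict[ResidueKey, str] = field(default_factory=dict)


def generate_sphere_points(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (golden-spiral lattice)."""
    if n < 12:
        raise ValueError("n must be ≥ 12")
    k = np.arange(n, dtype=float)
    # offset 0.5 avoids placing points exactly at the poles
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * (math.pi * (3.0 - math.sqrt(5.0)))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


_FRAME_SUPPORT = 8.0  # Å; lattice frames depend only on atoms this close


def _smooth_local_frames(coords: np.ndarray) -> np.ndarray:
    """Per-atom lattice orientations, covariant and locally supported.

    Each atom's frame is the eigenbasis of a smoothly weighted covariance
    of its neighbour displacements (weights (1−d/R)², support R = 8 Å),
    ordered by descending eigenvalue with signs fixed by the weighted third
    moment and handedness enforced. The construction rotates with the
    structure, varies smoothly with coordinates (no nearest-neighbour
    tie-breaking), and is unchanged by adding or deleting atoms farther
    than R — so deleting a distant segment cannot perturb the sampling of
    untouched atoms. Where the frame is ambiguous (isolated atoms, exactly
    symmetric environments, rank-deficient neighbourhoods) the ambiguity is
    harmless: the corresponding occluder symmetry makes the sampled areas
    independent of the arbitrary choice.
    """
    n = len(coords)
    frames = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    if n < 2:
        return frames
    tree = cKDTree(coords)
    neighbours = tree.query_ball_point(coords, _FRAME_SUPPORT)
    for i in range(n):
        idx = [j for j in neighbours[i] if j != i]
        if not idx:
            continue
        u = coords[idx] - coords[i]
        d = np.linalg.norm(u, axis=1)
        keep = d > 1e-9
        u, d = u[keep], d[keep]
        if len(u) == 0:
            continue
        w = (1.0 - d / _FRAME_SUPPORT) ** 2
        m2 = (u * w[:, None]).T @ u
        _, v = np.linalg.eigh(m2)
        v = v[:, ::-1]
        proj = u @ v
        m3 = (w[:, None] * proj**3).sum(axis=0)
        scale3 = float(np.sum(w * d**3)) + 1e-300
        # an axis sign is covariant only where the weighted third moment is
        # decisively nonzero; a (near-)zero moment marks a mirror-symmetric
        # environment, where the sign ambiguity cannot change occlusion
        # counts — but it must then not leak onto a reliable axis, so the
        # least-reliable axis is completed by cross product
        reliable = np.abs(m3) > 1e-6 * scale3
        for k in range(3):
            if reliable[k] and m3[k] < 0:
                v[:, k] = -v[:, k]
        if reliable.sum() >= 2:
            order = np.argsort(-np.abs(m3))
            a, b, c = int(order[0]), int(order[1]), int(order[2])
            sign = 1.0 if (a, b, c) in ((0, 1, 2), (1, 2, 0), (2, 0, 1)) else -1.0
            v[:, c] = sign * np.cross(v[:, a], v[:, b])
        elif np.dot(np.cross(v[:, 0], v[:, 1]), v[:, 2]) < 0:
            # resolve handedness through an unreliable (symmetry-protected) axis
            k = int(np.argmin(np.abs(m3)))
            v[:, k] = -v[:, k]
        frames[i] = v
    return frames


def compute_sasa(s: Structure, params: SasaParams | None = None) -> SasaResult:
    """Compute per-atom / per-residue solvent-accessible surface areas.

    Every included atom must have an assigned vdW radius. Neighbour search
    is cutoff-correct: atom j can occlude atom i only when their centre
    distance is below (r_i + probe) + (r_j + probe).
    """
    p = params or SasaParams()
    keys: list[AtomKey] = []
    reskeys: list[ResidueKey] = []
    resnames: dict[ResidueKey, str] = {}
    coords_list: list[np.ndarray] = []
    radii_list: list[float] = []
    for cid, res, atom in s.iter_atoms():
        if atom.is_hetero and not p.include_hetero:
            continue
        if atom.vdw_radius is None:
            raise ValueError(
                f"atom {cid}/{res.name3}{res.number}{res.icode}/{atom.name} "
                "has no vdW radius; call assign_radii first"
            )
        keys.append((cid, res.number, res.icode, atom.name))
        rk = (cid, res.number, res.icode)
        reskeys.append(rk)
        resnames[rk] = res.name3
        coords_list.append(atom.coords)
        radii_list.append(atom.vdw_radius)
    if not keys:
        return SasaResult({}, {}, 0.0, p, s.id)

    coords = np.asarray(coords_list)
    radii = np.asarray(radii_list) + p.probe_radius  # accessible-sphere radii
    n_atoms = len(coords)
    base_points = generate_sphere_points(p.n_points)
    frames = _smooth_local_frames(coords)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(n_atoms)
    for i in range(n_atoms):
        ri = radii[i]
        pts = coords[i] + ri * (base_points @ frames[i].T)
        neigh = tree.query_ball_point(coords[i], ri + max_r)
        neigh = [j for j in neigh if j != i]
        if neigh:
            nc = coords[neigh]
            nr = radii[np.asarray(neigh)]
            d = np.linalg.norm(nc - coords[i], axis=1)
            mask = d < ri + nr
            nc, nr = nc[mask], nr[mask]
        else:
            nc = np.empty((0, 3))
            nr = np.empty(0)
        if len(nc) == 0:
            exposed_frac = 1.0
        else:
            # order occluders nearest-first for early elimination
            order = np.argsort(np.linalg.norm(nc - coords[i], axis=1))
            nc, nr = nc[order], nr[order]
            alive = np.ones(len(pts), dtype=bool)
            for c, r in zip(nc, nr):
                if not alive.any():
                    break
                sub = pts[alive]
                d2 = np.einsum("ij,ij->i", sub - c, sub - c)
                alive[np.flatnonzero(alive)[d2 < r * r]] = False
            exposed_frac = alive.mean()
        areas[i] = exposed_frac * 4.0 * math.pi * ri * ri

    per_atom = {k: float(a) for k, a in zip(keys, areas)}
    per_residue: dict[ResidueKey, float] = {}
    for rk, a in zip(reskeys, areas):
        per_residue[rk] = per_residue.get(rk, 0.0) + float(a)
    return SasaResult(per_atom, per_residue, float(areas.sum()), p, s.id, resnames)


def sasa_of_selection(result: SasaResult, sel: AtomSelection) -> float:
    """Sum per-atom areas over an atom selection (Å²). Empty selection → 0."""
    missing = [k for k in sel.members if k not in result.per_atom]
    if missing:
        raise KeyError(
            f"{len(missing)} selection key(s) not present in SASA result, "
            f"e.g. {sorted(missing)[:5]}"
        )
    return float(sum(result.per_atom[k] for k in sel.members))


def sasa_table(result: SasaResult) -> "pandas.DataFrame":  # noqa: F821
    """Per-atom areas as a DataFrame (chain, resnum, icode, resname, atomname, area)."""
    import pandas as pd

    rows = [
        {
            "chain": c, "resnum": n, "icode": i,
            "resname": result.resnames.get((c, n, i), ""),
            "atomname": a, "area": area,
        }
        for (c, n, i, a), area in result.per_atom.items()
    ]
    return pd.DataFrame(rows, columns=["chain", "resnum", "icode", "resname", "atomname", "area"])
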