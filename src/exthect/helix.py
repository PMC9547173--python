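"""Amphipathic-helix detection and geometric secondary-structure assignment.

An amphipathic α-helix segregates hydrophobic residues onto one face. With
an ideal helical twist of 100°/residue, the Eisenberg hydrophobic moment

    μH = |Σ_n H(aa_n) · exp(i·n·δ)| / N

is large when hydrophobicity recurs with helical periodicity. Sliding-window
scans of μH locate candidate amphipathic segments; a backbone-dihedral
classifier provides a coordinate-based secondary-structure string.
"""

from __future__ import annotations

import cmath
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .structure import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "HydrophobicityScale",
    "HelixWindow",
    "SecondaryStructureString",
    "SCALES",
    "hydrophobic_moment",
    "scan_amphipathic",
    "assign_secondary_structure",
    "backbone_dihedrals",
]


@dataclass(frozen=True)
class HydrophobicityScale:
    """Named per-residue hydrophobicity values (unitless).

    Unknown one-letter codes resolve to the scale mean and are logged.
    """

    name: str
    values: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name} missing residues: {sorted(missing)}")

    @property
    def mean(self) -> float:
        return sum(self.values.values()) / len(self.values)

    def __getitem__(self, aa: str) -> float:
        aa = aa.upper()
        if aa not in self.values:
            logger.warning("scale %s: unknown residue %r -> scale mean", self.name, aa)
            return self.mean
        return self.values[aa]


#: Eisenberg consensus hydrophobicity scale.
EISENBERG = HydrophobicityScale(
    "eisenberg",
    {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
        "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
        "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
        "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    },
)

#: Binary hydrophobic set used throughout the HECT boundary analysis:
#: A, G, V, I, L, F, M, Y, W → 1, everything else → 0.
BINARY_HYDROPHOBIC = HydrophobicityScale(
    "binary-hydrophobic",
    {aa: (1.0 if aa in "AGVILFMYW" else 0.0) for aa in "ACDEFGHIKLMNPQRSTVWY"},
)

SCALES = {s.name: s for s in (EISENBERG, BINARY_HYDROPHOBIC)}


@dataclass
class HelixWindow:
    """A sequence window with its hydrophobic-moment statistics.

    Positions are 1-based inclusive within the scanned sequence.
    """

    seq_id: str
    start: int
    end: int
    mu_h: float
    mean_h: float
    face_angle: float
    hydrophobic_face_members: list[int] = field(default_factory=list)
    #: span of the single highest-moment window inside a merged segment;
    #: equals (start, end) for unmerged hits. The best window locates the
    #: helix less biased than the merged-union start.
    best_start: int = 0
    best_end: int = 0

    def __post_init__(self) -> None:
        if self.best_start == 0:
            self.best_start = self.start
        if self.best_end == 0:
            self.best_end = self.end


@dataclass
class SecondaryStructureString:
    """Per-residue H/E/C labels aligned to a chain's residue order."""

    seq_id: str
    labels: str
    residue_numbers: list[int] = field(default_factory=list)


def hydrophobic_moment(
    window: str,
    scale: HydrophobicityScale = EISENBERG,
    delta_deg: float = 100.0,
) -> tuple[float, float]:
    """Per-residue-normalized hydrophobic moment and its face angle.

    Returns ``(mu_h, face_angle)`` with ``mu_h = |Σ H_n e^{i n δ}| / N`` and
    ``face_angle`` the direction of the moment vector in degrees ∈ [0, 360),
    measured in the helical-wheel frame where residue 1 sits at 0°.
    """
    if not window:
        raise ValueError("window must contain at least one residue")
    if delta_deg <= 0:
        raise ValueError("delta_deg must be > 0")
    delta = math.radians(delta_deg)
    total = 0j
    for n, aa in enumerate(window):
        total += scale[aa] * cmath.exp(1j * n * delta)
    mu = abs(total) / len(window)
    angle = math.degrees(cmath.phase(total)) % 360.0
    return mu, angle


def _face_members(window: str, face_angle: float, delta_deg: float) -> list[int]:
    members = []
    for n, aa in enumerate(window):
        pos_angle = (n * delta_deg) % 360.0
        diff = abs((pos_angle - face_angle + 180.0) % 360.0 - 180.0)
        if diff <= 60.0 and BINARY_HYDROPHOBIC[aa] > 0:
            members.append(n + 1)
    return members


def scan_amphipathic(
    seq: str,
    window: int = 18,
    scale: HydrophobicityScale = EISENBERG,
    mu_min: float = 0.5,
    mean_h_max: float | None = None,
    delta_deg: float = 100.0,
    seq_id: str = "seq",
) -> list[HelixWindow]:
    """Scan a sequence for amphipathic windows.

    All windows of the given length with ``mu_h ≥ mu_min`` (and, when set,
    ``mean_h ≤ mean_h_max``) are collected; windows overlapping by more than
    half the window length are merged into one segment that keeps the best
    window's moment and face angle. Returns merged segments sorted by start.
    """
    seq = seq.upper()
    if len(seq) < window:
        logger.warning("sequence %s shorter than window (%d < %d)", seq_id, len(seq), window)
        return []
    hits: list[HelixWindow] = []
    for i in range(len(seq) - window + 1):
        sub = seq[i:i + window]
        mu, angle = hydrophobic_moment(sub, scale, delta_deg)
        mean_h = sum(scale[aa] for aa in sub) / window
        if mu >= mu_min and (mean_h_max is None or mean_h <= mean_h_max):
            hits.append(
                HelixWindow(seq_id, i + 1, i + window, mu, mean_h, angle,
                            _face_members(sub, angle, delta_deg))
            )
    merged: list[HelixWindow] = []
    for h in hits:
        if merged:
            prev = merged[-1]
            overlap = min(prev.end, h.end) - max(prev.start, h.start) + 1
            if overlap > window / 2:
                best = prev if prev.mu_h >= h.mu_h else h
                merged[-1] = HelixWindow(
                    seq_id, min(prev.start, h.start), max(prev.end, h.end),
                    best.mu_h, best.mean_h, best.face_angle,
                    best.hydrophobic_face_members,
                    best_start=best.best_start, best_end=best.best_end,
                )
                continue
        merged.append(h)
    return merged


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return math.degrees(math.atan2(y, x))


def backbone_dihedrals(
    s: Structure, chain_id: str
) -> list[tuple[int, float | None, float | None]]:
    """(residue number, φ, ψ) per residue; None where neighbours are missing.

    A chain break (consecutive CA–CA distance > 4.5 Å) severs the neighbour
    relation on both sides.
    """
    residues = s.chains.get(chain_id, [])
    out: list[tuple[int, float | None, float | None]] = []
    bb = []
    for res in residues:
        n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
        bb.append((res.number, n, ca, c))
    for i, (num, n, ca, c) in enumerate(bb):
        phi = psi = None
        if n is not None and ca is not None and c is not None:
            if i > 0:
                pnum, pn, pca, pc = bb[i - 1]
                if pc is not None and pca is not None and ca is not None:
                    if np.linalg.norm(ca.coords - pca.coords) <= 4.5:
                        phi = _dihedral(pc.coords, n.coords, ca.coords, c.coords)
            if i < len(bb) - 1:
                nnum, nn, nca, nc = bb[i + 1]
                if nn is not None and nca is not None:
                    if np.linalg.norm(nca.coords - ca.coords) <= 4.5:
                        psi = _dihedral(n.coords, ca.coords, c.coords, nn.coords)
        else:
            logger.warning("residue %s:%d missing backbone atoms", chain_id, num)
        out.append((num, phi, psi))
    return out


def assign_secondary_structure(s: Structure, chain_id: str | None = None) -> SecondaryStructureString:
    """Assign H/E/C labels from backbone φ/ψ dihedrals.

    A residue is an α candidate when φ ∈ (−100°, −30°) and ψ ∈ (−80°, −5°),
    and a β candidate when φ ∈ (−170°, −70°) and ψ ∈ (90°, 180°). Labels are
    emitted only for runs of ≥4 consecutive candidates (the residue plus at
    least three consecutive like neighbours); everything else, including
    residues flanking chain breaks or missing backbone atoms, is C.
    """
    if chain_id is None:
        if len(s.chains) != 1:
            raise ValueError("chain_id required for multi-chain structures")
        chain_id = next(iter(s.chains))
    dihedrals = backbone_dihedrals(s, chain_id)
    cand = []
    for _, phi, psi in dihedrals:
        if phi is not None and psi is not None and -100 < phi < -30 and -80 < psi < -5:
            cand.append("H")
        elif phi is not None and psi is not None and -170 < phi < -70 and 90 < psi <= 180:
            cand.append("E")
        else:
            cand.append("C")
    labels = ["C"] * len(cand)
    i = 0
    while i < len(cand):
        if cand[i] in "HE":
            j = i
            while j < len(cand) and cand[j] == cand[i]:
                j += 1
            if j - i >= 4:
                for k in range(i, j):
                    labels[k] = cand[i]
            i = j
        else:
            i += 1
    return SecondaryStructureString(
        seq_id=f"{s.id}:{chain_id}",
        labels="".join(labels),
        residue_numbers=[num for num, _, _ in dihedrals],
    )
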