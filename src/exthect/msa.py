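"""Alignment I/O, column conservation, and MSA-driven boundary extension.

The boundary-extension procedure emulates how an annotated domain start can
be pushed N-terminally when a conserved amphipathic helix is found upstream
in an ortholog alignment: scan the region upstream of the annotated start
for amphipathic windows (hydrophobic moment), require the corresponding
alignment columns to be conserved, and propose the most N-terminal
qualifying helix start as the new boundary.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

from .helix import EISENBERG, HydrophobicityScale, scan_amphipathic

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "ColumnProfile",
    "ResidueMap",
    "ExtensionProposal",
    "ProposalParams",
    "read_alignment",
    "column_conservation",
    "map_columns",
    "propose_extension",
]

_HYDROPHOBIC_1 = set("AGVILFMYW")


@dataclass
class Alignment:
    """Rows of equal-length aligned sequences ('-' gaps, upper case)."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        if self.rows:
            n = len(self.rows[0][1])
            for sid, seq in self.rows:
                if len(seq) != n:
                    raise ValueError(
                        f"ragged alignment: row {sid!r} has length {len(seq)} != {n}"
                    )

    @property
    def n_cols(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        for sid, seq in self.rows:
            if sid == seq_id:
                return seq
        raise KeyError(f"sequence id {seq_id!r} not in alignment")

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]


@dataclass
class ColumnProfile:
    """Per-column gap fraction, modal-residue conservation, hydrophobic fraction."""

    gap_fraction: np.ndarray
    conservation: np.ndarray
    hydrophobic_fraction: np.ndarray
    used: np.ndarray  # False where gap_fraction > gap_max
    gap_max: float = 0.5


@dataclass
class ResidueMap:
    """column index (0-based) → author residue number for one row."""

    seq_id: str
    col_to_resnum: dict[int, int] = field(default_factory=dict)

    def resnum_to_col(self) -> dict[int, int]:
        return {v: k for k, v in self.col_to_resnum.items()}


@dataclass
class ExtensionProposal:
    """Outcome of the upstream-helix boundary search for one sequence."""

    seq_id: str
    uniprot_start: int
    proposed_start: int
    status: str  # extended | unchanged | insufficient_signal
    supporting: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ProposalParams:
    """Tunables of the boundary-extension search.

    search_span : residues upstream of the annotated start to scan.
    c_min : minimum mean column conservation over a candidate helix.
    window / mu_min / scale parameters are passed to the amphipathic scan.
    """

    search_span: int = 120
    c_min: float = 0.5
    window: int = 18
    mu_min: float = 0.5
    gap_max: float = 0.5


def read_alignment(text: str, fmt: str = "fasta") -> Alignment:
    """Read an alignment from FASTA / Clustal / Stockholm text.

    Rows are upper-cased and '.' gaps normalized to '-'. Ragged rows raise
    a ValueError naming the offending id.
    """
    fmt = fmt.lower()
    if fmt not in ("fasta", "clustal", "stockholm"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    handle = io.StringIO(text)
    if fmt == "fasta":
        records = list(SeqIO.parse(handle, "fasta"))
    else:
        records = list(AlignIO.read(handle, fmt))
    if not records:
        raise ValueError("empty alignment")
    rows = [(r.id, str(r.seq).upper().replace(".", "-")) for r in records]
    return Alignment(rows)


def write_alignment_fasta(a: Alignment) -> str:
    return "".join(f">{sid}\n{seq}\n" for sid, seq in a.rows)


def column_conservation(a: Alignment, gap_max: float = 0.5) -> ColumnProfile:
    """Modal-residue conservation, gap fraction and hydrophobic fraction per column.

    Conservation is the frequency of the most common residue among non-gap
    entries; the hydrophobic fraction uses the binary A,G,V,I,L,F,M,Y,W set.
    Columns with gap fraction above ``gap_max`` are flagged unused.
    """
    if a.n_rows < 2:
        raise ValueError("column conservation requires at least 2 rows")
    arr = np.array([list(seq) for _, seq in a.rows])
    n_rows, n_cols = arr.shape
    gap_fraction = np.empty(n_cols)
    conservation = np.empty(n_cols)
    hydrophobic_fraction = np.empty(n_cols)
    for c in range(n_cols):
        col = arr[:, c]
        residues = col[col != "-"]
        gap_fraction[c] = 1.0 - len(residues) / n_rows
        if len(residues) == 0:
            conservation[c] = 0.0
            hydrophobic_fraction[c] = 0.0
            continue
        _, counts = np.unique(residues, return_counts=True)
        conservation[c] = counts.max() / len(residues)
        hydrophobic_fraction[c] = np.mean([r in _HYDROPHOBIC_1 for r in residues])
    used = gap_fraction <= gap_max
    return ColumnProfile(gap_fraction, conservation, hydrophobic_fraction, used, gap_max)


def map_columns(a: Alignment, seq_id: str, first_residue_number: int = 1) -> ResidueMap:
    """Map 0-based column indices to author residue numbers for one row.

    The k-th non-gap column (k = 0, 1, …) maps to
    ``first_residue_number + k``; gap columns are absent from the map.
    """
    seq = a.row(seq_id)
    mapping: dict[int, int] = {}
    k = 0
    for col, ch in enumerate(seq):
        if ch != "-":
            mapping[col] = first_residue_number + k
            k += 1
    if not mapping:
        logger.warning("map_columns: row %s is all gaps", seq_id)
    return ResidueMap(seq_id, mapping)


def propose_extension(
    a: Alignment,
    profile: ColumnProfile,
    maps: dict[str, ResidueMap],
    uniprot_starts: dict[str, int],
    scale: HydrophobicityScale = EISENBERG,
    params: ProposalParams | None = None,
) -> list[ExtensionProposal]:
    """Propose extended domain starts from conserved upstream amphipathic helices.

    For each sequence: take the ungapped residues in
    ``[uniprot_start − search_span, uniprot_start)``, scan them for
    amphipathic windows, keep windows whose alignment columns have mean
    conservation ≥ ``c_min`` (over columns not flagged unused), and propose
    the start of the most N-terminal qualifying window. Status is
    ``extended`` when a qualifying helix is found, ``unchanged`` when no
    amphipathic window exists, and ``insufficient_signal`` when windows
    exist but none is conserved enough. The proposal never moves the start
    inside the annotated domain.
    """
    p = params or ProposalParams()
    proposals: list[ExtensionProposal] = []
    for seq_id in a.ids:
        ustart = uniprot_starts[seq_id]
        rmap = maps[seq_id]
        # upstream residues in order, with their residue numbers and columns
        upstream = [
            (rn, col)
            for col, rn in sorted(rmap.col_to_resnum.items())
            if ustart - p.search_span <= rn < ustart
        ]
        if len(upstream) < p.window:
            proposals.append(
                ExtensionProposal(seq_id, ustart, ustart, "unchanged",
                                  {"reason": "upstream region shorter than window"})
            )
            continue
        row = a.row(seq_id)
        subseq = "".join(row[col] for _, col in upstream)
        hits = scan_amphipathic(
            subseq, window=p.window, scale=scale, mu_min=p.mu_min, seq_id=seq_id
        )
        if not hits:
            proposals.append(
                ExtensionProposal(seq_id, ustart, ustart, "unchanged",
                                  {"n_windows": 0})
            )
            continue
        qualifying = []
        for h in hits:
            cols = [upstream[i][1] for i in range(h.start - 1, h.end)]
            cols_used = [c for c in cols if profile.used[c]]
            if not cols_used:
                continue
            mean_cons = float(np.mean(profile.conservation[cols_used]))
            if mean_cons >= p.c_min:
                qualifying.append((h, mean_cons))
        if not qualifying:
            proposals.append(
                ExtensionProposal(
                    seq_id, ustart, ustart, "insufficient_signal",
                    {"n_windows": len(hits)},
                )
            )
            continue
        best = min(qualifying, key=lambda hc: hc[0].best_start)
        h, mean_cons = best
        proposed = min(upstream[h.best_start - 1][0], ustart)
        proposals.append(
            ExtensionProposal(
                seq_id, ustart, proposed, "extended",
                {
                    "mu_h": h.mu_h,
                    "mean_conservation": mean_cons,
                    "helix_span": (upstream[h.best_start - 1][0], upstream[h.best_end - 1][0]),
                    "n_windows": len(hits),
                },
            )
        )
    return proposals


def family_extension_length(proposals: list[ExtensionProposal]) -> float | None:
    """Family-level extension length: median of (uniprot_start − proposed_start)
    over rows with status ``extended``; None when no row was extended.

    An ortholog alignment yields one boundary proposal per protein family;
    the median across rows is robust to individual divergent orthologs.
    """
    import statistics

    ext = [
        p.uniprot_start - p.proposed_start
        for p in proposals
        if p.status == "extended"
    ]
    if not ext:
        return None
    return float(statistics.median(ext))
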