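"""Three-way domain-boundary comparison and mutation-region classification.

Compares, per HECT-family protein, the UniProt-annotated domain span, the
MSA-derived extended span, and the AlphaFold-model span, and classifies
residue positions into extension / core / outside regions. A transcription
of the published 28-member comparison table and the disease-mutation table
ship as packaged fixtures.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from statistics import median

import pandas as pd

__all__ = [
    "BoundarySet",
    "BoundaryTable",
    "RegionCall",
    "ComparisonReport",
    "load_boundary_table",
    "packaged_boundary_table",
    "packaged_mutation_table",
    "write_boundary_table",
    "extension_length",
    "classify_residue_region",
    "compare_boundaries",
]


@dataclass
class BoundarySet:
    """Per-protein (start, end) boundary triples; absent entries are None."""

    protein_id: str
    uniprot: tuple[int, int]
    msa: tuple[int, int] | None = None
    alphafold: tuple[int, int] | None = None
    family: str = ""
    notes: str = ""

    def __post_init__(self) -> None:
        for name in ("uniprot", "msa", "alphafold"):
            pair = getattr(self, name)
            if pair is not None and pair[0] > pair[1]:
                raise ValueError(f"{self.protein_id}: {name} start > end ({pair})")

    def get(self, which: str) -> tuple[int, int] | None:
        if which not in ("uniprot", "msa", "alphafold"):
            raise ValueError(f"unknown boundary source {which!r}")
        return getattr(self, which)


@dataclass
class BoundaryTable:
    rows: list[BoundarySet]
    source: str = ""

    def __post_init__(self) -> None:
        ids = [r.protein_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in boundary table")

    def __getitem__(self, protein_id: str) -> BoundarySet:
        for r in self.rows:
            if r.protein_id == protein_id:
                return r
        raise KeyError(f"protein {protein_id!r} not in table")

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class RegionCall:
    """Classification of one residue position relative to a boundary set."""

    protein_id: str
    residue_number: int
    region: str  # extension | core | outside
    which: str = "msa"


@dataclass
class ComparisonReport:
    """Summary of the three-way boundary comparison."""

    per_protein: pd.DataFrame
    n_proteins: int
    n_alphafold_present: int
    n_start_agreement: int  # msa start == alphafold start exactly
    median_msa_extension: float
    anomalies: list[str] = field(default_factory=list)


def _parse_range(text: str, row_id: str, column: str) -> tuple[int, int] | None:
    text = text.strip()
    if text.upper() in ("N/A", "NA", "", "-"):
        return None
    try:
        start_s, end_s = text.split("-")
        return int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"row {row_id!r}: unparseable {column} range {text!r}") from exc


def load_boundary_table(tsv_text: str, source: str = "") -> BoundaryTable:
    """Parse a TSV with columns protein_id, uniprot, msa, alphafold (+extras).

    Ranges are inclusive "start-end" strings; "N/A" marks an absent entry.
    """
    df = pd.read_csv(io.StringIO(tsv_text), sep="\t", dtype=str).fillna("")
    required = {"protein_id", "uniprot"}
    if not required.issubset(df.columns):
        raise ValueError(f"boundary table must have columns {sorted(required)}")
    if df.empty:
        raise ValueError("boundary table has no rows")
    rows = []
    for _, r in df.iterrows():
        pid = r["protein_id"].strip()
        uniprot = _parse_range(r["uniprot"], pid, "uniprot")
        if uniprot is None:
            raise ValueError(f"row {pid!r}: uniprot boundary is mandatory")
        rows.append(
            BoundarySet(
                protein_id=pid,
                uniprot=uniprot,
                msa=_parse_range(r.get("msa", ""), pid, "msa"),
                alphafold=_parse_range(r.get("alphafold", ""), pid, "alphafold"),
                family=r.get("family", "").strip(),
                notes=r.get("notes", "").strip(),
            )
        )
    return BoundaryTable(rows, source=source)


def write_boundary_table(t: BoundaryTable) -> str:
    """Serialize back to the TSV layout accepted by :func:`load_boundary_table`."""
    def fmt(pair):
        return "N/A" if pair is None else f"{pair[0]}-{pair[1]}"

    lines = ["protein_id\tfamily\tuniprot\tmsa\talphafold\tnotes"]
    for r in t.rows:
        lines.append(
            f"{r.protein_id}\t{r.family}\t{fmt(r.uniprot)}\t{fmt(r.msa)}"
            f"\t{fmt(r.alphafold)}\t{r.notes}"
        )
    return "\n".join(lines) + "\n"


def packaged_boundary_table() -> BoundaryTable:
    """The packaged 28-member HECT boundary comparison fixture."""
    text = resources.files("exthect.data").joinpath("table2_boundaries.tsv").read_text()
    return load_boundary_table(text, source="packaged table2_boundaries.tsv")


def packaged_mutation_table() -> pd.DataFrame:
    """The packaged disease-mutation fixture (protein, substitution, position)."""
    text = resources.files("exthect.data").joinpath("table1_mutations.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t")


def extension_length(b: BoundarySet, which: str = "msa") -> int | None:
    """uniprot.start − which.start; None when absent, may be negative (anomalous)."""
    pair = b.get(which)
    if pair is None:
        return None
    return b.uniprot[0] - pair[0]


def classify_residue_region(
    b: BoundarySet, resnum: int, which: str = "msa"
) -> RegionCall:
    """Classify a residue as extension / core / outside.

    extension: which.start ≤ resnum < uniprot.start;
    core: uniprot.start ≤ resnum ≤ uniprot.end; otherwise outside.
    """
    pair = b.get(which)
    if pair is None:
        raise ValueError(f"{b.protein_id}: {which} boundary absent")
    if b.uniprot[0] <= resnum <= b.uniprot[1]:
        region = "core"
    elif pair[0] <= resnum < b.uniprot[0]:
        region = "extension"
    else:
        region = "outside"
    return RegionCall(b.protein_id, resnum, region, which)


def compare_boundaries(t: BoundaryTable) -> ComparisonReport:
    """Per-protein extension lengths and MSA-vs-AlphaFold start agreement."""
    if len(t) == 0:
        raise ValueError("empty boundary table")
    records = []
    anomalies = []
    for b in t:
        ext_msa = extension_length(b, "msa")
        ext_af = extension_length(b, "alphafold")
        start_diff = (
            b.msa[0] - b.alphafold[0]
            if b.msa is not None and b.alphafold is not None
            else None
        )
        if ext_msa is not None and ext_msa < 0:
            anomalies.append(
                f"{b.protein_id}: msa start {b.msa[0]} lies inside the uniprot "
                f"domain (start {b.uniprot[0]}) — negative extension {ext_msa}"
            )
        records.append(
            {
                "protein_id": b.protein_id,
                "family": b.family,
                "uniprot_start": b.uniprot[0],
                "msa_start": b.msa[0] if b.msa else None,
                "alphafold_start": b.alphafold[0] if b.alphafold else None,
                "ext_msa": ext_msa,
                "ext_alphafold": ext_af,
                "msa_vs_alphafold_start_diff": start_diff,
            }
        )
    df = pd.DataFrame(records)
    present = df["alphafold_start"].notna()
    agree = int(((df["msa_vs_alphafold_start_diff"] == 0) & present).sum())
    ext_values = [e for e in df["ext_msa"] if e is not None and not pd.isna(e)]
    return ComparisonReport(
        per_protein=df,
        n_proteins=len(t),
        n_alphafold_present=int(present.sum()),
        n_start_agreement=agree,
        median_msa_extension=float(median(ext_values)),
        anomalies=anomalies,
    )
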