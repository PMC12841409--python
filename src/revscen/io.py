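"""Reading and writing the package's tabular formats.

The marker table is a TSV with columns ``region``, ``role`` (distal |
proximal | boundary), ``gene_id``, ``start``, ``end``, ``strand``,
``exons``, ``colocated_with``, ``ancestral_edge``, ``category``.  A region
appears once per flank, or once with role ``boundary`` when it is pinned to
an abstract ancestral edge without printed coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError
from .synteny import BreakpointRegion, GeneMarker

__all__ = [
    "read_marker_table",
    "read_arrangement_file",
    "read_single_arrangement",
]

_REQUIRED_COLUMNS = {"region", "role", "gene_id", "start", "end", "strand"}


def _opt(row: pd.Series, col: str) -> str | None:
    if col not in row or pd.isna(row[col]) or str(row[col]).strip() == "":
        return None
    return str(row[col]).strip()


def _marker_from_row(row: pd.Series) -> GeneMarker | None:
    gene = _opt(row, "gene_id")
    if gene is None:
        return None
    start, end = _opt(row, "start"), _opt(row, "end")
    strand = _opt(row, "strand")
    if start is None or end is None or strand is None:
        raise FormatError(
            f"marker {gene}: start, end and strand are all required"
        )
    return GeneMarker(
        gene_id=gene,
        start=int(float(start)),
        end=int(float(end)),
        strand=strand,
        probe_exons=_opt(row, "exons") or "",
    )


def read_marker_table(path: str | Path) -> tuple[BreakpointRegion, ...]:
    """Parse a marker TSV into breakpoint regions, one per ``region`` value,
    preserving first-appearance order."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = _REQUIRED_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(
            f"marker table {path}: missing columns {sorted(missing)}"
        )
    regions: list[BreakpointRegion] = []
    for name, grp in df.groupby("region", sort=False):
        distal = proximal = None
        coloc = edge = category = None
        for _, row in grp.iterrows():
            role = (_opt(row, "role") or "boundary").lower()
            marker = _marker_from_row(row)
            if role == "distal":
                distal = marker
            elif role == "proximal":
                proximal = marker
            elif role != "boundary":
                raise FormatError(
                    f"region {name}: unknown role {row['role']!r}"
                )
            coloc = coloc or _opt(row, "colocated_with")
            edge = edge or _opt(row, "ancestral_edge")
            category = category or _opt(row, "category")
        regions.append(
            BreakpointRegion(
                name=str(name),
                distal_flank=distal,
                proximal_flank=proximal,
                colocated_with=coloc,
                ancestral_edge=None if edge is None else int(float(edge)),
                category=category or "polymorphic",
            )
        )
    return tuple(regions)


def read_arrangement_file(path: str | Path):
    """Parse a GRIMM-like arrangement file into {name: Arrangement}."""
    from .signed_perm import parse_arrangements

    records = parse_arrangements(Path(path).read_text())
    if not records:
        raise FormatError(f"{path}: no arrangements found")
    return records


def read_single_arrangement(path: str | Path):
    """Parse a file expected to hold exactly one arrangement."""
    records = read_arrangement_file(path)
    if len(records) > 1:
        raise FormatError(
            f"{path}: expected one arrangement, found {len(records)}"
        )
    arr = next(iter(records.values()))
    return arr if arr.name else arr.renamed(Path(path).stem)
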