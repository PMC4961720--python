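"""In-silico peptide design by scanning mutagenesis.

The design procedure mirrors how the MTP2 antimicrobial candidate was derived
from the 13-residue N-terminal tail of carnitine palmitoyltransferase 1a:

1. :func:`glycine_scan` substitutes every position in turn with glycine and
   recomputes the full descriptor panel, exposing how much each side chain
   contributes to each descriptor.
2. :func:`reactive_positions` ranks positions by how much their glycine
   substitution improves a chosen criterion (Boman index by default) and
   returns the top *k*, ties included.
3. :func:`enumerate_candidates` exhaustively places a small alphabet of
   charged residues (e.g. K and D) onto the reactive positions — each
   alphabet residue used at most once by default — and ranks the resulting
   candidates by the criterion, with a deterministic tie-break (positions
   ascending, alphabet in the user-given order).
4. :func:`design_report` lays the result out as the familiar scan table
   (dash-notation substitution labels plus the five descriptor columns) in
   TSV or JSON.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .physchem import (
    DescriptorProfile,
    Mutation,
    PeptideSequence,
    apply_mutations,
    descriptor_profile,
    truncate_toward_zero,
)

__all__ = [
    "ScanRow",
    "ScanTable",
    "glycine_scan",
    "reactive_positions",
    "enumerate_candidates",
    "design_report",
    "substitution_label",
    "read_report",
]

#: Tolerance for treating two descriptor scores as tied.
_TIE_TOL = 1e-12

#: Criterion names accepted by the ranking operations.
CRITERIA = ("boman_index", "gravy", "ww_interface", "net_charge", "hydrophobic_ratio")


def substitution_label(parent: PeptideSequence, mutations: Sequence[Mutation]) -> str:
    """Dash notation for a mutant: one dash per unchanged position, the
    replacement letter at substituted positions (``-------K---D-``)."""
    chars = ["-"] * len(parent)
    for m in mutations:
        chars[m.position - 1] = m.replacement
    return "".join(chars)


@dataclass(frozen=True)
class ScanRow:
    """One mutant of the scan/design table with its descriptor panel and the
    deltas of the three energy-like descriptors versus the parent."""

    mutations: tuple[Mutation, ...]
    sequence: PeptideSequence
    profile: DescriptorProfile
    delta_boman: float
    delta_gravy: float
    delta_ww: float

    def label(self, parent: PeptideSequence) -> str:
        return substitution_label(parent, self.mutations)


@dataclass(frozen=True)
class ScanTable:
    """A parent peptide plus an ordered collection of mutant rows."""

    parent: PeptideSequence
    parent_profile: DescriptorProfile
    rows: tuple[ScanRow, ...]

    def __len__(self) -> int:
        return len(self.rows)


def _make_row(
    parent: PeptideSequence,
    parent_profile: DescriptorProfile,
    mutations: Sequence[Mutation],
) -> ScanRow:
    mutant = apply_mutations(parent, mutations)
    profile = descriptor_profile(mutant)
    return ScanRow(
        mutations=tuple(mutations),
        sequence=mutant,
        profile=profile,
        delta_boman=profile.boman_index - parent_profile.boman_index,
        delta_gravy=profile.gravy - parent_profile.gravy,
        delta_ww=profile.ww_interface - parent_profile.ww_interface,
    )


def glycine_scan(parent: PeptideSequence, replacement: str = "G") -> ScanTable:
    """Substitute every position in turn with ``replacement`` (glycine by
    default), one row per position in sequence order.

    Positions already holding the replacement residue yield rows identical to
    the parent profile (the substitution is recorded as e.g. ``G4G``).
    """
    parent_profile = descriptor_profile(parent)
    rows = tuple(
        _make_row(
            parent,
            parent_profile,
            [Mutation(pos, parent.residue_at(pos), replacement)],
        )
        for pos in range(1, len(parent) + 1)
    )
    return ScanTable(parent=parent, parent_profile=parent_profile, rows=rows)


def _row_delta(row: ScanRow, criterion: str) -> float:
    if criterion == "boman_index":
        return row.delta_boman
    if criterion == "gravy":
        return row.delta_gravy
    if criterion == "ww_interface":
        return row.delta_ww
    if criterion in CRITERIA:
        return float(getattr(row.profile, criterion))
    raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")


def reactive_positions(
    scan: ScanTable, k: int, criterion: str = "boman_index"
) -> list[int]:
    """Positions whose substitution most improves ``criterion``.

    Rows are ranked by descending delta versus the parent; the top ``k`` are
    returned together with every position tied (within 1e-12) with the k-th
    value.  The result is ordered by rank (delta descending, position
    ascending among ties).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(scan.parent):
        raise ValueError(f"k={k} exceeds parent length {len(scan.parent)}")
    # quantize so that mathematically tied deltas (summed in different
    # orders) compare equal and fall back to the position tie-break
    scored = [
        (round(_row_delta(row, criterion), 9), row.mutations[0].position)
        for row in scan.rows
    ]
    scored.sort(key=lambda item: (-item[0], item[1]))
    cutoff = scored[k - 1][0]
    return [pos for delta, pos in scored if delta > cutoff - _TIE_TOL]


def enumerate_candidates(
    parent: PeptideSequence,
    positions: Sequence[int],
    alphabet: Sequence[str],
    max_subs: int,
    criterion: str = "boman_index",
    allow_repeats: bool = False,
) -> list[ScanRow]:
    """Exhaustively rank substitutions of ``alphabet`` residues at ``positions``.

    Every assignment of alphabet residues to between 1 and ``max_subs`` of the
    given positions is evaluated; by default each alphabet residue is placed
    at most once (``allow_repeats=True`` lifts that).  Assignments containing
    an identity substitution are skipped.  The list is ranked by the
    criterion's value, descending, with a stable deterministic tie-break:
    generation order, i.e. fewer substitutions first, then positions
    ascending, then the alphabet in the user-given order.
    """
    positions = list(positions)
    alphabet = list(alphabet)
    if not positions or not alphabet:
        raise ValueError("positions and alphabet must be non-empty")
    if len(set(positions)) != len(positions):
        raise ValueError("positions must be distinct")
    for pos in positions:
        parent.residue_at(pos)  # range check
    if not 1 <= max_subs <= len(positions):
        raise ValueError("max_subs must be between 1 and the number of positions")
    if not allow_repeats and max_subs > len(alphabet):
        raise ValueError(
            "max_subs exceeds the alphabet size; pass allow_repeats=True to reuse residues"
        )
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}; choose from {CRITERIA}")

    parent_profile = descriptor_profile(parent)
    ordered_positions = sorted(positions)
    rows: list[ScanRow] = []
    for size in range(1, max_subs + 1):
        for subset in itertools.combinations(ordered_positions, size):
            assignments = (
                itertools.product(alphabet, repeat=size)
                if allow_repeats
                else itertools.permutations(alphabet, size)
            )
            for residues in assignments:
                muts = [
                    Mutation(pos, parent.residue_at(pos), res)
                    for pos, res in zip(subset, residues)
                ]
                if any(m.original == m.replacement for m in muts):
                    continue
                rows.append(_make_row(parent, parent_profile, muts))
    # stable sort keeps generation order among score ties
    rows.sort(key=lambda row: -float(getattr(row.profile, criterion)))
    return rows


# Table-layout column order and printed precisions of the scan table.
_REPORT_COLUMNS = [
    "label",
    "sequence",
    "boman_index",
    "hydrophobic_ratio",
    "net_charge",
    "gravy",
    "ww_interface",
]
_DISPLAY_DECIMALS = {"boman_index": 2, "gravy": 3, "ww_interface": 2}


def design_report(
    parent: PeptideSequence,
    scan: ScanTable | None = None,
    candidates: Sequence[ScanRow] | None = None,
    display: bool = False,
) -> pd.DataFrame:
    """Assemble the scan/design table: parent row first, then the glycine-scan
    rows, then any candidate rows, with dash-notation labels and the five
    descriptor columns.

    With ``display=True`` the three energy-like columns are truncated toward
    zero at the conventional printed precision (Boman 2, GRAVY 3, W–W 2);
    otherwise full precision is kept so that the table round-trips losslessly.
    """
    records: list[dict] = []
    parent_profile = (
        scan.parent_profile if scan is not None else descriptor_profile(parent)
    )
    records.append(_report_record("wild type", parent, parent_profile))
    for row in scan.rows if scan is not None else ():
        records.append(_report_record(row.label(parent), row.sequence, row.profile))
    for row in candidates or ():
        records.append(_report_record(row.label(parent), row.sequence, row.profile))
    frame = pd.DataFrame.from_records(records, columns=_REPORT_COLUMNS)
    if display:
        for column, ndigits in _DISPLAY_DECIMALS.items():
            frame[column] = [
                truncate_toward_zero(v, ndigits) for v in frame[column]
            ]
    return frame


def _report_record(
    label: str, sequence: PeptideSequence, profile: DescriptorProfile
) -> dict:
    record = {"label": label, "sequence": sequence.residues}
    record.update(
        {k: v for k, v in profile.as_dict().items() if k in _REPORT_COLUMNS}
    )
    return record


def write_report(frame: pd.DataFrame, path: str | Path, fmt: str = "tsv") -> None:
    """Write a design report as TSV or JSON (records orientation)."""
    if fmt == "tsv":
        frame.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        Path(path).write_text(
            json.dumps(frame.to_dict(orient="records"), indent=2) + "\n",
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unsupported report format {fmt!r} (tsv or json)")


def read_report(path: str | Path, fmt: str = "tsv") -> pd.DataFrame:
    """Read back a report written by :func:`write_report`."""
    if fmt == "tsv":
        return pd.read_csv(path, sep="\t")
    if fmt == "json":
        records = json.loads(Path(path).read_text(encoding="utf-8"))
        return pd.DataFrame.from_records(records, columns=_REPORT_COLUMNS)
    raise ValueError(f"unsupported report format {fmt!r} (tsv or json)")
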