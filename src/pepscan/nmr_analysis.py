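"""Chemical-shift tables, αCH secondary shifts and NOE-restraint accounting.

The conformational readout used here is the classical chemical-shift
deviation (CSD) argument: the deviation Δδ of an observed αCH proton shift
from the residue's random-coil reference is small in unstructured peptides,
while a sustained run of deviations below −0.1 ppm marks a helical segment.
Deviations within ±0.1 ppm are treated as random coil.  The same bundled
random-coil table (αH shifts of unstructured peptides in water) is applied
regardless of solvent; between-solvent comparisons of Δδ therefore reduce to
comparisons of the observed shifts themselves — a caveat documented in the
methods note.

Distance restraints (CYANA-style upper limits) are accounted for by sequence
separation: intraresidue (|i−j| = 0), sequential (|i−j| = 1), medium-range
(1 < |i−j| ≤ 4) and long-range (|i−j| > 4).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .physchem import AMINO_ACIDS, PeptideSequence

__all__ = [
    "ShiftRecord",
    "ShiftTable",
    "ShiftTableError",
    "RandomCoilReference",
    "CSDEntry",
    "CSDProfile",
    "StructureCall",
    "NOERestraint",
    "RestraintStats",
    "load_random_coil",
    "read_shift_table",
    "write_shift_table",
    "csd_alpha",
    "classify_structure",
    "restraint_stats",
    "noe_contact_summary",
    "read_upl",
    "write_upl",
]

SOLVENTS = ("DMSO", "TFE_H2O_1_1")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Greek/alternative atom spellings normalised to the ASCII labels used here.
_ATOM_ALIASES = {
    "NH": "NH", "HN": "NH",
    "ACH": "aCH", "HA": "aCH", "αCH": "aCH", "ALPHACH": "aCH",
    "BCH": "bCH", "HB": "bCH", "βCH": "bCH", "BETACH": "bCH",
    "GCH": "gCH", "HG": "gCH", "γCH": "gCH", "GAMMACH": "gCH",
}


class ShiftTableError(ValueError):
    """Malformed or inconsistent chemical-shift table."""


def normalize_atom(label: str) -> str:
    """Map an atom label to {NH, aCH, bCH, gCH, other:<text>}."""
    key = label.strip()
    canonical = _ATOM_ALIASES.get(key) or _ATOM_ALIASES.get(key.upper())
    if canonical:
        return canonical
    if key.startswith("other:"):
        return key
    return f"other:{key}"


def _one_letter(code: str, line_no: int | None = None) -> str:
    code = code.strip().upper()
    if len(code) == 3 and code in _THREE_TO_ONE:
        return _THREE_TO_ONE[code]
    if len(code) == 1 and code in AMINO_ACIDS:
        return code
    where = f" (line {line_no})" if line_no is not None else ""
    raise ShiftTableError(f"unknown residue code {code!r}{where}")


@dataclass(frozen=True)
class ShiftRecord:
    """One assigned proton resonance."""

    residue_index: int
    residue: str  # one-letter code
    atom: str  # NH, aCH, bCH, gCH or other:<text>
    shift: float  # ppm
    note: str = ""

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ShiftTableError("residue_index must be >= 1")
        if not 0.0 <= self.shift <= 12.0:
            raise ShiftTableError(
                f"proton shift {self.shift} ppm outside 0-12 ppm "
                f"(residue {self.residue_index})"
            )


@dataclass(frozen=True)
class ShiftTable:
    """A validated set of assigned shifts for one peptide in one solvent."""

    peptide: PeptideSequence
    records: tuple[ShiftRecord, ...]
    solvent: str = "DMSO"
    temperature: float = 298.0
    reference: str = ""

    def __post_init__(self) -> None:
        if self.solvent not in SOLVENTS:
            raise ShiftTableError(f"solvent must be one of {SOLVENTS}")
        seen_alpha: set[int] = set()
        for rec in self.records:
            if rec.residue_index > len(self.peptide):
                raise ShiftTableError(
                    f"residue_index {rec.residue_index} beyond peptide length "
                    f"{len(self.peptide)}"
                )
            expected = self.peptide.residue_at(rec.residue_index)
            if rec.residue != expected:
                raise ShiftTableError(
                    f"residue mismatch at position {rec.residue_index}: table says "
                    f"{rec.residue}, peptide {self.peptide.id!r} has {expected}"
                )
            if rec.atom == "aCH":
                if rec.residue_index in seen_alpha:
                    raise ShiftTableError(
                        f"duplicate aCH record for residue {rec.residue_index}"
                    )
                seen_alpha.add(rec.residue_index)

    def alpha_shift(self, position: int) -> float | None:
        """The αCH shift at a 1-based position, or None if unassigned."""
        for rec in self.records:
            if rec.residue_index == position and rec.atom == "aCH":
                return rec.shift
        return None


_SHIFT_COLUMNS = ["residue_index", "residue", "atom", "shift_ppm", "note"]


def read_shift_table(
    path: str | Path | io.TextIOBase,
    sequence: PeptideSequence,
    solvent: str = "DMSO",
    temperature: float = 298.0,
    reference: str = "",
) -> ShiftTable:
    """Parse the shift-table TSV dialect and validate it against ``sequence``.

    Dialect: UTF-8, tab-separated, '.' decimal, ``#`` comments, a header line
    ``residue_index  residue  atom  shift_ppm  note`` (note optional), residues
    as three- or one-letter codes.  Errors carry the offending line number.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        origin = "<stream>"
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        origin = str(path)
    records: list[ShiftRecord] = []
    header_seen = False
    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if not header_seen:
            if fields[: len(_SHIFT_COLUMNS) - 1] != _SHIFT_COLUMNS[:-1]:
                raise ShiftTableError(
                    f"{origin}: line {line_no}: expected header "
                    f"{_SHIFT_COLUMNS[:-1]} (+ optional 'note'), got {fields}"
                )
            header_seen = True
            continue
        if len(fields) < 4:
            raise ShiftTableError(
                f"{origin}: line {line_no}: expected >= 4 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            index = int(fields[0])
            shift = float(fields[3])
        except ValueError as exc:
            raise ShiftTableError(f"{origin}: line {line_no}: {exc}") from None
        residue = _one_letter(fields[1], line_no)
        note = fields[4] if len(fields) > 4 else ""
        try:
            records.append(
                ShiftRecord(index, residue, normalize_atom(fields[2]), shift, note)
            )
        except ShiftTableError as exc:
            raise ShiftTableError(f"{origin}: line {line_no}: {exc}") from None
    if not header_seen:
        raise ShiftTableError(f"{origin}: missing header line")
    return ShiftTable(
        peptide=sequence,
        records=tuple(records),
        solvent=solvent,
        temperature=temperature,
        reference=reference,
    )


_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    """Write a shift table in the TSV dialect accepted by :func:`read_shift_table`."""
    lines = ["\t".join(_SHIFT_COLUMNS)]
    for rec in table.records:
        lines.append(
            "\t".join(
                [
                    str(rec.residue_index),
                    _ONE_TO_THREE[rec.residue],
                    rec.atom,
                    f"{rec.shift:.3f}",
                    rec.note,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class RandomCoilReference:
    """Per-residue αH random-coil shifts (ppm), complete over the 20 residues."""

    values: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        if missing:
            raise ValueError(f"random-coil reference missing residues {missing}")
        for residue, value in self.values.items():
            if not 3.9 <= value <= 4.9:
                raise ValueError(
                    f"implausible αH random-coil shift {value} ppm for {residue}"
                )

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def load_random_coil() -> RandomCoilReference:
    """The bundled αH random-coil reference table."""
    text = (
        resources.files("pepscan") / "data" / "random_coil_alpha.tsv"
    ).read_text(encoding="utf-8")
    values: dict[str, float] = {}
    source = ""
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("source:"):
                source = body.partition(":")[2].strip()
            continue
        residue, _, value = line.partition("\t")
        values[residue.strip()] = float(value)
    return RandomCoilReference(values=values, source=source)


@dataclass(frozen=True)
class CSDEntry:
    index: int
    residue: str
    delta: float | None  # Δδ(αCH) = observed − random coil, ppm; None if unassigned
    label: str = "unassigned"  # {"helical", "coil", "unassigned"}


@dataclass(frozen=True)
class CSDProfile:
    """Per-residue αCH chemical-shift deviations for one peptide/solvent."""

    peptide: PeptideSequence
    solvent: str
    entries: tuple[CSDEntry, ...]

    def deltas(self) -> list[float | None]:
        return [e.delta for e in self.entries]

    def mean_delta(self) -> float:
        """Mean Δδ over residues with an assigned αCH."""
        assigned = [e.delta for e in self.entries if e.delta is not None]
        if not assigned:
            raise ValueError("no assigned αCH records")
        return sum(assigned) / len(assigned)

    def to_dataframe(self) -> pd.DataFrame:
        """Plot-ready table (one bar per residue)."""
        return pd.DataFrame(
            {
                "residue_index": [e.index for e in self.entries],
                "residue": [e.residue for e in self.entries],
                "delta_ppm": [e.delta for e in self.entries],
                "label": [e.label for e in self.entries],
            }
        )


def csd_alpha(table: ShiftTable, reference: RandomCoilReference) -> CSDProfile:
    """Δδ(i) = observed αCH(i) − random-coil(residue i) for every residue with
    an αCH record; residues without one are left unassigned."""
    entries = []
    for position in range(1, len(table.peptide) + 1):
        residue = table.peptide.residue_at(position)
        observed = table.alpha_shift(position)
        delta = None if observed is None else observed - reference[residue]
        entries.append(CSDEntry(index=position, residue=residue, delta=delta))
    return CSDProfile(
        peptide=table.peptide, solvent=table.solvent, entries=tuple(entries)
    )


@dataclass(frozen=True)
class StructureCall:
    """Residue labels plus the overall helix/coil call."""

    profile: CSDProfile  # entries relabelled
    overall: str  # "helical" if any qualifying run exists, else "coil"
    helical_runs: tuple[tuple[int, int], ...]  # inclusive 1-based (start, end)

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.profile.entries]


def classify_structure(
    csd: CSDProfile, helix_threshold: float = -0.1, min_run: int = 4
) -> StructureCall:
    """Label residues helical/coil from their αCH secondary shifts.

    A residue is helical when it belongs to a maximal run of at least
    ``min_run`` consecutive residues with Δδ below ``helix_threshold``
    (default −0.1 ppm, roughly one helical turn of four residues).
    Unassigned residues break runs and keep the label "unassigned".
    The overall call is helical if any qualifying run exists.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    below = [
        e.delta is not None and e.delta < helix_threshold for e in csd.entries
    ]
    helical = [False] * len(below)
    runs: list[tuple[int, int]] = []
    i = 0
    while i < len(below):
        if below[i]:
            j = i
            while j < len(below) and below[j]:
                j += 1
            if j - i >= min_run:
                runs.append((i + 1, j))  # 1-based inclusive
                for p in range(i, j):
                    helical[p] = True
            i = j
        else:
            i += 1
    entries = tuple(
        CSDEntry(
            index=e.index,
            residue=e.residue,
            delta=e.delta,
            label="unassigned"
            if e.delta is None
            else ("helical" if helical[k] else "coil"),
        )
        for k, e in enumerate(csd.entries)
    )
    relabelled = CSDProfile(peptide=csd.peptide, solvent=csd.solvent, entries=entries)
    return StructureCall(
        profile=relabelled,
        overall="helical" if runs else "coil",
        helical_runs=tuple(runs),
    )


@dataclass(frozen=True)
class NOERestraint:
    """One upper-limit distance restraint between two protons."""

    residue_i: int
    residue_j: int
    atom_i: str
    atom_j: str
    upper_bound: float | None = None  # Å
    resname_i: str = ""
    resname_j: str = ""

    def __post_init__(self) -> None:
        if self.residue_i < 1 or self.residue_j < 1:
            raise ValueError("restraint residue indices must be >= 1")
        if self.upper_bound is not None and self.upper_bound <= 0:
            raise ValueError("restraint upper bound must be positive")

    @property
    def gap(self) -> int:
        return abs(self.residue_i - self.residue_j)


@dataclass(frozen=True)
class RestraintStats:
    """Restraint counts by sequence-separation category, plus torsions."""

    total: int
    intraresidue: int  # |i−j| = 0
    sequential: int  # |i−j| = 1
    medium_range: int  # 1 < |i−j| ≤ 4
    long_range: int  # |i−j| > 4
    torsion_count: int = 0

    def __post_init__(self) -> None:
        parts = self.intraresidue + self.sequential + self.medium_range + self.long_range
        if parts != self.total:
            raise ValueError(
                f"category counts sum to {parts}, expected total {self.total}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "intraresidue": self.intraresidue,
            "sequential": self.sequential,
            "medium_range": self.medium_range,
            "long_range": self.long_range,
            "torsion_count": self.torsion_count,
        }


def gap_category(gap: int) -> str:
    """Sequence-separation class of a restraint gap |i−j|."""
    if gap == 0:
        return "intraresidue"
    if gap == 1:
        return "sequential"
    if gap <= 4:
        return "medium_range"
    return "long_range"


def restraint_stats(
    restraints: Iterable[NOERestraint], torsions: int = 0
) -> RestraintStats:
    """Count restraints per |i−j| category; counts always sum to the total."""
    counts = {"intraresidue": 0, "sequential": 0, "medium_range": 0, "long_range": 0}
    total = 0
    for restraint in restraints:
        counts[gap_category(restraint.gap)] += 1
        total += 1
    return RestraintStats(total=total, torsion_count=torsions, **counts)


def noe_contact_summary(restraints: Iterable[NOERestraint]) -> pd.DataFrame:
    """Per-(i, j) contact counts with their gap class — the data behind an
    NOE-contact diagram.  Pairs are ordered so that i ≤ j."""
    rows: dict[tuple[int, int], int] = {}
    for restraint in restraints:
        i, j = sorted((restraint.residue_i, restraint.residue_j))
        rows[(i, j)] = rows.get((i, j), 0) + 1
    frame = pd.DataFrame(
        [
            {
                "residue_i": i,
                "residue_j": j,
                "gap": j - i,
                "category": gap_category(j - i),
                "n_restraints": n,
            }
            for (i, j), n in sorted(rows.items())
        ],
        columns=["residue_i", "residue_j", "gap", "category", "n_restraints"],
    )
    return frame


def read_upl(path: str | Path) -> list[NOERestraint]:
    """Parse a CYANA-style UPL restraint file.

    Whitespace-delimited, 7 columns per line: index, residue name, atom,
    index, residue name, atom, upper bound (Å).  ``#`` comments and blank
    lines are skipped; malformed lines raise with their line number.
    """
    restraints: list[NOERestraint] = []
    for line_no, raw in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 7:
            raise ValueError(
                f"{path}: line {line_no}: expected 7 whitespace-delimited fields, "
                f"got {len(fields)}"
            )
        try:
            restraint = NOERestraint(
                residue_i=int(fields[0]),
                resname_i=fields[1],
                atom_i=fields[2],
                residue_j=int(fields[3]),
                resname_j=fields[4],
                atom_j=fields[5],
                upper_bound=float(fields[6]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {line_no}: {exc}") from None
        restraints.append(restraint)
    return restraints


def write_upl(restraints: Iterable[NOERestraint], path: str | Path) -> None:
    """Write restraints in the UPL format accepted by :func:`read_upl`."""
    lines = []
    for r in restraints:
        if r.upper_bound is None:
            raise ValueError("cannot write a UPL line without an upper bound")
        lines.append(
            f"{r.residue_i:>4d} {r.resname_i or 'XAA':>4s} {r.atom_i:>4s} "
            f"{r.residue_j:>4d} {r.resname_j or 'XAA':>4s} {r.atom_j:>4s} "
            f"{r.upper_bound:6.2f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
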