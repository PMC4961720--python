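"""Residue scales and whole-sequence physicochemical descriptors.

This module carries the quantities used to rank antimicrobial-peptide
candidates:

* **Boman index** (protein-binding potential) — the arithmetic mean over
  residues of the sign-inverted cyclohexane-to-water transfer free energy
  (kcal/mol); higher values mean a more hydrophilic, protein-binding peptide.
* **GRAVY** — the grand average of Kyte–Doolittle hydropathy (dimensionless).
* **Wimley–White interface value** — the *sum* of whole-residue free energies
  of transfer from water to the POPC bilayer interface (kcal/mol).
* **Net charge** — side-chain formal charge: (K + R) − (D + E), His neutral,
  termini ignored.
* **Hydrophobic ratio** — the percentage of residues in the hydrophobic set
  {A, C, F, I, L, M, V, W}, truncated to an integer.
* **Molecular weight** — average (isotope-abundance-weighted) mass in Da.

All scales ship as versioned plain-text tables under ``pepscan/data/scales``
and are loaded with :func:`load_scale`.  Printed reference values in the
source tables are truncated toward zero at the printed precision;
:func:`truncate_toward_zero` implements that display convention (internal
computation always keeps full float precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from decimal import ROUND_DOWN, Decimal
from functools import lru_cache
from importlib import resources
from types import MappingProxyType
from typing import Iterable, Iterator, Mapping

__all__ = [
    "AMINO_ACIDS",
    "HYDROPHOBIC_RESIDUES",
    "WATER_MASS",
    "PeptideSequence",
    "Mutation",
    "ResidueScale",
    "DescriptorProfile",
    "available_scales",
    "load_scale",
    "boman_index",
    "gravy",
    "ww_interface",
    "net_charge",
    "hydrophobic_ratio",
    "molecular_weight",
    "descriptor_profile",
    "apply_mutations",
    "truncate_toward_zero",
]

#: The twenty canonical amino acids, one-letter codes, alphabetical.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Hydrophobic set used for the hydrophobic-ratio descriptor (glycine excluded).
HYDROPHOBIC_RESIDUES: frozenset[str] = frozenset("ACFILMVW")

#: Average mass of one water molecule (Da), added once for free termini.
WATER_MASS: float = 18.01528

# Terminal-group mass adjustments relative to the free-acid/free-amine default.
_AMIDE_DELTA = -0.98476  # C-terminal CONH2: replace OH (17.00734) with NH2 (16.02258)
_ACETYL_DELTA = 42.03668  # N-terminal acetyl: add C2H2O


class UnknownScaleError(KeyError):
    """Raised when :func:`load_scale` is asked for a scale that is not bundled."""


def truncate_toward_zero(value: float, ndigits: int) -> float:
    """Truncate ``value`` toward zero at ``ndigits`` decimal places.

    A small decimal guard (9 significant decimals) absorbs binary floating
    point noise first, so that e.g. ``1.3 / 13`` — exactly 0.1 — truncates to
    0.1 and not 0.099.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    guarded = Decimal(f"{value:.9f}")
    return float(guarded.quantize(quantum, rounding=ROUND_DOWN))


@dataclass(frozen=True)
class PeptideSequence:
    """A validated peptide built from the 20 canonical one-letter codes.

    Positions are 1-based throughout the package (``residue_at(1)`` is the
    N-terminal residue).  Terminal chemistry is metadata: descriptors other
    than the molecular weight ignore it.
    """

    residues: str
    id: str = "peptide"
    n_terminus: str = "free"  # {"free", "acetyl"}
    c_terminus: str = "free_acid"  # {"free_acid", "amide"}

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("peptide sequence must be non-empty")
        bad = sorted({r for r in self.residues if r not in AMINO_ACIDS})
        if bad:
            raise ValueError(
                f"non-canonical residue code(s) {bad!r} in sequence {self.residues!r}"
            )
        if self.n_terminus not in ("free", "acetyl"):
            raise ValueError(f"unknown n_terminus {self.n_terminus!r}")
        if self.c_terminus not in ("free_acid", "amide"):
            raise ValueError(f"unknown c_terminus {self.c_terminus!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def __str__(self) -> str:
        return self.residues

    def residue_at(self, position: int) -> str:
        """Return the residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(
                f"position {position} outside 1..{len(self.residues)} for {self.id!r}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class Mutation:
    """A single point substitution, 1-based, recorded as original -> replacement."""

    position: int
    original: str
    replacement: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("mutation position must be >= 1")
        for code in (self.original, self.replacement):
            if code not in AMINO_ACIDS:
                raise ValueError(f"non-canonical residue code {code!r} in mutation")

    def __str__(self) -> str:
        return f"{self.original}{self.position}{self.replacement}"


def apply_mutations(
    seq: PeptideSequence, mutations: Iterable[Mutation]
) -> PeptideSequence:
    """Apply point substitutions at distinct positions; the parent is unmodified.

    Raises ``ValueError`` if two mutations hit the same position, a position is
    out of range, or a mutation's ``original`` disagrees with the parent.
    """
    muts = list(mutations)
    positions = [m.position for m in muts]
    if len(set(positions)) != len(positions):
        raise ValueError(f"mutations clash at position(s) {sorted(positions)}")
    chars = list(seq.residues)
    for m in muts:
        actual = seq.residue_at(m.position)  # range-checks the position
        if actual != m.original:
            raise ValueError(
                f"mutation {m} does not match parent: residue {m.position} is {actual}"
            )
        chars[m.position - 1] = m.replacement
    if not muts:
        return seq
    label = "+".join(str(m) for m in muts)
    return replace(seq, residues="".join(chars), id=f"{seq.id}|{label}")


@dataclass(frozen=True)
class ResidueScale:
    """A named per-residue numeric table covering all 20 canonical residues."""

    name: str
    unit: str
    values: Mapping[str, float]
    sign_convention: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("scale unit must be non-empty")
        missing = sorted(set(AMINO_ACIDS) - set(self.values))
        extra = sorted(set(self.values) - set(AMINO_ACIDS))
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 canonical residues "
                f"(missing {missing}, extra {extra})"
            )
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def mean(self, seq: PeptideSequence | str) -> float:
        residues = str(seq)
        return sum(self.values[r] for r in residues) / len(residues)

    def sum(self, seq: PeptideSequence | str) -> float:
        return sum(self.values[r] for r in str(seq))

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


_SCALE_FILES = {
    "boman": "scales/boman.tsv",
    "kyte_doolittle": "scales/kyte_doolittle.tsv",
    "ww_interface": "scales/ww_interface.tsv",
    "residue_mass": "scales/residue_mass.tsv",
}


def available_scales() -> tuple[str, ...]:
    """Identifiers accepted by :func:`load_scale`."""
    return tuple(sorted(_SCALE_FILES))


def _parse_scale_text(text: str, fallback_name: str) -> ResidueScale:
    meta = {"name": fallback_name, "unit": "", "sign_convention": "", "source": ""}
    values: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            key, _, val = body.partition(":")
            if _ and key.strip() in meta:
                meta[key.strip()] = val.strip()
            continue
        residue, _, value = line.partition("\t")
        values[residue.strip()] = float(value)
    return ResidueScale(values=values, **meta)


@lru_cache(maxsize=None)
def load_scale(name: str) -> ResidueScale:
    """Load a bundled residue scale by identifier.

    Bundled scales: ``boman`` (sign-inverted cyclohexane→water transfer),
    ``kyte_doolittle`` (hydropathy), ``ww_interface`` (Wimley–White
    whole-residue water→POPC-interface, charged D/E, neutral H) and
    ``residue_mass`` (average masses).
    """
    try:
        relpath = _SCALE_FILES[name]
    except KeyError:
        raise UnknownScaleError(
            f"unknown scale {name!r}; available scales: {', '.join(available_scales())}"
        ) from None
    text = (resources.files("pepscan") / "data" / relpath).read_text(encoding="utf-8")
    return _parse_scale_text(text, name)


@dataclass(frozen=True)
class DescriptorProfile:
    """The six-descriptor panel for one peptide."""

    mol_weight: float
    boman_index: float
    hydrophobic_ratio: int
    net_charge: int
    gravy: float
    ww_interface: float

    def __post_init__(self) -> None:
        if not 0 <= self.hydrophobic_ratio <= 100:
            raise ValueError("hydrophobic_ratio must lie in [0, 100]")
        if self.mol_weight <= 0:
            raise ValueError("mol_weight must be positive")

    def as_dict(self) -> dict[str, float | int]:
        return {
            "mol_weight": self.mol_weight,
            "boman_index": self.boman_index,
            "hydrophobic_ratio": self.hydrophobic_ratio,
            "net_charge": self.net_charge,
            "gravy": self.gravy,
            "ww_interface": self.ww_interface,
        }

    def display(self) -> dict[str, float | int]:
        """The panel truncated toward zero at the conventional printed precision
        (molecular weight and interface value to 2 decimals, Boman index to 2,
        GRAVY to 3)."""
        return {
            "mol_weight": truncate_toward_zero(self.mol_weight, 2),
            "boman_index": truncate_toward_zero(self.boman_index, 2),
            "hydrophobic_ratio": self.hydrophobic_ratio,
            "net_charge": self.net_charge,
            "gravy": truncate_toward_zero(self.gravy, 3),
            "ww_interface": truncate_toward_zero(self.ww_interface, 2),
        }


def boman_index(seq: PeptideSequence | str) -> float:
    """Protein-binding potential: mean sign-inverted cyclohexane→water transfer
    free energy over residues, kcal/mol."""
    return load_scale("boman").mean(_coerce(seq))


def gravy(seq: PeptideSequence | str) -> float:
    """Grand average of Kyte–Doolittle hydropathy (dimensionless)."""
    return load_scale("kyte_doolittle").mean(_coerce(seq))


def ww_interface(seq: PeptideSequence | str) -> float:
    """Whole-peptide sum of Wimley–White whole-residue water→POPC-interface
    transfer free energies, kcal/mol (charged D/E, neutral H)."""
    return load_scale("ww_interface").sum(_coerce(seq))


def net_charge(seq: PeptideSequence | str) -> int:
    """Side-chain formal charge (#K + #R) − (#D + #E); His neutral, termini ignored."""
    residues = str(_coerce(seq))
    return sum(residues.count(r) for r in "KR") - sum(residues.count(r) for r in "DE")


def hydrophobic_ratio(seq: PeptideSequence | str) -> int:
    """Percentage of residues in {A,C,F,I,L,M,V,W}, truncated toward zero."""
    residues = str(_coerce(seq))
    n_hydrophobic = sum(1 for r in residues if r in HYDROPHOBIC_RESIDUES)
    return math.trunc(100 * n_hydrophobic / len(residues))


def molecular_weight(seq: PeptideSequence | str) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water,
    adjusted for acetylated N-terminus / amidated C-terminus when the sequence
    metadata says so (free termini by default)."""
    peptide = _coerce(seq)
    mass = load_scale("residue_mass").sum(peptide) + WATER_MASS
    if peptide.c_terminus == "amide":
        mass += _AMIDE_DELTA
    if peptide.n_terminus == "acetyl":
        mass += _ACETYL_DELTA
    return mass


def descriptor_profile(seq: PeptideSequence | str) -> DescriptorProfile:
    """All six descriptors in one pass; field-wise equal to the single calls."""
    peptide = _coerce(seq)
    return DescriptorProfile(
        mol_weight=molecular_weight(peptide),
        boman_index=boman_index(peptide),
        hydrophobic_ratio=hydrophobic_ratio(peptide),
        net_charge=net_charge(peptide),
        gravy=gravy(peptide),
        ww_interface=ww_interface(peptide),
    )


def _coerce(seq: PeptideSequence | str) -> PeptideSequence:
    if isinstance(seq, PeptideSequence):
        return seq
    return PeptideSequence(residues=str(seq))
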