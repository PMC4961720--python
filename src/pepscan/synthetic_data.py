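"""Seeded generators for every input class the pipeline consumes.

These generators emulate the statistical structure the analyses assume —
random peptide sequences with a given residue composition, assigned-shift
tables with planted helical segments (mean αCH secondary shift −0.35 ppm,
well beyond the −0.1 ppm helix threshold) plus Gaussian noise, and
restraint lists with prescribed sequence-separation category counts.  Every
generator takes an explicit seed and owns a single NumPy ``Generator``
stream; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .nmr_analysis import (
    NOERestraint,
    RandomCoilReference,
    ShiftRecord,
    ShiftTable,
)
from .physchem import AMINO_ACIDS, PeptideSequence

__all__ = [
    "GeneratorConfig",
    "random_peptide",
    "synthetic_shift_table",
    "synthetic_restraints",
]

# Plausible filler resonances (ppm) for atoms the CSD analysis ignores.
_NH_FILL = 8.30  # backbone amide region
_BCH_FILL = 1.80  # generic aliphatic side-chain region

_ONE_TO_THREE_GAPLESS = "GLY"  # glycine has no beta proton record


@dataclass(frozen=True)
class GeneratorConfig:
    """Settings shared by the generators.

    ``helix_segments`` are inclusive 1-based (start, end) ranges whose αCH
    shifts are displaced by ``helix_mean`` (−0.35 ppm by default); elsewhere
    the displacement is zero.  ``noise_sd`` is the Gaussian noise on every
    generated αCH shift, in ppm.
    """

    seed: int = 0
    length: int = 15
    composition: Mapping[str, float] | None = None  # default: uniform over 20
    helix_segments: tuple[tuple[int, int], ...] = ()
    helix_mean: float = -0.35
    noise_sd: float = 0.03
    category_counts: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.composition is not None:
            unknown = sorted(set(self.composition) - set(AMINO_ACIDS))
            if unknown:
                raise ValueError(f"composition has non-canonical residues {unknown}")
            total = float(sum(self.composition.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition probabilities sum to {total}, not 1")
        for start, end in self.helix_segments:
            if not 1 <= start <= end <= self.length:
                raise ValueError(
                    f"helix segment ({start}, {end}) outside [1, {self.length}]"
                )


def random_peptide(config: GeneratorConfig) -> PeptideSequence:
    """Draw a peptide of ``config.length`` from ``config.composition``
    (uniform over the 20 canonical residues by default); bit-reproducible
    for a given seed."""
    rng = np.random.default_rng(config.seed)
    letters = list(AMINO_ACIDS)
    if config.composition is None:
        probabilities = None
    else:
        probabilities = np.array(
            [config.composition.get(r, 0.0) for r in letters], dtype=float
        )
        probabilities = probabilities / probabilities.sum()
    drawn = rng.choice(letters, size=config.length, p=probabilities)
    return PeptideSequence(
        residues="".join(drawn), id=f"synthetic_seed{config.seed}"
    )


def _in_segments(position: int, segments: Sequence[tuple[int, int]]) -> bool:
    return any(start <= position <= end for start, end in segments)


def synthetic_shift_table(
    seq: PeptideSequence,
    config: GeneratorConfig,
    reference: RandomCoilReference,
    solvent: str = "TFE_H2O_1_1",
) -> ShiftTable:
    """Generate an assigned-shift table with planted helical segments.

    αCH(i) = reference[residue i] + μ(i) + N(0, noise_sd), with μ equal to
    ``config.helix_mean`` inside ``config.helix_segments`` and 0 elsewhere.
    NH and βCH records are filled with plausible constants (8.30 and
    1.80 ppm; glycine gets no βCH record) so the table exercises the full
    reader, and the first residue has no NH (free amine, as in real tables).
    """
    rng = np.random.default_rng(config.seed)
    records: list[ShiftRecord] = []
    for position in range(1, len(seq) + 1):
        residue = seq.residue_at(position)
        mu = config.helix_mean if _in_segments(position, config.helix_segments) else 0.0
        alpha = reference[residue] + mu + rng.normal(0.0, config.noise_sd)
        if position > 1:
            records.append(ShiftRecord(position, residue, "NH", _NH_FILL))
        records.append(ShiftRecord(position, residue, "aCH", float(alpha)))
        if residue != "G":
            records.append(ShiftRecord(position, residue, "bCH", _BCH_FILL))
    return ShiftTable(
        peptide=seq,
        records=tuple(records),
        solvent=solvent,
        reference="synthetic",
    )


_CATEGORY_KEYS = ("intraresidue", "sequential", "medium_range", "long_range")


def synthetic_restraints(
    length: int, category_counts: Mapping[str, int], seed: int = 0
) -> list[NOERestraint]:
    """Generate a restraint list whose per-category counts are exactly
    ``category_counts`` (keys: intraresidue, sequential, medium_range,
    long_range; missing keys mean zero).

    Raises ``ValueError`` when a requested category is infeasible for the
    peptide length (e.g. sequential pairs need length ≥ 2, medium-range
    needs length ≥ 3, long-range needs length ≥ 6).
    """
    unknown = sorted(set(category_counts) - set(_CATEGORY_KEYS))
    if unknown:
        raise ValueError(f"unknown restraint categories {unknown}")
    counts = {key: int(category_counts.get(key, 0)) for key in _CATEGORY_KEYS}
    if any(count < 0 for count in counts.values()):
        raise ValueError("category counts must be non-negative")
    min_length = {"intraresidue": 1, "sequential": 2, "medium_range": 3, "long_range": 6}
    for key, needed in min_length.items():
        if counts[key] > 0 and length < needed:
            raise ValueError(
                f"{key} restraints infeasible for a peptide of length {length}"
            )
    rng = np.random.default_rng(seed)
    restraints: list[NOERestraint] = []
    gap_ranges = {
        "intraresidue": (0, 0),
        "sequential": (1, 1),
        "medium_range": (2, 4),
        "long_range": (5, length - 1),
    }
    for key in _CATEGORY_KEYS:
        lo, hi = gap_ranges[key]
        hi = min(hi, length - 1) if key != "intraresidue" else hi
        for _ in range(counts[key]):
            gap = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            i = int(rng.integers(1, length - gap + 1))
            atoms = ("HA", "HN") if gap else ("HA", "HB")
            restraints.append(
                NOERestraint(
                    residue_i=i,
                    residue_j=i + gap,
                    atom_i=atoms[0],
                    atom_j=atoms[1],
                    upper_bound=float(np.round(rng.uniform(2.5, 5.5), 2)),
                )
            )
    return restraints
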