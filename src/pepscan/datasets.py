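"""Bundled study sequences and transcribed assigned-shift tables.

The two designed antimicrobial peptides and their parent:

* ``WILD_TYPE`` — MAEAHQAVAFQFT, residues 1–13 of the N-terminal tail of
  carnitine palmitoyltransferase 1a (CPT-1a), the glycine-scan parent.
* ``MTP1`` — KVSGVLFGTGLWVAL.
* ``MTP2`` — MAEAHQAKAFQDT, the designed double mutant (V8K, F12D) of the
  wild type.

Assigned proton shift tables for MTP1 and MTP2 in DMSO-d6 and TFE/H2O 1:1
ship as plain-text fixtures and are loaded with :func:`load_shift_table`.
The NMR samples were C-terminally amidated; descriptor calculations on the
module-level sequence constants use free termini (the convention of the
descriptor panel).
"""

from __future__ import annotations

from importlib import resources

from .nmr_analysis import ShiftTable, read_shift_table
from .physchem import PeptideSequence

__all__ = ["WILD_TYPE", "MTP1", "MTP2", "load_shift_table"]

WILD_TYPE = PeptideSequence("MAEAHQAVAFQFT", id="CPT1a_1_13")
MTP1 = PeptideSequence("KVSGVLFGTGLWVAL", id="MTP1")
MTP2 = PeptideSequence("MAEAHQAKAFQDT", id="MTP2")

_FIXTURES = {
    ("MTP1", "DMSO"): ("mtp1_dmso.tsv", "DMSO (2.5 ppm)"),
    ("MTP1", "TFE_H2O_1_1"): ("mtp1_tfe.tsv", "TSP"),
    ("MTP2", "DMSO"): ("mtp2_dmso.tsv", "DMSO (2.5 ppm)"),
    ("MTP2", "TFE_H2O_1_1"): ("mtp2_tfe.tsv", "TSP"),
}

_PEPTIDES = {"MTP1": MTP1, "MTP2": MTP2}


def load_shift_table(peptide: str, solvent: str) -> ShiftTable:
    """Load a bundled assigned-shift table.

    ``peptide`` is ``"MTP1"`` or ``"MTP2"``; ``solvent`` is ``"DMSO"`` or
    ``"TFE_H2O_1_1"``.  All four tables were recorded at 298 K.
    """
    try:
        filename, reference = _FIXTURES[(peptide, solvent)]
    except KeyError:
        raise KeyError(
            f"no bundled shift table for ({peptide!r}, {solvent!r}); "
            f"available: {sorted(_FIXTURES)}"
        ) from None
    path = resources.files("pepscan") / "data" / "shifts" / filename
    with resources.as_file(path) as fspath:
        return read_shift_table(
            fspath,
            sequence=_PEPTIDES[peptide],
            solvent=solvent,
            temperature=298.0,
            reference=reference,
        )
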