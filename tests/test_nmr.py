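"""Tests for shift-table parsing, αCH secondary shifts and restraint accounting."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepscan import (
    CSDProfile,
    NOERestraint,
    PeptideSequence,
    ShiftRecord,
    ShiftTable,
    classify_structure,
    csd_alpha,
    datasets,
    load_random_coil,
    noe_contact_summary,
    read_shift_table,
    read_upl,
    restraint_stats,
    write_shift_table,
    write_upl,
)
from pepscan.nmr_analysis import CSDEntry, ShiftTableError, gap_category


class TestShiftTableIO:
    def test_bundled_mtp1_tfe_fixture(self):
        table = datasets.load_shift_table("MTP1", "TFE_H2O_1_1")
        assert len({r.residue_index for r in table.records}) == 15
        assert table.alpha_shift(13) == pytest.approx(3.72)
        nh13 = [r for r in table.records
                if r.residue_index == 13 and r.atom == "NH"]
        assert nh13[0].shift == pytest.approx(7.40)

    def test_bundled_mtp2_dmso_fixture(self):
        table = datasets.load_shift_table("MTP2", "DMSO")
        assert table.alpha_shift(1) == pytest.approx(3.84)

    def test_all_four_fixtures_validate(self):
        for peptide in ("MTP1", "MTP2"):
            for solvent in ("DMSO", "TFE_H2O_1_1"):
                table = datasets.load_shift_table(peptide, solvent)
                assert table.solvent == solvent

    def test_unknown_residue_code_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "residue_index\tresidue\tatom\tshift_ppm\tnote\n1\tZZZ\taCH\t4.2\t\n"
        )
        with pytest.raises(ShiftTableError, match="line 2"):
            read_shift_table(path, PeptideSequence("MA"))

    def test_residue_mismatch_rejected(self, tmp_path):
        path = tmp_path / "mismatch.tsv"
        path.write_text(
            "residue_index\tresidue\tatom\tshift_ppm\tnote\n1\tGLY\taCH\t4.2\t\n"
        )
        with pytest.raises(ShiftTableError, match="mismatch"):
            read_shift_table(path, PeptideSequence("MA"))

    def test_duplicate_alpha_record_rejected(self):
        with pytest.raises(ShiftTableError, match="duplicate aCH"):
            ShiftTable(
                peptide=PeptideSequence("MA"),
                records=(
                    ShiftRecord(1, "M", "aCH", 4.2),
                    ShiftRecord(1, "M", "aCH", 4.3),
                ),
            )

    def test_write_read_round_trip(self, tmp_path):
        table = datasets.load_shift_table("MTP2", "TFE_H2O_1_1")
        path = tmp_path / "out.tsv"
        write_shift_table(table, path)
        back = read_shift_table(
            path, datasets.MTP2, solvent="TFE_H2O_1_1", reference=table.reference
        )
        assert len(back.records) == len(table.records)
        for a, b in zip(back.records, table.records):
            assert a.residue_index == b.residue_index
            assert a.atom == b.atom
            assert a.shift == pytest.approx(b.shift, abs=5e-4)


class TestCSD:
    def _table_from_alpha(self, seq, alphas, solvent="DMSO"):
        records = tuple(
            ShiftRecord(i + 1, seq.residue_at(i + 1), "aCH", shift)
            for i, shift in enumerate(alphas)
            if shift is not None
        )
        return ShiftTable(peptide=seq, records=records, solvent=solvent)

    def test_reference_shifts_give_zero_deviation(self):
        ref = load_random_coil()
        seq = PeptideSequence("MAEAHQAVAFQFT")
        table = self._table_from_alpha(seq, [ref[r] for r in seq])
        profile = csd_alpha(table, ref)
        assert all(d == pytest.approx(0.0) for d in profile.deltas())

    def test_constructed_helix_offset(self):
        ref = load_random_coil()
        seq = PeptideSequence("KVSGVLFGTG")
        table = self._table_from_alpha(seq, [ref[r] - 0.30 for r in seq])
        profile = csd_alpha(table, ref)
        assert all(d == pytest.approx(-0.30) for d in profile.deltas())

    def test_mtp1_val13_is_helical_range(self):
        profile = csd_alpha(
            datasets.load_shift_table("MTP1", "TFE_H2O_1_1"), load_random_coil()
        )
        assert profile.entries[12].delta < -0.1

    def test_missing_alpha_left_unassigned(self):
        ref = load_random_coil()
        seq = PeptideSequence("MAE")
        table = self._table_from_alpha(seq, [4.5, None, 4.2])
        profile = csd_alpha(table, ref)
        assert profile.entries[1].delta is None
        labels = classify_structure(profile).labels
        assert labels[1] == "unassigned"

    @given(offset=st.floats(min_value=-0.5, max_value=0.5))
    @settings(max_examples=50, derandomize=True)
    def test_linearity_under_global_shift(self, offset):
        """Adding +c to every observed αCH adds exactly +c to every Δδ."""
        ref = load_random_coil()
        seq = PeptideSequence("MAEAHQAVAFQFT")
        base = [4.3, 4.4, 4.2, 4.35, 4.6, 4.3, 4.3, 4.2, 4.3, 4.6, 4.3, 4.7, 4.4]
        p0 = csd_alpha(self._table_from_alpha(seq, base), ref)
        p1 = csd_alpha(
            self._table_from_alpha(seq, [b + offset for b in base]), ref
        )
        for d0, d1 in zip(p0.deltas(), p1.deltas()):
            assert d1 - d0 == pytest.approx(offset, abs=1e-12)


class TestClassification:
    def _profile(self, deltas):
        seq = PeptideSequence("A" * len(deltas))
        entries = tuple(
            CSDEntry(index=i + 1, residue="A", delta=d) for i, d in enumerate(deltas)
        )
        return CSDProfile(peptide=seq, solvent="DMSO", entries=entries)

    def test_uniform_helix(self):
        call = classify_structure(self._profile([-0.3] * 10))
        assert call.overall == "helical"
        assert set(call.labels) == {"helical"}
        assert call.helical_runs == ((1, 10),)

    def test_uniform_coil(self):
        call = classify_structure(self._profile([0.0] * 10))
        assert call.overall == "coil"
        assert set(call.labels) == {"coil"}

    def test_isolated_dips_below_min_run_stay_coil(self):
        deltas = [0.0] * 9
        for i in (1, 4, 7):
            deltas[i] = -0.3
        call = classify_structure(self._profile(deltas), min_run=4)
        assert call.overall == "coil"

    def test_run_extraction_against_brute_force(self, rng):
        """Run labelling equals a brute-force check of every window."""
        for _ in range(50):
            deltas = list(rng.choice([-0.3, 0.0], size=20))
            call = classify_structure(self._profile(deltas), min_run=4)
            expected = [False] * 20
            for start in range(20):
                for end in range(start + 4, 21):
                    window = deltas[start:end]
                    if all(d < -0.1 for d in window):
                        for k in range(start, end):
                            expected[k] = True
            got = [label == "helical" for label in call.labels]
            assert got == expected

    def test_min_run_validation(self):
        with pytest.raises(ValueError):
            classify_structure(self._profile([0.0]), min_run=0)


class TestRestraints:
    def test_table_style_category_counts(self):
        restraints = (
            [NOERestraint(i % 15 + 1, i % 15 + 1, "HA", "HB") for i in range(60)]
            + [NOERestraint(i % 14 + 1, i % 14 + 2, "HA", "HN") for i in range(37)]
            + [NOERestraint(1, 1 + 2 + i % 3, "HA", "HN") for i in range(14)]
        )
        stats = restraint_stats(restraints, torsions=4)
        assert stats.as_dict() == {
            "total": 111, "intraresidue": 60, "sequential": 37,
            "medium_range": 14, "long_range": 0, "torsion_count": 4,
        }

    def test_empty_and_boundary(self):
        assert restraint_stats([]).total == 0
        assert gap_category(4) == "medium_range"
        assert restraint_stats([NOERestraint(1, 8, "HA", "HN")]).long_range == 1

    @given(
        pairs=st.lists(
            st.tuples(st.integers(1, 30), st.integers(1, 30)), max_size=200
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_category_conservation_fuzz(self, pairs):
        restraints = [NOERestraint(i, j, "HA", "HN") for i, j in pairs]
        stats = restraint_stats(restraints)
        assert (
            stats.intraresidue + stats.sequential + stats.medium_range
            + stats.long_range
            == stats.total
            == len(restraints)
        )

    def test_contact_summary_bands(self):
        sequential = [NOERestraint(i, i + 1, "HN", "HN") for i in range(1, 10)]
        summary = noe_contact_summary(sequential)
        assert set(summary["gap"]) == {1}
        assert set(summary["category"]) == {"sequential"}
        i3 = [NOERestraint(i, i + 3, "HA", "HN") for i in range(1, 8)]
        summary3 = noe_contact_summary(i3)
        assert set(summary3["gap"]) == {3}
        assert set(summary3["category"]) == {"medium_range"}
        assert noe_contact_summary([]).empty

    def test_upl_parse_single_line(self, tmp_path):
        path = tmp_path / "one.upl"
        path.write_text("1 LYS HA 2 VAL HN 3.5\n")
        restraints = read_upl(path)
        assert len(restraints) == 1
        assert restraints[0].gap == 1
        assert restraints[0].upper_bound == pytest.approx(3.5)

    def test_upl_comments_and_errors(self, tmp_path):
        empty = tmp_path / "comments.upl"
        empty.write_text("# nothing here\n\n# still nothing\n")
        assert read_upl(empty) == []
        bad = tmp_path / "bad.upl"
        bad.write_text("1 LYS HA 2 VAL HN -3.5\n")
        with pytest.raises(ValueError, match="line 1"):
            read_upl(bad)
        short = tmp_path / "short.upl"
        short.write_text("1 LYS HA 2 VAL 3.5\n")
        with pytest.raises(ValueError, match="7"):
            read_upl(short)

    def test_upl_round_trip(self, tmp_path):
        restraints = [
            NOERestraint(1, 2, "HA", "HN", 3.5, "LYS", "VAL"),
            NOERestraint(3, 7, "HB", "HN", 5.0, "SER", "PHE"),
        ]
        path = tmp_path / "rt.upl"
        write_upl(restraints, path)
        back = read_upl(path)
        assert back == restraints
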