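"""Prosit/MaxQuant/msp readers and the synthetic-library generator."""

import gzip

import pytest

from diasim import chem
from diasim.library_io import (LibraryError, generate_synthetic_library,
                               read_maxquant_evidence, read_msp,
                               read_prosit_library, write_prosit_csv)

PROSIT_HEADER = (
    "ModifiedPeptide,StrippedPeptide,PrecursorCharge,PrecursorMz,iRT,"
    "FragmentMz,FragmentType,FragmentNumber,FragmentCharge,RelativeIntensity\n"
)


class TestPrositReader:
    def test_two_fragment_rows_one_precursor(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text(
            PROSIT_HEADER
            + "PEPTIDEK,PEPTIDEK,2,464.73,30.1,175.119,y,1,1,0.5\n"
            + "PEPTIDEK,PEPTIDEK,2,464.73,30.1,303.178,y,2,1,1.0\n"
        )
        records = read_prosit_library(path)
        assert len(records) == 1
        record = records[0]
        assert record.charge == 2
        assert record.irt == pytest.approx(30.1)
        assert [f.rel_intensity for f in record.fragments] == [0.5, 1.0]
        assert [f.series for f in record.fragments] == ["y", "y"]

    def test_intensities_normalised_to_base_peak(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text(
            PROSIT_HEADER
            + "AAAK,AAAK,2,159.1,10,100.0,b,1,1,40\n"
            + "AAAK,AAAK,2,159.1,10,200.0,y,1,1,80\n"
        )
        record = read_prosit_library(path)[0]
        assert [f.rel_intensity for f in record.fragments] == [0.5, 1.0]

    def test_conflicting_precursor_mz_rejected(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text(
            PROSIT_HEADER
            + "AAAK,AAAK,2,159.10,10,100.0,b,1,1,1\n"
            + "AAAK,AAAK,2,159.20,10,200.0,y,1,1,1\n"
        )
        with pytest.raises(LibraryError, match="10 ppm"):
            read_prosit_library(path)

    def test_missing_columns_listed(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text("ModifiedPeptide,PrecursorCharge\nAAAK,2\n")
        with pytest.raises(LibraryError, match="iRT"):
            read_prosit_library(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "lib.csv"
        path.write_text(PROSIT_HEADER)
        with pytest.raises(LibraryError, match="empty"):
            read_prosit_library(path)


class TestSyntheticGenerator:
    def test_seeded_determinism(self):
        a = generate_synthetic_library(10, seed=1)
        b = generate_synthetic_library(10, seed=1)
        assert a == b
        c = generate_synthetic_library(10, seed=2)
        assert a != c

    def test_precursor_mz_consistent_with_chem(self, small_library):
        for record in small_library:
            comp = chem.peptide_composition(record.stripped_sequence)
            expected = chem.ion_mz(chem.monoisotopic_mass(comp), record.charge)
            assert record.precursor_mz == expected  # exact, same arithmetic path

    def test_tryptic_properties_over_large_sample(self):
        records = generate_synthetic_library(1000, seed=7)
        assert len(records) == 1000
        for record in records:
            assert record.stripped_sequence[-1] in "KR"
            assert 7 <= len(record.stripped_sequence) <= 20
            assert record.charge in (2, 3)
            assert max(f.rel_intensity for f in record.fragments) == 1.0

    def test_csv_round_trip_reproduces_records(self, small_library, tmp_path):
        path = tmp_path / "synthetic.csv"
        write_prosit_csv(small_library, path)
        back = read_prosit_library(path)
        assert len(back) == len(small_library)
        for ours, theirs in zip(small_library, back):
            assert theirs.stripped_sequence == ours.stripped_sequence
            assert theirs.modified_sequence == ours.modified_sequence
            assert theirs.charge == ours.charge
            assert theirs.precursor_mz == ours.precursor_mz
            assert theirs.irt == ours.irt
            assert theirs.base_abundance == ours.base_abundance
            assert theirs.fragments == ours.fragments

    def test_gzip_supported(self, small_library, tmp_path):
        plain = tmp_path / "lib.csv"
        write_prosit_csv(small_library[:5], plain)
        zipped = tmp_path / "lib.csv.gz"
        zipped.write_bytes(gzip.compress(plain.read_bytes()))
        assert len(read_prosit_library(zipped)) == 5


MSP_ENTRY = """Name: decoy_lipid_1
PrecursorMZ: 760.5851
Num Peaks: 3
184.0733 100.0
104.1070 25.0
86.0964 12.5

"""


class TestMspReader:
    def test_single_entry(self, tmp_path):
        path = tmp_path / "decoys.msp"
        path.write_text(MSP_ENTRY)
        records = read_msp(path)
        assert len(records) == 1
        assert records[0].precursor_mz == pytest.approx(760.5851)
        assert len(records[0].fragments) == 3
        assert records[0].fragments[0][1] == 1.0  # normalised

    def test_mw_and_charge_fallback(self, tmp_path):
        path = tmp_path / "decoys.msp"
        path.write_text(
            "Name: decoy_2\nMW: 1000.0\nCharge: 2\nNum Peaks: 1\n100.0 50.0\n"
        )
        record = read_msp(path)[0]
        assert record.precursor_mz == pytest.approx(chem.ion_mz(1000.0, 2))

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "decoys.msp"
        path.write_text("")
        assert read_msp(path) == []

    def test_peak_count_mismatch_names_entry(self, tmp_path):
        path = tmp_path / "decoys.msp"
        path.write_text(
            "Name: bad_entry\nPrecursorMZ: 500.0\nNum Peaks: 2\n100.0 50.0\n"
        )
        with pytest.raises(LibraryError, match="bad_entry"):
            read_msp(path)


EVIDENCE_HEADER = (
    "Sequence\tModifications\tCharge\tm/z\tRetention time\tIntensity\tBest MS/MS\n"
)
MSMS_HEADER = "id\tMatches\tMasses\tIntensities\n"


class TestMaxQuantReader:
    def _write(self, tmp_path, evidence_rows, msms_rows):
        (tmp_path / "evidence.txt").write_text(EVIDENCE_HEADER + evidence_rows)
        (tmp_path / "msms.txt").write_text(MSMS_HEADER + msms_rows)
        return tmp_path

    def test_minimal_record_has_observed_rt(self, tmp_path):
        directory = self._write(
            tmp_path,
            "PEPTIDEK\tUnmodified\t2\t464.73\t25.5\t1e6\t0\n",
            "0\ty1;y2\t147.11;275.21\t100;50\n",
        )
        records = read_maxquant_evidence(directory)
        assert len(records) == 1
        assert records[0].observed_rt == pytest.approx(25.5)
        assert records[0].irt is None
        assert len(records[0].fragments) == 2
        assert records[0].fragments[0].rel_intensity == 1.0

    def test_disallowed_modification_dropped(self, tmp_path, caplog):
        directory = self._write(
            tmp_path,
            "PEPTIDEK\tUnmodified\t2\t464.73\t25.5\t1e6\t0\n"
            "MPEPTIDEK\tOxidation (M)\t2\t472.73\t26.0\t1e6\t1\n"
            "CPEPTIDEK\tCarbamidomethyl (C)\t2\t516.24\t27.0\t1e6\t0\n",
            "0\ty1\t147.11\t100\n",
        )
        with caplog.at_level("WARNING"):
            records = read_maxquant_evidence(directory)
        assert [r.stripped_sequence for r in records] == ["PEPTIDEK", "CPEPTIDEK"]
        assert "modifications" in caplog.text

    def test_missing_intensity_imputed_with_median(self, tmp_path):
        rows = "".join(
            f"PEPTID{c}K\tUnmodified\t2\t464.73\t25.5\t{i}\t0\n"
            for c, i in zip("ACDEF", ["10", "20", "30", "40", ""])
        )
        directory = self._write(tmp_path, rows, "0\ty1\t147.11\t100\n")
        records = read_maxquant_evidence(directory)
        # median of (10, 20, 30, 40) = 25
        assert records[-1].base_abundance == pytest.approx(25.0)

    def test_missing_columns_rejected(self, tmp_path):
        (tmp_path / "evidence.txt").write_text("Sequence\tCharge\nPEPK\t2\n")
        (tmp_path / "msms.txt").write_text(MSMS_HEADER + "0\ty1\t147.1\t100\n")
        with pytest.raises(LibraryError, match="missing columns"):
            read_maxquant_evidence(tmp_path)

    def test_row_without_fragments_dropped_with_warning(self, tmp_path, caplog):
        directory = self._write(
            tmp_path,
            "PEPTIDEK\tUnmodified\t2\t464.73\t25.5\t1e6\t0\n"
            "AEPTIDEK\tUnmodified\t2\t450.00\t26.5\t1e6\t\n",
            "0\ty1\t147.11\t100\n",
        )
        with caplog.at_level("WARNING"):
            records = read_maxquant_evidence(directory)
        assert len(records) == 1
        assert "fragment" in caplog.text
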