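"""Spectrum synthesis: peak placement, weighting, superposition, noise."""

import numpy as np
import pytest

from diasim.acquisition import IsolationWindow, default_schema, schedule_run
from diasim.chromatography import ElutionProfile, emg_intensity
from diasim.spectra import (InstrumentModel, SimSpecies, active_species,
                            centroid_peaks_ms1, centroid_peaks_ms2, profileize,
                            simulate_run)


def make_species(species_id=0, mz=500.0, apex=100.0, abundance=1000.0,
                 sigma=2.0, tau=0.0, n_iso=3, fragments=((300.0, 1.0), (600.0, 0.5))):
    fractions = np.array([0.6, 0.3, 0.1])[:n_iso]
    return SimSpecies(
        species_id=species_id,
        label=f"sp{species_id}",
        precursor_mz=mz,
        envelope_mz=mz + np.arange(n_iso) * 0.5,
        envelope_frac=fractions,
        fragment_mz=np.array([f[0] for f in fragments]),
        fragment_rel=np.array([f[1] for f in fragments]),
        profile=ElutionProfile(apex_rt=apex, sigma=sigma, tau=tau),
        abundance=abundance,
    )


class TestActiveSpecies:
    def test_far_outside_supports_empty(self):
        profiles = {0: ElutionProfile(apex_rt=100.0, sigma=2.0)}
        assert active_species(500.0, profiles) == []

    def test_apex_weight_equals_apex_intensity(self):
        profile = ElutionProfile(apex_rt=100.0, sigma=2.0, area_scale=50.0)
        [(key, weight)] = active_species(100.0, {7: profile})
        assert key == 7
        assert weight == pytest.approx(float(emg_intensity(profile, 100.0)))

    def test_coeluting_pair_pointwise(self):
        profiles = {
            0: ElutionProfile(apex_rt=100.0, sigma=2.0),
            1: ElutionProfile(apex_rt=101.0, sigma=2.0),
        }
        result = dict(active_species(100.5, profiles))
        assert set(result) == {0, 1}
        for key, profile in profiles.items():
            assert result[key] == pytest.approx(float(emg_intensity(profile, 100.5)))


class TestCentroidPeaks:
    def test_ms1_counts_and_weighting(self):
        sp = make_species()
        inst = InstrumentModel()
        mz, inten = centroid_peaks_ms1([(sp, 10.0)], inst)
        assert len(mz) == 3
        assert inten == pytest.approx(10.0 * sp.envelope_frac)

    def test_systematic_ppm_shift(self):
        sp = make_species(mz=500.0, n_iso=1)
        inst = InstrumentModel(ppm_error_systematic=10.0)
        mz, _ = centroid_peaks_ms1([(sp, 1.0)], inst)
        assert mz[0] == pytest.approx(500.005, abs=1e-9)

    def test_shared_mz_superposes(self):
        a = make_species(species_id=0, mz=500.0, n_iso=1)
        b = make_species(species_id=1, mz=500.0, n_iso=1)
        mz, inten = centroid_peaks_ms1([(a, 2.0), (b, 3.0)], InstrumentModel())
        assert len(mz) == 1
        assert inten[0] == pytest.approx(5.0 * 0.6)

    def test_ms2_window_half_open(self):
        inst = InstrumentModel()
        window = IsolationWindow(400.0, 420.0)
        at_lower = make_species(mz=400.0)
        at_upper = make_species(species_id=1, mz=420.0)
        mz, _ = centroid_peaks_ms2(window, [(at_lower, 1.0), (at_upper, 1.0)], inst)
        assert len(mz) == 2  # only at_lower's two fragments

    def test_ms2_empty_window(self):
        mz, inten = centroid_peaks_ms2(
            IsolationWindow(900.0, 920.0), [(make_species(), 1.0)], InstrumentModel()
        )
        assert len(mz) == 0 and len(inten) == 0

    def test_ms2_union_of_two_precursors(self):
        a = make_species(species_id=0, mz=405.0, fragments=((300.0, 1.0),))
        b = make_species(species_id=1, mz=410.0, fragments=((700.0, 1.0), (800.0, 0.2)))
        window = IsolationWindow(400.0, 420.0)
        mz, inten = centroid_peaks_ms2(window, [(a, 2.0), (b, 5.0)], InstrumentModel())
        assert list(mz) == [300.0, 700.0, 800.0]
        assert inten == pytest.approx([2.0, 5.0, 1.0])

    def test_scan_range_filter(self):
        sp = make_species(mz=1999.5, n_iso=3)  # isotopes at 1999.5, 2000.0, 2000.5
        mz, _ = centroid_peaks_ms1([(sp, 1.0)], InstrumentModel(scan_range=(100, 2000)))
        assert mz.max() <= 2000.0
        assert len(mz) == 2


class TestProfileize:
    def test_gaussian_area_preserved(self):
        inst = InstrumentModel(profile_shape="gaussian", resolution=30000,
                               profile_grid_step=0.001)
        mz, inten = profileize(np.array([600.0]), np.array([1000.0]), inst)
        assert inten.sum() * 0.001 == pytest.approx(1000.0, rel=0.01)
        # FWHM check: 600/30000 = 0.02 Th
        above_half = mz[inten > inten.max() / 2]
        assert above_half.max() - above_half.min() == pytest.approx(0.02, abs=0.002)

    def test_lorentzian_tails_heavier(self):
        gauss = InstrumentModel(profile_shape="gaussian", resolution=30000,
                                profile_grid_step=0.001)
        lorentz = InstrumentModel(profile_shape="lorentzian", resolution=30000,
                                  profile_grid_step=0.001)
        fwhm = 600.0 / 30000
        probe = 600.0 + 3 * fwhm

        def value_at(inst):
            mz, inten = profileize(np.array([600.0]), np.array([1.0]), inst)
            return inten[np.argmin(np.abs(mz - probe))]

        assert value_at(lorentz) > value_at(gauss)

    def test_undersampled_grid_rejected(self):
        inst = InstrumentModel(profile_shape="gaussian", resolution=30000,
                               profile_grid_step=0.01, scan_range=(100.0, 2000.0))
        with pytest.raises(ValueError, match="undersample"):
            profileize(np.array([600.0]), np.array([1.0]), inst)


@pytest.fixture(scope="module")
def small_run_inputs():
    schema = default_schema(400, 600, 50, 0.05, 0.02)  # cycle 0.13 s
    events = schedule_run(schema, 120.0)
    species = [
        make_species(species_id=0, mz=450.0, apex=40.0, abundance=1000.0),
        make_species(species_id=1, mz=520.0, apex=60.0, abundance=500.0),
        make_species(species_id=2, mz=450.2, apex=41.0, abundance=200.0),
    ]
    return species, events


class TestSimulateRun:
    def test_seeded_determinism_bitwise(self, small_run_inputs):
        species, events = small_run_inputs
        inst = InstrumentModel(ppm_error_sd=2.0, spray_instability_sd=0.1)
        a = simulate_run(species, events, inst, seed=5)
        b = simulate_run(species, events, inst, seed=5)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.mz_array, sb.mz_array)
            assert np.array_equal(sa.intensity_array, sb.intensity_array)

    def test_abundance_doubling_is_exactly_linear(self, small_run_inputs):
        species, events = small_run_inputs
        inst = InstrumentModel(ppm_error_sd=1.0, spray_instability_sd=0.2)
        from dataclasses import replace
        doubled = [replace(species[0], abundance=species[0].abundance * 2.0)] + species[1:]
        base = simulate_run(species, events, inst, seed=5)
        twice = simulate_run(doubled, events, inst, seed=5)
        checked = 0
        for sa, sb in zip(base.spectra, twice.spectra):
            assert np.array_equal(sa.mz_array, sb.mz_array)
            ratio = np.where(sa.intensity_array > 0,
                             sb.intensity_array / sa.intensity_array, 1.0)
            assert np.all((ratio == 1.0) | (ratio == 2.0))
            checked += int(np.any(ratio == 2.0))
        assert checked > 10

    def test_noise_free_ms1_tic_traces_summed_profiles(self, small_run_inputs):
        species, events = small_run_inputs
        run = simulate_run(species, events, InstrumentModel(), seed=1)
        for spectrum in run.ms1_spectra():
            t = spectrum.scan_start_time
            expected = 0.0
            for sp in species:
                inten = sp.abundance * float(
                    emg_intensity(
                        ElutionProfile(sp.profile.apex_rt, sp.profile.sigma,
                                       sp.profile.tau), t)
                )
                from diasim.chromatography import profile_support
                t0, t1 = profile_support(sp.profile, 1e-3)
                if t0 <= t <= t1:
                    expected += inten * sp.envelope_frac.sum()
            assert spectrum.tic == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_fragments_only_in_containing_windows(self, small_run_inputs):
        species, events = small_run_inputs
        run = simulate_run(species, events, InstrumentModel(), seed=1)
        frag_sets = {0: {300.0, 600.0}, 1: {300.0, 600.0}, 2: {300.0, 600.0}}
        for spectrum in run.spectra:
            if spectrum.ms_level != 2:
                continue
            expected: set[float] = set()
            for sp in species:
                from diasim.chromatography import profile_support
                t0, t1 = profile_support(sp.profile, 1e-3)
                if spectrum.window.contains(sp.precursor_mz) and \
                        t0 <= spectrum.scan_start_time <= t1:
                    expected |= frag_sets[sp.species_id]
            assert set(spectrum.mz_array) == expected

    def test_decoy_addition_leaves_precursor_draws_unchanged(self, small_run_inputs):
        species, events = small_run_inputs
        inst = InstrumentModel(ppm_error_sd=3.0)
        decoy = SimSpecies(
            species_id=99, label="decoy", precursor_mz=580.0,
            envelope_mz=np.array([580.0]), envelope_frac=np.array([1.0]),
            fragment_mz=np.array([123.0]), fragment_rel=np.array([1.0]),
            profile=ElutionProfile(apex_rt=90.0, sigma=2.0), abundance=100.0,
            is_decoy=True,
        )
        without = simulate_run(species, events, inst, seed=5)
        with_decoy = simulate_run(species + [decoy], events, inst, seed=5)
        for sa, sb in zip(without.spectra, with_decoy.spectra):
            if sb.window is not None and sb.window.contains(580.0):
                continue  # decoy fragments live here
            keep = np.abs(sb.mz_array - 580.0) > 0.05  # decoy MS1 peak (ppm-jittered)
            assert np.array_equal(sa.mz_array, sb.mz_array[keep])
            assert np.array_equal(sa.intensity_array, sb.intensity_array[keep])

    def test_noise_rate_adds_random_centroids(self, small_run_inputs):
        species, events = small_run_inputs
        inst = InstrumentModel(noise_rate=2.0)
        run = simulate_run(species, events, inst, seed=3)
        clean = simulate_run(species, events, InstrumentModel(), seed=3)
        extra = sum(len(s.mz_array) for s in run.spectra) - sum(
            len(s.mz_array) for s in clean.spectra
        )
        assert extra == pytest.approx(2.0 * len(events), rel=0.1)

    def test_all_emitted_mz_within_scan_range(self, small_run_inputs):
        species, events = small_run_inputs
        inst = InstrumentModel(scan_range=(350.0, 550.0))
        run = simulate_run(species, events, inst, seed=2)
        for spectrum in run.spectra:
            if len(spectrum.mz_array):
                assert spectrum.mz_array.min() >= 350.0
                assert spectrum.mz_array.max() <= 550.0
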