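"""Synthesis of MS1 and DIA MS2 spectra along the scheduled run.

Every scan event yields one spectrum.  MS1 spectra contain the isotope
envelopes of all precursors eluting at the scan time, each peak weighted by
the precursor's EMG elution intensity; MS2 spectra collect the fragments of
every precursor whose m/z falls inside the event's half-open isolation
window, with the same elution weighting.  Co-eluting species superpose:
coincident m/z values (within 1e-6 Th) are summed.

Instrument imperfections: a systematic ppm mass shift plus per-peak Gaussian
ppm jitter, a per-scan multiplicative lognormal ionization-instability
factor (applied coherently to all peaks of a scan), and an optional uniform
random-centroid noise floor.  Spectra are emitted as centroids or, on
request, as Gaussian / Lorentzian / EMG profile shapes on a uniform m/z
grid.

Randomness discipline: every species draws its mass-error jitter from its
own seeded substream, and per-scan spray factors and noise peaks come from
dedicated substreams — so adding or removing decoys (or any other species)
leaves everything else bit-for-bit unchanged at a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import IsolationWindow, ScanEvent
from .chromatography import ElutionProfile, emg_density, emg_intensity, profile_support

__all__ = [
    "InstrumentModel",
    "SpectrumData",
    "SimSpecies",
    "SimulatedRun",
    "active_species",
    "centroid_peaks_ms1",
    "centroid_peaks_ms2",
    "profileize",
    "simulate_run",
]

_GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...
_MERGE_TOL = 1e-6  # Th; coincident-peak superposition tolerance


@dataclass(frozen=True)
class InstrumentModel:
    """Mass-spectral acquisition settings."""

    resolution: float = 30000.0          # FWHM-defining: FWHM = mz / resolution
    scan_range: tuple[float, float] = (100.0, 2000.0)
    ppm_error_systematic: float = 0.0
    ppm_error_sd: float = 0.0
    profile_shape: str = "centroid"      # centroid | gaussian | lorentzian | emg
    profile_grid_step: float = 0.001     # Th
    profile_emg_tail: float = 0.25       # EMG m/z tail constant, in FWHM units
    spray_instability_sd: float = 0.0    # sd of ln(per-scan intensity factor)
    abundance_to_counts: float = 1.0
    noise_rate: float = 0.0              # expected random centroids per scan
    noise_intensity: float = 100.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.ppm_error_sd < 0 or self.spray_instability_sd < 0:
            raise ValueError("error sds must be >= 0")
        if self.profile_grid_step <= 0:
            raise ValueError("profile_grid_step must be > 0")
        if self.profile_shape not in ("centroid", "gaussian", "lorentzian", "emg"):
            raise ValueError(f"unknown profile_shape {self.profile_shape!r}")


@dataclass
class SpectrumData:
    """One simulated spectrum."""

    mz_array: np.ndarray
    intensity_array: np.ndarray
    ms_level: int
    scan_start_time: float               # seconds
    window: IsolationWindow | None = None
    mode: str = "centroid"

    def __post_init__(self) -> None:
        if len(self.mz_array) != len(self.intensity_array):
            raise ValueError("m/z and intensity arrays differ in length")
        if len(self.mz_array) > 1 and np.any(np.diff(self.mz_array) <= 0):
            raise ValueError("m/z array must be strictly ascending")

    @property
    def tic(self) -> float:
        return float(self.intensity_array.sum())


@dataclass(frozen=True)
class SimSpecies:
    """A simulatable species: precursor peptide or decoy contaminant."""

    species_id: int
    label: str
    precursor_mz: float
    envelope_mz: np.ndarray        # MS1 centroid positions (1 peak for decoys)
    envelope_frac: np.ndarray      # matching isotope mole fractions
    fragment_mz: np.ndarray
    fragment_rel: np.ndarray
    profile: ElutionProfile
    abundance: float
    is_decoy: bool = False


@dataclass
class SimulatedRun:
    """Ordered spectra of one sample plus the schedule that produced them."""

    sample_name: str
    spectra: list[SpectrumData]
    events: list[ScanEvent]
    cycle_time: float
    run_length: float

    def ms1_spectra(self) -> list[SpectrumData]:
        return [s for s in self.spectra if s.ms_level == 1]


def active_species(
    t: float,
    profiles: dict[int, ElutionProfile],
    threshold_frac: float = 1e-3,
) -> list[tuple[int, float]]:
    """Species whose elution profile is above ``threshold_frac`` of its apex
    at time ``t``, with their absolute (area-scaled) elution weights."""
    if not 0 < threshold_frac < 1:
        raise ValueError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    out = []
    for key, profile in profiles.items():
        t_start, t_end = profile_support(profile, threshold_frac)
        if t_start <= t <= t_end:
            out.append((key, float(emg_intensity(profile, t))))
    return out


def _apply_ppm(mz: np.ndarray, instrument: InstrumentModel,
               rng: np.random.Generator | None) -> np.ndarray:
    ppm = np.full(mz.shape, instrument.ppm_error_systematic, dtype=float)
    if instrument.ppm_error_sd > 0:
        if rng is None:
            raise ValueError("ppm_error_sd > 0 requires an rng stream")
        ppm = ppm + rng.normal(0.0, instrument.ppm_error_sd, size=mz.shape)
    return mz * (1.0 + ppm * 1e-6)


def _merge_sorted(mz: np.ndarray, intensity: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum peaks that coincide within 1e-6 Th (input sorted by m/z)."""
    if len(mz) < 2:
        return mz, intensity
    new_group = np.empty(len(mz), dtype=bool)
    new_group[0] = True
    new_group[1:] = np.diff(mz) >= _MERGE_TOL
    if new_group.all():
        return mz, intensity
    starts = np.flatnonzero(new_group)
    return mz[starts], np.add.reduceat(intensity, starts)


def _assemble(mz: np.ndarray, intensity: np.ndarray,
              scan_range: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    keep = (mz >= scan_range[0]) & (mz <= scan_range[1]) & (intensity > 0)
    mz, intensity = mz[keep], intensity[keep]
    order = np.argsort(mz, kind="stable")
    return _merge_sorted(mz[order], intensity[order])


def centroid_peaks_ms1(
    species: list[tuple[SimSpecies, float]],
    instrument: InstrumentModel,
    rng: np.random.Generator | None = None,
    spray_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid peak list of one MS1 scan from (species, elution_weight)
    pairs.  Reference per-scan path; `simulate_run` computes the identical
    quantities in bulk."""
    mzs, intens = [], []
    for sp, weight in species:
        mzs.append(_apply_ppm(sp.envelope_mz, instrument, rng))
        intens.append(weight * sp.envelope_frac * instrument.abundance_to_counts * spray_factor)
    if not mzs:
        return np.empty(0), np.empty(0)
    return _assemble(np.concatenate(mzs), np.concatenate(intens), instrument.scan_range)


def centroid_peaks_ms2(
    window: IsolationWindow,
    species: list[tuple[SimSpecies, float]],
    instrument: InstrumentModel,
    rng: np.random.Generator | None = None,
    spray_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid peak list of one DIA MS2 scan: every fragment of every
    active species whose precursor m/z lies in the half-open window."""
    mzs, intens = [], []
    for sp, weight in species:
        if not window.contains(sp.precursor_mz):
            continue
        mzs.append(_apply_ppm(sp.fragment_mz, instrument, rng))
        intens.append(weight * sp.fragment_rel * instrument.abundance_to_counts * spray_factor)
    if not mzs:
        return np.empty(0), np.empty(0)
    return _assemble(np.concatenate(mzs), np.concatenate(intens), instrument.scan_range)


def profileize(
    mz: np.ndarray, intensity: np.ndarray, instrument: InstrumentModel
) -> tuple[np.ndarray, np.ndarray]:
    """Replace centroids by profile peak shapes on a uniform m/z grid.

    Each centroid of intensity I becomes an area-I peak (grid sum x step
    approximates I): Gaussian (sigma = FWHM/2.3548), Lorentzian
    (gamma = FWHM/2) or m/z-domain EMG with tail ``profile_emg_tail x FWHM``,
    where FWHM = mz / resolution.  Grid points are anchored at integer
    multiples of the grid step so overlapping peaks sum on shared points;
    all-zero grid regions are omitted.
    """
    step = instrument.profile_grid_step
    fwhm_min = instrument.scan_range[0] / instrument.resolution
    if step > fwhm_min / 2:
        raise ValueError(
            f"profile grid step {step} undersamples peaks: FWHM at the scan "
            f"range minimum is {fwhm_min:.6g}"
        )
    if len(mz) == 0:
        return np.empty(0), np.empty(0)
    idx_chunks, val_chunks = [], []
    for center, height in zip(mz, intensity):
        fwhm = center / instrument.resolution
        lo = int(math.ceil((center - 6 * fwhm) / step))
        hi = int(math.floor((center + 6 * fwhm) / step))
        idx = np.arange(lo, hi + 1)
        x = idx * step
        if instrument.profile_shape == "gaussian":
            sigma = fwhm / _GAUSS_FWHM
            values = height * np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        elif instrument.profile_shape == "lorentzian":
            gamma = fwhm / 2.0
            values = height * (gamma / math.pi) / ((x - center) ** 2 + gamma**2)
        else:  # emg
            sigma = fwhm / _GAUSS_FWHM
            tau = instrument.profile_emg_tail * fwhm
            values = height * emg_density(x, center, sigma, tau)
        idx_chunks.append(idx)
        val_chunks.append(values)
    all_idx = np.concatenate(idx_chunks)
    all_val = np.concatenate(val_chunks)
    uniq, inverse = np.unique(all_idx, return_inverse=True)
    summed = np.bincount(inverse, weights=all_val)
    keep = summed > 0
    return uniq[keep] * step, summed[keep]


def _species_event_hits(
    sp: SimSpecies,
    times: np.ndarray,
    levels: np.ndarray,
    win_lower: np.ndarray,
    win_upper: np.ndarray,
    threshold_frac: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of (MS1 events, MS2 events) during which the species elutes;
    MS2 restricted to windows containing the precursor m/z (half-open)."""
    t_start, t_end = profile_support(sp.profile, threshold_frac)
    i0 = int(np.searchsorted(times, t_start, side="left"))
    i1 = int(np.searchsorted(times, t_end, side="right"))
    sl = slice(i0, i1)
    lv = levels[sl]
    ms1 = np.flatnonzero(lv == 1) + i0
    in_window = (win_lower[sl] <= sp.precursor_mz) & (sp.precursor_mz < win_upper[sl])
    ms2 = np.flatnonzero((lv == 2) & in_window) + i0
    return ms1, ms2


def simulate_run(
    species: list[SimSpecies],
    events: list[ScanEvent],
    instrument: InstrumentModel,
    seed: int | list[int],
    sample_name: str = "sample",
    threshold_frac: float = 1e-3,
    run_length: float | None = None,
) -> SimulatedRun:
    """Simulate every scheduled scan event into a spectrum.

    Deterministic for a given seed.  Species contribute only within the
    support of their elution profile (intensity above ``threshold_frac`` of
    apex); a per-event lognormal spray factor multiplies all peaks of that
    event coherently.
    """
    entropy = list(seed) if isinstance(seed, (list, tuple)) else [int(seed)]
    n_events = len(events)
    times = np.array([e.start_time for e in events])
    levels = np.array([e.ms_level for e in events], dtype=np.int8)
    win_lower = np.array(
        [e.window.lower_mz if e.window else np.nan for e in events]
    )
    win_upper = np.array(
        [e.window.upper_mz if e.window else np.nan for e in events]
    )

    spray_rng = np.random.default_rng(np.random.SeedSequence(entropy + [0x5978A1]))
    if instrument.spray_instability_sd > 0:
        spray = np.exp(spray_rng.normal(0.0, instrument.spray_instability_sd, n_events))
    else:
        spray = np.ones(n_events)

    ev_chunks: list[np.ndarray] = []
    mz_chunks: list[np.ndarray] = []
    int_chunks: list[np.ndarray] = []
    for sp in species:
        if sp.abundance <= 0 or not np.isfinite(sp.abundance):
            continue
        ms1_idx, ms2_idx = _species_event_hits(
            sp, times, levels, win_lower, win_upper, threshold_frac
        )
        jitter_rng = (
            np.random.default_rng(np.random.SeedSequence(entropy + [0x9914, sp.species_id]))
            if instrument.ppm_error_sd > 0
            else None
        )
        prof = sp.profile
        if len(ms1_idx) and len(sp.envelope_mz):
            weights = sp.abundance * emg_density(times[ms1_idx], prof.apex_rt, prof.sigma, prof.tau)
            k = len(sp.envelope_mz)
            mz = np.tile(sp.envelope_mz, len(ms1_idx))
            mz = _apply_ppm(mz, instrument, jitter_rng)
            inten = (weights[:, None] * sp.envelope_frac[None, :]).ravel()
            ev_chunks.append(np.repeat(ms1_idx, k))
            mz_chunks.append(mz)
            int_chunks.append(inten)
        if len(ms2_idx) and len(sp.fragment_mz):
            weights = sp.abundance * emg_density(times[ms2_idx], prof.apex_rt, prof.sigma, prof.tau)
            k = len(sp.fragment_mz)
            mz = np.tile(sp.fragment_mz, len(ms2_idx))
            mz = _apply_ppm(mz, instrument, jitter_rng)
            inten = (weights[:, None] * sp.fragment_rel[None, :]).ravel()
            ev_chunks.append(np.repeat(ms2_idx, k))
            mz_chunks.append(mz)
            int_chunks.append(inten)

    if instrument.noise_rate > 0:
        noise_rng = np.random.default_rng(np.random.SeedSequence(entropy + [0x901213]))
        counts = noise_rng.poisson(instrument.noise_rate, n_events)
        total = int(counts.sum())
        if total:
            ev_chunks.append(np.repeat(np.arange(n_events), counts))
            mz_chunks.append(noise_rng.uniform(*instrument.scan_range, total))
            int_chunks.append(noise_rng.uniform(0.0, instrument.noise_intensity, total))

    if ev_chunks:
        ev = np.concatenate(ev_chunks)
        mz = np.concatenate(mz_chunks)
        inten = np.concatenate(int_chunks) * instrument.abundance_to_counts
        inten = inten * spray[ev]
        lo, hi = instrument.scan_range
        keep = (mz >= lo) & (mz <= hi) & (inten > 0)
        ev, mz, inten = ev[keep], mz[keep], inten[keep]
        order = np.lexsort((mz, ev))
        ev, mz, inten = ev[order], mz[order], inten[order]
        bounds = np.searchsorted(ev, np.arange(n_events + 1))
    else:
        bounds = np.zeros(n_events + 1, dtype=int)
        mz = np.empty(0)
        inten = np.empty(0)

    mode = "centroid" if instrument.profile_shape == "centroid" else "profile"
    spectra: list[SpectrumData] = []
    for pos, event in enumerate(events):
        a, b = bounds[pos], bounds[pos + 1]
        peak_mz, peak_int = _merge_sorted(mz[a:b], inten[a:b])
        if instrument.profile_shape != "centroid":
            peak_mz, peak_int = profileize(peak_mz, peak_int, instrument)
        spectra.append(
            SpectrumData(
                mz_array=peak_mz,
                intensity_array=peak_int,
                ms_level=event.ms_level,
                scan_start_time=event.start_time,
                window=event.window,
                mode=mode,
            )
        )
    cycle = 0.0
    ms1_times = times[levels == 1]
    if len(ms1_times) > 1:
        cycle = float(ms1_times[1] - ms1_times[0])
    return SimulatedRun(
        sample_name=sample_name,
        spectra=spectra,
        events=events,
        cycle_time=cycle,
        run_length=run_length if run_length is not None else float(times[-1]),
    )
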