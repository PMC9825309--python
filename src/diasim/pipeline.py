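"""End-to-end orchestration: library -> design -> schedule -> spectra -> files.

``run_simulation`` is the single entry point behind both the Python API and
the CLI.  Given a resolved configuration it loads (or generates) the
precursor library, expands the study design, schedules the acquisition,
synthesises every sample's spectra and — when an output directory is given —
writes the four output artifacts: one mzML per sample, the ground-truth
TSV, a replay yaml and the resolved-parameter yaml.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import chem
from .acquisition import (AcquisitionSchema, ScanEvent, default_schema,
                          expected_points_per_peak, read_schema, schedule_run)
from .chromatography import ElutionProfile, GradientModel, make_profiles, map_rt
from .config import ConfigError, RunConfig
from .library_io import (DecoyRecord, PrecursorRecord, generate_synthetic_library,
                         read_maxquant_evidence, read_msp, read_prosit_library)
from .output_io import (ReplayBundle, ground_truth_frame,
                        library_fingerprint_from_file, read_mzml_spectra,
                        read_replay, write_ground_truth, write_mzml,
                        write_params_yaml, write_replay)
from .spectra import (InstrumentModel, SimSpecies, SimulatedRun, SpectrumData,
                      simulate_run)
from .study_design import (AbundanceMatrix, StudyDesign, apply_missingness,
                           place_decoys, sample_abundances, sample_names)

logger = logging.getLogger(__name__)

__all__ = ["SimulationResult", "run_simulation", "replay", "preview",
           "load_run_from_mzml", "PreviewResult"]


@dataclass
class SimulationResult:
    """All artifacts of one simulation, in memory."""

    config: RunConfig
    records: list[PrecursorRecord]
    decoys: list[DecoyRecord]
    gradient: GradientModel
    schema: AcquisitionSchema
    events: list[ScanEvent]
    matrix: AbundanceMatrix
    apex_rts: np.ndarray
    profiles: list[ElutionProfile]
    truth: pd.DataFrame
    runs: dict[str, SimulatedRun] = field(default_factory=dict)
    out_dir: Path | None = None
    library_fingerprint: str = ""


def _load_library(config: RunConfig) -> tuple[list[PrecursorRecord], str]:
    sources = [s for s in ("library_csv", "maxquant_dir", "synthetic_n")
               if config.get(s) is not None]
    if len(sources) != 1:
        raise ConfigError(
            f"exactly one library source required, got {sources or 'none'} "
            "(set library_csv, maxquant_dir or synthetic_n)"
        )
    source = sources[0]
    if source == "library_csv":
        records = read_prosit_library(config["library_csv"])
        fingerprint = library_fingerprint_from_file(config["library_csv"])
    elif source == "maxquant_dir":
        records = read_maxquant_evidence(config["maxquant_dir"])
        root = Path(config["maxquant_dir"])
        evidence = root / "evidence.txt" if root.is_dir() else root
        fingerprint = library_fingerprint_from_file(evidence)
    else:
        n = int(config["synthetic_n"])
        records = generate_synthetic_library(n, seed=int(config["seed"]))
        fingerprint = hashlib.sha256(
            f"synthetic:{n}:{int(config['seed'])}".encode()
        ).hexdigest()
    if not records:
        raise ConfigError("library source produced no precursor records")
    return records, fingerprint


def _build_instrument(config: RunConfig) -> InstrumentModel:
    return InstrumentModel(
        resolution=config["resolution"],
        scan_range=(config["scan_range_min"], config["scan_range_max"]),
        ppm_error_systematic=config["ppm_systematic"],
        ppm_error_sd=config["ppm_sd"],
        profile_shape=config["profile_shape"],
        profile_grid_step=config["grid_step"],
        profile_emg_tail=config["profile_emg_tail"],
        spray_instability_sd=config["spray_instability_sd"],
        abundance_to_counts=config["abundance_to_counts"],
        noise_rate=config["noise_rate"],
        noise_intensity=config["noise_intensity"],
    )


def _build_design(config: RunConfig) -> StudyDesign:
    return StudyDesign(
        n_groups=config["n_groups"],
        n_replicates_per_group=config["n_replicates"],
        between_group_log2_sd=config["between_group_log2_sd"],
        within_group_log2_sd=config["within_group_log2_sd"],
        prob_missing_group=config["prob_missing_group"],
        prob_missing_sample=config["prob_missing_sample"],
        seed=int(config["seed"]),
    )


def _envelope_arrays(
    record: PrecursorRecord, max_peaks: int, min_fraction: float,
    cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]],
) -> tuple[np.ndarray, np.ndarray]:
    """Isotope peak offsets anchored at the record's precursor m/z.

    Mole fractions come from the peptide's elemental composition
    (carbamidomethyl-Cys fixed); positions are the library's precursor m/z
    plus aggregate-neutron spacings, so the ground-truth m/z stays exact
    even if the library's value differs minutely from our own mass scale.
    """
    key = (record.stripped_sequence, record.charge)
    if key not in cache:
        comp = chem.peptide_composition(record.stripped_sequence)
        envelope = chem.isotope_envelope(comp, max_peaks=max_peaks,
                                         min_fraction=min_fraction)
        offsets = np.round(
            (envelope.mz - envelope.mz[0]) / chem.NEUTRON_DELTA
        ).astype(int)
        mz = record.precursor_mz + offsets * chem.NEUTRON_DELTA / record.charge
        cache[key] = (mz, envelope.rel_abundance)
    return cache[key]


def _build_species_template(
    records: list[PrecursorRecord],
    profiles: list[ElutionProfile],
    decoys: list[DecoyRecord],
    decoy_profiles: list[ElutionProfile],
    config: RunConfig,
) -> list[SimSpecies]:
    cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    species: list[SimSpecies] = []
    for i, record in enumerate(records):
        env_mz, env_frac = _envelope_arrays(
            record, int(config["max_isotope_peaks"]),
            config["min_isotope_fraction"], cache,
        )
        species.append(
            SimSpecies(
                species_id=i,
                label=f"{record.modified_sequence}/{record.charge}",
                precursor_mz=record.precursor_mz,
                envelope_mz=env_mz,
                envelope_frac=env_frac,
                fragment_mz=np.array([f.mz for f in record.fragments]),
                fragment_rel=np.array([f.rel_intensity for f in record.fragments]),
                profile=profiles[i],
                abundance=record.base_abundance,
            )
        )
    n = len(records)
    for j, (decoy, profile) in enumerate(zip(decoys, decoy_profiles)):
        frag = np.array(decoy.fragments) if decoy.fragments else np.empty((0, 2))
        species.append(
            SimSpecies(
                species_id=n + j,
                label=f"decoy:{decoy.name}",
                precursor_mz=decoy.precursor_mz,
                envelope_mz=np.array([decoy.precursor_mz]),
                envelope_frac=np.array([1.0]),
                fragment_mz=frag[:, 0] if len(frag) else np.empty(0),
                fragment_rel=frag[:, 1] if len(frag) else np.empty(0),
                profile=profile,
                abundance=decoy.base_abundance,
                is_decoy=True,
            )
        )
    return species


def run_simulation(
    config: RunConfig | Mapping[str, Any],
    out_dir: str | Path | None = None,
) -> SimulationResult:
    """Run a full simulation; write the output contract if ``out_dir`` given."""
    if not isinstance(config, RunConfig):
        config = RunConfig.resolve(overrides=config)
    t0 = time.perf_counter()
    seed = int(config["seed"])

    records, fingerprint = _load_library(config)
    logger.info("library: %d precursors", len(records))

    coords = np.array([r.rt_coordinate for r in records])
    gradient = GradientModel(
        run_length=config["run_length"],
        rt_window=(float(coords.min()), float(coords.max())),
        padding=config.rt_padding_resolved,
    )
    apex_rts = np.array([map_rt(c, gradient) for c in coords])
    profiles = make_profiles(
        apex_rts,
        sigma=config["peak_sigma"],
        tau=config["peak_tau"],
        sigma_cv=config["sigma_cv"],
        rng=np.random.default_rng(np.random.SeedSequence([seed, 0xC40])),
    )

    decoys: list[DecoyRecord] = []
    if config.get("msp_path"):
        decoys = read_msp(config["msp_path"])
        decoys = place_decoys(
            decoys, gradient,
            np.random.default_rng(np.random.SeedSequence([seed, 0xDEC0])),
        )
        logger.info("decoys: %d from %s", len(decoys), config["msp_path"])
    decoy_profiles = [
        ElutionProfile(apex_rt=d.assigned_rt, sigma=config["peak_sigma"],
                       tau=config["peak_tau"])
        for d in decoys
    ]

    design = _build_design(config)
    matrix = apply_missingness(sample_abundances(records, design), design)

    if config.get("schema_path"):
        schema = read_schema(config["schema_path"])
    else:
        schema = default_schema(
            config["mz_min"], config["mz_max"], config["window_width"],
            config["ms1_duration"], config["ms2_duration"],
        )
    events = schedule_run(schema, config["run_length"])
    logger.info("schedule: %d events/cycle, cycle %.3f s, %d events total",
                len(schema.events), schema.cycle_time, len(events))

    instrument = _build_instrument(config)
    template = _build_species_template(records, profiles, decoys, decoy_profiles, config)
    n_precursors = len(records)

    truth = ground_truth_frame(matrix, records, apex_rts, decoys)
    runs: dict[str, SimulatedRun] = {}
    for sample_idx, sample in enumerate(sample_names(design)):
        abundances = matrix.abundances[sample].to_numpy(float)
        species = [
            replace(sp, abundance=float(abundances[sp.species_id]))
            if sp.species_id < n_precursors else sp
            for sp in template
        ]
        run = simulate_run(
            species, events, instrument,
            seed=[seed, sample_idx],
            sample_name=sample,
            threshold_frac=config["elution_threshold_frac"],
            run_length=config["run_length"],
        )
        run.cycle_time = schema.cycle_time
        runs[sample] = run
        logger.info("sample %s: %d spectra", sample, len(run.spectra))

    result = SimulationResult(
        config=config, records=records, decoys=decoys, gradient=gradient,
        schema=schema, events=events, matrix=matrix, apex_rts=apex_rts,
        profiles=profiles, truth=truth, runs=runs,
        library_fingerprint=fingerprint,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    logger.info("simulation finished in %.1f s", time.perf_counter() - t0)
    return result


def write_outputs(result: SimulationResult, out_dir: str | Path) -> Path:
    """Write the four-artifact output contract into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample, run in result.runs.items():
        write_mzml(run, out_dir / f"{sample}.mzml")
    write_ground_truth(result.matrix, result.records, result.apex_rts,
                       out_dir / "ground_truth.tsv", result.decoys)
    write_replay(
        ReplayBundle(
            config=dict(result.config),
            seed=int(result.config["seed"]),
            library_fingerprint=result.library_fingerprint,
        ),
        out_dir / "replay.yaml",
    )
    write_params_yaml(dict(result.config), out_dir / "parameters.yaml")
    result.out_dir = out_dir
    return out_dir


def replay(replay_path: str | Path, out_dir: str | Path | None = None) -> SimulationResult:
    """Re-run a recorded simulation; errors if the library file has changed."""
    bundle = read_replay(replay_path)
    config = RunConfig.resolve(overrides=bundle.config)
    _, fingerprint = _load_library(config)
    if fingerprint != bundle.library_fingerprint:
        raise ConfigError(
            "library fingerprint mismatch: replay file recorded "
            f"{bundle.library_fingerprint[:12]}..., current library is "
            f"{fingerprint[:12]}..."
        )
    result = run_simulation(config)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def load_run_from_mzml(path: str | Path, sample_name: str | None = None) -> SimulatedRun:
    """Reconstruct a (spectra-only) run from an mzML file for validation."""
    from .acquisition import IsolationWindow

    spectra = []
    for entry in read_mzml_spectra(path):
        window = None
        if entry["ms_level"] == 2 and "window" in entry:
            window = IsolationWindow(*entry["window"])
        spectra.append(
            SpectrumData(
                mz_array=np.asarray(entry["mz_array"], dtype=float),
                intensity_array=np.asarray(entry["intensity_array"], dtype=float),
                ms_level=entry["ms_level"],
                scan_start_time=entry["scan_start_time"],
                window=window,
            )
        )
    times = [s.scan_start_time for s in spectra if s.ms_level == 1]
    cycle = times[1] - times[0] if len(times) > 1 else 0.0
    return SimulatedRun(
        sample_name=sample_name or Path(path).stem,
        spectra=spectra,
        events=[],
        cycle_time=cycle,
        run_length=spectra[-1].scan_start_time if spectra else 0.0,
    )


@dataclass
class PreviewResult:
    record: PrecursorRecord
    apex_rt: float
    window_indices: list[int]
    expected_ppp: dict[int, float]
    xic_times: np.ndarray
    xic_intensities: np.ndarray
    ms1_spectrum: SpectrumData | None
    ms2_spectrum: SpectrumData | None
    summary: str = ""


def preview(
    config: RunConfig | Mapping[str, Any], selector: str
) -> PreviewResult:
    """Simulate a single precursor over only the scans it elutes in.

    ``selector`` is a stripped or modified sequence, optionally with
    ``/charge`` (e.g. ``"AAAPGVEDEPLLR/2"``).  Matching zero or several
    precursors is an error listing the near-matches.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.resolve(overrides=config)
    seed = int(config["seed"])
    records, _ = _load_library(config)

    sequence, _, charge_text = selector.partition("/")
    matches = [
        (i, r) for i, r in enumerate(records)
        if sequence in (r.stripped_sequence, r.modified_sequence)
        and (not charge_text or r.charge == int(charge_text))
    ]
    if len(matches) != 1:
        near = [f"{r.stripped_sequence}/{r.charge}" for _, r in matches[:5]] or [
            f"{r.stripped_sequence}/{r.charge}"
            for r in records if sequence[:4] in r.stripped_sequence
        ][:5]
        raise ConfigError(
            f"selector {selector!r} matched {len(matches)} precursors; "
            f"candidates: {near}"
        )
    idx, record = matches[0]

    coords = np.array([r.rt_coordinate for r in records])
    gradient = GradientModel(
        run_length=config["run_length"],
        rt_window=(float(coords.min()), float(coords.max())),
        padding=config.rt_padding_resolved,
    )
    apex = map_rt(record.rt_coordinate, gradient)
    profile = ElutionProfile(apex_rt=apex, sigma=config["peak_sigma"],
                             tau=config["peak_tau"])
    if config.get("schema_path"):
        schema = read_schema(config["schema_path"])
    else:
        schema = default_schema(config["mz_min"], config["mz_max"],
                                config["window_width"], config["ms1_duration"],
                                config["ms2_duration"])
    events = schedule_run(schema, config["run_length"])
    from .chromatography import profile_support

    t_start, t_end = profile_support(profile, config["elution_threshold_frac"])
    subset = [e for e in events if t_start <= e.start_time <= t_end]

    species = _build_species_template([record], [profile], [], [], config)
    run = simulate_run(
        species, subset, _build_instrument(config),
        seed=[seed, 0], sample_name="preview",
        threshold_frac=config["elution_threshold_frac"],
        run_length=config["run_length"],
    )
    window_indices = [
        i for i, w in enumerate(schema.windows) if w.contains(record.precursor_mz)
    ]
    ms1 = [s for s in run.spectra if s.ms_level == 1]
    ms2 = [
        s for s in run.spectra
        if s.ms_level == 2 and s.window and s.window.contains(record.precursor_mz)
    ]
    nearest = lambda spectra: (
        min(spectra, key=lambda s: abs(s.scan_start_time - apex)) if spectra else None
    )
    xic_times = np.array([s.scan_start_time for s in ms1])
    xic = np.array([s.intensity_array.sum() for s in ms1])
    ppp = expected_points_per_peak(schema, profile)
    summary = (
        f"precursor {record.modified_sequence}/{record.charge}+  "
        f"m/z {record.precursor_mz:.4f}  apex RT {apex:.2f} s  "
        f"windows {window_indices}  expected PPP "
        + ", ".join(f"MS{lvl}: {v:.1f}" for lvl, v in sorted(ppp.items()))
    )
    return PreviewResult(
        record=record, apex_rt=apex, window_indices=window_indices,
        expected_ppp=ppp, xic_times=xic_times, xic_intensities=xic,
        ms1_spectrum=nearest(ms1), ms2_spectrum=nearest(ms2), summary=summary,
    )
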