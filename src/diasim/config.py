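"""Configuration registry and resolution.

Every tunable of the simulator has exactly one entry here, with a default
and a help string.  A run resolves its settings in the order
defaults < config file (yaml) < explicit overrides (e.g. CLI flags);
unknown keys are rejected at every layer, and the fully resolved mapping —
including untouched defaults — is what gets written to the parameter yaml
of each simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["ConfigKey", "REGISTRY", "RunConfig", "ConfigError", "default_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ConfigKey:
    name: str
    default: Any
    type: type
    help: str


def _k(name: str, default: Any, typ: type, help: str) -> ConfigKey:
    return ConfigKey(name, default, typ, help)


_KEYS: list[ConfigKey] = [
    # ---- library source (exactly one) ----
    _k("library_csv", None, str, "Prosit-style spectral library CSV path."),
    _k("maxquant_dir", None, str, "MaxQuant txt directory (evidence.txt + msms.txt)."),
    _k("synthetic_n", None, int, "Generate a synthetic library with this many precursors."),
    _k("msp_path", None, str, "Optional NIST .msp decoy library path."),
    # ---- global ----
    _k("seed", 0, int, "Master seed; every random draw derives from it."),
    # ---- chromatography ----
    _k("run_length", 300.0, float, "Gradient/run length in seconds."),
    _k("rt_padding", None, float,
       "Elution-free padding at run start/end, seconds (default: 5% of run_length)."),
    _k("peak_sigma", 2.5, float, "Gaussian width of elution peaks, seconds."),
    _k("peak_tau", 0.3, float, "Exponential tailing constant of elution peaks, seconds."),
    _k("sigma_cv", 0.0, float, "CV of lognormal per-precursor peak-width jitter."),
    # ---- acquisition ----
    _k("mz_min", 400.0, float, "Lower bound of the DIA precursor window range, Th."),
    _k("mz_max", 1000.0, float, "Upper bound of the DIA precursor window range, Th."),
    _k("window_width", 20.0, float, "Width of default fixed DIA windows, Th."),
    _k("ms1_duration", 0.05, float, "MS1 scan-event duration, seconds."),
    _k("ms2_duration", 0.02, float, "MS2 scan-event duration, seconds."),
    _k("schema_path", None, str, "Acquisition-schema CSV overriding the default windows."),
    # ---- instrument / spectra ----
    _k("resolution", 30000.0, float, "Resolving power; peak FWHM = m/z / resolution."),
    _k("scan_range_min", 100.0, float, "Lower m/z bound of emitted peaks, Th."),
    _k("scan_range_max", 2000.0, float, "Upper m/z bound of emitted peaks, Th."),
    _k("profile_shape", "centroid", str,
       "Peak representation: centroid, gaussian, lorentzian or emg."),
    _k("grid_step", 0.001, float, "Profile-mode m/z grid step, Th."),
    _k("profile_emg_tail", 0.25, float, "Profile-mode EMG tail constant, in FWHM units."),
    _k("ppm_systematic", 0.0, float, "Systematic mass error, ppm."),
    _k("ppm_sd", 0.0, float, "Per-peak Gaussian mass-error jitter sd, ppm."),
    _k("spray_instability_sd", 0.0, float,
       "Sd of ln(per-scan lognormal ionization-instability factor)."),
    _k("abundance_to_counts", 1.0, float, "Abundance-to-detector-counts scale factor."),
    _k("noise_rate", 0.0, float, "Expected random noise centroids per scan."),
    _k("noise_intensity", 100.0, float, "Upper bound of uniform noise-peak intensity."),
    _k("elution_threshold_frac", 1e-3, float,
       "Fraction of apex intensity below which a species stops contributing."),
    # ---- isotope envelopes ----
    _k("max_isotope_peaks", 5, int, "Isotope peaks simulated per precursor."),
    _k("min_isotope_fraction", 1e-4, float, "Drop envelope peaks below this mole fraction."),
    # ---- study design ----
    _k("n_groups", 1, int, "Number of treatment groups."),
    _k("n_replicates", 1, int, "Replicates per group (one mzML per sample)."),
    _k("between_group_log2_sd", 1.0, float, "Sd of per-precursor group log2 fold changes."),
    _k("within_group_log2_sd", 0.2, float, "Sd of within-group replicate log2 noise."),
    _k("prob_missing_group", 0.0, float, "P(precursor absent from an entire group)."),
    _k("prob_missing_sample", 0.0, float, "P(precursor absent from a single sample)."),
    # ---- validation ----
    _k("xic_ppm_tol", 10.0, float, "XIC extraction tolerance, ppm."),
]

REGISTRY: dict[str, ConfigKey] = {key.name: key for key in _KEYS}


def default_config() -> dict[str, Any]:
    return {key.name: key.default for key in _KEYS}


def _coerce(key: ConfigKey, value: Any) -> Any:
    if value is None:
        return None
    if key.type is float and isinstance(value, (int, float)):
        return float(value)
    if key.type is int:
        if isinstance(value, float) and not value.is_integer():
            raise ConfigError(f"{key.name}: expected integer, got {value}")
        return int(value)
    if key.type is str:
        return str(value)
    return key.type(value)


class RunConfig(dict):
    """Fully resolved configuration mapping (a dict with validation)."""

    @classmethod
    def resolve(
        cls,
        config_file: str | Path | None = None,
        overrides: Mapping[str, Any] | None = None,
    ) -> "RunConfig":
        merged = default_config()
        for layer_name, layer in (("config file", _load_file(config_file)),
                                  ("overrides", dict(overrides or {}))):
            unknown = set(layer) - set(REGISTRY)
            if unknown:
                raise ConfigError(f"unknown {layer_name} keys: {sorted(unknown)}")
            for name, value in layer.items():
                merged[name] = _coerce(REGISTRY[name], value)
        return cls(merged)

    @property
    def rt_padding_resolved(self) -> float:
        if self["rt_padding"] is not None:
            return float(self["rt_padding"])
        return 0.05 * float(self["run_length"])


def _load_file(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return data
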