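"""Spectral-library input: Prosit-style CSV, MaxQuant-style evidence tables,
NIST ``.msp`` decoy libraries, and a seeded synthetic-library generator.

All readers transparently accept gzip-compressed files.  Fragment relative
intensities are normalised to base peak = 1 within each precursor so that
Prosit, MaxQuant and synthetic sources are commensurable.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentRecord",
    "PrecursorRecord",
    "DecoyRecord",
    "SyntheticLibraryParams",
    "read_prosit_library",
    "read_maxquant_evidence",
    "read_msp",
    "generate_synthetic_library",
    "write_prosit_csv",
    "PROSIT_COLUMNS",
    "MAXQUANT_EVIDENCE_COLUMNS",
    "MAXQUANT_MSMS_COLUMNS",
]


class LibraryError(ValueError):
    """Raised for malformed or inconsistent library files."""


@dataclass(frozen=True)
class FragmentRecord:
    """One product ion of a precursor."""

    series: str           # "b" / "y" / "other"
    index: int            # residue count from the relevant terminus (0 if n/a)
    charge: int
    mz: float
    rel_intensity: float  # fraction of the precursor's base peak, in (0, 1]

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise LibraryError(f"fragment m/z must be > 0, got {self.mz}")
        if not 0 < self.rel_intensity <= 1:
            raise LibraryError(
                f"fragment rel_intensity must be in (0, 1], got {self.rel_intensity}"
            )


@dataclass(frozen=True)
class PrecursorRecord:
    """One peptide precursor ion and its fragment complement."""

    stripped_sequence: str
    modified_sequence: str
    charge: int
    precursor_mz: float
    fragments: tuple[FragmentRecord, ...]
    source: str                      # prosit | maxquant | synthetic | decoy
    irt: float | None = None         # Prosit / synthetic retention coordinate
    observed_rt: float | None = None # MaxQuant retention time, minutes
    base_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise LibraryError(f"charge must be >= 1, got {self.charge}")
        if self.precursor_mz <= 0:
            raise LibraryError(f"precursor m/z must be > 0, got {self.precursor_mz}")
        if (self.irt is None) == (self.observed_rt is None):
            raise LibraryError(
                "exactly one of irt / observed_rt must be set "
                f"({self.modified_sequence}/{self.charge})"
            )

    @property
    def rt_coordinate(self) -> float:
        return self.irt if self.irt is not None else self.observed_rt


@dataclass(frozen=True)
class DecoyRecord:
    """A non-peptide species (contaminant/noise surrogate) from an .msp file."""

    name: str
    precursor_mz: float
    fragments: tuple[tuple[float, float], ...]  # (mz, rel_intensity)
    assigned_rt: float | None = None            # set at simulation time
    base_abundance: float = 1.0

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0:
            raise LibraryError(f"decoy precursor m/z must be > 0, got {self.precursor_mz}")


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


# Default column names of a generic Prosit library export; remap with the
# ``column_map`` argument when a dialect differs.
PROSIT_COLUMNS = {
    "modified_sequence": "ModifiedPeptide",
    "stripped_sequence": "StrippedPeptide",
    "precursor_charge": "PrecursorCharge",
    "precursor_mz": "PrecursorMz",
    "irt": "iRT",
    "fragment_mz": "FragmentMz",
    "fragment_type": "FragmentType",
    "fragment_number": "FragmentNumber",
    "fragment_charge": "FragmentCharge",
    "relative_intensity": "RelativeIntensity",
}
#: Optional Prosit column carrying a precursor abundance (non-standard).
PROSIT_ABUNDANCE_COLUMN = "PrecursorAbundance"


def read_prosit_library(
    path: str | Path, column_map: dict[str, str] | None = None
) -> list[PrecursorRecord]:
    """Read a Prosit-style spectral-library CSV.

    Rows are grouped by (modified sequence, charge) into one
    :class:`PrecursorRecord` each, in order of first appearance.  Conflicting
    precursor m/z values within a group (>10 ppm apart) are an error.
    """
    cols = dict(PROSIT_COLUMNS)
    cols.update(column_map or {})
    table = pd.read_csv(path, float_precision="round_trip")
    if table.empty:
        raise LibraryError(f"empty Prosit library: {path}")
    missing = [c for c in cols.values() if c not in table.columns]
    if missing:
        raise LibraryError(f"Prosit library missing columns: {missing}")
    has_abundance = PROSIT_ABUNDANCE_COLUMN in table.columns

    records: list[PrecursorRecord] = []
    keys = table[[cols["modified_sequence"], cols["precursor_charge"]]].apply(tuple, axis=1)
    for (modified, charge), group in table.groupby(keys, sort=False):
        mzs = group[cols["precursor_mz"]].to_numpy(float)
        if (mzs.max() - mzs.min()) / mzs.mean() > 10e-6:
            raise LibraryError(
                f"conflicting precursor m/z for {modified}/{charge}: "
                f"{mzs.min()} vs {mzs.max()} (>10 ppm)"
            )
        rel = group[cols["relative_intensity"]].to_numpy(float)
        top = rel.max()
        if top <= 0:
            raise LibraryError(f"no positive fragment intensity for {modified}/{charge}")
        fragments = tuple(
            FragmentRecord(
                series=str(row[cols["fragment_type"]]),
                index=int(row[cols["fragment_number"]]),
                charge=int(row[cols["fragment_charge"]]),
                mz=float(row[cols["fragment_mz"]]),
                rel_intensity=float(row[cols["relative_intensity"]]) / top,
            )
            for _, row in group.iterrows()
            if float(row[cols["relative_intensity"]]) > 0
        )
        records.append(
            PrecursorRecord(
                stripped_sequence=str(group.iloc[0][cols["stripped_sequence"]]),
                modified_sequence=str(modified),
                charge=int(charge),
                precursor_mz=float(mzs[0]),
                fragments=fragments,
                source="prosit",
                irt=float(group.iloc[0][cols["irt"]]),
                base_abundance=float(group.iloc[0][PROSIT_ABUNDANCE_COLUMN])
                if has_abundance
                else 1.0,
            )
        )
    return records


MAXQUANT_EVIDENCE_COLUMNS = {
    "sequence": "Sequence",
    "modifications": "Modifications",
    "charge": "Charge",
    "mz": "m/z",
    "retention_time": "Retention time",
    "intensity": "Intensity",
    "msms_id": "Best MS/MS",
}
MAXQUANT_MSMS_COLUMNS = {
    "id": "id",
    "matches": "Matches",
    "masses": "Masses",
    "intensities": "Intensities",
}

#: Modification strings accepted by the simulator (fixed Cys alkylation only).
_ALLOWED_MODIFICATIONS = {"unmodified"}


def _modifications_allowed(text: str) -> bool:
    text = str(text).strip().lower()
    if text in _ALLOWED_MODIFICATIONS or text == "" or text == "nan":
        return True
    # e.g. "2 Carbamidomethyl (C)" — allowed as the single fixed modification
    parts = [p.strip() for p in text.split(",")]
    return all("carbamidomethyl" in p for p in parts)


def _parse_match_token(token: str) -> tuple[str, int]:
    token = token.strip()
    if len(token) > 1 and token[0] in "by" and token[1:].split("-")[0].isdigit():
        return token[0], int(token[1:].split("-")[0])
    return "other", 0


def read_maxquant_evidence(
    path: str | Path,
    evidence_map: dict[str, str] | None = None,
    msms_map: dict[str, str] | None = None,
) -> list[PrecursorRecord]:
    """Read an evidence/msms column subset of a MaxQuant ``txt`` output.

    ``path`` may be the txt directory (containing ``evidence.txt`` and
    ``msms.txt``) or the evidence file itself (with ``msms.txt`` alongside).
    Rows with modifications other than carbamidomethyl-Cys, and rows without
    linked fragment data, are dropped with logged counts.  Missing precursor
    intensities are imputed with the library median.
    """
    path = Path(path)
    if path.is_dir():
        evidence_path, msms_path = path / "evidence.txt", path / "msms.txt"
    else:
        evidence_path, msms_path = path, path.parent / "msms.txt"
    ecols = dict(MAXQUANT_EVIDENCE_COLUMNS)
    ecols.update(evidence_map or {})
    mcols = dict(MAXQUANT_MSMS_COLUMNS)
    mcols.update(msms_map or {})

    evidence = pd.read_csv(evidence_path, sep="\t")
    msms = pd.read_csv(msms_path, sep="\t")
    for frame, cols, name in ((evidence, ecols, "evidence"), (msms, mcols, "msms")):
        missing = [c for c in cols.values() if c not in frame.columns]
        if missing:
            raise LibraryError(f"MaxQuant {name} table missing columns: {missing}")

    msms_by_id = msms.set_index(msms[mcols["id"]].astype(int))
    intensities = pd.to_numeric(evidence[ecols["intensity"]], errors="coerce")
    median_intensity = float(intensities.median()) if intensities.notna().any() else 1.0

    records: list[PrecursorRecord] = []
    n_dropped_mods = n_dropped_frags = 0
    for i, row in evidence.iterrows():
        if not _modifications_allowed(row[ecols["modifications"]]):
            n_dropped_mods += 1
            continue
        msms_id = row[ecols["msms_id"]]
        try:
            msms_row = msms_by_id.loc[int(msms_id)]
        except (ValueError, TypeError, KeyError):
            n_dropped_frags += 1
            continue
        tokens = str(msms_row[mcols["matches"]]).split(";")
        masses = [float(x) for x in str(msms_row[mcols["masses"]]).split(";")]
        heights = [float(x) for x in str(msms_row[mcols["intensities"]]).split(";")]
        if not masses or len(masses) != len(heights):
            n_dropped_frags += 1
            continue
        top = max(heights)
        fragments = []
        for token, mz, height in zip(tokens, masses, heights):
            if height <= 0:
                continue
            series, number = _parse_match_token(token)
            fragments.append(
                FragmentRecord(series, number, 1, mz, height / top)
            )
        intensity = intensities.iloc[i] if i in intensities.index else np.nan
        records.append(
            PrecursorRecord(
                stripped_sequence=str(row[ecols["sequence"]]),
                modified_sequence=str(row[ecols["sequence"]]),
                charge=int(row[ecols["charge"]]),
                precursor_mz=float(row[ecols["mz"]]),
                fragments=tuple(fragments),
                source="maxquant",
                observed_rt=float(row[ecols["retention_time"]]),
                base_abundance=float(intensity)
                if np.isfinite(intensity)
                else median_intensity,
            )
        )
    if n_dropped_mods:
        logger.warning(
            "dropped %d evidence rows with modifications other than "
            "carbamidomethyl-Cys", n_dropped_mods,
        )
    if n_dropped_frags:
        logger.warning("dropped %d evidence rows without usable fragment data", n_dropped_frags)
    return records


def read_msp(path: str | Path) -> list[DecoyRecord]:
    """Read a NIST ``.msp`` spectral library into decoy records.

    Each entry needs ``Name:``, ``Num Peaks:`` and either ``PrecursorMZ:``
    or ``MW:`` plus ``Charge:`` (the m/z is then computed by protonation).
    Peak intensities are normalised to base peak = 1.  An empty file yields
    an empty list (decoys are optional).
    """
    records: list[DecoyRecord] = []
    name = None
    precursor_mz = None
    mw = None
    charge = None
    declared_peaks = None
    peaks: list[tuple[float, float]] = []

    def flush() -> None:
        nonlocal name, precursor_mz, mw, charge, declared_peaks, peaks
        if name is None:
            return
        if declared_peaks is not None and len(peaks) != declared_peaks:
            raise LibraryError(
                f"msp entry {name!r}: declared {declared_peaks} peaks, found {len(peaks)}"
            )
        mz = precursor_mz
        if mz is None:
            if mw is None:
                raise LibraryError(f"msp entry {name!r}: no PrecursorMZ or MW")
            mz = chem.ion_mz(mw, charge or 1)
        top = max((h for _, h in peaks), default=1.0)
        fragments = tuple((m, h / top) for m, h in peaks if h > 0)
        records.append(DecoyRecord(name=name, precursor_mz=mz, fragments=fragments))
        name = precursor_mz = mw = charge = declared_peaks = None
        peaks = []

    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                flush()
                continue
            key, _, value = line.partition(":")
            lowered = key.strip().lower()
            if lowered == "name":
                flush()
                name = value.strip()
            elif lowered in ("precursormz", "precursor_mz"):
                precursor_mz = float(value)
            elif lowered == "mw":
                mw = float(value)
            elif lowered == "charge":
                charge = int(value.strip().rstrip("+"))
            elif lowered == "num peaks":
                declared_peaks = int(value)
            elif name is not None and not value and key:
                fields = key.replace("\t", " ").split()
                if len(fields) >= 2:
                    peaks.append((float(fields[0]), float(fields[1])))
    flush()
    return records


@dataclass(frozen=True)
class SyntheticLibraryParams:
    """Settings of the tryptic-like synthetic library generator.

    Peptides are 7–20 residues ending in K/R (tryptic C-terminus, no missed
    cleavages), at charges 2–3; iRT is uniform over the configured range and
    base abundances follow the broad lognormal typical of label-free
    proteome data (about 3 orders of magnitude at the defaults).
    """

    min_length: int = 7
    max_length: int = 20
    charges: tuple[int, ...] = (2, 3)
    irt_range: tuple[float, float] = (0.0, 100.0)
    abundance_log10_mean: float = 6.0
    abundance_log10_sd: float = 0.6
    max_fragments: int = 12
    min_rel_intensity: float = 0.05


# internal residues: everything except K/R (kept terminal) — C included so
# carbamidomethylation is exercised.
_INTERNAL_RESIDUES = "GASPVTCLINDQEMHFYW"
_MODIFIED_CYS = "C[CAM]"


def generate_synthetic_library(
    n_precursors: int,
    seed: int,
    params: SyntheticLibraryParams | None = None,
) -> list[PrecursorRecord]:
    """Generate a reproducible synthetic Prosit-like library.

    Precursor m/z is computed exactly from the peptide composition
    (carbamidomethyl-Cys fixed); fragments are b/y ladders at charge 1 with
    seeded random relative intensities, keeping the ``max_fragments`` most
    intense.
    """
    if n_precursors < 1:
        raise LibraryError(f"n_precursors must be >= 1, got {n_precursors}")
    p = params or SyntheticLibraryParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5EED]))
    records: list[PrecursorRecord] = []
    seen: set[tuple[str, int]] = set()
    while len(records) < n_precursors:
        length = int(rng.integers(p.min_length, p.max_length + 1))
        body = "".join(rng.choice(list(_INTERNAL_RESIDUES), size=length - 1))
        sequence = body + ("K" if rng.random() < 0.5 else "R")
        charge = int(rng.choice(p.charges))
        if (sequence, charge) in seen:
            continue
        seen.add((sequence, charge))
        comp = chem.peptide_composition(sequence)
        precursor_mz = chem.ion_mz(chem.monoisotopic_mass(comp), charge)
        fragments: list[FragmentRecord] = []
        for series in ("b", "y"):
            for index in range(1, length):
                mz = chem.fragment_mz(sequence, (chem.CARBAMIDOMETHYL,), series, index, 1)
                rel = float(rng.uniform(p.min_rel_intensity, 1.0))
                fragments.append(FragmentRecord(series, index, 1, mz, rel))
        fragments.sort(key=lambda f: f.rel_intensity, reverse=True)
        fragments = fragments[: p.max_fragments]
        top = fragments[0].rel_intensity
        fragments = tuple(
            replace(f, rel_intensity=f.rel_intensity / top) for f in fragments
        )
        records.append(
            PrecursorRecord(
                stripped_sequence=sequence,
                modified_sequence=sequence.replace("C", _MODIFIED_CYS),
                charge=charge,
                precursor_mz=precursor_mz,
                fragments=fragments,
                source="synthetic",
                irt=float(rng.uniform(*p.irt_range)),
                base_abundance=float(
                    10.0 ** rng.normal(p.abundance_log10_mean, p.abundance_log10_sd)
                ),
            )
        )
    return records


def write_prosit_csv(records: list[PrecursorRecord], path: str | Path) -> None:
    """Serialise records to the Prosit-style CSV accepted by
    :func:`read_prosit_library`.  Floats are written with ``repr`` (shortest
    round-trip form) so re-reading reproduces the records exactly."""
    import csv as _csv

    header = [
        PROSIT_COLUMNS["modified_sequence"],
        PROSIT_COLUMNS["stripped_sequence"],
        PROSIT_COLUMNS["precursor_charge"],
        PROSIT_COLUMNS["precursor_mz"],
        PROSIT_COLUMNS["irt"],
        PROSIT_COLUMNS["fragment_mz"],
        PROSIT_COLUMNS["fragment_type"],
        PROSIT_COLUMNS["fragment_number"],
        PROSIT_COLUMNS["fragment_charge"],
        PROSIT_COLUMNS["relative_intensity"],
        PROSIT_ABUNDANCE_COLUMN,
    ]
    with open(path, "w", newline="") as handle:
        writer = _csv.writer(handle)
        writer.writerow(header)
        for record in records:
            if record.irt is None:
                raise LibraryError(
                    "Prosit serialisation requires iRT coordinates "
                    f"({record.modified_sequence}/{record.charge})"
                )
            for fragment in record.fragments:
                writer.writerow([
                    record.modified_sequence,
                    record.stripped_sequence,
                    record.charge,
                    repr(float(record.precursor_mz)),
                    repr(float(record.irt)),
                    repr(float(fragment.mz)),
                    fragment.series,
                    fragment.index,
                    fragment.charge,
                    repr(float(fragment.rel_intensity)),
                    repr(float(record.base_abundance)),
                ])
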