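"""Output contract of a simulation: indexed mzML file(s), the ground-truth
table, a replay file and a resolved-parameter record — plus readers for
re-ingesting our own outputs.

The mzML writer emits indexed mzML 1.1.0 with the conventional encoding
choices (64-bit m/z, 32-bit intensity, zlib compression, scan start times in
minutes, isolation-window target plus lower/upper offsets on MS2 spectra).
It is written directly as XML text with a byte-offset index and SHA-1
checksum; the test suite validates outputs with this module's own
CV-param-driven reader and, independently, with Bioconductor mzR.
"""

from __future__ import annotations

import base64
import hashlib
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Any
from xml.sax.saxutils import quoteattr

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .library_io import DecoyRecord, PrecursorRecord
from .spectra import SimulatedRun, SpectrumData
from .study_design import AbundanceMatrix

__all__ = [
    "ground_truth_frame",
    "write_mzml",
    "read_mzml_spectra",
    "write_ground_truth",
    "read_ground_truth",
    "ReplayBundle",
    "write_replay",
    "read_replay",
    "write_params_yaml",
]

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _cv(accession: str, name: str, value: str | None = None,
        unit: tuple[str, str, str] | None = None) -> str:
    parts = [f'<cvParam cvRef="MS" accession={quoteattr(accession)} name={quoteattr(name)}']
    parts.append(f' value={quoteattr(value if value is not None else "")}')
    if unit is not None:
        ref, acc, uname = unit
        parts.append(
            f' unitCvRef={quoteattr(ref)} unitAccession={quoteattr(acc)}'
            f' unitName={quoteattr(uname)}'
        )
    parts.append("/>")
    return "".join(parts)


_UNIT_MINUTE = ("UO", "UO:0000031", "minute")
_UNIT_MZ = ("MS", "MS:1000040", "m/z")
_UNIT_COUNTS = ("MS", "MS:1000131", "number of detector counts")


def _binary_block(array: np.ndarray, dtype: str, array_cv: tuple[str, str],
                  unit: tuple[str, str, str]) -> str:
    raw = np.asarray(array, dtype=dtype).tobytes()
    encoded = base64.b64encode(zlib.compress(raw)).decode("ascii")
    bits_cv = (
        _cv("MS:1000523", "64-bit float")
        if dtype == "<f8"
        else _cv("MS:1000521", "32-bit float")
    )
    return (
        f'<binaryDataArray encodedLength="{len(encoded)}">'
        + bits_cv
        + _cv("MS:1000574", "zlib compression")
        + _cv(array_cv[0], array_cv[1], unit=unit)
        + f"<binary>{encoded}</binary>"
        + "</binaryDataArray>"
    )


def _spectrum_xml(spectrum: SpectrumData, index: int) -> tuple[str, str]:
    """Return (id, xml) of one <spectrum> element."""
    spectrum_id = f"scan={index + 1}"
    n = len(spectrum.mz_array)
    parts = [
        f'<spectrum index="{index}" id={quoteattr(spectrum_id)} defaultArrayLength="{n}">'
    ]
    parts.append(_cv("MS:1000511", "ms level", str(spectrum.ms_level)))
    if spectrum.ms_level == 1:
        parts.append(_cv("MS:1000579", "MS1 spectrum"))
    else:
        parts.append(_cv("MS:1000580", "MSn spectrum"))
    if spectrum.mode == "centroid":
        parts.append(_cv("MS:1000127", "centroid spectrum"))
    else:
        parts.append(_cv("MS:1000128", "profile spectrum"))
    parts.append(_cv("MS:1000285", "total ion current", repr(spectrum.tic)))
    parts.append(
        '<scanList count="1">'
        + _cv("MS:1000795", "no combination")
        + "<scan>"
        + _cv(
            "MS:1000016",
            "scan start time",
            repr(spectrum.scan_start_time / 60.0),
            unit=_UNIT_MINUTE,
        )
        + "</scan></scanList>"
    )
    if spectrum.ms_level == 2 and spectrum.window is not None:
        window = spectrum.window
        target = window.target_mz
        offset = 0.5 * (window.upper_mz - window.lower_mz)
        parts.append(
            '<precursorList count="1"><precursor>'
            "<isolationWindow>"
            + _cv("MS:1000827", "isolation window target m/z", repr(target), unit=_UNIT_MZ)
            + _cv("MS:1000828", "isolation window lower offset", repr(offset), unit=_UNIT_MZ)
            + _cv("MS:1000829", "isolation window upper offset", repr(offset), unit=_UNIT_MZ)
            + "</isolationWindow>"
            '<selectedIonList count="1"><selectedIon>'
            + _cv("MS:1000744", "selected ion m/z", repr(target), unit=_UNIT_MZ)
            + "</selectedIon></selectedIonList>"
            "<activation>"
            + _cv("MS:1000422", "beam-type collision-induced dissociation")
            + "</activation></precursor></precursorList>"
        )
    parts.append(
        '<binaryDataArrayList count="2">'
        + _binary_block(spectrum.mz_array, "<f8", ("MS:1000514", "m/z array"), _UNIT_MZ)
        + _binary_block(
            spectrum.intensity_array, "<f4", ("MS:1000515", "intensity array"), _UNIT_COUNTS
        )
        + "</binaryDataArrayList></spectrum>"
    )
    return spectrum_id, "".join(parts)


def write_mzml(run: SimulatedRun, path: str | Path) -> Path:
    """Write a simulated run as an indexed mzML 1.1.0 file."""
    path = Path(path)
    starts = [s.scan_start_time for s in run.spectra]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise ValueError("spectra must be sorted by scan start time")

    head = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        f'<indexedmzML xmlns="{_MZML_NS}" '
        'xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance" '
        f'xsi:schemaLocation="{_MZML_NS} '
        'http://psidev.info/files/ms/mzML/xsd/mzML1.1.2_idx.xsd">\n'
        f'<mzML xmlns="{_MZML_NS}" id={quoteattr(run.sample_name)} version="1.1.0">\n'
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'version="4.1.0" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" version="09:04:2014" '
        'URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>'
        "</cvList>\n"
        "<fileDescription><fileContent>"
        + _cv("MS:1000579", "MS1 spectrum")
        + _cv("MS:1000580", "MSn spectrum")
        + "</fileContent></fileDescription>\n"
        f'<softwareList count="1"><software id="diasim" version="{__version__}">'
        + _cv("MS:1000799", "custom unreleased software tool", "diasim")
        + "</software></softwareList>\n"
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1">'
        + _cv("MS:1000031", "instrument model")
        + "</instrumentConfiguration></instrumentConfigurationList>\n"
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="0" softwareRef="diasim">'
        + _cv("MS:1000544", "Conversion to mzML")
        + "</processingMethod></dataProcessing></dataProcessingList>\n"
        f'<run id={quoteattr(run.sample_name)} defaultInstrumentConfigurationRef="IC1">\n'
        f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="DP1">\n'
    )
    chunks: list[bytes] = [head.encode("utf-8")]
    offset = len(chunks[0])
    index_entries: list[tuple[str, int]] = []
    for i, spectrum in enumerate(run.spectra):
        spectrum_id, xml = _spectrum_xml(spectrum, i)
        index_entries.append((spectrum_id, offset))
        chunk = (xml + "\n").encode("utf-8")
        chunks.append(chunk)
        offset += len(chunk)
    tail = "</spectrumList>\n</run>\n</mzML>\n"
    chunks.append(tail.encode("utf-8"))
    offset += len(chunks[-1])

    index_list_offset = offset
    index_parts = ['<indexList count="1">\n<index name="spectrum">\n']
    for spectrum_id, byte_offset in index_entries:
        index_parts.append(
            f"<offset idRef={quoteattr(spectrum_id)}>{byte_offset}</offset>\n"
        )
    index_parts.append("</index>\n</indexList>\n")
    index_parts.append(f"<indexListOffset>{index_list_offset}</indexListOffset>\n")
    index_parts.append("<fileChecksum>")
    chunks.append("".join(index_parts).encode("utf-8"))

    digest = hashlib.sha1()
    for chunk in chunks:
        digest.update(chunk)
    chunks.append(f"{digest.hexdigest()}</fileChecksum>\n</indexedmzML>\n".encode("utf-8"))
    with open(path, "wb") as handle:
        for chunk in chunks:
            handle.write(chunk)
    return path


def _decode_binary(element: Any, ns: str) -> np.ndarray:
    accessions = {
        child.get("accession")
        for child in element.iter(f"{ns}cvParam")
    }
    dtype = "<f8" if "MS:1000523" in accessions else "<f4"
    node = element.find(f"{ns}binary")
    text = (node.text or "").strip()
    if not text:
        return np.empty(0)
    raw = base64.b64decode(text)
    if "MS:1000574" in accessions:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml_spectra(path: str | Path) -> list[dict[str, Any]]:
    """Parse an mzML file into plain dicts: m/z and intensity arrays, ms
    level, scan start time in seconds, and MS2 isolation-window bounds.

    A generic CV-param-driven reader (lxml): it accepts any mzML 1.1.x
    file using zlib/uncompressed 32/64-bit float arrays, not just this
    package's own output.
    """
    from lxml import etree

    ns = f"{{{_MZML_NS}}}"
    spectra: list[dict[str, Any]] = []
    for _, element in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        params: dict[str, str] = {}
        for cv in element.iter(f"{ns}cvParam"):
            params.setdefault(cv.get("accession"), cv.get("value"))
        level = int(params.get("MS:1000511", 1))
        # scan start time: minutes (UO:0000031) or seconds (UO:0000010)
        time_value = None
        for cv in element.iter(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":
                time_value = float(cv.get("value"))
                if cv.get("unitAccession") == "UO:0000031":
                    time_value *= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in element.iter(f"{ns}binaryDataArray"):
            accs = {c.get("accession") for c in bda.iter(f"{ns}cvParam")}
            data = _decode_binary(bda, ns)
            if "MS:1000514" in accs:
                arrays["mz"] = data
            elif "MS:1000515" in accs:
                arrays["intensity"] = data
        record: dict[str, Any] = {
            "mz_array": arrays.get("mz", np.empty(0)),
            "intensity_array": arrays.get("intensity", np.empty(0)),
            "ms_level": level,
            "scan_start_time": time_value if time_value is not None else 0.0,
        }
        if level == 2:
            window = element.find(
                f"{ns}precursorList/{ns}precursor/{ns}isolationWindow"
            )
            if window is not None:
                wp = {c.get("accession"): float(c.get("value"))
                      for c in window.iter(f"{ns}cvParam")}
                target = wp.get("MS:1000827")
                if target is not None:
                    record["window"] = (
                        target - wp.get("MS:1000828", 0.0),
                        target + wp.get("MS:1000829", 0.0),
                    )
        spectra.append(record)
        element.clear()
    return spectra


def ground_truth_frame(
    matrix: AbundanceMatrix,
    records: list[PrecursorRecord],
    apex_rts: np.ndarray,
    decoys: list[DecoyRecord] | None = None,
) -> pd.DataFrame:
    """Ground-truth table: one row per simulated species, ordered by apex
    time then m/z.

    Columns: sequence, modified_sequence, charge, precursor_mz, source,
    apex_rt_s, fc_group{g} (g >= 2) and abundance_{sample} per sample
    (NaN = absent).
    """
    rows = []
    for i, record in enumerate(records):
        row: dict[str, Any] = {
            "sequence": record.stripped_sequence,
            "modified_sequence": record.modified_sequence,
            "charge": record.charge,
            "precursor_mz": record.precursor_mz,
            "source": "precursor",
            "apex_rt_s": float(apex_rts[i]),
        }
        for g, col in enumerate(matrix.true_log2_fc.columns, start=2):
            row[f"fc_group{g}"] = matrix.true_log2_fc.iloc[i][col]
        for sample in matrix.abundances.columns:
            row[f"abundance_{sample}"] = matrix.abundances.iloc[i][sample]
        rows.append(row)
    for decoy in decoys or []:
        row = {
            "sequence": decoy.name,
            "modified_sequence": decoy.name,
            "charge": 1,
            "precursor_mz": decoy.precursor_mz,
            "source": "decoy",
            "apex_rt_s": decoy.assigned_rt,
        }
        for g, _ in enumerate(matrix.true_log2_fc.columns, start=2):
            row[f"fc_group{g}"] = 0.0
        for sample in matrix.abundances.columns:
            row[f"abundance_{sample}"] = decoy.base_abundance
        rows.append(row)
    frame = pd.DataFrame(rows)
    return frame.sort_values(["apex_rt_s", "precursor_mz"], kind="stable").reset_index(drop=True)


def write_ground_truth(
    matrix: AbundanceMatrix,
    records: list[PrecursorRecord],
    apex_rts: np.ndarray,
    path: str | Path,
    decoys: list[DecoyRecord] | None = None,
) -> Path:
    """Write the ground-truth TSV (absent cells as empty fields, not zero)."""
    path = Path(path)
    frame = ground_truth_frame(matrix, records, apex_rts, decoys)
    frame.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    """Re-read a ground-truth TSV (empty abundance fields become NaN)."""
    return pd.read_csv(path, sep="\t")


@dataclass(frozen=True)
class ReplayBundle:
    """Everything needed to repeat a simulation byte-for-byte."""

    config: dict[str, Any]
    seed: int
    library_fingerprint: str
    software_version: str = __version__


def library_fingerprint_from_file(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def write_replay(bundle: ReplayBundle, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "software_version": bundle.software_version,
        "seed": bundle.seed,
        "library_fingerprint": bundle.library_fingerprint,
        "config": bundle.config,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=True)
    return path


def read_replay(path: str | Path) -> ReplayBundle:
    with open(path) as handle:
        payload = yaml.safe_load(handle)
    return ReplayBundle(
        config=payload["config"],
        seed=int(payload["seed"]),
        library_fingerprint=str(payload["library_fingerprint"]),
        software_version=str(payload["software_version"]),
    )


def write_params_yaml(config: dict[str, Any], path: str | Path) -> Path:
    """Human-readable record of every resolved setting (defaults included)."""
    path = Path(path)
    with open(path, "w") as handle:
        yaml.safe_dump(config, handle, sort_keys=True)
    return path
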