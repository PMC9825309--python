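"""Peptide elemental compositions, monoisotopic masses and isotope envelopes.

Masses are computed from a bundled table of stable-isotope masses and
abundances (``data/isotopes.tsv``, IUPAC/CIAAW values), so no runtime lookup
against an external database is required.  Only the 20 standard amino acids
are supported, with carbamidomethylation of cysteine (+C2H3NO, +57.02146 Da)
as the single fixed modification — mirroring the constraint of HCD spectral
libraries predicted for unmodified/carbamidomethylated peptides.

Isotope envelopes are aggregated (unit-mass binned) distributions obtained by
convolving per-element isotope patterns; peak *k* of an envelope is placed at
``monoisotopic + k * 1.00286864`` Da (the averagine-style aggregate spacing),
not at the exact fine-structure positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PROTON_MASS",
    "NEUTRON_DELTA",
    "CARBAMIDOMETHYL",
    "ElementalComposition",
    "IsotopeEnvelope",
    "peptide_composition",
    "monoisotopic_mass",
    "ion_mz",
    "fragment_mz",
    "isotope_envelope",
]

#: Mass of a proton in Da.
PROTON_MASS = 1.007276466

#: Aggregate isotope peak spacing in Da (mass excess of one extra neutron in
#: an averagine-like organic composition).
NEUTRON_DELTA = 1.00286864

#: Name of the only supported fixed modification.
CARBAMIDOMETHYL = "carbamidomethyl"


class ChemError(ValueError):
    """Raised for unknown residues, elements or invalid charges."""


def _load_isotope_table() -> dict[str, list[tuple[int, float, float]]]:
    table: dict[str, list[tuple[int, float, float]]] = {}
    text = resources.files("diasim.data").joinpath("isotopes.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        element, nucleons, mass, abundance = line.split("\t")
        table.setdefault(element, []).append(
            (int(nucleons), float(mass), float(abundance))
        )
    for isotopes in table.values():
        isotopes.sort()
    return table


#: element -> list of (nucleon count, mass Da, abundance fraction), sorted by
#: nucleon count.  The lightest isotope of every listed element is also its
#: most abundant, so "monoisotopic" means "all-lightest" throughout.
ISOTOPES = _load_isotope_table()


class ElementalComposition(dict):
    """Counts per element symbol.  Supports ``+`` and integer ``*``."""

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        super().__init__()
        merged: dict[str, int] = dict(counts or {})
        merged.update(kwargs)
        for element, count in merged.items():
            if count < 0:
                raise ChemError(f"negative count for element {element!r}: {count}")
            if count:
                self[element] = int(count)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self)
        for element, count in other.items():
            out[element] = out.get(element, 0) + count
        return ElementalComposition(out)

    def __mul__(self, n: int) -> "ElementalComposition":
        if n < 0:
            raise ChemError(f"cannot multiply composition by negative {n}")
        return ElementalComposition({el: c * n for el, c in self.items()})

    __rmul__ = __mul__

    @property
    def n_atoms(self) -> int:
        return sum(self.values())

    def mass(self) -> float:
        return monoisotopic_mass(self)


def _comp(formula: Mapping[str, int]) -> ElementalComposition:
    return ElementalComposition(formula)


#: Residue (in-chain, i.e. minus water) compositions of the 20 standard
#: amino acids.
RESIDUES: dict[str, ElementalComposition] = {
    "G": _comp({"C": 2, "H": 3, "N": 1, "O": 1}),
    "A": _comp({"C": 3, "H": 5, "N": 1, "O": 1}),
    "S": _comp({"C": 3, "H": 5, "N": 1, "O": 2}),
    "P": _comp({"C": 5, "H": 7, "N": 1, "O": 1}),
    "V": _comp({"C": 5, "H": 9, "N": 1, "O": 1}),
    "T": _comp({"C": 4, "H": 7, "N": 1, "O": 2}),
    "C": _comp({"C": 3, "H": 5, "N": 1, "O": 1, "S": 1}),
    "L": _comp({"C": 6, "H": 11, "N": 1, "O": 1}),
    "I": _comp({"C": 6, "H": 11, "N": 1, "O": 1}),
    "N": _comp({"C": 4, "H": 6, "N": 2, "O": 2}),
    "D": _comp({"C": 4, "H": 5, "N": 1, "O": 3}),
    "Q": _comp({"C": 5, "H": 8, "N": 2, "O": 2}),
    "K": _comp({"C": 6, "H": 12, "N": 2, "O": 1}),
    "E": _comp({"C": 5, "H": 7, "N": 1, "O": 3}),
    "M": _comp({"C": 5, "H": 9, "N": 1, "O": 1, "S": 1}),
    "H": _comp({"C": 6, "H": 7, "N": 3, "O": 1}),
    "F": _comp({"C": 9, "H": 9, "N": 1, "O": 1}),
    "R": _comp({"C": 6, "H": 12, "N": 4, "O": 1}),
    "Y": _comp({"C": 9, "H": 9, "N": 1, "O": 2}),
    "W": _comp({"C": 11, "H": 10, "N": 2, "O": 1}),
}

WATER = _comp({"H": 2, "O": 1})
#: Mass/composition delta added to Cys by iodoacetamide alkylation.
CARBAMIDOMETHYL_DELTA = _comp({"C": 2, "H": 3, "N": 1, "O": 1})


def peptide_composition(
    sequence: str, fixed_mods: Iterable[str] = (CARBAMIDOMETHYL,)
) -> ElementalComposition:
    """Elemental composition of an intact (neutral) peptide.

    Parameters
    ----------
    sequence:
        Amino-acid string using the 20 standard one-letter codes.
    fixed_mods:
        Set of fixed-modification names.  Only ``"carbamidomethyl"``
        (applied to every Cys) is supported.
    """
    mods = set(fixed_mods)
    unknown_mods = mods - {CARBAMIDOMETHYL}
    if unknown_mods:
        raise ChemError(f"unsupported fixed modifications: {sorted(unknown_mods)}")
    total = ElementalComposition(WATER)
    for position, letter in enumerate(sequence):
        residue = RESIDUES.get(letter)
        if residue is None:
            raise ChemError(
                f"unknown residue {letter!r} at position {position} in {sequence!r}"
            )
        total = total + residue
        if letter == "C" and CARBAMIDOMETHYL in mods:
            total = total + CARBAMIDOMETHYL_DELTA
    return total


def monoisotopic_mass(comp: Mapping[str, int]) -> float:
    """Monoisotopic (all-lightest-isotope) mass of a composition, in Da."""
    mass = 0.0
    for element, count in comp.items():
        isotopes = ISOTOPES.get(element)
        if isotopes is None:
            raise ChemError(f"element {element!r} not in the bundled isotope table")
        mass += count * isotopes[0][1]
    return mass


def ion_mz(neutral_mass: float, charge: int) -> float:
    """m/z of a protonated ion: ``(M + z * m_proton) / z``."""
    if charge < 1:
        raise ChemError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def fragment_mz(
    sequence: str,
    fixed_mods: Iterable[str],
    series: str,
    index: int,
    charge: int,
) -> float:
    """m/z of a b- or y-series backbone fragment ion.

    ``index`` counts residues from the N-terminus for b ions and from the
    C-terminus for y ions; valid indices are ``1 .. len(sequence) - 1``.
    """
    n = len(sequence)
    if not 1 <= index <= n - 1:
        raise ChemError(
            f"fragment index {index} out of range for length-{n} peptide"
        )
    if series == "b":
        piece = sequence[:index]
        comp = peptide_composition(piece, fixed_mods)
        # b ion = residues only (no C-terminal water)
        neutral = monoisotopic_mass(comp) - monoisotopic_mass(WATER)
    elif series == "y":
        piece = sequence[n - index :]
        neutral = monoisotopic_mass(peptide_composition(piece, fixed_mods))
    else:
        raise ChemError(f"unsupported fragment series {series!r} (only b/y)")
    return ion_mz(neutral, charge)


@dataclass(frozen=True)
class IsotopeEnvelope:
    """Aggregated isotope distribution of one ion.

    ``mz`` is strictly increasing; ``rel_abundance`` holds raw isotopologue
    mole fractions of the full distribution (NOT renormalised after
    truncation), so ``truncated_fraction`` — the mass fraction lost to
    truncation — is directly measurable as ``1 - rel_abundance.sum()``.
    """

    mz: np.ndarray
    rel_abundance: np.ndarray
    charge: int | None = None
    truncated_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mz) <= 0):
            raise ChemError("envelope m/z values must be strictly increasing")


def _element_pattern(element: str) -> np.ndarray:
    """Abundance indexed by extra-nucleon offset from the lightest isotope."""
    isotopes = ISOTOPES[element]
    lightest = isotopes[0][0]
    pattern = np.zeros(isotopes[-1][0] - lightest + 1)
    for nucleons, _mass, abundance in isotopes:
        pattern[nucleons - lightest] = abundance
    return pattern


def _pattern_power(pattern: np.ndarray, n: int, max_len: int) -> np.ndarray:
    """``pattern`` convolved with itself ``n`` times, truncated to max_len."""
    result = np.array([1.0])
    base = pattern.copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:max_len]
        n >>= 1
        if n:
            base = np.convolve(base, base)[:max_len]
    return result


def isotope_envelope(
    comp: Mapping[str, int],
    max_peaks: int = 5,
    charge: int | None = None,
    min_fraction: float = 1e-4,
) -> IsotopeEnvelope:
    """Aggregated isotope envelope of a composition.

    The unit-mass-binned isotopologue distribution is obtained by iterative
    convolution of per-element isotope patterns.  The envelope is truncated
    to the first ``max_peaks`` peaks starting at the monoisotopic one, then
    peaks with mole fraction below ``min_fraction`` are dropped.  Abundances
    are not renormalised, so the truncation loss stays measurable.

    If ``charge`` is given, peak positions are m/z of the protonated ion;
    otherwise they are neutral masses.
    """
    if max_peaks < 1:
        raise ChemError(f"max_peaks must be >= 1, got {max_peaks}")
    keep = max_peaks + 4  # working head room before final truncation
    dist = np.array([1.0])
    for element, count in comp.items():
        if element not in ISOTOPES:
            raise ChemError(f"element {element!r} not in the bundled isotope table")
        dist = np.convolve(dist, _pattern_power(_element_pattern(element), count, keep))
        dist = dist[:keep]
    dist = dist[:max_peaks]
    offsets = np.arange(len(dist))
    mask = dist >= min_fraction
    if not mask.any():
        mask[int(np.argmax(dist))] = True
    dist, offsets = dist[mask], offsets[mask]

    mono = monoisotopic_mass(comp)
    masses = mono + offsets * NEUTRON_DELTA
    if charge is not None:
        positions = (masses + charge * PROTON_MASS) / charge if charge >= 1 else None
        if positions is None:
            raise ChemError(f"charge must be >= 1, got {charge}")
    else:
        positions = masses
    return IsotopeEnvelope(
        mz=positions,
        rel_abundance=dist,
        charge=charge,
        truncated_fraction=float(1.0 - dist.sum()),
    )
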