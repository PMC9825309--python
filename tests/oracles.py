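"""Independent reference computations used by the tests.

Everything here is deliberately written by a different route than the
package code it checks: brute-force enumeration instead of convolution,
hard-coded standard residue masses instead of elemental bookkeeping, and
quadrature instead of closed forms.
"""

from itertools import combinations_with_replacement
from math import factorial, prod

# Standard monoisotopic residue masses (Da), as tabulated in any proteomics
# reference — independent of the package's elemental composition route.
RESIDUE_MASSES = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MASS = 18.010565
PROTON_MASS = 1.0072765
CARBAMIDOMETHYL_MASS = 57.02146


def peptide_mass(sequence: str, carbamidomethyl: bool = False) -> float:
    mass = WATER_MASS + sum(RESIDUE_MASSES[r] for r in sequence)
    if carbamidomethyl:
        mass += CARBAMIDOMETHYL_MASS * sequence.count("C")
    return mass


def brute_force_envelope(
    comp: dict[str, int],
    isotopes: dict[str, list[tuple[int, float, float]]],
) -> dict[int, float]:
    """Exact aggregated isotope distribution by enumerating every
    isotopologue combination (feasible for small atom counts).

    Returns extra-nucleon offset -> probability.
    """
    total = {0: 1.0}
    for element, n in comp.items():
        iso = isotopes[element]
        base = iso[0][0]
        eldist: dict[int, float] = {}
        for combo in combinations_with_replacement(range(len(iso)), n):
            counts = [combo.count(i) for i in range(len(iso))]
            multinomial = factorial(n) // prod(factorial(c) for c in counts)
            p = multinomial * prod(iso[i][2] ** c for i, c in enumerate(counts))
            offset = sum((iso[i][0] - base) * c for i, c in enumerate(counts))
            eldist[offset] = eldist.get(offset, 0.0) + p
        merged: dict[int, float] = {}
        for k1, p1 in total.items():
            for k2, p2 in eldist.items():
                merged[k1 + k2] = merged.get(k1 + k2, 0.0) + p1 * p2
        total = merged
    return total


def enumerate_schedule(durations: list[float], run_length: float) -> int:
    """Count scheduled scan events by direct simulation of the clock."""
    t = 0.0
    count = 0
    while True:
        advanced = False
        for duration in durations:
            if t + duration > run_length + 1e-9:
                return count
            t += duration
            count += 1
            advanced = True
        if not advanced:  # pragma: no cover
            return count
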