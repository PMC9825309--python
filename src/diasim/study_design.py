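"""Multi-group replicate designs: abundance matrices, fold changes and
missing values.

One library is expanded into an (n precursors) x (n samples) abundance
matrix.  Per-precursor group offsets (the true log2 fold changes, group 1
being the reference) and within-group replicate noise are both drawn from
Normal distributions on the log2 scale; missingness is applied afterwards
either group-wise (a precursor disappears from every replicate of a group)
or sample-wise (independent cells), encoded as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromatography import GradientModel
from .library_io import DecoyRecord, PrecursorRecord

__all__ = ["StudyDesign", "AbundanceMatrix", "sample_abundances",
           "apply_missingness", "place_decoys", "sample_names"]


@dataclass(frozen=True)
class StudyDesign:
    n_groups: int = 1
    n_replicates_per_group: int = 1
    between_group_log2_sd: float = 1.0
    within_group_log2_sd: float = 0.2
    prob_missing_group: float = 0.0
    prob_missing_sample: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.n_replicates_per_group < 1:
            raise ValueError("need at least one group and one replicate")
        if self.between_group_log2_sd < 0 or self.within_group_log2_sd < 0:
            raise ValueError("log2 sds must be >= 0")
        for p in (self.prob_missing_group, self.prob_missing_sample):
            if not 0 <= p <= 1:
                raise ValueError(f"missingness probability {p} outside [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_groups * self.n_replicates_per_group


def sample_names(design: StudyDesign) -> list[str]:
    """Column names ``group{g}_rep{r}``, group-major order."""
    return [
        f"group{g}_rep{r}"
        for g in range(1, design.n_groups + 1)
        for r in range(1, design.n_replicates_per_group + 1)
    ]


def group_of_sample(name: str) -> int:
    return int(name.split("_")[0].removeprefix("group"))


@dataclass
class AbundanceMatrix:
    """Per-sample abundances (NaN = absent) and true per-group log2 fold
    changes relative to group 1."""

    abundances: pd.DataFrame      # index: precursor position, columns: samples
    true_log2_fc: pd.DataFrame    # columns: group2..groupG (empty if 1 group)
    design: StudyDesign

    def group_columns(self, group: int) -> list[str]:
        return [c for c in self.abundances.columns if group_of_sample(c) == group]


def sample_abundances(
    records: list[PrecursorRecord], design: StudyDesign
) -> AbundanceMatrix:
    """Draw the per-sample abundance matrix for a library.

    For precursor i with base abundance A_i, the abundance in replicate r of
    group g is ``A_i * 2**(fc_{i,g} + eps_{i,g,r})`` with
    ``fc_{i,g} ~ N(0, between_sd)`` (zero for the reference group 1) and
    ``eps ~ N(0, within_sd)``.  Fully seeded and reproducible.
    """
    n = len(records)
    base = np.array([r.base_abundance for r in records], dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0xAB]))
    fc = np.zeros((n, design.n_groups))
    if design.n_groups > 1:
        fc[:, 1:] = rng.normal(0.0, design.between_group_log2_sd, size=(n, design.n_groups - 1))
    eps = rng.normal(
        0.0, design.within_group_log2_sd, size=(n, design.n_samples)
    )
    group_per_sample = np.repeat(np.arange(design.n_groups), design.n_replicates_per_group)
    values = base[:, None] * 2.0 ** (fc[:, group_per_sample] + eps)
    columns = sample_names(design)
    abundances = pd.DataFrame(values, columns=columns)
    true_fc = pd.DataFrame(
        fc[:, 1:], columns=[f"group{g}" for g in range(2, design.n_groups + 1)]
    )
    return AbundanceMatrix(abundances=abundances, true_log2_fc=true_fc, design=design)


def apply_missingness(matrix: AbundanceMatrix, design: StudyDesign) -> AbundanceMatrix:
    """Mask cells of the abundance matrix as absent (NaN).

    Group-wise and sample-wise missingness are independent mechanisms: with
    probability ``prob_missing_group`` per (precursor, group) every replicate
    of that group is masked; with probability ``prob_missing_sample`` per
    (precursor, sample) a single cell is masked.
    """
    rng = np.random.default_rng(np.random.SeedSequence([design.seed, 0x3115]))
    values = matrix.abundances.to_numpy(copy=True)
    n = values.shape[0]
    group_mask = rng.random((n, design.n_groups)) < design.prob_missing_group
    cell_mask = rng.random((n, design.n_samples)) < design.prob_missing_sample
    group_per_sample = np.repeat(np.arange(design.n_groups), design.n_replicates_per_group)
    mask = group_mask[:, group_per_sample] | cell_mask
    values[mask] = np.nan
    out = pd.DataFrame(values, columns=matrix.abundances.columns,
                       index=matrix.abundances.index)
    return AbundanceMatrix(abundances=out, true_log2_fc=matrix.true_log2_fc, design=design)


def place_decoys(
    decoys: list[DecoyRecord],
    gradient: GradientModel,
    rng: np.random.Generator,
    abundance_log10_mean: float = 6.0,
    abundance_log10_sd: float = 0.6,
) -> list[DecoyRecord]:
    """Assign each decoy a uniform random apex time within the usable
    gradient and a lognormal abundance (same family as synthetic
    precursors)."""
    placed = []
    for decoy in decoys:
        rt = float(rng.uniform(gradient.padding, gradient.run_length - gradient.padding))
        abundance = float(10.0 ** rng.normal(abundance_log10_mean, abundance_log10_sd))
        placed.append(
            DecoyRecord(
                name=decoy.name,
                precursor_mz=decoy.precursor_mz,
                fragments=decoy.fragments,
                assigned_rt=rt,
                base_abundance=abundance,
            )
        )
    return placed
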