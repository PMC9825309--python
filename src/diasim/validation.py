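"""Naive XIC quantification of simulated runs and fold-change recovery.

This module plays the role that a DIA search engine plays on real data, at
the level needed to benchmark quantitative accuracy against the simulator's
own ground truth: it integrates the monoisotopic MS1 extracted-ion
chromatogram (XIC) of every precursor in every sample, counts the data
points per chromatographic peak (PPP), estimates per-precursor log2 fold
changes from group mean areas, and regresses them against the true values.
Peptide identification and FDR control are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra import SimulatedRun
from .study_design import StudyDesign, group_of_sample

__all__ = [
    "XicResult",
    "RecoveryReport",
    "extract_xic",
    "extract_xic_table",
    "fold_change_recovery",
    "plot_recovery",
]


@dataclass(frozen=True)
class XicResult:
    """Integrated MS1 trace of one precursor in one run."""

    area: float              # intensity * seconds
    points_per_peak: int     # MS1 points above half the XIC maximum
    times: np.ndarray
    intensities: np.ndarray


def _ms1_arrays(run: SimulatedRun) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All MS1 peaks of a run, sorted by m/z: (mz, intensity, scan idx, scan times)."""
    ms1 = run.ms1_spectra()
    scan_times = np.array([s.scan_start_time for s in ms1])
    mzs = [s.mz_array for s in ms1]
    lengths = np.array([len(a) for a in mzs], dtype=int)
    if lengths.sum() == 0:
        return np.empty(0), np.empty(0), np.empty(0, dtype=int), scan_times
    mz = np.concatenate(mzs)
    intensity = np.concatenate([s.intensity_array for s in ms1])
    scan_idx = np.repeat(np.arange(len(ms1)), lengths)
    order = np.argsort(mz, kind="stable")
    return mz[order], intensity[order], scan_idx[order], scan_times


def _xic_from_sorted(
    mz: np.ndarray,
    intensity: np.ndarray,
    scan_idx: np.ndarray,
    scan_times: np.ndarray,
    target_mz: float,
    ppm_tol: float,
    rt: float | None = None,
    rt_half_window: float | None = None,
) -> XicResult:
    n_scans = len(scan_times)
    lo = target_mz * (1.0 - ppm_tol * 1e-6)
    hi = target_mz * (1.0 + ppm_tol * 1e-6)
    a, b = np.searchsorted(mz, (lo, hi))
    trace = np.zeros(n_scans)
    if b > a:
        np.add.at(trace, scan_idx[a:b], intensity[a:b])
    if rt is not None and rt_half_window is not None:
        s0, s1 = np.searchsorted(scan_times, (rt - rt_half_window, rt + rt_half_window))
        trace = trace[s0:s1]
        scan_times = scan_times[s0:s1]
        n_scans = len(scan_times)
    if n_scans > 1:
        dt = float(np.median(np.diff(scan_times)))
    else:
        dt = 0.0
    area = float(trace.sum() * dt)
    peak = trace.max() if n_scans else 0.0
    ppp = int((trace > 0.5 * peak).sum()) if peak > 0 else 0
    return XicResult(area=area, points_per_peak=ppp, times=scan_times, intensities=trace)


def extract_xic(
    run: SimulatedRun,
    target_mz: float,
    ppm_tol: float = 10.0,
    rt: float | None = None,
    rt_half_window: float | None = None,
) -> XicResult:
    """Monoisotopic MS1 XIC of one precursor m/z in one run.

    The area is the Riemann sum of the trace times the MS1 scan spacing;
    points-per-peak is the number of scans above half the trace maximum.
    When ``rt`` and ``rt_half_window`` are given the trace is restricted to
    scans within that retention-time window (standard practice: without it,
    any species sharing the m/z tolerance anywhere in the gradient would
    contaminate the area).
    """
    if ppm_tol <= 0:
        raise ValueError(f"ppm_tol must be > 0, got {ppm_tol}")
    return _xic_from_sorted(*_ms1_arrays(run), target_mz, ppm_tol,
                            rt=rt, rt_half_window=rt_half_window)


def extract_xic_table(
    runs: dict[str, SimulatedRun],
    truth: pd.DataFrame,
    ppm_tol: float = 10.0,
    rt_half_window: float | None = None,
) -> pd.DataFrame:
    """XIC areas and PPP for every precursor row of a ground-truth table in
    every run.  Returns the truth frame augmented with ``area_{sample}`` and
    ``ppp_{sample}`` columns.  ``rt_half_window`` (seconds) restricts each
    XIC to scans around the precursor's true apex time."""
    out = truth.copy()
    targets = truth["precursor_mz"].to_numpy(float)
    apexes = truth["apex_rt_s"].to_numpy(float) if "apex_rt_s" in truth else None
    for sample, run in runs.items():
        mz, intensity, scan_idx, scan_times = _ms1_arrays(run)
        areas = np.empty(len(targets))
        ppps = np.empty(len(targets), dtype=int)
        for i, target in enumerate(targets):
            rt = apexes[i] if (apexes is not None and rt_half_window is not None) else None
            xic = _xic_from_sorted(mz, intensity, scan_idx, scan_times, target,
                                   ppm_tol, rt=rt, rt_half_window=rt_half_window)
            areas[i] = xic.area
            ppps[i] = xic.points_per_peak
        out[f"area_{sample}"] = areas
        out[f"ppp_{sample}"] = ppps
    return out


@dataclass
class RecoveryReport:
    """Estimated-vs-true log2 fold changes and their agreement."""

    table: pd.DataFrame       # per precursor: true_log2_fc, estimated_log2_fc
    r2: float                 # squared Pearson correlation (regression R^2)
    avg_ppp: float
    n_used: int
    reliable: bool


def fold_change_recovery(
    xic_table: pd.DataFrame,
    design: StudyDesign,
    group_a: int = 1,
    group_b: int = 2,
    fc_range: tuple[float, float] = (-5.0, 5.0),
) -> RecoveryReport:
    """Compare XIC-estimated log2 fold changes (group_b vs group_a) with the
    true simulated values.

    Precursors with any absent sample are excluded ("no missing values"
    rule), as are decoys; the reported regression is restricted to true fold
    changes within ``fc_range`` for comparability across scenarios.
    """
    if design.n_groups < 2:
        raise ValueError("fold-change recovery needs at least two groups")
    samples = [
        f"group{g}_rep{r}"
        for g in range(1, design.n_groups + 1)
        for r in range(1, design.n_replicates_per_group + 1)
    ]
    frame = xic_table
    if "source" in frame.columns:
        frame = frame[frame["source"] == "precursor"]
    abundance_cols = [f"abundance_{s}" for s in samples]
    complete = frame[abundance_cols].notna().all(axis=1)
    frame = frame[complete]

    cols_a = [f"area_{s}" for s in samples if group_of_sample(s) == group_a]
    cols_b = [f"area_{s}" for s in samples if group_of_sample(s) == group_b]
    mean_a = frame[cols_a].mean(axis=1)
    mean_b = frame[cols_b].mean(axis=1)
    usable = (mean_a > 0) & (mean_b > 0)
    frame = frame[usable]
    estimated = np.log2(mean_b[usable] / mean_a[usable])
    true_fc = frame[f"fc_group{group_b}"].to_numpy(float)
    if group_a != 1:
        true_fc = true_fc - frame[f"fc_group{group_a}"].to_numpy(float)

    in_range = (true_fc >= fc_range[0]) & (true_fc <= fc_range[1])
    table = pd.DataFrame(
        {
            "precursor_mz": frame["precursor_mz"].to_numpy(float),
            "true_log2_fc": true_fc,
            "estimated_log2_fc": estimated.to_numpy(float),
            "in_range": in_range,
        }
    )
    ppp_cols = [f"ppp_{s}" for s in samples]
    avg_ppp = float(frame[ppp_cols].to_numpy(float).mean()) if len(frame) else float("nan")
    n_used = int(in_range.sum())
    if n_used >= 3:
        x = table.loc[table["in_range"], "true_log2_fc"]
        y = table.loc[table["in_range"], "estimated_log2_fc"]
        r = np.corrcoef(x, y)[0, 1]
        r2 = float(r * r)
        reliable = True
    else:
        r2 = float("nan")
        reliable = False
    return RecoveryReport(table=table, r2=r2, avg_ppp=avg_ppp, n_used=n_used,
                          reliable=reliable)


def plot_recovery(reports: dict[str, RecoveryReport], path: str) -> None:
    """Scatter grid of estimated vs true log2 fold changes, one panel per
    scenario, annotated with average PPP and r^2."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = len(reports)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 4), squeeze=False)
    for ax, (label, report) in zip(axes[0], reports.items()):
        sub = report.table[report.table["in_range"]]
        ax.scatter(sub["true_log2_fc"], sub["estimated_log2_fc"], s=4, alpha=0.4)
        ax.plot([-5, 5], [-5, 5], "k--", lw=0.8)
        ax.set_xlim(-5, 5)
        ax.set_ylim(-5, 5)
        ax.set_xlabel("true log2 FC")
        ax.set_ylabel("estimated log2 FC")
        ax.set_title(f"{label}\nAvg PPP {report.avg_ppp:.1f}, r$^2$ {report.r2:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
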