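"""Alignment-frame RMSD observables and their summaries.

Each RMSD preset names two atom selections: an *alignment* group used to
superpose every frame onto the reference frame, and a *measurement* group
over which the unfitted RMSD against the reference is then taken.  This
separates "where is the domain relative to X" (align on X, measure the
domain) from internal flexibility.  When the two selections coincide the
value is exactly the Kabsch-minimal RMSD of that group.

Summaries report the mean and population standard deviation of a series
(a spread of a full observable stream, not an estimator from a sample),
plus a fixed-width histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import geometry
from .membrane_metrics import MetricSeries, burn_in_slice
from .structio import AtomIndexSet, Structure, Trajectory, parse_selection

__all__ = [
    "RmsdPreset",
    "DistributionSummary",
    "PRESET_NAMES",
    "rmsd_series",
    "summarize",
    "correlate",
]

PRESET_NAMES = ("gtpase_vs_gap", "gtpase_vs_rbd", "rbd_vs_gap", "dimer_helices", "custom")


@dataclass(frozen=True)
class RmsdPreset:
    """A named pair of (alignment, measurement) selection strings.

    The stock preset names mirror the positional observables of a
    GTPase-bound plexin system: e.g. ``gtpase_vs_gap`` aligns on the GAP
    domain Cα atoms and measures the GTPase Cα RMSD from its initial
    position.  ``dimer_helices`` uses the same selection for both, giving
    the fitted (Kabsch-minimal) RMSD of the helix pair.
    """

    name: str
    align_sel: str
    measure_sel: str

    def __post_init__(self) -> None:
        if self.name not in PRESET_NAMES:
            raise ValueError(f"unknown preset name {self.name!r}; use one of {PRESET_NAMES}")
        if not self.align_sel.strip() or not self.measure_sel.strip():
            raise ValueError("preset selections must be nonempty")

    def resolve(self, topology: Structure) -> tuple[AtomIndexSet, AtomIndexSet]:
        align = parse_selection(self.align_sel, topology)
        measure = parse_selection(self.measure_sel, topology)
        if len(align) == 0 or len(measure) == 0:
            raise ValueError(
                f"preset {self.name!r}: empty selection "
                f"(align {len(align)} atoms, measure {len(measure)} atoms)"
            )
        return align, measure


@dataclass(frozen=True)
class DistributionSummary:
    """Mean, population SD and histogram of a metric distribution."""

    mean: float
    spread: float  # population standard deviation, same units
    n: int
    bin_edges: np.ndarray
    bin_counts: np.ndarray


def rmsd_series(
    traj: Trajectory,
    preset: RmsdPreset,
    reference: int = 0,
) -> MetricSeries:
    """RMSD of the measurement group vs the reference frame, after
    superposing each frame on the reference via the alignment group.

    The reference defaults to the first frame, i.e. RMSD with respect to
    initial positions.
    """
    align, measure = preset.resolve(traj.topology)
    if len(align) < 3:
        raise geometry.DegenerateGeometryError(
            f"alignment selection resolves to {len(align)} atoms; need ≥ 3"
        )
    ref = traj.coords(reference)
    midx = measure.as_array()
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        fitted = geometry.superpose_frame(traj.coords(f), align, ref)
        values[f] = geometry.rmsd(fitted[midx], ref[midx])
    return MetricSeries(traj.times, values, label=f"rmsd_{preset.name}", units="A")


def summarize(
    series: MetricSeries,
    burn_in_fraction: float = 0.0,
    n_bins: int = 50,
) -> DistributionSummary:
    """Mean, population standard deviation and histogram of the retained
    values (first ⌈f·n⌉ frames discarded)."""
    keep = burn_in_slice(len(series), burn_in_fraction)
    vals = series.values[keep]
    if vals.size == 0:
        raise ValueError("no values left after burn-in")
    lo, hi = float(vals.min()), float(vals.max())
    if hi == lo:
        hi = lo + 1e-12
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return DistributionSummary(
        mean=float(vals.mean()),
        spread=float(vals.std(ddof=0)),
        n=int(vals.size),
        bin_edges=edges,
        bin_counts=counts,
    )


def correlate(
    a: MetricSeries,
    b: MetricSeries,
) -> tuple[float | None, float | None, int, pd.DataFrame]:
    """Pearson r and Spearman ρ between two series sharing identical times.

    Returns ``(pearson_r, spearman_rho, n, paired_table)``.  Times must
    match exactly — no interpolation; resample explicitly if they differ.
    A zero-variance series makes the correlations undefined (``None``).
    The paired table carries the scatter data (time, a, b).
    """
    if len(a) != len(b) or not np.array_equal(a.times, b.times):
        raise ValueError("series times do not match; resample explicitly")
    n = len(a)
    table = pd.DataFrame(
        {"time_ns": a.times, a.label or "a": a.values, b.label or "b": b.values}
    )
    if n < 2 or np.std(a.values) == 0 or np.std(b.values) == 0:
        return None, None, n, table
    pear = float(stats.pearsonr(a.values, b.values).statistic)
    spear = float(stats.spearmanr(a.values, b.values).statistic)
    return pear, spear, n, table
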