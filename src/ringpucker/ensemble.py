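"""Ensemble aggregation: summaries, histograms, occupancy maps, populations.

These are the reporting primitives of the pipeline: per-index distribution
summaries (range / mean / median), relative-frequency histograms of the
puckering amplitude S, circular (S, ψ) occupancy grids, and conformer-class
population tables.  Everything here is a pure, order-independent function of
the per-frame records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conformers import ConformerAssignment, ConformerClass


@dataclass(frozen=True)
class SummaryStats:
    """Range (max − min), mean and median of a per-frame quantity."""

    range_width: float
    mean: float
    median: float
    n_frames: int


@dataclass(frozen=True)
class PopulationTable:
    """Planar fraction plus one fraction per conformer class (sum to 1)."""

    planar_fraction: float
    class_fractions: dict  # label -> fraction
    n_frames: int

    def __post_init__(self) -> None:
        total = self.planar_fraction + sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class OccupancyGrid:
    """2D histogram over (S, ψ) with circular ψ binning."""

    s_edges: np.ndarray
    psi_edges: np.ndarray
    counts: np.ndarray  # (n_s_bins, n_psi_bins) integers

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())


def _values(seq, attr: str) -> np.ndarray:
    arr = np.asarray(
        [getattr(x, attr) if hasattr(x, attr) else x for x in seq], dtype=float
    )
    return arr


def summarize(values) -> SummaryStats:
    """Range/mean/median summary; median of an even count is the midpoint."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sequence")
    return SummaryStats(
        range_width=float(arr.max() - arr.min()),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        n_frames=int(arr.size),
    )


def histogram_s(states, bin_width: float) -> pd.DataFrame:
    """Relative-frequency histogram of puckering amplitude S.

    Bins are [k·w, (k+1)·w) from 0 to just past the maximum; frequencies sum
    to 1.  Accepts PuckerState records or raw S values.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    s = _values(states, "S")
    n_bins = max(1, int(np.floor(s.max() / bin_width)) + 1)
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(s, bins=edges)
    return pd.DataFrame(
        {
            "s_lo": edges[:-1],
            "s_hi": edges[1:],
            "frequency": counts / s.size,
        }
    )


def occupancy_grid(states, s_bins: int, psi_bins: int, s_max: float | None = None) -> OccupancyGrid:
    """Joint (S, ψ) occupancy counts; ψ is binned circularly on [0, 360)."""
    if s_bins < 1 or psi_bins < 1:
        raise ValueError("bin counts must be ≥ 1")
    s = _values(states, "S")
    psi = _values(states, "psi") % 360.0
    if s_max is None:
        s_max = float(s.max()) if s.max() > 0 else 1.0
    s_edges = np.linspace(0.0, s_max, s_bins + 1)
    psi_edges = np.linspace(0.0, 360.0, psi_bins + 1)
    s_idx = np.clip(np.digitize(s, s_edges) - 1, 0, s_bins - 1)
    psi_idx = np.clip(np.digitize(psi, psi_edges) - 1, 0, psi_bins - 1)
    counts = np.zeros((s_bins, psi_bins), dtype=int)
    np.add.at(counts, (s_idx, psi_idx), 1)
    return OccupancyGrid(s_edges=s_edges, psi_edges=psi_edges, counts=counts)


def occupancy_table(grid: OccupancyGrid) -> pd.DataFrame:
    """Long-format table of the occupancy grid with explicit bin edges."""
    rows = []
    for i in range(grid.counts.shape[0]):
        for j in range(grid.counts.shape[1]):
            rows.append(
                {
                    "s_lo": grid.s_edges[i],
                    "s_hi": grid.s_edges[i + 1],
                    "psi_lo": grid.psi_edges[j],
                    "psi_hi": grid.psi_edges[j + 1],
                    "count": grid.counts[i, j],
                }
            )
    return pd.DataFrame(rows)


def populations(
    assignments: list[ConformerAssignment],
    classes: list[ConformerClass] | None = None,
) -> PopulationTable:
    """Planar fraction and per-class fractions over a set of assignments.

    Classes absent from the assignments get fraction 0 when ``classes`` is
    supplied (so population tables from different runs align).
    """
    if not assignments:
        raise ValueError("cannot compute populations of an empty assignment list")
    n = len(assignments)
    planar = sum(1 for a in assignments if a.planar)
    labels = [c.label for c in classes] if classes is not None else []
    counts: dict[str, int] = {lbl: 0 for lbl in labels}
    for a in assignments:
        if a.cls is not None:
            counts[a.cls.label] = counts.get(a.cls.label, 0) + 1
    return PopulationTable(
        planar_fraction=planar / n,
        class_fractions={lbl: c / n for lbl, c in counts.items()},
        n_frames=n,
    )
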