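"""Temporal reorganization of the functional network.

Quantifies how fast the network rewires: strength increments between
consecutive windows, ``ΔS = |S_i − S_{i−1}|`` at the network level and
``Δs_i = |s_{i,t} − s_{i,t−1}|`` per node, their empirical survival
(complementary cumulative) distributions ``P_c(ΔS) = P(ΔS ≥ x)`` per group
and regime, between-group survival differences, and nodal contrast maps.

Each increment inherits the regime of its *later* window, so the single
increment straddling the maintenance→interference boundary counts as
interference.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .network_metrics import GroupMetricSummary, MetricSeries
from .synthetic_data import SensorLayout


@dataclass
class FluctuationEntry:
    """Strength increments of one subject at one level (network or node)."""

    subject_id: str | None
    group: str | None
    level: str  # "network" or "node"
    increments: np.ndarray  # (W-1,) or (W-1, N)
    regimes: np.ndarray  # (W-1,) regime of the later window


@dataclass
class FluctuationSeries:
    """Collection of per-subject strength-increment records."""

    entries: list

    def subset(self, group: str | None = None,
               level: str | None = None) -> "FluctuationSeries":
        kept = [e for e in self.entries
                if (group is None or e.group == group)
                and (level is None or e.level == level)]
        return FluctuationSeries(kept)

    @classmethod
    def pool(cls, parts: Sequence["FluctuationSeries"]) -> "FluctuationSeries":
        entries: list = []
        for p in parts:
            entries.extend(p.entries)
        return cls(entries)


def strength_increments(metrics: MetricSeries,
                        level: str = "network") -> FluctuationSeries:
    """Absolute first differences of the strength trace(s) of one subject."""
    if level not in ("network", "node"):
        raise ValueError("level must be 'network' or 'node'")
    if metrics.n_windows < 2:
        raise ValueError("need at least 2 windows to form increments")
    trace = (metrics.network["S"] if level == "network"
             else metrics.node_strength)
    inc = np.abs(np.diff(trace, axis=0))
    regimes = np.asarray(metrics.regimes)[1:]
    entry = FluctuationEntry(
        subject_id=metrics.subject_id,
        group=metrics.group,
        level=level,
        increments=inc,
        regimes=regimes,
    )
    return FluctuationSeries([entry])


class SurvivalCurve(NamedTuple):
    """Empirical survival distribution of pooled strength increments."""

    grid: np.ndarray
    probs: np.ndarray  # P(increment >= grid value)
    group: str | None
    regime: str | None
    n_obs: int


def _pooled_increments(flucts: FluctuationSeries, group: str,
                       regime: str) -> np.ndarray:
    vals = []
    for e in flucts.entries:
        if e.group != group or e.level != "network":
            continue
        mask = e.regimes == regime
        vals.append(np.asarray(e.increments)[mask])
    if not vals:
        return np.empty(0)
    return np.concatenate(vals)


def survival_distribution(flucts: FluctuationSeries, group: str, regime: str,
                          grid: np.ndarray | None = None) -> SurvivalCurve:
    """``P_c(x) = P(ΔS ≥ x)`` for one group × regime cell.

    Increments are pooled across subjects and time steps.  By default the
    grid is the exact set of observed values plus 0, giving the exact
    empirical curve (``P_c(0) = 1``, non-increasing); an explicit grid can
    be supplied for plotting or between-group comparison.
    """
    data = _pooled_increments(flucts, group, regime)
    if data.size == 0:
        raise ValueError(f"no increments for group={group!r}, regime={regime!r}")
    if grid is None:
        grid = np.unique(np.concatenate([[0.0], data]))
    else:
        grid = np.asarray(grid, dtype=float)
        if np.any(np.diff(grid) < 0):
            raise ValueError("grid must be sorted ascending")
    # P(X >= x): count of data >= x
    probs = 1.0 - np.searchsorted(np.sort(data), grid, side="left") / data.size
    return SurvivalCurve(grid=grid, probs=probs, group=group, regime=regime,
                         n_obs=int(data.size))


class DifferenceCurve(NamedTuple):
    """Pointwise difference of two survival curves on a common grid."""

    grid: np.ndarray
    diff: np.ndarray  # P_c(first) - P_c(second)
    regime: str | None


def survival_group_difference(curve_a: SurvivalCurve,
                              curve_b: SurvivalCurve) -> DifferenceCurve:
    """Pointwise ``P_c^A − P_c^B``; both curves must share the grid."""
    if curve_a.grid.shape != curve_b.grid.shape or \
            not np.allclose(curve_a.grid, curve_b.grid):
        raise ValueError("survival curves must share a common grid")
    return DifferenceCurve(grid=curve_a.grid,
                           diff=curve_a.probs - curve_b.probs,
                           regime=curve_a.regime)


def nodal_strength_contrast(summary_a: GroupMetricSummary,
                            summary_b: GroupMetricSummary,
                            regime: str,
                            group_a: str | None = None,
                            group_b: str | None = None) -> np.ndarray:
    """Per-node difference of group-mean regime-averaged strengths (A − B).

    Each summary contributes one group (picked explicitly via
    ``group_a``/``group_b`` when a summary holds several).
    """
    def _pick(summary: GroupMetricSummary, label: str | None) -> np.ndarray:
        if label is None:
            if len(summary.groups) != 1:
                raise ValueError("summary holds several groups; name one")
            label = next(iter(summary.groups))
        nodal = summary.groups[label].nodal_strength
        if regime not in nodal:
            raise ValueError(f"no {regime!r} windows in summary")
        return nodal[regime]

    a = _pick(summary_a, group_a)
    b = _pick(summary_b, group_b)
    if a.shape != b.shape:
        raise ValueError("node sets differ between groups")
    return a - b


def nodal_fluctuation_contrast(flucts: FluctuationSeries,
                               group: str) -> np.ndarray:
    """Per-node mean ``Δs`` in maintenance minus mean ``Δs`` in interference.

    Nodal increments of the group are pooled across subjects and time steps
    within each regime; positive values mark nodes that reorganize more
    during maintenance than under interference.
    """
    per_regime = {}
    for regime in ("MM", "I"):
        parts = []
        for e in flucts.entries:
            if e.group != group or e.level != "node":
                continue
            mask = e.regimes == regime
            parts.append(np.asarray(e.increments)[mask])
        if not parts or sum(p.shape[0] for p in parts) == 0:
            raise ValueError(f"no nodal increments in regime {regime!r}")
        per_regime[regime] = np.concatenate(parts, axis=0).mean(axis=0)
    return per_regime["MM"] - per_regime["I"]


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------
def survival_to_tsv(curves: Sequence[SurvivalCurve], path) -> None:
    """Write survival curves as a long TSV (group, regime, x, P_c)."""
    import pandas as pd

    rows = []
    for c in curves:
        for x, p in zip(c.grid, c.probs):
            rows.append({"group": c.group, "regime": c.regime,
                         "x": x, "P_c": p})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def nodal_map_to_tsv(values: np.ndarray, layout: SensorLayout, path) -> None:
    """Write a nodal map as TSV (node, x, y, z, value) for topography plots."""
    import pandas as pd

    if len(values) != layout.n_channels:
        raise ValueError("one value per sensor required")
    df = pd.DataFrame(layout.coords, columns=["x", "y", "z"])
    df.insert(0, "node", list(layout.channels))
    df["value"] = np.asarray(values, dtype=float)
    df.to_csv(path, sep="\t", index=False)
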