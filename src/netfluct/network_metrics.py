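"""Weighted network measures of the time-varying synchronization graphs.

Five measures are computed per 50-ms window, first per node and then at the
network level:

- strength ``s_i = Σ_j w_ij`` — total coupling of a node;
- outreach ``o_i = Σ_j w_ij · l_ij`` with ``l_ij`` the physical sensor
  distance in meters — how synchronization correlates with link length;
- weighted clustering ``c_i`` (Onnela geometric-mean triangle intensity,
  weights normalized by the global maximum) — local triplet density;
- average shortest path ``SP`` and global efficiency ``E_g`` over the
  topological link lengths ``d_ij = 1/w_ij``.

Network-level S, O and C_w are means over nodes (comparable across channel
counts); E_g and SP are global by construction.  Graphs stay fully weighted
— no thresholding or binarization is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .synthetic_data import SensorLayout
from .spectral_sync import SyncMatrixSeries

#: network-level metric names, in reporting order
NETWORK_METRICS = ("S", "O", "Cw", "Eg", "SP")

#: window-averaging spans: memory maintenance, interference, whole epoch
SPANS = ("MM", "I", "MM+I")


def _check_weight_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be a square matrix")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("W must be symmetric")
    if (W < 0).any():
        raise ValueError("W must be non-negative")
    if np.abs(np.diag(W)).max(initial=0.0) > 1e-12:
        raise ValueError("W must have a zero diagonal")
    return W


def node_strength(W: np.ndarray) -> np.ndarray:
    """Nodal strength ``s_i = Σ_j w_ij``."""
    W = _check_weight_matrix(W)
    return W.sum(axis=1)


def node_outreach(W: np.ndarray, layout: SensorLayout) -> np.ndarray:
    """Nodal outreach ``o_i = Σ_j w_ij · l_ij`` (weight × meters)."""
    W = _check_weight_matrix(W)
    if layout.n_channels != W.shape[0]:
        raise ValueError("layout does not cover all nodes")
    return (W * layout.distances()).sum(axis=1)


def weighted_clustering(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    ``c_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i (k_i − 1))`` with
    ``ŵ = w / max(w)`` and ``k_i`` the number of neighbors with nonzero
    weight; nodes with fewer than two neighbors get 0.  Values lie in
    [0, 1], reaching 1 only for a clique of maximal equal weights.
    """
    W = _check_weight_matrix(W)
    n = W.shape[0]
    if n < 3:
        raise ValueError("clustering requires at least 3 nodes")
    wmax = W.max()
    if wmax == 0:
        return np.zeros(n)
    a = np.cbrt(W / wmax)
    num = np.einsum("ij,ih,jh->i", a, a, a)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    out = np.zeros(n)
    mask = denom > 0
    out[mask] = num[mask] / denom[mask]
    return out


class PathStats(NamedTuple):
    """Shortest-path summary of one weighted graph."""

    sp: float  # mean shortest-path distance over connected pairs
    eg: float  # global efficiency (inverse harmonic mean of distances)
    distances: np.ndarray  # (N, N) all-pairs shortest-path matrix
    connected: bool  # False when some pair is unreachable


def shortest_path_stats(W: np.ndarray) -> PathStats:
    """Average shortest path and global efficiency.

    Link lengths are the inverse weights ``d_ij = 1/w_ij`` (absent links are
    infinitely long); distances are all-pairs shortest paths over those
    lengths.  ``SP`` averages the finite off-diagonal distances (pairs in
    different components are excluded and flagged); ``E_g`` averages
    ``1/D_ij`` with unreachable pairs contributing 0 — for a connected
    graph this is the inverse harmonic mean of the distances.
    """
    W = _check_weight_matrix(W)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    ii, jj = np.nonzero(W)
    lengths = coo_matrix((1.0 / W[ii, jj], (ii, jj)), shape=W.shape)
    D = _csgraph_shortest_path(lengths.tocsr(), directed=False)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(D) & off
    connected = bool(finite.sum() == n * (n - 1))
    if finite.any():
        sp = float(D[finite].mean())
    else:
        sp = float("inf")
    inv = np.zeros_like(D)
    inv[finite] = 1.0 / D[finite]
    eg = float(inv[off].mean())
    return PathStats(sp=sp, eg=eg, distances=D, connected=connected)


@dataclass
class MetricSeries:
    """Nodal and network-level metric values for every window of one subject."""

    subject_id: str | None
    group: str | None
    band: str
    window_starts_ms: np.ndarray  # (W,)
    window_ms: float
    regimes: np.ndarray  # (W,) "MM" / "I"
    node_strength: np.ndarray  # (W, N)
    node_outreach: np.ndarray  # (W, N)
    node_clustering: np.ndarray  # (W, N)
    network: dict  # metric name -> (W,) array
    connected: np.ndarray  # (W,) bool

    @property
    def n_windows(self) -> int:
        return self.node_strength.shape[0]

    @property
    def n_channels(self) -> int:
        return self.node_strength.shape[1]

    def to_tidy(self):
        """Long-format table: one row per (window, metric, node-or-network)."""
        import pandas as pd

        rows = []
        nodal = {"S": self.node_strength, "O": self.node_outreach,
                 "Cw": self.node_clustering}
        for w in range(self.n_windows):
            base = {
                "subject": self.subject_id, "group": self.group,
                "band": self.band, "window_index": w,
                "window_start_ms": self.window_starts_ms[w],
                "regime": self.regimes[w],
            }
            for m in NETWORK_METRICS:
                rows.append({**base, "metric": m, "level": "network",
                             "value": self.network[m][w]})
            for m, arr in nodal.items():
                for node in range(self.n_channels):
                    rows.append({**base, "metric": m, "level": str(node),
                                 "value": arr[w, node]})
        return pd.DataFrame(rows)


def metric_series(series: SyncMatrixSeries, layout: SensorLayout) -> MetricSeries:
    """All five network measures for every window of a matrix series."""
    if layout.n_channels != series.n_channels:
        raise ValueError("layout does not cover all nodes")
    dist = layout.distances()
    nw, n = series.n_windows, series.n_channels
    s = np.empty((nw, n))
    o = np.empty((nw, n))
    c = np.empty((nw, n))
    eg = np.empty(nw)
    sp = np.empty(nw)
    conn = np.empty(nw, dtype=bool)
    for w in range(nw):
        W = series.matrices[w]
        s[w] = node_strength(W)
        o[w] = (W * dist).sum(axis=1)
        c[w] = weighted_clustering(W)
        stats = shortest_path_stats(W)
        eg[w], sp[w], conn[w] = stats.eg, stats.sp, stats.connected
    network = {"S": s.mean(axis=1), "O": o.mean(axis=1), "Cw": c.mean(axis=1),
               "Eg": eg, "SP": sp}
    return MetricSeries(
        subject_id=series.subject_id,
        group=series.group,
        band=str(series.band),
        window_starts_ms=np.array([a for a, _ in series.windows]),
        window_ms=series.window_ms,
        regimes=np.asarray(series.regimes),
        node_strength=s,
        node_outreach=o,
        node_clustering=c,
        network=network,
        connected=conn,
    )


def span_mask(regimes: np.ndarray, span: str) -> np.ndarray:
    """Boolean window mask for an averaging span (MM, I or MM+I)."""
    regimes = np.asarray(regimes)
    if span == "MM+I":
        return np.ones(regimes.shape, dtype=bool)
    if span in ("MM", "I"):
        return regimes == span
    raise ValueError(f"span must be one of {SPANS}")


def average_windows(metrics: MetricSeries, span: str) -> dict:
    """Window-average of every network metric over one span."""
    mask = span_mask(metrics.regimes, span)
    if not mask.any():
        raise ValueError(f"no windows in span {span!r}")
    return {m: float(metrics.network[m][mask].mean()) for m in NETWORK_METRICS}


@dataclass
class GroupSummary:
    """Ensemble mean ± standard error for one group."""

    n_subjects: int
    window_mean: dict  # metric -> (W,)
    window_sem: dict  # metric -> (W,); NaN when n_subjects < 2
    span_mean: dict  # span -> {metric: float}
    span_sem: dict  # span -> {metric: float}
    nodal_strength: dict = field(default_factory=dict)  # regime -> (N,)
    sem_defined: bool = True


@dataclass
class GroupMetricSummary:
    """Per-group ensemble summaries on a common window grid."""

    window_starts_ms: np.ndarray
    regimes: np.ndarray
    groups: dict  # group label -> GroupSummary


def _sem(values: np.ndarray, axis: int = 0) -> np.ndarray:
    n = values.shape[axis]
    if n < 2:
        return np.full(np.delete(values.shape, axis), np.nan)
    return values.std(axis=axis, ddof=1) / np.sqrt(n)


def group_summary(cohort_metrics: Sequence[MetricSeries]) -> GroupMetricSummary:
    """Average each metric over the subjects of each group.

    Produces per-window and per-span means with their standard errors, plus
    the group-mean regime-averaged nodal strength maps used by the nodal
    contrast analyses.  With a single subject in a group the mean is
    reported and the standard error flagged undefined (NaN).
    """
    if not cohort_metrics:
        raise ValueError("no metric series given")
    ref = cohort_metrics[0]
    for m in cohort_metrics[1:]:
        if not np.array_equal(m.window_starts_ms, ref.window_starts_ms):
            raise ValueError("all subjects must share the window grid")
    groups: dict = {}
    labels = sorted({m.group for m in cohort_metrics}, key=str)
    for g in labels:
        members = [m for m in cohort_metrics if m.group == g]
        stacked = {metric: np.stack([m.network[metric] for m in members])
                   for metric in NETWORK_METRICS}
        window_mean = {k: v.mean(axis=0) for k, v in stacked.items()}
        window_sem = {k: _sem(v) for k, v in stacked.items()}
        span_mean: dict = {}
        span_sem: dict = {}
        for span in SPANS:
            per_subject = {metric: np.array(
                [average_windows(m, span)[metric] for m in members])
                for metric in NETWORK_METRICS}
            span_mean[span] = {k: float(v.mean()) for k, v in per_subject.items()}
            span_sem[span] = {k: float(_sem(v)) for k, v in per_subject.items()}
        nodal = {}
        for regime in ("MM", "I"):
            mask = span_mask(ref.regimes, regime)
            if mask.any():
                nodal[regime] = np.stack(
                    [m.node_strength[mask].mean(axis=0) for m in members]
                ).mean(axis=0)
        groups[g] = GroupSummary(
            n_subjects=len(members),
            window_mean=window_mean,
            window_sem=window_sem,
            span_mean=span_mean,
            span_sem=span_sem,
            nodal_strength=nodal,
            sem_defined=len(members) >= 2,
        )
    return GroupMetricSummary(
        window_starts_ms=ref.window_starts_ms,
        regimes=ref.regimes,
        groups=groups,
    )


def metrics_to_tsv(cohort_metrics: Sequence[MetricSeries], path) -> None:
    """Write tidy per-window metric tables for a whole cohort as TSV."""
    import pandas as pd

    pd.concat([m.to_tidy() for m in cohort_metrics],
              ignore_index=True).to_csv(path, sep="\t", index=False)
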