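"""Shared fixtures: small synthetic objects built programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from netfluct import (EpochSet, MetricSeries, PhaseTensor, BandSpec,
                      make_sensor_layout)

FS = 678.17  # Hz, the acquisition rate of the emulated system
ALPHA_BAND = BandSpec(8.0, 12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def layout6():
    return make_sensor_layout(6, seed=0)


def make_epochs(data: np.ndarray, fs: float = FS, t0_ms: float = -500.0,
                boundary_ms: float = 500.0, labels=None,
                baseline: np.ndarray | None = None,
                group: str = "young") -> EpochSet:
    if baseline is None:
        baseline = np.zeros((data.shape[1], int(round(0.1 * fs))))
    return EpochSet(subject_id="test", group=group, data=data,
                    sampling_rate=fs, t0_ms=t0_ms,
                    regime_boundary_ms=boundary_ms, labels=labels,
                    baseline=baseline)


def make_phases(phases: np.ndarray, fs: float = FS,
                boundary_ms: float = 500.0) -> PhaseTensor:
    return PhaseTensor(phases=phases, band=ALPHA_BAND, sampling_rate=fs,
                       t0_ms=-boundary_ms, regime_boundary_ms=boundary_ms)


def make_metrics(strength_trace: np.ndarray, boundary_ms: float = 500.0,
                 window_ms: float = 50.0, n_channels: int = 4,
                 node_strength: np.ndarray | None = None,
                 subject_id: str = "s", group: str = "young") -> MetricSeries:
    """MetricSeries with a prescribed network strength trace.

    Nodal strengths default to the network trace replicated per node; the
    other metrics are filled with placeholder copies of the trace.
    """
    s = np.asarray(strength_trace, dtype=float)
    nw = s.size
    starts = np.arange(nw) * window_ms
    regimes = np.where(starts >= boundary_ms, "I", "MM")
    if node_strength is None:
        node_strength = np.repeat(s[:, None], n_channels, axis=1)
    network = {m: s.copy() for m in ("S", "O", "Cw", "Eg", "SP")}
    network["S"] = node_strength.mean(axis=1)
    return MetricSeries(
        subject_id=subject_id, group=group, band="alpha",
        window_starts_ms=starts, window_ms=window_ms, regimes=regimes,
        node_strength=node_strength,
        node_outreach=node_strength.copy(),
        node_clustering=np.clip(node_strength, 0, 1),
        network=network,
        connected=np.ones(nw, dtype=bool),
    )
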