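"""Time-resolved weighted synchronization matrices from phase locking.

The pipeline stage that turns cleaned epochs into the time-varying network:
narrow-band decomposition (4-Hz bands from 8 to 48 Hz), instantaneous
phases via the Hilbert transform, phase-locking value (PLV) in consecutive
non-overlapping 50-ms windows, normalization against a short resting
baseline, and merging of narrow bands into the classical broad bands.

For two phase series the PLV over a window is

    PLV = |⟨e^{iφ(t)}⟩| = sqrt(⟨cos φ⟩² + ⟨sin φ⟩²),   φ = φ_i − φ_j,

with the average taken over all samples of the window pooled across trials.
PLV is 1 when the relative phase is constant and 0 when it is uniformly
spread over the unit circle.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal

from .preprocessing import EpochSet

logger = logging.getLogger("netfluct")

#: broad-band spans in Hz; downstream analysis defaults to alpha
BROAD_BANDS = {"alpha": (8.0, 12.0), "beta": (12.0, 30.0), "gamma": (30.0, 48.0)}


@dataclass(frozen=True)
class BandSpec:
    """A narrow frequency band ``[low, high]`` with its center frequency."""

    low: float
    high: float
    center: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        center = self.center
        if center is None:
            center = 0.5 * (self.low + self.high)
        object.__setattr__(self, "center", float(center))
        if not self.low < self.center < self.high:
            raise ValueError("band requires low < center < high")


def make_bands(f_start: float = 8.0, f_stop: float = 48.0,
               step: float = 4.0) -> list[BandSpec]:
    """Contiguous narrow bands covering ``[f_start, f_stop]`` in steps of ``step``."""
    if f_start >= f_stop:
        raise ValueError("f_start must be below f_stop")
    if step <= 0:
        raise ValueError("step must be positive")
    n = (f_stop - f_start) / step
    if abs(n - round(n)) > 1e-9:
        raise ValueError("(f_stop - f_start) must be divisible by step")
    return [BandSpec(f_start + k * step, f_start + (k + 1) * step)
            for k in range(int(round(n)))]


@dataclass
class PhaseTensor:
    """Instantaneous phases of band-limited signals, radians in (−π, π]."""

    phases: np.ndarray  # (trials, channels, samples)
    band: BandSpec
    sampling_rate: float
    t0_ms: float = 0.0
    regime_boundary_ms: float = 0.0  # epoch time of the MM -> I switch
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 3:
            raise ValueError("phases must be (trials, channels, samples)")

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    @property
    def n_channels(self) -> int:
        return self.phases.shape[1]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[2]


def _bandpass_phase(arr: np.ndarray, fs: float, band: BandSpec,
                    pad_ms: float) -> np.ndarray:
    """Band-pass filter and return Hilbert phases, edge-padded.

    The signal is extended by reflection before filtering and the analytic
    transform, and the extension is discarded afterwards, which suppresses
    the edge artifacts the Hilbert transform otherwise produces.  The pad is
    capped at ``n_samples − 1`` (reflection cannot exceed the signal).
    """
    n = arr.shape[-1]
    n_pad = min(int(round(pad_ms / 1000.0 * fs)), n - 1)
    if n_pad > 0:
        arr = np.concatenate(
            [arr[..., 1:n_pad + 1][..., ::-1], arr,
             arr[..., -n_pad - 1:-1][..., ::-1]], axis=-1)
    sos = signal.butter(4, [band.low, band.high], btype="bandpass", fs=fs,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, arr, axis=-1)
    analytic = signal.hilbert(filtered, axis=-1)
    phases = np.angle(analytic)
    if n_pad > 0:
        phases = phases[..., n_pad:n_pad + n]
    return phases


def extract_phase(epochs: EpochSet, band: BandSpec, pad_ms: float = 200.0,
                  which: str = "trials") -> PhaseTensor:
    """Instantaneous phase per trial/channel in one narrow band.

    ``which="baseline"`` extracts phases from the resting baseline segment
    instead (returned as a single-trial tensor).
    """
    nyq = epochs.sampling_rate / 2.0
    if not 0 < band.low < band.high < nyq:
        raise ValueError(f"band must lie inside (0, {nyq}) Hz")
    if pad_ms < 0:
        raise ValueError("pad_ms must be >= 0")
    if which == "trials":
        arr = epochs.data
    elif which == "baseline":
        if epochs.baseline is None:
            raise ValueError("epochs carry no baseline segment")
        arr = epochs.baseline[None, :, :]
    else:
        raise ValueError("which must be 'trials' or 'baseline'")
    phases = _bandpass_phase(arr, epochs.sampling_rate, band, pad_ms)
    return PhaseTensor(
        phases=phases,
        band=band,
        sampling_rate=epochs.sampling_rate,
        t0_ms=epochs.t0_ms,
        regime_boundary_ms=epochs.regime_boundary_ms,
        subject_id=epochs.subject_id,
        group=epochs.group,
    )


@dataclass
class SyncMatrixSeries:
    """Per-window N×N symmetric weighted synchronization matrices.

    ``windows`` holds half-open ``(start_ms, stop_ms)`` intervals in epoch
    time (0 at epoch start); a window belongs to the interference regime
    iff its start lies at or after the regime boundary.
    """

    windows: list  # [(start_ms, stop_ms), ...]
    matrices: np.ndarray  # (n_windows, N, N)
    band: str | BandSpec
    regimes: np.ndarray  # (n_windows,) "MM" / "I"
    normalized: bool = False
    window_ms: float = 50.0
    subject_id: str | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3 or self.matrices.shape[1] != self.matrices.shape[2]:
            raise ValueError("matrices must be (n_windows, N, N)")
        if len(self.windows) != self.matrices.shape[0]:
            raise ValueError("one (start, stop) pair per window required")
        self.regimes = np.asarray(self.regimes)

    @property
    def n_windows(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[1]


def _window_sample_edges(n_samples: int, fs: float,
                         window_ms: float) -> list[tuple[int, int]]:
    """Sample index edges of consecutive non-overlapping windows.

    Edges are placed at ``round(w · window_ms · fs / 1000)`` so rounding
    error never accumulates: a nominal 1500-ms epoch at 678.17 Hz (1017
    samples) yields exactly 30 windows of 33–34 samples.  A trailing
    partial window is dropped with a warning.
    """
    spw = window_ms * fs / 1000.0
    edges = []
    w = 0
    while True:
        a = int(round(w * spw))
        b = int(round((w + 1) * spw))
        if b > n_samples:
            if n_samples - a >= 1 and edges:
                logger.warning("dropping trailing partial window of %d samples",
                               n_samples - a)
            break
        edges.append((a, b))
        w += 1
    return edges


def plv_matrix(phases: np.ndarray) -> np.ndarray:
    """PLV between all channel pairs, pooling every sample given.

    ``phases`` is (trials, channels, samples) or (channels, samples); the
    unit phasors of all trials and samples are pooled per channel and the
    PLV of a pair is the modulus of the mean phasor of their phase
    difference.  The diagonal is zeroed (self-coupling carries no network
    information).
    """
    if phases.ndim == 2:
        phases = phases[None]
    z = np.exp(1j * phases)  # (trials, channels, samples)
    v = z.transpose(1, 0, 2).reshape(phases.shape[1], -1)
    m = v.shape[1]
    g = (v @ v.conj().T) / m
    plv = np.abs(g)
    plv = 0.5 * (plv + plv.T)
    np.clip(plv, 0.0, 1.0, out=plv)
    np.fill_diagonal(plv, 0.0)
    return plv


def windowed_plv(phases: PhaseTensor, window_ms: float = 50.0) -> SyncMatrixSeries:
    """PLV matrices in consecutive non-overlapping windows.

    Samples are pooled across trials within each window, giving one matrix
    per window per subject.  Entries lie in [0, 1]; matrices are symmetric
    with zero diagonal.
    """
    spw = window_ms * phases.sampling_rate / 1000.0
    if spw < 2:
        raise ValueError("window must span at least 2 samples")
    edges = _window_sample_edges(phases.n_samples, phases.sampling_rate,
                                 window_ms)
    if not edges:
        raise ValueError("epoch shorter than one window")
    mats = np.empty((len(edges), phases.n_channels, phases.n_channels))
    for w, (a, b) in enumerate(edges):
        mats[w] = plv_matrix(phases.phases[:, :, a:b])
    windows = [(w * window_ms, (w + 1) * window_ms) for w in range(len(edges))]
    regimes = np.array(["I" if start >= phases.regime_boundary_ms else "MM"
                        for start, _ in windows])
    return SyncMatrixSeries(
        windows=windows,
        matrices=mats,
        band=phases.band,
        regimes=regimes,
        normalized=False,
        window_ms=window_ms,
        subject_id=phases.subject_id,
        group=phases.group,
    )


def normalize_to_baseline(series: SyncMatrixSeries, baseline: PhaseTensor,
                          baseline_ms: float | None = None,
                          floor: float = 0.05) -> SyncMatrixSeries:
    """Divide task-window PLVs by each pair's resting-baseline PLV.

    The whole baseline segment is treated as a single window (a 100-ms
    baseline is too short for stable sub-windows).  Baseline PLVs are
    floored at ``floor`` before division so near-zero resting coupling
    cannot blow the ratio up; floored pairs are counted and logged.
    """
    if series.normalized:
        raise ValueError("series is already normalized")
    if baseline.n_channels != series.n_channels:
        raise ValueError("baseline channel count differs from series")
    if isinstance(series.band, BandSpec) and isinstance(baseline.band, BandSpec):
        if (series.band.low, series.band.high) != (baseline.band.low,
                                                   baseline.band.high):
            raise ValueError("baseline band differs from series band")
    n = baseline.n_samples
    if baseline_ms is not None:
        if baseline_ms < series.window_ms:
            raise ValueError("baseline_ms must be >= the analysis window")
        n = min(n, int(round(baseline_ms / 1000.0 * baseline.sampling_rate)))
    b = plv_matrix(baseline.phases[:, :, :n])
    off = ~np.eye(series.n_channels, dtype=bool)
    n_floored = int((b[off] < floor).sum()) // 2
    if n_floored:
        logger.info("%s: %d baseline pairs floored at %g",
                    series.subject_id, n_floored, floor)
    denom = np.maximum(b, floor)
    mats = series.matrices / denom[None, :, :]
    for m in mats:
        np.fill_diagonal(m, 0.0)
    return replace(series, matrices=mats, normalized=True)


def merge_bands(series_list: Sequence[SyncMatrixSeries],
                target: str) -> SyncMatrixSeries:
    """Average narrow-band matrix series into one broad band.

    A narrow band is a constituent of the broad band iff its center lies in
    the half-open broad interval ``[low, high)`` — for the canonical 4-Hz
    scheme this makes alpha = {8–12}, beta = {12–16, …, 24–28} and
    gamma = {28–32, …, 44–48} with every edge band assigned to exactly one
    broad band.  The output is the elementwise arithmetic mean per window.
    """
    if target not in BROAD_BANDS:
        raise ValueError(f"unknown broad band {target!r}")
    low, high = BROAD_BANDS[target]
    members = [s for s in series_list
               if isinstance(s.band, BandSpec) and low <= s.band.center < high]
    if not members:
        raise ValueError(f"no constituent narrow band for {target!r}")
    ref = members[0]
    for s in members[1:]:
        if s.n_channels != ref.n_channels or s.windows != ref.windows:
            raise ValueError("constituent series must share windows and channels")
        if s.normalized != ref.normalized:
            raise ValueError("cannot mix normalized and raw series")
    mats = np.mean([s.matrices for s in members], axis=0)
    return replace(ref, matrices=mats, band=target)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------
def save_sync_hdf5(series: SyncMatrixSeries, path) -> None:
    """Persist a matrix series (/windows, /W, /meta)."""
    import h5py

    with h5py.File(path, "w") as f:
        win = np.array([(a, b) for a, b in series.windows], dtype=float)
        f.create_dataset("windows", data=win)
        f.create_dataset("regimes", data=np.array(series.regimes, dtype="S"))
        f.create_dataset("W", data=series.matrices)
        meta = f.create_group("meta")
        band = series.band
        meta.attrs["band"] = (f"{band.low}-{band.high}"
                              if isinstance(band, BandSpec) else str(band))
        meta.attrs["normalized"] = series.normalized
        meta.attrs["window_ms"] = series.window_ms
        meta.attrs["subject_id"] = series.subject_id or ""
        meta.attrs["group"] = series.group or ""


def save_sync_csv(series: SyncMatrixSeries, directory) -> None:
    """Export per-window matrices as CSV files."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for w, mat in enumerate(series.matrices):
        np.savetxt(d / f"window_{w:02d}.csv", mat, delimiter=",")
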