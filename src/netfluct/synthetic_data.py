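"""Two-group, two-regime synthetic multichannel oscillator cohorts.

Generates epoched signals whose channels are band-limited phase-coupled
oscillators (stochastic mean-field Kuramoto model) so that every downstream
stage of the analysis — phase extraction, windowed phase-locking, network
metrics, fluctuation statistics and group tests — can be exercised against
a known ground truth.

Model
-----
Each channel ``k`` of a trial carries ``x_k(t) = sin(θ_k(t)) + ε_k(t)``
where the phases evolve by Euler–Maruyama integration at the sampling rate:

    dθ_k = 2π f dt + K(t) · r · sin(ψ − θ_k) dt + σ_p √dt · ξ

with ``f`` the band-center frequency, ``r e^{iψ}`` the Kuramoto mean field
over channels of the trial, ``σ_p`` the phase-noise scale (rad/√s) and
``ε`` white measurement noise.  The global coupling ``K(t)`` takes the
maintenance value before the regime boundary and the interference value
after it — the switch is instantaneous, mirroring an abrupt stimulus onset
— and is additionally jittered per 50-ms block by ``exp(σ_vol · Z)`` with
``Z`` standard normal, shared across trials of a subject, which produces
controllable window-to-window strength fluctuations.  A separate resting
baseline segment is generated with coupling 0.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .preprocessing import ERROR, HIT, EpochSet

logger = logging.getLogger("netfluct")

GROUPS = ("young", "old")
REGIMES = ("MM", "I")


# ---------------------------------------------------------------------------
# sensor layout
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class SensorLayout:
    """Channel identifiers with 3D positions (meters).

    The Euclidean distance between sensors supplies the physical link
    lengths entering the outreach metric.
    """

    channels: tuple
    coords: np.ndarray  # (N, 3), meters

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.channels) != coords.shape[0]:
            raise ValueError("one coordinate row per channel required")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "channels", tuple(self.channels))

    @property
    def n_channels(self) -> int:
        return self.coords.shape[0]

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distance matrix in meters."""
        return squareform(pdist(self.coords))

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.coords, columns=["x", "y", "z"])
        df.insert(0, "channel", list(self.channels))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorLayout":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(tuple(df["channel"].astype(str)),
                   df[["x", "y", "z"]].to_numpy(float))


def make_sensor_layout(n_channels: int, seed: int = 0,
                       radius: float = 0.1) -> SensorLayout:
    """Deterministic helmet-like sensor layout.

    Places ``n_channels`` points on the upper hemisphere of a shell of the
    given radius using Fibonacci-spiral spacing (roughly uniform), plus a
    tiny seeded angular jitter so distinct seeds give distinct but equally
    realistic geometries.  All pairwise distances are strictly positive.
    """
    if n_channels < 2:
        raise ValueError("n_channels must be >= 2")
    i = np.arange(n_channels)
    # cos(colatitude) uniform on (0, 1]: upper hemisphere
    z = 1.0 - (i + 0.5) / n_channels  # in (0, 1)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    az = golden * i
    sin_co = np.sqrt(1.0 - z**2)
    pts = np.column_stack([sin_co * np.cos(az), sin_co * np.sin(az), z])
    rng = np.random.default_rng(seed)
    pts = pts + 0.002 * rng.standard_normal(pts.shape)
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    coords = radius * pts
    channels = tuple(f"MEG{k:03d}" for k in range(1, n_channels + 1))
    return SensorLayout(channels, coords)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
def _as_group_map(value, name: str) -> dict:
    """Broadcast a scalar to both groups; validate a mapping."""
    if isinstance(value, Mapping):
        out = {g: float(value[g]) for g in GROUPS}
    else:
        out = {g: float(value) for g in GROUPS}
    for g, v in out.items():
        if v < 0:
            raise ValueError(f"{name}[{g}] must be >= 0")
    return out


def _as_group_regime_map(value, name: str) -> dict:
    """Normalize volatility to {group: {regime: sigma}}.

    Accepts a scalar (same everywhere), a mapping group -> scalar, or a
    mapping group -> (sigma_MM, sigma_I) / {regime: sigma}.
    """
    out: dict = {}
    for g in GROUPS:
        v = value[g] if isinstance(value, Mapping) else value
        if isinstance(v, Mapping):
            pair = {r: float(v[r]) for r in REGIMES}
        elif np.iterable(v) and not isinstance(v, str):
            vv = list(v)
            if len(vv) != 2:
                raise ValueError(f"{name}[{g}] needs (MM, I) values")
            pair = {"MM": float(vv[0]), "I": float(vv[1])}
        else:
            pair = {r: float(v) for r in REGIMES}
        if any(s < 0 for s in pair.values()):
            raise ValueError(f"{name}[{g}] must be >= 0")
        out[g] = pair
    return out


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the acquisition and design constants of the emulated
    study: 148 channels at 678.17 Hz, 1500 ms epochs with the
    maintenance→interference switch 500 ms in, a 100 ms resting baseline,
    32 trials per subject and 9 young / 11 older subjects.  Coupling and
    noise levels are chosen so that windowed phase-locking sits in its
    sensitive mid-range (see the package methods note).
    """

    n_subjects_per_group: Mapping[str, int] | int = field(
        default_factory=lambda: {"young": 9, "old": 11})
    n_channels: int = 148
    n_trials: int = 32
    sampling_rate: float = 678.17
    epoch_ms: float = 1500.0
    regime_boundary_ms: float = 500.0  # epoch time of the MM -> I switch
    baseline_ms: float = 100.0
    band_center: float = 10.0  # Hz, alpha
    coupling_mm: Mapping[str, float] | float = field(
        default_factory=lambda: {"young": 26.0, "old": 28.0})
    coupling_int: Mapping[str, float] | float = field(
        default_factory=lambda: {"young": 12.0, "old": 21.0})
    coupling_volatility: object = field(
        default_factory=lambda: {"young": (1.0, 0.1), "old": (0.1, 1.0)})
    phase_noise_sd: float = 4.0  # rad / sqrt(s)
    noise_sd: float = 0.1
    hit_rate: float = 0.85
    seed: int = 0
    block_ms: float = 50.0  # volatility-jitter block length
    burnin_ms: float = 1000.0  # discarded pre-epoch settling at MM coupling

    def __post_init__(self) -> None:
        if isinstance(self.n_subjects_per_group, int):
            self.n_subjects_per_group = {g: self.n_subjects_per_group
                                         for g in GROUPS}
        else:
            self.n_subjects_per_group = {g: int(self.n_subjects_per_group[g])
                                         for g in GROUPS}
        if any(n < 1 for n in self.n_subjects_per_group.values()):
            raise ValueError("need at least one subject per group")
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for name in ("sampling_rate", "epoch_ms", "baseline_ms", "block_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.regime_boundary_ms < self.epoch_ms:
            raise ValueError("regime_boundary_ms must lie inside the epoch")
        if not 0 <= self.hit_rate <= 1:
            raise ValueError("hit_rate must be in [0, 1]")
        if self.phase_noise_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.burnin_ms < 0:
            raise ValueError("burnin_ms must be >= 0")
        self.coupling_mm = _as_group_map(self.coupling_mm, "coupling_mm")
        self.coupling_int = _as_group_map(self.coupling_int, "coupling_int")
        self.coupling_volatility = _as_group_regime_map(
            self.coupling_volatility, "coupling_volatility")

    def coupling_for(self, group: str, regime: str) -> float:
        return (self.coupling_mm if regime == "MM" else self.coupling_int)[group]

    def volatility_for(self, group: str, regime: str) -> float:
        return self.coupling_volatility[group][regime]


@dataclass
class GroundTruth:
    """Realized coupling schedule of one simulated subject."""

    subject_id: str
    group: str
    block_starts_ms: np.ndarray  # (n_blocks,)
    regimes: np.ndarray  # (n_blocks,) "MM" / "I"
    coupling: np.ndarray  # (n_blocks,) realized K per block
    base_coupling: dict  # {"MM": K, "I": K} before jitter
    volatility: dict  # {"MM": sigma, "I": sigma}
    phases: np.ndarray | None = None  # (trials, channels, samples) if kept


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------
def _integrate_phases(rng: np.random.Generator, theta: np.ndarray,
                      n_samples: int, dt: float, omega: float,
                      coupling_per_sample: np.ndarray,
                      phase_noise_sd: float) -> np.ndarray:
    """Euler–Maruyama integration of the mean-field phase model.

    Starts from the state ``theta`` (n_trials, n_channels) and returns
    phases (n_trials, n_channels, n_samples); sample ``s`` holds the state
    *before* the ``s``-th update, so the first sample carries ``theta``.
    """
    n_trials, n_channels = theta.shape
    noise = (phase_noise_sd * np.sqrt(dt)
             * rng.standard_normal((n_samples, n_trials, n_channels)))
    out = np.empty((n_trials, n_channels, n_samples))
    for s in range(n_samples):
        out[:, :, s] = theta
        m = np.exp(1j * theta).mean(axis=1)  # mean field per trial
        pull = np.abs(m)[:, None] * np.sin(np.angle(m)[:, None] - theta)
        theta = theta + omega * dt + coupling_per_sample[s] * pull * dt + noise[s]
    return out


def simulate_subject(config: SyntheticConfig, group: str, subject_seed: int,
                     subject_id: str | None = None,
                     keep_phases: bool = False) -> tuple[EpochSet, GroundTruth]:
    """Simulate one subject's epoched trials, baseline and labels.

    The RNG is seeded with ``subject_seed`` only, so a subject is bit-wise
    reproducible independently of the rest of the cohort.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    rng = np.random.default_rng(subject_seed)
    if subject_id is None:
        subject_id = f"{group}-{subject_seed}"
    fs = config.sampling_rate
    dt = 1.0 / fs
    omega = 2.0 * np.pi * config.band_center
    n_samples = int(round(config.epoch_ms / 1000.0 * fs))

    # per-block coupling schedule, shared across trials
    n_blocks = int(config.epoch_ms // config.block_ms)
    block_starts = np.arange(n_blocks) * config.block_ms
    regimes = np.where(block_starts >= config.regime_boundary_ms, "I", "MM")
    base = np.array([config.coupling_for(group, r) for r in regimes])
    sigma = np.array([config.volatility_for(group, r) for r in regimes])
    z = rng.standard_normal(n_blocks)
    coupling = base * np.exp(sigma * z)

    t_ms = np.arange(n_samples) / fs * 1000.0
    block_of = np.minimum((t_ms // config.block_ms).astype(int), n_blocks - 1)
    coupling_per_sample = coupling[block_of]

    # The epoch opens mid-maintenance: the ensemble has been coupled for a
    # while already, so the recorded segment must not start from incoherent
    # phases.  A discarded burn-in at the maintenance coupling brings each
    # trial to its (partially) locked steady state before sample 0.
    theta0 = rng.uniform(-np.pi, np.pi,
                         size=(config.n_trials, config.n_channels))
    n_burn = int(round(config.burnin_ms / 1000.0 * fs))
    if n_burn > 0:
        k_burn = np.full(n_burn, config.coupling_mm[group])
        burn = _integrate_phases(rng, theta0, n_burn, dt, omega, k_burn,
                                 config.phase_noise_sd)
        theta0 = burn[:, :, -1]
    phases = _integrate_phases(rng, theta0, n_samples, dt, omega,
                               coupling_per_sample, config.phase_noise_sd)
    data = np.sin(phases)
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal(data.shape)

    # resting baseline: uncoupled dynamics, same noise model
    n_base = int(round(config.baseline_ms / 1000.0 * fs))
    theta_b = rng.uniform(-np.pi, np.pi, size=(1, config.n_channels))
    base_phases = _integrate_phases(rng, theta_b, n_base, dt,
                                    omega, np.zeros(n_base),
                                    config.phase_noise_sd)
    baseline = np.sin(base_phases[0])
    if config.noise_sd > 0:
        baseline = baseline + config.noise_sd * rng.standard_normal(baseline.shape)

    labels = np.where(rng.random(config.n_trials) < config.hit_rate, HIT, ERROR)

    epochs = EpochSet(
        subject_id=subject_id,
        group=group,
        data=data,
        sampling_rate=fs,
        t0_ms=-config.regime_boundary_ms,
        regime_boundary_ms=config.regime_boundary_ms,
        labels=labels,
        baseline=baseline,
    )
    truth = GroundTruth(
        subject_id=subject_id,
        group=group,
        block_starts_ms=block_starts,
        regimes=regimes,
        coupling=coupling,
        base_coupling={"MM": config.coupling_mm[group],
                       "I": config.coupling_int[group]},
        volatility=dict(config.coupling_volatility[group]),
        phases=phases if keep_phases else None,
    )
    return epochs, truth


def simulate_cohort(config: SyntheticConfig,
                    keep_phases: bool = False) -> list[tuple[EpochSet, GroundTruth]]:
    """Simulate the full two-group cohort.

    Per-subject seeds are derived deterministically from ``config.seed`` via
    a :class:`numpy.random.SeedSequence`, so the cohort is reproducible as a
    whole and each subject is reproducible in isolation.
    """
    n_total = sum(config.n_subjects_per_group.values())
    seeds = np.random.SeedSequence(config.seed).generate_state(n_total)
    out = []
    k = 0
    for group in GROUPS:
        for i in range(config.n_subjects_per_group[group]):
            sid = f"{group}-{i + 1:02d}"
            out.append(simulate_subject(config, group, int(seeds[k]),
                                        subject_id=sid, keep_phases=keep_phases))
            k += 1
    return out


# ---------------------------------------------------------------------------
# container I/O
# ---------------------------------------------------------------------------
def save_epochs_hdf5(epochs: EpochSet, path) -> None:
    """Write one subject as an HDF5 container (/trials, /baseline, /labels, /meta)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=epochs.data)
        if epochs.baseline is not None:
            f.create_dataset("baseline", data=epochs.baseline)
        f.create_dataset("labels",
                         data=np.array(epochs.labels, dtype="S"))
        meta = f.create_group("meta")
        meta.attrs["subject_id"] = epochs.subject_id
        meta.attrs["group"] = epochs.group
        meta.attrs["sampling_rate"] = epochs.sampling_rate
        meta.attrs["t0_ms"] = epochs.t0_ms
        meta.attrs["regime_boundary_ms"] = epochs.regime_boundary_ms


def load_epochs_hdf5(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        return EpochSet(
            subject_id=str(meta["subject_id"]),
            group=str(meta["group"]),
            data=f["trials"][()],
            sampling_rate=float(meta["sampling_rate"]),
            t0_ms=float(meta["t0_ms"]),
            regime_boundary_ms=float(meta["regime_boundary_ms"]),
            labels=f["labels"][()].astype(str),
            baseline=f["baseline"][()] if "baseline" in f else None,
        )


def save_epochs_csv(epochs: EpochSet, directory) -> None:
    """Write one subject as per-trial CSV matrices plus meta/labels sidecars."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for t in range(epochs.n_trials):
        np.savetxt(d / f"trial_{t:03d}.csv", epochs.data[t], delimiter=",")
    if epochs.baseline is not None:
        np.savetxt(d / "baseline.csv", epochs.baseline, delimiter=",")
    meta = {
        "subject_id": epochs.subject_id,
        "group": epochs.group,
        "sampling_rate": epochs.sampling_rate,
        "t0_ms": epochs.t0_ms,
        "regime_boundary_ms": epochs.regime_boundary_ms,
        "labels": list(map(str, epochs.labels)),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=1))


def load_epochs_csv(directory) -> EpochSet:
    d = Path(directory)
    meta = json.loads((d / "meta.json").read_text())
    trials = sorted(d.glob("trial_*.csv"))
    data = np.stack([np.loadtxt(p, delimiter=",") for p in trials])
    base_path = d / "baseline.csv"
    baseline = np.loadtxt(base_path, delimiter=",") if base_path.exists() else None
    return EpochSet(
        subject_id=meta["subject_id"],
        group=meta["group"],
        data=data,
        sampling_rate=meta["sampling_rate"],
        t0_ms=meta["t0_ms"],
        regime_boundary_ms=meta["regime_boundary_ms"],
        labels=np.array(meta["labels"]),
        baseline=baseline,
    )
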