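# netfluct

Time-varying functional-network analysis of multichannel oscillatory
recordings: phase-locking networks in short sliding windows, weighted graph
metrics, strength-fluctuation statistics, and permutation-corrected group
comparisons — with a coupled-oscillator cohort generator for validation.

## The problem

During a cognitive task the brain's functional network is not static: it
forms, reorganizes and dissolves on the scale of tens of milliseconds.
Averaging connectivity over a whole task can therefore hide group
differences that only exist in short task phases.  `netfluct` implements
the time-resolved alternative for sensor-space recordings (e.g. MEG
magnetometers): it tracks the network topology window by window across a
task with two regimes — a memory-maintenance period (MM) and a subsequent
interference period (I) — and asks *when* two groups of subjects differ
and *how fast* their networks reorganize.

It is written for researchers analyzing epoched multichannel time series
(trials × channels × samples) with per-trial response labels, a sensor
layout, and a short resting baseline per subject.

## Method

1. **Preprocessing** — baseline correction on a 100 ms pre-stimulus
   window, zero-phase 48 Hz low-pass, peak-to-peak amplitude rejection,
   selection of hit trials equalized to 32 per subject, segmentation into
   1500 ms epochs (500 ms MM + 1000 ms I).
2. **Synchronization** — band-pass into ten 4-Hz bands from 8 to 48 Hz,
   instantaneous phases φ via the Hilbert transform, and for every channel
   pair and non-overlapping 50 ms window the phase-locking value

       PLV = |⟨e^{iφ(t)}⟩| = sqrt(⟨cos φ⟩² + ⟨sin φ⟩²),  φ = φ_i − φ_j,

   pooled over the samples of all trials.  PLV is 1 for a constant
   relative phase and 0 for uniformly scattered phases.  Pair-wise values
   are normalized by the resting-baseline PLV and narrow bands merged into
   alpha (8–12 Hz), beta (12–30 Hz) and gamma (30–48 Hz); a 1500 ms epoch
   yields 30 weighted N×N networks per subject and band.
3. **Graph metrics** — per window, per node and network-wide: strength
   S = Σ_j w_ij, outreach O = Σ_j w_ij·l_ij (l_ij the physical sensor
   distance), Onnela weighted clustering C_w, global efficiency E_g and
   average shortest path SP over link lengths 1/w_ij.
4. **Fluctuations** — strength increments ΔS = |S_i − S_{i−1}| between
   consecutive windows, their empirical survival distributions P_c(ΔS) per
   group and regime, between-group survival differences, and nodal
   contrast maps.
5. **Statistics** — Kruskal–Wallis tests per window (or per averaged
   span), corrected for multiple comparisons with max-statistic
   permutation of group labels; Spearman correlation of metrics with task
   performance.

The synthetic-data module generates two-group cohorts of stochastic
mean-field Kuramoto oscillators whose global coupling switches at the
regime boundary and jitters per 50 ms block, so every stage can be tested
against a known ground truth.

## Worked example

Simulate a small two-group cohort whose coupling differs only during the
interference regime, compute the alpha-band network strength per 50 ms
window, and compare the groups window by window:

```python
import numpy as np
from netfluct import (SyntheticConfig, simulate_cohort, make_sensor_layout,
                      subject_metric_series, compare_timecourses,
                      average_windows)

cfg = SyntheticConfig(n_subjects_per_group={"young": 6, "old": 6},
                      n_channels=12, n_trials=16, seed=1)
layout = make_sensor_layout(cfg.n_channels, seed=1)
metrics = [subject_metric_series(ep, layout)
           for ep, _ in simulate_cohort(cfg)]
young = [m for m in metrics if m.group == "young"]
old = [m for m in metrics if m.group == "old"]

for span in ("MM", "I"):
    sy = np.mean([average_windows(m, span)["S"] for m in young])
    so = np.mean([average_windows(m, span)["S"] for m in old])
    print(f"{span:4s} mean strength  young {sy:5.2f}   old {so:5.2f}")

comp = compare_timecourses(young, old, metric="S", n_perm=1000, seed=1)
print("significant windows:",
      comp.table[comp.table.significant].test.tolist())
```

prints

```
MM   mean strength  young  9.09   old  8.86
I    mean strength  young  3.59   old  8.41
significant windows: ['window_12', 'window_13', 'window_14', 'window_15',
 'window_16', 'window_17', 'window_18', 'window_19', 'window_20',
 'window_21', 'window_26', 'window_27', 'window_28', 'window_29']
```

During maintenance the group-mean strengths are indistinguishable (9.09
vs 8.86); during interference the older group stays strongly synchronized
(8.41) while the young group's network strength collapses (3.59), and the
permutation-corrected comparison flags only interference windows (the
first interference window is `window_10`).

A command-line interface wraps the same pipeline:

```
netfluct simulate --config cohort.yaml --out data/ --seed 1
netfluct analyze --config analysis.yaml --epochs data/ \
    --layout data/sensors.csv --out results/ --seed 1
```

## Layout

- `src/netfluct/synthetic_data.py` — cohort generator and sensor layouts
- `src/netfluct/preprocessing.py` — epoch cleaning chain
- `src/netfluct/spectral_sync.py` — phases, windowed PLV, band handling
- `src/netfluct/network_metrics.py` — weighted graph measures
- `src/netfluct/fluctuations.py` — ΔS statistics and survival curves
- `src/netfluct/group_stats.py` — tests, permutation correction, pipeline
- `docs/methods.md` — modeling assumptions and numerical choices
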