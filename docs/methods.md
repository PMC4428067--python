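# Methods

This note documents the models, parameter choices and numerical
conventions behind `netfluct`, and what its validation suite does and does
not demonstrate.

## Windowed phase-locking networks

The core statistic is the phase-locking value between two instantaneous
phase series, `PLV = |⟨e^{iφ(t)}⟩|` with `φ` the pairwise phase
difference.  Phases come from a 4th-order Butterworth band-pass applied
forward and backward (zero phase distortion, which matters because any
phase lag introduced by filtering would bias the statistic) followed by
the Hilbert transform.  Signals are extended by reflection — 200 ms per
side by default, capped at the signal length — before filtering and the
analytic transform, and the extension is discarded, which suppresses the
edge artifacts the transform otherwise produces.  Frequencies below 8 Hz
are not analyzed: at a 50 ms window even 8 Hz fits less than half a cycle,
and lower bands would be dominated by those edge effects.

**Pooling.** One PLV per channel pair per window per subject is computed
from the samples of all trials pooled together.  With 32 trials and
~34 samples per window this gives ~1000 phasors per estimate.  An
alternative — averaging per-trial PLVs — weighs trials equally but is not
used; pooling is the natural reading of one matrix series per subject and
is isolated in a single function should the convention need changing.

**Windowing.** Window edges are placed at `round(w · window_ms · fs/1000)`
samples so rounding never accumulates: 1500 ms at 678.17 Hz (1017 samples)
gives exactly 30 windows of 33–34 samples, and the window-count law
`n_windows = floor(epoch_ms / window_ms)` holds; a trailing partial window
is dropped with a warning.  A window belongs to the interference regime
iff its start lies at or after the regime boundary (500 ms of epoch time
by default).

**Baseline normalization.** Task PLVs are divided, pair-wise, by the PLV
of a short resting baseline (100 ms, treated as a single window — splitting
it would only add estimator noise).  The ratio preserves the
non-negativity required by the inverse-weight path lengths downstream.
Baseline PLVs are floored at 0.05 before division; without the floor a
near-zero resting coupling would blow the ratio up.  Floored pairs are
counted and logged.  Subtraction and z-scoring are plausible alternative
operators; the ratio is the package's choice and is confined to
`normalize_to_baseline`.

**Band merging.** A narrow band is a constituent of a broad band iff its
center lies in the half-open broad interval `[low, high)`.  For the
canonical 4-Hz scheme this yields alpha = {8–12}, beta = {12–16, 16–20,
20–24, 24–28} and gamma = {28–32, …, 44–48}: each edge band is assigned to
exactly one broad band, decided by its center.  Downstream analysis
defaults to alpha; the other bands are computed on request.

## Graph metrics

All five measures operate on the symmetric, non-negative, zero-diagonal
weight matrix of each window; graphs stay fully weighted (no threshold,
no binarization).

- Strength `s_i = Σ_j w_ij`; outreach `o_i = Σ_j w_ij · l_ij` with `l_ij`
  the Euclidean sensor distance in meters.
- Weighted clustering uses the Onnela geometric-mean triangle intensity
  with weights normalized by the global maximum, `c_i ∈ [0, 1]`, nodes
  with fewer than two neighbors scoring 0.  The Barrat and Zhang–Horvath
  variants measure related but different quantities; one canonical
  definition is kept and cross-checked against networkx.
- Path statistics use topological link lengths `d_ij = 1/w_ij` (absent
  links are infinite).  `SP` averages finite off-diagonal shortest-path
  distances; unreachable pairs are excluded from `SP` and contribute 0 to
  `E_g`, which equals the inverse harmonic mean of the distances on a
  connected graph.  Disconnection is flagged; with ratio-normalized PLV
  weights it is a degenerate case rather than an expected one.
- Network-level S, O and C_w are **means** over nodes, not sums, so values
  are comparable across channel counts; E_g and SP are global quantities.

Averaging spans: MM = windows starting before the boundary (1–10 with
defaults), I = the rest (11–30), MM+I = all.  Group summaries report the
across-subject mean and standard error per window and per span; with one
subject the error is flagged undefined rather than reported as 0.

## Fluctuation statistics

Strength increments `ΔS_t = |S_t − S_{t−1}|` (and nodal `Δs_i,t`) quantify
how fast the network reorganizes.  The increment straddling the regime
boundary is assigned to the interference regime — its later window lies
there, and the choice only moves one of 29 increments.  Survival curves
`P_c(x) = P(ΔS ≥ x)` pool increments across subjects and time steps within
a group × regime cell; by default the grid is the exact set of observed
values plus zero (the exact empirical curve), with explicit common grids
for between-group differences.  `≥` rather than `>` is used; for
continuous data the two differ on a null set.

## Group statistics

Between-group location differences are tested with the tie-corrected
Kruskal–Wallis H (χ² reference distribution).  Multiplicity is controlled
with a max-statistic permutation scheme: group labels are permuted across
subjects, every test of the family is recomputed, and each observed H is
referred to the permutation distribution of the family maximum.  Families
are: all windows of one metric (time-course comparisons) and the five
metrics within one span (averaged comparisons).

Numerical conventions: the add-one estimator
`p = (1 + #{max ≥ obs}) / (1 + n_perm)` keeps permutation p-values
strictly positive; when the number of distinct relabelings does not exceed
`n_perm` the full enumeration is used and p-values are exact; corrected
p-values are floored at the raw p so that correction can never *gain*
significance; identical-value degenerate input yields H = 0, p = 1.  The
default `n_perm` is 10 000.  Behavior correlations use Spearman's rank
coefficient, consistent with the rank-based tests elsewhere; constant
inputs make it undefined (NaN with a warning, not an error).

Note that with very small groups the exhaustive max-statistic correction
has limited resolution: with 4 vs 4 subjects the 70 distinct relabelings
cannot produce a family-wise p below what a 30-test family consumes, so
per-window significance is effectively unreachable — a property of the
method, not a bug.

## The synthetic cohort generator

Channels are identical-frequency phase oscillators with mean-field
(Kuramoto) coupling, integrated by Euler–Maruyama at the sampling rate:

    dθ_k = 2πf dt + K(t) · r sin(ψ − θ_k) dt + σ_p √dt ξ,
    x_k = sin θ_k + ε_k,

with `r e^{iψ}` the per-trial mean field, `σ_p` the phase-noise scale and
`ε` white measurement noise.  `K(t)` switches instantaneously from the
maintenance to the interference value at the regime boundary (the task's
stimulus onset is abrupt) and is multiplied per 50 ms block by
`exp(σ_vol Z)`, `Z` standard normal, drawn once per subject per block and
shared across trials — per-trial jitter would average out of the pooled
PLV, whereas shared jitter produces the window-to-window strength
fluctuations the ΔS statistics measure.  The resting baseline segment is
generated with coupling 0: the emulated baseline is rest, and no
quantitative description of resting synchrony is assumed.

Defaults (one subject ≈ the emulated acquisition): 148 channels at
678.17 Hz, 1500 ms epochs with the boundary at 500 ms, 100 ms baseline,
32 trials, 9 young / 11 older subjects, band center 10 Hz.

**Operating point.**  The dynamical parameters were fixed once, by design
calibration, at `σ_p = 4 rad/√s`, maintenance coupling 26 (young) / 28
(old), interference coupling 12 (young) / 21 (old), volatility
(σ_MM, σ_I) = (1.0, 0.1) for young and (0.1, 1.0) for old.  Three
considerations drove the choice:

- the windowed PLV must sit in its sensitive mid-range (neither at the
  uncoupled floor ≈ 1/√n_trials nor saturated at 1), which places the
  couplings around the locking threshold `K_c ≈ σ_p²`;
- the locking dynamics must track the coupling schedule within a couple of
  windows (relaxation time `~1/(K r)` of tens of milliseconds), otherwise
  the regime switch smears across the epoch and 50 ms coupling jitter is
  filtered out before it reaches the PLV — this is what rules out slower,
  lower-noise regimes;
- the group structure mirrors the emulated phenomenon: maintenance
  coupling nearly equal between groups, interference coupling clearly
  higher in the old group, and the volatility schedule reversed across
  regimes (young fluctuate more during maintenance, old more under
  interference).

A discarded burn-in (1000 ms) at the maintenance coupling precedes each
epoch, because epochs open mid-maintenance: without it the early windows
show a locking transient from random initial phases instead of the
maintenance plateau.

**What the generator does not emulate:** volume conduction and field
spread, 1/f background spectra, heterogeneous oscillator frequencies,
spatially structured (distance-dependent) coupling, ocular or muscular
artifacts, and behavior that depends on the signals (labels are i.i.d.
Bernoulli).  Passing tests therefore show that the pipeline recovers known
coupling structure from phase-coupled oscillators — not that it is robust
to the confounds of real sensor recordings, where leakage alone can
produce spurious zero-lag synchronization.

Sensor layouts place channels on an upper hemispherical shell (10 cm
radius) by Fibonacci-spiral spacing with a small seeded jitter: a
deterministic, roughly uniform, helmet-like geometry whose distance
distribution is adequate for the outreach metric.

Determinism: a cohort derives one seed per subject from the master seed
via `numpy.random.SeedSequence`, so identical configurations reproduce
bit-identical cohorts and any subject can be regenerated in isolation.

## Validation problem sizes

The test suite exercises the full 148-channel geometry for matrix-shape
checks, and scaled-down cohorts elsewhere so the whole suite runs in a few
minutes: the interference-effect recovery uses the study's 9 vs 11
subjects at 12 channels × 16 trials with 500 permutations over 20
replicates; the family-wise error simulation uses 6 vs 6 null subjects at
8 channels × 12 trials over 200 replicates; the fluctuation-reversal and
volatility-recovery checks use 10-channel cohorts at 24–32 trials.  Graph
metrics are verified exactly (1e-12) against brute-force loops,
Floyd–Warshall and triple enumeration on 100 random graphs of up to 8
nodes.

## Known limitations

- PLV estimation noise contributes to ΔS and is itself level-dependent
  (noisier for weakly synchronized networks), so fluctuation comparisons
  between groups with very different synchronization levels mix true
  volatility with estimator variance.  The volatility manipulation in the
  validation suite is strong enough to dominate this term; subtler
  real-data effects may not be.
- The 3 pT-style rejection rule is interpreted per channel (maximum over
  channels of the per-channel peak-to-peak); a global-field reading would
  reject slightly different trials.
- The exact family definition of the max-statistic correction is a
  configuration choice; other groupings (e.g. one family across all
  metrics and windows) are legitimate and give different corrected values.
- Sensor-space analysis only: no source localization, no leakage
  correction, no PLI/wPLI-style zero-lag-insensitive indices.
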