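# Methods

## Signal model and conventions

A respiratory signal is a finite sequence `x_0, …, x_{M−1}` of amplitudes
in mm on a uniform time grid with interval `Δτ` (default 0.03 s). The
grid is treated as exactly uniform; signals with NaN/Inf are rejected at
ingestion rather than interpolated, and irregular time columns are read
as uniform with a logged warning when first differences deviate more than
1 % from their median. No unit conversion is performed — amplitudes are
millimetres throughout.

Seconds are converted to sample points by the ceiling `⌈s/Δτ⌉`, with
quotients within one part in 10⁹ of an integer snapped to that integer
first (so `k·Δτ` maps to exactly `k` despite binary floating point).
The ceiling, rather than rounding, is what makes a 0.336 s latency 12
points at Δτ = 0.03 s; it also errs on the conservative side, never
modelling hardware as faster than specified.

The gating threshold β defaults to the median of the first `N` samples
(mean of the central pair for even `N`), overridable everywhere.

## Smoothing operator

The low-pass smoother on an N-point window `x` is

    smooth(x) = W⁻¹ · Re( IDFT( mask_α( DFT( W·x ) ) ) )

with the Hamming window `w_k = 0.54 − 0.46 cos(2πk/(N−1))` applied and
inverted elementwise, an *unnormalized* forward DFT and a `1/N` inverse
(this convention is pinned; many FFT libraries differ), and a mask that
zeroes bin `k` iff `|k − N/2| < N/2 − α` — a strict inequality, so
boundary bins survive. The kept set is symmetric under `k ↦ N−k`, which
keeps the filtered spectrum of a real window conjugate-symmetric; the
imaginary part discarded by `Re` is pure round-off (≲1e−9 relative).
A cutoff `f` in Hz maps to `α = N·Δτ·f`, constrained to `[0, 1/(2Δτ)]`;
`α` is kept real (no rounding — the strict inequality consumes it
directly), and `α ≥ N/2` short-circuits to the identity. The minimum
Hamming weight is 0.08, so the inverse window is well conditioned; a
defensive check still errors if any weight falls below 1e−12. For odd
`N`, `N/2` is a half-integer and the inequality is applied verbatim.

The operator is linear and idempotent up to round-off, and is verified in
the tests against a literal O(N²) direct-summation implementation.

## Nearest-neighbour multistep prediction

From a smoothed N-point window, the learning set is every overlapping
pair (history `n`-tuple, future `m`-tuple) at stride 1 — `N − n − m + 1`
entries in window order. Prediction is 1-nearest-neighbour under the
Euclidean metric: the query history's closest stored history contributes
its future verbatim (no interpolation or averaging). Among co-minimal
distances the **largest index** (most recent entry) wins; distances are
compared as exact floats with no tie epsilon, since any total order on
floats already yields a deterministic answer, and the implementation is
cross-checked against exhaustive search including forced ties.

The rolling protocol, at each time `t` from `N + n` to `M − m`, rebuilds
the learning set from the `N` *raw* samples ending at `t − n − 1`
(smoothed on entry) and queries it with the *raw* history
`(x_{t−n}, …, x_{t−1})`. Querying with a raw history against smoothed
entries follows the letter of the gating definition; a
`smooth_test_history` switch (default off) smooths the query too, for
experimentation. A `refresh_stride` option (default 1 = exact) reuses a
learning set across a few steps as a documented approximation. Accuracy
is scored as the RMSE of the `m`-th (furthest-ahead) predicted coordinate
against the actual observation over all `M − N − n − m + 1` scored
indices; a full-horizon per-tuple output is available from
`rolling_predict` for other analyses.

## Gating simulators

**Command model.** The hardware is modelled edge-triggered: whenever the
desired beam state differs from the last issued command, a new command is
issued immediately; an on-command issued at `t` executes at `t + m1`, an
off-command at `t + m0`. The realized state at index `j` follows the
command with the latest execution time ≤ `j`, ties broken by the later
issue time. The initial state is beam-off (the conservative clinical
default; configurable). Commands can overtake each other when
`m1 ≠ m0`; the execution-time ordering resolves this and reproduces the
familiar picture of windows shifted late by `m1` at the start and `m0`
at the end whenever threshold crossings are separated by more than
`m1 + m0` points. The exact hardware scheduling is not observable from
published latency tables, so this reconstruction is validated by its
consequences (the shifted-window picture, and exact hand-stepped traces)
rather than line-by-line.

**Conventional gating** requests the beam on iff `x_t < β` (strict: a
sample exactly at β requests off) and applies the command model.

**Predictive gating** at each `t ≥ N + n` builds two learning sets from
the same smoothed window — futures of length `2·m1 + 1` and `2·m0 + 1` —
queries both with the raw history, and feeds the forecasts to the
decision rule: with sign sum `ξ(a) = Σ_k sgn(a_k − β)` (samples exactly
at β count zero), the beam is requested on iff the forecast windows lie
mostly below β — either window sufficing when `m1 ≥ m0`, both required
when `m1 < m0`. Each forecast window is centred on the corresponding
command's execution time; that look-ahead is the entire compensation
mechanism — the latencies themselves still apply unchanged to every
issued command. During warm-up (`t < N + n`) the desired state is off.

**Scoring.** Both simulators are scored over the same index set
`S = {N + n + m1 − 1, …, M − 1}` (the `m1` lower bound is used for both
latency orderings), which excludes the warm-up. nErr is the mean over
`S` of `(x_j − β)⁺` where the beam is on and `(x_j − β)⁻` where it is
off — the average mis-irradiated amplitude per time point, in mm. It is
non-negative, zero exactly for ideal gating, and invariant under jointly
shifting signal and threshold.

Both learning sets share one distance computation per step (their
histories are identical prefixes), which keeps a 4000-point simulation
with a 1500-point window under a second.

## Synthetic signals

The generator emulates chest-wall motion with the exhalation-plateau
waveform `b0 + A·cos^{2p}(πt/T + φ)`: even powers of a cosine spend most
of each cycle near the exhalation baseline with brief inhalation peaks,
the standard idealization of quiet breathing. Defaults: baseline 0 mm,
amplitude 10 mm, period 4 s, `p = 2`, phase π/2 (start at the trough) —
within the 5–15 mm / 3–5 s range typical of adult chest-wall excursion.
Optional features:

- **per-cycle jitter** of amplitude and period (relative sd, redrawn once
  per cycle *at the trough* so each breath is internally coherent and the
  trace stays continuous);
- **white sensor noise** (sd in mm);
- **baseline drift**, linear (mm/s) by default or a random walk for
  stress tests;
- **noise bursts**: a seeded sinusoid confined to `[start, end)`.

All randomness flows from one seed; identical parameters give
bit-identical output. Presets: `phantom` (no jitter/noise/drift, 20 s —
a motion stage), `volunteer_regular` (5 %/3 % jitter, 0.2 mm noise,
120 s), `volunteer_irregular` (25 %/15 %, 0.5 mm), `volunteer_drift`
(regular + 0.05 mm/s drift, ≈6 mm over 120 s against a ~2.4 mm
threshold).

What the generator does **not** model: cardiac superposition, breath
holds, cough, amplitude–period correlation, sensor quantization, or any
specific patient's physiology. Passing tests therefore demonstrate the
algorithmic properties of the pipeline — not clinical performance on
measured data, which additionally exhibits irregularity the
`volunteer_irregular` and `volunteer_drift` presets only caricature.
Externally measured CSV traces can be run through the same pipeline via
`respgate import-figshare`.

## Problem sizes and numerical choices

The test suite and the acceptance script run a desk-scale protocol:
120 s signals (M = 4000 points), learning window N = 1500, history
n = 60, horizon m = 10, 1 Hz smoothing cutoff, five seeds per
configuration — large enough that every window holds tens of breathing
cycles, while a full comparison completes in seconds. The package
equally supports the full-scale configuration (M = 10000, N = 4000,
n = 100) through the same entry points.

Key tolerances: the FFT smoother matches the direct-sum oracle to 1e−10
absolute for N ≤ 64; idempotence/linearity hold to ~1e−8 relative;
periodic-signal recovery is asserted below 1e−3 mm RMSE (measured
~1e−14). Degenerate inputs fail loudly: empty tuples, mismatched
lengths, windows shorter than 2, learning windows that cannot hold
history plus look-ahead, and signals shorter than `N + n + m1` all raise
`ValueError` before any computation.

## Known limitations

- Fixed-threshold gating degrades under baseline drift; the predictive
  scheme inherits the problem (its advantage shrinks markedly on the
  `volunteer_drift` preset, and can invert on stronger drift). Adaptive
  thresholds are out of scope.
- The nearest-neighbour predictor copies observed futures; it cannot
  extrapolate patterns absent from the learning window, so erratic
  breathing defeats it.
- Only amplitude-based exhalation gating is modelled — no phase-based
  gating, no inhalation windows, no dose calculation.
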