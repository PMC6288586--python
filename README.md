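# respgate

Prediction-based compensation for gate on/off latency in
respiratory-gated radiotherapy (RGRT).

## The problem

In amplitude-based exhalation gating, the treatment beam should be on
exactly while the respiratory amplitude `x_t` (mm, sampled every
Δτ = 0.03 s) is below a threshold β. Commercial gating systems take
hundreds of milliseconds between detecting a threshold crossing and
actually switching the beam (e.g. Abches: 336 ms on / 88 ms off; AlignRT:
356 ms / 529 ms), so every gating window opens and closes late —
irradiating normal tissue and under-dosing the target near the window
edges. `respgate` implements a prediction-based gating scheme that issues
commands early enough for them to *execute* on time, together with the
simulators and metrics needed to quantify the benefit.

## Method

1. **Smoothing.** An N-point window is low-passed by the chain
   Hamming-multiply → unnormalized DFT → zero bins `k` with
   `|k − N/2| < N/2 − α` → 1/N inverse DFT → real part → Hamming-divide,
   with `α = N Δτ f` for a cutoff `f` in Hz.
2. **Prediction.** From the smoothed window, every overlapping pair
   (history `n`-tuple, future `m`-tuple) forms a learning set; the next
   `m` samples are forecast by 1-nearest-neighbour lookup under the
   Euclidean metric (ties go to the most recent entry).
3. **Prediction-based gating.** With gate-on/off latencies of `m1`/`m0`
   points, two forecasts of length `2·m1+1` and `2·m0+1` — each centred
   on the corresponding command's *execution* time — are reduced to sign
   sums `ξ = Σ sgn(x̂ − β)`; the beam is requested on when the forecast
   windows lie mostly below β (either window if `m1 ≥ m0`, both if
   `m1 < m0`).
4. **Metrics.** Prediction quality is the RMSE of the `m`-step-ahead
   coordinate over a rolling protocol; gating quality is nErr (mm), the
   mean amplitude excess above β while the beam is on plus the deficit
   below β while it is off, over a common scored index set.

A synthetic generator (`cos^{2p}` exhalation-plateau waveform with
per-cycle jitter, sensor noise, baseline drift and noise bursts) makes the
whole pipeline testable without any measured data.

## Worked example

```bash
respgate simulate --preset volunteer_regular --seed 1 --duration 120 \
    --system abches --N 1500 --n 60 --cutoff-hz 1.0 --mode both
```

prints (reformatted):

```json
{"mode": "simulate", "signal_points": 4000, "dt_s": 0.03, "seed": 1,
 "source": "preset:volunteer_regular", "system": "Abches",
 "gate_on_delay_s": 0.336, "gate_off_delay_s": 0.088,
 "m1": 12, "m0": 3, "N": 1500, "n": 60, "beta_mm": 2.3740,
 "nerr_conventional_mm": 0.4579, "nerr_predictive_mm": 0.0029}
```

Reading: a 120 s quasi-periodic breathing trace was gated with the Abches
latency profile (336 ms → 12 points, 88 ms → 3 points); the threshold β
was set to the median of the first 1500 samples (2.374 mm). Conventional
threshold-triggered gating mis-irradiates an average of 0.46 mm of
amplitude per scored time point; the prediction-based scheme reduces that
to 0.003 mm — the gating windows are realigned almost perfectly.

The same library surface is importable directly
(`respgate.simulate_predictive`, `respgate.serial_prediction`, …); see
`docs/methods.md` for the model details and parameter conventions.

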