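"""Synthetic respiratory-signal generator.

Quiet breathing measured at the chest or abdomen spends most of each cycle
near the exhalation level, with relatively brief inhalation peaks.  The
generator models this with the standard exhalation-plateau waveform

    z(t) = b0 + A * cos^(2p)(pi * t / T + phi)

(baseline b0 mm, peak amplitude A mm, period T s, even power 2p shaping
the plateau), optionally decorated with per-cycle amplitude and period
jitter, additive white noise, linear or random-walk baseline drift, and a
localized high-frequency noise burst.  Jitter is redrawn once per cycle at
the waveform's trough, so each breath is internally coherent and the
jittered trace stays continuous.

All randomness flows from a single seed, so identical parameters give
bit-identical signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .signal_core import RespiratorySignal, duration_to_points

__all__ = ["SynthParams", "generate", "preset", "add_noise_burst", "PRESET_NAMES"]


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic breathing model.

    baseline/amplitude in mm, period/duration/dt in s; shape_exponent p
    gives the cos^(2p) waveform; amp_jitter and period_jitter are relative
    standard deviations applied once per cycle; noise_sd is white-noise sd
    in mm; drift_rate a linear baseline trend in mm/s (``drift_mode``
    "walk" instead accumulates a random walk with that step scale per
    second); burst, if set, is (start_s, end_s, amplitude_mm, freq_hz).
    """

    baseline: float = 0.0
    amplitude: float = 10.0
    period: float = 4.0
    shape_exponent: int = 2
    phase: float = math.pi / 2
    amp_jitter: float = 0.0
    period_jitter: float = 0.0
    noise_sd: float = 0.0
    drift_rate: float = 0.0
    drift_mode: str = "linear"
    burst: tuple[float, float, float, float] | None = None
    seed: int = 0
    duration: float = 20.0
    dt: float = 0.03

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.shape_exponent < 1:
            raise ValueError("shape_exponent must be a positive integer")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.amp_jitter < 0 or self.period_jitter < 0:
            raise ValueError("jitter fractions must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.drift_mode not in ("linear", "walk"):
            raise ValueError("drift_mode must be 'linear' or 'walk'")


#: Named parameter sets emulating the kinds of traces the simulators are
#: exercised on.  "phantom" is a perfectly regular motion stage;
#: "volunteer_regular" adds mild cycle jitter and sensor noise typical of
#: a calm, cooperative subject; "volunteer_irregular" is erratic
#: breathing; "volunteer_drift" adds a slow baseline trend, the known
#: failure mode of fixed-threshold gating.
_PRESETS: dict[str, SynthParams] = {
    "phantom": SynthParams(
        baseline=0.0, amplitude=10.0, period=4.0, shape_exponent=2,
        duration=20.0,
    ),
    "volunteer_regular": SynthParams(
        baseline=0.0, amplitude=10.0, period=4.0, shape_exponent=2,
        amp_jitter=0.05, period_jitter=0.03, noise_sd=0.2, duration=120.0,
    ),
    "volunteer_irregular": SynthParams(
        baseline=0.0, amplitude=8.0, period=3.5, shape_exponent=2,
        amp_jitter=0.25, period_jitter=0.15, noise_sd=0.5, duration=120.0,
    ),
    "volunteer_drift": SynthParams(
        baseline=0.0, amplitude=10.0, period=4.0, shape_exponent=2,
        amp_jitter=0.05, period_jitter=0.03, noise_sd=0.2, drift_rate=0.05,
        duration=120.0,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, **overrides) -> SynthParams:
    """Return a named parameter set, optionally with fields overridden."""
    try:
        params = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}"
        ) from None
    return replace(params, **overrides) if overrides else params


def generate(params: SynthParams) -> RespiratorySignal:
    """Generate a respiratory signal from the breathing model.

    Deterministic in ``params.seed``.  The sample count is the ceiling of
    duration/dt.
    """
    n_pts = duration_to_points(params.duration, params.dt)
    t = np.arange(n_pts) * params.dt
    rng = np.random.default_rng(params.seed)
    p2 = 2 * params.shape_exponent

    if params.amp_jitter == 0.0 and params.period_jitter == 0.0:
        # Exact closed form keeps the trace periodic to round-off.
        breathing = params.baseline + params.amplitude * np.cos(
            np.pi * t / params.period + params.phase
        ) ** p2
    else:
        breathing = _jittered_waveform(params, n_pts, rng)

    values = breathing
    if params.drift_rate != 0.0:
        if params.drift_mode == "linear":
            values = values + params.drift_rate * t
        else:
            steps = rng.normal(
                0.0, params.drift_rate * math.sqrt(params.dt), n_pts
            )
            values = values + np.cumsum(steps)
    if params.noise_sd > 0.0:
        values = values + rng.normal(0.0, params.noise_sd, n_pts)

    signal = RespiratorySignal(values=values, dt=params.dt)
    if params.burst is not None:
        start, end, amplitude, freq = params.burst
        signal = add_noise_burst(
            signal, start, end, amplitude, freq, seed=params.seed + 1
        )
    return signal


def _jittered_waveform(
    params: SynthParams, n_pts: int, rng: np.random.Generator
) -> np.ndarray:
    """cos^(2p) waveform with per-cycle amplitude/period redraws.

    The phase advances sample by sample; crossing a trough (phase
    pi/2 + k*pi, where the waveform touches the baseline) starts a new
    cycle and redraws its amplitude and period, so redraws never create
    jumps.
    """
    b0, p2 = params.baseline, 2 * params.shape_exponent

    def draw_amp() -> float:
        return params.amplitude * max(
            0.0, 1.0 + params.amp_jitter * rng.standard_normal()
        )

    def draw_period() -> float:
        return params.period * max(
            0.1, 1.0 + params.period_jitter * rng.standard_normal()
        )

    theta = params.phase
    amp, per = draw_amp(), draw_period()
    next_switch = (math.floor((theta - math.pi / 2) / math.pi) + 1) * math.pi \
        + math.pi / 2
    out = np.empty(n_pts)
    for j in range(n_pts):
        out[j] = b0 + amp * math.cos(theta) ** p2
        theta += math.pi * params.dt / per
        if theta >= next_switch:
            amp, per = draw_amp(), draw_period()
            next_switch += math.pi
    return out


def add_noise_burst(
    signal: RespiratorySignal,
    start: float,
    end: float,
    amplitude: float,
    freq: float,
    seed: int = 0,
) -> RespiratorySignal:
    """Add a high-frequency sinusoidal burst on the interval [start, end).

    The burst is ``amplitude * sin(2 pi freq t + phi)`` with a seeded
    random phase, applied only to the samples whose index falls in
    ``[ceil(start/dt), ceil(end/dt))``; everything else is untouched.
    """
    duration = len(signal) * signal.dt
    if not (0.0 <= start < end <= duration + 1e-12):
        raise ValueError(
            f"burst interval [{start}, {end}) invalid for a {duration:.3f} s signal"
        )
    i0 = duration_to_points(start, signal.dt)
    i1 = duration_to_points(end, signal.dt)
    values = signal.values.copy()
    if amplitude != 0.0 and i1 > i0:
        rng = np.random.default_rng(seed)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        t_burst = np.arange(i0, i1) * signal.dt
        values[i0:i1] += amplitude * np.sin(2.0 * math.pi * freq * t_burst + phi)
    return RespiratorySignal(
        values=values, dt=signal.dt, origin_time=signal.origin_time
    )
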