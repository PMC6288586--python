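"""Latency-aware gating simulators for conventional and predictive RGRT.

Amplitude-based exhalation gating: the beam should be on exactly while the
signal is below a threshold beta.  Real gating systems execute on/off
commands only after hardware latencies of m1 (gate on) and m0 (gate off)
sample points, which shifts every gating window late.  The predictive
variant forecasts two windows of 2*m1+1 and 2*m0+1 future samples — each
centred on the command's execution time — and decides from the sign
balance of the forecasts, so that commands are issued early enough to
execute on time.

The command/latency mechanics are edge-triggered: a command is issued
whenever the desired state differs from the last issued command; an
on-command issued at t executes at t + m1, an off-command at t + m0.  The
realized state at index j is set by the command with the latest execution
time <= j (ties broken by the later issue time).

nErr scores a simulation as the mean, over the scored index set, of the
amplitude excess above beta while the beam is on plus the deficit below
beta while it is off (mm); ideal gating scores exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_core import RespiratorySignal, gating_threshold
from .smoothing import SmoothingConfig, smooth
from .prediction import _largest_argmin

__all__ = [
    "GatingConfig",
    "GateTrace",
    "sign_sum",
    "gate_decision",
    "apply_latency",
    "simulate_conventional",
    "simulate_predictive",
    "nerr",
]


@dataclass(frozen=True)
class GatingConfig:
    """Parameters of a gating simulation.

    beta : gating threshold (mm); ``None`` means "median of the first N
    samples", resolved per signal.  m1/m0 : gate-on/off latencies in
    points.  N/n : learning-window and history lengths for the predictive
    simulator.  The prediction windows (2*m1+1 and 2*m0+1 points) must fit
    in the learning window alongside the history.
    """

    m1: int
    m0: int
    N: int
    n: int
    beta: float | None = None
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig.identity)
    initial_state: int = 0

    def __post_init__(self) -> None:
        if self.m1 < 0 or self.m0 < 0:
            raise ValueError("latencies m1, m0 must be non-negative")
        if self.N < 1 or self.n < 1:
            raise ValueError("N and n must be positive")
        needed = self.n + max(2 * self.m1 + 1, 2 * self.m0 + 1)
        if needed > self.N:
            raise ValueError(
                f"learning window too short: need n + max(2*m1+1, 2*m0+1) "
                f"= {needed} <= N = {self.N}"
            )
        if self.initial_state not in (0, 1):
            raise ValueError("initial_state must be 0 or 1")

    def resolve_beta(self, signal: RespiratorySignal) -> float:
        if self.beta is not None:
            return self.beta
        return gating_threshold(signal, self.N)


@dataclass(frozen=True)
class GateTrace:
    """Per-index beam states of one simulation plus its scored index set.

    ``states[j]`` is 0/1 for every sample of the simulated signal; the
    scored set S runs from ``scored_start`` to the last index.  S1 / S0
    partition S into beam-on and beam-off indices.
    """

    states: np.ndarray
    scored_start: int

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int64)
        if s.ndim != 1:
            raise ValueError("states must be 1-D")
        if not np.isin(s, (0, 1)).all():
            raise ValueError("states must be 0/1")
        if not (0 <= self.scored_start < s.size):
            raise ValueError(
                f"scored_start {self.scored_start} outside [0, {s.size - 1}]"
            )
        s.setflags(write=False)
        object.__setattr__(self, "states", s)

    @property
    def scored_set(self) -> np.ndarray:
        """S: indices over which the simulation is scored."""
        return np.arange(self.scored_start, self.states.size)

    @property
    def on_set(self) -> np.ndarray:
        """S1: scored indices with the beam on."""
        s = self.scored_set
        return s[self.states[s] == 1]

    @property
    def off_set(self) -> np.ndarray:
        """S0 = S \\ S1: scored indices with the beam off."""
        s = self.scored_set
        return s[self.states[s] == 0]


def sign_sum(a, beta: float) -> int:
    """Sum of ``sgn(a_k - beta)`` over a tuple; values equal to beta count 0."""
    arr = np.asarray(a, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("sign_sum of an empty tuple is undefined")
    return int(np.sign(arr - beta).sum())


def gate_decision(
    pred_on, pred_off, beta: float, m1: int, m0: int
) -> int:
    """Prediction-based gating decision from two forecast windows.

    ``pred_on`` forecasts the 2*m1+1 samples centred on the on-command's
    execution time, ``pred_off`` the 2*m0+1 samples centred on the
    off-command's.  A negative sign sum means the window lies mostly below
    the threshold.  With m1 >= m0 the beam is requested on if EITHER
    window is mostly below beta; with m1 < m0, only if BOTH are.
    """
    pred_on = np.asarray(pred_on, dtype=np.float64)
    pred_off = np.asarray(pred_off, dtype=np.float64)
    if pred_on.size != 2 * m1 + 1:
        raise ValueError(
            f"pred_on has length {pred_on.size}, expected 2*m1+1 = {2 * m1 + 1}"
        )
    if pred_off.size != 2 * m0 + 1:
        raise ValueError(
            f"pred_off has length {pred_off.size}, expected 2*m0+1 = {2 * m0 + 1}"
        )
    xi_on = sign_sum(pred_on, beta)
    xi_off = sign_sum(pred_off, beta)
    if m1 >= m0:
        return 1 if (xi_on < 0 or xi_off < 0) else 0
    return 1 if (xi_on < 0 and xi_off < 0) else 0


def apply_latency(desired, m1: int, m0: int, initial_state: int = 0) -> np.ndarray:
    """Realized beam states given desired states and command latencies.

    Edge-triggered: a command equal to ``desired[t]`` is issued whenever it
    differs from the last issued command; on-commands execute m1 points
    later, off-commands m0 points later.  The realized state at j follows
    the command with the latest execution time <= j (ties: later issue
    wins).  Before any command executes, the state is ``initial_state``.
    """
    if m1 < 0 or m0 < 0:
        raise ValueError("latencies must be non-negative")
    if initial_state not in (0, 1):
        raise ValueError("initial_state must be 0 or 1")
    d = np.asarray(desired, dtype=np.int64)
    if not np.isin(d, (0, 1)).all():
        raise ValueError("desired states must be 0/1")
    T = d.size
    realized = np.full(T, initial_state, dtype=np.int64)
    events: list[tuple[int, int, int]] = []  # (execute, issue, state)
    last_cmd = initial_state
    for t in range(T):
        if d[t] != last_cmd:
            last_cmd = int(d[t])
            delay = m1 if last_cmd == 1 else m0
            events.append((t + delay, t, last_cmd))
    # Applying in (execution, issue) order lets later writes win, which is
    # exactly the tie rule.
    events.sort()
    for execute, _issue, state in events:
        if execute < T:
            realized[execute:] = state
    return realized


def simulate_conventional(
    signal: RespiratorySignal, config: GatingConfig
) -> GateTrace:
    """Threshold-triggered gating with hardware latencies.

    The desired state at every index is ``x < beta`` (strict); latencies
    are then applied.  Scored over S = {N + n + m1 - 1, ..., M - 1} so
    that conventional and predictive runs are compared on the same
    indices.
    """
    x = signal.values
    M = x.size
    _check_length(M, config)
    beta = config.resolve_beta(signal)
    desired = (x < beta).astype(np.int64)
    realized = apply_latency(desired, config.m1, config.m0, config.initial_state)
    return GateTrace(states=realized, scored_start=config.N + config.n + config.m1 - 1)


def simulate_predictive(
    signal: RespiratorySignal, config: GatingConfig
) -> GateTrace:
    """Prediction-based gating with the same hardware latencies.

    At each index t >= N + n, two learning sets are built from the raw
    window of the N samples ending at t - n - 1 (smoothed, then sliced):
    one with 2*m1+1-point futures, one with 2*m0+1-point futures.  Both
    are queried with the raw history (x[t-n], ..., x[t-1]); the forecasts
    feed ``gate_decision``.  During the warm-up t < N + n the desired
    state is off; the scored set starts after the warm-up, so nErr is
    unaffected.

    Latencies still apply to every issued command — the compensation comes
    solely from the decision windows being centred on the execution times.
    """
    x = signal.values
    M = x.size
    _check_length(M, config)
    N, n, m1, m0 = config.N, config.n, config.m1, config.m0
    beta = config.resolve_beta(signal)
    k1, k0 = 2 * m1 + 1, 2 * m0 + 1
    c1 = N - n - k1 + 1  # entry counts of the two learning sets
    c0 = N - n - k0 + 1
    cmax = max(c1, c0)

    desired = np.zeros(M, dtype=np.int64)
    for t in range(N + n, M):
        window = x[t - n - N : t - n]
        sm = smooth(window, config.smoothing, dt=signal.dt)
        hist = sliding_window_view(sm, n)  # row i = (sm[i], ..., sm[i+n-1])
        q = x[t - n : t]
        d2 = np.sum((hist[:cmax] - q) ** 2, axis=1)
        p1 = _largest_argmin(d2[:c1])
        p0 = _largest_argmin(d2[:c0])
        pred_on = sm[p1 + n : p1 + n + k1]
        pred_off = sm[p0 + n : p0 + n + k0]
        desired[t] = gate_decision(pred_on, pred_off, beta, m1, m0)
    realized = apply_latency(desired, m1, m0, config.initial_state)
    return GateTrace(states=realized, scored_start=N + n + m1 - 1)


def nerr(signal: RespiratorySignal, trace: GateTrace, beta: float) -> float:
    """Normalized gating error (mm): mean over the scored set of
    ``(x - beta)+`` where the beam is on and ``(x - beta)-`` where it is off.

    Zero iff the beam is on exactly when the signal is at or below the
    threshold; always non-negative.
    """
    S = trace.scored_set
    if S.size == 0:
        raise ValueError("scored set is empty")
    if S[-1] >= len(signal):
        raise ValueError("scored set extends beyond the signal")
    xs = signal.values[S]
    on = trace.states[S] == 1
    dev = np.where(on, np.maximum(xs - beta, 0.0), np.maximum(beta - xs, 0.0))
    return float(dev.mean())


def _check_length(M: int, config: GatingConfig) -> None:
    needed = config.N + config.n + config.m1
    if M < needed:
        raise ValueError(
            f"signal length {M} too short: need at least N + n + m1 = {needed}"
        )
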