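"""Core respiratory-signal container and shared gating primitives.

A respiratory signal is a uniformly sampled sequence of amplitudes (mm)
with sampling interval ``dt`` seconds.  Everything downstream — smoothing,
prediction, gating simulation — operates on this container.  This module
also holds the seconds-to-points conversions used to translate hardware
gate latencies into sample counts, and the amplitude-based gating
threshold rule (median of an initial signal segment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RespiratorySignal",
    "LatencyProfile",
    "LATENCY_PRESETS",
    "latency_to_points",
    "duration_to_points",
    "gating_threshold",
]


@dataclass(frozen=True)
class RespiratorySignal:
    """Uniformly sampled respiratory amplitude series.

    Parameters
    ----------
    values : array-like of float
        Amplitudes in mm.  Must be finite and non-empty.
    dt : float
        Sampling interval in seconds; must be positive.
    origin_time : float, optional
        Time (s) of the first sample.  Defaults to 0.
    """

    values: np.ndarray
    dt: float
    origin_time: float = 0.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.ndim != 1:
            raise ValueError(f"signal values must be 1-D, got shape {vals.shape}")
        if vals.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(vals)):
            raise ValueError("signal contains NaN or Inf values")
        if not (self.dt > 0):
            raise ValueError(f"sampling interval dt must be positive, got {self.dt}")
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.origin_time + np.arange(self.values.size) * self.dt

    @property
    def duration(self) -> float:
        """Total span covered by the samples, in seconds."""
        return self.values.size * self.dt


@dataclass(frozen=True)
class LatencyProfile:
    """Gate on/off delays of a gating system, in seconds."""

    gate_on_delay: float
    gate_off_delay: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.gate_on_delay < 0 or self.gate_off_delay < 0:
            raise ValueError("gate latencies must be non-negative")

    def to_points(self, dt: float) -> tuple[int, int]:
        """Return ``(m1, m0)``: the delays expressed in sample points."""
        return (
            latency_to_points(self.gate_on_delay, dt),
            latency_to_points(self.gate_off_delay, dt),
        )


#: Published gate on/off latencies of commercial gating systems (seconds).
LATENCY_PRESETS: dict[str, LatencyProfile] = {
    "abches": LatencyProfile(0.336, 0.088, "Abches"),
    "alignrt": LatencyProfile(0.356, 0.529, "AlignRT"),
    "calypso": LatencyProfile(0.209, 0.060, "Calypso"),
    "catalyst": LatencyProfile(0.851, 0.215, "Catalyst"),
}

# Relative tolerance for snapping near-integer quotients in the
# seconds->points conversions, so that k*dt seconds maps to exactly k
# points despite binary floating-point representation of dt.
_SNAP_RTOL = 1e-9


def _seconds_to_points(seconds: float, dt: float) -> int:
    if not (dt > 0):
        raise ValueError(f"dt must be positive, got {dt}")
    if seconds < 0:
        raise ValueError(f"duration/delay must be non-negative, got {seconds}")
    q = seconds / dt
    k = round(q)
    if abs(q - k) <= _SNAP_RTOL * max(1.0, abs(q)):
        return int(k)
    return int(math.ceil(q))


def latency_to_points(delay: float, dt: float) -> int:
    """Convert a gate latency in seconds to a count of sample points.

    The conversion is a ceiling: a delay that falls between grid points is
    rounded up to the next whole sample, so the simulated system never
    reacts faster than the hardware it models.
    """
    return _seconds_to_points(delay, dt)


def duration_to_points(duration: float, dt: float) -> int:
    """Convert a measurement duration in seconds to a sample count (ceiling)."""
    return _seconds_to_points(duration, dt)


def gating_threshold(signal: RespiratorySignal, N: int) -> float:
    """Gating threshold beta: the median of the first ``N`` samples (mm).

    For even ``N`` the median is the mean of the two central order
    statistics.
    """
    if N < 1:
        raise ValueError(f"N must be at least 1, got {N}")
    if N > len(signal):
        raise ValueError(
            f"N={N} exceeds signal length {len(signal)}"
        )
    return float(np.median(signal.values[:N]))
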