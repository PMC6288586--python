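"""Nearest-neighbour multistep-ahead prediction of respiratory signals.

A learning set is built from an N-point signal window by smoothing the
window and slicing every overlapping (history n-tuple, future m-tuple)
pair at stride 1.  Prediction of the next m samples from a test history is
a 1-nearest-neighbour lookup under the Euclidean metric: the returned
future is the one attached to the closest stored history, and among
co-minimal histories the one with the LARGEST index wins.  The rolling
protocol rebuilds the learning set at every time step from the most recent
raw window, queries it with the raw current history, and is scored by the
root-mean-square error of the m-th (furthest-ahead) predicted coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_core import RespiratorySignal
from .smoothing import SmoothingConfig, smooth

__all__ = [
    "LearningSet",
    "PredictorConfig",
    "euclidean_distance",
    "build_learning_set",
    "nn_predict",
    "rolling_predict",
    "serial_prediction",
    "rmse",
]


@dataclass(frozen=True)
class LearningSet:
    """Ordered (history, future) pairs sliced from a smoothed window.

    ``histories`` has shape (k, n) and ``futures`` (k, m); row ``i`` holds
    the pair starting at offset ``i`` in the source window, so row order is
    the total order used for tie-breaking.
    """

    histories: np.ndarray
    futures: np.ndarray

    def __post_init__(self) -> None:
        if self.histories.ndim != 2 or self.futures.ndim != 2:
            raise ValueError("histories and futures must be 2-D arrays")
        if self.histories.shape[0] != self.futures.shape[0]:
            raise ValueError("histories and futures must have equal entry counts")

    def __len__(self) -> int:
        return int(self.histories.shape[0])

    @property
    def n(self) -> int:
        return int(self.histories.shape[1])

    @property
    def m(self) -> int:
        return int(self.futures.shape[1])


@dataclass(frozen=True)
class PredictorConfig:
    """Shape of the rolling predictor.

    N : learning-window length (points); n : history length; m : horizon.
    ``n + m <= N`` so at least one pair fits in the window.
    ``smoothing`` is applied to the learning window only; the query history
    stays raw unless ``smooth_test_history`` is set.  ``refresh_stride``
    rebuilds the learning set only every so many steps (an approximation;
    stride 1 is exact).
    """

    N: int
    n: int
    m: int
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig.identity)
    smooth_test_history: bool = False
    refresh_stride: int = 1

    def __post_init__(self) -> None:
        if self.N < 1 or self.n < 1 or self.m < 1:
            raise ValueError("N, n and m must all be positive")
        if self.n + self.m > self.N:
            raise ValueError(
                f"need n + m <= N, got n={self.n}, m={self.m}, N={self.N}"
            )
        if self.refresh_stride < 1:
            raise ValueError("refresh_stride must be >= 1")


def euclidean_distance(a, b) -> float:
    """Euclidean metric between two equal-length tuples."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def build_learning_set(
    window,
    n: int,
    m: int,
    smoothing: SmoothingConfig | None = None,
    dt: float | None = None,
) -> LearningSet:
    """Smooth an N-point window and slice all (history, future) pairs.

    Produces ``N - n - m + 1`` pairs at stride 1.  ``smoothing=None``
    skips the smoothing step.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("window must be 1-D")
    N = x.size
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    if n + m > N:
        raise ValueError(f"need n + m <= window length, got {n}+{m} > {N}")
    if smoothing is not None:
        x = smooth(x, smoothing, dt)
    pairs = sliding_window_view(x, n + m)[: N - n - m + 1]
    return LearningSet(histories=pairs[:, :n], futures=pairs[:, n:])


def _largest_argmin(d: np.ndarray) -> int:
    """Index of the minimum; among exact ties, the largest index."""
    return int(d.size - 1 - np.argmin(d[::-1]))


def nn_predict(learning_set: LearningSet, test_history) -> np.ndarray:
    """Return the future of the stored history nearest to ``test_history``.

    Ties in distance are broken in favour of the most recent (highest
    index) entry.
    """
    if len(learning_set) == 0:
        raise ValueError("learning set is empty")
    q = np.asarray(test_history, dtype=np.float64)
    if q.shape != (learning_set.n,):
        raise ValueError(
            f"test history length {q.size} != learning-set history length "
            f"{learning_set.n}"
        )
    d2 = np.sum((learning_set.histories - q) ** 2, axis=1)
    return np.array(learning_set.futures[_largest_argmin(d2)])


def rolling_predict(
    signal: RespiratorySignal,
    config: PredictorConfig,
    t_range=None,
) -> np.ndarray:
    """Serial multistep prediction over a signal.

    For each time index ``t`` the learning window is the ``N`` raw samples
    ending at ``t - n - 1``; a learning set is (re)built from it with the
    configured smoothing, and queried with the raw history
    ``(x[t-n], ..., x[t-1])``.  Valid ``t`` run from ``N + n`` to
    ``M - m`` inclusive.

    Returns an array of shape ``(len(t_range), m)`` of predicted m-tuples;
    row ``i`` forecasts ``x[t_i], ..., x[t_i + m - 1]``.
    """
    x = signal.values
    M = x.size
    N, n, m = config.N, config.n, config.m
    if M < N + n + m:
        raise ValueError(f"signal length {M} < N + n + m = {N + n + m}")
    t_lo, t_hi = N + n, M - m
    if t_range is None:
        t_range = range(t_lo, t_hi + 1)
    t_range = list(t_range)
    for t in t_range:
        if not (t_lo <= t <= t_hi):
            raise ValueError(f"t={t} outside the valid range [{t_lo}, {t_hi}]")

    preds = np.empty((len(t_range), m))
    ls: LearningSet | None = None
    for i, t in enumerate(t_range):
        if ls is None or i % config.refresh_stride == 0:
            ls = build_learning_set(
                x[t - n - N : t - n], n, m, config.smoothing, dt=signal.dt
            )
        q = x[t - n : t]
        if config.smooth_test_history:
            q = smooth(q, config.smoothing, dt=signal.dt)
        preds[i] = nn_predict(ls, q)
    return preds


def serial_prediction(
    signal: RespiratorySignal, config: PredictorConfig
) -> dict:
    """Run the full rolling protocol and score the m-step-ahead coordinate.

    Returns a dict with the scored time indices (``t + m - 1`` for each
    prediction origin ``t``), the m-th predicted coordinates, the matching
    actual observations, and their RMSE in mm.
    """
    x = signal.values
    M = x.size
    N, n, m = config.N, config.n, config.m
    preds = rolling_predict(signal, config)
    t_vals = np.arange(N + n, M - m + 1)
    scored = t_vals + m - 1
    predicted_last = preds[:, m - 1]
    actual = x[scored]
    return {
        "indices": scored,
        "predicted": predicted_last,
        "actual": actual,
        "rmse_mm": rmse(predicted_last, actual),
    }


def rmse(predicted, actual) -> float:
    """Root-mean-square error between two equal-length sequences (mm)."""
    p = np.asarray(predicted, dtype=np.float64)
    a = np.asarray(actual, dtype=np.float64)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty sequences is undefined")
    return float(np.sqrt(np.mean((p - a) ** 2)))
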