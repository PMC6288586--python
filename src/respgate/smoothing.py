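"""Low-pass smoothing of respiratory signals via the finite Fourier transform.

The smoothing operator applied to an N-point window is the chain

    Hamming-multiply -> forward DFT -> zero high-frequency bins
    -> inverse DFT -> real part -> Hamming-divide

where the forward transform is unnormalized and the inverse carries the
1/N factor.  The frequency mask zeroes bin ``k`` iff ``|k - N/2| < N/2 - alpha``
(strict inequality, boundary bins kept); the kept set is symmetric under
``k -> N - k`` so the filtered spectrum of a real window stays
conjugate-symmetric and the imaginary residue before the real-part step is
pure round-off.  The cutoff parameter ``alpha`` is in frequency bins; a
physical cutoff ``f`` in Hz maps to ``alpha = N * dt * f``.  ``alpha >= N/2``
keeps every bin and the whole chain collapses to the identity.

The Hamming weights never drop below 0.08, so the elementwise division by
the window on the way out is well conditioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SmoothingConfig",
    "hamming_weights",
    "frequency_mask",
    "alpha_from_cutoff",
    "smooth",
    "power_spectrum",
]


@dataclass(frozen=True)
class SmoothingConfig:
    """Cutoff for the low-pass smoother, as bins (``alpha``) or Hz (``cutoff_hz``).

    Exactly one of the two must be set.  ``cutoff_hz`` is converted to
    ``alpha`` per window at smoothing time, which requires the sampling
    interval.  ``SmoothingConfig.identity()`` builds a configuration whose
    mask keeps every bin, i.e. smoothing disabled.
    """

    alpha: float | None = None
    cutoff_hz: float | None = None

    def __post_init__(self) -> None:
        if (self.alpha is None) == (self.cutoff_hz is None):
            raise ValueError("exactly one of alpha / cutoff_hz must be given")
        if self.alpha is not None and self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")
        if self.cutoff_hz is not None and self.cutoff_hz < 0:
            raise ValueError(f"cutoff_hz must be non-negative, got {self.cutoff_hz}")

    @classmethod
    def identity(cls) -> "SmoothingConfig":
        """A configuration under which smoothing is the identity map."""
        return cls(alpha=math.inf)

    @property
    def is_identity(self) -> bool:
        return self.alpha is not None and math.isinf(self.alpha)

    def resolve_alpha(self, N: int, dt: float | None = None) -> float:
        """Resolve the bin-domain cutoff for an ``N``-point window."""
        if self.alpha is not None:
            return self.alpha
        if dt is None:
            raise ValueError("dt is required to resolve a cutoff given in Hz")
        return alpha_from_cutoff(self.cutoff_hz, N, dt)


def hamming_weights(N: int) -> np.ndarray:
    """Hamming window ``w_k = 0.54 - 0.46 cos(2 pi k / (N - 1))``.

    Symmetric, with endpoints 0.08 and maximum 1.  Requires ``N >= 2``.
    """
    if N < 2:
        raise ValueError(f"Hamming window needs N >= 2, got {N}")
    k = np.arange(N)
    w = 0.54 - 0.46 * np.cos(2.0 * np.pi * k / (N - 1))
    if np.any(w < 1e-12):  # cannot happen for the 0.54/0.46 coefficients
        raise ValueError("degenerate window weight; inverse window unsafe")
    return w


def frequency_mask(coefficients: np.ndarray, alpha: float) -> np.ndarray:
    """Zero the spectral bins ``k`` with ``|k - N/2| < N/2 - alpha``.

    The strict inequality keeps boundary bins.  ``alpha`` may be any
    non-negative real; ``alpha >= N/2`` leaves the spectrum untouched.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    c = np.asarray(coefficients, dtype=np.complex128)
    N = c.size
    k = np.arange(N)
    out = c.copy()
    out[np.abs(k - N / 2.0) < N / 2.0 - alpha] = 0.0
    return out


def alpha_from_cutoff(f: float, N: int, dt: float) -> float:
    """Convert a cutoff frequency in Hz to the bin-domain ``alpha = N dt f``.

    ``f`` must lie in ``[0, 1/(2 dt)]`` (up to Nyquist).  The result is kept
    real-valued; the mask inequality consumes it directly.
    """
    if not (dt > 0):
        raise ValueError(f"dt must be positive, got {dt}")
    nyquist = 1.0 / (2.0 * dt)
    if not (0.0 <= f <= nyquist):
        raise ValueError(f"cutoff {f} Hz outside [0, {nyquist}] Hz")
    return N * dt * f


def smooth(
    window,
    config: SmoothingConfig,
    dt: float | None = None,
) -> np.ndarray:
    """Apply the Hamming-windowed Fourier low-pass smoother to a window.

    Parameters
    ----------
    window : array-like of float, length N >= 2
    config : SmoothingConfig
    dt : float, optional
        Sampling interval; needed only when the cutoff is given in Hz.

    Returns
    -------
    numpy.ndarray
        The smoothed window, same length, real and finite.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("window must be a 1-D sequence of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains NaN or Inf")
    N = x.size
    alpha = config.resolve_alpha(N, dt)
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    if alpha >= N / 2.0:
        return x.copy()
    w = hamming_weights(N)
    s = np.fft.fft(w * x)
    u = np.fft.ifft(frequency_mask(s, alpha))
    return u.real / w


def power_spectrum(window, dt: float | None = None) -> np.ndarray:
    """Magnitudes ``|s_k|`` of the Hamming-windowed spectrum, k = 0..floor((N-1)/2).

    Display helper for inspecting which components a cutoff removes.
    """
    x = np.asarray(window, dtype=np.float64)
    N = x.size
    s = np.fft.fft(hamming_weights(N) * x)
    return np.abs(s[: (N - 1) // 2 + 1])
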