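"""Shared DSP primitives for the respiration and ECG pipelines.

All filters operate on :class:`SampledSignal`, are length-preserving and
deterministic, and are realised zero-phase so that event timing downstream
(which is compared against windows of ~±140 ms) is never distorted by group
delay.

Conventions
-----------
Sample indices are 0-based; sample ``i`` of a signal lives at time
``t0 + i / fs`` seconds.  All windows elsewhere in the package are closed
intervals in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "SampledSignal",
    "PeakSet",
    "bandpass",
    "moving_mean",
    "savgol",
    "find_peaks",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled waveform.

    Parameters
    ----------
    values : ndarray
        Amplitudes in arbitrary units.
    fs : float
        Sampling rate in Hz, strictly positive.
    t0 : float
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if v.ndim != 1 or v.size < 1:
            raise InvalidParameterError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("signal contains non-finite values")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Record span in seconds (first to last sample)."""
        return (len(self) - 1) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample time axis in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs

    def replace_values(self, values: np.ndarray) -> "SampledSignal":
        """A copy of this signal carrying ``values`` (same fs and t0)."""
        return SampledSignal(values, self.fs, self.t0)


@dataclass(frozen=True)
class PeakSet:
    """Constrained local maxima of a sampled signal.

    ``indices`` are strictly increasing sample indices; ``heights`` are the
    signal amplitudes at those indices; ``fs`` converts indices to seconds.
    """

    indices: np.ndarray
    heights: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "heights", h)
        if idx.size != h.size:
            raise InvalidParameterError("indices and heights must align")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise InvalidParameterError("peak indices must be strictly increasing")

    def __len__(self) -> int:
        return self.indices.size

    @property
    def times(self) -> np.ndarray:
        """Peak times in seconds."""
        return self.t0 + self.indices / self.fs


def bandpass(x: SampledSignal, f_lo: float, f_hi: float, order: int = 4) -> SampledSignal:
    """Zero-phase Butterworth band-pass.

    A forward-backward (``sosfiltfilt``) pass of an order-``order`` Butterworth
    design, so pass-band events keep their timing exactly and the effective
    attenuation slope is doubled.

    Raises
    ------
    InvalidParameterError
        If the band edges are not ``0 < f_lo < f_hi < fs/2``.
    DegenerateInputError
        If the signal is shorter than the filter warm-up (padding) length.
    """
    nyq = x.fs / 2.0
    if not (0.0 < f_lo < f_hi < nyq):
        raise InvalidParameterError(
            f"band edges must satisfy 0 < f_lo < f_hi < fs/2; got "
            f"({f_lo}, {f_hi}) at fs={x.fs}"
        )
    sos = sps.butter(order, [f_lo, f_hi], btype="bandpass", fs=x.fs, output="sos")
    min_padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= min_padlen:
        raise DegenerateInputError(
            f"signal of {len(x)} samples is shorter than the filter warm-up "
            f"({min_padlen} samples)"
        )
    # low corner frequencies need padding on the scale of their settling
    # time, or boundary transients dominate low-frequency bands
    padlen = min(max(min_padlen, int(round(3.0 * x.fs / f_lo))), len(x) - 1)
    y = sps.sosfiltfilt(sos, x.values, padlen=padlen)
    return x.replace_values(y)


def moving_mean(x: SampledSignal, frame: int) -> SampledSignal:
    """Centred moving average with the window clipped to the signal bounds.

    ``out[i]`` is the mean of ``x[max(0, i-(frame-1)//2) : min(n, i+frame//2+1)]``;
    near the edges the window shrinks rather than padding, so a constant signal
    maps to itself everywhere and no spurious boundary transients appear.
    """
    frame = int(frame)
    if frame < 1:
        raise InvalidParameterError(f"frame must be >= 1, got {frame}")
    n = len(x)
    if frame > n:
        raise InvalidParameterError(f"frame {frame} exceeds signal length {n}")
    if frame == 1:
        return x.replace_values(x.values.copy())
    left = (frame - 1) // 2
    right = frame // 2
    csum = np.concatenate(([0.0], np.cumsum(x.values)))
    i = np.arange(n)
    lo = np.maximum(i - left, 0)
    hi = np.minimum(i + right + 1, n)
    y = (csum[hi] - csum[lo]) / (hi - lo)
    return x.replace_values(y)


def savgol(x: SampledSignal, order: int, frame: int) -> SampledSignal:
    """Savitzky-Golay smoothing with mirror (reflect) edge handling.

    The frame is a sample count; if even it is rounded up to the next odd
    value with a warning (the frame length is typically derived from an
    inter-beat interval and need not come out odd).  Exactly reproduces any
    polynomial of degree <= ``order``.
    """
    frame = int(frame)
    order = int(order)
    if frame % 2 == 0:
        warnings.warn(
            f"Savitzky-Golay frame {frame} is even; using {frame + 1}",
            stacklevel=2,
        )
        frame += 1
    if frame <= order:
        raise InvalidParameterError(
            f"frame ({frame}) must exceed polynomial order ({order})"
        )
    if frame > len(x):
        raise DegenerateInputError(
            f"frame {frame} exceeds signal length {len(x)}"
        )
    y = sps.savgol_filter(x.values, frame, order, mode="mirror")
    return x.replace_values(y)


def find_peaks(
    x: SampledSignal,
    min_distance: int,
    min_height: float | None = None,
    min_prominence: float | None = None,
) -> PeakSet:
    """Constrained local-maxima search.

    Every returned index is a strict local maximum (greater than both
    neighbours) passing the height and prominence thresholds.  Among
    candidates closer than ``min_distance`` samples the taller is kept;
    equal heights keep the earlier index.  An all-flat signal yields an
    empty :class:`PeakSet`.

    Notes
    -----
    With ``min_prominence`` the result is invariant under adding a constant
    to the signal; with ``min_height`` (an absolute threshold) it is not.
    """
    min_distance = int(min_distance)
    if min_distance < 1:
        raise InvalidParameterError(f"min_distance must be >= 1, got {min_distance}")
    v = x.values
    n = v.size
    if n < 3:
        return PeakSet(np.empty(0, np.int64), np.empty(0), x.fs, x.t0)
    interior = np.arange(1, n - 1)
    is_max = (v[interior] > v[interior - 1]) & (v[interior] > v[interior + 1])
    cand = interior[is_max]
    if min_height is not None:
        cand = cand[v[cand] > min_height]
    if min_prominence is not None and cand.size:
        prom = sps.peak_prominences(v, cand)[0]
        cand = cand[prom >= min_prominence]
    if cand.size == 0:
        return PeakSet(np.empty(0, np.int64), np.empty(0), x.fs, x.t0)
    # Greedy suppression: tallest first, ties keep the earlier index.
    order = np.lexsort((cand, -v[cand]))
    kept: list[int] = []
    suppressed = np.zeros(cand.size, dtype=bool)
    for oi in order:
        if suppressed[oi]:
            continue
        idx = cand[oi]
        kept.append(idx)
        lo = np.searchsorted(cand, idx - min_distance + 1, side="left")
        hi = np.searchsorted(cand, idx + min_distance - 1, side="right")
        suppressed[lo:hi] = True
    kept_arr = np.sort(np.asarray(kept, dtype=np.int64))
    return PeakSet(kept_arr, v[kept_arr], x.fs, x.t0)
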