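"""Digital band-pass filtering and overlapping-window segmentation.

Filtering uses a causal single-pass Butterworth band-pass whose overall
transfer-function order equals the requested order (a band-pass doubles the
low-pass prototype order, so ``order=4`` designs a 2nd-order prototype).
Segmentation slices fixed-length windows with a fixed step; trailing samples
that do not fill a window are discarded, so the window count is
``floor((N - W) / S) + 1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .errors import DataError, ParameterError
from .synth import Recording


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass: 10–500 Hz, 4th order by default."""

    low_hz: float = 10.0
    high_hz: float = 500.0
    order: int = 4

    def __post_init__(self) -> None:
        if self.low_hz <= 0 or self.high_hz <= self.low_hz:
            raise ParameterError("need 0 < low_hz < high_hz")
        if self.order < 2 or self.order % 2 != 0:
            raise ParameterError("band-pass order must be an even integer >= 2")


@dataclass(frozen=True)
class WindowSpec:
    """Overlapping analysis windows: 250 ms length, 190 ms overlap by default."""

    length_ms: float = 250.0
    overlap_ms: float = 190.0

    def __post_init__(self) -> None:
        if self.length_ms <= 0:
            raise ParameterError("length_ms must be positive")
        if not 0 <= self.overlap_ms < self.length_ms:
            raise ParameterError("need 0 <= overlap_ms < length_ms")

    def window_samples(self, fs: float) -> int:
        return int(round(self.length_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        return int(round((self.length_ms - self.overlap_ms) * fs / 1000.0))


@dataclass
class WindowSet:
    """Ordered fixed-length segments of one recording.

    ``windows`` has shape ``(n_windows, n_channels, window_samples)``;
    ``offsets[i]`` is the start sample of window ``i`` within the (trimmed)
    source signal.
    """

    windows: np.ndarray
    offsets: np.ndarray
    source: Recording

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]


def design_bandpass(fspec: FilterSpec, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Return (b, a) for the band-pass at sampling rate ``fs``.

    When the upper cutoff reaches Nyquist (e.g. 500 Hz at fs = 1 kHz), it is
    clipped to 0.99·fs/2 with a warning; an infeasible low cutoff raises.
    """
    high = fspec.high_hz
    nyq = fs / 2.0
    if high >= nyq:
        high = 0.99 * nyq
        warnings.warn(
            f"high cutoff {fspec.high_hz} Hz >= Nyquist ({nyq} Hz); clipped to {high} Hz",
            stacklevel=2,
        )
    if not fspec.low_hz < high:
        raise ParameterError(f"low cutoff {fspec.low_hz} Hz not below clipped high {high} Hz")
    return signal.butter(fspec.order // 2, [fspec.low_hz, high], btype="band", fs=fs)


def bandpass(rec: Recording, fspec: FilterSpec = FilterSpec()) -> Recording:
    """Causal band-pass of every channel; shape and metadata preserved."""
    b, a = design_bandpass(fspec, rec.fs)
    filtered = signal.lfilter(b, a, rec.samples, axis=-1)
    return replace(rec, samples=filtered)


def window_count(n_samples: int, window: int, step: int) -> int:
    """Number of full windows: floor((N - W) / S) + 1, or 0 if N < W."""
    if window <= 0 or step <= 0:
        raise ParameterError("window and step must be positive")
    if n_samples < window:
        return 0
    return (n_samples - window) // step + 1


def segment(
    rec: Recording,
    wspec: WindowSpec = WindowSpec(),
    trim_start_s: float = 0.0,
    trim_end_s: float = 0.0,
) -> WindowSet:
    """Slice a recording into overlapping windows.

    ``trim_start_s`` / ``trim_end_s`` drop the given durations from the
    beginning and end before windowing (used to exclude the resting lead-in
    and select the movement-only portion).
    """
    if trim_start_s < 0 or trim_end_s < 0:
        raise ParameterError("trims must be non-negative")
    start = int(round(trim_start_s * rec.fs))
    stop = rec.n_samples - int(round(trim_end_s * rec.fs))
    if stop <= start:
        raise DataError("trims remove the whole recording")
    x = rec.samples[:, start:stop]
    w = wspec.window_samples(rec.fs)
    s = wspec.step_samples(rec.fs)
    n = window_count(x.shape[1], w, s)
    if n == 0:
        raise DataError(
            f"recording segment of {x.shape[1]} samples is shorter than one "
            f"window ({w} samples)"
        )
    offsets = np.arange(n) * s
    view = np.lib.stride_tricks.sliding_window_view(x, w, axis=1)[:, offsets, :]
    return WindowSet(windows=np.moveaxis(view, 0, 1).copy(), offsets=offsets, source=rec)
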