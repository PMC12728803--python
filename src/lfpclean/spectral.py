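"""Hanning/Welch and multitaper spectral estimation with explicit resolution control.

Window length, DFT length and taper count interact: a window of ``N``
samples at rate ``fs`` can resolve nothing below ``fs/N`` Hz, the DFT bin
spacing is ``fs/nfft``, and a Hanning taper smooths the spectrum over a
main-lobe half-bandwidth of ``2*fs/nfft`` Hz.  The multitaper estimator
trades that fixed smoothing for variance reduction: with window duration
``T`` seconds and half-bandwidth ``W`` Hz it supports
``floor(2*T*W) - 1`` Slepian tapers whose per-taper spectra are averaged.
These four pieces of arithmetic are exposed as first-class functions so
parameter choices can be reasoned about (and tested) before any data are
touched.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .exceptions import InvalidArgumentError, TooShortError
from .recording import LfpRecording

__all__ = [
    "SpectralParams",
    "Psd",
    "Spectrogram",
    "min_frequency",
    "fft_resolution",
    "hanning_halfbandwidth",
    "n_tapers",
    "welch_psd",
    "multitaper_psd",
    "short_time_spectrogram",
]

#: Canonical oscillatory bands (Hz) used throughout the pipeline.
BANDS = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "slow_gamma": (30.0, 50.0),
    "high_gamma": (50.0, 100.0),
}


# ---------------------------------------------------------------------------
# resolution arithmetic
# ---------------------------------------------------------------------------

def min_frequency(fs: float, N: int) -> float:
    """Lowest observable frequency for a window of ``N`` samples: ``fs/N``.

    One full period of an oscillation must fit inside the window for the
    oscillation to be represented at all.
    """
    if N < 1:
        raise InvalidArgumentError(f"window length must be >= 1 sample, got {N}")
    return fs / N


def fft_resolution(fs: float, nfft: int) -> float:
    """DFT bin spacing ``fs/nfft`` in Hz."""
    if nfft < 1:
        raise InvalidArgumentError(f"nfft must be >= 1, got {nfft}")
    return fs / nfft


def hanning_halfbandwidth(fs: float, nfft: int) -> float:
    """Hanning-window smoothing half-bandwidth ``2*fs/nfft`` in Hz.

    The Hanning main lobe spans two DFT bins on either side of a tone, so
    the effective frequency resolution is twice the bin spacing (main-lobe
    width is twice this value again).
    """
    if nfft < 1:
        raise InvalidArgumentError(f"nfft must be >= 1, got {nfft}")
    return 2.0 * fs / nfft


def n_tapers(T: float, W_hz: float) -> int:
    """Number of Slepian tapers for duration ``T`` s and half-bandwidth ``W`` Hz.

    ``floor(2*T*W) - 1`` — the standard rule keeping every taper's energy
    concentrated inside the half-bandwidth.
    """
    tw = T * W_hz
    if tw < 1:
        raise InvalidArgumentError(
            f"time-halfbandwidth product {tw} < 1 admits no valid taper"
        )
    return int(math.floor(2.0 * tw)) - 1


def _next_pow2(n: int) -> int:
    return 1 << (int(n) - 1).bit_length()


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectralParams:
    """Spectral-estimation parameters.

    ``nfft`` defaults to the next power of two at or above the window
    length.  For the multitaper method, the half-bandwidth defaults to the
    Hanning smoothing half-bandwidth of the same window, but is held at a
    floor of 1 Hz for long windows so that extra window length buys tapers
    (variance reduction) instead of sub-1-Hz smoothing that neural
    recordings rarely support.
    """

    fs: float
    window_length: int
    nfft: Optional[int] = None
    overlap: float = 0.5
    method: str = "multitaper"
    half_bandwidth: Optional[float] = None

    def __post_init__(self):
        if self.fs <= 0:
            raise InvalidArgumentError("fs must be positive")
        if self.window_length < 1:
            raise InvalidArgumentError("window_length must be >= 1")
        if not (0 <= self.overlap < 1):
            raise InvalidArgumentError("overlap must be in [0, 1)")
        if self.method not in ("hanning_welch", "multitaper"):
            raise InvalidArgumentError(f"unknown method {self.method!r}")
        if self.nfft is None:
            object.__setattr__(self, "nfft", _next_pow2(self.window_length))
        if self.nfft < self.window_length:
            raise InvalidArgumentError("nfft must be >= window_length")
        if self.half_bandwidth is None and self.method == "multitaper":
            w = max(1.0, hanning_halfbandwidth(self.fs, self.nfft))
            object.__setattr__(self, "half_bandwidth", w)
        if self.half_bandwidth is not None and self.half_bandwidth <= 0:
            raise InvalidArgumentError("half_bandwidth must be positive")

    @classmethod
    def from_duration(cls, fs: float, window_sec: float = 2.0, **kw) -> "SpectralParams":
        return cls(fs=fs, window_length=int(round(window_sec * fs)), **kw)

    @property
    def T(self) -> float:
        """Window duration in seconds."""
        return self.window_length / self.fs

    @property
    def n_tapers(self) -> int:
        if self.method != "multitaper":
            raise InvalidArgumentError("n_tapers only defined for multitaper")
        return n_tapers(self.T, self.half_bandwidth)

    @property
    def step(self) -> int:
        """Hop between window starts in samples."""
        return max(1, int(round(self.window_length * (1.0 - self.overlap))))


# ---------------------------------------------------------------------------
# spectra containers
# ---------------------------------------------------------------------------

@dataclass
class Psd:
    """One-sided power spectral density.

    ``power`` is a density in uV^2/Hz on the grid ``frequencies``
    (spacing ``fs/nfft`` from 0 to the Nyquist frequency).  The DC bin is
    retained but excluded from downstream model fits.
    """

    frequencies: np.ndarray
    power: np.ndarray
    params: SpectralParams

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise InvalidArgumentError("frequency and power grids differ in length")

    @property
    def power_db(self) -> np.ndarray:
        """Power in decibels, ``10*log10(power)``."""
        with np.errstate(divide="ignore"):
            return 10.0 * np.log10(self.power)

    @property
    def df(self) -> float:
        return self.params.fs / self.params.nfft

    def band_slice(self, band: Sequence[float]) -> np.ndarray:
        """Boolean mask selecting ``band[0] <= f <= band[1]``."""
        lo, hi = band
        return (self.frequencies >= lo) & (self.frequencies <= hi)

    def band_power(self, band: Sequence[float]) -> float:
        """Integrated power (uV^2) over a frequency band."""
        m = self.band_slice(band)
        return float(np.sum(self.power[m]) * self.df)

    def plot(self, ax=None, db: bool = True, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = self.power_db if db else self.power
        ax.plot(self.frequencies, y, **kw)
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("power (dB)" if db else "power (uV$^2$/Hz)")
        return ax


@dataclass
class Spectrogram:
    """Time-ordered sequence of PSD windows from a short-time transform."""

    windows: list  # list[Psd]
    start_samples: list  # list[int]
    params: SpectralParams

    def __post_init__(self):
        starts = np.asarray(self.start_samples)
        if len(starts) != len(self.windows):
            raise InvalidArgumentError("one start per window required")
        if len(starts) > 1 and not np.all(np.diff(starts) > 0):
            raise InvalidArgumentError("window starts must be strictly increasing")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def frequencies(self) -> np.ndarray:
        return self.windows[0].frequencies

    @property
    def start_times(self) -> np.ndarray:
        return np.asarray(self.start_samples) / self.params.fs

    def power_matrix(self) -> np.ndarray:
        """Linear power, shape (n_windows, n_freqs)."""
        return np.stack([w.power for w in self.windows])

    def db_matrix(self) -> np.ndarray:
        """dB power, shape (n_windows, n_freqs)."""
        return np.stack([w.power_db for w in self.windows])

    def subset(self, indices) -> "Spectrogram":
        indices = sorted(indices)
        return Spectrogram(
            windows=[self.windows[i] for i in indices],
            start_samples=[self.start_samples[i] for i in indices],
            params=self.params,
        )

    def plot(self, ax=None, **kw):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.pcolormesh(self.start_times, self.frequencies, self.db_matrix().T,
                      shading="nearest", **kw)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("frequency (Hz)")
        return ax


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_trace(rec, channel=0) -> tuple:
    if isinstance(rec, LfpRecording):
        return rec.channel(channel), rec.fs
    x = np.asarray(rec, dtype=float)
    if x.ndim != 1:
        raise InvalidArgumentError("expected a 1-D trace or an LfpRecording")
    return x, None


def _check_length(x: np.ndarray, params: SpectralParams):
    if len(x) < params.window_length:
        raise TooShortError(
            f"trace of {len(x)} samples shorter than one "
            f"{params.window_length}-sample window"
        )


def welch_psd(rec, params: SpectralParams, channel=0) -> Psd:
    """Hanning-windowed, overlap-averaged (Welch) PSD.

    Segments of ``window_length`` samples are Hanning tapered, zero padded
    to ``nfft``, transformed, squared, density normalized and averaged.
    Zero padding interpolates the spectrum onto a finer grid; the placement
    of the padding (symmetric or trailing) shifts only phase and leaves the
    magnitude spectrum unchanged.
    """
    x, fs = _as_trace(rec, channel)
    fs = fs if fs is not None else params.fs
    _check_length(x, params)
    N = params.window_length
    freqs, pxx = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=N,
        noverlap=N - params.step,
        nfft=params.nfft,
        detrend=False,
        scaling="density",
        return_onesided=True,
    )
    p = replace(params, method="hanning_welch") if params.method != "hanning_welch" else params
    return Psd(frequencies=freqs, power=pxx, params=p)


def multitaper_psd(rec, params: SpectralParams, channel=0) -> Psd:
    """Multitaper PSD: per-taper periodograms averaged with equal weights.

    The trace is cut into ``window_length``-sample segments stepped by
    ``step`` (matching the Welch segmentation); each segment is tapered by
    every Slepian in the family, per-taper spectra are averaged, and the
    per-segment estimates are averaged again.
    """
    x, fs = _as_trace(rec, channel)
    fs = fs if fs is not None else params.fs
    if params.method != "multitaper":
        params = replace(params, method="multitaper", half_bandwidth=params.half_bandwidth)
    _check_length(x, params)
    N = params.window_length
    K = params.n_tapers  # validates >= 1
    NW = params.T * params.half_bandwidth
    tapers = signal.windows.dpss(N, NW, Kmax=K, return_ratios=False)
    tapers = np.atleast_2d(tapers)

    step = params.step
    starts = range(0, len(x) - N + 1, step)
    nfft = params.nfft
    acc = np.zeros(nfft // 2 + 1)
    n_seg = 0
    for s in starts:
        seg = x[s:s + N]
        spec = np.fft.rfft(seg[np.newaxis, :] * tapers, n=nfft, axis=1)
        pxx = (spec.real ** 2 + spec.imag ** 2) / fs  # tapers are unit-energy
        pxx = pxx.mean(axis=0)
        # one-sided density: double everything except DC (and Nyquist if present)
        pxx[1:] *= 2.0
        if nfft % 2 == 0:
            pxx[-1] /= 2.0
        acc += pxx
        n_seg += 1
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return Psd(frequencies=freqs, power=acc / n_seg, params=params)


def estimate_psd(rec, params: SpectralParams, channel=0) -> Psd:
    """Dispatch to :func:`welch_psd` or :func:`multitaper_psd` per ``params.method``."""
    if params.method == "hanning_welch":
        return welch_psd(rec, params, channel)
    return multitaper_psd(rec, params, channel)


def short_time_spectrogram(rec, params: Optional[SpectralParams] = None,
                           channel=0) -> Spectrogram:
    """Short-time transform: one PSD per overlapping window.

    Defaults follow the pipeline's working configuration: 2 s windows with
    50% overlap and, for the multitaper method, a 1 Hz half-bandwidth
    (hence 3 Slepian tapers per window).
    """
    x, fs = _as_trace(rec, channel)
    if params is None:
        if fs is None:
            raise InvalidArgumentError("params required when input is a bare array")
        params = SpectralParams.from_duration(fs, 2.0, half_bandwidth=1.0)
    fs = fs if fs is not None else params.fs
    _check_length(x, params)
    N = params.window_length
    single = replace(params, overlap=0.0)  # each window transformed whole
    windows, starts = [], []
    for s in range(0, len(x) - N + 1, params.step):
        seg = x[s:s + N]
        windows.append(estimate_psd(seg, single))
        starts.append(s)
    return Spectrogram(windows=windows, start_samples=starts, params=params)
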