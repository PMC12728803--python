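"""Synthetic LFP generator with ground-truth annotations.

Emulates the statistical structure a chronically sensed thalamic LFP is
assumed to have: a 1/f-with-knee aperiodic background, band-limited
oscillatory peaks, a quasi-periodic cardiac QRS artifact train that is
time-locked across hemispheres but scaled differently per channel, short
high-amplitude transients (interictal-like events and stimulation on/off
edges), and round-to-nearest digitization.  Every generated component is
returned alongside the contaminated recording so downstream stages can be
scored against exact ground truth.

The background is synthesized by frequency-domain amplitude shaping: the
one-sided target power density ``10**(b - log10(k + f**x))`` (uV^2/Hz) is
imposed on uniformly random phases, giving direct control of the aperiodic
model parameters for parameter-recovery tests.  Oscillations are
band-filtered Gaussian noise scaled to a requested RMS amplitude, not pure
tones.  The QRS complex is a biphasic spike built from three
Gaussian-windowed deflections (Q and S negative, R positive) about 55
samples wide at 250 Hz — wide enough to fill the detection stage's minimum
capture window.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .exceptions import InvalidArgumentError
from .recording import LfpRecording, StimSegment

__all__ = [
    "BackgroundSpec",
    "OscillationSpec",
    "QrsSpec",
    "TransientSpec",
    "SimulationSpec",
    "GroundTruth",
    "simulate_background",
    "add_oscillation",
    "simulate_qrs_train",
    "assemble_recording",
]


# ---------------------------------------------------------------------------
# specification types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundSpec:
    """Aperiodic background: log10 power density = b - log10(k + f**x).

    ``knee`` (k, units Hz**exponent) bends the decay, ``exponent`` (x) sets
    its steepness, ``offset`` (b) shifts the whole spectrum vertically in
    log10(uV^2/Hz).  ``offset = -inf`` is the guarded zero-amplitude case.
    """

    knee: float = 2.0
    exponent: float = 1.5
    offset: float = 1.0

    def __post_init__(self):
        if self.knee < 0:
            raise InvalidArgumentError("knee must be >= 0")
        if self.exponent < 0:
            raise InvalidArgumentError("exponent must be >= 0")

    def log10_power(self, f: np.ndarray) -> np.ndarray:
        """Model log10 power density on a frequency grid (f > 0)."""
        return self.offset - np.log10(self.knee + np.asarray(f, float) ** self.exponent)


@dataclass(frozen=True)
class OscillationSpec:
    """A narrowband stochastic oscillation."""

    center_freq: float
    bandwidth: float = 2.0
    amplitude: float = 1.0  # uV RMS


@dataclass(frozen=True)
class QrsSpec:
    """Quasi-periodic cardiac QRS artifact train.

    ``channel_scales`` gives the per-hemisphere amplitude asymmetry;
    ``stim_on_scale`` rescales complexes that fall inside stimulation-on
    segments (artifact intensity can differ by recording state).
    """

    heart_rate: float = 70.0  # bpm
    rate_jitter: float = 0.03  # fractional inter-beat-interval jitter
    amplitude: float = 20.0  # uV at the R apex, before channel scaling
    polarity: int = 1
    channel_scales: tuple = (1.0, 0.3)
    stim_on_scale: float = 1.0


@dataclass(frozen=True)
class TransientSpec:
    """Short high-amplitude transient: interictal-like or stimulation edge."""

    onset: float  # s
    duration: float  # s
    amplitude: float  # uV
    kind: str = "ied"  # "ied" | "stim_edge"

    def __post_init__(self):
        if self.kind not in ("ied", "stim_edge"):
            raise InvalidArgumentError(f"unknown transient kind {self.kind!r}")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic recording."""

    sampling_rate: float = 250.0
    duration: float = 60.0
    seed: int = 0
    background: BackgroundSpec = field(default_factory=BackgroundSpec)
    oscillations: tuple = (OscillationSpec(20.0, 4.0, 1.5),)
    qrs: Optional[QrsSpec] = field(default_factory=QrsSpec)
    transients: tuple = ()
    quantization_step: float = 0.0
    stim_segments: tuple = ()

    def __post_init__(self):
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise InvalidArgumentError("duration and sampling_rate must be positive")
        n = self.duration * self.sampling_rate
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise InvalidArgumentError(
                f"duration x sampling_rate = {n} is not a positive integer"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def n_channels(self) -> int:
        return len(self.qrs.channel_scales) if self.qrs is not None else 2


@dataclass
class GroundTruth:
    """Exact per-component decomposition of a simulated recording."""

    clean_trace: np.ndarray  # (n_channels, n_samples): background + oscillations
    qrs_trace: np.ndarray  # artifact component, same shape
    transient_trace: np.ndarray  # same shape
    qrs_event_samples: np.ndarray  # sorted R-apex sample indices
    transient_windows: list  # list of (start_sample, end_sample)
    true_background_psd: tuple  # (frequencies Hz, log10 power density)

    def total(self) -> np.ndarray:
        """Sum of all components: the pre-quantization contaminated trace."""
        return self.clean_trace + self.qrs_trace + self.transient_trace


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _child_rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


def simulate_background(spec: SimulationSpec, seed=None,
                        rng: Optional[np.random.Generator] = None) -> LfpRecording:
    """One channel of aperiodic background via frequency-domain shaping.

    Random uniform phases are given the amplitude profile implied by the
    background model; DC is forced to zero and the inverse transform is
    real by construction.  Deterministic given the seed.
    """
    if spec.duration < 4.0:
        raise InvalidArgumentError("background synthesis needs duration >= 4 s")
    rng = rng if rng is not None else _child_rng(
        spec.seed if seed is None else seed, 0xB6
    )
    n = spec.n_samples
    fs = spec.sampling_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    bg = spec.background
    amp = np.zeros_like(freqs)
    if np.isfinite(bg.offset):
        with np.errstate(divide="ignore"):
            p = 10.0 ** bg.log10_power(freqs[1:])  # uV^2/Hz, one-sided density
        # |X_k|^2 * 2 / (fs * n) estimates the one-sided density
        amp[1:] = np.sqrt(p * fs * n / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    spectrum = amp * np.exp(1j * phases)
    spectrum[0] = 0.0
    if n % 2 == 0:
        spectrum[-1] = amp[-1] * np.sign(np.cos(phases[-1]))  # Nyquist bin must be real
    x = np.fft.irfft(spectrum, n=n)
    return LfpRecording(x, fs)


def add_oscillation(rec: LfpRecording, center_freq: float, bandwidth: float,
                    amplitude: float, seed=0, channel: int = 0) -> LfpRecording:
    """Add band-filtered Gaussian noise of a given RMS to one channel."""
    nyq = rec.fs / 2.0
    if not (0 < center_freq < nyq):
        raise InvalidArgumentError(
            f"center frequency {center_freq} Hz outside (0, {nyq}) Hz"
        )
    if amplitude == 0:
        return rec.with_data(rec.data.copy())
    rng = _child_rng(seed, 0x05C, int(center_freq * 1000))
    lo = max(center_freq - bandwidth / 2.0, 1e-3)
    hi = min(center_freq + bandwidth / 2.0, nyq * 0.999)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    noise = rng.standard_normal(rec.n_samples)
    osc = signal.sosfiltfilt(sos, noise)
    osc *= amplitude / np.std(osc)
    data = rec.data.copy()
    data[channel] += osc
    return rec.with_data(data)


def qrs_waveform(fs: float, amplitude: float = 1.0, polarity: int = 1) -> tuple:
    """Stereotyped biphasic QRS complex and its apex index.

    Three Gaussian-windowed deflections (Q negative, R positive dominant,
    S negative) spanning ~0.22 s (55 samples at 250 Hz); peak value equals
    ``amplitude * polarity`` at the returned apex index.
    """
    half = int(round(0.11 * fs))
    t = (np.arange(2 * half + 1) - half) / fs
    w = (
        1.00 * np.exp(-0.5 * (t / 0.011) ** 2)          # R
        - 0.22 * np.exp(-0.5 * ((t + 0.033) / 0.012) ** 2)  # Q
        - 0.32 * np.exp(-0.5 * ((t - 0.036) / 0.014) ** 2)  # S
    )
    apex = int(np.argmax(w))
    w = w / w[apex] * amplitude * polarity
    return w, apex


def simulate_qrs_train(spec: SimulationSpec, seed=None) -> tuple:
    """QRS artifact traces (one per channel) and ground-truth apex indices.

    Beats are placed quasi-periodically: the inter-beat interval is
    ``60/heart_rate`` seconds jittered by a uniform fraction
    ``+-rate_jitter``.  Event times are shared across channels
    (time-locked); each channel applies its own scale, and complexes inside
    stimulation-on segments are rescaled by ``stim_on_scale``.
    """
    q = spec.qrs
    if q is None:
        raise InvalidArgumentError("spec.qrs is None")
    if q.heart_rate <= 0:
        raise InvalidArgumentError("heart_rate must be positive")
    fs = spec.sampling_rate
    n = spec.n_samples
    ibi = 60.0 / q.heart_rate  # s
    if spec.duration / ibi < 2:
        raise InvalidArgumentError("fewer than 2 beats fit in the recording")
    rng = _child_rng(spec.seed if seed is None else seed, 0x9B5)
    times, t = [], ibi
    while t < spec.duration:
        times.append(t)
        t += ibi * (1.0 + q.rate_jitter * rng.uniform(-1.0, 1.0))
    events = np.unique(np.round(np.asarray(times) * fs).astype(int))
    events = events[(events >= 0) & (events < n)]

    wave, apex = qrs_waveform(fs, q.amplitude, q.polarity)
    traces = np.zeros((len(q.channel_scales), n))
    stim_on = np.zeros(len(events), dtype=bool)
    for j, e in enumerate(events):
        te = e / fs
        stim_on[j] = any(s.contains(te) for s in spec.stim_segments)
    for c, scale in enumerate(q.channel_scales):
        for e, on in zip(events, stim_on):
            s = scale * (q.stim_on_scale if on else 1.0)
            lo, hi = e - apex, e - apex + len(wave)
            wlo, whi = max(0, -lo), len(wave) - max(0, hi - n)
            lo, hi = max(lo, 0), min(hi, n)
            traces[c, lo:hi] += s * wave[wlo:whi]
    return traces, events


def _transient_trace(spec: SimulationSpec) -> tuple:
    """Sum of all transients (shared across channels) and their windows."""
    n, fs = spec.n_samples, spec.sampling_rate
    trace = np.zeros(n)
    windows = []
    for tr in spec.transients:
        s0 = int(round(tr.onset * fs))
        s1 = min(n, s0 + max(1, int(round(tr.duration * fs))))
        if s0 >= n or s1 <= 0:
            continue
        s0 = max(s0, 0)
        m = s1 - s0
        t = np.arange(m) / fs
        if tr.kind == "ied":
            # sharp spike followed by a slow wave, Hanning-gated to the window
            mid = tr.duration / 2.0
            y = tr.amplitude * (
                np.exp(-0.5 * ((t - mid * 0.6) / (tr.duration * 0.04)) ** 2)
                - 0.6 * np.exp(-0.5 * ((t - mid * 1.3) / (tr.duration * 0.18)) ** 2)
            )
            y *= np.hanning(m) if m > 2 else 1.0
        else:  # stim_edge: step transient decaying exponentially after onset
            y = tr.amplitude * np.exp(-t / max(tr.duration / 3.0, 1.0 / fs))
        trace[s0:s1] += y
        windows.append((s0, s1))
    return trace, windows


def assemble_recording(spec: SimulationSpec) -> tuple:
    """Build the full contaminated recording and its ground truth.

    Per channel: independent background + oscillations; a QRS train with
    shared (time-locked) event times; transients shared across channels;
    the sum optionally quantized to ``quantization_step`` (0 disables).
    """
    n, fs = spec.n_samples, spec.sampling_rate
    n_ch = spec.n_channels
    clean = np.zeros((n_ch, n))
    for c in range(n_ch):
        bg = simulate_background(spec, rng=_child_rng(spec.seed, 0xB6, c))
        x = bg.channel(0)
        for i, osc in enumerate(spec.oscillations):
            tmp = LfpRecording(x, fs)
            tmp = add_oscillation(tmp, osc.center_freq, osc.bandwidth,
                                  osc.amplitude,
                                  seed=np.random.SeedSequence([spec.seed, 0x05C, c, i])
                                  .generate_state(1)[0] % (2 ** 31))
            x = tmp.channel(0)
        clean[c] = x

    if spec.qrs is not None:
        qrs_trace, events = simulate_qrs_train(spec)
    else:
        qrs_trace, events = np.zeros((n_ch, n)), np.array([], dtype=int)

    tr, windows = _transient_trace(spec)
    transient_trace = np.tile(tr, (n_ch, 1))

    contaminated = clean + qrs_trace + transient_trace
    if spec.quantization_step > 0:
        contaminated = np.round(contaminated / spec.quantization_step) * spec.quantization_step

    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[1:]
    truth = GroundTruth(
        clean_trace=clean,
        qrs_trace=qrs_trace,
        transient_trace=transient_trace,
        qrs_event_samples=events,
        transient_windows=windows,
        true_background_psd=(freqs, spec.background.log10_power(freqs)),
    )
    labels = ("right", "left") if n_ch == 2 else tuple(f"ch{i}" for i in range(n_ch))
    stim_state = "mixed" if spec.stim_segments else "off"
    rec = LfpRecording(contaminated, fs, channel_labels=labels,
                       stim_state=stim_state,
                       stim_segments=list(spec.stim_segments))
    return rec, truth
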