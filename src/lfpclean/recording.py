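"""In-memory container for sampled LFP voltage traces.

An :class:`LfpRecording` holds one or more channels of a bipolar LFP
recording in microvolts, together with the sampling rate and the
stimulation-state annotation that the ECG-removal stage needs to build
per-state QRS templates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["LfpRecording", "StimSegment"]


@dataclass(frozen=True)
class StimSegment:
    """A contiguous stretch of stimulation with a fixed amplitude."""

    start_s: float
    end_s: float
    amplitude_ma: float = 0.0

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class LfpRecording:
    """Sampled voltage trace(s) with sampling rate and annotations.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts.  A 1-D array is promoted to one channel.
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        One label per channel (e.g. ``("right", "left")``).
    stim_state : {"on", "off", "mixed"}
        Stimulation state over the whole recording; ``"mixed"`` means the
        state varies and is described by ``stim_segments``.
    stim_segments : list of StimSegment
        Stimulation-on intervals; only meaningful when ``stim_state`` is
        ``"mixed"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple = ()
    stim_state: str = "off"
    stim_segments: list = field(default_factory=list)

    def __post_init__(self):
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2:
            raise InvalidArgumentError("data must be 1-D or 2-D")
        if self.fs <= 0:
            raise InvalidArgumentError(f"sampling rate must be positive, got {self.fs}")
        if self.stim_state not in ("on", "off", "mixed"):
            raise InvalidArgumentError(f"unknown stim_state {self.stim_state!r}")
        self.data = arr
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(arr.shape[0]))
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != arr.shape[0]:
            raise InvalidArgumentError(
                f"{len(self.channel_labels)} labels for {arr.shape[0]} channels"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, key=0) -> np.ndarray:
        """Return one channel as a 1-D array, by index or label."""
        if isinstance(key, str):
            key = self.channel_labels.index(key)
        return self.data[key]

    def with_data(self, data: np.ndarray) -> "LfpRecording":
        """Copy of this recording with the samples replaced."""
        return replace(self, data=np.asarray(data, dtype=float))

    def stim_state_at(self, sample: int) -> str:
        """Stimulation state ("on"/"off") at a sample index."""
        if self.stim_state != "mixed":
            return self.stim_state
        t = sample / self.fs
        for seg in self.stim_segments:
            if seg.contains(t):
                return "on"
        return "off"
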