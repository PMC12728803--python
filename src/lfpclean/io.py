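"""On-disk recording format and best-effort device-export ingestion.

The canonical format is desk-scale and human-inspectable: a CSV data file
(``time_s`` column plus one column per channel, in microvolts) with a JSON
sidecar carrying the sampling rate, channel labels and stimulation-state
annotation.  PSDs and spectrograms are written as CSV with a JSON params
block.  Percept-style session JSON exports are ingested best-effort
against community-documented key names; arrays that cannot be parsed are
skipped with a logged reason, and the stimulation state is never
fabricated (it is marked ``"mixed"`` when absent).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import RecordingFormatError
from .recording import LfpRecording, StimSegment
from .spectral import Psd, SpectralParams

log = logging.getLogger(__name__)

__all__ = [
    "write_recording",
    "read_recording",
    "write_psd",
    "read_percept_json",
]


def _sidecar_path(data_path: Path) -> Path:
    return data_path.with_suffix(".json")


def write_recording(rec: LfpRecording, data_path, provenance: str = "") -> Path:
    """Write the CSV data file and its JSON sidecar; returns the sidecar path."""
    data_path = Path(data_path)
    df = pd.DataFrame({"time_s": rec.times})
    for label, row in zip(rec.channel_labels, rec.data):
        df[label] = row
    df.to_csv(data_path, index=False, float_format="%.12g")
    sidecar = {
        "sampling_rate_hz": rec.fs,
        "channel_labels": list(rec.channel_labels),
        "stim_state": rec.stim_state,
        "stim_segments": [
            {"start_s": s.start_s, "end_s": s.end_s, "amplitude_ma": s.amplitude_ma}
            for s in rec.stim_segments
        ],
        "duration_s": rec.duration,
        "provenance": provenance,
    }
    path = _sidecar_path(data_path)
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(data_path) -> LfpRecording:
    """Read a CSV + JSON-sidecar recording, validating the format contract.

    Checks: the sidecar exists; the file is non-empty; ``time_s`` advances
    with a constant step of ``1/sampling_rate`` (to 1e-9 s); the row count
    matches ``sampling_rate x duration`` within one sample.
    """
    data_path = Path(data_path)
    sidecar_path = _sidecar_path(data_path)
    if not sidecar_path.exists():
        raise RecordingFormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    fs = float(meta["sampling_rate_hz"])
    try:
        df = pd.read_csv(data_path)
    except pd.errors.EmptyDataError as err:
        raise RecordingFormatError(f"empty recording file {data_path}") from err
    if df.empty or "time_s" not in df.columns:
        raise RecordingFormatError(f"no samples / no time_s column in {data_path}")
    t = df["time_s"].to_numpy()
    if len(t) > 1:
        steps = np.diff(t)
        if np.max(np.abs(steps - 1.0 / fs)) > 1e-9:
            raise RecordingFormatError(
                f"time_s step deviates from 1/{fs} s by more than 1e-9"
            )
    if "duration_s" in meta and meta["duration_s"] is not None:
        expected = float(meta["duration_s"]) * fs
        if abs(len(df) - expected) > 1:
            raise RecordingFormatError(
                f"row count {len(df)} inconsistent with sampling_rate x duration "
                f"= {expected:g} (tolerance 1)"
            )
    labels = meta.get("channel_labels") or [c for c in df.columns if c != "time_s"]
    missing = [c for c in labels if c not in df.columns]
    if missing:
        raise RecordingFormatError(f"sidecar channels missing from CSV: {missing}")
    data = df[labels].to_numpy().T
    segments = [StimSegment(s["start_s"], s["end_s"], s.get("amplitude_ma", 0.0))
                for s in meta.get("stim_segments", [])]
    return LfpRecording(data, fs, tuple(labels),
                        stim_state=meta.get("stim_state", "off"),
                        stim_segments=segments)


def write_psd(psd: Psd, csv_path, params_path=None) -> Path:
    """Write a PSD as CSV (frequency, power, power_db) plus a JSON params block."""
    csv_path = Path(csv_path)
    pd.DataFrame({
        "frequency_hz": psd.frequencies,
        "power": psd.power,
        "power_db": psd.power_db,
    }).to_csv(csv_path, index=False, float_format="%.9g")
    p = psd.params
    block = {
        "fs": p.fs, "window_length": p.window_length, "nfft": p.nfft,
        "overlap": p.overlap, "method": p.method,
        "half_bandwidth": p.half_bandwidth,
        "n_tapers": p.n_tapers if p.method == "multitaper" else None,
    }
    params_path = Path(params_path) if params_path else csv_path.with_suffix(".json")
    params_path.write_text(json.dumps(block, indent=1))
    return csv_path


# ---------------------------------------------------------------------------
# Percept-style session JSON (best effort)
# ---------------------------------------------------------------------------

_TIME_DOMAIN_SECTIONS = ("BrainSenseTimeDomain", "IndefiniteStreaming",
                         "SenseChannelTests", "CalibrationTests")


def _parse_time_domain_entry(entry: dict):
    data = entry.get("TimeDomainData")
    fs = entry.get("SampleRateInHz") or entry.get("SampleRate")
    if data is None or fs is None:
        return None
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        return None
    label = str(entry.get("Channel", "ch0"))
    stamp = entry.get("FirstPacketDateTime", "")
    return arr, float(fs), label, stamp


def read_percept_json(path) -> list:
    """Best-effort extraction of time-domain arrays from a session export.

    Looks for known time-domain sections; entries sharing a packet
    timestamp and sampling rate are merged into one multi-channel
    recording.  Unparseable entries are skipped with a logged reason.
    Returns an empty list (with a warning) when no time-domain content is
    found.  Malformed JSON raises a :class:`RecordingFormatError` naming
    the byte offset.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as err:
        raise RecordingFormatError(
            f"malformed JSON in {path} at byte offset {err.pos}: {err.msg}"
        ) from err
    groups = {}
    order = []
    for section in _TIME_DOMAIN_SECTIONS:
        entries = doc.get(section)
        if not isinstance(entries, list):
            continue
        for i, entry in enumerate(entries):
            if not isinstance(entry, dict):
                log.warning("skipping %s[%d]: not an object", section, i)
                continue
            parsed = _parse_time_domain_entry(entry)
            if parsed is None:
                log.warning("skipping %s[%d]: no time-domain data or rate",
                            section, i)
                continue
            arr, fs, label, stamp = parsed
            key = (section, stamp, fs, len(arr))
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append((label, arr))
    recordings = []
    for key in order:
        section, stamp, fs, _ = key
        labels, arrays = zip(*groups[key])
        recordings.append(LfpRecording(np.stack(arrays), fs, tuple(labels),
                                       stim_state="mixed"))
    if not recordings:
        log.warning("no time-domain content found in %s", path)
    return recordings
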