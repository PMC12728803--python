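"""End-to-end preprocessing pipeline with a serializable configuration.

Stage order is fixed by the physics of the problem and is not
reorderable (stages can only be skipped): transient, predictable
interference is removed first in the time domain (ECG template
subtraction), because a transient's spectral footprint is broadband; the
signal is then transformed with a short-time multitaper spectrogram;
nonstationary windows are rejected and survivors averaged into a
background PSD; finally the aperiodic 1/f component is fit and removed
from that background.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import ecg, rejection
from .aperiodic import AperiodicModel
from .exceptions import LfpCleanError
from .io import write_psd, write_recording
from .recording import LfpRecording
from .spectral import SpectralParams, estimate_psd, short_time_spectrogram

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class EcgConfig:
    enabled: bool = True
    max_heart_rate: float = 120.0
    prominence_mult: float = 2.5
    pre: int = 36
    post: int = 36
    allow_inversion: bool = True
    per_state: bool = True


@dataclass
class SpectralConfig:
    window_sec: float = 2.0
    overlap: float = 0.5
    half_bandwidth: float = 1.0
    method: str = "multitaper"
    nfft: int = None


@dataclass
class RejectionConfig:
    enabled: bool = True
    alpha: float = 0.05
    band_corr: tuple = rejection.BROADBAND
    band_power: tuple = rejection.LOWFREQ_BAND
    use_correlation: bool = True
    use_lowfreq: bool = True
    method: str = "threshold"  # "threshold" | "pca"


@dataclass
class DetrendConfig:
    enabled: bool = True
    band: tuple = (4.0, 75.0)
    high_band: tuple = (55.0, 75.0)
    min_prominence: float = 0.05
    two_pass: bool = True


@dataclass
class PipelineConfig:
    """All stage parameters plus enable flags and a global seed."""

    seed: int = 0
    ecg: EcgConfig = field(default_factory=EcgConfig)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    rejection: RejectionConfig = field(default_factory=RejectionConfig)
    detrend: DetrendConfig = field(default_factory=DetrendConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        def build(klass, sub):
            fields = {f.name for f in dataclasses.fields(klass)}
            kwargs = {k: v for k, v in sub.items() if k in fields}
            for k, v in kwargs.items():
                if isinstance(v, list):
                    kwargs[k] = tuple(v)
            return klass(**kwargs)

        return cls(
            seed=d.get("seed", 0),
            ecg=build(EcgConfig, d.get("ecg", {})),
            spectral=build(SpectralConfig, d.get("spectral", {})),
            rejection=build(RejectionConfig, d.get("rejection", {})),
            detrend=build(DetrendConfig, d.get("detrend", {})),
        )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    def spectral_params(self, fs: float) -> SpectralParams:
        sc = self.spectral
        kw = dict(overlap=sc.overlap, method=sc.method, nfft=sc.nfft)
        if sc.method == "multitaper":
            kw["half_bandwidth"] = sc.half_bandwidth
        return SpectralParams.from_duration(fs, sc.window_sec, **kw)


@dataclass
class PipelineResult:
    """Per-channel outputs of one pipeline run."""

    config: PipelineConfig
    cleaned: LfpRecording
    ecg_report: dict
    spectrograms: dict  # label -> Spectrogram
    backgrounds: dict  # label -> BackgroundPsd
    aperiodic: dict  # label -> AperiodicResult or None
    run_log: list  # JSON-serializable stage records


def _stage_record(name: str, **info) -> dict:
    return {"stage": name, "time": time.time(), **info}


def run_pipeline(config: PipelineConfig, rec: LfpRecording,
                 outdir=None) -> PipelineResult:
    """Run all enabled stages in their fixed order on one recording.

    When ``outdir`` is given, each stage's outputs are written there
    (cleaned recording CSV, per-channel background PSD and detrended
    residual CSVs, fit-parameter JSON, and a JSON-lines run log); every
    file name carries the configuration hash.
    """
    run_log = []
    chash = config.config_hash
    run_log.append(_stage_record("start", config_hash=chash, seed=config.seed,
                                 n_channels=rec.n_channels,
                                 n_samples=rec.n_samples, fs=rec.fs))

    # 1. time-domain ECG removal
    ecg_report = {}
    cleaned = rec
    if config.ecg.enabled:
        e = config.ecg
        try:
            if rec.n_channels == 2:
                left = LfpRecording(rec.data[1], rec.fs,
                                    (rec.channel_labels[1],),
                                    rec.stim_state, rec.stim_segments)
                right = LfpRecording(rec.data[0], rec.fs,
                                     (rec.channel_labels[0],),
                                     rec.stim_state, rec.stim_segments)
                lc, rc, ecg_report = ecg.remove_ecg_bilateral(
                    left, right, e.max_heart_rate, e.prominence_mult,
                    e.pre, e.post, e.allow_inversion, e.per_state)
                cleaned = rec.with_data(np.vstack([rc.data, lc.data]))
            else:
                cleaned, ecg_report = ecg.remove_ecg(
                    rec, 0, e.max_heart_rate, e.prominence_mult,
                    e.pre, e.post, e.allow_inversion)
        except LfpCleanError as err:
            raise LfpCleanError(f"stage ecg_removal failed: {err}") from err
        run_log.append(_stage_record("ecg_removal", report=ecg_report))

    params = config.spectral_params(rec.fs)

    # 2-4. per-channel: spectrogram -> window rejection -> aperiodic detrend
    spectrograms, backgrounds, fits = {}, {}, {}
    for ci, label in enumerate(cleaned.channel_labels):
        try:
            sg = short_time_spectrogram(cleaned, params, channel=ci)
        except LfpCleanError as err:
            raise LfpCleanError(f"stage spectrogram failed on {label}: {err}") from err
        spectrograms[label] = sg
        run_log.append(_stage_record("spectrogram", channel=label,
                                     n_windows=sg.n_windows))

        rj = config.rejection
        try:
            if not rj.enabled:
                bg = rejection.BackgroundPsd(
                    estimate_psd(cleaned, params, channel=ci),
                    np.arange(sg.n_windows), "mean_of_kept")
            elif rj.method == "pca":
                bg = rejection.pca_background(sg, rj.band_corr)
            else:
                bg = rejection.background_psd(
                    sg, rj.use_correlation, rj.use_lowfreq, rj.alpha,
                    rj.band_corr, rj.band_power)
        except LfpCleanError as err:
            raise LfpCleanError(f"stage window_rejection failed on {label}: {err}") from err
        backgrounds[label] = bg
        run_log.append(_stage_record(
            "window_rejection", channel=label, method=bg.method,
            n_kept=len(bg.kept_windows),
            n_rejected=sg.n_windows - len(bg.kept_windows)))

        dt = config.detrend
        if dt.enabled:
            try:
                res = AperiodicModel(bg.psd, dt.band, dt.high_band,
                                     dt.min_prominence).fit(two_pass=dt.two_pass)
            except LfpCleanError as err:
                raise LfpCleanError(f"stage detrend failed on {label}: {err}") from err
            fits[label] = res
            run_log.append(_stage_record("aperiodic_detrend", channel=label,
                                         params=res.params,
                                         n_minima=len(res.minima)))
        else:
            fits[label] = None

    result = PipelineResult(config, cleaned, ecg_report, spectrograms,
                            backgrounds, fits, run_log)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    h = result.config.config_hash
    result.config.to_json(outdir / f"config_{h}.json")
    write_recording(result.cleaned, outdir / f"cleaned_{h}.csv",
                    provenance=f"lfpclean pipeline config {h}")
    summary = {"config_hash": h, "channels": {}}
    for label, bg in result.backgrounds.items():
        write_psd(bg.psd, outdir / f"background_{label}_{h}.csv")
        entry = {"background_method": bg.method,
                 "kept_windows": [int(i) for i in bg.kept_windows]}
        res = result.aperiodic.get(label)
        if res is not None:
            entry["aperiodic"] = res.params
            ds = res.detrended()
            import pandas as pd

            pd.DataFrame({"frequency_hz": ds.frequencies,
                          "residual_log10": ds.residual}).to_csv(
                outdir / f"detrended_{label}_{h}.csv", index=False,
                float_format="%.9g")
        summary["channels"][label] = entry
    (outdir / f"summary_{h}.json").write_text(json.dumps(summary, indent=1))
    with open(outdir / f"runlog_{h}.jsonl", "w") as fh:
        for recd in result.run_log:
            fh.write(json.dumps(recd) + "\n")
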