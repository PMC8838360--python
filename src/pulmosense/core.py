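"""Core data model: uniformly sampled time series, recording sessions, and
the analysis configuration.

A *session* is one wearable measurement: up to four lung-sound audio channels,
multi-frequency impedance-pneumography (IP) resistance streams, a block of
bioimpedance-spectroscopy (BIS) sweeps, and optional IMU / skin-temperature
channels, tagged with a subject id and a visit tag (admission / mid /
discharge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Optional

import numpy as np
import yaml

#: Visit tags of the three-measurement hospitalization scheme.
SESSION_TAGS = ("admission", "mid", "discharge")

#: Per-frequency sample rate of the continuous IP mode (Hz).
CONTINUOUS_IP_RATE_HZ = 16.0

#: Sweep rate of the spectroscopy mode: one 32-frequency sweep every 2 s.
SPECTROSCOPY_SWEEP_RATE_HZ = 0.5

#: Excitation frequencies of the continuous multi-frequency IP mode (kHz).
IP_FREQUENCIES_KHZ = (5, 50, 100, 150)

#: Number of excitation frequencies in one BIS sweep.
BIS_N_FREQUENCIES = 32

#: Nominal hardware audio sampling rate (Hz); any PCM rate >= 4 kHz is accepted.
AUDIO_HW_RATE_HZ = 46875.0


class SessionFormatError(ValueError):
    """Raised when an on-disk session file does not follow the documented layout."""


@dataclass
class TimeSeries:
    """A uniformly sampled channel.

    Sample ``i`` occurs at ``start_time + i / rate`` seconds from the start of
    the session.

    Parameters
    ----------
    values : array-like of float
        Finite sample values.
    rate : float
        Sampling rate in Hz, strictly positive.
    start_time : float, optional
        Offset of the first sample within the session, seconds.
    units : str, optional
        Physical units of the values (e.g. ``"ohm"``, ``"a.u."``, ``"degC"``).
    label : str, optional
        Free-text channel label.
    """

    values: np.ndarray
    rate: float
    start_time: float = 0.0
    units: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.rate > 0):
            raise ValueError("TimeSeries rate must be > 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Span of the series in seconds (``n / rate``)."""
        return len(self.values) / self.rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    def times(self) -> np.ndarray:
        """Sample times in seconds from session start."""
        return self.start_time + np.arange(len(self.values)) / self.rate

    def slice(self, t0: float, t1: float) -> "TimeSeries":
        """Return the sub-series covering ``[t0, t1)`` (session-clock seconds)."""
        i0 = max(0, int(np.ceil((t0 - self.start_time) * self.rate - 1e-9)))
        i1 = min(len(self.values), int(np.ceil((t1 - self.start_time) * self.rate - 1e-9)))
        i1 = max(i0, i1)
        return TimeSeries(
            self.values[i0:i1],
            self.rate,
            start_time=self.start_time + i0 / self.rate,
            units=self.units,
            label=self.label,
        )

    def value_at(self, t: float) -> float:
        """Value of the sample nearest to time ``t``."""
        i = int(round((t - self.start_time) * self.rate))
        i = min(max(i, 0), len(self.values) - 1)
        return float(self.values[i])


@dataclass
class Session:
    """One multimodal measurement session.

    ``ip_channels`` maps excitation frequency in kHz to the resistance stream;
    ``ip_reactance`` optionally carries the matching reactance streams.
    ``audio_channels`` maps channel id (1..4) to mono audio. At least one of
    the IP / audio / BIS blocks must be non-empty.
    """

    subject: str = ""
    tag: str = "admission"
    posture: str = ""
    ip_channels: dict = field(default_factory=dict)
    ip_reactance: dict = field(default_factory=dict)
    audio_channels: dict = field(default_factory=dict)
    bis_sweeps: list = field(default_factory=list)
    imu: dict = field(default_factory=dict)
    temperature: Optional[TimeSeries] = None

    def __post_init__(self) -> None:
        if self.tag not in SESSION_TAGS:
            raise ValueError(f"session tag must be one of {SESSION_TAGS}, got {self.tag!r}")

    def validate(self) -> None:
        if not (self.ip_channels or self.audio_channels or self.bis_sweeps):
            raise ValueError("session must contain at least one of IP, audio, or BIS data")


@dataclass
class AnalysisConfig:
    """Every tunable of the analysis pipeline, with its default value.

    Defaults reproduce the processing constants of the clinical protocol this
    package models: a 0.1–0.8 Hz respiratory pass-band (6–48 breaths/min) on
    IP resampled to 100 Hz, 26 s quality windows with 80 % overlap, a 0.7
    template-correlation and 0.5 duration-CoV signal-quality gate, 4–60 bpm
    plausibility bounds, ±4 MAD outlier rejection, audio resampled to 6 kHz
    and band-passed 100–1000 Hz, 300 ms / 95 % overlap STFT, BIS probe
    frequencies 5 and 150 kHz, and a 0.05 significance level.
    """

    # --- impedance pneumography ---
    ip_channel_khz: int = 100
    ip_band_hz: tuple = (0.1, 0.8)
    ip_target_rate_hz: float = 100.0
    ip_transition_hz: float = 0.06
    ip_atten_db: float = 30.0          # single pass; doubled by forward-backward use
    window_len_s: float = 26.0
    window_overlap: float = 0.8
    template_corr_threshold: float = 0.7
    duration_cov_threshold: float = 0.5
    rr_min_bpm: float = 4.0
    rr_max_bpm: float = 60.0
    mad_multiplier: float = 4.0
    onset_fusion_tol_s: float = 0.25
    min_trough_separation_s: float = 1.0
    onset_rise_iqr_factor: float = 0.2
    # absolute rise floor as a fraction of the whole-series IQR: rejects
    # band-pass leakage ripples (~3 % of neighbouring breath amplitude) in
    # near-silent stretches such as apneas, where the per-window IQR floor
    # collapses with the window content
    onset_rise_global_iqr_factor: float = 0.3
    # --- lung sounds ---
    audio_target_rate_hz: float = 6000.0
    audio_band_hz: tuple = (100.0, 1000.0)
    audio_transition_hz: float = 50.0
    audio_atten_db: float = 45.0       # single pass
    stft_window_s: float = 0.3
    stft_overlap: float = 0.95
    spectral_band_hz: tuple = (100.0, 1000.0)
    # --- bioimpedance spectroscopy ---
    bis_probe_freqs_hz: tuple = (5000.0, 150000.0)
    # --- statistics ---
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            self.ip_target_rate_hz, self.ip_transition_hz, self.ip_atten_db,
            self.window_len_s, self.template_corr_threshold,
            self.duration_cov_threshold, self.rr_min_bpm, self.rr_max_bpm,
            self.mad_multiplier, self.onset_fusion_tol_s,
            self.min_trough_separation_s, self.onset_rise_iqr_factor,
            self.audio_target_rate_hz, self.audio_transition_hz,
            self.audio_atten_db, self.stft_window_s, self.alpha,
        ]
        if not all(v > 0 for v in positive):
            raise ValueError("all thresholds must be positive")
        for lo, hi in (self.ip_band_hz, self.audio_band_hz,
                       self.spectral_band_hz, self.bis_probe_freqs_hz):
            if not (0 < lo < hi):
                raise ValueError(f"band edges must be ordered and positive: ({lo}, {hi})")
        for ov in (self.window_overlap, self.stft_overlap):
            if not (0 <= ov < 1):
                raise ValueError("overlap must lie in [0, 1)")
        if not self.rr_min_bpm < self.rr_max_bpm:
            raise ValueError("rr bounds must be ordered")

    def as_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for f in fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


def band_to_bpm(band_hz: tuple) -> tuple:
    """Convert a respiratory frequency band in Hz to breaths per minute.

    The default 0.1–0.8 Hz IP pass-band corresponds to 6–48 bpm.
    """
    lo, hi = band_hz
    return (lo * 60.0, hi * 60.0)
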