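"""Lung-sound processing: resampling, band-pass, spectrogram, mean spectrum,
spectral features, and breath-phase segmentation.

Audio is resampled to 6 kHz and band-passed 100–1000 Hz with a zero-phase
minimum-order Kaiser FIR — the lower edge suppresses heart-sound
interference, the upper edge room noise (alarms, speech) that dominates
above ~1.8 kHz. Spectrograms use a 300 ms window with 95 % overlap; the mean
spectrum is the Welch average of the same frames. Spectral features over an
analysis band are the spectral peak Fmax and the frequencies F50 / F95 below
which 50 % / 95 % of the band power lies. The concurrent IP breath table
splits the audio into inspiratory / expiratory phase segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._filters import design_bandpass, rational_resample, zero_phase_filter
from .core import AnalysisConfig, TimeSeries
from .resp import Breath


@dataclass
class Spectrogram:
    times: np.ndarray           # frame centres, s (session clock)
    freqs: np.ndarray           # Hz
    power: np.ndarray           # (freq, time), linear PSD units
    window_s: float
    overlap: float


@dataclass
class Spectrum:
    freqs: np.ndarray
    power: np.ndarray


@dataclass
class SpectralFeatures:
    """Fmax / F50 / F95 of a spectrum restricted to ``band``."""

    fmax: float
    f50: float
    f95: float
    band: tuple

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (lo <= self.fmax <= hi and lo <= self.f50 <= self.f95 <= hi):
            raise ValueError("spectral features must lie inside the band, ordered")


def preprocess_audio(series: TimeSeries,
                     config: Optional[AnalysisConfig] = None) -> TimeSeries:
    """Resample to the 6 kHz analysis rate and band-pass 100–1000 Hz.

    Input rates below the target are kept as-is (only the band-pass is
    applied); rates below 4 kHz are rejected since they cannot carry the
    full analysis band comfortably.
    """
    config = config or AnalysisConfig()
    if series.rate < 4000:
        raise ValueError("audio rate must be >= 4 kHz")
    target = min(config.audio_target_rate_hz, series.rate)
    rs = rational_resample(series, target)
    lo, hi = config.audio_band_hz
    taps = design_bandpass(rs.rate, lo, hi, config.audio_transition_hz,
                           config.audio_atten_db)
    if len(rs) <= len(taps):
        raise ValueError(
            f"audio too short for band-pass warm-up: need > "
            f"{len(taps) / rs.rate:.2f} s"
        )
    y = zero_phase_filter(rs.values, taps)
    return TimeSeries(y, rate=rs.rate, start_time=rs.start_time,
                      units=series.units, label=f"{series.label} (filtered)")


def compute_spectrogram(series: TimeSeries, window_s: float = 0.3,
                        overlap: float = 0.95,
                        window: str = "hann") -> Spectrogram:
    """STFT power spectrogram.

    Hop is ``(1 - overlap) * window_s`` (15 ms by default) and the frame
    count is ``floor((L - W)/H) + 1`` — no boundary padding, so every frame
    covers real signal. Power is one-sided PSD (units²/Hz); with a boxcar
    window the per-frame Parseval identity ``sum(P)·df = mean(x²)`` holds
    exactly.
    """
    nperseg = int(round(window_s * series.rate))
    if len(series) < nperseg:
        raise ValueError("series shorter than one STFT window")
    noverlap = int(round(overlap * nperseg))
    f, t, p = sps.spectrogram(series.values, fs=series.rate, window=window,
                              nperseg=nperseg, noverlap=noverlap,
                              detrend=False, scaling="density", mode="psd")
    return Spectrogram(times=series.start_time + t, freqs=f, power=p,
                       window_s=window_s, overlap=overlap)


def compute_mean_spectrum(series: TimeSeries, window_s: float = 0.3,
                          overlap: float = 0.95,
                          window: str = "hann") -> Spectrum:
    """Welch mean spectrum using the same framing as the spectrogram."""
    nperseg = int(round(window_s * series.rate))
    if series.duration < 2.0:
        raise ValueError("need at least 2 s of audio for a mean spectrum")
    noverlap = int(round(overlap * nperseg))
    f, p = sps.welch(series.values, fs=series.rate, window=window,
                     nperseg=nperseg, noverlap=noverlap, detrend=False,
                     scaling="density")
    return Spectrum(freqs=f, power=p)


def extract_spectral_features(spectrum: Spectrum,
                              band: tuple = (100.0, 1000.0)) -> SpectralFeatures:
    """Fmax, F50, F95 of ``spectrum`` restricted to ``band``.

    Fmax is the frequency of the band maximum; F50 / F95 are the smallest
    grid frequencies at which the cumulative band power reaches 50 % / 95 %
    of the total. Scale-invariant in the spectrum amplitude.
    """
    lo, hi = band
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    f = spectrum.freqs[mask]
    p = spectrum.power[mask]
    if len(f) == 0 or p.sum() <= 0:
        raise ValueError("zero spectral power inside the requested band")
    fmax = float(f[np.argmax(p)])
    cum = np.cumsum(p) / p.sum()
    f50 = float(f[np.searchsorted(cum, 0.5 - 1e-12)])
    f95 = float(f[np.searchsorted(cum, 0.95 - 1e-12)])
    return SpectralFeatures(fmax=fmax, f50=f50, f95=f95, band=(lo, hi))


def segment_audio_by_breath(audio: TimeSeries,
                            breaths: Sequence[Breath]) -> pd.DataFrame:
    """Split audio into breath-phase segments using the IP breath table.

    Each accepted breath contributes an inspiration segment ``[onset, peak)``
    and an expiration segment ``[peak, end)``; audio outside any breath is
    returned as ``unscored`` segments. One row per segment with its RMS.
    """
    rows = []

    def _add(t0: float, t1: float, phase: str, breath_id) -> None:
        t0 = max(t0, audio.start_time)
        t1 = min(t1, audio.end_time)
        if t1 - t0 <= 0:
            return
        seg = audio.slice(t0, t1)
        rms = float(np.sqrt(np.mean(seg.values ** 2))) if len(seg) else 0.0
        rows.append({"start": t0, "end": t1, "phase": phase,
                     "breath_id": breath_id, "rms": rms})

    cursor = audio.start_time
    for i, b in enumerate(sorted(breaths, key=lambda b: b.onset)):
        if b.onset > cursor:
            _add(cursor, b.onset, "unscored", None)
        _add(b.onset, b.peak, "inspiration", i)
        _add(b.peak, b.end, "expiration", i)
        cursor = max(cursor, b.end)
    if cursor < audio.end_time:
        _add(cursor, audio.end_time, "unscored", None)
    return pd.DataFrame(rows, columns=["start", "end", "phase", "breath_id", "rms"])
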