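"""Synthetic multimodal session generator with exact ground truth.

Every analysis stage in this package can be exercised against signals whose
truth is known by construction:

* quasi-periodic impedance-pneumography breath trains (asymmetric
  raised-cosine pulses, controllable rate, Ti:Te asymmetry, amplitude,
  baseline drift and noise),
* Cheyne–Stokes respiration: a periodic waxing–waning envelope bounded by
  apneic periods,
* Cole-model bioimpedance sweeps with additive measurement noise,
* lung audio whose band-limited noise intensity is gated by the respiratory
  phase, with optional crackle transients and low-frequency heart sounds,
* targeted corruption of signal segments for signal-quality tests.

All generators are pure functions of (parameters, seed). Default parameter
values place the signals in the hospitalized heart-failure regime the
analysis targets: mean respiratory rate ≈ 23 breaths/min, Te:Ti ≈ 1.1, a
16 Hz raw IP rate, ~30 BIS sweeps per session with ≈ 0.5 Ω sweep noise, and
fluid ratios K ≈ 1.27 (admission) rising to ≈ 1.32 (discharge).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._filters import design_bandpass, zero_phase_filter
from .core import (CONTINUOUS_IP_RATE_HZ, IP_FREQUENCIES_KHZ, Session,
                   TimeSeries)
from .fluid import BISweep, make_freq_grid

# ---------------------------------------------------------------------------
# parameter and truth containers
# ---------------------------------------------------------------------------


@dataclass
class BreathTrainParams:
    """Parameters of a synthetic IP breath train."""

    duration_s: float = 300.0
    rr_mean_bpm: float = 23.12
    rr_jitter_cv: float = 0.08
    ti_te_ratio: float = 0.91       # Ti : Te; ~1/1.10, inspiration slightly shorter
    amplitude_ohm: float = 1.0
    amplitude_cv: float = 0.10
    baseline_drift_amp_ohm: float = 2.0
    drift_freq_hz: float = 0.02     # slow sinusoid, well below the 0.1 Hz high-pass
    noise_sd_ohm: float = 0.05
    sample_rate_hz: float = CONTINUOUS_IP_RATE_HZ
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.rr_mean_bpm < 120):
            raise ValueError("rr_mean_bpm must lie in (0, 120)")
        if self.ti_te_ratio <= 0:
            raise ValueError("ti_te_ratio must be > 0")
        if self.sample_rate_hz <= 2 * self.rr_mean_bpm / 60.0:
            raise ValueError("sample rate must exceed twice the breathing frequency")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass
class CSRParams:
    """Cheyne–Stokes cycle: raised-cosine hyperpnea–hypopnea envelope
    bounded by apneic periods covering ``apnea_fraction`` of each cycle."""

    cycle_length_s: float = 60.0
    apnea_fraction: float = 0.25
    n_cycles: int = 4

    def validate(self) -> None:
        if not (0 < self.apnea_fraction < 1):
            raise ValueError("apnea_fraction must lie in (0, 1)")
        if self.cycle_length_s <= 0 or self.n_cycles < 1:
            raise ValueError("cycle_length and n_cycles must be positive")


@dataclass
class ColeParams:
    """Single-dispersion Cole tissue-impedance model
    ``Z(f) = Rinf + (R0 - Rinf) / (1 + (j 2 pi f tau_c)^alpha)``."""

    r0: float = 42.0
    rinf: float = 25.0
    tau_c: float = 2e-6
    alpha: float = 0.7

    def validate(self) -> None:
        if not (self.r0 > self.rinf > 0):
            raise ValueError("need R0 > Rinf > 0")
        if self.tau_c <= 0:
            raise ValueError("tau_c must be > 0")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class BreathTruth:
    """Ground-truth breath emitted by the generator."""

    onset: float
    peak: float
    end: float
    amplitude: float
    in_apnea: bool = False

    def __post_init__(self) -> None:
        if not (self.onset < self.peak < self.end):
            raise ValueError("truth requires onset < peak < end")


@dataclass
class AcousticEventTruth:
    kind: str                   # "crackle" | "heart_sound" | "phase_noise"
    time: float
    channel: int
    center_freq_hz: float


@dataclass
class LungAudioParams:
    """Parameters of the phase-gated lung-audio generator.

    Breath noise is band-limited to ``band`` and its envelope follows the
    breath phase (inspiration louder than expiration, near-silent between
    breaths). Crackles default to a 750 Hz centre, inside the fine-crackle
    band (> 650 Hz); heart sounds are ~40 Hz thumps at ~1 Hz repetition,
    i.e. below the analysis band so the 100 Hz high-pass suppresses them.
    """

    sample_rate_hz: float = 8000.0
    band_hz: tuple = (100.0, 1000.0)
    insp_gain: float = 1.0
    exp_gain: float = 0.45
    base_gain: float = 0.02
    track_breath_amplitude: bool = True
    n_crackles: int = 0
    crackle_freq_hz: float = 750.0
    crackle_amp: float = 3.0
    heart_sounds: bool = True
    heart_rate_hz: float = 1.1
    heart_freq_hz: float = 40.0
    heart_amp: float = 0.25
    tail_s: float = 2.0

    def validate(self) -> None:
        if self.sample_rate_hz < 4000:
            raise ValueError("audio sample rate must be >= 4 kHz")
        lo, hi = self.band_hz
        if not 0 < lo < hi < self.sample_rate_hz / 2:
            raise ValueError("band must fit below Nyquist")


# ---------------------------------------------------------------------------
# breath trains
# ---------------------------------------------------------------------------

def _draw_breath_truths(params: BreathTrainParams,
                        rng: np.random.Generator) -> list:
    """Draw contiguous breath timings/amplitudes covering the train."""
    mean_ibi = 60.0 / params.rr_mean_bpm
    r = params.ti_te_ratio
    lead = min(1.0, 0.1 * params.duration_s)
    if params.duration_s < lead + mean_ibi:
        raise ValueError(
            f"duration {params.duration_s:g} s too short for one breath "
            f"(mean IBI {mean_ibi:.2f} s)"
        )
    truths, t = [], lead
    while True:
        ibi = mean_ibi * (1.0 + params.rr_jitter_cv * rng.standard_normal())
        ibi = max(ibi, 0.4 * mean_ibi)
        if t + ibi > params.duration_s - 0.2:
            break
        amp = params.amplitude_ohm * (1.0 + params.amplitude_cv * rng.standard_normal())
        amp = max(amp, 0.1 * params.amplitude_ohm)
        ti = ibi * r / (1.0 + r)
        truths.append(BreathTruth(onset=t, peak=t + ti, end=t + ibi, amplitude=amp))
        t += ibi
    if not truths:
        raise ValueError("duration too short for one breath")
    return truths


def render_breath_pulses(truths: Sequence[BreathTruth], duration_s: float,
                         sample_rate_hz: float) -> np.ndarray:
    """Noise-free pulse waveform for a truth list.

    Each breath is an asymmetric raised cosine: a rising half-cosine of
    duration Ti (onset to peak) followed by a falling half-cosine of
    duration Te (peak to end).
    """
    n = int(round(duration_s * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    x = np.zeros(n)
    for b in truths:
        ti, te = b.peak - b.onset, b.end - b.peak
        m = (t >= b.onset) & (t < b.end)
        tt = t[m] - b.onset
        rise = tt < ti
        seg = np.empty(tt.shape)
        seg[rise] = 0.5 * b.amplitude * (1.0 - np.cos(np.pi * tt[rise] / ti))
        seg[~rise] = 0.5 * b.amplitude * (1.0 + np.cos(np.pi * (tt[~rise] - ti) / te))
        x[m] += seg
    return x


def make_breath_train(params: Optional[BreathTrainParams] = None,
                      ) -> tuple:
    """Generate a synthetic IP breath train and its ground truth.

    Returns ``(TimeSeries, [BreathTruth, ...])``. The waveform is baseline
    drift + white Gaussian noise + breath pulses; the truth list matches the
    emitted pulses exactly and everything is reproducible from the seed.
    """
    params = params or BreathTrainParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    truths = _draw_breath_truths(params, rng)
    series = _render_train(truths, params, rng)
    return series, truths


def _render_train(truths: Sequence[BreathTruth], params: BreathTrainParams,
                  rng: np.random.Generator, offset_ohm: float = 0.0) -> TimeSeries:
    n = int(round(params.duration_s * params.sample_rate_hz))
    t = np.arange(n) / params.sample_rate_hz
    phase = rng.uniform(0, 2 * np.pi)
    drift = params.baseline_drift_amp_ohm * np.sin(
        2 * np.pi * params.drift_freq_hz * t + phase)
    noise = params.noise_sd_ohm * rng.standard_normal(n)
    pulses = render_breath_pulses(truths, params.duration_s, params.sample_rate_hz)
    return TimeSeries(offset_ohm + drift + noise + pulses,
                      rate=params.sample_rate_hz, units="ohm",
                      label=f"IP synthetic ({params.rr_mean_bpm:g} bpm)")


# ---------------------------------------------------------------------------
# Cheyne-Stokes envelope
# ---------------------------------------------------------------------------

def csr_envelope(t: np.ndarray, csr: CSRParams) -> np.ndarray:
    """Periodic hyperpnea–hypopnea envelope in [0, 1].

    Each cycle starts and ends with half an apneic period (envelope exactly
    zero); the breathing part in between is a raised cosine peaking
    mid-cycle. Apnea covers ``apnea_fraction`` of every cycle.
    """
    T = csr.cycle_length_s
    a = csr.apnea_fraction * T
    b = T - a
    phi = np.mod(t, T)
    env = np.zeros_like(t, dtype=float)
    breathing = (phi >= a / 2) & (phi <= T - a / 2)
    env[breathing] = 0.5 * (1.0 - np.cos(2 * np.pi * (phi[breathing] - a / 2) / b))
    return env


def apply_csr_envelope(series: TimeSeries, truths: Sequence[BreathTruth],
                       csr: Optional[CSRParams] = None) -> tuple:
    """Modulate a breath train with a Cheyne–Stokes envelope.

    The whole series is multiplied by the periodic envelope, so during
    apneic periods the signal magnitude falls to (at most) the modulated
    noise floor. Truth breaths whose span touches an apneic region
    (envelope < 1 % of maximum) are flagged ``in_apnea``; surviving
    amplitudes are rescaled by the envelope at the breath peak.
    """
    csr = csr or CSRParams()
    csr.validate()
    if truths:
        mean_dur = float(np.mean([b.end - b.onset for b in truths]))
        if csr.cycle_length_s < 2 * mean_dur:
            raise ValueError("CSR cycle must span at least two mean breath durations")
    t = series.times()
    env = csr_envelope(t - series.start_time, csr)
    out = TimeSeries(series.values * env, rate=series.rate,
                     start_time=series.start_time, units=series.units,
                     label=f"{series.label} (CSR)")
    new_truths = []
    for b in truths:
        probe = np.linspace(b.onset, b.end, 33) - series.start_time
        e = csr_envelope(probe, csr)
        peak_env = float(csr_envelope(np.array([b.peak - series.start_time]), csr)[0])
        new_truths.append(BreathTruth(
            onset=b.onset, peak=b.peak, end=b.end,
            amplitude=b.amplitude * peak_env,
            in_apnea=bool(e.min() < 0.01)))
    return out, new_truths


# ---------------------------------------------------------------------------
# Cole-model bioimpedance
# ---------------------------------------------------------------------------

def cole_impedance(params: ColeParams, frequency) -> np.ndarray:
    """Complex tissue impedance of the single-dispersion Cole model."""
    params.validate()
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be > 0")
    jwt = (1j * 2 * np.pi * f * params.tau_c) ** params.alpha
    z = params.rinf + (params.r0 - params.rinf) / (1.0 + jwt)
    return z if z.shape else complex(z)


def cole_params_for_k(k_target: float, rinf: float = 25.0, tau_c: float = 2e-6,
                      alpha: float = 0.7,
                      probe_freqs: tuple = (5000.0, 150000.0)) -> ColeParams:
    """Cole parameters whose noiseless K = R(5 kHz)/R(150 kHz) equals ``k_target``.

    Solves for the dispersion magnitude R0 − Rinf in closed form given the
    other parameters, keeping the curve in the thoracic tens-of-ohms regime.
    """
    if k_target <= 1.0:
        raise ValueError("k_target must exceed 1 for a dispersive tissue model")
    f_lo, f_hi = probe_freqs

    def a(f: float) -> float:
        return (1.0 / (1.0 + (1j * 2 * np.pi * f * tau_c) ** alpha)).real

    denom = a(f_lo) - k_target * a(f_hi)
    if denom <= 0:
        raise ValueError("k_target unreachable with these tau_c/alpha")
    delta = rinf * (k_target - 1.0) / denom
    return ColeParams(r0=rinf + delta, rinf=rinf, tau_c=tau_c, alpha=alpha)


def make_bis_sweeps(cole: Optional[ColeParams] = None,
                    freq_grid: Optional[np.ndarray] = None,
                    n_sweeps: int = 30, noise_sd: float = 0.5,
                    seed: int = 0, start_time: float = 0.0) -> list:
    """Simulate a session's BIS block: ``n_sweeps`` noisy Cole sweeps.

    Each sweep is the noiseless Cole curve over the grid plus independent
    zero-mean Gaussian noise of sd ``noise_sd`` on both R and X, one sweep
    every 2 s.
    """
    cole = cole or ColeParams()
    if n_sweeps < 1:
        raise ValueError("need at least one sweep")
    grid = make_freq_grid() if freq_grid is None else np.asarray(freq_grid, float)
    rng = np.random.default_rng(seed)
    clean = cole_impedance(cole, grid)
    sweeps = []
    for i in range(n_sweeps):
        nr = noise_sd * rng.standard_normal(len(grid))
        nx = noise_sd * rng.standard_normal(len(grid))
        sweeps.append(BISweep(freqs=grid, impedances=clean + nr + 1j * nx,
                              timestamp=start_time + 2.0 * i))
    return sweeps


# ---------------------------------------------------------------------------
# lung audio
# ---------------------------------------------------------------------------

def make_lung_audio(truths: Sequence[BreathTruth],
                    params: Optional[LungAudioParams] = None,
                    seed: int = 0, channel: int = 1) -> tuple:
    """Phase-gated synthetic lung audio with an exact acoustic event list.

    Band-limited Gaussian noise is amplitude-gated by the breath phase
    (inspiration gain > expiration gain >> inter-breath base gain, scaled by
    the breath amplitude so deeper breaths sound louder). Optional crackle
    transients (short damped oscillations placed inside inspiratory
    intervals of non-apneic breaths) and heart-sound thumps are added.
    Returns ``(TimeSeries, [AcousticEventTruth, ...])``.
    """
    params = params or LungAudioParams()
    params.validate()
    if not truths:
        raise ValueError("need a non-empty breath truth list")
    rng = np.random.default_rng(seed)
    fs = params.sample_rate_hz
    duration = max(b.end for b in truths) + params.tail_s
    n = int(round(duration * fs))

    # phase-gated gain envelope
    gain = np.full(n, params.base_gain)
    amax = max(b.amplitude for b in truths) or 1.0
    for b in truths:
        w = b.amplitude / amax if params.track_breath_amplitude else 1.0
        i0, i1 = int(b.onset * fs), int(b.peak * fs)
        i2 = int(b.end * fs)
        gain[i0:i1] = params.insp_gain * w
        gain[i1:i2] = params.exp_gain * w
    smooth = max(1, int(0.025 * fs))
    gain = np.convolve(gain, np.ones(smooth) / smooth, mode="same")

    lo, hi = params.band_hz
    taps = design_bandpass(fs, lo, hi, transition=50.0, atten_db=45.0)
    noise = zero_phase_filter(rng.standard_normal(n), taps)
    noise /= max(noise.std(), 1e-12)
    x = gain * noise
    events = []

    # crackles: short damped oscillations during inspiration
    candidates = [b for b in truths if not b.in_apnea]
    for _ in range(params.n_crackles):
        b = candidates[rng.integers(len(candidates))]
        ti = b.peak - b.onset
        t0 = b.onset + rng.uniform(0.15, 0.80) * ti
        dur = 0.008
        k = int(t0 * fs)
        tt = np.arange(int(dur * fs)) / fs
        burst = np.exp(-tt / 0.002) * np.sin(2 * np.pi * params.crackle_freq_hz * tt)
        amp = params.crackle_amp * max(gain[k], params.base_gain)
        x[k:k + len(burst)] += amp * burst[:max(0, n - k)]
        events.append(AcousticEventTruth("crackle", float(t0), channel,
                                         params.crackle_freq_hz))

    # heart sounds: low-frequency thumps at ~1 Hz repetition
    if params.heart_sounds:
        period = 1.0 / params.heart_rate_hz
        tt = np.arange(int(0.08 * fs)) / fs
        thump = (np.exp(-0.5 * ((tt - 0.04) / 0.012) ** 2)
                 * np.sin(2 * np.pi * params.heart_freq_hz * tt))
        t0 = rng.uniform(0, period)
        while t0 < duration - 0.1:
            k = int(t0 * fs)
            x[k:k + len(thump)] += params.heart_amp * thump[:max(0, n - k)]
            events.append(AcousticEventTruth("heart_sound", float(t0), channel,
                                             params.heart_freq_hz))
            t0 += period

    series = TimeSeries(x, rate=fs, units="a.u.", label=f"lung audio ch{channel}")
    return series, events


# ---------------------------------------------------------------------------
# corruption fixture
# ---------------------------------------------------------------------------

def corrupt_segment(series: TimeSeries, interval: tuple, mode: str,
                    seed: int = 0, scale: Optional[float] = None) -> TimeSeries:
    """Replace ``interval = (t0, t1)`` with a pathological segment.

    Modes: ``white-noise`` (Gaussian noise, sd = ``scale`` or 5x the series
    sd), ``flatline`` (constant at the interval's first sample), or
    ``spike-train`` (flat with alternating-sign spikes every 0.5 s).
    Samples outside the interval are bit-identical to the input.
    """
    t0, t1 = interval
    if not (series.start_time <= t0 < t1 <= series.end_time + 1e-9):
        raise ValueError("interval must lie inside the series")
    rng = np.random.default_rng(seed)
    x = series.values.copy()
    i0 = int(round((t0 - series.start_time) * series.rate))
    i1 = int(round((t1 - series.start_time) * series.rate))
    i1 = min(i1, len(x))
    m = i1 - i0
    if mode == "white-noise":
        sd = scale if scale is not None else 5.0 * float(series.values.std())
        x[i0:i1] = float(series.values.mean()) + sd * rng.standard_normal(m)
    elif mode == "flatline":
        x[i0:i1] = x[i0]
    elif mode == "spike-train":
        amp = scale if scale is not None else 10.0 * float(series.values.std())
        x[i0:i1] = float(series.values.mean())
        step = max(1, int(0.5 * series.rate))
        for j, k in enumerate(range(i0, i1, step)):
            x[k] += amp * (-1.0) ** j
    else:
        raise ValueError(f"unknown corruption mode {mode!r}")
    return TimeSeries(x, rate=series.rate, start_time=series.start_time,
                      units=series.units, label=f"{series.label} ({mode})")


# ---------------------------------------------------------------------------
# full sessions and studies
# ---------------------------------------------------------------------------

@dataclass
class SessionTruth:
    """Ground truth bundled with a simulated session."""

    breaths: list = field(default_factory=list)
    events: list = field(default_factory=list)
    cole: Optional[ColeParams] = None
    k_true: float = float("nan")
    rr_mean_bpm: float = float("nan")
    ti_te_ratio: float = float("nan")


#: per-excitation-frequency baseline resistance and relative respiratory
#: modulation depth of the synthetic IP channels (kHz -> (offset, scale))
_IP_CHANNEL_PROFILE = {5: (40.0, 0.6), 50: (34.0, 0.85), 100: (30.0, 1.0),
                       150: (27.0, 0.9)}


def simulate_session(subject: str = "S01", tag: str = "admission",
                     kind: str = "quiet", seed: int = 0,
                     duration_s: float = 420.0,
                     rr_mean_bpm: float = 23.12, ti_te_ratio: float = 0.91,
                     k_target: float = 1.27, rinf: float = 25.0,
                     bis_noise_sd: float = 0.5, n_sweeps: int = 30,
                     include_audio: bool = True,
                     audio_channels: Sequence[int] = (1,),
                     audio_duration_s: float = 60.0,
                     n_crackles: int = 0,
                     csr: Optional[CSRParams] = None,
                     train: Optional[BreathTrainParams] = None) -> tuple:
    """Build a full multimodal session plus its ground truth.

    ``kind`` is ``"quiet"`` (steady breathing) or ``"csr"`` (Cheyne–Stokes
    modulated). The default 420 s of continuous IP and 30 spectroscopy
    sweeps mirror a 7 min continuous + 1 min spectroscopy protocol. All four
    IP excitation frequencies are rendered from one shared breath truth with
    per-channel baselines, modulation depths and independent noise.
    """
    if kind not in ("quiet", "csr"):
        raise ValueError("kind must be 'quiet' or 'csr'")
    rng = np.random.default_rng(seed)
    base = train or BreathTrainParams(duration_s=duration_s,
                                      rr_mean_bpm=rr_mean_bpm,
                                      ti_te_ratio=ti_te_ratio)
    base = replace(base, seed=int(rng.integers(2**31 - 1)))
    base.validate()
    truth_rng = np.random.default_rng(base.seed)
    truths = _draw_breath_truths(base, truth_rng)

    csr_params = csr or (CSRParams() if kind == "csr" else None)
    ip_channels, ip_truths = {}, truths
    for khz in IP_FREQUENCIES_KHZ:
        offset, scale = _IP_CHANNEL_PROFILE[khz]
        ch_truths = [replace(b, amplitude=b.amplitude * scale) for b in truths]
        ch = _render_train(ch_truths, base,
                           np.random.default_rng(int(rng.integers(2**31 - 1))),
                           offset_ohm=offset)
        ch.label = f"IP {khz} kHz"
        if csr_params is not None:
            ch, ch_truths = apply_csr_envelope(ch, ch_truths, csr_params)
        ip_channels[khz] = ch
        if khz == 100:
            ip_truths = ch_truths

    cole = cole_params_for_k(k_target, rinf=rinf)
    sweeps = make_bis_sweeps(cole, n_sweeps=n_sweeps, noise_sd=bis_noise_sd,
                             seed=int(rng.integers(2**31 - 1)))
    z = cole_impedance(cole, np.array([5000.0, 150000.0]))
    k_true = float(z[0].real / z[1].real)

    audio, events = {}, []
    if include_audio:
        audio_truths = [b for b in ip_truths if b.end <= audio_duration_s]
        if audio_truths:
            for ch_id in audio_channels:
                ap = LungAudioParams(n_crackles=n_crackles)
                snd, ev = make_lung_audio(audio_truths, ap,
                                          seed=int(rng.integers(2**31 - 1)),
                                          channel=ch_id)
                audio[ch_id] = snd
                events.extend(ev)

    session = Session(subject=subject, tag=tag, posture="semi-recumbent",
                      ip_channels=ip_channels, audio_channels=audio,
                      bis_sweeps=sweeps)
    truth = SessionTruth(breaths=ip_truths, events=events, cole=cole,
                         k_true=k_true, rr_mean_bpm=base.rr_mean_bpm,
                         ti_te_ratio=base.ti_te_ratio)
    return session, truth


def simulate_study(seed: int = 0, duration_s: float = 420.0,
                   include_audio: bool = False) -> list:
    """Simulate the three-visit hospitalization study.

    Fourteen subjects: eight measured at admission, mid-stay and discharge,
    two at admission and mid-stay, four at admission only (32 sessions in
    total, eight admission/discharge pairs). Subject-level markers are drawn
    around the decompensated-regime group statistics: RR ≈ 23 ± 5.5 bpm,
    Te:Ti ≈ 1.10 ± 0.27 at admission drifting up by ≈ 0.13 by discharge,
    and K ≈ 1.27 ± 0.12 at admission rising by ≈ 0.05 by discharge.
    Returns ``[(Session, SessionTruth), ...]``.
    """
    rng = np.random.default_rng(seed)
    plan = [3] * 8 + [2] * 2 + [1] * 4
    tags_for = {3: ("admission", "mid", "discharge"),
                2: ("admission", "mid"), 1: ("admission",)}
    out = []
    for s_idx, n_visits in enumerate(plan):
        subject = f"S{s_idx + 1:02d}"
        rr0 = float(np.clip(rng.normal(23.12, 5.53), 10.0, 45.0))
        teti0 = float(np.clip(rng.normal(1.10, 0.27), 0.6, 2.2))
        dteti = rng.normal(0.13, 0.15)
        k0 = float(np.clip(rng.normal(1.27, 0.12), 1.05, 1.7))
        dk = rng.normal(0.05, 0.04)
        rinf = float(np.clip(rng.normal(27.0, 4.0), 16.0, 40.0))
        for tag in tags_for[n_visits]:
            frac = {"admission": 0.0, "mid": 0.5, "discharge": 1.0}[tag]
            rr = float(np.clip(rr0 + rng.normal(-0.39 * frac, 1.0), 8.0, 50.0))
            teti = float(np.clip(teti0 + dteti * frac + rng.normal(0, 0.05),
                                 0.5, 2.5))
            k = float(np.clip(k0 + dk * frac, 1.02, 1.9))
            sess, truth = simulate_session(
                subject=subject, tag=tag, seed=int(rng.integers(2**31 - 1)),
                duration_s=duration_s, rr_mean_bpm=rr,
                ti_te_ratio=1.0 / teti, k_target=k, rinf=rinf,
                include_audio=include_audio)
            out.append((sess, truth))
    return out
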