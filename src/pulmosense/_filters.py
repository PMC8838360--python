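"""Shared FIR filtering and resampling helpers.

All band-pass stages in the package use linear-phase Kaiser-window FIR
filters applied forward-backward (zero net phase, squared magnitude
response), so breath timings and acoustic event times are not biased by
filter delay.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .core import TimeSeries


def design_bandpass(fs: float, lo: float, hi: float, transition: float,
                    atten_db: float) -> np.ndarray:
    """Design a linear-phase Kaiser band-pass FIR.

    ``lo`` and ``hi`` are the -6 dB cutoffs; each transition band of width
    ``transition`` Hz is centred on its cutoff, so the filter reaches
    ``atten_db`` attenuation at ``lo - transition/2`` / ``hi + transition/2``
    and full gain at ``lo + transition/2`` / ``hi - transition/2``.
    """
    nyq = fs / 2.0
    if not (0 < lo - transition / 2 and hi + transition / 2 < nyq):
        raise ValueError("band plus transition width must fit inside (0, Nyquist)")
    numtaps, beta = signal.kaiserord(atten_db, transition / nyq)
    numtaps |= 1  # odd length -> type I linear phase, integer group delay
    return signal.firwin(numtaps, [lo, hi], window=("kaiser", beta),
                         pass_zero=False, fs=fs)


def zero_phase_filter(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply an FIR forward and backward with odd-reflection edge padding.

    Equivalent to ``filtfilt`` but FFT-based, so long kernels (the ~15 s
    respiratory band-pass) stay cheap. Requires ``len(x) > len(taps)``.
    """
    n, m = len(x), len(taps)
    if n <= m:
        raise ValueError(
            f"signal too short for filter warm-up: need more than {m} samples "
            f"({m} filter taps), got {n}"
        )
    # 2m padding keeps the zero-extension transient of the cascaded passes
    # strictly outside the retained samples (each pass spreads it by m/2)
    pad = min(2 * m, n - 1)
    # odd reflection continues the signal without a step at the edges
    left = 2.0 * x[0] - x[pad:0:-1]
    right = 2.0 * x[-1] - x[-2:-pad - 2:-1]
    xp = np.concatenate([left, x, right])
    y = signal.fftconvolve(xp, taps, mode="same")
    y = signal.fftconvolve(y[::-1], taps, mode="same")[::-1]
    return y[pad:pad + n]


def rational_resample(series: TimeSeries, target_rate: float) -> TimeSeries:
    """Resample to ``target_rate`` with a polyphase anti-aliasing FIR.

    The rate ratio is approximated by a rational number with denominator
    <= 1000, exact for all nominal device rates (16 -> 100, 8000 -> 6000,
    46875 -> 6000, ...).
    """
    if series.rate == target_rate:
        return series
    frac = Fraction(target_rate / series.rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    # line padding: zero-padding would ring at the edges of offset signals
    y = signal.resample_poly(series.values, up, down, padtype="line")
    return TimeSeries(y, rate=series.rate * up / down,
                      start_time=series.start_time,
                      units=series.units, label=series.label)
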