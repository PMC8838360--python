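"""Optional matplotlib figures: filtered IP with detected breaths, lung-sound
spectrograms, and averaged BIS curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .audio import Spectrogram
from .fluid import BISCurve


def plot_ip_breaths(resp_result, path) -> None:
    """Filtered IP trace with onset/peak markers, colored by quality."""
    filt = resp_result.preprocessed
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(filt.times(), filt.values, lw=0.6, color="0.3")
    for b in resp_result.breaths:
        color = "tab:green" if b.quality == "good" else "tab:red"
        ax.axvline(b.onset, color=color, lw=0.5, alpha=0.6)
        ax.plot([b.peak], [filt.value_at(b.peak)], ".", color=color, ms=4)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("filtered IP (Ω)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_spectrogram(spec: Spectrogram, path, db_floor: float = -80.0) -> None:
    """Log-power spectrogram image."""
    p = 10 * np.log10(np.maximum(spec.power, 1e-20))
    p -= p.max()
    fig, ax = plt.subplots(figsize=(10, 4))
    im = ax.pcolormesh(spec.times, spec.freqs, np.maximum(p, db_floor),
                       shading="auto", cmap="magma")
    fig.colorbar(im, ax=ax, label="power (dB re max)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bis_curve(curve: BISCurve, path) -> None:
    """Averaged resistance vs excitation frequency."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.semilogx(curve.freqs / 1000.0, curve.impedances.real, "o-", ms=3)
    ax.set_xlabel("excitation frequency (kHz)")
    ax.set_ylabel("resistance (Ω)")
    ax.set_title(f"mean of {curve.n_sweeps} sweeps")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
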