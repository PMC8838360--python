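"""Bioimpedance-spectroscopy fluid-status analysis.

A spectroscopy block is a set of frequency sweeps (nominally 32
log-spaced excitation frequencies, 5–150 kHz, one sweep every 2 s, about 30
sweeps per session). All sweeps of a session are averaged into a single
representative curve; the resistances at the lowest and highest probe
frequencies, R5k and R150k, are read off and their ratio

    K = R5k / R150k

is the fluid-status marker: low-frequency current travels extracellular
paths only, high-frequency current both compartments, so K rises as
extracellular (edema) fluid clears or redistributes intracellularly. The
ratio is dimensionless and cancels inter-subject differences in absolute
thoracic resistance. No tissue-model fitting is performed — the marker is
read directly from the averaged curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class BISweep:
    """One complex-impedance frequency sweep."""

    freqs: np.ndarray           # Hz, strictly increasing
    impedances: np.ndarray      # complex ohm, R + jX
    timestamp: float = 0.0      # seconds from session start

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.impedances = np.asarray(self.impedances, dtype=complex)
        if len(self.freqs) != len(self.impedances):
            raise ValueError("freqs and impedances must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("sweep frequencies must be strictly increasing")
        if np.any(self.impedances.real <= 0):
            raise ValueError("sweep resistances must be positive")


@dataclass
class BISCurve:
    """Session-averaged BIS curve."""

    freqs: np.ndarray
    impedances: np.ndarray      # complex mean per frequency
    n_sweeps: int

    def __post_init__(self) -> None:
        if self.n_sweeps < 1:
            raise ValueError("a BIS curve must average at least one sweep")


@dataclass
class FluidMarkers:
    """Low/high-frequency resistances and their ratio K."""

    r5k: float
    r150k: float
    k: float

    def __post_init__(self) -> None:
        if self.r5k <= 0 or self.r150k <= 0:
            raise ValueError("resistances must be positive")


def make_freq_grid(n: int = 32, fmin: float = 5000.0,
                   fmax: float = 150000.0) -> np.ndarray:
    """Logarithmically spaced excitation-frequency grid with exact endpoints."""
    if n < 2:
        raise ValueError("grid needs at least 2 frequencies")
    if not (0 < fmin < fmax):
        raise ValueError("need 0 < fmin < fmax")
    grid = np.geomspace(fmin, fmax, n)
    grid[0], grid[-1] = fmin, fmax
    return grid


def average_sweeps(sweeps: Sequence[BISweep]) -> BISCurve:
    """Arithmetic complex mean of all sweeps of a session.

    Averaging over ~1 minute suppresses the respiration- and motion-induced
    variability of individual sweeps. All sweeps must share one grid.
    """
    if len(sweeps) == 0:
        raise ValueError("cannot average an empty sweep list")
    grid = sweeps[0].freqs
    for s in sweeps[1:]:
        if len(s.freqs) != len(grid) or not np.allclose(s.freqs, grid):
            raise ValueError("sweeps have mismatched frequency grids")
    mean = np.mean([s.impedances for s in sweeps], axis=0)
    return BISCurve(freqs=grid.copy(), impedances=mean, n_sweeps=len(sweeps))


def resistance_at(curve: BISCurve, frequency: float) -> float:
    """Resistance (real part) at the grid node nearest ``frequency``.

    5 and 150 kHz are exact endpoints of the default grid, so the lookup is
    exact there; no extrapolation outside the grid span.
    """
    if not (curve.freqs[0] <= frequency <= curve.freqs[-1]):
        raise ValueError(
            f"frequency {frequency:g} Hz outside grid span "
            f"[{curve.freqs[0]:g}, {curve.freqs[-1]:g}] Hz"
        )
    i = int(np.argmin(np.abs(curve.freqs - frequency)))
    return float(curve.impedances[i].real)


def compute_k_ratio(curve: BISCurve,
                    probe_freqs: tuple = (5000.0, 150000.0)) -> FluidMarkers:
    """Fluid markers (R5k, R150k, K) from an averaged curve."""
    f_lo, f_hi = probe_freqs
    r_lo = resistance_at(curve, f_lo)
    r_hi = resistance_at(curve, f_hi)
    if r_hi <= 0:
        raise ValueError("high-frequency resistance must be positive")
    return FluidMarkers(r5k=r_lo, r150k=r_hi, k=r_lo / r_hi)
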