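"""Impedance-pneumography respiratory pipeline.

Stages, in order:

1. :func:`preprocess_ip` — resample to 100 Hz, zero-phase Kaiser FIR
   band-pass 0.1–0.8 Hz (6–48 breaths/min).
2. :func:`window_segments` — overlapping analysis windows (26 s, 80 %
   overlap, stride 5.2 s).
3. :func:`detect_breath_onsets` per window + :func:`fuse_onsets` — breath
   onsets as inspiratory troughs; per-window detections merged into one set.
4. :func:`score_window_sqi` — binary per-window signal-quality label from
   the mean template correlation of member breaths and the coefficient of
   variation of their durations.
5. :func:`label_breaths` — OR-fusion: a breath is good if any window that
   contains it is good.
6. :func:`plausibility_filter` — keep breaths with 4 <= RR <= 60 bpm.
7. :func:`extract_breath_features` — RR, Ti, Te, Te:Ti, Rpki, Rpke per breath.
8. :func:`reject_outliers_mad` — per-feature ±k·MAD flags, fused by union.

:func:`process_ip_channel` chains all stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from ._filters import design_bandpass, rational_resample, zero_phase_filter
from .core import AnalysisConfig, TimeSeries

FEATURE_COLUMNS = ("rr", "ti", "te", "te_ti", "rpki", "rpke")


@dataclass
class Breath:
    """A detected breath spanning onset -> next onset.

    ``onset`` and ``end`` are consecutive inspiratory troughs; ``peak`` is
    the inspiratory maximum in between. ``ibi = end - onset`` is the
    inter-breath interval.
    """

    onset: float
    peak: float
    end: float
    quality: str = "bad"            # "good" | "bad"
    window_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.onset < self.peak < self.end):
            raise ValueError("breath requires onset < peak < end")

    @property
    def ibi(self) -> float:
        return self.end - self.onset


@dataclass
class WindowLabel:
    """Binary signal-quality verdict for one analysis window."""

    start: float
    end: float
    label: str                      # "good" | "bad"
    mean_template_corr: float       # NaN when < 2 member breaths
    duration_cov: float             # NaN when < 2 member breaths
    member_breaths: list = field(default_factory=list)


@dataclass
class RespSummary:
    """Counts plus mean/sd of each breath feature over the final breath set."""

    n_breaths_detected: int
    n_breaths_good: int
    n_breaths_after_outlier: int
    feature_mean: dict
    feature_sd: dict

    def __post_init__(self) -> None:
        if not (self.n_breaths_after_outlier <= self.n_breaths_good
                <= self.n_breaths_detected):
            raise ValueError("summary counts must be nested")


@dataclass
class RespResult:
    """Full output bundle of :func:`process_ip_channel`."""

    preprocessed: TimeSeries
    windows: list
    window_labels: list
    onsets: np.ndarray
    breaths: list
    features: pd.DataFrame          # all good+plausible breaths
    retained: pd.DataFrame          # after MAD outlier rejection
    summary: RespSummary


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess_ip(series: TimeSeries, config: Optional[AnalysisConfig] = None) -> TimeSeries:
    """Resample an IP resistance stream to 100 Hz and band-pass it.

    The band-pass is a zero-phase (forward-backward) Kaiser FIR over the
    respiratory band, removing baseline drift and cardiogenic / motion
    content. Raises ``ValueError`` when the series is shorter than the
    filter kernel, naming the minimum length.
    """
    config = config or AnalysisConfig()
    if series.rate < 2:
        raise ValueError("IP series rate must be >= 2 Hz")
    # centring makes the pipeline exactly invariant to the arbitrary DC level
    # of an impedance channel (the FIR's DC null is only finite)
    centred = TimeSeries(series.values - series.values.mean(),
                         rate=series.rate, start_time=series.start_time,
                         units=series.units, label=series.label)
    rs = rational_resample(centred, config.ip_target_rate_hz)
    lo, hi = config.ip_band_hz
    taps = design_bandpass(rs.rate, lo, hi, config.ip_transition_hz,
                           config.ip_atten_db)
    if len(rs) <= len(taps):
        raise ValueError(
            "IP series too short for band-pass warm-up: need > "
            f"{len(taps) / rs.rate:.1f} s at {rs.rate:g} Hz, got {rs.duration:.1f} s"
        )
    y = zero_phase_filter(rs.values, taps)
    return TimeSeries(y, rate=rs.rate, start_time=rs.start_time,
                      units=series.units, label=f"{series.label} (filtered)")


# ---------------------------------------------------------------------------
# windowing and onset detection
# ---------------------------------------------------------------------------

def window_segments(series: TimeSeries, window_len: float,
                    overlap: float) -> list:
    """Overlapping window spans ``[(start, end), ...]`` on the session clock.

    Stride is ``(1 - overlap) * window_len`` (5.2 s for 26 s / 80 %).
    A series shorter than one window yields a single window spanning it.
    """
    if window_len <= 0:
        raise ValueError("window_len must be > 0")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must lie in [0, 1)")
    t0, dur = series.start_time, series.duration
    if dur <= window_len:
        return [(t0, t0 + dur)]
    stride = (1.0 - overlap) * window_len
    k = int(math.floor((dur - window_len) / stride + 1e-9)) + 1
    return [(t0 + i * stride, t0 + i * stride + window_len) for i in range(k)]


def detect_breath_onsets(window: TimeSeries, min_separation: float = 1.0,
                         rise_iqr_factor: float = 0.2,
                         valley_fraction: float = 0.15,
                         min_rise: float = 0.0) -> np.ndarray:
    """Breath onsets (inspiratory troughs) within one window.

    A trough qualifies when it is a local minimum separated from other
    candidate troughs by at least ``min_separation`` seconds and the signal
    rise that follows it (to the maximum before the next trough) exceeds
    ``rise_iqr_factor`` times the interquartile range of the window — an
    adaptive amplitude floor that rejects noise ripples. ``min_rise`` adds an
    absolute floor on the rise; the session pipeline sets it to a small
    fraction of the whole-series IQR so that windows landing on a
    near-silent stretch (an apnea) do not promote filter-leakage ripples,
    whose amplitude is orders of magnitude below any real breath, into
    breath candidates.

    The reported onset time is a refined valley centre rather than the raw
    ``argmin``: the chord between the two neighbouring signal peaks is
    subtracted (cancelling the slow tilt that band-pass filtering leaves
    under a valley), and the onset is the midpoint of the region within
    ``valley_fraction`` of the detrended valley depth. At slow respiratory
    rates the valley bottom is nearly flat, so this centre estimate is far
    less noise-sensitive than the minimum sample itself.
    """
    x = window.values
    if len(x) < 3:
        return np.array([])
    rate = window.rate
    dist = max(1, int(round(min_separation * rate)))
    troughs, _ = sps.find_peaks(-x, distance=dist)
    if len(troughs) == 0:
        return np.array([])
    peaks, _ = sps.find_peaks(x, distance=max(1, dist // 2))
    q75, q25 = np.percentile(x, [75, 25])
    thr = max(rise_iqr_factor * (q75 - q25), min_rise)
    onsets = []
    bounds = list(troughs[1:]) + [len(x) - 1]
    for tr, nxt in zip(troughs, bounds):
        seg = x[tr:nxt + 1]
        if len(seg) == 0 or (seg.max() - x[tr]) <= thr:
            continue
        right = peaks[peaks > tr]
        left = peaks[peaks < tr]
        pn = int(right[0]) if len(right) else int(tr + np.argmax(seg))
        pp = int(left[-1]) if len(left) else 0
        if pn <= pp + 2:
            onsets.append(window.start_time + tr / rate)
            continue
        valley = x[pp:pn + 1] - np.linspace(x[pp], x[pn], pn - pp + 1)
        k = int(np.argmin(valley))
        h = (1.0 - valley_fraction) * valley[k]   # valley[k] <= 0
        i = k
        while i > 0 and valley[i - 1] <= h:
            i -= 1
        j = k
        while j < len(valley) - 1 and valley[j + 1] <= h:
            j += 1
        onsets.append(window.start_time + (pp + 0.5 * (i + j)) / rate)
    out = np.asarray(sorted(onsets))
    return out[np.concatenate(([True], np.diff(out) > min_separation))] if len(out) else out


def fuse_onsets(onset_lists: Iterable[Sequence[float]],
                tolerance: float = 0.25,
                return_support: bool = False):
    """Merge per-window onset detections into one unique set.

    Onsets from different windows within ``tolerance`` seconds of each other
    are averaged; the merge is repeated until all survivors are more than
    ``tolerance`` apart. Idempotent on already-fused sets. With
    ``return_support`` the number of raw detections behind each fused onset
    is returned as well.
    """
    allon = np.sort(np.concatenate([np.asarray(l, dtype=float)
                                    for l in onset_lists if len(l)] or [np.array([])]))
    if len(allon) == 0:
        empty = np.array([])
        return (empty, np.array([], dtype=int)) if return_support else empty
    merged, support = allon, np.ones(len(allon), dtype=int)
    while True:
        clusters, counts = [[merged[0]]], [[support[0]]]
        for t, c in zip(merged[1:], support[1:]):
            if t - np.mean(clusters[-1]) <= tolerance:
                clusters[-1].append(t)
                counts[-1].append(c)
            else:
                clusters.append([t])
                counts.append([c])
        new = np.array([np.mean(c) for c in clusters])
        new_support = np.array([int(np.sum(c)) for c in counts])
        if len(new) == len(merged):
            return (new, new_support) if return_support else new
        merged, support = new, new_support


def build_breaths(series: TimeSeries, onsets: Sequence[float],
                  crest_fraction: float = 0.15) -> list:
    """Assemble breaths from consecutive fused onsets.

    The peak is located between the two onsets by the same centre estimate
    used for onsets: the chord between the onset samples is subtracted and
    the peak is the midpoint of the region within ``crest_fraction`` of the
    detrended crest height (robust against the flat crests of slow breaths).
    A breath whose crest collapses onto a boundary is dropped (degenerate).
    """
    breaths = []
    for a, b in zip(onsets[:-1], onsets[1:]):
        seg = series.slice(a, b)
        if len(seg) < 3:
            continue
        v = seg.values - np.linspace(seg.values[0], seg.values[-1], len(seg))
        k = int(np.argmax(v))
        h = (1.0 - crest_fraction) * v[k]
        i = k
        while i > 0 and v[i - 1] >= h:
            i -= 1
        j = k
        while j < len(v) - 1 and v[j + 1] >= h:
            j += 1
        peak = seg.start_time + 0.5 * (i + j) / seg.rate
        if not (a < peak < b):
            continue
        breaths.append(Breath(onset=float(a), peak=float(peak), end=float(b)))
    return breaths


# ---------------------------------------------------------------------------
# signal quality
# ---------------------------------------------------------------------------

_TEMPLATE_LEN = 101


def _resample_breath(series: TimeSeries, breath: Breath) -> Optional[np.ndarray]:
    seg = series.slice(breath.onset, breath.end)
    if len(seg) < 4:
        return None
    src = np.linspace(0.0, 1.0, len(seg))
    dst = np.linspace(0.0, 1.0, _TEMPLATE_LEN)
    return np.interp(dst, src, seg.values)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def score_window_sqi(window: TimeSeries, breaths: Sequence[Breath],
                     corr_threshold: float = 0.7,
                     cov_threshold: float = 0.5,
                     member_ids: Optional[Sequence[int]] = None) -> WindowLabel:
    """Label one window good/bad from its member breaths.

    Each member breath is linearly resampled to a fixed 101-point template
    length; the window template is their mean, and the morphology score is
    the mean Pearson correlation of each breath with the template. The
    regularity score is the coefficient of variation (sd/mean) of the
    inter-breath intervals. A window is *good* iff it holds at least two
    breaths, the mean correlation is >= ``corr_threshold`` and the CoV is
    <= ``cov_threshold``; with fewer than two breaths both diagnostics are
    undefined (NaN) and the label is *bad*.
    """
    ids = list(member_ids) if member_ids is not None else list(range(len(breaths)))
    start, end = window.start_time, window.end_time
    resampled = [_resample_breath(window, b) for b in breaths]
    keep = [(i, r, b) for i, r, b in zip(ids, resampled, breaths) if r is not None]
    if len(keep) < 2:
        return WindowLabel(start, end, "bad", float("nan"), float("nan"),
                           [i for i, _, _ in keep])
    mat = np.vstack([r for _, r, _ in keep])
    template = mat.mean(axis=0)
    corr = float(np.mean([_pearson(r, template) for r in mat]))
    ibis = np.array([b.ibi for _, _, b in keep])
    cov = float(ibis.std(ddof=1) / ibis.mean()) if ibis.mean() > 0 else float("inf")
    good = corr >= corr_threshold and cov <= cov_threshold
    return WindowLabel(start, end, "good" if good else "bad", corr, cov,
                       [i for i, _, _ in keep])


def label_breaths(breaths: Sequence[Breath],
                  window_labels: Sequence[WindowLabel]) -> list:
    """OR-fuse window labels onto breaths.

    A breath is *good* if at least one window containing it is labelled
    good; a breath appearing in no window stays *bad*. Returns the per-breath
    quality strings and records window membership on each breath.
    """
    for b in breaths:
        b.window_ids = []
    for wid, wl in enumerate(window_labels):
        for i in wl.member_breaths:
            breaths[i].window_ids.append(wid)
    flags = []
    for b in breaths:
        good = any(window_labels[w].label == "good" for w in b.window_ids)
        b.quality = "good" if good else "bad"
        flags.append(b.quality)
    return flags


def plausibility_filter(breaths: Sequence[Breath], rr_min: float = 4.0,
                        rr_max: float = 60.0) -> list:
    """Keep breaths whose RR = 60/IBI lies within the physiological bounds."""
    return [b for b in breaths if rr_min <= 60.0 / b.ibi <= rr_max]


# ---------------------------------------------------------------------------
# features and outlier rejection
# ---------------------------------------------------------------------------

def extract_breath_features(series: TimeSeries,
                            breaths: Sequence[Breath]) -> pd.DataFrame:
    """Breath-by-breath timing and amplitude features.

    Per breath: Ti = peak − onset, Te = end − peak (Ti + Te = IBI),
    Te:Ti = Te/Ti, RR = 60/IBI, and the amplitude excursions
    Rpki = x(peak) − x(onset) and Rpke = x(peak) − x(end).
    """
    rows = []
    for b in breaths:
        ti = b.peak - b.onset
        te = b.end - b.peak
        if ti <= 0 or te <= 0:
            continue
        rows.append({
            "onset": b.onset, "peak": b.peak, "end": b.end, "ibi": b.ibi,
            "rr": 60.0 / b.ibi, "ti": ti, "te": te, "te_ti": te / ti,
            "rpki": series.value_at(b.peak) - series.value_at(b.onset),
            "rpke": series.value_at(b.peak) - series.value_at(b.end),
        })
    return pd.DataFrame(rows, columns=["onset", "peak", "end", "ibi",
                                       *FEATURE_COLUMNS])


def mad_flags(values: np.ndarray, multiplier: float = 4.0) -> np.ndarray:
    """Boolean outlier flags: |x − median| > multiplier × MAD.

    MAD is the raw median absolute deviation (no normal-consistency
    scaling). A zero MAD (e.g. all values equal) flags nothing.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros(len(values), dtype=bool)
    return np.abs(values - med) > multiplier * mad


def reject_outliers_mad(features: pd.DataFrame, multiplier: float = 4.0,
                        columns: Sequence[str] = FEATURE_COLUMNS) -> tuple:
    """Fuse per-feature MAD flags and drop every flagged breath.

    Each feature column is screened independently against ±multiplier·MAD
    of its own median; a row flagged in *any* column is removed (union of
    flags). Returns ``(retained_frame, union_flag_mask)``.
    """
    if len(features) == 0:
        raise ValueError("cannot reject outliers on an empty feature table")
    flagged = np.zeros(len(features), dtype=bool)
    for col in columns:
        flagged |= mad_flags(features[col].to_numpy(), multiplier)
    return features.loc[~flagged].reset_index(drop=True), flagged


def summarize_resp(retained: pd.DataFrame, n_detected: int,
                   n_good: int) -> RespSummary:
    mean = {c: float(retained[c].mean()) if len(retained) else float("nan")
            for c in FEATURE_COLUMNS}
    sd = {c: float(retained[c].std(ddof=1)) if len(retained) > 1 else 0.0
          for c in FEATURE_COLUMNS}
    return RespSummary(n_breaths_detected=n_detected, n_breaths_good=n_good,
                       n_breaths_after_outlier=len(retained),
                       feature_mean=mean, feature_sd=sd)


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def process_ip_channel(series: TimeSeries,
                       config: Optional[AnalysisConfig] = None) -> RespResult:
    """Run the complete respiratory pipeline on one raw IP channel."""
    config = config or AnalysisConfig()
    filt = preprocess_ip(series, config)
    windows = window_segments(filt, config.window_len_s, config.window_overlap)
    gq75, gq25 = np.percentile(filt.values, [75, 25])
    floor = config.onset_rise_global_iqr_factor * (gq75 - gq25)
    onset_lists = [
        detect_breath_onsets(filt.slice(a, b),
                             min_separation=config.min_trough_separation_s,
                             rise_iqr_factor=config.onset_rise_iqr_factor,
                             min_rise=floor)
        for a, b in windows
    ]
    onsets, support = fuse_onsets(onset_lists,
                                  tolerance=config.onset_fusion_tol_s,
                                  return_support=True)
    # de-glitch: an onset seen in only one of several covering windows is a
    # window-edge artifact; genuine onsets recur across the 80 % overlap
    if len(onsets):
        cover = np.array([sum(1 for a, b in windows if a <= t <= b)
                          for t in onsets])
        keep = support >= np.minimum(2, cover)
        onsets = onsets[keep]
    breaths = build_breaths(filt, onsets)

    labels = []
    for a, b in windows:
        member = [i for i, br in enumerate(breaths)
                  if br.onset >= a - 1e-9 and br.end <= b + 1e-9]
        labels.append(score_window_sqi(
            filt.slice(a, b), [breaths[i] for i in member],
            corr_threshold=config.template_corr_threshold,
            cov_threshold=config.duration_cov_threshold, member_ids=member))
    label_breaths(breaths, labels)

    good = [b for b in breaths if b.quality == "good"]
    plausible = plausibility_filter(good, config.rr_min_bpm, config.rr_max_bpm)
    features = extract_breath_features(filt, plausible)
    if len(features):
        retained, _ = reject_outliers_mad(features, config.mad_multiplier)
    else:
        retained = features
    summary = summarize_resp(retained, n_detected=len(breaths),
                             n_good=len(plausible))
    return RespResult(preprocessed=filt, windows=windows, window_labels=labels,
                      onsets=onsets, breaths=breaths, features=features,
                      retained=retained, summary=summary)
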