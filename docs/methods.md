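# Methods

This note records the models, the numerical choices, and the limits of what
the test suite demonstrates. It states no result that the tests or
`scripts/acceptance.py` do not themselves compute.

## Signals and data model

A *session* is one wearable measurement: multi-frequency IP resistance
streams (excitations 5/50/100/150 kHz, 16 Hz per frequency), lung-sound
audio (any PCM rate ≥ 4 kHz; 8 kHz default in simulation, 6 kHz analysis
rate), BIS sweeps (32 log-spaced frequencies 5–150 kHz, one sweep per 2 s),
and optional IMU/temperature channels, tagged `admission | mid | discharge`.
All channels are uniform-rate `TimeSeries` on a shared session clock. On
disk a session is a directory of CSV/WAV files plus a YAML metadata file;
CSV channels round-trip bit-exactly (full-precision floats, round-trip
parser), audio within 16-bit PCM quantization.

## Respiratory pipeline

Assumptions: breathing occupies 0.1–0.8 Hz; the 100 kHz excitation carries
the cleanest respiratory modulation; onset = inspiratory trough; a breath
spans onset → next onset, so Ti + Te = IBI exactly.

**Band-pass.** Kaiser-window FIR, −6 dB cutoffs at 0.1 and 0.8 Hz,
transition width 0.06 Hz, 30 dB single-pass design applied
forward–backward: zero net phase (timings unbiased) and ~60 dB effective
stop-band. The kernel spans 25.6 s, which sets the minimum input length;
signals are centred (mean-subtracted) first so the pipeline is exactly
invariant to the arbitrary DC level of an impedance channel. The 0.06 Hz
transition keeps 8 bpm breathing (0.133 Hz) at unit gain while reaching
full attenuation by 0.05 Hz. A wider transition was rejected because it
attenuated the slowest physiological rates; a narrower one would push the
kernel past the shortest inputs the pipeline accepts.

**Onset detection.** Per 26 s window (80 % overlap): local minima with a
1 s refractory whose following rise exceeds 0.2× the window IQR *and* an
absolute floor of 0.3× the whole-series IQR. The absolute floor matters
only in near-silent stretches (apneas), where the window IQR collapses and
band-pass impulse-response leakage (~1–3 % of neighbouring breath
amplitude) would otherwise be promoted to breath candidates. Onset *time*
is not the raw argmin: the chord between the two neighbouring signal peaks
is subtracted (cancelling the slow tilt filtering leaves under a valley)
and the onset is the midpoint of the region within 15 % of the detrended
valley depth. Slow breaths have nearly flat valley bottoms, so this centre
estimate is markedly less noise-sensitive than the minimum sample. Breath
peaks are located by the mirrored crest estimate. Per-window detections are
fused by iterative mean-merging with a 0.25 s tolerance; a fused onset
backed by a single detection where two or more windows overlap is dropped
as a window-edge artifact.

**Quality gating.** Window SQI: member breaths (fully inside the window)
are linearly resampled to 101 points; the window is *good* iff it holds
≥ 2 breaths, their mean Pearson correlation with the mean-breath template
is ≥ 0.7, and the CoV (sd/mean, n−1 denominator) of their IBIs is ≤ 0.5.
Breath labels are the OR over containing windows; breaths in no window are
bad. Plausibility keeps 4 ≤ 60/IBI ≤ 60 bpm (inclusive). Feature-level
outlier rejection flags values beyond ±4 MAD of each feature's median —
MAD unscaled (no 1.4826 normal-consistency factor) — and removes every row
flagged in any column.

## Fluid-status pipeline

All sweeps of a session are averaged complex-valued into one curve
(respiration/movement variability averages out over the ~1 min block);
resistances are read at the grid node nearest 5 and 150 kHz — exact grid
endpoints by construction, so no interpolation or extrapolation — and
K = R5k/R150k. No Cole-model fitting is performed on measured curves
(forward Cole evaluation exists only in the generator); no sweep-level
outlier screening is applied, matching the plain-averaging procedure.
Reactance is retained after averaging for diagnostics but unused by K.

## Lung-sound pipeline

Resample to 6 kHz (polyphase FIR, line-padded edges), zero-phase Kaiser
band-pass with −6 dB points at 75 and 1025 Hz and 50 Hz transitions, i.e.
full gain across 100–1000 Hz, ≥ 40 dB (single-pass; ~80 dB cascaded) by
50 Hz and far before 1.8 kHz. STFT: Hann window, 300 ms, 95 % overlap
(250 ms available as a parameter for crackle visualization), no boundary
padding, so frames = ⌊(L−W)/H⌋+1; PSD scaling with the documented
rectangular energy bookkeeping `Σ P·df·(W/fs) = Σx²/fs` exact for a boxcar
window. The mean spectrum is the Welch average over the same frames — the
spectrogram parameters are reused deliberately rather than inventing a
second estimator. Spectral features restrict to a band (default
100–1000 Hz, the preprocessing pass-band, an explicit assumption): Fmax is
the argmax; F50/F95 are the smallest grid frequencies where cumulative
bin power reaches 50 %/95 % — scale-invariant by construction. Phase
segmentation maps each accepted breath to inspiration `[onset, peak)` and
expiration `[peak, end)`, everything else unscored, with per-segment RMS.

## Statistics

Shapiro–Wilk on each group (not on differences — the gate follows the
protocol's literal wording; statistically unconventional and noted as
such); both p > α → two-tailed paired t, else two-tailed Wilcoxon
signed-rank. The signed-rank null is computed exactly for n ≤ 25 by
convolution over doubled ranks (zeros dropped per Wilcoxon's rule, ties
mid-ranked, statistic = min(W⁺, W⁻), two-sided p = 2·min(tail masses),
capped at 1); scipy's normal approximation is used beyond n = 25. All-zero
differences return p = 1 with a warning. Group summaries are mean ± sample
sd; a single value reports sd = 0 with n = 1 flagging the degeneracy.

## Synthetic data: what it emulates, what it does not

Breath trains are contiguous asymmetric raised-cosine pulses: IBI drawn
per breath around 60/RR with CoV `rr_jitter_cv` (default 0.08), split
Ti:Te = `ti_te_ratio` (default 0.91, i.e. Te:Ti ≈ 1.10), amplitude CoV
0.10, plus a 0.02 Hz baseline-drift sinusoid (amplitude 2 Ω, exercising
the high-pass) and white Gaussian noise (default sd 0.05 Ω = 5 % of the
1 Ω breath amplitude). Defaults target the decompensated-patient regime
(RR ≈ 23 bpm). Cheyne–Stokes modulation multiplies the signal by a
periodic raised-cosine envelope with an apneic fraction per cycle
(defaults 60 s cycle, 25 % apnea — placeholders, as no quantitative cycle
length is established for this regime; truth breaths touching envelope
< 1 % of maximum are flagged `in_apnea`). BIS sweeps are forward Cole
evaluations `Z = R∞ + (R0−R∞)/(1+(j2πf τc)^α)` plus independent Gaussian
noise on R and X (default 0.5 Ω, the bench accuracy scale of such
front-ends); `cole_params_for_k` solves the dispersion magnitude in closed
form so a session's noiseless K is exact. Lung audio is 100–1000 Hz
Gaussian noise amplitude-gated by breath phase (inspiration 1.0,
expiration 0.45, base 0.02, scaled by breath depth), with optional 750 Hz
damped-oscillation crackles placed inside inspirations and ~40 Hz
heart-sound thumps at ~1.1 Hz.

The generator reproduces the *statistical structure* the analysis assumes —
quasi-periodicity, phase asymmetry, envelope modulation, band-limited
acoustics — not real physiology: no cardiogenic IP component, no
electrode-motion artifacts, no airflow–sound transfer model, no
posture/electrode-placement effects. Passing tests therefore demonstrate
correctness of the algorithms under those assumptions, not clinical
performance.

The study generator draws subject-level markers around the group
statistics of the hospitalized regime (RR 23.1 ± 5.5 bpm; Te:Ti
1.10 ± 0.27 at admission, rising ≈ 0.13 by discharge; K 1.27 ± 0.12 at
admission, rising ≈ 0.05 by discharge) and reproduces the visit structure:
8 subjects with three visits, 2 with two, 4 with one — 32 sessions, 8
admission/discharge pairs. Sessions default to 420 s of continuous IP and
30 spectroscopy sweeps, mirroring the 7 min + 1 min protocol; the study
generator omits audio by default because the paired markers do not consume
it (single-session simulation includes it).

## Problem sizes

The test suite and acceptance script use: 20 trains × 300 s for breath
recovery (pooled onset matching, ±0.15 s), 50 corrupted 240 s trains for
SQI discrimination, 20 spectroscopy sessions × 30 sweeps for K recovery,
brute-force enumeration up to n = 10 for the signed-rank and MAD oracles,
and the full 32-session study for the paired statistics. Everything runs
in a few minutes on one CPU.

## Known limitations

- **Band-limited Te:Ti compression.** The 0.1–0.8 Hz band removes the
  harmonics that carry inspiratory/expiratory asymmetry, so Te:Ti
  estimates are biased toward 1 (about −0.06 at Te:Ti = 1.10, more at
  stronger asymmetry). Group *differences* survive but are attenuated; any
  quantitative Te:Ti comparison should treat the absolute level as
  band-dependent.
- **Slow breathing.** At 8 bpm the breathing fundamental sits just above
  the band edge and cycle-length jitter spreads energy below it; filtered
  valley positions then wander by up to a few hundred ms, so per-train
  mean Te error can reach ≈ 0.2 s at 8 bpm even though pooled onset
  recovery across 8–40 bpm stays above 95 %.
- **SQI vs in-band noise.** White Gaussian noise band-passed to 0.1–0.8 Hz
  yields quasi-regular unimodal bumps (template correlation ≈ 0.82,
  duration CoV ≈ 0.28) that *pass* a correlation/CoV gate at the 0.7/0.5
  thresholds. The two-feature SQI reliably flags flatline and spike
  corruption (electrode detachment, motion), not noise that mimics the
  respiratory band; richer quality features would be needed for that.
- **No volume calibration.** Amplitude features (Rpki/Rpke) are used only
  for outlier rejection, never as tidal-volume surrogates; IP amplitude
  depends on electrode placement and posture and would require spirometer
  calibration.
- **Spectral features are band- and device-dependent.** Fmax/F50/F95 are
  defined relative to the configured analysis band; absolute values from
  different hardware are not directly comparable.
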