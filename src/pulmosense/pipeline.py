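"""End-to-end analysis: chain every stage over one or more sessions and
compare paired admission-vs-discharge markers across subjects.

Per session the pipeline produces a breath table and respiratory summary
(from the selected IP channel), fluid markers (R5k, R150k, K) from the BIS
block, and per-channel lung-sound spectral features. Across sessions, every
subject contributing both an admission and a discharge measurement enters
two-group paired comparisons of K, mean RR, and mean Te:Ti. The report is a
plain dict (JSON-serializable) that echoes the configuration and logs every
threshold applied and every omission.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import audio as _audio
from . import fluid as _fluid
from . import resp as _resp
from .core import AnalysisConfig, Session
from .io import read_session
from .stats import compare_paired

logger = logging.getLogger("pulmosense")

_COMPARED_METRICS = ("k", "mean_rr", "mean_te_ti")


def analyze_session(session: Session,
                    config: Optional[AnalysisConfig] = None) -> dict:
    """Run every applicable stage on one session.

    Returns a dict with ``resp`` / ``fluid`` / ``spectral`` blocks; blocks
    whose modality is absent are omitted and listed under ``omissions``.
    The breath table is attached under ``breath_table`` (DataFrame).
    """
    config = config or AnalysisConfig()
    out = {"subject": session.subject, "tag": session.tag, "omissions": []}

    if config.ip_channel_khz in session.ip_channels:
        result = _resp.process_ip_channel(
            session.ip_channels[config.ip_channel_khz], config)
        s = result.summary
        out["resp"] = {
            "n_breaths_detected": s.n_breaths_detected,
            "n_breaths_good": s.n_breaths_good,
            "n_breaths_after_outlier": s.n_breaths_after_outlier,
            "feature_mean": s.feature_mean,
            "feature_sd": s.feature_sd,
        }
        out["breath_table"] = result.retained
        out["_resp_result"] = result
    else:
        out["omissions"].append(
            f"no {config.ip_channel_khz} kHz IP channel: respiratory block skipped")
        logger.info(out["omissions"][-1])

    if session.bis_sweeps:
        curve = _fluid.average_sweeps(session.bis_sweeps)
        markers = _fluid.compute_k_ratio(curve, config.bis_probe_freqs_hz)
        out["fluid"] = {"r5k": markers.r5k, "r150k": markers.r150k,
                        "k": markers.k, "n_sweeps": curve.n_sweeps}
    else:
        out["omissions"].append("no BIS sweeps: fluid block skipped")
        logger.info(out["omissions"][-1])

    if session.audio_channels:
        spectral = {}
        for ch_id, ts in sorted(session.audio_channels.items()):
            try:
                clean = _audio.preprocess_audio(ts, config)
                spec = _audio.compute_mean_spectrum(
                    clean, config.stft_window_s, config.stft_overlap)
                feats = _audio.extract_spectral_features(
                    spec, config.spectral_band_hz)
            except ValueError as exc:
                out["omissions"].append(f"audio ch{ch_id}: {exc}")
                logger.info(out["omissions"][-1])
                continue
            spectral[str(ch_id)] = {"fmax": feats.fmax, "f50": feats.f50,
                                    "f95": feats.f95,
                                    "band_lo": feats.band[0],
                                    "band_hi": feats.band[1]}
        if spectral:
            out["spectral"] = spectral
    else:
        out["omissions"].append("no audio channels: spectral block skipped")
        logger.info(out["omissions"][-1])
    return out


def _paired_values(blocks: Sequence[dict], metric: str) -> tuple:
    """Admission/discharge value pairs for one metric across subjects."""
    per_subject = {}
    for b in blocks:
        if metric == "k":
            val = b.get("fluid", {}).get("k")
        elif metric == "mean_rr":
            val = b.get("resp", {}).get("feature_mean", {}).get("rr")
        else:
            val = b.get("resp", {}).get("feature_mean", {}).get("te_ti")
        if val is None or not np.isfinite(val):
            continue
        per_subject.setdefault(b["subject"], {})[b["tag"]] = val
    adm, dis, subjects = [], [], []
    for subj in sorted(per_subject):
        d = per_subject[subj]
        if "admission" in d and "discharge" in d:
            adm.append(d["admission"])
            dis.append(d["discharge"])
            subjects.append(subj)
    return adm, dis, subjects


def run_pipeline(config: Optional[AnalysisConfig],
                 sessions: Sequence,
                 out_dir=None, plots: bool = False) -> dict:
    """Analyze sessions (directories or :class:`Session` objects) and build
    the study report.

    The report carries one block per session, the paired
    admission-vs-discharge comparisons for K / mean RR / mean Te:Ti (or the
    marker ``"insufficient pairs"``), the full configuration used, and a log
    of every threshold applied. Deterministic for fixed (config, inputs).
    When ``out_dir`` is given, report.json plus CSV tables (breath tables,
    fluid markers, comparisons) are written there.
    """
    config = config or AnalysisConfig()
    if not sessions:
        raise ValueError("need at least one session")
    loaded = [s if isinstance(s, Session) else read_session(s) for s in sessions]

    blocks = [analyze_session(s, config) for s in loaded]

    comparisons = {}
    for metric in _COMPARED_METRICS:
        adm, dis, subjects = _paired_values(blocks, metric)
        if len(adm) < 3:
            comparisons[metric] = {"status": "insufficient pairs",
                                   "n_pairs": len(adm)}
            continue
        res = compare_paired(adm, dis, alpha=config.alpha)
        comparisons[metric] = {
            "status": "ok", "subjects": subjects, "n_pairs": res.n_pairs,
            "test_name": res.test_name, "statistic": res.statistic,
            "p_value": res.p_value, "significant": res.significant,
            "admission_mean": float(np.mean(adm)),
            "admission_sd": float(np.std(adm, ddof=1)),
            "discharge_mean": float(np.mean(dis)),
            "discharge_sd": float(np.std(dis, ddof=1)),
        }

    thresholds_log = [
        f"ip band-pass {config.ip_band_hz[0]}-{config.ip_band_hz[1]} Hz at "
        f"{config.ip_target_rate_hz:g} Hz",
        f"windows {config.window_len_s:g} s, overlap {config.window_overlap:g} "
        f"(stride {(1 - config.window_overlap) * config.window_len_s:g} s)",
        f"SQI: template corr >= {config.template_corr_threshold:g}, "
        f"duration CoV <= {config.duration_cov_threshold:g}",
        f"plausibility: {config.rr_min_bpm:g} <= RR <= {config.rr_max_bpm:g} bpm",
        f"outliers: +/-{config.mad_multiplier:g} MAD per feature, union-fused",
        f"audio band {config.audio_band_hz[0]:g}-{config.audio_band_hz[1]:g} Hz "
        f"at {config.audio_target_rate_hz:g} Hz",
        f"BIS probes {config.bis_probe_freqs_hz[0]:g} / "
        f"{config.bis_probe_freqs_hz[1]:g} Hz",
        f"significance level alpha = {config.alpha:g}",
    ]

    session_blocks = []
    for b in blocks:
        clean = {k: v for k, v in b.items()
                 if k not in ("breath_table", "_resp_result")}
        session_blocks.append(clean)
    report = {"config": config.as_dict(), "sessions": session_blocks,
              "comparisons": comparisons, "thresholds_log": thresholds_log}

    if out_dir is not None:
        _write_report(report, blocks, Path(out_dir), plots, config)
    return report


def _write_report(report: dict, blocks: Sequence[dict], out_dir: Path,
                  plots: bool, config: AnalysisConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)

    marker_rows, spectral_rows = [], []
    for b in blocks:
        if "breath_table" in b and len(b["breath_table"]):
            b["breath_table"].to_csv(
                out_dir / f"breaths_{b['subject']}_{b['tag']}.csv", index=False)
        if "fluid" in b:
            marker_rows.append({"subject": b["subject"], "tag": b["tag"],
                                **b["fluid"]})
        for ch, f in b.get("spectral", {}).items():
            spectral_rows.append({"subject": b["subject"], "tag": b["tag"],
                                  "channel": ch, **f})
    if marker_rows:
        pd.DataFrame(marker_rows).to_csv(out_dir / "fluid_markers.csv",
                                         index=False)
    if spectral_rows:
        pd.DataFrame(spectral_rows).to_csv(out_dir / "spectral_features.csv",
                                           index=False)
    comp_rows = []
    for metric, c in report["comparisons"].items():
        if c.get("status") == "ok":
            comp_rows.append({"metric": metric, "n_pairs": c["n_pairs"],
                              "test_name": c["test_name"],
                              "statistic": c["statistic"],
                              "p_value": c["p_value"],
                              "significant": c["significant"]})
        else:
            comp_rows.append({"metric": metric, "n_pairs": c["n_pairs"],
                              "test_name": c["status"], "statistic": "",
                              "p_value": "", "significant": ""})
    pd.DataFrame(comp_rows).to_csv(out_dir / "comparisons.csv", index=False)

    if plots:
        from . import plotting
        for b in blocks:
            if "_resp_result" in b:
                plotting.plot_ip_breaths(
                    b["_resp_result"],
                    out_dir / f"ip_{b['subject']}_{b['tag']}.png")


def merge_reports(report_paths: Sequence, alpha: float = 0.05) -> dict:
    """Merge session blocks from several report.json files and recompute the
    paired comparisons across the union."""
    blocks = []
    config = None
    for p in report_paths:
        with open(p, "r", encoding="utf-8") as fh:
            rep = json.load(fh)
        blocks.extend(rep.get("sessions", []))
        config = config or rep.get("config")
    comparisons = {}
    for metric in _COMPARED_METRICS:
        adm, dis, subjects = _paired_values(blocks, metric)
        if len(adm) < 3:
            comparisons[metric] = {"status": "insufficient pairs",
                                   "n_pairs": len(adm)}
            continue
        res = compare_paired(adm, dis, alpha=alpha)
        comparisons[metric] = {
            "status": "ok", "subjects": subjects, "n_pairs": res.n_pairs,
            "test_name": res.test_name, "statistic": res.statistic,
            "p_value": res.p_value, "significant": res.significant}
    return {"config": config, "sessions": blocks, "comparisons": comparisons}
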