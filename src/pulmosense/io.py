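"""On-disk session layout: one directory per measurement.

Layout (all text except PCM WAV audio)::

    <session>/
        meta.yaml        subject, tag, posture, per-channel rates/units
        audio_chN.wav    mono 16-bit PCM, one file per audio channel
        ip_fKK.csv       time_s, r_ohm [, x_ohm]; KK = excitation kHz
        bis.csv          sweep_index, frequency_hz, r_ohm, x_ohm [, timestamp_s]
        imu_<axis>.csv   time_s, value          (optional)
        temperature.csv  time_s, temp_c          (optional)

CSV dialect is fixed: comma separated, header row, '.' decimal, UTF-8,
times in seconds from session start. Floats are written with full
precision, so CSV-backed channels round-trip bit-exactly; audio round-trips
within 16-bit PCM quantization.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .core import Session, SessionFormatError, TimeSeries
from .fluid import BISweep

_IP_RE = re.compile(r"^ip_f(\d+)\.csv$")
_AUDIO_RE = re.compile(r"^audio_ch(\d+)\.wav$")
_IMU_RE = re.compile(r"^imu_([a-z0-9]+)\.csv$")

_FLOAT_FMT = "%.17g"


def _read_csv(path: Path, required: tuple) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise SessionFormatError(f"{path.name}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(
            f"{path.name}, line 1: missing required column(s) {missing}, "
            f"found {list(df.columns)}")
    return df


def _series_from_frame(df: pd.DataFrame, value_col: str, meta: dict,
                       name: str) -> TimeSeries:
    t = df["time_s"].to_numpy(dtype=float)
    info = meta.get("channels", {}).get(name, {})
    if "rate" in info:
        rate = float(info["rate"])
        start = float(info.get("start_time", t[0] if len(t) else 0.0))
    elif len(t) >= 2:
        rate = (len(t) - 1) / (t[-1] - t[0])
        start = float(t[0])
    else:
        rate, start = 1.0, float(t[0]) if len(t) else 0.0
    return TimeSeries(df[value_col].to_numpy(dtype=float), rate=rate,
                      start_time=start, units=info.get("units", ""),
                      label=name)


def write_session(session: Session, directory, overwrite: bool = False) -> None:
    """Write a session to ``directory`` in the documented layout.

    Refuses to overwrite an existing non-empty directory unless
    ``overwrite=True``.
    """
    session.validate()
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} exists and is not empty (pass overwrite=True)")
    directory.mkdir(parents=True, exist_ok=True)

    meta = {"subject": session.subject, "tag": session.tag,
            "posture": session.posture, "channels": {}}

    for khz in sorted(session.ip_channels):
        ts = session.ip_channels[khz]
        name = f"ip_f{khz}"
        cols = {"time_s": ts.times(), "r_ohm": ts.values}
        if khz in session.ip_reactance:
            cols["x_ohm"] = session.ip_reactance[khz].values
        pd.DataFrame(cols).to_csv(directory / f"{name}.csv", index=False,
                                  float_format=_FLOAT_FMT)
        meta["channels"][name] = {"rate": float(ts.rate),
                                  "start_time": float(ts.start_time),
                                  "units": ts.units or "ohm"}

    for ch_id in sorted(session.audio_channels):
        ts = session.audio_channels[ch_id]
        pcm = np.clip(np.round(ts.values * 32767.0), -32768, 32767).astype(np.int16)
        wavfile.write(directory / f"audio_ch{ch_id}.wav", int(round(ts.rate)), pcm)
        meta["channels"][f"audio_ch{ch_id}"] = {
            "rate": float(ts.rate), "start_time": float(ts.start_time),
            "units": ts.units or "a.u."}

    if session.bis_sweeps:
        rows = []
        for i, sw in enumerate(session.bis_sweeps):
            for f, z in zip(sw.freqs, sw.impedances):
                rows.append((i, f, z.real, z.imag, sw.timestamp))
        pd.DataFrame(rows, columns=["sweep_index", "frequency_hz", "r_ohm",
                                    "x_ohm", "timestamp_s"]
                     ).to_csv(directory / "bis.csv", index=False,
                              float_format=_FLOAT_FMT)

    for axis, ts in sorted(session.imu.items()):
        pd.DataFrame({"time_s": ts.times(), "value": ts.values}
                     ).to_csv(directory / f"imu_{axis}.csv", index=False,
                              float_format=_FLOAT_FMT)
        meta["channels"][f"imu_{axis}"] = {"rate": float(ts.rate),
                                           "start_time": float(ts.start_time),
                                           "units": ts.units or "m/s^2"}

    if session.temperature is not None:
        ts = session.temperature
        pd.DataFrame({"time_s": ts.times(), "temp_c": ts.values}
                     ).to_csv(directory / "temperature.csv", index=False,
                              float_format=_FLOAT_FMT)
        meta["channels"]["temperature"] = {"rate": float(ts.rate),
                                           "start_time": float(ts.start_time),
                                           "units": ts.units or "degC"}

    with open(directory / "meta.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_session(directory) -> Session:
    """Read a session directory written by :func:`write_session`.

    Missing optional channels yield absent entries; a directory with no
    recognized channel files raises ``SessionFormatError``.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such session directory: {directory}")

    meta = {}
    meta_path = directory / "meta.yaml"
    if meta_path.exists():
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = yaml.safe_load(fh) or {}

    session = Session(subject=str(meta.get("subject", directory.name)),
                      tag=str(meta.get("tag", "admission")),
                      posture=str(meta.get("posture", "")))

    for path in sorted(directory.iterdir()):
        m = _IP_RE.match(path.name)
        if m:
            khz = int(m.group(1))
            df = _read_csv(path, ("time_s", "r_ohm"))
            session.ip_channels[khz] = _series_from_frame(
                df, "r_ohm", meta, f"ip_f{khz}")
            if "x_ohm" in df.columns:
                session.ip_reactance[khz] = _series_from_frame(
                    df, "x_ohm", meta, f"ip_f{khz}")
            continue
        m = _AUDIO_RE.match(path.name)
        if m:
            ch_id = int(m.group(1))
            rate, data = wavfile.read(path)
            if data.ndim != 1:
                raise SessionFormatError(
                    f"{path.name}: expected mono audio, got "
                    f"{data.shape[1]} channels")
            if data.dtype == np.int16:
                values = data.astype(float) / 32767.0
            elif data.dtype == np.int32:          # 24/32-bit PCM
                values = data.astype(float) / 2147483647.0
            else:
                values = data.astype(float)
            info = meta.get("channels", {}).get(f"audio_ch{ch_id}", {})
            session.audio_channels[ch_id] = TimeSeries(
                values, rate=float(rate),
                start_time=float(info.get("start_time", 0.0)),
                units=info.get("units", "a.u."), label=f"audio_ch{ch_id}")
            continue
        m = _IMU_RE.match(path.name)
        if m:
            df = _read_csv(path, ("time_s", "value"))
            session.imu[m.group(1)] = _series_from_frame(
                df, "value", meta, f"imu_{m.group(1)}")
            continue
        if path.name == "bis.csv":
            df = _read_csv(path, ("sweep_index", "frequency_hz", "r_ohm", "x_ohm"))
            for idx, grp in df.groupby("sweep_index", sort=True):
                ts = float(grp["timestamp_s"].iloc[0]) if "timestamp_s" in grp else 0.0
                grp = grp.sort_values("frequency_hz")
                session.bis_sweeps.append(BISweep(
                    freqs=grp["frequency_hz"].to_numpy(float),
                    impedances=grp["r_ohm"].to_numpy(float)
                    + 1j * grp["x_ohm"].to_numpy(float),
                    timestamp=ts))
            continue
        if path.name == "temperature.csv":
            df = _read_csv(path, ("time_s", "temp_c"))
            session.temperature = _series_from_frame(df, "temp_c", meta,
                                                     "temperature")

    if not (session.ip_channels or session.audio_channels or session.bis_sweeps):
        raise SessionFormatError(f"{directory}: no recognized channels")
    return session
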