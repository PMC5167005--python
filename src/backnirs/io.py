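"""On-disk study layout: plain TSV recordings plus JSON metadata.

One directory per subject containing ``od.tsv`` (time_s, then one
``ch{n}_{wavelength}`` column per channel-wavelength OD trace),
``protocol.tsv`` (condition, onset_s, duration_s), ``hr.tsv`` (time_s,
bpm) and ``params.json``; the study root holds ``probe.yaml`` and a
``manifest.json`` with the seed, parameter hash and package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .heartrate import HeartRateSeries
from .simulate import Oscillator, SimulationParams, StimulusEvent, StimulusProtocol
from .timeseries import ChannelTimeSeries


def write_recording_tsv(path, series: ChannelTimeSeries) -> None:
    cols = {"time_s": np.round(series.times_s, 6)}
    for i, (ch, band) in enumerate(series.labels):
        cols[f"ch{ch}_{band}"] = series.values[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_recording_tsv(path, sampling_rate_hz: float,
                       kind: str = "optical_density") -> ChannelTimeSeries:
    df = pd.read_csv(path, sep="\t")
    labels = []
    rows = []
    for col in df.columns:
        if col == "time_s":
            continue
        ch, band = col.removeprefix("ch").split("_")
        band = int(band) if band.isdigit() else band
        labels.append((int(ch), band))
        rows.append(df[col].to_numpy())
    t0 = float(df["time_s"].iloc[0]) if len(df) else 0.0
    return ChannelTimeSeries(np.vstack(rows), labels, sampling_rate_hz, t0, kind)


def write_protocol_tsv(path, protocol: StimulusProtocol) -> None:
    df = pd.DataFrame([{"condition": e.condition, "onset_s": e.onset_s,
                        "duration_s": e.duration_s} for e in protocol.events])
    with open(path, "w") as fh:
        fh.write(f"# baseline_s={protocol.baseline_s}\tisi_s={protocol.isi_s}"
                 f"\tsampling_rate_hz={protocol.sampling_rate_hz}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_protocol_tsv(path) -> StimulusProtocol:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(item.split("=") for item in header.lstrip("# ").split("\t"))
        df = pd.read_csv(fh, sep="\t")
    events = [StimulusEvent(r.condition, float(r.onset_s), float(r.duration_s))
              for r in df.itertuples()]
    return StimulusProtocol(float(meta["baseline_s"]), float(meta["isi_s"]),
                            events, float(meta["sampling_rate_hz"]))


def write_hr_tsv(path, hr: HeartRateSeries) -> None:
    t = hr.t0_s + np.arange(len(hr.bpm)) / hr.sampling_rate_hz
    pd.DataFrame({"time_s": t, "bpm": hr.bpm}).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_hr_tsv(path) -> HeartRateSeries:
    df = pd.read_csv(path, sep="\t")
    t0 = float(df["time_s"].iloc[0]) if len(df) else 0.0
    return HeartRateSeries(df["bpm"].to_numpy(), 1.0, t0)


def _params_to_jsonable(params: SimulationParams) -> dict:
    doc = dataclasses.asdict(params)
    doc["hrf_amplitude"] = {"|".join(k): v for k, v in params.hrf_amplitude.items()}
    doc["channel_amplitude_offsets"] = {
        "|".join(k): {str(ch): x for ch, x in v.items()}
        for k, v in params.channel_amplitude_offsets.items()}
    doc["oscillators"] = [dataclasses.asdict(o) for o in params.oscillators]
    return doc


def write_params_json(path, params: SimulationParams) -> None:
    with open(path, "w") as fh:
        json.dump(_params_to_jsonable(params), fh, indent=1)


def read_params_json(path) -> SimulationParams:
    with open(path) as fh:
        doc = json.load(fh)
    doc["hrf_amplitude"] = {tuple(k.split("|")): v
                            for k, v in doc["hrf_amplitude"].items()}
    doc["channel_amplitude_offsets"] = {
        tuple(k.split("|")): {int(ch): x for ch, x in v.items()}
        for k, v in doc["channel_amplitude_offsets"].items()}
    doc["oscillators"] = [Oscillator(**o) for o in doc["oscillators"]]
    return SimulationParams(**doc)


def config_hash(obj) -> str:
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(path, seed: int, config: dict) -> None:
    doc = {"package": "backnirs", "version": __version__, "seed": seed,
           "config": config, "config_hash": config_hash(config)}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def subject_dirs(study_dir) -> list[Path]:
    root = Path(study_dir)
    return sorted(p for p in root.iterdir()
                  if p.is_dir() and p.name.startswith("subject"))


def write_report_tsv(path, frame: pd.DataFrame, seed: int, cfg_hash: str) -> None:
    """Tidy TSV with a provenance header (version, seed, config hash)."""
    with open(path, "w") as fh:
        fh.write(f"# backnirs {__version__}\tseed={seed}\tconfig={cfg_hash}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")
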