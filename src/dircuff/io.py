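"""Recording container: little-endian float32 binaries plus a JSON sidecar.

Layout of a recording directory::

    recording.json   sidecar: channel table (name, file, n_samples,
                     sampling_rate, units), optional scenario-config echo
    neural.f32       (4, n) contact voltages, channel-major, µV
    ecg.f32 / bp.f32 / ggemg.f32   single channels at their own rates
    manifest.json    ground-truth manifest (synthetic recordings only)

A CSV export is provided for short fixtures (≤ 10 s).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .construct import ContactTraces
from .synth import Channel, GroundTruthManifest, SyntheticRecording


def write_recording(directory, recording: SyntheticRecording, config_echo: dict | None = None) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    neural = recording.contacts.stack().astype("<f4")
    neural.tofile(d / "neural.f32")
    channels = [
        {
            "name": "neural",
            "file": "neural.f32",
            "n_channels": 4,
            "n_samples": recording.contacts.n_samples,
            "sampling_rate": recording.contacts.sampling_rate,
            "units": "uV",
        }
    ]
    for ch in (recording.ecg, recording.bp, recording.ggemg):
        fname = f"{ch.name.lower()}.f32"
        ch.data.astype("<f4").tofile(d / fname)
        channels.append(
            {
                "name": ch.name,
                "file": fname,
                "n_channels": 1,
                "n_samples": ch.data.size,
                "sampling_rate": ch.sampling_rate,
                "units": ch.units,
            }
        )
    sidecar = {"format": "dircuff-recording/1", "channels": channels}
    if config_echo is not None:
        sidecar["config"] = config_echo
    with open(d / "recording.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    recording.manifest.to_json(d / "manifest.json")
    return d


def read_recording(directory) -> SyntheticRecording:
    d = Path(directory)
    with open(d / "recording.json") as fh:
        sidecar = json.load(fh)
    by_name = {c["name"]: c for c in sidecar["channels"]}
    nc = by_name["neural"]
    neural = np.fromfile(d / nc["file"], dtype="<f4").reshape(nc["n_channels"], nc["n_samples"])
    contacts = ContactTraces(*neural.astype(float), sampling_rate=nc["sampling_rate"])
    chans = {}
    for name in ("ECG", "BP", "GGEMG"):
        c = by_name[name]
        data = np.fromfile(d / c["file"], dtype="<f4").astype(float)
        chans[name] = Channel(data, c["sampling_rate"], c["units"], name)
    manifest = GroundTruthManifest.from_json(d / "manifest.json")
    return SyntheticRecording(contacts, chans["ECG"], chans["BP"], chans["GGEMG"], manifest)


def export_csv(directory, recording: SyntheticRecording, max_duration_s: float = 10.0) -> Path:
    """Plain-text export of a short recording's neural channels."""
    if recording.contacts.duration > max_duration_s:
        raise ValueError("CSV export is limited to short fixtures (≤ 10 s)")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    fs = recording.contacts.sampling_rate
    df = pd.DataFrame(recording.contacts.stack().T, columns=["v1", "v2", "v3", "v4"])
    df.insert(0, "time_s", np.arange(len(df)) / fs)
    path = d / "neural.csv"
    df.to_csv(path, index=False, float_format="%.6g")
    return path
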