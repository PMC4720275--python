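"""On-disk formats: epoch container, EDF and BrainVision readers/writers.

The epoch container is a directory holding ``data.npy`` (trials x channels
x time, float64, little-endian, C order) and ``meta.json`` (time axis,
channel labels, trial labels, bookkeeping).

The EDF and BrainVision implementations are deliberately minimal, covering
the subset of each format that plain continuous EEG uses: EDF with
identical sampling rate on every signal; BrainVision with a binary
multiplexed IEEE float32 / int16 data file and a standard marker file.
Writers exist mainly to enable round-trip testing and data exchange.
"""

from __future__ import annotations

import configparser
import json
import warnings
from pathlib import Path

import numpy as np

from .preprocess import ContinuousRecording, EpochSet
from .protocol import StimulusEvent, StimulusType, enumerate_stimulus_types


# ---------------------------------------------------------------------------
# epoch container

def save_epochs(ep: EpochSet, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / "data.npy", np.ascontiguousarray(ep.data, dtype="<f8"))
    meta = {
        "fs_hz": ep.fs_hz,
        "time_axis_ms": ep.time_axis_ms.tolist(),
        "channel_labels": list(ep.channel_labels),
        "labels": [[l.frequency_hz, l.modality] for l in ep.labels],
        "bad_channel_log": list(ep.bad_channel_log),
        "rejected_trials": list(map(int, ep.rejected_trials)),
        "shape": list(ep.data.shape),
        "dtype": "<f8",
        "order": "C",
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=1))


def load_epochs(directory: str | Path) -> EpochSet:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    data = np.load(directory / "data.npy")
    if list(data.shape) != meta["shape"]:
        raise ValueError("epoch container shape mismatch between data and metadata")
    return EpochSet(
        data=data,
        time_axis_ms=np.asarray(meta["time_axis_ms"], dtype=float),
        channel_labels=list(meta["channel_labels"]),
        labels=[StimulusType(int(f), m) for f, m in meta["labels"]],
        fs_hz=float(meta["fs_hz"]),
        bad_channel_log=list(meta.get("bad_channel_log", [])),
        rejected_trials=list(meta.get("rejected_trials", [])),
    )


# ---------------------------------------------------------------------------
# EDF (European Data Format), continuous signals, uniform rate

def _edf_field(text: str, width: int) -> bytes:
    s = text[:width].ljust(width)
    return s.encode("ascii")


def write_edf(rec: ContinuousRecording, path: str | Path,
              record_duration_s: float = 1.0) -> None:
    """Write a minimal EDF file (int16 samples, physical range from data)."""
    path = Path(path)
    ns = rec.n_channels
    spr = int(round(record_duration_s * rec.fs_hz))      # samples per record
    n_records = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((ns, n_records * spr))
    padded[:, :rec.n_samples] = rec.data

    phys_min = float(min(padded.min(), -1.0))
    phys_max = float(max(padded.max(), 1.0))
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * scale + dig_min).astype("<i2")

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),                       # patient id
        _edf_field("Startdate X X X X", 80),             # recording id
        _edf_field("01.01.00", 8), _edf_field("00.00.00", 8),
        _edf_field(str(256 * (1 + ns)), 8),
        _edf_field("", 44),
        _edf_field(str(n_records), 8),
        _edf_field(f"{record_duration_s:g}", 8),
        _edf_field(str(ns), 4),
    ])
    per = b"".join([
        b"".join(_edf_field(l, 16) for l in rec.channel_labels),
        b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(_edf_field("uV", 8) for _ in range(ns)),
        b"".join(_edf_field(f"{phys_min:.8g}"[:8], 8) for _ in range(ns)),
        b"".join(_edf_field(f"{phys_max:.8g}"[:8], 8) for _ in range(ns)),
        b"".join(_edf_field(str(dig_min), 8) for _ in range(ns)),
        b"".join(_edf_field(str(dig_max), 8) for _ in range(ns)),
        b"".join(_edf_field("", 80) for _ in range(ns)),
        b"".join(_edf_field(str(spr), 8) for _ in range(ns)),
        b"".join(_edf_field("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + per)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path: str | Path,
             events: list[StimulusEvent] | None = None) -> ContinuousRecording:
    """Read a continuous EDF file; all signals must share one sampling rate."""
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError("truncated EDF header")
        n_records = int(head[236:244].decode("ascii").strip())
        rec_dur = float(head[244:252].decode("ascii").strip())
        ns = int(head[252:256].decode("ascii").strip())
        per = fh.read(256 * ns)

        # layout offsets in bytes within the per-signal block
        def block(start_bytes: int, width: int) -> list[str]:
            return [per[start_bytes + i * width: start_bytes + (i + 1) * width]
                    .decode("ascii").strip() for i in range(ns)]

        labels = block(0, 16)
        phys_min = np.array([float(v) for v in block(ns * (16 + 80 + 8), 8)])
        phys_max = np.array([float(v) for v in block(ns * (16 + 80 + 8 + 8), 8)])
        dig_min = np.array([float(v) for v in block(ns * (16 + 80 + 8 + 8 + 8), 8)])
        dig_max = np.array([float(v) for v in block(ns * (16 + 80 + 8 + 8 + 8 + 8), 8)])
        spr = np.array([int(v) for v in
                        block(ns * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80), 8)])
        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates are not supported")
        spr0 = int(spr[0])
        fs = spr0 / rec_dur

        raw = np.frombuffer(fh.read(2 * spr0 * ns * n_records), dtype="<i2")
        raw = raw.reshape(n_records, ns, spr0)
        data = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
        gain = (phys_max - phys_min) / (dig_max - dig_min)
        data = (data - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    return ContinuousRecording(data=data, fs_hz=fs, channel_labels=labels,
                               events=list(events or []))


# ---------------------------------------------------------------------------
# BrainVision (vhdr / vmrk / binary data)

_STYPE_INDEX = {s: i + 1 for i, s in enumerate(enumerate_stimulus_types())}
_INDEX_STYPE = {i: s for s, i in _STYPE_INDEX.items()}


def write_brainvision(rec: ContinuousRecording, vhdr_path: str | Path,
                      binary_format: str = "IEEE_FLOAT_32") -> None:
    """Write vhdr + vmrk + multiplexed binary data.

    Stimulus events become ``Stimulus,S  <k>`` markers where k is the 1-based
    index of the stimulus type in canonical order.
    """
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.with_suffix("")
    eeg_path, vmrk_path = stem.with_suffix(".eeg"), stem.with_suffix(".vmrk")

    if binary_format == "IEEE_FLOAT_32":
        payload = rec.data.T.astype("<f4").tobytes()     # multiplexed
        fmt_lines = "BinaryFormat=IEEE_FLOAT_32\n"
        resolutions = [1.0] * rec.n_channels
    elif binary_format == "INT_16":
        res = np.maximum(np.abs(rec.data).max(axis=1) / 32000.0, 1e-6)
        payload = np.round(rec.data / res[:, None]).T.astype("<i2").tobytes()
        fmt_lines = "BinaryFormat=INT_16\n"
        resolutions = res.tolist()
    else:
        raise ValueError(f"unsupported BinaryFormat {binary_format!r}")
    eeg_path.write_bytes(payload)

    sampling_interval_us = 1e6 / rec.fs_hz
    chan_lines = "".join(
        f"Ch{i+1}={label},,{resolutions[i]:.10g},µV\n"
        for i, label in enumerate(rec.channel_labels))
    vhdr_path.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg_path.name}\n"
        f"MarkerFile={vmrk_path.name}\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={rec.n_channels}\n"
        f"SamplingInterval={sampling_interval_us:.10g}\n"
        "[Binary Infos]\n" + fmt_lines +
        "[Channel Infos]\n" + chan_lines,
        encoding="utf-8")

    marker_lines = ["Mk1=New Segment,,1,1,0"]
    for i, ev in enumerate(rec.events):
        pos = int(round(ev.onset_ms * rec.fs_hz / 1000.0)) + 1   # 1-based
        k = _STYPE_INDEX[ev.stype]
        marker_lines.append(f"Mk{i+2}=Stimulus,S{k:>3},{pos},1,0")
    vmrk_path.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg_path.name}\n"
        "[Marker Infos]\n" + "\n".join(marker_lines) + "\n",
        encoding="utf-8")


def read_brainvision(vhdr_path: str | Path) -> ContinuousRecording:
    """Read a BrainVision triple; stimulus markers map back to stimulus types."""
    vhdr_path = Path(vhdr_path)
    cp = configparser.ConfigParser(strict=False, interpolation=None)
    text = vhdr_path.read_text(encoding="utf-8")
    cp.read_string(text[text.index("["):])

    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError("only BINARY DataFormat supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation supported")
    n_channels = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    data_file = vhdr_path.parent / common["DataFile"]
    marker_file = vhdr_path.parent / common["MarkerFile"] \
        if "MarkerFile" in common else None

    labels, resolutions = [], []
    for i in range(n_channels):
        parts = cp["Channel Infos"][f"Ch{i+1}"].split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)

    fmt = cp["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32").upper()
    raw = data_file.read_bytes()
    if fmt == "IEEE_FLOAT_32":
        arr = np.frombuffer(raw, dtype="<f4")
    elif fmt == "INT_16":
        arr = np.frombuffer(raw, dtype="<i2")
    else:
        raise ValueError(f"unsupported BinaryFormat {fmt!r}")
    data = arr.reshape(-1, n_channels).T.astype(float) \
        * np.asarray(resolutions)[:, None]

    events: list[StimulusEvent] = []
    if marker_file is not None and marker_file.exists():
        mcp = configparser.ConfigParser(strict=False, interpolation=None)
        mtext = marker_file.read_text(encoding="utf-8")
        mcp.read_string(mtext[mtext.index("["):])
        for key, val in mcp["Marker Infos"].items():
            parts = val.split(",")
            if parts[0].strip() != "Stimulus":
                continue
            desc = parts[1].strip()
            try:
                k = int(desc.lstrip("Ss").strip())
            except ValueError:
                warnings.warn(f"unrecognized stimulus marker {desc!r}; skipped")
                continue
            if k not in _INDEX_STYPE:
                warnings.warn(f"stimulus code {k} outside the 12-type space; skipped")
                continue
            onset_ms = (int(parts[2]) - 1) * 1000.0 / fs
            events.append(StimulusEvent(onset_ms, _INDEX_STYPE[k]))
    events.sort(key=lambda e: e.onset_ms)
    return ContinuousRecording(data=data, fs_hz=fs, channel_labels=labels,
                               events=events)


# ---------------------------------------------------------------------------
# plain numeric matrix

def read_matrix(path: str | Path, fs_hz: float,
                channel_labels: list[str] | None = None,
                events: list[StimulusEvent] | None = None) -> ContinuousRecording:
    """Load a channels x samples matrix from .npy or delimited text."""
    path = Path(path)
    if path.suffix == ".npy":
        data = np.load(path)
    else:
        data = np.loadtxt(path, delimiter="," if path.suffix == ".csv" else None)
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = channel_labels or [f"ch{i}" for i in range(data.shape[0])]
    return ContinuousRecording(data=data, fs_hz=fs_hz, channel_labels=labels,
                               events=list(events or []))
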