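"""File readers and writers: EDF, BrainVision, TSV matrices, HDF5 bundles.

The EDF and BrainVision codecs are deliberately minimal, self-contained
implementations of the published formats (fixed-width ASCII header plus
16-bit records for EDF; INI-style header plus raw binary for BrainVision),
covering what the pipeline needs: continuous multichannel data in
microvolts, channel labels, sampling rate and, for BrainVision, stimulus
markers.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import EEGRecording, SegmentSet

__all__ = [
    "write_edf", "read_edf",
    "write_brainvision", "read_brainvision",
    "write_tsv_recording", "read_tsv_recording",
    "write_pli_tsv", "read_pli_tsv",
    "save_recordings_h5", "load_recordings_h5",
    "save_segments_h5", "load_segments_h5",
    "read_eeg",
]


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: EEGRecording, path) -> None:
    """Write a recording as EDF (16-bit, per-channel physical scaling).

    Uses 1-s data records when the sample count divides evenly by the
    (integral) sampling rate, otherwise a single record spanning the file.
    """
    path = Path(path)
    n_ch, n = recording.n_channels, recording.n_samples
    fs = recording.fs
    if float(fs).is_integer() and n % int(fs) == 0:
        spr, record_dur = int(fs), 1.0
        n_records = n // spr
    else:
        spr, record_dur = n, n / fs
        n_records = 1

    pmin = recording.data.min(axis=1)
    pmax = recording.data.max(axis=1)
    flat = pmax - pmin < 1e-9
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)
    dmin, dmax = -32768, 32767

    header = b"".join([
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field(f"Startdate X X X X cond_{recording.condition or 'none'}", 80),
        _edf_field("01.01.20", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + n_ch), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(f"{record_dur:g}", 8),
        _edf_field(n_ch, 4),
    ])
    for getter, width in [
        (lambda i: recording.labels[i], 16),
        (lambda i: "", 80),
        (lambda i: "uV", 8),
        (lambda i: f"{pmin[i]:.6g}", 8),
        (lambda i: f"{pmax[i]:.6g}", 8),
        (lambda i: dmin, 8),
        (lambda i: dmax, 8),
        (lambda i: "", 80),
        (lambda i: spr, 8),
        (lambda i: "", 32),
    ]:
        header += b"".join(_edf_field(getter(i), width) for i in range(n_ch))

    # re-read the header's own (string-rounded) physical range so that the
    # round trip is limited by 16-bit quantization only
    pmin_r = np.array([float(f"{v:.6g}") for v in pmin])
    pmax_r = np.array([float(f"{v:.6g}") for v in pmax])
    scale = (dmax - dmin) / (pmax_r - pmin_r)
    digital = np.round((recording.data - pmin_r[:, None]) * scale[:, None] + dmin)
    digital = np.clip(digital, dmin, dmax).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path, channels: list[str] | None = None) -> EEGRecording:
    """Read an EDF/EDF+ continuous file into microvolts."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header field: {exc}") from None
        sig = fh.read(256 * n_ch)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                    for i in range(n_ch)]

        labels = fields(0, 16)
        pmin = np.array([float(v) for v in fields(16 * 1 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError(f"{path}: mixed per-signal sampling rates unsupported")
        spr0 = spr[0]
        raw = np.frombuffer(fh.read(), dtype="<i2")

    expected = n_records * n_ch * spr0
    if raw.size < expected:
        raise ValueError(f"{path}: expected {expected} samples, found {raw.size}")
    raw = raw[:expected].reshape(n_records, n_ch, spr0)
    data = np.concatenate([raw[r] for r in range(n_records)], axis=1).astype(float)
    scale = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * scale[:, None] + pmin[:, None]
    fs = spr0 / record_dur
    rec = EEGRecording(data=data, fs=fs, labels=labels)
    if channels is not None:
        rec = rec.pick(channels)
    return rec


# ---------------------------------------------------------------------------
# BrainVision
# ---------------------------------------------------------------------------

def write_brainvision(recording: EEGRecording, vhdr_path,
                      onsets_s: np.ndarray | None = None) -> None:
    """Write .vhdr/.eeg (IEEE float32, multiplexed) and a .vmrk with markers."""
    vhdr_path = Path(vhdr_path)
    stem = vhdr_path.with_suffix("")
    eeg_name, vmrk_name = stem.name + ".eeg", stem.name + ".vmrk"
    interval_us = 1e6 / recording.fs
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg_name}",
        f"MarkerFile={vmrk_name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={recording.n_channels}",
        f"SamplingInterval={interval_us:g}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lbl in enumerate(recording.labels, start=1):
        lines.append(f"Ch{i}={lbl},,1,µV")
    vhdr_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    recording.data.T.astype("<f4").tofile(stem.with_suffix(".eeg"))

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg_name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    if onsets_s is not None:
        for k, onset in enumerate(np.asarray(onsets_s, dtype=float), start=2):
            pos = int(round(onset * recording.fs)) + 1  # 1-based
            mlines.append(f"Mk{k}=Stimulus,S  1,{pos},1,0")
    stem.with_suffix(".vmrk").write_text("\n".join(mlines) + "\n", encoding="utf-8")


def _parse_vhdr_sections(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = sections.setdefault(m.group(1), {})
            continue
        if current is not None and "=" in line:
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
    return sections


def read_brainvision(vhdr_path, channels: list[str] | None = None
                     ) -> tuple[EEGRecording, np.ndarray]:
    """Read a BrainVision triplet; returns (recording, stimulus onsets in s).

    Supports IEEE_FLOAT_32 and INT_16 binary data in MULTIPLEXED or
    VECTORIZED orientation, with per-channel resolution scaling.
    """
    vhdr_path = Path(vhdr_path)
    if not vhdr_path.exists():
        raise FileNotFoundError(vhdr_path)
    sections = _parse_vhdr_sections(vhdr_path.read_text(encoding="utf-8"))
    try:
        common = sections["Common Infos"]
        n_ch = int(common["NumberOfChannels"])
        fs = 1e6 / float(common["SamplingInterval"])
        data_file = common["DataFile"]
    except KeyError as exc:
        raise ValueError(f"{vhdr_path}: missing header field {exc}") from None
    fmt = sections.get("Binary Infos", {}).get("BinaryFormat", "IEEE_FLOAT_32")
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()

    labels, resolutions = [], []
    ch_section = sections.get("Channel Infos", {})
    for i in range(1, n_ch + 1):
        entry = ch_section.get(f"Ch{i}", f"ch{i:02d},,1")
        parts = entry.split(",")
        labels.append(parts[0])
        try:
            resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
        except ValueError:
            resolutions.append(1.0)

    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(fmt)
    if dtype is None:
        raise ValueError(f"{vhdr_path}: unsupported BinaryFormat={fmt}")
    raw = np.fromfile(vhdr_path.parent / data_file, dtype=dtype).astype(float)
    if raw.size % n_ch:
        raise ValueError(f"{vhdr_path}: data size not divisible by channel count")
    if orientation == "MULTIPLEXED":
        data = raw.reshape(-1, n_ch).T
    elif orientation == "VECTORIZED":
        data = raw.reshape(n_ch, -1)
    else:
        raise ValueError(f"{vhdr_path}: unsupported DataOrientation={orientation}")
    data = data * np.asarray(resolutions)[:, None]

    onsets: list[float] = []
    marker_file = common.get("MarkerFile")
    if marker_file and (vhdr_path.parent / marker_file).exists():
        msec = _parse_vhdr_sections(
            (vhdr_path.parent / marker_file).read_text(encoding="utf-8"))
        for key, val in msec.get("Marker Infos", {}).items():
            parts = val.split(",")
            if parts and parts[0] == "Stimulus" and len(parts) >= 3:
                onsets.append((int(parts[2]) - 1) / fs)

    rec = EEGRecording(data=data, fs=fs, labels=labels)
    if channels is not None:
        rec = rec.pick(channels)
    return rec, np.array(sorted(onsets))


# ---------------------------------------------------------------------------
# plain-text matrices
# ---------------------------------------------------------------------------

def write_tsv_recording(recording: EEGRecording, path) -> None:
    """Channels x samples TSV (first column = label) plus a JSON sidecar with fs."""
    path = Path(path)
    df = pd.DataFrame(recording.data, index=recording.labels)
    df.index.name = "label"
    df.to_csv(path, sep="\t", float_format="%.6g")
    sidecar = {"sampling_rate": recording.fs, "condition": recording.condition}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_tsv_recording(path, fs: float | None = None) -> EEGRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    condition = None
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = fs if fs is not None else meta.get("sampling_rate")
        condition = meta.get("condition")
    if fs is None:
        raise ValueError(f"{path}: sampling rate not given and no sidecar found")
    return EEGRecording(data=df.to_numpy(), fs=float(fs),
                        labels=[str(x) for x in df.index], condition=condition)


def write_pli_tsv(values: np.ndarray, labels: list[str], path) -> None:
    df = pd.DataFrame(values, index=labels, columns=labels)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_pli_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(c) for c in df.columns]


# ---------------------------------------------------------------------------
# HDF5 bundles
# ---------------------------------------------------------------------------

def save_recordings_h5(recordings: dict[tuple[str, str], EEGRecording],
                       onsets: dict[tuple[str, str], np.ndarray], path) -> None:
    with h5py.File(path, "w") as fh:
        for (subject, cond), rec in recordings.items():
            grp = fh.create_group(f"{subject}/{cond}")
            grp.create_dataset("data", data=rec.data, compression="gzip", shuffle=True)
            grp.attrs["fs"] = rec.fs
            grp.attrs["labels"] = [s.encode() for s in rec.labels]
            grp.attrs["condition"] = cond
            key = (subject, cond)
            if key in onsets:
                grp.create_dataset("onsets", data=np.asarray(onsets[key], dtype=float))


def load_recordings_h5(path) -> tuple[dict[tuple[str, str], EEGRecording],
                                      dict[tuple[str, str], np.ndarray]]:
    recordings: dict[tuple[str, str], EEGRecording] = {}
    onsets: dict[tuple[str, str], np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        for subject in fh:
            for cond in fh[subject]:
                grp = fh[subject][cond]
                labels = [s.decode() if isinstance(s, bytes) else str(s)
                          for s in grp.attrs["labels"]]
                recordings[(subject, cond)] = EEGRecording(
                    data=grp["data"][()], fs=float(grp.attrs["fs"]), labels=labels,
                    condition=cond)
                if "onsets" in grp:
                    onsets[(subject, cond)] = grp["onsets"][()]
    return recordings, onsets


def save_segments_h5(segsets: dict[tuple[str, str, str], SegmentSet], path) -> None:
    """Keys are (subject, condition, band)."""
    with h5py.File(path, "w") as fh:
        for (subject, cond, band), ss in segsets.items():
            grp = fh.create_group(f"{subject}/{cond}/{band}")
            grp.create_dataset("segments", data=np.stack(ss.segments),
                               compression="gzip", shuffle=True)
            grp.create_dataset("provenance", data=np.asarray(ss.provenance))
            grp.attrs["fs"] = ss.fs
            grp.attrs["labels"] = [s.encode() for s in ss.labels]


def load_segments_h5(path) -> dict[tuple[str, str, str], SegmentSet]:
    out: dict[tuple[str, str, str], SegmentSet] = {}
    with h5py.File(path, "r") as fh:
        for subject in fh:
            for cond in fh[subject]:
                for band in fh[subject][cond]:
                    grp = fh[subject][cond][band]
                    labels = [s.decode() if isinstance(s, bytes) else str(s)
                              for s in grp.attrs["labels"]]
                    out[(subject, cond, band)] = SegmentSet(
                        segments=list(grp["segments"][()]), fs=float(grp.attrs["fs"]),
                        labels=labels, band=band, condition=cond,
                        provenance=list(grp["provenance"][()]))
    return out


def read_eeg(path, format: str | None = None, fs: float | None = None,
             channels: list[str] | None = None) -> EEGRecording:
    """Read EEG from EDF, BrainVision (.vhdr) or TSV, inferring format from suffix."""
    path = Path(path)
    if format is None:
        format = {".edf": "edf", ".vhdr": "brainvision", ".tsv": "tsv"}.get(
            path.suffix.lower())
        if format is None:
            raise ValueError(f"cannot infer EEG format from suffix {path.suffix!r}")
    if format == "edf":
        return read_edf(path, channels)
    if format == "brainvision":
        return read_brainvision(path, channels)[0]
    if format == "tsv":
        rec = read_tsv_recording(path, fs)
        return rec.pick(channels) if channels else rec
    raise ValueError(f"unknown format {format!r}")
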