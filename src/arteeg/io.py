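"""Reading and writing recordings.

Two dialects are supported:

* BrainVision-style triplets (``.vhdr`` header, ``.vmrk`` markers, ``.eeg``
  IEEE float-32 multiplexed binary) — the acquisition format of the study
  hardware. Reading goes through :mod:`mne`, which validates the headers our
  writer emits.
* A plain tab-separated dialect (one column per channel, ``# key: value``
  header lines, a ``marker`` column) for fully text-based round trips.

Ground truth emitted by the synthetic generator travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .recording import Recording

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by arteeg

[Common Infos]
Codepage=UTF-8
DataFile={name}.eeg
MarkerFile={name}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval_us}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
; Ch<nr>=<name>,<ref>,<resolution in µV>,<unit>
{channel_lines}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={name}.eeg

[Marker Infos]
; Mk<nr>=<type>,<description>,<position>,<points>,<channel>
Mk1=New Segment,,1,1,0
{marker_lines}
"""


def write_brainvision(rec: Recording, basepath: str | Path) -> Path:
    """Write ``basepath``.vhdr/.vmrk/.eeg; returns the header path."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name

    ch_lines = "\n".join(
        f"Ch{i + 1}={ch},,1,µV" for i, ch in enumerate(rec.ch_names)
    )
    vhdr = _VHDR_TEMPLATE.format(
        name=name, n_channels=rec.n_channels,
        sampling_interval_us=f"{1e6 / rec.fs:g}", channel_lines=ch_lines,
    )
    (base.with_suffix(".vhdr")).write_text(vhdr, encoding="utf-8")

    mk_lines = "\n".join(
        # BrainVision marker positions are 1-based
        f"Mk{i + 2}=Stimulus,{lbl},{s + 1},1,0"
        for i, (lbl, s) in enumerate(rec.annotations)
    )
    vmrk = _VMRK_TEMPLATE.format(name=name, marker_lines=mk_lines)
    (base.with_suffix(".vmrk")).write_text(vmrk, encoding="utf-8")

    rec.data.T.astype("<f4").tofile(base.with_suffix(".eeg"))
    return base.with_suffix(".vhdr")


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Load a BrainVision triplet through mne and convert back to microvolts."""
    import mne

    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # mne holds volts internally
    ann = []
    for a in raw.annotations:
        desc = a["description"]
        if desc.startswith("Stimulus/"):
            desc = desc.split("/", 1)[1]
        elif desc.startswith("New Segment"):
            continue
        ann.append((desc, int(round(a["onset"] * raw.info["sfreq"]))))
    return Recording(data_uv, list(raw.ch_names), float(raw.info["sfreq"]), ann)


def write_tsv(rec: Recording, path: str | Path) -> Path:
    """Plain delimited dialect: header comments, channel columns, marker column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    markers = {s: lbl for lbl, s in rec.annotations}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# fs_hz: {rec.fs:g}\n")
        fh.write(f"# n_channels: {rec.n_channels}\n")
        fh.write("\t".join(rec.ch_names) + "\tmarker\n")
        for t in range(rec.n_samples):
            row = "\t".join(f"{v:.6f}" for v in rec.data[:, t])
            fh.write(row + "\t" + markers.get(t, "") + "\n")
    return path


def read_tsv(path: str | Path) -> Recording:
    path = Path(path)
    fs = None
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header_end = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            if key.strip() == "fs_hz":
                fs = float(val)
        else:
            header_end = i
            break
    if fs is None:
        raise ValueError(f"{path}: missing '# fs_hz:' header line")
    cols = lines[header_end].split("\t")
    if cols[-1] != "marker":
        raise ValueError(f"{path}: last column must be 'marker'")
    ch_names = cols[:-1]
    data_rows, ann = [], []
    for t, line in enumerate(lines[header_end + 1:]):
        parts = line.split("\t")
        data_rows.append([float(v) for v in parts[:-1]])
        if parts[-1]:
            ann.append((parts[-1], t))
    return Recording(np.array(data_rows).T, ch_names, fs, ann)


def write_ground_truth(truth: dict, path: str | Path) -> Path:
    """JSON sidecar for generator ground truth (arrays become lists)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(truth, indent=1, default=_default), encoding="utf-8")
    return path


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
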