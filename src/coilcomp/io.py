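"""File formats and run reporting.

BrainVision triplets (.vhdr INI dialect, .vmrk marker table, .eeg
binary) are written as multiplexed IEEE 32-bit float and read back
bit-exactly; 16-bit integer data with per-channel resolution scaling is
also read. Tabular results go to CSV with deterministic column order
and fixed float precision; the JSON run report carries the config hash,
seeds, and per-stage provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Montage


@dataclass
class ContinuousRecording:
    """Continuous multichannel record with stimulus markers."""

    data: np.ndarray  # (n_channels, n_samples), uV
    srate: float
    ch_names: tuple
    markers: list  # (description, sample index)
    resolutions: tuple = None

    @property
    def pulse_samples(self) -> list:
        return [s for desc, s in self.markers if desc.startswith("S")]


def write_brainvision(path_base, data: np.ndarray, srate: float, ch_names,
                      markers=(), resolutions=None) -> Path:
    """Write a BrainVision triplet (<base>.vhdr/.vmrk/.eeg), float32 multiplexed.

    ``data`` is (n_channels, n_samples) in microvolts; ``markers`` is a
    sequence of (description, sample_index). Returns the header path.
    """
    base = Path(path_base)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    data = np.asarray(data, dtype=np.float32)
    n_ch, n_samp = data.shape
    if len(ch_names) != n_ch:
        raise ValueError("channel name count mismatch")
    sampling_interval_us = 1e6 / srate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; Written by coilcomp",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        f"MarkerFile={name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:.6g}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, ch in enumerate(ch_names):
        lines.append(f"Ch{i + 1}={ch},,1,µV")
    (base.with_suffix(".vhdr")).write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for k, (desc, samp) in enumerate(markers, start=2):
        mlines.append(f"Mk{k}=Stimulus,{desc},{int(samp) + 1},1,0")
    (base.with_suffix(".vmrk")).write_text("\n".join(mlines) + "\n", encoding="utf-8")

    data.T.astype("<f4").tofile(base.with_suffix(".eeg"))
    return base.with_suffix(".vhdr")


def _parse_ini(text: str) -> dict:
    sections: dict = {}
    current = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = {}
        elif "=" in line and current is not None:
            key, val = line.split("=", 1)
            sections[current][key.strip()] = val.strip()
    return sections


def read_brainvision(header_path) -> ContinuousRecording:
    """Read a BrainVision triplet into a continuous recording.

    Honors multiplexed orientation with IEEE_FLOAT_32 or INT_16 binary
    format (the latter scaled by the per-channel resolution). Raises on
    missing member files, unknown formats, and byte-count mismatches.
    """
    hdr_path = Path(header_path)
    if not hdr_path.exists():
        raise FileNotFoundError(f"header file not found: {hdr_path}")
    sections = _parse_ini(hdr_path.read_text(encoding="utf-8"))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    chinfo = sections.get("Channel Infos", {})

    data_file = hdr_path.parent / common["DataFile"]
    marker_file = hdr_path.parent / common["MarkerFile"]
    if not data_file.exists():
        raise FileNotFoundError(f"data file not found: {data_file}")
    n_ch = int(common["NumberOfChannels"])
    srate = 1e6 / float(common["SamplingInterval"])
    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise ValueError(f"unsupported data orientation: {orientation}")
    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32").upper()
    if fmt == "IEEE_FLOAT_32":
        dtype, itemsize = np.dtype("<f4"), 4
    elif fmt == "INT_16":
        dtype, itemsize = np.dtype("<i2"), 2
    else:
        raise ValueError(f"unknown binary format: {fmt}")

    ch_names, resolutions = [], []
    for i in range(n_ch):
        entry = chinfo.get(f"Ch{i + 1}", f"Ch{i + 1},,1")
        parts = entry.split(",")
        ch_names.append(parts[0])
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    raw = data_file.read_bytes()
    frame = n_ch * itemsize
    if len(raw) % frame != 0:
        n_samp = len(raw) // frame
        raise ValueError(
            f"truncated data file: {len(raw)} bytes is not a multiple of the "
            f"{frame}-byte frame ({n_ch} channels x {itemsize} bytes); "
            f"expected {(n_samp + 1) * frame} or {n_samp * frame} bytes"
        )
    arr = np.frombuffer(raw, dtype=dtype).reshape(-1, n_ch).T
    if fmt == "INT_16":
        arr = arr.astype(np.float64) * np.asarray(resolutions)[:, None]
    else:
        arr = arr.astype(np.float32)

    markers = []
    if marker_file.exists():
        msec = _parse_ini(marker_file.read_text(encoding="utf-8")).get("Marker Infos", {})
        for key in sorted(msec, key=lambda k: int(k[2:])):
            parts = msec[key].split(",")
            mtype, desc = parts[0], parts[1]
            if mtype == "Stimulus":
                markers.append((desc, int(parts[2]) - 1))
    return ContinuousRecording(
        data=arr, srate=srate, ch_names=tuple(ch_names), markers=markers,
        resolutions=tuple(resolutions),
    )


def write_montage(path, montage: Montage) -> Path:
    path = Path(path)
    path.write_text(montage.to_table(), encoding="utf-8")
    return path


def read_montage(path) -> Montage:
    return Montage.from_table(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# results and reports


@dataclass
class RunReport:
    """Append-only provenance for a full run; serializable to JSON."""

    seeds: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    entries: list = field(default_factory=list)

    def add(self, stage: str, **fields) -> None:
        self.entries.append({"stage": stage, **fields})

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.config, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seeds": self.seeds,
            "config": self.config,
            "entries": self.entries,
        }

    def validate(self) -> None:
        d = self.to_dict()
        for key in ("config_hash", "seeds", "config", "entries"):
            if key not in d:
                raise ValueError(f"report missing {key}")
        if not isinstance(d["entries"], list):
            raise ValueError("entries must be a list")
        for e in d["entries"]:
            if "stage" not in e:
                raise ValueError("every entry needs a stage")
        json.dumps(d, default=str)  # must be serializable


def write_results(out_dir, tables: dict, report: RunReport, float_fmt: str = "%.6g") -> dict:
    """Write CSV tables plus the JSON run report; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in sorted(tables.items()):
        p = out / f"{name}.csv"
        pd.DataFrame(df).to_csv(p, index=False, float_format=float_fmt)
        paths[name] = p
    report.validate()
    rp = out / "report.json"
    rp.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True, default=str),
                  encoding="utf-8")
    paths["report"] = rp
    return paths
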