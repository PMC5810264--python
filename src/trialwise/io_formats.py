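"""Readers and writers for the formats the pipeline touches.

BrainVision (.vhdr/.vmrk/.eeg, multiplexed INT_16 / IEEE_FLOAT_32), montage
CSV (label,x,y,z[,type]), the versioned HDF5 trial-store container, and the
long-format CSV export that feeds the mixed-model stage.  Amplitudes are
microvolts everywhere; readers convert at ingestion.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .store import TrialStore, mean_amplitude

__all__ = [
    "RawRecording",
    "ChannelLayout",
    "read_brainvision",
    "write_brainvision",
    "read_montage",
    "write_montage",
    "save_store",
    "load_store",
    "export_long",
]

STORE_SCHEMA_VERSION = 1


@dataclass
class RawRecording:
    """Continuous multichannel recording in microvolts plus event markers."""

    data: np.ndarray                       # channels x samples, uV
    sampling_rate: float                   # Hz
    channel_labels: list[str]
    reference_label: str = "A1"
    events: list[tuple[int, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        n = self.data.shape[1]
        for s, _code in self.events:
            if not 0 <= s < n:
                raise ValueError(f"event sample {s} outside [0, {n})")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ChannelLayout:
    """Ordered channel labels with 3-D positions and a scalp/non-scalp flag."""

    labels: list[str]
    positions: np.ndarray                  # n x 3
    scalp: np.ndarray                      # boolean per channel

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.scalp = np.asarray(self.scalp, dtype=bool)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in layout")
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be n x 3")
        if self.scalp.shape != (len(self.labels),):
            raise ValueError("one scalp flag per channel required")
        bad = [
            l for l, p, s in zip(self.labels, self.positions, self.scalp)
            if s and not np.all(np.isfinite(p))
        ]
        if bad:
            raise ValueError(f"non-finite position for scalp channel(s) {bad}")

    def position_of(self, label: str) -> np.ndarray:
        try:
            return self.positions[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None

    def scalp_labels(self) -> list[str]:
        return [l for l, s in zip(self.labels, self.scalp) if s]


# ---------------------------------------------------------------------------
# BrainVision dialect: multiplexed binary, INT_16 or IEEE_FLOAT_32

_BV_FORMATS = {"INT_16": np.int16, "IEEE_FLOAT_32": np.float32}


def _read_ini(path: Path) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str  # keys are case sensitive (Ch1 vs ch1)
    text = path.read_text(encoding="utf-8", errors="replace")
    # header files start with a non-INI banner line
    body = "\n".join(
        ln for ln in text.splitlines() if not ln.startswith(("Brain Vision", ";"))
    )
    cp.read_string(body)
    return cp


def read_brainvision(header_path: str | Path) -> RawRecording:
    """Read a BrainVision triplet given the .vhdr path; amplitudes in uV."""
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header file not found: {header_path}")
    cp = _read_ini(header_path)
    common = cp["Common Infos"]

    orientation = common.get("DataOrientation", "MULTIPLEXED").upper()
    if orientation != "MULTIPLEXED":
        raise ValueError(
            f"unsupported data orientation {orientation!r}; only MULTIPLEXED "
            "binary files are supported"
        )
    fmt = cp["Binary Infos"].get("BinaryFormat", "").upper()
    if fmt not in _BV_FORMATS:
        raise ValueError(
            f"unsupported binary format {fmt!r}; supported: "
            + ", ".join(_BV_FORMATS)
        )

    n_channels = int(common["NumberOfChannels"])
    sampling_rate = 1e6 / float(common["SamplingInterval"])  # interval in us

    labels, resolutions, reference = [], [], ""
    for i in range(1, n_channels + 1):
        parts = cp["Channel Infos"][f"Ch{i}"].split(",")
        labels.append(parts[0])
        if len(parts) > 1 and parts[1] and not reference:
            reference = parts[1]
        res = parts[2] if len(parts) > 2 and parts[2] else "1"
        resolutions.append(float(res))

    data_file = header_path.parent / common["DataFile"]
    marker_file = header_path.parent / common["MarkerFile"]
    if not data_file.exists():
        raise FileNotFoundError(f"data file referenced by header not found: {data_file}")
    if not marker_file.exists():
        raise FileNotFoundError(
            f"marker file referenced by header not found: {marker_file}"
        )

    raw = np.fromfile(data_file, dtype=_BV_FORMATS[fmt])
    if raw.size % n_channels:
        raise ValueError(
            f"data size {raw.size} not divisible by {n_channels} channels"
        )
    data = raw.reshape(-1, n_channels).T.astype(float)
    data *= np.asarray(resolutions)[:, None]

    events = _read_vmrk(marker_file)
    return RawRecording(
        data=data,
        sampling_rate=sampling_rate,
        channel_labels=labels,
        reference_label=reference or "A1",
        events=events,
        meta={"source": str(header_path)},
    )


def _read_vmrk(path: Path) -> list[tuple[int, str]]:
    cp = _read_ini(path)
    events: list[tuple[int, str]] = []
    if "Marker Infos" not in cp:
        return events
    for key in sorted(cp["Marker Infos"], key=lambda k: int(k[2:])):
        parts = cp["Marker Infos"][key].split(",")
        mtype, desc = parts[0], parts[1] if len(parts) > 1 else ""
        if mtype == "New Segment":
            continue
        position = int(parts[2]) - 1  # 1-based in the file
        events.append((position, desc))
    return events


def write_brainvision(
    rec: RawRecording,
    base_path: str | Path,
    binary_format: str = "INT_16",
) -> tuple[Path, Path, Path]:
    """Write a RawRecording as a BrainVision triplet; returns the three paths.

    INT_16 uses a per-channel resolution of max|x|/32000 uV per bit, so the
    round-trip quantization error is below half a bit step.
    """
    if rec.n_samples == 0:
        raise ValueError("refusing to write a zero-length recording")
    if binary_format not in _BV_FORMATS:
        raise ValueError(f"unsupported binary format {binary_format!r}")
    base = Path(base_path)
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))

    if binary_format == "INT_16":
        peak = np.maximum(np.abs(rec.data).max(axis=1), 1e-12)
        resolutions = peak / 32000.0
        scaled = np.round(rec.data / resolutions[:, None]).astype(np.int16)
    else:
        resolutions = np.ones(rec.data.shape[0])
        scaled = rec.data.astype(np.float32)
    scaled.T.tofile(eeg)  # multiplexed: sample-major

    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.data.shape[0]}",
        f"SamplingInterval={1e6 / rec.sampling_rate:g}",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "[Channel Infos]",
    ]
    for i, (label, res) in enumerate(zip(rec.channel_labels, resolutions), 1):
        ref = rec.reference_label if i == 1 else ""
        lines.append(f"Ch{i}={label},{ref},{res:.10g},µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "[Marker Infos]",
    ]
    for i, (sample, code) in enumerate(rec.events, 1):
        mlines.append(f"Mk{i}=Stimulus,{code},{sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr, vmrk, eeg


# ---------------------------------------------------------------------------
# Montage CSV

def read_montage(path: str | Path) -> ChannelLayout:
    """Read a montage CSV with columns label,x,y,z and optional type.

    ``type`` values other than "scalp" (e.g. "eog", "ref") mark non-scalp
    channels; absent column means all scalp.
    """
    df = pd.read_csv(path)
    required = {"label", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"montage CSV missing column(s): {sorted(missing)}")
    if df["label"].duplicated().any():
        dups = df.loc[df["label"].duplicated(), "label"].tolist()
        raise ValueError(f"duplicate channel label(s) in montage: {dups}")
    coords = df[["x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    if coords.isna().any().any():
        bad = df.loc[coords.isna().any(axis=1), "label"].tolist()
        raise ValueError(f"non-numeric coordinates for channel(s): {bad}")
    if "type" in df.columns:
        scalp = df["type"].astype(str).str.lower().eq("scalp").to_numpy()
    else:
        scalp = np.ones(len(df), dtype=bool)
    return ChannelLayout(
        labels=df["label"].astype(str).tolist(),
        positions=coords.to_numpy(),
        scalp=scalp,
    )


def write_montage(layout: ChannelLayout, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "label": layout.labels,
            "x": layout.positions[:, 0],
            "y": layout.positions[:, 1],
            "z": layout.positions[:, 2],
            "type": np.where(layout.scalp, "scalp", "other"),
        }
    )
    df.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# HDF5 trial-store container

def save_store(store: TrialStore, path: str | Path) -> Path:
    """Persist a TrialStore to HDF5 (versioned schema, lossless)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["trialwise_store_version"] = STORE_SCHEMA_VERSION
        f.create_dataset("amplitudes", data=store.amplitudes)
        f.create_dataset("time_ms", data=store.time_ms)
        f.create_dataset(
            "channel_labels",
            data=np.array(store.channel_labels, dtype=h5py.string_dtype()),
        )
        g = f.create_group("meta")
        g.attrs["columns"] = list(store.meta.columns)
        for col in store.meta.columns:
            vals = store.meta[col]
            if pd.api.types.is_bool_dtype(vals):
                g.create_dataset(col, data=vals.to_numpy(dtype=bool))
                g[col].attrs["kind"] = "bool"
            elif pd.api.types.is_numeric_dtype(vals):
                g.create_dataset(col, data=vals.to_numpy(dtype=float))
                g[col].attrs["kind"] = "float"
            else:
                g.create_dataset(
                    col,
                    data=np.array(
                        vals.astype(str).to_numpy(), dtype=h5py.string_dtype()
                    ),
                )
                g[col].attrs["kind"] = "str"
    return path


def load_store(path: str | Path) -> TrialStore:
    path = Path(path)
    with h5py.File(path, "r") as f:
        version = f.attrs.get("trialwise_store_version")
        if version != STORE_SCHEMA_VERSION:
            raise ValueError(
                f"store schema version {version!r} not supported "
                f"(expected {STORE_SCHEMA_VERSION})"
            )
        amplitudes = f["amplitudes"][()]
        time_ms = f["time_ms"][()]
        labels = [s.decode() if isinstance(s, bytes) else s
                  for s in f["channel_labels"][()]]
        g = f["meta"]
        cols = {}
        for col in g.attrs["columns"]:
            ds = g[col]
            kind = ds.attrs["kind"]
            vals = ds[()]
            if kind == "str":
                vals = np.array(
                    [v.decode() if isinstance(v, bytes) else v for v in vals]
                )
            elif kind == "bool":
                vals = vals.astype(bool)
            cols[col] = vals
        meta = pd.DataFrame(cols)
    return TrialStore(
        amplitudes=amplitudes, time_ms=time_ms, channel_labels=labels, meta=meta
    )


# ---------------------------------------------------------------------------
# Long-format export for the statistics stage

def export_long(
    store: TrialStore,
    channels: Sequence[str],
    window_ms: tuple[float, float],
    path: str | Path,
    amplitude_column: str = "amplitude",
) -> Path:
    """One CSV row per *valid* trial: metadata plus mean ROI amplitude (uV)."""
    path = Path(path)
    vals = mean_amplitude(store, channels, window_ms)
    valid = np.asarray(store.meta["eeg_valid"], dtype=bool)
    out = store.meta.loc[valid].copy()
    out[amplitude_column] = vals[valid]
    out.to_csv(path, index=False)
    return path
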