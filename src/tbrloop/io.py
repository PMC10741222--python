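"""Reading and writing of EEG recordings and event tables.

Supported on-disk formats:

* BrainVision triplets (``.vhdr``/``.vmrk``/``.eeg``), written as
  multiplexed IEEE float32 in microvolts.
* EDF (16-bit integer, documented as lossy; annotations are not stored).
* BIDS-style tab-separated event tables (``onset``, ``duration``,
  ``trial_type`` plus free columns), all times in seconds.

The in-memory containers (:class:`EEGRecording`, :class:`EventTable`) are
the universal currency of the toolkit.
"""

from __future__ import annotations

import os
import re
import struct
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "EventTable",
    "FormatError",
    "UnitError",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "DEFAULT_ECG_NAMES",
]

#: Case-insensitive channel names treated as ECG on read.
DEFAULT_ECG_NAMES = ("ECG",)

_UNIT_TO_UV = {
    "µV": 1.0,
    "uV": 1.0,
    "mV": 1e3,
    "V": 1e6,
}


class FormatError(ValueError):
    """A file does not conform to the named standard."""


class UnitError(FormatError):
    """A channel declares a unit the reader does not understand."""


@dataclass
class EEGRecording:
    """A multichannel recording: ``data`` is channels x samples in µV.

    ``ch_roles`` marks each channel as ``"eeg"`` or ``"ecg"``; exactly the
    channels with role ``"ecg"`` are excluded from scalp-average
    computations downstream. ``annotations`` are ``(onset_s, duration_s,
    label)`` triplets, kept in seconds so resampling does not invalidate
    them. ``metadata`` is free-form ground truth / provenance and is never
    serialized.
    """

    data: np.ndarray
    sfreq: float
    ch_names: list[str]
    ch_roles: list[str]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.ch_names)} channel names"
            )
        if len(self.ch_names) != len(self.ch_roles):
            raise ValueError("ch_names and ch_roles length mismatch")
        if not self.sfreq > 0:
            raise ValueError("sfreq must be positive")
        bad = [r for r in self.ch_roles if r not in ("eeg", "ecg")]
        if bad:
            raise ValueError(f"unknown channel roles: {bad}")
        dur = self.n_samples / self.sfreq
        for onset, d, label in self.annotations:
            if not (0 <= onset <= dur):
                raise ValueError(f"annotation {label!r} onset {onset} outside [0, {dur}]")
            if d < 0:
                raise ValueError(f"annotation {label!r} has negative duration")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq

    def eeg_picks(self) -> np.ndarray:
        """Indices of channels with role ``eeg``."""
        return np.array([i for i, r in enumerate(self.ch_roles) if r == "eeg"], dtype=int)

    def pick(self, name: str) -> np.ndarray:
        """Return the 1-D signal of the named channel."""
        try:
            return self.data[self.ch_names.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def copy(self) -> "EEGRecording":
        return replace(
            self,
            data=self.data.copy(),
            ch_names=list(self.ch_names),
            ch_roles=list(self.ch_roles),
            annotations=list(self.annotations),
            metadata=dict(self.metadata),
        )


class EventTable:
    """Ordered table of ``(onset_s, duration_s, label, metadata)`` rows."""

    def __init__(self, rows=None):
        rows = list(rows or [])
        norm = []
        for r in rows:
            if len(r) == 3:
                onset, duration, label = r
                meta = {}
            else:
                onset, duration, label, meta = r
            if duration < 0:
                raise ValueError(f"event {label!r} has negative duration")
            norm.append((float(onset), float(duration), str(label), dict(meta)))
        onsets = [r[0] for r in norm]
        if onsets != sorted(onsets):
            raise ValueError("event onsets must be non-decreasing")
        self.rows = norm

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def __eq__(self, other):
        return isinstance(other, EventTable) and self.rows == other.rows

    def select(self, label: str) -> "EventTable":
        return EventTable([r for r in self.rows if r[2] == label])

    def to_frame(self) -> pd.DataFrame:
        extra_cols: list[str] = []
        for _, _, _, meta in self.rows:
            for k in meta:
                if k not in extra_cols:
                    extra_cols.append(k)
        recs = []
        for onset, duration, label, meta in self.rows:
            rec = {"onset": onset, "duration": duration, "trial_type": label}
            for k in extra_cols:
                rec[k] = meta.get(k, "")
            recs.append(rec)
        cols = ["onset", "duration", "trial_type"] + extra_cols
        return pd.DataFrame(recs, columns=cols)


# ---------------------------------------------------------------------------
# events TSV

def write_events(table: EventTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_events(path, on_unsorted: str = "raise") -> EventTable:
    """Read a BIDS-style events TSV.

    ``on_unsorted`` controls behavior when onsets are not non-decreasing:
    ``"raise"`` (default) or ``"sort"`` (stable sort with a warning).
    """
    if on_unsorted not in ("raise", "sort"):
        raise ValueError("on_unsorted must be 'raise' or 'sort'")
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing required columns {sorted(required - set(df.columns))}")
    label_col = "trial_type" if "trial_type" in df.columns else "label"
    if label_col not in df.columns:
        raise FormatError(f"{path}: no trial_type/label column")
    for col in ("onset", "duration"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise FormatError(f"{path}: malformed {col} at line {int(bad[0]) + 2}")
    df["onset"] = df["onset"].astype(float)
    df["duration"] = df["duration"].astype(float)
    if not df["onset"].is_monotonic_increasing:
        if on_unsorted == "raise":
            raise FormatError(f"{path}: event onsets are not sorted")
        warnings.warn(f"{path}: unsorted onsets; sorting", stacklevel=2)
        df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    extra = [c for c in df.columns if c not in ("onset", "duration", label_col)]
    rows = []
    for _, row in df.iterrows():
        meta = {c: row[c] for c in extra if not (isinstance(row[c], float) and np.isnan(row[c]))}
        rows.append((row["onset"], row["duration"], row[label_col], meta))
    return EventTable(rows)


# ---------------------------------------------------------------------------
# BrainVision

_VHDR_TEMPLATE = """\
Brain Vision Data Exchange Header File Version 1.0
; Written by tbrloop

[Common Infos]
Codepage=UTF-8
DataFile={datafile}
MarkerFile={markerfile}
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={nchan}
SamplingInterval={sampling_interval}
DataPoints={npts}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channels}
"""

_VMRK_TEMPLATE = """\
Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={datafile}

[Marker Infos]
{markers}
"""


def _write_brainvision(rec: EEGRecording, path: str) -> None:
    base, _ = os.path.splitext(path)
    stem = os.path.basename(base)
    ch_lines = []
    for i, name in enumerate(rec.ch_names):
        # Ch<n>=<name>,<ref>,<resolution>,<unit>
        ch_lines.append(f"Ch{i + 1}={name},,1,µV")
    mk_lines = ["Mk1=New Segment,,1,1,0"]
    for j, (onset, duration, label) in enumerate(rec.annotations, start=2):
        pos = int(round(onset * rec.sfreq)) + 1
        pts = int(round(duration * rec.sfreq))
        safe = str(label).replace(",", r"\,")
        mk_lines.append(f"Mk{j}=Stimulus,{safe},{pos},{pts},0")
    hdr = _VHDR_TEMPLATE.format(
        datafile=stem + ".eeg",
        markerfile=stem + ".vmrk",
        nchan=rec.n_channels,
        sampling_interval=repr(1e6 / rec.sfreq),
        npts=rec.n_samples,
        channels="\n".join(ch_lines),
    )
    with open(base + ".vhdr", "w", encoding="utf-8") as f:
        f.write(hdr)
    with open(base + ".vmrk", "w", encoding="utf-8") as f:
        f.write(_VMRK_TEMPLATE.format(datafile=stem + ".eeg", markers="\n".join(mk_lines)))
    with open(base + ".eeg", "wb") as f:
        rec.data.astype("<f4").T.tofile(f)  # multiplexed: sample-major


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(";"):
            continue
        m = re.match(r"\[(.+)\]$", line)
        if m:
            current = m.group(1)
            sections[current] = {}
            continue
        if current is not None and "=" in line:
            key, _, val = line.partition("=")
            sections[current][key.strip()] = val.strip()
    return sections


def _read_brainvision(path: str, ecg_names) -> EEGRecording:
    base, _ = os.path.splitext(path)
    vhdr = base + ".vhdr"
    if not os.path.exists(vhdr):
        raise FormatError(f"missing BrainVision header file: {vhdr}")
    with open(vhdr, encoding="utf-8") as f:
        sec = _parse_ini(f.read())
    common = sec.get("Common Infos", {})
    binary = sec.get("Binary Infos", {})
    folder = os.path.dirname(os.path.abspath(vhdr))
    datafile = os.path.join(folder, common.get("DataFile", os.path.basename(base) + ".eeg"))
    markerfile = common.get("MarkerFile")
    if not os.path.exists(datafile):
        raise FormatError(f"missing BrainVision data file: {datafile}")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise FormatError("only MULTIPLEXED BrainVision data is supported")
    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32")
    if fmt == "IEEE_FLOAT_32":
        dtype, itemsize = "<f4", 4
    elif fmt == "INT_16":
        dtype, itemsize = "<i2", 2
    else:
        raise FormatError(f"unsupported BinaryFormat {fmt!r}")
    nchan = int(common["NumberOfChannels"])
    sfreq = 1e6 / float(common["SamplingInterval"])

    ch_names, scales = [], []
    for i in range(nchan):
        entry = sec.get("Channel Infos", {}).get(f"Ch{i + 1}")
        if entry is None:
            raise FormatError(f"channel Ch{i + 1} missing from header")
        parts = entry.split(",")
        name = parts[0]
        resolution = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
        unit = parts[3] if len(parts) > 3 and parts[3] else "µV"
        if unit == "μV":  # greek mu vs micro sign
            unit = "µV"
        if unit not in _UNIT_TO_UV:
            raise UnitError(f"channel {name!r}: unknown unit {unit!r}")
        ch_names.append(name)
        scales.append(resolution * _UNIT_TO_UV[unit])

    raw = np.fromfile(datafile, dtype=dtype)
    n_found, rem = divmod(raw.size, nchan)
    declared = common.get("DataPoints")
    if declared is not None:
        expected = int(declared)
        actual_bytes = os.path.getsize(datafile)
        if actual_bytes != expected * nchan * itemsize:
            found = actual_bytes / (nchan * itemsize)
            raise FormatError(
                f"{datafile}: truncated data, expected {expected} samples/channel "
                f"but found {found:g}"
            )
    elif rem:
        raise FormatError(f"{datafile}: size is not a whole number of frames")
    data = raw.reshape(n_found, nchan).T.astype(float)
    data *= np.asarray(scales)[:, None]

    annotations: list[tuple[float, float, str]] = []
    if markerfile:
        mpath = os.path.join(folder, markerfile)
        if not os.path.exists(mpath):
            raise FormatError(f"missing BrainVision marker file: {mpath}")
        with open(mpath, encoding="utf-8") as f:
            msec = _parse_ini(f.read())
        for key in sorted(msec.get("Marker Infos", {}), key=lambda k: int(k[2:])):
            val = msec["Marker Infos"][key]
            parts = re.split(r"(?<!\\),", val)
            mtype = parts[0]
            if mtype == "New Segment":
                continue
            label = parts[1].replace(r"\,", ",") if len(parts) > 1 else ""
            pos = int(parts[2]) if len(parts) > 2 else 1
            pts = int(parts[3]) if len(parts) > 3 else 0
            annotations.append(((pos - 1) / sfreq, pts / sfreq, label))

    roles = _assign_roles(ch_names, ecg_names)
    return EEGRecording(data, sfreq, ch_names, roles, annotations)


# ---------------------------------------------------------------------------
# EDF (16-bit; a single data record holding the whole signal)

def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", errors="replace")[:n]
    return b + b" " * (n - len(b))


def _write_edf(rec: EEGRecording, path: str) -> None:
    ns = rec.n_channels
    n_samp = rec.n_samples
    record_dur = n_samp / rec.sfreq
    phys_min = rec.data.min(axis=1)
    phys_max = rec.data.max(axis=1)
    # avoid a zero physical range (flat channel)
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b""
    header += _pad("0", 8)
    header += _pad("X X X X", 80)  # patient id (anonymous)
    header += _pad("Startdate X X X X", 80)
    header += _pad("01.01.00", 8)
    header += _pad("00.00.00", 8)
    header += _pad(str(256 * (1 + ns)), 8)
    header += _pad("", 44)
    header += _pad("1", 8)  # number of data records
    header += _pad(f"{record_dur:.6f}"[:8], 8)
    header += _pad(str(ns), 4)

    header += b"".join(_pad(n, 16) for n in rec.ch_names)
    header += b"".join(_pad("", 80) for _ in range(ns))  # transducer
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(f"{v:.6g}"[:8], 8) for v in phys_min)
    header += b"".join(_pad(f"{v:.6g}"[:8], 8) for v in phys_max)
    header += b"".join(_pad(str(dig_min), 8) for _ in range(ns))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))  # prefiltering
    header += b"".join(_pad(str(n_samp), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    with open(path, "wb") as f:
        f.write(header)
        for i in range(ns):
            dig = np.round((rec.data[i] - phys_min[i]) / gain[i]) + dig_min
            f.write(np.clip(dig, dig_min, dig_max).astype("<i2").tobytes())


def _read_edf(path: str, ecg_names) -> EEGRecording:
    with open(path, "rb") as f:
        hdr = f.read(256)
        if len(hdr) < 256:
            raise FormatError(f"{path}: EDF header truncated")
        n_records = int(hdr[236:244].decode().strip())
        record_dur = float(hdr[244:252].decode().strip())
        ns = int(hdr[252:256].decode().strip())
        sig_hdr = f.read(256 * ns)
        if len(sig_hdr) < 256 * ns:
            raise FormatError(f"{path}: EDF signal header truncated")

        # per-signal header block: fixed-width ascii fields, signal-major
        pos = 0
        ch_names = [sig_hdr[pos + i * 16: pos + (i + 1) * 16].decode().strip() for i in range(ns)]
        pos += 16 * ns + 80 * ns
        units = [sig_hdr[pos + i * 8: pos + (i + 1) * 8].decode().strip() for i in range(ns)]
        pos += 8 * ns
        phys_min = np.array([float(sig_hdr[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += 8 * ns
        phys_max = np.array([float(sig_hdr[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += 8 * ns
        dig_min = np.array([float(sig_hdr[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += 8 * ns
        dig_max = np.array([float(sig_hdr[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)])
        pos += 8 * ns + 80 * ns
        n_per_rec = [int(sig_hdr[pos + i * 8: pos + (i + 1) * 8]) for i in range(ns)]

        for name, u in zip(ch_names, units):
            if u not in ("uV", "µV", "mV", "V", ""):
                raise UnitError(f"channel {name!r}: unknown unit {u!r}")

        chunks = [[] for _ in range(ns)]
        for _ in range(n_records):
            for i in range(ns):
                raw = f.read(2 * n_per_rec[i])
                if len(raw) < 2 * n_per_rec[i]:
                    raise FormatError(f"{path}: EDF data truncated")
                chunks[i].append(np.frombuffer(raw, dtype="<i2"))

    scale = {"uV": 1.0, "µV": 1.0, "": 1.0, "mV": 1e3, "V": 1e6}
    rows = []
    for i in range(ns):
        dig = np.concatenate(chunks[i]).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        rows.append((phys_min[i] + (dig - dig_min[i]) * gain) * scale[units[i]])
    data = np.vstack(rows)
    sfreq = n_per_rec[0] / record_dur
    roles = _assign_roles(ch_names, ecg_names)
    return EEGRecording(data, sfreq, ch_names, roles)


# ---------------------------------------------------------------------------
# public API

def _assign_roles(ch_names, ecg_names) -> list[str]:
    lowered = {n.lower() for n in ecg_names}
    return ["ecg" if n.lower() in lowered else "eeg" for n in ch_names]


def write_recording(rec: EEGRecording, path, format: str = "brainvision") -> None:
    """Write ``rec`` to disk; BrainVision is float32 µV, EDF is 16-bit."""
    if rec.n_samples == 0 or rec.n_channels == 0:
        raise ValueError("refusing to write an empty recording")
    if format == "brainvision":
        _write_brainvision(rec, os.fspath(path))
    elif format == "edf":
        _write_edf(rec, os.fspath(path))
    else:
        raise ValueError(f"unknown format {format!r}")


def read_recording(path, format: str | None = None,
                   ecg_names=DEFAULT_ECG_NAMES) -> EEGRecording:
    """Read a recording; ``format`` is inferred from the extension if omitted."""
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower()
        format = {"" : "brainvision", ".vhdr": "brainvision", ".eeg": "brainvision",
                  ".edf": "edf"}.get(ext)
        if format is None:
            raise ValueError(f"cannot infer format from {path!r}")
    if format == "brainvision":
        return _read_brainvision(path, ecg_names)
    if format == "edf":
        if not os.path.exists(path):
            raise FormatError(f"no such file: {path}")
        return _read_edf(path, ecg_names)
    raise ValueError(f"unknown format {format!r}")
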