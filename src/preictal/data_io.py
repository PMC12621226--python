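"""Reading and writing the pipeline's on-disk formats.

Three formats are handled:

* **EDF** (European Data Format) recordings — a minimal 16-bit codec
  supporting one-second data records, which is all the pipeline needs.
  Signals are quantized to the per-channel physical range chosen at write
  time, so a write/read round trip is exact up to one quantization step.
* **Seizure-annotation summaries** — the plain-text dialect used by the
  CHB-MIT corpus (``File Name:`` / ``Seizure Start Time: ... seconds``
  blocks).
* **Window stores** — containers of labeled, epoch-shaped training windows
  plus per-window provenance, serialized as ``.npz``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RecordingMeta",
    "SeizureEvent",
    "WindowStore",
    "read_recording",
    "write_recording",
    "parse_annotations",
    "format_annotations",
    "save_windows",
    "load_windows",
]

CLASS_MAP = {0: "preictal", 1: "interictal"}

_DIG_MIN, _DIG_MAX = -32768, 32767


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class RecordingMeta:
    file_id: str
    n_channels: int
    fs: float
    n_samples: int
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.fs <= 0:
            raise ValueError("n_samples and fs must be positive")
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must equal n_channels")

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SeizureEvent:
    file_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(
                f"{self.file_id}: need 0 <= start < end, got ({self.start_s}, {self.end_s})"
            )


@dataclass
class WindowStore:
    """Labeled epoch windows: data [n, channels, rows, cols], labels in {0,1}."""

    data: np.ndarray
    labels: np.ndarray
    provenance: list[tuple[str, int]] = field(default_factory=list)
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels)
        if self.labels.shape[0] != self.data.shape[0]:
            raise FormatError("labels length must equal number of windows")
        if self.labels.size and not np.isin(self.labels, list(self.class_map)).all():
            raise FormatError(f"labels must be codes in {sorted(self.class_map)}")
        if self.provenance and len(self.provenance) != self.data.shape[0]:
            raise FormatError("provenance length must equal number of windows")

    def __len__(self) -> int:
        return int(self.data.shape[0])

    def subset(self, idx: np.ndarray) -> "WindowStore":
        prov = [self.provenance[i] for i in idx] if self.provenance else []
        return WindowStore(self.data[idx], self.labels[idx], prov, dict(self.class_map))


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

def _fmt8(x: float) -> str:
    """Format a number into at most 8 ASCII characters (EDF header field)."""
    for spec in ("%.6g", "%.5g", "%.4g", "%.3g", "%.2g", "%.1g"):
        s = spec % x
        if len(s) <= 8:
            return s
    raise FormatError(f"cannot format {x} into 8 characters")


def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_recording(
    path: str | Path,
    signal: np.ndarray,
    fs: float,
    channel_names: Sequence[str] | None = None,
    file_id: str | None = None,
) -> RecordingMeta:
    """Write a [n_channels x n_samples] signal as 16-bit EDF.

    Uses one-second data records; the sample count must be a whole number
    of seconds. Each channel gets a symmetric physical range just above its
    peak amplitude, so the quantization step is ~range/65535.
    """
    path = Path(path)
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    n_ch, n_samp = signal.shape
    if n_ch == 0 or n_samp == 0:
        raise FormatError("cannot write an empty signal")
    spr = int(round(fs))  # samples per 1-s record
    if abs(fs - spr) > 1e-9:
        raise FormatError(f"writer requires an integer sampling rate, got {fs}")
    if n_samp % spr != 0:
        raise FormatError(
            f"signal length {n_samp} is not a whole number of seconds at fs={fs}"
        )
    n_records = n_samp // spr
    names = list(channel_names) if channel_names else [f"EEG {i:03d}" for i in range(n_ch)]
    if len(names) != n_ch:
        raise FormatError("channel_names length must equal channel count")
    fid = file_id or path.stem

    # Per-channel physical ranges; written strings are parsed back so the
    # gains used for encoding match what a reader will reconstruct.
    phys_min, phys_max = [], []
    for ch in range(n_ch):
        peak = float(np.max(np.abs(signal[ch]))) if n_samp else 0.0
        pm = peak * 1.0001 if peak > 0 else 1.0
        pm = float(_fmt8(pm))
        phys_min.append(-pm)
        phys_max.append(pm)

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad(f"Startdate 01-JAN-2000 {fid}", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(nm, 16) for nm in names],
        [_pad("", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(_fmt8(phys_min[ch]), 8) for ch in range(n_ch)],
        [_pad(_fmt8(phys_max[ch]), 8) for ch in range(n_ch)],
        [_pad(str(_DIG_MIN), 8)] * n_ch,
        [_pad(str(_DIG_MAX), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    header += b"".join(b"".join(col) for col in fields)

    gains = np.array(
        [(phys_max[c] - phys_min[c]) / (_DIG_MAX - _DIG_MIN) for c in range(n_ch)]
    )
    digital = np.round((signal - np.array(phys_min)[:, None]) / gains[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # record-major, channel blocks within each record
        for rec in range(n_records):
            block = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(block.tobytes())

    return RecordingMeta(fid, n_ch, float(spr), n_samp, tuple(names))


def _read_field(buf: bytes, offset: int, width: int) -> str:
    return buf[offset:offset + width].decode("ascii", errors="replace").strip()


def read_recording(
    path: str | Path,
    channel_limit: int | None = 22,
    channels: Sequence[int] | None = None,
) -> tuple[RecordingMeta, np.ndarray]:
    """Read an EDF recording into (meta, [n_channels x n_samples] array).

    By default recordings with more than ``channel_limit`` channels are
    truncated to the first ``channel_limit`` in header order; pass an
    explicit ``channels`` index list to override, or ``channel_limit=None``
    to keep everything.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(_read_field(head, 236, 8))
            record_dur = float(_read_field(head, 244, 8))
            n_sig = int(_read_field(head, 252, 4))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF header: {exc}") from exc
        if n_sig <= 0:
            raise FormatError(f"{path}: channel count must be positive, got {n_sig}")
        sig_head = fh.read(256 * n_sig)
        if len(sig_head) < 256 * n_sig:
            raise FormatError(f"{path}: truncated EDF signal header")

        def col(width: int, base: int) -> list[str]:
            return [
                _read_field(sig_head, base * n_sig + i * width, width)
                for i in range(n_sig)
            ]

        names = col(16, 0)
        base = 16 + 80 + 8
        phys_min = [float(v) for v in col(8, base)]
        phys_max = [float(v) for v in col(8, base + 8)]
        dig_min = [int(float(v)) for v in col(8, base + 16)]
        dig_max = [int(float(v)) for v in col(8, base + 24)]
        spr = [int(v) for v in col(8, base + 32 + 80)]

        raw = fh.read()

    total_per_record = sum(spr)
    expected = n_records * total_per_record * 2
    if len(raw) < expected:
        raise FormatError(f"{path}: data section shorter than header promises")
    data = np.frombuffer(raw[:expected], dtype="<i2").reshape(n_records, total_per_record)

    offsets = np.cumsum([0] + spr)
    sel = list(channels) if channels is not None else list(range(n_sig))
    if channels is None and channel_limit is not None and n_sig > channel_limit:
        sel = sel[:channel_limit]

    out = []
    for ch in sel:
        gain = (phys_max[ch] - phys_min[ch]) / (dig_max[ch] - dig_min[ch])
        dig = data[:, offsets[ch]:offsets[ch + 1]].reshape(-1).astype(np.float64)
        out.append((dig - dig_min[ch]) * gain + phys_min[ch])
    signal = np.vstack(out)

    fs = spr[sel[0]] / record_dur
    meta = RecordingMeta(
        file_id=path.stem,
        n_channels=len(sel),
        fs=fs,
        n_samples=signal.shape[1],
        channel_names=tuple(names[ch] for ch in sel),
    )
    return meta, signal


def edf_quantization_step(signal: np.ndarray) -> np.ndarray:
    """Per-channel quantization step the writer will use for this signal."""
    signal = np.atleast_2d(signal)
    peaks = np.max(np.abs(signal), axis=1)
    pm = np.array([float(_fmt8(p * 1.0001 if p > 0 else 1.0)) for p in peaks])
    return 2 * pm / (_DIG_MAX - _DIG_MIN)


# ---------------------------------------------------------------------------
# Annotation summaries
# ---------------------------------------------------------------------------

_FILE_RE = re.compile(r"^File Name:\s*(\S+)")
_NSEIZ_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)")
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*seconds")
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*seconds")


def parse_annotations(summary_text: str) -> list[SeizureEvent]:
    """Parse a CHB-MIT-style seizure summary into events.

    Events are attached to the most recent ``File Name:`` line and returned
    sorted by (file order, start time).
    """
    events: list[SeizureEvent] = []
    current_file: str | None = None
    pending_start: float | None = None
    per_file: list[SeizureEvent] = []

    def flush() -> None:
        nonlocal per_file, pending_start
        if pending_start is not None:
            raise FormatError(
                f"{current_file}: seizure start at {pending_start}s has no end time"
            )
        events.extend(sorted(per_file, key=lambda e: e.start_s))
        per_file = []

    for line in summary_text.splitlines():
        line = line.strip()
        if m := _FILE_RE.match(line):
            flush()
            current_file = m.group(1)
            continue
        if m := _START_RE.match(line):
            if current_file is None:
                raise FormatError("seizure start before any File Name block")
            if pending_start is not None:
                raise FormatError(f"{current_file}: consecutive start times without an end")
            pending_start = float(m.group(1))
            continue
        if m := _END_RE.match(line):
            if pending_start is None:
                raise FormatError(f"{current_file}: seizure end without a start")
            end = float(m.group(1))
            if end <= pending_start:
                raise FormatError(
                    f"{current_file}: seizure end {end}s <= start {pending_start}s"
                )
            per_file.append(SeizureEvent(current_file, pending_start, end))
            pending_start = None
    flush()
    return events


def format_annotations(
    events_by_file: dict[str, list[SeizureEvent]],
) -> str:
    """Serialize events back into the summary dialect (parse round-trips)."""
    lines: list[str] = []
    for fname, evs in events_by_file.items():
        lines.append(f"File Name: {fname}")
        lines.append(f"Number of Seizures in File: {len(evs)}")
        for i, ev in enumerate(sorted(evs, key=lambda e: e.start_s), start=1):
            lines.append(f"Seizure {i} Start Time: {ev.start_s:g} seconds")
            lines.append(f"Seizure {i} End Time: {ev.end_s:g} seconds")
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Window stores
# ---------------------------------------------------------------------------

def save_windows(store: WindowStore, path: str | Path) -> None:
    """Serialize a WindowStore losslessly to ``.npz``."""
    prov_files = np.array([p[0] for p in store.provenance], dtype=object)
    prov_starts = np.array([p[1] for p in store.provenance], dtype=np.int64)
    class_codes = np.array(sorted(store.class_map), dtype=np.int64)
    class_names = np.array([store.class_map[c] for c in class_codes], dtype=object)
    np.savez(
        path,
        data=store.data,
        labels=store.labels,
        prov_files=prov_files,
        prov_starts=prov_starts,
        class_codes=class_codes,
        class_names=class_names,
    )


def load_windows(path: str | Path) -> WindowStore:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with np.load(path, allow_pickle=True) as z:
        data = z["data"]
        labels = z["labels"]
        if labels.shape[0] != data.shape[0]:
            raise FormatError(
                f"{path}: label count {labels.shape[0]} != window count {data.shape[0]}"
            )
        prov = list(zip(z["prov_files"].tolist(), z["prov_starts"].tolist()))
        class_map = dict(zip(z["class_codes"].tolist(), z["class_names"].tolist()))
    return WindowStore(data=data, labels=labels, provenance=prov, class_map=class_map)
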