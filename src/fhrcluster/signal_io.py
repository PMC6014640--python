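"""Readers and writers for ECG signals, beat annotations and detection output.

Plain text is the canonical format: signals are one float per line (or one
column of a delimited file), annotations one integer sample index per line.
A minimal WFDB reader/writer (``.hea`` header + format-16 ``.dat`` signal
files, as distributed by PhysioNet) is included so standard abdominal-ECG
records can be loaded without extra dependencies.

All sample indexing is 0-based internally; plain-text annotation files are
0-based as well.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

ANNOTATION_KINDS = ("fetal_reference", "fetal_detected", "maternal_detected")


@dataclass(frozen=True)
class EcgRecord:
    """A sampled single-channel voltage series.

    Parameters
    ----------
    record_id : str
        Identity label, e.g. ``"r01"``.
    channel : str
        Channel label, e.g. ``"Ab-1"``.
    fs : float
        Sampling rate in Hz; must be positive.
    samples : numpy.ndarray
        Voltage samples in arbitrary units (typically mV); finite values.
    """

    record_id: str
    channel: str
    fs: float
    samples: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class AnnotationSet:
    """Strictly increasing 0-based R-peak sample positions for one record."""

    record_id: str
    kind: str
    indices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise ValueError(f"unknown annotation kind {self.kind!r}; expected one of {ANNOTATION_KINDS}")
        idx = np.asarray(self.indices, dtype=np.int64)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1:
            raise ValueError("indices must be 1-D")
        if idx.size and idx.min() < 0:
            raise ValueError("negative annotation index")
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("annotation indices must be strictly increasing")

    def __len__(self) -> int:
        return int(self.indices.size)

    def times_s(self, fs: float) -> np.ndarray:
        return self.indices / fs


def read_signal_csv(
    path: str | Path,
    fs: float,
    record_id: str = "",
    channel: str = "",
    column: int = 0,
    delimiter: str | None = None,
) -> EcgRecord:
    """Read a plain-text signal file: one numeric value per line, or one
    column of a delimited file.

    Non-numeric rows raise a :class:`ValueError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    if not fs > 0:
        raise ValueError(f"sampling rate must be > 0, got {fs}")
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(delimiter) if delimiter else line.split(",") if "," in line else [line]
            try:
                values.append(float(fields[column]))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse {line!r} as a number") from exc
    if not values:
        raise ValueError(f"empty signal: {path}")
    return EcgRecord(record_id=record_id or path.stem, channel=channel, fs=fs, samples=np.array(values))


def read_annotations(
    path: str | Path,
    record_id: str = "",
    kind: str = "fetal_reference",
) -> AnnotationSet:
    """Read a plain-text annotation file, one integer sample index per line.

    Indices are sorted ascending; duplicates are removed with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    indices: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                value = int(line)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer annotation {line!r}") from exc
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative annotation index {value}")
            indices.append(value)
    arr = np.array(sorted(indices), dtype=np.int64)
    unique = np.unique(arr)
    if unique.size != arr.size:
        logger.warning("%s: %d duplicate annotation indices removed", path, arr.size - unique.size)
    return AnnotationSet(record_id=record_id or path.stem, kind=kind, indices=unique)


def write_detections(ann: AnnotationSet, path: str | Path) -> None:
    """Write annotations as plain text, one 0-based index per line."""
    path = Path(path)
    with open(path, "w") as fh:
        for idx in ann.indices:
            fh.write(f"{int(idx)}\n")


def write_detections_csv(ann: AnnotationSet, fs: float, path: str | Path, label: str | None = None) -> None:
    """Write annotations as CSV with columns (index, time_s, label)."""
    label = label if label is not None else ann.kind
    with open(Path(path), "w") as fh:
        fh.write("index,time_s,label\n")
        for idx in ann.indices:
            fh.write(f"{int(idx)},{idx / fs:.6f},{label}\n")


# ---------------------------------------------------------------------------
# Minimal WFDB support (header + format-16 signal files)
# ---------------------------------------------------------------------------

def _parse_header(header_path: Path) -> dict:
    lines = [
        ln.strip()
        for ln in header_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = lines[0].split()
    record_name = rec_fields[0].split("/")[0]
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0]) if len(rec_fields) > 2 else 250.0
    n_samp = int(rec_fields[3]) if len(rec_fields) > 3 else 0
    signals = []
    for line in lines[1 : 1 + n_sig]:
        f = line.split()
        fname, fmt = f[0], f[1].split("x")[0].split(":")[0].split("+")[0]
        # gain field: gain(baseline)/units
        gain, baseline, units = 200.0, 0, "mV"
        if len(f) > 2:
            gspec = f[2]
            if "/" in gspec:
                gspec, units = gspec.split("/", 1)
            if "(" in gspec:
                gspec, bspec = gspec.split("(")
                baseline = int(bspec.rstrip(")"))
            gain = float(gspec) if gspec else 200.0
            if gain == 0:
                gain = 200.0
        adc_zero = int(f[4]) if len(f) > 4 else 0
        if "(" not in (f[2] if len(f) > 2 else ""):
            baseline = adc_zero
        name = f[-1] if len(f) >= 9 else f"ch{len(signals)}"
        signals.append(
            {"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline, "units": units, "name": name}
        )
    return {"record": record_name, "n_sig": n_sig, "fs": fs, "n_samp": n_samp, "signals": signals}


def read_wfdb_record(path_stem: str | Path, channel: str | int = 0) -> EcgRecord:
    """Read one channel of a WFDB record (``<stem>.hea`` + format-16 ``.dat``).

    The digital values are converted to physical units via the header's
    gain and baseline: ``physical = (digital - baseline) / gain``.

    Parameters
    ----------
    path_stem : path
        Record path without extension.
    channel : str or int
        Channel (signal) name or index.
    """
    stem = Path(path_stem)
    header_path = stem.with_suffix(".hea")
    if not header_path.exists():
        raise FileNotFoundError(f"WFDB header not found: {header_path}")
    hdr = _parse_header(header_path)
    names = [s["name"] for s in hdr["signals"]]
    if isinstance(channel, int):
        if not 0 <= channel < hdr["n_sig"]:
            raise ValueError(f"channel index {channel} out of range; record has channels {names}")
        ch = channel
    else:
        if channel not in names:
            raise ValueError(f"channel {channel!r} not found; available channels: {names}")
        ch = names.index(channel)
    sig = hdr["signals"][ch]
    if sig["fmt"] != "16":
        raise NotImplementedError(f"WFDB format {sig['fmt']} not supported (only format 16)")
    dat_path = stem.parent / sig["file"]
    raw = np.fromfile(dat_path, dtype="<i2")
    # format 16 multiplexes all channels stored in the same .dat file
    in_file = [i for i, s in enumerate(hdr["signals"]) if s["file"] == sig["file"]]
    frame = len(in_file)
    raw = raw[: (raw.size // frame) * frame].reshape(-1, frame)
    digital = raw[:, in_file.index(ch)].astype(float)
    physical = (digital - sig["baseline"]) / sig["gain"]
    return EcgRecord(record_id=hdr["record"], channel=sig["name"], fs=hdr["fs"], samples=physical)


def write_wfdb_record(
    path_stem: str | Path,
    fs: float,
    channels: Sequence[tuple[str, np.ndarray]],
    gain: float = 1000.0,
) -> None:
    """Write a multi-channel format-16 WFDB record (used for round-trip tests).

    Physical values are quantized to ``round(x * gain)`` 16-bit integers.
    """
    stem = Path(path_stem)
    n_samp = len(channels[0][1])
    dat_name = stem.name + ".dat"
    with open(stem.with_suffix(".hea"), "w") as fh:
        fh.write(f"{stem.name} {len(channels)} {fs:g} {n_samp}\n")
        for name, _ in channels:
            fh.write(f"{dat_name} 16 {gain:g}(0)/mV 16 0 0 0 0 {name}\n")
    digital = np.column_stack(
        [np.clip(np.round(x * gain), -32768, 32767).astype("<i2") for _, x in channels]
    )
    digital.tofile(stem.parent / dat_name)


__all__ = [
    "EcgRecord",
    "AnnotationSet",
    "read_signal_csv",
    "read_annotations",
    "write_detections",
    "write_detections_csv",
    "read_wfdb_record",
    "write_wfdb_record",
]
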