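"""Record and annotation I/O: WFDB (header + format-16 signal + MIT
annotations), CSV, and JSON reports.

The WFDB support is a self-contained reader/writer for the subset the
pipelines need: multi-channel format-16 records with per-channel gain and
baseline (the layout used by the PhysioNet Fantasia records), and the
standard MIT annotation byte stream for beat annotations.  Annotation times
are held in seconds internally; converters to/from sample indices are the
``fs`` arguments.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidParameterError
from .evaluation import EventSeries
from .signal_core import SampledSignal

__all__ = [
    "Record",
    "read_wfdb",
    "write_wfdb",
    "read_annotations",
    "write_annotations",
    "read_csv_signal",
    "write_outputs",
]

_BEAT_CODES = set(range(1, 50))  # MIT annotation codes that mark beats
_SKIP, _NUM, _SUB, _CHN, _AUX = 59, 60, 61, 62, 63


@dataclass
class Record:
    """A multi-channel physiological record with a common sampling rate."""

    signals: dict[str, SampledSignal]
    fs: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.signals.values()}
        if len(lengths) > 1:
            raise InvalidParameterError("all channels must share one length")
        for s in self.signals.values():
            if s.fs != self.fs:
                raise InvalidParameterError("all channels must share fs")

    @property
    def duration(self) -> float:
        first = next(iter(self.signals.values()))
        return first.duration

    def __getitem__(self, name: str) -> SampledSignal:
        return self.signals[name]


def _parse_header(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        raise FormatError(f"empty header file {hea_path}")
    rec_fields = lines[0].split()
    if len(rec_fields) < 4:
        raise FormatError(f"malformed record line in {hea_path}: {lines[0]!r}")
    name = rec_fields[0].split("/")[0]
    nsig = int(rec_fields[1])
    fs = float(rec_fields[2].split("/")[0])
    nsamp = int(rec_fields[3])
    if len(lines) < 1 + nsig:
        raise FormatError(f"{hea_path} declares {nsig} signals but lists fewer")
    specs = []
    for ln in lines[1 : 1 + nsig]:
        f = ln.split()
        if len(f) < 2:
            raise FormatError(f"malformed signal line in {hea_path}: {ln!r}")
        fmt = f[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, units = 200.0, None, "adu"
        if len(f) >= 3:
            g = f[2]
            if "/" in g:
                g, units = g.split("/", 1)
            if "(" in g:
                g, b = g.rstrip(")").split("(")
                baseline = int(b)
            gain = float(g) if g else 200.0
        adczero = int(f[4]) if len(f) >= 5 else 0
        desc = " ".join(f[8:]) if len(f) >= 9 else f"ch{len(specs)}"
        specs.append(
            {
                "filename": f[0],
                "format": fmt,
                "gain": gain if gain != 0 else 200.0,
                "baseline": baseline if baseline is not None else adczero,
                "units": units,
                "description": desc,
            }
        )
    return name, nsig, fs, nsamp, specs


def _decode_212(dat: Path, n_samples: int) -> np.ndarray:
    """Unpack WFDB format 212: two 12-bit two's-complement samples per 3 bytes."""
    b = np.frombuffer(dat.read_bytes(), dtype=np.uint8)
    n_triplets = b.size // 3
    b = b[: n_triplets * 3].reshape(-1, 3).astype(np.int32)
    s0 = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
    s1 = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
    out = np.empty(n_triplets * 2, dtype=np.int32)
    out[0::2] = np.where(s0 > 2047, s0 - 4096, s0)
    out[1::2] = np.where(s1 > 2047, s1 - 4096, s1)
    return out[:n_samples] if out.size >= n_samples else out


def read_wfdb(path: str | Path) -> Record:
    """Read a WFDB record (``.hea`` plus format-16 ``.dat``).

    ``path`` may be the header path or the record basename.  Amplitudes are
    converted to physical units via each channel's gain and baseline.  A
    signal file shorter than the header's sample count raises
    :class:`FormatError` rather than silently truncating.
    """
    path = Path(path)
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FormatError(f"header file not found: {hea}")
    name, nsig, fs, nsamp, specs = _parse_header(hea)
    fmts = {s["format"] for s in specs}
    if fmts - {"16", "212"}:
        raise FormatError(
            f"unsupported WFDB signal format(s) {fmts - {'16', '212'}}"
        )
    if len(fmts) != 1:
        raise FormatError("mixed signal formats are not supported")
    files = {s["filename"] for s in specs}
    if len(files) != 1:
        raise FormatError("multi-file records are not supported")
    dat = hea.parent / files.pop()
    if not dat.exists():
        raise FormatError(f"signal file not found: {dat}")
    if fmts == {"212"}:
        raw = _decode_212(dat, nsamp * nsig)
    else:
        raw = np.fromfile(dat, dtype="<i2").astype(np.int32)
    if raw.size < nsamp * nsig:
        raise FormatError(
            f"{dat} holds {raw.size} samples; header declares {nsamp * nsig}"
        )
    raw = raw[: nsamp * nsig].reshape(nsamp, nsig)
    signals: dict[str, SampledSignal] = {}
    for k, s in enumerate(specs):
        phys = (raw[:, k].astype(float) - s["baseline"]) / s["gain"]
        label = s["description"] or f"ch{k}"
        if label in signals:
            label = f"{label}_{k}"
        signals[label] = SampledSignal(phys, fs)
    return Record(
        signals=signals,
        fs=fs,
        metadata={"record_name": name, "units": [s["units"] for s in specs]},
    )


def write_wfdb(record: Record, prefix: str | Path) -> None:
    """Write a record as ``prefix.hea`` + ``prefix.dat`` (format 16).

    Each channel is digitized with a gain mapping its absolute maximum to
    ~90% of the int16 range, baseline 0.
    """
    prefix = Path(prefix)
    names = list(record.signals)
    n = len(record.signals[names[0]])
    data = np.empty((n, len(names)), dtype="<i2")
    lines = [f"{prefix.name} {len(names)} {record.fs:g} {n}"]
    for k, name in enumerate(names):
        v = record.signals[name].values
        vmax = float(np.max(np.abs(v))) or 1.0
        gain = 0.9 * 32767 / vmax
        data[:, k] = np.round(v * gain).astype("<i2")
        lines.append(
            f"{prefix.name}.dat 16 {gain:.6f}(0)/au 16 0 {data[0, k]} 0 0 {name}"
        )
    prefix.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    data.tofile(prefix.with_suffix(".dat"))


def _read_mit_annotations(path: Path, fs: float) -> np.ndarray:
    """Beat sample indices from a MIT-format annotation byte stream."""
    buf = path.read_bytes()
    if len(buf) % 2:
        raise FormatError(f"{path}: odd byte count, not MIT annotation format")
    words = np.frombuffer(buf, dtype="<u2")
    samples: list[int] = []
    t = 0
    i = 0
    while i < len(words):
        w = int(words[i])
        code, inc = w >> 10, w & 0x3FF
        i += 1
        if code == 0 and inc == 0:
            break
        if code == _SKIP:
            if i + 2 > len(words):
                raise FormatError(f"{path}: truncated SKIP interval")
            t += (int(words[i]) << 16) | int(words[i + 1])
            i += 2
        elif code == _AUX:
            i += (inc + 1) // 2  # aux bytes, padded to an even count
        elif code in (_NUM, _SUB, _CHN):
            continue
        else:
            t += inc
            if code in _BEAT_CODES:
                samples.append(t)
    return np.asarray(samples, dtype=np.int64)


def write_annotations(times_s: np.ndarray, path: str | Path, fs: float) -> None:
    """Write beat times (seconds) as a MIT-format annotation stream (code 1)."""
    path = Path(path)
    samples = np.round(np.asarray(times_s) * fs).astype(np.int64)
    out = bytearray()
    prev = 0
    for s in samples:
        dt = int(s - prev)
        prev = int(s)
        if dt >= 1024:
            out += struct.pack("<H", (_SKIP << 10))
            out += struct.pack("<HH", (dt >> 16) & 0xFFFF, dt & 0xFFFF)
            dt = 0
        out += struct.pack("<H", (1 << 10) | dt)
    out += struct.pack("<H", 0)
    path.write_bytes(bytes(out))


def read_annotations(
    path: str | Path, format: str = "csv", fs: float = 250.0
) -> EventSeries:
    """Read beat/breath annotations as an :class:`EventSeries` in seconds.

    ``format="csv"`` expects a single ``time_s`` column (header optional);
    ``format="wfdb_ann"`` reads the MIT binary annotation stream, converting
    sample indices to seconds at ``fs``.  Unsorted input is sorted with a
    warning; duplicate timestamps are collapsed with a warning.
    """
    path = Path(path)
    if format == "wfdb_ann":
        times = _read_mit_annotations(path, fs) / fs
    elif format == "csv":
        if path.stat().st_size == 0:
            return EventSeries(np.empty(0), source="reference")
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas names the line
            raise FormatError(f"could not parse {path}: {exc}") from exc
        col = "time_s" if "time_s" in df.columns else df.columns[0]
        try:
            float(col)
            # headerless file: the "column name" was actually the first value
            df = pd.read_csv(path, header=None)
            times = df[df.columns[0]].to_numpy(dtype=float)
        except ValueError:
            times = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(times)):
            bad = int(np.flatnonzero(~np.isfinite(times))[0]) + 2
            raise FormatError(f"{path}: unparseable value near line {bad}")
    else:
        raise InvalidParameterError(f"unknown annotation format {format!r}")
    if times.size > 1 and np.any(np.diff(times) < 0):
        warnings.warn(f"{path}: annotation times unsorted; sorting", stacklevel=2)
        times = np.sort(times)
    uniq = np.unique(times)
    if uniq.size != times.size:
        warnings.warn(
            f"{path}: {times.size - uniq.size} duplicate timestamp(s) collapsed",
            stacklevel=2,
        )
    return EventSeries(uniq, source="reference")


def write_outputs(result, path: str | Path, kind: str) -> None:
    """Write pipeline artifacts with stable column order and 6-decimal floats.

    ``kind`` is one of ``beats_csv`` (EventSeries), ``composite_csv``
    (SampledSignal) or ``report_json`` (dict).
    """
    path = Path(path)
    if kind == "beats_csv":
        df = pd.DataFrame(
            {
                "beat_index": np.arange(len(result.times)),
                "time_s": np.round(result.times, 6),
            }
        )
        df.to_csv(path, index=False, float_format="%.6f")
    elif kind == "composite_csv":
        df = pd.DataFrame(
            {"time_s": np.round(result.times, 6), "amplitude": result.values}
        )
        df.to_csv(path, index=False, float_format="%.6f")
    elif kind == "report_json":
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"not JSON serializable: {type(o)}")
        path.write_text(json.dumps(result, indent=2, sort_keys=True,
                                   default=_default) + "\n")
    else:
        raise InvalidParameterError(f"unknown output kind {kind!r}")


def read_csv_signal(path: str | Path, fs: float | None = None) -> SampledSignal:
    """Read a (time_s, value) CSV as a :class:`SampledSignal`.

    The sampling rate is inferred from the median time step unless given.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (time_s, value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if fs is None:
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise FormatError(f"{path}: non-increasing time column")
        fs = 1.0 / dt
    return SampledSignal(v, fs, t0=float(t[0]))
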