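"""Readers and writers: raw binary + JSON sidecar, plain EDF, CSV tables.

The rawbin dialect is the package's lossless fixture format:
little-endian float32, channels stored planar (one block per channel),
with a ``<file>.json`` sidecar declaring ``fs``, ``roles`` (channel
order), ``n_samples`` and ``dtype``.  EDF (plain, 16-bit, one data
record per second) is provided for interoperability; samples survive a
round trip to within the declared physical range / 2^16.
"""

from __future__ import annotations

import csv
import json
import struct
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .core import (
    DetectionParams,
    EventSet,
    FormatError,
    Hypnogram,
    IntegrityError,
    OscEvent,
    ParameterError,
    Recording,
    StateInterval,
)

# ---------------------------------------------------------------------------
# rawbin


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_rawbin(rec: Recording, path: str | Path) -> None:
    path = Path(path)
    roles = list(rec.channels)
    data = np.concatenate([rec.channels[r].astype("<f4") for r in roles])
    path.write_bytes(data.tobytes())
    sidecar = {
        "fs": rec.fs,
        "roles": roles,
        "n_samples": rec.n_samples,
        "dtype": "float32",
        "start_offset_s": rec.start_offset_s,
        "meta": {k: v for k, v in rec.meta.items() if _jsonable(v)},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_rawbin(path: str | Path) -> Recording:
    path = Path(path)
    sc_path = _sidecar_path(path)
    if not sc_path.exists():
        raise FormatError(f"missing sidecar {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    for key in ("fs", "roles", "n_samples", "dtype"):
        if key not in sidecar:
            raise FormatError(f"sidecar lacks required field {key!r}")
    if sidecar["dtype"] != "float32":
        raise FormatError(f"unsupported dtype {sidecar['dtype']!r}")
    n, roles = int(sidecar["n_samples"]), list(sidecar["roles"])
    raw = np.frombuffer(path.read_bytes(), dtype="<f4")
    if raw.size != n * len(roles):
        raise IntegrityError(
            f"file holds {raw.size} samples, sidecar declares {n * len(roles)}"
        )
    channels = {
        role: raw[i * n : (i + 1) * n].astype(np.float64)
        for i, role in enumerate(roles)
    }
    return Recording(
        channels=channels,
        fs=float(sidecar["fs"]),
        start_offset_s=float(sidecar.get("start_offset_s", 0.0)),
        meta=dict(sidecar.get("meta", {})),
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


# ---------------------------------------------------------------------------
# plain EDF (16-bit, one data record per second)


def _fit_number(v: float) -> str:
    """Shortest decimal representation of ``v`` that fits 8 ASCII chars
    (EDF numeric header fields), rounding upward in magnitude so the
    declared physical range always covers the data."""
    for prec in range(9, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8 and len(f"{-v:.{prec}g}") <= 8:
            if abs(float(s)) >= abs(v) or prec == 1:
                return s
    return f"{v:.1g}"


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    rec: Recording,
    path: str | Path,
    phys_range: float | None = None,
) -> None:
    """Write a plain EDF file (one data record per second).

    ``phys_range`` optionally declares the symmetric physical range per
    channel; amplitudes exceeding it raise a range error.  By default
    the range is taken from the data.  The sampling rate must be an
    integer and the duration a whole number of seconds.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    if rec.n_samples % fs != 0:
        raise ParameterError("EDF writer requires a whole number of seconds")
    n_records = rec.n_samples // fs
    roles = list(rec.channels)
    ns = len(roles)

    ranges = {}
    for r in roles:
        x = rec.channels[r]
        peak = float(np.max(np.abs(x))) if x.size else 0.0
        if phys_range is not None:
            if peak > phys_range:
                raise ParameterError(
                    f"channel {r}: amplitude {peak:.4g} exceeds declared "
                    f"physical range {phys_range:.4g}"
                )
            pr = phys_range
        else:
            pr = peak if peak > 0 else 1.0
        # the header stores the range as ASCII; use exactly what is stored
        ranges[r] = float(_fit_number(pr))

    sig_hdr = b""
    sig_hdr += b"".join(_edf_field(r, 16) for r in roles)
    sig_hdr += b"".join(_edf_field("", 80) for _ in roles)  # transducer
    sig_hdr += b"".join(_edf_field("au", 8) for _ in roles)  # dimension
    sig_hdr += b"".join(_edf_field(_fit_number(-ranges[r]), 8) for r in roles)
    sig_hdr += b"".join(_edf_field(_fit_number(ranges[r]), 8) for r in roles)
    sig_hdr += b"".join(_edf_field(-32768, 8) for _ in roles)
    sig_hdr += b"".join(_edf_field(32767, 8) for _ in roles)
    sig_hdr += b"".join(_edf_field("", 80) for _ in roles)  # prefiltering
    sig_hdr += b"".join(_edf_field(fs, 8) for _ in roles)
    sig_hdr += b"".join(_edf_field("", 32) for _ in roles)

    base = b""
    base += _edf_field("0", 8)
    base += _edf_field("X X X X", 80)
    base += _edf_field("Startdate X X X X", 80)
    base += _edf_field("01.01.00", 8)
    base += _edf_field("00.00.00", 8)
    base += _edf_field(256 * (1 + ns), 8)
    base += _edf_field("", 44)
    base += _edf_field(n_records, 8)
    base += _edf_field(1, 8)
    base += _edf_field(ns, 4)

    digital = {}
    for r in roles:
        pr = ranges[r]
        # exact inverse of the reader's affine map [-pr, pr] <-> [-32768, 32767]
        d = np.round((rec.channels[r] + pr) / (2 * pr) * 65535.0 - 32768.0)
        digital[r] = np.clip(d, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(base + sig_hdr)
        for rec_i in range(n_records):
            for r in roles:
                fh.write(digital[r][rec_i * fs : (rec_i + 1) * fs].tobytes())


def read_edf(path: str | Path, role_map: dict[str, str] | None = None) -> Recording:
    """Read a plain EDF file written by this package (or compatible).

    ``role_map`` renames stored channel labels to the standard roles
    (identity by default).
    """
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 256:
        raise FormatError("file too short to be EDF")

    def f(lo, hi):
        return blob[lo:hi].decode("ascii", errors="replace").strip()

    try:
        n_records = int(f(236, 244))
        record_dur = float(f(244, 252))
        ns = int(f(252, 256))
    except ValueError as e:
        raise FormatError(f"malformed EDF header: {e}") from None
    off = 256
    def sig(width):
        nonlocal off
        vals = [f(off + i * width, off + (i + 1) * width) for i in range(ns)]
        off += ns * width
        return vals

    labels = sig(16)
    sig(80)  # transducer
    sig(8)  # dimension
    pmin = [float(v) for v in sig(8)]
    pmax = [float(v) for v in sig(8)]
    dmin = [int(v) for v in sig(8)]
    dmax = [int(v) for v in sig(8)]
    sig(80)  # prefiltering
    spr = [int(v) for v in sig(8)]
    sig(32)

    data_off = 256 * (1 + ns)
    per_record = sum(spr) * 2
    need = data_off + per_record * n_records
    if len(blob) < need:
        raise IntegrityError("EDF data shorter than header declares")
    chans = {lab: np.empty(n_records * s) for lab, s in zip(labels, spr)}
    pos = data_off
    for rec_i in range(n_records):
        for i, lab in enumerate(labels):
            cnt = spr[i]
            d = np.frombuffer(blob, dtype="<i2", count=cnt, offset=pos)
            pos += cnt * 2
            scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
            chans[lab][rec_i * cnt : rec_i * cnt + cnt] = (
                d.astype(np.float64) - dmin[i]
            ) * scale + pmin[i]
    fs = spr[0] / record_dur
    if any(s != spr[0] for s in spr):
        raise IntegrityError("channels with unequal sampling rates")
    role_map = role_map or {}
    channels = {role_map.get(lab, lab): x for lab, x in chans.items()}
    return Recording(channels=channels, fs=fs)


# ---------------------------------------------------------------------------
# front door


def write_recording(rec: Recording, path: str | Path, format: str = "rawbin",
                    **kw) -> None:
    if format == "rawbin":
        write_rawbin(rec, path)
    elif format == "edf":
        write_edf(rec, path, **kw)
    else:
        raise ParameterError(f"unknown format {format!r}")


def read_recording(path: str | Path, format: str = "rawbin", **kw) -> Recording:
    if format == "rawbin":
        return read_rawbin(path)
    if format == "edf":
        return read_edf(path, **kw)
    raise ParameterError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# event tables (CSV, RFC-4180, '#'-prefixed metadata lines)

_EVENT_COLUMNS = ["kind", "start_s", "end_s", "center_s", "peak_time_s", "peak_amp"]


def write_event_table(es: EventSet, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "kind": es.kind,
        "source_role": es.source_role,
        "params": asdict(es.params) if es.params is not None else None,
        "restricted_to": [(iv.start_s, iv.end_s) for iv in es.restricted_to],
    }
    with open(path, "w", newline="") as fh:
        fh.write(f"# ripplekit-events {json.dumps(meta)}\n")
        writer = csv.writer(fh)
        writer.writerow(_EVENT_COLUMNS)
        for e in es.events:
            writer.writerow(
                [e.kind]
                + [f"{v:.17g}" for v in (e.start_s, e.end_s, e.center_s,
                                         e.peak_time_s, e.peak_amp)]
            )


def read_event_table(path: str | Path) -> EventSet:
    path = Path(path)
    meta: dict = {}
    rows: list[OscEvent] = []
    with open(path, newline="") as fh:
        lines = fh.readlines()
    body = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            tag = "# ripplekit-events "
            if line.startswith(tag):
                meta = json.loads(line[len(tag):])
            continue
        body.append((lineno, line))
    if not body:
        raise FormatError("event table has no header row")
    header = next(csv.reader([body[0][1]]))
    if header != _EVENT_COLUMNS:
        raise FormatError(f"unexpected columns {header}")
    for lineno, line in body[1:]:
        if not line.strip():
            continue
        vals = next(csv.reader([line]))
        if len(vals) != len(_EVENT_COLUMNS):
            raise FormatError(f"line {lineno}: expected "
                              f"{len(_EVENT_COLUMNS)} fields, got {len(vals)}")
        try:
            kind = vals[0]
            start, end, center, peak_t, peak_a = map(float, vals[1:])
        except ValueError as e:
            raise FormatError(f"line {lineno}: {e}") from None
        if end <= start:
            raise FormatError(f"line {lineno}: end_s <= start_s")
        if abs(center - 0.5 * (start + end)) > 1e-6:
            raise FormatError(f"line {lineno}: center_s is not the midpoint")
        try:
            rows.append(OscEvent(kind=kind, start_s=start, end_s=end,
                                 peak_amp=peak_a, peak_time_s=peak_t))
        except IntegrityError as e:
            raise FormatError(f"line {lineno}: {e}") from None
    params = None
    if meta.get("params"):
        params = DetectionParams(**meta["params"])
    restricted = [
        StateInterval(a, b, "NREM") for a, b in meta.get("restricted_to", [])
    ]
    return EventSet(
        kind=meta.get("kind", rows[0].kind if rows else "event"),
        events=rows,
        params=params,
        source_role=meta.get("source_role"),
        restricted_to=restricted,
    )


# ---------------------------------------------------------------------------
# hypnograms


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# ripplekit-hypnogram duration_s={hyp.recording_duration_s!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["start_s", "end_s", "state"])
        for iv in hyp.intervals:
            writer.writerow([f"{iv.start_s:.17g}", f"{iv.end_s:.17g}", iv.state])


def read_hypnogram(path: str | Path) -> Hypnogram:
    duration = None
    intervals = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                if "duration_s=" in line:
                    duration = float(line.split("duration_s=")[1])
                continue
            vals = next(csv.reader([line]))
            if vals == ["start_s", "end_s", "state"]:
                continue
            if not line.strip():
                continue
            try:
                intervals.append(
                    StateInterval(float(vals[0]), float(vals[1]), vals[2])
                )
            except (ValueError, IndexError, IntegrityError) as e:
                raise FormatError(f"line {lineno}: {e}") from None
    if duration is None:
        duration = intervals[-1].end_s if intervals else 0.0
    return Hypnogram(intervals, duration)
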