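"""Minimal EDF (European Data Format) reader and writer.

Supports the plain EDF subset this package needs: 16-bit integer data
records, per-signal sampling rates, physical scaling from the header
calibration fields. Per-channel rates are preserved exactly as stored —
nothing is resampled — and values are returned in each signal's native
physical unit from the header (mV for the bundled synthetic fixtures).

Not supported: EDF+ annotation signals, discontinuous records, logarithmic
transducer types.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np

from .errors import DataFormatError, ValidationError

HEADER_BYTES = 256
SIGNAL_HEADER_BYTES = 256
DIG_MIN, DIG_MAX = -32768, 32767


@dataclass
class EdfHeader:
    patient_id: str
    recording_id: str
    start_date: str
    start_time: str
    n_records: int
    record_duration: float
    labels: List[str]
    units: List[str]
    phys_min: List[float]
    phys_max: List[float]
    dig_min: List[int]
    dig_max: List[int]
    samples_per_record: List[int]

    @property
    def n_signals(self) -> int:
        return len(self.labels)

    def fs(self, i: int) -> float:
        return self.samples_per_record[i] / self.record_duration


def _ascii(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValidationError(f"EDF header field {s!r} longer than {width} chars")
    return s.ljust(width).encode("ascii")


def _parse_num(raw: bytes, field_name: str, cast):
    try:
        return cast(raw.decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise DataFormatError(
            f"malformed EDF header field {field_name!r}: {raw!r}"
        ) from exc


def read_header(path: str | Path) -> EdfHeader:
    """Parse and validate the EDF header, including a file-size check.

    A file whose size disagrees with ``n_records`` x record size is reported
    as truncated rather than silently shortened.
    """
    path = Path(path)
    with open(path, "rb") as f:
        head = f.read(HEADER_BYTES)
        if len(head) < HEADER_BYTES:
            raise DataFormatError(f"{path}: file shorter than the 256-byte EDF header")
        patient_id = head[8:88].decode("ascii", "replace").strip()
        recording_id = head[88:168].decode("ascii", "replace").strip()
        start_date = head[168:176].decode("ascii", "replace").strip()
        start_time = head[176:184].decode("ascii", "replace").strip()
        header_bytes = _parse_num(head[184:192], "number of bytes in header", int)
        n_records = _parse_num(head[236:244], "number of data records", int)
        record_duration = _parse_num(head[244:252], "duration of a data record", float)
        ns = _parse_num(head[252:256], "number of signals", int)
        if ns <= 0:
            raise DataFormatError(f"{path}: non-positive signal count {ns}")
        if header_bytes != HEADER_BYTES * (ns + 1):
            raise DataFormatError(
                f"{path}: header-size field {header_bytes} inconsistent with "
                f"{ns} signals (expected {HEADER_BYTES * (ns + 1)})"
            )
        sig = f.read(SIGNAL_HEADER_BYTES * ns)
        if len(sig) < SIGNAL_HEADER_BYTES * ns:
            raise DataFormatError(f"{path}: truncated signal header")

    def fields(offset: int, width: int) -> List[bytes]:
        base = offset * ns
        return [sig[base + i * width : base + (i + 1) * width] for i in range(ns)]

    # cumulative per-signal byte offsets: label 0, transducer 16, unit 96,
    # phys min 104, phys max 112, dig min 120, dig max 128, prefilter 136,
    # samples/record 216, reserved 224
    labels = [b.decode("ascii", "replace").strip() for b in fields(0, 16)]
    units = [b.decode("ascii", "replace").strip() for b in fields(96, 8)]
    phys_min = [_parse_num(b, "physical minimum", float) for b in fields(104, 8)]
    phys_max = [_parse_num(b, "physical maximum", float) for b in fields(112, 8)]
    dig_min = [_parse_num(b, "digital minimum", int) for b in fields(120, 8)]
    dig_max = [_parse_num(b, "digital maximum", int) for b in fields(128, 8)]
    spr = [_parse_num(b, "samples per record", int) for b in fields(216, 8)]

    for i in range(ns):
        if dig_max[i] <= dig_min[i]:
            raise DataFormatError(
                f"{path}: signal {labels[i]!r} has digital maximum <= minimum"
            )
        if phys_max[i] == phys_min[i]:
            raise DataFormatError(
                f"{path}: signal {labels[i]!r} has equal physical min and max"
            )
        if spr[i] <= 0:
            raise DataFormatError(
                f"{path}: signal {labels[i]!r} has non-positive samples per record"
            )
    record_bytes = 2 * sum(spr)
    expected = HEADER_BYTES * (ns + 1) + n_records * record_bytes
    actual = path.stat().st_size
    if actual != expected:
        raise DataFormatError(
            f"{path}: file size {actual} does not match header "
            f"(number of data records {n_records} implies {expected} bytes); "
            "file is truncated or padded"
        )
    return EdfHeader(
        patient_id=patient_id,
        recording_id=recording_id,
        start_date=start_date,
        start_time=start_time,
        n_records=n_records,
        record_duration=record_duration,
        labels=labels,
        units=units,
        phys_min=phys_min,
        phys_max=phys_max,
        dig_min=dig_min,
        dig_max=dig_max,
        samples_per_record=spr,
    )


def read_edf(path: str | Path) -> tuple[EdfHeader, Dict[str, np.ndarray]]:
    """Read an EDF file into per-channel physical-unit arrays."""
    header = read_header(path)
    ns = header.n_signals
    spr = header.samples_per_record
    raw = np.fromfile(
        path, dtype="<i2", offset=HEADER_BYTES * (ns + 1)
    ).reshape(header.n_records, sum(spr))
    offsets = np.concatenate(([0], np.cumsum(spr)))
    data: Dict[str, np.ndarray] = {}
    for i, label in enumerate(header.labels):
        dig = raw[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(np.float64)
        gain = (header.phys_max[i] - header.phys_min[i]) / (
            header.dig_max[i] - header.dig_min[i]
        )
        data[label] = (dig - header.dig_min[i]) * gain + header.phys_min[i]
    return header, data


def write_edf(
    path: str | Path,
    signals: Dict[str, np.ndarray],
    fs: Dict[str, float] | float,
    *,
    units: str | Dict[str, str] = "mV",
    phys_range: Dict[str, float] | float = 100.0,
    patient_id: str = "X",
    recording_id: str = "Startdate X",
    start_date: str = "01.01.01",
    start_time: str = "00.00.00",
) -> None:
    """Write channels to EDF with 1-s data records and 16-bit quantization.

    ``phys_range`` r maps to a symmetric physical scale [-r, +r] per channel;
    values outside are clipped. Every channel's length must be a whole number
    of seconds at its rate so records tile exactly.
    """
    labels = list(signals)
    if not labels:
        raise ValidationError("no signals to write")
    fs_map = {ch: float(fs[ch] if isinstance(fs, dict) else fs) for ch in labels}
    unit_map = {ch: (units[ch] if isinstance(units, dict) else units) for ch in labels}
    range_map = {
        ch: float(phys_range[ch] if isinstance(phys_range, dict) else phys_range)
        for ch in labels
    }
    spr = {}
    n_records = None
    for ch in labels:
        if fs_map[ch] <= 0 or fs_map[ch] != int(fs_map[ch]):
            raise ValidationError(f"channel {ch!r}: fs must be a positive integer Hz")
        if range_map[ch] <= 0:
            raise ValidationError(f"channel {ch!r}: phys_range must be positive")
        # encode with the same value the 8-char ASCII header field stores,
        # so decode gain matches encode gain exactly
        range_map[ch] = float(f"{range_map[ch]:g}")
        spr[ch] = int(fs_map[ch])
        n = len(signals[ch])
        if n == 0 or n % spr[ch]:
            raise ValidationError(
                f"channel {ch!r}: length {n} is not a whole number of seconds "
                f"at {spr[ch]} Hz"
            )
        nrec = n // spr[ch]
        if n_records is None:
            n_records = nrec
        elif nrec != n_records:
            raise ValidationError("all channels must span the same duration")

    ns = len(labels)
    head = b"0".ljust(8)
    head += _ascii(patient_id, 80)
    head += _ascii(recording_id, 80)
    head += _ascii(start_date, 8)
    head += _ascii(start_time, 8)
    head += _ascii(str(HEADER_BYTES * (ns + 1)), 8)
    head += b" " * 44
    head += _ascii(str(n_records), 8)
    head += _ascii("1", 8)
    head += _ascii(str(ns), 4)

    def block(values: Sequence[object], width: int) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    head += block(labels, 16)
    head += block(["" for _ in labels], 80)  # transducer type
    head += block([unit_map[ch] for ch in labels], 8)
    head += block([f"{-range_map[ch]:g}" for ch in labels], 8)
    head += block([f"{range_map[ch]:g}" for ch in labels], 8)
    head += block([str(DIG_MIN) for _ in labels], 8)
    head += block([str(DIG_MAX) for _ in labels], 8)
    head += block(["" for _ in labels], 80)  # prefiltering
    head += block([str(spr[ch]) for ch in labels], 8)
    head += block(["" for _ in labels], 32)  # reserved

    digital = {}
    for ch in labels:
        r = range_map[ch]
        gain = (DIG_MAX - DIG_MIN) / (2.0 * r)
        dig = np.rint((np.asarray(signals[ch], dtype=float) + r) * gain) + DIG_MIN
        digital[ch] = np.clip(dig, DIG_MIN, DIG_MAX).astype("<i2")

    path = Path(path)
    try:
        with open(path, "wb") as f:
            f.write(head)
            for rec in range(n_records):
                for ch in labels:
                    f.write(digital[ch][rec * spr[ch] : (rec + 1) * spr[ch]].tobytes())
    except OSError as exc:
        raise DataFormatError(f"failed to write EDF to {path}: {exc}") from exc
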