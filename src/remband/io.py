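"""Recordings, hypnograms, and REM epoch extraction.

A :class:`Recording` holds the bipolar EEG channels of one overnight
polysomnogram with per-channel sampling rates and physical units. A
:class:`Hypnogram` is the expert sleep scoring: an ordered, non-overlapping
list of ``(stage, onset, duration)`` annotations in seconds from recording
start (half-open intervals). REM annotations are tiled into consecutive,
non-overlapping 30-s epochs starting at each annotation onset; a trailing
remainder shorter than one epoch is discarded.

Hypnogram dialect: UTF-8 text, one annotation per line,
``STAGE ONSET_SECONDS DURATION_SECONDS`` separated by whitespace, ``#``
starts a comment. Stages: W, S1, S2, S3, S4, REM, MT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import edf
from .errors import DataFormatError, ValidationError

EPOCH_SECONDS = 30.0
STAGES = ("W", "S1", "S2", "S3", "S4", "REM", "MT")


@dataclass
class Recording:
    """Multichannel signal container; no resampling, native units."""

    subject_id: str
    channels: Dict[str, np.ndarray]
    fs: Dict[str, float]
    units: Dict[str, str]

    def __post_init__(self) -> None:
        for ch, sig in self.channels.items():
            if len(sig) == 0:
                raise ValidationError(f"channel {ch!r} is empty")
            if self.fs.get(ch, 0) <= 0:
                raise ValidationError(f"channel {ch!r} has non-positive fs")

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            raise LookupError(
                f"channel {label!r} not in recording {self.subject_id!r}; "
                f"available: {sorted(self.channels)}"
            )
        return self.channels[label]


@dataclass
class Hypnogram:
    """Ordered list of (stage, onset, duration) annotations, seconds."""

    entries: List[Tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = -np.inf
        prev_onset = -np.inf
        for stage, onset, duration in self.entries:
            if stage not in STAGES:
                raise ValidationError(f"unknown sleep stage {stage!r}")
            if duration <= 0:
                raise ValidationError(
                    f"non-positive duration {duration} at onset {onset}"
                )
            if onset < prev_onset:
                raise ValidationError(
                    f"onsets not non-decreasing at onset {onset}"
                )
            if onset < prev_end - 1e-9:
                raise ValidationError(
                    f"overlapping annotations at onset {onset}"
                )
            prev_onset, prev_end = onset, onset + duration

    def __len__(self) -> int:
        return len(self.entries)

    def rem_intervals(self) -> List[Tuple[float, float]]:
        return [(on, dur) for stage, on, dur in self.entries if stage == "REM"]


@dataclass
class RemEpoch:
    """One 30-s single-channel REM segment with its provenance."""

    subject_id: str
    group: str
    channel: str
    signal: np.ndarray
    fs: float
    onset: float

    def __post_init__(self) -> None:
        expected = int(round(EPOCH_SECONDS * self.fs))
        if len(self.signal) != expected:
            raise ValidationError(
                f"epoch length {len(self.signal)} != {expected} samples "
                f"(30 s at {self.fs} Hz)"
            )


def read_recording(path: str | Path, subject_id: str | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (native units, native rates)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDF file: {path}")
    header, data = edf.read_edf(path)
    fs = {label: header.fs(i) for i, label in enumerate(header.labels)}
    units = dict(zip(header.labels, header.units))
    return Recording(
        subject_id=subject_id or path.stem,
        channels=data,
        fs=fs,
        units=units,
    )


def read_hypnogram(path: str | Path) -> Hypnogram:
    """Parse the whitespace hypnogram dialect; errors carry line numbers."""
    entries: List[Tuple[str, float, float]] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise DataFormatError(
                f"{path}:{lineno}: expected 'STAGE ONSET DURATION', got {line!r}"
            )
        stage = parts[0]
        if stage not in STAGES:
            raise DataFormatError(
                f"{path}:{lineno}: unknown stage code {stage!r} "
                f"(expected one of {', '.join(STAGES)})"
            )
        try:
            onset, duration = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise DataFormatError(
                f"{path}:{lineno}: non-numeric onset/duration in {line!r}"
            ) from exc
        entries.append((stage, onset, duration))
    try:
        return Hypnogram(entries=entries)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    lines = [f"{stage} {onset:g} {duration:g}" for stage, onset, duration in hyp.entries]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def extract_rem_epochs(
    rec: Recording,
    hyp: Hypnogram,
    channel: str,
    group: str,
    epoch_seconds: float = EPOCH_SECONDS,
) -> List[RemEpoch]:
    """Tile every REM annotation into consecutive non-overlapping epochs.

    Tiling starts at each annotation onset; a remainder shorter than
    ``epoch_seconds`` is discarded. No epoch crosses an annotation boundary.
    """
    signal = rec.channel(channel)
    fs = rec.fs[channel]
    n_samples = int(round(epoch_seconds * fs))
    if abs(epoch_seconds * fs - n_samples) > 1e-9:
        raise ValidationError(
            f"epoch length {epoch_seconds} s is not integral at fs={fs} Hz"
        )
    epochs: List[RemEpoch] = []
    for onset, duration in hyp.rem_intervals():
        count = int(duration // epoch_seconds)
        for k in range(count):
            t0 = onset + k * epoch_seconds
            i0 = int(round(t0 * fs))
            if i0 + n_samples > len(signal):
                break  # annotation extends past the recorded signal
            epochs.append(
                RemEpoch(
                    subject_id=rec.subject_id,
                    group=group,
                    channel=channel,
                    signal=signal[i0 : i0 + n_samples],
                    fs=fs,
                    onset=t0,
                )
            )
    return epochs


def rem_accounting(epochs: Iterable[RemEpoch]) -> pd.DataFrame:
    """Per-subject epoch counts and REM seconds, with subtotals appended."""
    counts: Dict[str, int] = {}
    groups: Dict[str, str] = {}
    for ep in epochs:
        counts[ep.subject_id] = counts.get(ep.subject_id, 0) + 1
        groups[ep.subject_id] = ep.group
    return accounting_from_counts(
        {s: (groups[s], c) for s, c in counts.items()}
    )


def accounting_from_counts(
    per_subject: Dict[str, Tuple[str, int]],
    epoch_seconds: float = EPOCH_SECONDS,
) -> pd.DataFrame:
    """Accounting table from ``{subject: (group, epoch_count)}``.

    Appends one subtotal row per group and a grand-total row; seconds are
    ``epoch_count * epoch_seconds`` throughout.
    """
    rows = [
        {
            "subject": s,
            "group": g,
            "epoch_count": int(c),
            "total_seconds": float(c) * epoch_seconds,
        }
        for s, (g, c) in per_subject.items()
    ]
    table = pd.DataFrame(rows, columns=["subject", "group", "epoch_count", "total_seconds"])
    extras = []
    for g, sub in table.groupby("group", sort=True):
        extras.append(
            {
                "subject": f"subtotal:{g}",
                "group": g,
                "epoch_count": int(sub["epoch_count"].sum()),
                "total_seconds": float(sub["total_seconds"].sum()),
            }
        )
    extras.append(
        {
            "subject": "total",
            "group": "all",
            "epoch_count": int(table["epoch_count"].sum()),
            "total_seconds": float(table["total_seconds"].sum()),
        }
    )
    return pd.concat([table, pd.DataFrame(extras)], ignore_index=True)


def read_manifest(path: str | Path) -> List[Dict[str, str]]:
    """Read a cohort manifest: list of subject records with file paths."""
    path = Path(path)
    try:
        records = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise DataFormatError(f"{path}: invalid JSON manifest: {exc}") from exc
    required = {"subject_id", "group", "edf_path", "hypnogram_path"}
    for rec in records:
        missing = required - set(rec)
        if missing:
            raise DataFormatError(f"{path}: manifest entry missing {missing}")
    return records
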