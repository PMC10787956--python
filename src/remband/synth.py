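"""Seeded two-group synthetic polysomnography cohorts.

The generator emulates the statistical structure the downstream pipeline
measures, not EEG morphology: each channel is a sum of four independent
band-limited Gaussian noise components (zero-phase Butterworth band-pass of
white noise at the nominal band edges, rescaled to a target standard
deviation in mV), optionally plus a sub-1-Hz sinusoidal drift and a >30 Hz
contaminant that exercise the wavelet band filtering. Hypnograms interleave
REM blocks with non-REM filler stages so epoch extraction faces distractor
annotations.

Setting group profiles from target *relative* band powers is non-trivial:
the analysis chain's Welch settings (128-sample Hamming window, a 4-Hz
resolution bandwidth) and the dyadic DB5 band split both leak power across
neighbouring bands, so measured RPSD is a known linear distortion of the
component variances. :func:`profile_from_rpsd` therefore calibrates a 4x4
leakage matrix of the analysis chain once (Monte-Carlo, fixed internal seed)
and solves for non-negative component variances whose *measured* RPSD hits
the targets. Without this step a variance-proportional profile misses
delta-dominant targets by tens of percentage points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import nnls
from scipy.signal import butter, sosfiltfilt

from .bands import BANDS, BAND_ORDER, dwt_band_split
from .errors import DataFormatError, ValidationError
from .io import Hypnogram, Recording, write_hypnogram
from . import edf as edf_mod
from . import spectral

#: Channel montage of the study recordings.
DEFAULT_CHANNELS: Tuple[str, ...] = ("F4C4", "C4P4", "Fp1F3", "F3C3", "C4A1")

#: Butterworth order for the band-limited noise components. Order 6 keeps the
#: out-of-band skirts small enough that a single-band component holds >=90%
#: of its 1-30 Hz power inside the nominal range.
COMPONENT_FILTER_ORDER = 6

_CALIBRATION_SEED = 202406  # internal; independent of user cohort seeds
_CALIBRATION_REPS = 20


@dataclass(frozen=True)
class BandProfile:
    """Per-band target SDs (mV) plus artifact amplitudes of one group."""

    band_sd: Mapping[str, float]
    drift_amp: float = 0.0  # sub-1-Hz sinusoidal drift, mV
    hf_amp: float = 0.0  # >30 Hz contamination, mV

    def __post_init__(self) -> None:
        if set(self.band_sd) != set(BANDS):
            raise ValidationError(
                f"band_sd keys must be exactly {set(BANDS)}, got {set(self.band_sd)}"
            )
        if any(v < 0 for v in self.band_sd.values()):
            raise ValidationError("band SDs must be non-negative")
        if self.drift_amp < 0 or self.hf_amp < 0:
            raise ValidationError("artifact amplitudes must be non-negative")

    @property
    def max_sd(self) -> float:
        return max(self.band_sd.values())


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate a cohort deterministically."""

    n_subjects_per_group: int = 2
    epochs_per_subject: Union[int, Mapping[str, Sequence[int]]] = 50
    epoch_len: float = 30.0
    fs: float = 512.0
    group_profiles: Mapping[str, BandProfile] = None
    seed: int = 0
    channels: Tuple[str, ...] = DEFAULT_CHANNELS
    rem_block_epochs: int = 10  # REM annotation blocks of up to this many epochs

    def __post_init__(self) -> None:
        if self.group_profiles is None:
            object.__setattr__(self, "group_profiles", default_group_profiles())
        if self.fs <= 60.0:
            raise ValidationError(f"fs must exceed 60 Hz (2 x 30 Hz), got {self.fs}")
        if self.epoch_len <= 0:
            raise ValidationError("epoch_len must be positive")
        if self.n_subjects_per_group < 1 or self.rem_block_epochs < 1:
            raise ValidationError("counts must be >= 1")
        for g, counts in self._counts_by_group().items():
            if any(c < 1 for c in counts):
                raise ValidationError(f"group {g!r} has a subject with zero epochs")

    def _counts_by_group(self) -> Dict[str, List[int]]:
        groups = list(self.group_profiles)
        if isinstance(self.epochs_per_subject, int):
            return {g: [self.epochs_per_subject] * self.n_subjects_per_group for g in groups}
        counts = {g: list(v) for g, v in self.epochs_per_subject.items()}
        if set(counts) != set(groups):
            raise ValidationError("epochs_per_subject mapping must cover every group")
        return counts


@dataclass
class SyntheticCohort:
    """Generated recordings with their hypnograms and ground truth."""

    spec: CohortSpec
    recordings: List[Recording]
    hypnograms: Dict[str, Hypnogram]
    groups: Dict[str, str]

    def recording(self, subject_id: str) -> Recording:
        for rec in self.recordings:
            if rec.subject_id == subject_id:
                return rec
        raise LookupError(f"no such subject {subject_id!r}")


#: Seconds of noise synthesized beyond each end and trimmed off, so the IIR
#: startup transient (seconds long for the 1-Hz delta edge) never reaches the
#: emitted signal.
_FILTER_PAD_SECONDS = 8.0


def _band_component(
    band: str, fs: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    lo, hi = BANDS[band]
    sos = butter(
        COMPONENT_FILTER_ORDER, [lo, hi], btype="band", fs=fs, output="sos"
    )
    pad = int(round(_FILTER_PAD_SECONDS * fs))
    y = sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad : pad + n]
    sd = y.std()
    return y / sd if sd > 0 else y


def synth_epoch(
    profile: BandProfile,
    fs: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One band-structured signal segment (mV), deterministic given ``rng``.

    Sum over bands of zero-phase band-pass-filtered white noise, each
    component rescaled to its target SD, plus the profile's drift and
    high-frequency components.
    """
    if duration <= 0 or fs <= 0:
        raise ValidationError("duration and fs must be positive")
    n_float = duration * fs
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 or n < 256:
        raise ValidationError(
            f"duration x fs must be an integer >= 256 samples, got {n_float}"
        )
    x = np.zeros(n)
    for band in BAND_ORDER:
        sd = float(profile.band_sd[band])
        if sd > 0:
            x += sd * _band_component(band, fs, n, rng)
    t = np.arange(n) / fs
    if profile.drift_amp > 0:
        f_d = rng.uniform(0.1, 0.5)
        x += profile.drift_amp * np.sin(2 * np.pi * f_d * t + rng.uniform(0, 2 * np.pi))
    if profile.hf_amp > 0:
        f_h = rng.uniform(32.0, min(45.0, 0.45 * fs))
        x += profile.hf_amp * np.sin(2 * np.pi * f_h * t + rng.uniform(0, 2 * np.pi))
    return x


@lru_cache(maxsize=8)
def leakage_matrix(fs: float = 512.0, duration: float = 30.0) -> np.ndarray:
    """4x4 matrix M with M[i, j] = measured APSD in band i per unit variance
    of a band-j noise component, under the full analysis chain (DB5 band
    split, study Welch settings, nominal-range integration).

    Monte-Carlo estimate over a fixed internal seed, so it is deterministic
    and independent of cohort seeds.
    """
    n = int(round(duration * fs))
    M = np.zeros((4, 4))
    rng = np.random.default_rng(_CALIBRATION_SEED)
    for j, band in enumerate(BAND_ORDER):
        acc = np.zeros(4)
        for _ in range(_CALIBRATION_REPS):
            comp = _band_component(band, fs, n, rng)
            powers = spectral.band_powers(dwt_band_split(comp, fs))
            acc += np.array([powers.apsd[b] for b in BAND_ORDER])
        M[:, j] = acc / _CALIBRATION_REPS
    return M


def profile_from_rpsd(
    rpsd_percent: Mapping[str, float],
    total_sd: float,
    *,
    fs: float = 512.0,
    duration: float = 30.0,
    drift_amp: float = 0.0,
    hf_amp: float = 0.0,
) -> BandProfile:
    """Band profile whose pipeline-measured RPSD matches the given targets.

    Solves the leakage-calibrated non-negative least-squares system for the
    component variances, then scales them so the summed component variance
    equals ``total_sd**2``. Targets are normalized to sum to 100.
    """
    if total_sd <= 0:
        raise ValidationError("total_sd must be positive")
    targets = np.array([float(rpsd_percent[b]) for b in BAND_ORDER])
    if (targets < 0).any() or targets.sum() <= 0:
        raise ValidationError("RPSD targets must be non-negative with positive sum")
    p = targets / targets.sum()
    var, _residual = nnls(leakage_matrix(fs, duration), p)
    if var.sum() <= 0:
        raise ValidationError("degenerate RPSD target: no positive solution")
    var *= total_sd**2 / var.sum()
    band_sd = dict(zip(BAND_ORDER, np.sqrt(var)))
    return BandProfile(band_sd=band_sd, drift_amp=drift_amp, hf_amp=hf_amp)


def default_group_profiles() -> Dict[str, BandProfile]:
    """Study conditions: group-mean relative band powers of the two groups
    (delta/theta/alpha/beta, percent), with the bruxism group carrying more
    total power so its theta/alpha/beta band SDs exceed the healthy group's.

    Healthy: 65.26 / 20.619 / 8.424 / 5.696 %, total SD 10.0 mV.
    Bruxism: 65.302 / 17.480 / 9.931 / 7.287 %, total SD 11.5 mV.
    Both include a 2 mV sub-1-Hz drift and a 0.5 mV >30 Hz component to
    exercise the band filtering.
    """
    healthy = profile_from_rpsd(
        {"delta": 65.26, "theta": 20.619, "alpha": 8.424, "beta": 5.696},
        total_sd=10.0,
        drift_amp=2.0,
        hf_amp=0.5,
    )
    bruxism = profile_from_rpsd(
        {"delta": 65.302, "theta": 17.480, "alpha": 9.931, "beta": 7.287},
        total_sd=11.5,
        drift_amp=2.0,
        hf_amp=0.5,
    )
    return {"healthy": healthy, "bruxism": bruxism}


_FILLER_STAGES = ("S2", "S1", "S3", "S4", "W")
_FILLER_SECONDS = 60.0


def _subject_hypnogram(n_epochs: int, epoch_len: float, block_epochs: int) -> Hypnogram:
    """REM blocks tiling exactly ``n_epochs * epoch_len`` seconds, interleaved
    with non-REM filler stages as extraction distractors."""
    entries: List[Tuple[str, float, float]] = []
    t = 0.0
    entries.append(("W", t, _FILLER_SECONDS))
    t += _FILLER_SECONDS
    remaining = n_epochs
    filler_i = 0
    while remaining > 0:
        k = min(block_epochs, remaining)
        entries.append(("REM", t, k * epoch_len))
        t += k * epoch_len
        remaining -= k
        stage = _FILLER_STAGES[filler_i % len(_FILLER_STAGES)]
        filler_i += 1
        entries.append((stage, t, _FILLER_SECONDS))
        t += _FILLER_SECONDS
    return Hypnogram(entries=entries)


def _total_seconds(hyp: Hypnogram) -> float:
    last = hyp.entries[-1]
    return last[1] + last[2]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate one recording and hypnogram per subject.

    Channels are independent draws from the subject's group profile; the
    random stream of each (subject, channel) derives from
    ``(spec.seed, subject index, channel index)`` so output is reproducible
    sample-for-sample.
    """
    counts = spec._counts_by_group()
    recordings: List[Recording] = []
    hypnograms: Dict[str, Hypnogram] = {}
    groups: Dict[str, str] = {}
    subject_index = 0
    for group in spec.group_profiles:
        profile = spec.group_profiles[group]
        for i, n_epochs in enumerate(counts[group]):
            subject_id = f"{group}{i + 1:02d}"
            hyp = _subject_hypnogram(n_epochs, spec.epoch_len, spec.rem_block_epochs)
            duration = _total_seconds(hyp)
            channels = {}
            for ci, ch in enumerate(spec.channels):
                rng = np.random.default_rng(
                    np.random.SeedSequence([int(spec.seed), subject_index, ci])
                )
                channels[ch] = synth_epoch(profile, spec.fs, duration, rng)
            recordings.append(
                Recording(
                    subject_id=subject_id,
                    channels=channels,
                    fs={ch: spec.fs for ch in spec.channels},
                    units={ch: "mV" for ch in spec.channels},
                )
            )
            hypnograms[subject_id] = hyp
            groups[subject_id] = group
            subject_index += 1
    return SyntheticCohort(
        spec=spec, recordings=recordings, hypnograms=hypnograms, groups=groups
    )


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> Dict[str, Path]:
    """Write one EDF + hypnogram per subject and a JSON manifest.

    The EDF quantization range is +-(8 x largest band SD + artifact
    amplitudes) per group so quantization error stays well below 0.1% of the
    signal SD. Header timestamps are fixed from the cohort seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seed = int(cohort.spec.seed)
    start_time = f"{seed % 24:02d}.{seed // 24 % 60:02d}.{seed // 1440 % 60:02d}"
    manifest = []
    for rec in cohort.recordings:
        group = cohort.groups[rec.subject_id]
        profile = cohort.spec.group_profiles[group]
        phys_range = 8.0 * profile.max_sd + profile.drift_amp + profile.hf_amp
        phys_range = max(phys_range, 1.0)
        edf_path = directory / f"{rec.subject_id}.edf"
        hyp_path = directory / f"{rec.subject_id}.hyp.txt"
        try:
            edf_mod.write_edf(
                edf_path,
                rec.channels,
                rec.fs,
                units="mV",
                phys_range=phys_range,
                patient_id=rec.subject_id,
                recording_id=f"Startdate 01.01.01 {rec.subject_id} synthetic",
                start_date="01.01.01",
                start_time=start_time,
            )
            write_hypnogram(cohort.hypnograms[rec.subject_id], hyp_path)
        except OSError as exc:
            raise DataFormatError(f"failed writing fixture under {directory}: {exc}") from exc
        manifest.append(
            {
                "subject_id": rec.subject_id,
                "group": group,
                "edf_path": edf_path.name,
                "hypnogram_path": hyp_path.name,
            }
        )
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return {
        "manifest": manifest_path,
        **{m["subject_id"]: directory / m["edf_path"] for m in manifest},
    }
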