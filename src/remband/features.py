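"""The 28-feature vector per REM epoch.

Per band (delta/theta/alpha/beta): mean, population SD and RMS of the
band-reconstructed signal (12 time-domain features, mV); relative band power
RPSD (%) and absolute band power APSD plus the spectral ratios
(theta+alpha)/beta, alpha/delta, alpha/theta, alpha/beta (12 frequency-domain
features); and sample entropy SampEn(m=5, r=0.2*SD) of the band signal
(4 nonlinear features).

Sample entropy follows the Richman-Moorman counting definition: with
templates of length m built from the series, B counts template pairs whose
Chebyshev distance is <= r, A counts the same pairs extended to length m+1,
self-matches excluded, and SampEn = -ln(A/B). Both lengths use the same
N - m template starts so the ratio is a conditional probability. The kernel
is exact integer counting (box-assisted: templates sorted by first sample so
only first-coordinate-compatible pairs are scanned), not an approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .bands import BANDS, BAND_ORDER, BandSignals, dwt_band_split
from .errors import DegenerateEpochError, ValidationError
from .io import RemEpoch
from .spectral import BandPowerSet, band_powers, band_powers_raw

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampEnParams:
    """Template length m and tolerance r as a fraction of the series SD."""

    m_max: int = 5
    r_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m_max < 1:
            raise ValidationError("m_max must be >= 1")
        if not 0.0 < self.r_frac < 1.0:
            raise ValidationError("r_frac must be in (0, 1)")


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-stage knobs; defaults reproduce the study settings."""

    sampen: SampEnParams = field(default_factory=SampEnParams)
    psd_on: str = "bands"  # "bands" (per band-signal Welch) or "raw" (one PSD)

    def __post_init__(self) -> None:
        if self.psd_on not in ("bands", "raw"):
            raise ValidationError("psd_on must be 'bands' or 'raw'")


def _names() -> List[str]:
    time = [f"{stat}_{b}" for stat in ("mean", "sd", "rms") for b in BAND_ORDER]
    freq = (
        [f"rpsd_{b}" for b in BAND_ORDER]
        + ["ratio_theta_alpha_beta", "ratio_alpha_delta", "ratio_alpha_theta", "ratio_alpha_beta"]
        + [f"apsd_{b}" for b in BAND_ORDER]
    )
    nonlinear = [f"sampen_{b}" for b in BAND_ORDER]
    return time + freq + nonlinear


#: Canonical ordering of the 28 features: 12 time, 12 frequency, 4 nonlinear.
FEATURE_NAMES: Tuple[str, ...] = tuple(_names())


def time_features(bands: BandSignals) -> Dict[str, float]:
    """Mean, population SD, and RMS per band signal (mV)."""
    out: Dict[str, float] = {}
    for b in BAND_ORDER:
        x = bands[b]
        out[f"mean_{b}"] = float(np.mean(x))
        out[f"sd_{b}"] = float(np.std(x))  # population SD (ddof=0)
        out[f"rms_{b}"] = float(np.sqrt(np.mean(x**2)))
    return out


def ratio_features(rpsd: Dict[str, float]) -> Dict[str, float]:
    """Spectral ratios from the RPSD percentages (scale-invariant)."""
    th, al, be, de = rpsd["theta"], rpsd["alpha"], rpsd["beta"], rpsd["delta"]
    if min(de, th, be) <= 0:
        raise DegenerateEpochError(
            "zero band power denominator in spectral ratios; epoch excluded"
        )
    return {
        "ratio_theta_alpha_beta": (th + al) / be,
        "ratio_alpha_delta": al / de,
        "ratio_alpha_theta": al / th,
        "ratio_alpha_beta": al / be,
    }


@njit(cache=True)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> Tuple[int, int]:
    """Exact (A, B) template-match counts, Chebyshev distance, matches at
    distance <= r, self-matches excluded. Box-assisted: template starts are
    sorted by first sample, so only pairs compatible in the first coordinate
    are examined; identical comparisons to the naive O(N^2) scan."""
    n_templates = x.shape[0] - m  # same starts for lengths m and m+1
    order = np.argsort(x[:n_templates], kind="mergesort")
    v = x[:n_templates][order]
    A = 0
    B = 0
    for p in range(n_templates - 1):
        q = p + 1
        while q < n_templates and v[q] - v[p] <= r:
            i = order[p]
            j = order[q]
            ok = True
            for k in range(1, m):
                d = x[i + k] - x[j + k]
                if d < 0.0:
                    d = -d
                if d > r:
                    ok = False
                    break
            if ok:
                B += 1
                d = x[i + m] - x[j + m]
                if d < 0.0:
                    d = -d
                if d <= r:
                    A += 1
            q += 1
    return A, B


def sample_entropy(signal: np.ndarray, params: SampEnParams = SampEnParams()) -> float:
    """SampEn(m, r) with m = ``params.m_max`` and r = ``params.r_frac`` x SD.

    Conventions for degenerate counts (each logged, never silent NaN):
    a constant series returns 0.0; B = 0 (no template matches at length m)
    returns 0.0; A = 0 with B > 0 returns ln(B), i.e. -ln(A/B) evaluated with
    A set to 1, the conventional cap when no m+1 match is observed.
    """
    x = np.ascontiguousarray(signal, dtype=np.float64)
    m = params.m_max
    if x.ndim != 1 or len(x) < m + 2:
        raise ValidationError(
            f"sample entropy needs a 1-D series of length >= {m + 2}"
        )
    sd = float(np.std(x))
    if sd == 0.0:
        logger.info("sample_entropy: constant series, returning 0 by convention")
        return 0.0
    r = params.r_frac * sd
    A, B = _sampen_counts(x, m, r)
    if B == 0:
        logger.info("sample_entropy: no length-%d template matches, returning 0", m)
        return 0.0
    if A == 0:
        logger.info(
            "sample_entropy: no length-%d matches among %d; capping at ln(B)", m + 1, B
        )
        return float(np.log(B))
    return float(-np.log(A / B))


def feature_vector(
    epoch: RemEpoch, cfg: FeatureConfig = FeatureConfig()
) -> Dict[str, float]:
    """Compute the canonical 28-entry feature vector for one epoch.

    Raises :class:`DegenerateEpochError` for zero-power epochs so callers can
    exclude them with a logged reason instead of emitting a NaN row.
    """
    bands = dwt_band_split(epoch.signal, epoch.fs)
    if cfg.psd_on == "bands":
        powers: BandPowerSet = band_powers(bands)
    else:
        powers = band_powers_raw(epoch.signal, epoch.fs)
    values: Dict[str, float] = {}
    values.update(time_features(bands))
    values.update({f"rpsd_{b}": powers.rpsd[b] for b in BAND_ORDER})
    values.update(ratio_features(powers.rpsd))
    values.update({f"apsd_{b}": powers.apsd[b] for b in BAND_ORDER})
    for b in BAND_ORDER:
        values[f"sampen_{b}"] = sample_entropy(bands[b], cfg.sampen)
    return {name: values[name] for name in FEATURE_NAMES}


def feature_table(
    epochs: List[RemEpoch], cfg: FeatureConfig = FeatureConfig()
) -> Tuple[pd.DataFrame, List[Dict[str, str]]]:
    """Feature rows for a list of epochs plus the exclusion log.

    Returns a DataFrame with epoch provenance columns (subject_id, group,
    channel, onset) followed by the 28 canonical feature columns, and a list
    of ``{subject_id, channel, onset, reason}`` records for excluded epochs.
    """
    rows = []
    exclusions: List[Dict[str, str]] = []
    for ep in epochs:
        try:
            feats = feature_vector(ep, cfg)
        except DegenerateEpochError as exc:
            record = {
                "subject_id": ep.subject_id,
                "channel": ep.channel,
                "onset": str(ep.onset),
                "reason": str(exc),
            }
            logger.warning("excluding epoch %s", record)
            exclusions.append(record)
            continue
        rows.append(
            {
                "subject_id": ep.subject_id,
                "group": ep.group,
                "channel": ep.channel,
                "onset": ep.onset,
                **feats,
            }
        )
    columns = ["subject_id", "group", "channel", "onset", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns), exclusions
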