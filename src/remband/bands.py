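"""Dyadic DB5 wavelet decomposition of an epoch into EEG rhythm bands.

The clinical bands are delta (1-4 Hz), theta (4-8 Hz), alpha (8-13 Hz) and
beta (13-30 Hz). A multilevel discrete wavelet transform with the Daubechies-5
mother wavelet splits the signal into dyadic detail bands; each rhythm is
reconstructed by inverting the transform with every other level zeroed. At
512 Hz the mapping is beta <- D4 (16-32 Hz), alpha <- D5 (8-16 Hz),
theta <- D6 (4-8 Hz), delta <- D7 u D8 (1-4 Hz); the approximation (< 1 Hz,
slow drift and ocular artifacts) and D1-D3 (> 32 Hz) are discarded, which is
what confines the analysis to the 1-30 Hz range.

Dyadic edges do not coincide with the nominal 13-30 / 8-13 Hz band edges;
downstream band power is therefore integrated over the *nominal* ranges (see
:mod:`remband.spectral`), so the dyadic mismatch only contributes residual
leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple

import numpy as np
import pywt

from .errors import UnsupportedRateError, ValidationError

#: Nominal band edges in Hz, in canonical order.
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_ORDER: Tuple[str, ...] = tuple(BANDS)

WAVELET = "db5"
BOUNDARY_MODE = "symmetric"  # symmetric extension; no wrap-around artifacts


@dataclass
class BandSignals:
    """Band-limited reconstructions of one epoch.

    ``signals`` maps each of the four bands to a series with the epoch's
    length; ``residual`` is the reconstruction of the discarded levels
    (approximation plus >32 Hz details), kept so that the perfect
    reconstruction identity ``sum(bands) + residual == original`` is checkable.
    """

    signals: Dict[str, np.ndarray]
    fs: float
    residual: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if set(self.signals) != set(BANDS):
            raise ValidationError(
                f"bands must be exactly {set(BANDS)}, got {set(self.signals)}"
            )
        lengths = {len(v) for v in self.signals.values()}
        if len(lengths) != 1:
            raise ValidationError(f"band series lengths differ: {lengths}")

    def __getitem__(self, band: str) -> np.ndarray:
        return self.signals[band]


def band_level_map(fs: float) -> Dict[str, List[int]]:
    """Map each band to the DWT detail levels covering its nominal range.

    Detail level *k* spans ``[fs/2**(k+1), fs/2**k]`` Hz, so the edges land on
    the clinical band boundaries only when ``fs = 32 * 2**j`` for an integer
    ``j >= 1`` (64, 128, 256, 512, ... Hz). For other rates no dyadic mapping
    covers 1-30 Hz and :class:`UnsupportedRateError` is raised.
    """
    if fs <= 0:
        raise ValidationError(f"fs must be positive, got {fs}")
    j = math.log2(fs / 32.0)
    if abs(j - round(j)) > 1e-9 or round(j) < 1:
        raise UnsupportedRateError(
            f"no dyadic DB5 band mapping covers 1-30 Hz at fs={fs} Hz; "
            "supported rates are 64*2**n Hz (64, 128, 256, 512, ...)"
        )
    k_beta = int(round(j))  # fs / 2**k_beta == 32
    return {
        "beta": [k_beta],
        "alpha": [k_beta + 1],
        "theta": [k_beta + 2],
        "delta": [k_beta + 3, k_beta + 4],
    }


def max_level(fs: float) -> int:
    """Decomposition depth: deepest detail level reaches down to 1 Hz."""
    return band_level_map(fs)["delta"][-1]


def dwt_band_split(signal: np.ndarray, fs: float) -> BandSignals:
    """Decompose ``signal`` into the four rhythm bands via multilevel DB5 DWT.

    Each band is the inverse transform keeping only its mapped detail levels;
    all reconstructions preserve the input length. The returned ``residual``
    holds everything outside 1-30 Hz (approximation + top detail levels).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"signal must be 1-D, got shape {x.shape}")
    levels = band_level_map(fs)
    depth = levels["delta"][-1]
    if len(x) < 2**depth:
        raise ValidationError(
            f"signal of length {len(x)} too short for a depth-{depth} "
            f"decomposition (need >= {2**depth} samples)"
        )
    coeffs = pywt.wavedec(x, WAVELET, mode=BOUNDARY_MODE, level=depth)
    # coeffs = [cA_depth, cD_depth, ..., cD_1]; detail level k sits at index depth-k+1
    n = len(x)

    def reconstruct(keep: List[int], keep_approx: bool) -> np.ndarray:
        kept = [
            c if (i == 0 and keep_approx) or (i > 0 and depth - i + 1 in keep) else np.zeros_like(c)
            for i, c in enumerate(coeffs)
        ]
        return pywt.waverec(kept, WAVELET, mode=BOUNDARY_MODE)[:n]

    signals = {b: reconstruct(ks, keep_approx=False) for b, ks in levels.items()}
    mapped = {k for ks in levels.values() for k in ks}
    discarded = [k for k in range(1, depth + 1) if k not in mapped]
    residual = reconstruct(discarded, keep_approx=True)
    return BandSignals(signals=signals, fs=fs, residual=residual)
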