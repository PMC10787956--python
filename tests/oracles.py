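"""Independent brute-force oracles used to cross-check the implementations.

Each oracle is deliberately naive — direct enumeration or O(N^2) counting —
and shares no code with the package paths it verifies.
"""

from __future__ import annotations

import itertools
from typing import Dict, Optional, Tuple

import numpy as np


def sampen_bruteforce(x: np.ndarray, m: int, r: float) -> Tuple[int, int]:
    """(A, B) template-match counts by all-pairs Chebyshev comparison.

    Templates of lengths m and m+1 both start at indices 0..N-m-1;
    self-matches excluded; a match is distance <= r.
    """
    x = np.asarray(x, dtype=float)
    n_templates = len(x) - m
    Xm = np.lib.stride_tricks.sliding_window_view(x, m)[:n_templates]
    Xm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:n_templates]
    A = B = 0
    for i in range(n_templates - 1):
        dm = np.max(np.abs(Xm[i + 1 :] - Xm[i]), axis=1)
        dm1 = np.max(np.abs(Xm1[i + 1 :] - Xm1[i]), axis=1)
        B += int(np.sum(dm <= r))
        A += int(np.sum(dm1 <= r))
    return A, B


def sampen_bruteforce_value(x: np.ndarray, m: int, r_frac: float) -> float:
    """SampEn value with the package's degenerate-count conventions."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    A, B = sampen_bruteforce(x, m, r_frac * sd)
    if B == 0:
        return 0.0
    if A == 0:
        return float(np.log(B))
    return float(-np.log(A / B))


def mw_u_statistic(x_ranks: Tuple[int, ...], n: int) -> int:
    """U of x from its pooled 0-based rank positions (tie-free)."""
    n1 = len(x_ranks)
    rank_sum = sum(r + 1 for r in x_ranks)
    return int(rank_sum - n1 * (n1 + 1) // 2)


def mw_enumerate(n1: int, n2: int) -> Dict[int, int]:
    """Exact null distribution of U by enumerating every rank assignment."""
    n = n1 + n2
    dist: Dict[int, int] = {}
    for subset in itertools.combinations(range(n), n1):
        u = mw_u_statistic(subset, n)
        dist[u] = dist.get(u, 0) + 1
    return dist


def mw_exact_two_sided_p(u: float, n1: int, n2: int, dist: Optional[Dict[int, int]] = None) -> float:
    """Two-sided exact p: 2*min(P(U<=u), P(U>=u)) clipped to 1."""
    if dist is None:
        dist = mw_enumerate(n1, n2)
    total = sum(dist.values())
    le = sum(c for v, c in dist.items() if v <= u + 1e-12)
    ge = sum(c for v, c in dist.items() if v >= u - 1e-12)
    return min(1.0, 2.0 * min(le, ge) / total)


def gini_oracle(neg: int, pos: int) -> float:
    n = neg + pos
    return 1.0 - (neg / n) ** 2 - (pos / n) ** 2


def cart_best_first_split(
    X: np.ndarray, y: np.ndarray, min_leaf: int = 1
) -> Optional[Tuple[float, int, float]]:
    """Exhaustive search over every (feature, midpoint) candidate.

    Returns (weighted impurity decrease, feature, threshold) with ties
    broken by lowest feature index then lowest threshold, or None if the
    node is pure or admits no valid split. Zero-gain candidates count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if len(set(y.tolist())) < 2:
        return None  # pure node: nothing to split
    parent = n * gini_oracle(int(np.sum(y == 0)), int(np.sum(y == 1)))
    best = None
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            t = (a + b) / 2
            left = X[:, f] < t
            nl, nr = int(left.sum()), int((~left).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            dec = (
                parent
                - nl * gini_oracle(int(np.sum(y[left] == 0)), int(np.sum(y[left] == 1)))
                - nr * gini_oracle(int(np.sum(y[~left] == 0)), int(np.sum(y[~left] == 1)))
            )
            if best is None or dec > best[0] + 1e-12:
                best = (dec, f, t)
    return best


def averaged_periodogram(
    x: np.ndarray, fs: float, nperseg: int = 128, noverlap: int = 64, nfft: int = 256
) -> Tuple[np.ndarray, np.ndarray]:
    """Naive Welch re-derivation: mean of modified periodograms of
    mean-detrended, Hamming-windowed, 50%-overlapping segments, one-sided
    density scaling."""
    from scipy.signal import get_window

    win = get_window("hamming", nperseg)  # periodic variant, as in Welch
    step = nperseg - noverlap
    n_seg = (len(x) - nperseg) // step + 1
    acc = np.zeros(nfft // 2 + 1)
    for s in range(n_seg):
        seg = x[s * step : s * step + nperseg]
        seg = (seg - seg.mean()) * win
        spec = np.abs(np.fft.rfft(seg, n=nfft)) ** 2
        acc += spec
    dens = acc / n_seg / (fs * np.sum(win**2))
    dens[1:-1] *= 2.0  # one-sided
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, dens
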