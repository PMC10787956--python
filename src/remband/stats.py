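"""Per-feature two-group screening: normality gate, rank-sum test, stars.

Epochs are pooled across subjects within each group and compared feature by
feature. A Shapiro-Wilk test gates each group's sample; under the ``auto``
policy a Welch two-sample t-test is used when both groups pass normality at
alpha = 0.05, otherwise the Mann-Whitney rank-sum test. The default policy
``force-mw`` applies the rank-sum test to every feature, which is the choice
actually made for this kind of data, where normality is mixed across
features. Raw p-values are reported per feature; no multiple-testing
correction is applied by default (a Benjamini-Hochberg option exists).

Stars: '**' for p <= 0.001, '*' for p <= 0.05, 'ns' otherwise.

Caveat, documented rather than resolved: epochs from the same subject are
not independent, yet the two-group tests treat pooled epochs as exchangeable
units. With few subjects per group the p-values are anti-conservative under
between-subject heterogeneity (pseudo-replication).
"""

from __future__ import annotations

from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .features import FEATURE_NAMES

ALPHA_STAR = 0.05
ALPHA_DOUBLE_STAR = 0.001

#: Sample-size ceiling below which the exact Mann-Whitney null is enumerated.
MW_EXACT_MAX_N = 16


def stars(p: float) -> str:
    if np.isnan(p):
        return "na"
    if p <= ALPHA_DOUBLE_STAR:
        return "**"
    if p <= ALPHA_STAR:
        return "*"
    return "ns"


def shapiro_wilk(sample: Sequence[float]) -> Tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value; valid for 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValidationError(
            f"Shapiro-Wilk requires 3 <= n <= 5000, got n={len(x)}"
        )
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Mann-Whitney U (for ``x``) and the two-sided p-value.

    The exact null distribution is enumerated when the pooled sample has at
    most :data:`MW_EXACT_MAX_N` observations and no ties; otherwise the
    normal approximation with tie and continuity corrections is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= MW_EXACT_MAX_N and tie_free) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _one_feature(
    a: np.ndarray, b: np.ndarray, policy: str
) -> Tuple[str, float]:
    """Choose and run the test for one feature; returns (test name, p)."""
    if np.ptp(np.concatenate([a, b])) == 0.0:
        return "degenerate", np.nan  # all pooled values identical; flagged
    if policy == "auto":
        normal = all(shapiro_wilk(s)[1] > ALPHA_STAR for s in (a, b))
        if normal:
            res = sps.ttest_ind(a, b, equal_var=False)  # Welch variant
            return "t", float(res.pvalue)
    _, p = mann_whitney(a, b)
    return "mann-whitney", p


def compare_groups(
    features_by_group: Dict[str, pd.DataFrame],
    policy: str = "force-mw",
    channel: str = "",
    feature_names: Sequence[str] = FEATURE_NAMES,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Significance table over features for two groups of epochs.

    ``features_by_group`` maps the two group names to DataFrames whose
    columns include ``feature_names``. Rows: channel, feature, per-group
    mean and SD, test used, p-value, stars. With ``bh_correct`` the stars
    are assigned on Benjamini-Hochberg adjusted p-values (off by default,
    matching the raw-p-value reporting convention).
    """
    if policy not in ("force-mw", "auto"):
        raise ValidationError(f"unknown stats policy {policy!r}")
    if len(features_by_group) != 2:
        raise ValidationError("compare_groups expects exactly two groups")
    (g1, df1), (g2, df2) = features_by_group.items()
    if len(df1) < 2 or len(df2) < 2:
        raise ValidationError("each group needs at least 2 epochs")
    rows = []
    for feat in feature_names:
        a = df1[feat].to_numpy(dtype=float)
        b = df2[feat].to_numpy(dtype=float)
        test_used, p = _one_feature(a, b, policy)
        rows.append(
            {
                "channel": channel,
                "feature": feat,
                f"{g1}_mean": float(a.mean()),
                f"{g1}_sd": float(a.std()),
                f"{g2}_mean": float(b.mean()),
                f"{g2}_sd": float(b.std()),
                "test_used": test_used,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    p_for_stars = table["p_value"]
    if bh_correct:
        p_for_stars = pd.Series(_benjamini_hochberg(table["p_value"].to_numpy()))
    table["stars"] = [stars(p) for p in p_for_stars]
    return table


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    ok = ~np.isnan(p)
    adj = np.full_like(p, np.nan, dtype=float)
    pv = p[ok]
    n = len(pv)
    order = np.argsort(pv)
    ranked = pv[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    adj[ok] = out
    return adj


def rpsd_group_summary(features: pd.DataFrame) -> pd.DataFrame:
    """Grouped-bar data: per (channel, band, group) mean and SE of RPSD."""
    rows = []
    for (channel, group), sub in features.groupby(["channel", "group"], sort=True):
        for band in ("delta", "theta", "alpha", "beta"):
            col = sub[f"rpsd_{band}"]
            rows.append(
                {
                    "channel": channel,
                    "band": band,
                    "group": group,
                    "mean": float(col.mean()),
                    "se": float(col.std(ddof=1) / np.sqrt(len(col))) if len(col) > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)
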