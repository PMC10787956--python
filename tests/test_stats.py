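"""Normality gate, rank-sum testing, and the significance table."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from remband import (
    ValidationError,
    compare_groups,
    mann_whitney,
    rpsd_group_summary,
    shapiro_wilk,
    stars,
)
from remband.features import FEATURE_NAMES

from oracles import mw_enumerate, mw_exact_two_sided_p, mw_u_statistic


class TestShapiroWilk:
    def test_matches_r_reference(self):
        """W and p agree with R's shapiro.test to 1e-6 on a seeded sample."""
        x = np.random.default_rng(42).standard_normal(50)
        W, p = shapiro_wilk(x)
        r = subprocess.run(
            [
                "Rscript",
                "-e",
                "x <- scan('stdin', quiet=TRUE); r <- shapiro.test(x);"
                " cat(sprintf('%.12f %.12f', r$statistic, r$p.value))",
            ],
            input=" ".join(f"{v:.17g}" for v in x),
            capture_output=True,
            text=True,
            check=True,
        )
        W_ref, p_ref = map(float, r.stdout.split())
        assert W == pytest.approx(W_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-6)

    def test_detects_heavy_skew(self):
        x = np.random.default_rng(1).exponential(size=200)
        _, p = shapiro_wilk(x)
        assert p < 0.05

    def test_accepts_gaussian(self):
        x = np.random.default_rng(2).standard_normal(200)
        _, p = shapiro_wilk(x)
        assert p > 0.05

    @pytest.mark.parametrize("n", [2, 5001])
    def test_sample_size_limits(self, n):
        with pytest.raises(ValidationError):
            shapiro_wilk(np.zeros(n))


class TestMannWhitney:
    def test_extreme_separation(self):
        U, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert p == pytest.approx(0.1)  # 2/20 enumerated arrangements

    def test_central_u(self):
        U, p = mann_whitney([1, 4], [2, 3])
        assert U == 2.0  # n1*n2/2
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(3, 3), (2, 5), (5, 4), (8, 8)])
    def test_exact_path_equals_enumeration(self, n1, n2):
        """Tie-free exact p equals the full-enumeration oracle for every
        achievable value of U at these sample sizes."""
        n = n1 + n2
        dist = mw_enumerate(n1, n2)
        seen = set()
        for subset in itertools.combinations(range(n), n1):
            u = mw_u_statistic(subset, n)
            if u in seen:
                continue
            seen.add(u)
            x = [float(r) for r in subset]
            y = [float(r) for r in range(n) if r not in subset]
            U, p = mann_whitney(x, y)
            assert U == u
            assert p == pytest.approx(mw_exact_two_sided_p(u, n1, n2, dist), abs=1e-12)

    def test_asymptotic_close_to_enumeration_at_8_plus_8(self):
        # the continuity-corrected normal approximation deviates from the
        # exact null by at most 0.0109 over every achievable U at n=8+8
        rng = np.random.default_rng(3)
        dist = mw_enumerate(8, 8)
        for _ in range(20):
            pooled = rng.standard_normal(16)
            x, y = pooled[:8], pooled[8:]
            ranks = np.argsort(np.argsort(pooled))
            u = mw_u_statistic(tuple(ranks[:8]), 16)
            exact = mw_exact_two_sided_p(u, 8, 8, dist)
            res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert abs(res.pvalue - exact) <= 0.011


def _feature_frame(rng, n, shift=0.0):
    data = {name: rng.standard_normal(n) + shift for name in FEATURE_NAMES}
    return pd.DataFrame(data)


class TestCompareGroups:
    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(0)
        df = _feature_frame(rng, 20)
        table = compare_groups({"healthy": df, "bruxism": df.copy()})
        assert (table["p_value"] == 1.0).all()
        assert (table["stars"] == "ns").all()
        assert len(table) == 28

    def test_shifted_feature_detected_with_direction(self):
        rng = np.random.default_rng(4)
        a = _feature_frame(rng, 60)
        b = _feature_frame(rng, 60)
        b["rpsd_beta"] += 2.0
        table = compare_groups({"healthy": a, "bruxism": b}, channel="C4P4")
        row = table[table["feature"] == "rpsd_beta"].iloc[0]
        assert row["stars"] in ("*", "**")
        assert row["bruxism_mean"] > row["healthy_mean"]
        assert row["channel"] == "C4P4"
        assert row["test_used"] == "mann-whitney"

    def test_auto_policy_picks_t_for_gaussian_mw_for_skewed(self):
        rng = np.random.default_rng(5)
        a = _feature_frame(rng, 80)
        b = _feature_frame(rng, 80)
        a["mean_delta"] = rng.exponential(size=80)  # heavy skew in one group
        b["mean_delta"] = rng.exponential(size=80)
        table = compare_groups({"healthy": a, "bruxism": b}, policy="auto")
        used = dict(zip(table["feature"], table["test_used"]))
        assert used["mean_delta"] == "mann-whitney"
        assert (table["test_used"] == "t").sum() > 14  # gaussian features use Welch t

    def test_degenerate_feature_flagged_not_crashed(self):
        rng = np.random.default_rng(6)
        a = _feature_frame(rng, 10)
        b = _feature_frame(rng, 10)
        a["sd_delta"] = 1.0
        b["sd_delta"] = 1.0
        table = compare_groups({"healthy": a, "bruxism": b})
        row = table[table["feature"] == "sd_delta"].iloc[0]
        assert row["test_used"] == "degenerate"
        assert row["stars"] == "na"

    def test_bad_policy_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValidationError):
            compare_groups(
                {"healthy": _feature_frame(rng, 5), "bruxism": _feature_frame(rng, 5)},
                policy="bonferroni",
            )


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.051, "ns"),
            (0.05, "*"),
            (0.01, "*"),
            (0.001, "**"),
            (1e-6, "**"),
            (float("nan"), "na"),
        ],
    )
    def test_thresholds(self, p, expected):
        assert stars(p) == expected


def test_rpsd_group_summary_shape():
    rng = np.random.default_rng(8)
    df = _feature_frame(rng, 12)
    df["channel"] = "C4P4"
    df["group"] = ["healthy"] * 6 + ["bruxism"] * 6
    out = rpsd_group_summary(df)
    assert len(out) == 8  # 1 channel x 4 bands x 2 groups
    assert set(out.columns) == {"channel", "band", "group", "mean", "se"}
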