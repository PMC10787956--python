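"""The 28-feature vector: time stats, ratios, sample entropy, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from remband import (
    DegenerateEpochError,
    FEATURE_NAMES,
    RemEpoch,
    SampEnParams,
    ValidationError,
    dwt_band_split,
    feature_table,
    feature_vector,
    ratio_features,
    sample_entropy,
    synth_epoch,
    time_features,
)
from remband.bands import BandSignals

from conftest import single_band_profile
from oracles import sampen_bruteforce_value


def _bands_from(values):
    sig = {b: np.asarray(v, dtype=float) for b, v in values.items()}
    return BandSignals(signals=sig, fs=512.0)


def _epoch(signal, group="healthy"):
    return RemEpoch(
        subject_id="s1", group=group, channel="C4P4",
        signal=np.asarray(signal, dtype=float), fs=512.0, onset=0.0,
    )


class TestTimeFeatures:
    def test_constant_band(self):
        bands = _bands_from({b: np.full(16, 2.5) for b in ("delta", "theta", "alpha", "beta")})
        feats = time_features(bands)
        assert feats["mean_delta"] == 2.5
        assert feats["sd_delta"] == 0.0
        assert feats["rms_delta"] == 2.5

    def test_plus_minus_three(self):
        bands = _bands_from({b: [3.0, -3.0] for b in ("delta", "theta", "alpha", "beta")})
        feats = time_features(bands)
        assert feats["mean_theta"] == 0.0
        assert feats["sd_theta"] == 3.0
        assert feats["rms_theta"] == 3.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
            min_size=2,
            max_size=64,
        )
    )
    def test_rms_identity(self, values):
        bands = _bands_from({b: values for b in ("delta", "theta", "alpha", "beta")})
        f = time_features(bands)
        lhs = f["rms_alpha"] ** 2
        rhs = f["sd_alpha"] ** 2 + f["mean_alpha"] ** 2
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


class TestRatios:
    def test_symmetric_rpsd(self):
        r = ratio_features({b: 25.0 for b in ("delta", "theta", "alpha", "beta")})
        assert r == {
            "ratio_theta_alpha_beta": 2.0,
            "ratio_alpha_delta": 1.0,
            "ratio_alpha_theta": 1.0,
            "ratio_alpha_beta": 1.0,
        }

    def test_arithmetic(self):
        r = ratio_features({"delta": 50.0, "theta": 25.0, "alpha": 12.5, "beta": 12.5})
        assert r["ratio_theta_alpha_beta"] == pytest.approx(3.0)
        assert r["ratio_alpha_delta"] == pytest.approx(0.25)
        assert r["ratio_alpha_theta"] == pytest.approx(0.5)
        assert r["ratio_alpha_beta"] == pytest.approx(1.0)

    def test_zero_denominator_is_degenerate(self):
        with pytest.raises(DegenerateEpochError):
            ratio_features({"delta": 50.0, "theta": 25.0, "alpha": 25.0, "beta": 0.0})


class TestSampleEntropy:
    def test_constant_series_is_zero(self):
        assert sample_entropy(np.ones(100)) == 0.0

    def test_period3_matches_bruteforce_exactly(self):
        x = np.tile([1.0, 2.0, 3.0], 20)
        params = SampEnParams(m_max=2, r_frac=0.2)
        ours = sample_entropy(x, params)
        oracle = sampen_bruteforce_value(x, 2, 0.2)
        assert ours == oracle

    def test_noisy_series_matches_bruteforce_and_exceeds_periodic(self):
        # a correlated-but-noisy series keeps template matches at m=5 (pure
        # iid noise at this length has essentially none, SampEn degenerates)
        rng = np.random.default_rng(123)
        t = np.arange(500)
        x = np.sin(2 * np.pi * 0.02 * t) + 0.3 * rng.standard_normal(500)
        ours = sample_entropy(x, SampEnParams(m_max=5, r_frac=0.2))
        assert ours == sampen_bruteforce_value(x, 5, 0.2)
        assert ours > 0.0
        periodic = sample_entropy(
            np.tile([1.0, 2.0, 3.0], 20), SampEnParams(m_max=2, r_frac=0.2)
        )
        assert ours > periodic  # perfectly periodic series has zero SampEn

    @pytest.mark.parametrize("seed", range(6))
    def test_kernel_equals_bruteforce_on_varied_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 400))
        kind = seed % 3
        if kind == 0:
            x = rng.standard_normal(n)
        elif kind == 1:  # strongly autocorrelated AR(1)
            x = np.zeros(n)
            eps = rng.standard_normal(n)
            for i in range(1, n):
                x[i] = 0.95 * x[i - 1] + eps[i]
        else:  # coarsely quantized, many exact ties
            x = np.round(rng.uniform(0, 4, n))
        m = int(rng.integers(1, 6))
        params = SampEnParams(m_max=m, r_frac=0.2)
        assert sample_entropy(x, params) == sampen_bruteforce_value(x, m, 0.2)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            sample_entropy(np.arange(5.0), SampEnParams(m_max=5))

    def test_param_validation(self):
        with pytest.raises(ValidationError):
            SampEnParams(m_max=0)
        with pytest.raises(ValidationError):
            SampEnParams(r_frac=1.5)


class TestFeatureVector:
    def test_exactly_28_named_features(self):
        x = synth_epoch(single_band_profile("alpha"), 512, 30, np.random.default_rng(1))
        feats = feature_vector(_epoch(x))
        assert list(feats) == list(FEATURE_NAMES)
        assert len(feats) == 28
        # 12 time, 12 frequency, 4 nonlinear
        time = [n for n in feats if n.split("_")[0] in ("mean", "sd", "rms")]
        freq = [n for n in feats if n.startswith(("rpsd", "ratio", "apsd"))]
        nonlinear = [n for n in feats if n.startswith("sampen")]
        assert (len(time), len(freq), len(nonlinear)) == (12, 12, 4)

    def test_pure_10hz_sine_has_alpha_rpsd_largest(self):
        t = np.arange(15360) / 512.0
        feats = feature_vector(_epoch(np.sin(2 * np.pi * 10.0 * t)))
        rpsds = {b: feats[f"rpsd_{b}"] for b in ("delta", "theta", "alpha", "beta")}
        assert max(rpsds, key=rpsds.get) == "alpha"

    def test_zero_epoch_excluded_not_nan(self):
        table, exclusions = feature_table([_epoch(np.zeros(15360))])
        assert len(table) == 0
        assert len(exclusions) == 1
        assert "power" in exclusions[0]["reason"]

    def test_scaling_behaviour(self):
        """x -> c*x: mean/sd/rms scale by c, apsd by c^2, rpsd/ratios fixed."""
        rng = np.random.default_rng(9)
        x = synth_epoch(single_band_profile("theta", 2.0), 512, 30, rng)
        f1 = feature_vector(_epoch(x))
        f2 = feature_vector(_epoch(2.0 * x))
        for b in ("delta", "theta", "alpha", "beta"):
            assert f2[f"sd_{b}"] == pytest.approx(2.0 * f1[f"sd_{b}"], rel=1e-9)
            assert f2[f"rms_{b}"] == pytest.approx(2.0 * f1[f"rms_{b}"], rel=1e-9)
            assert f2[f"apsd_{b}"] == pytest.approx(4.0 * f1[f"apsd_{b}"], rel=1e-9)
            assert f2[f"rpsd_{b}"] == pytest.approx(f1[f"rpsd_{b}"], rel=1e-9)
        for r in ("ratio_theta_alpha_beta", "ratio_alpha_delta"):
            assert f2[r] == pytest.approx(f1[r], rel=1e-9)

    def test_feature_table_order_invariance(self):
        rng = np.random.default_rng(2)
        eps = [
            _epoch(synth_epoch(single_band_profile("alpha"), 512, 30, rng))
            for _ in range(3)
        ]
        t1, _ = feature_table(eps)
        t2, _ = feature_table(eps[::-1])
        # identical per-epoch rows regardless of processing order
        for i in range(3):
            row1 = t1.iloc[i][list(FEATURE_NAMES)].astype(float)
            row2 = t2[::-1].reset_index(drop=True).iloc[i][list(FEATURE_NAMES)].astype(float)
            np.testing.assert_array_equal(row1.to_numpy(), row2.to_numpy())
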