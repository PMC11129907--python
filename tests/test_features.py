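"""Feature catalog oracles, MI ranking behaviour and selection determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorkit import FEATURE_NAMES, approximate_entropy, extract_features
from tremorkit.features import (
    LABEL_COLUMN,
    autocorr_zero_lag,
    frequency_features,
    mutual_information_ranking,
    select_top_k,
    time_domain_features,
    welch_psd,
)

FS = 50.0


def apen_bruteforce(x, m, r):
    """Independent O(n^2 m) double-loop ApEn (Pincus), self-matches included."""
    n = len(x)
    phis = []
    for mm in (m, m + 1):
        count_n = n - mm + 1
        log_sum = 0.0
        for i in range(count_n):
            count = 0
            for j in range(count_n):
                d = max(abs(x[i + k] - x[j + k]) for k in range(mm))
                if d <= r:
                    count += 1
            log_sum += np.log(count / count_n)
        phis.append(log_sum / count_n)
    return phis[0] - phis[1]


class TestTimeDomain:
    def test_constant_series(self):
        out = time_domain_features(np.full(100, 3.0))
        assert out["mean"] == 3.0
        assert out["std"] == 0.0
        assert out["iqr"] == 0.0
        assert out["rms"] == 3.0
        assert out["cv"] == 0.0

    def test_hand_arithmetic_1234(self):
        out = time_domain_features(np.array([1.0, 2.0, 3.0, 4.0]))
        assert out["mean"] == pytest.approx(2.5)
        assert out["std"] == pytest.approx(1.29099, abs=1e-5)
        assert out["rms"] == pytest.approx(2.73861, abs=1e-5)
        assert out["iqr"] == pytest.approx(1.5)

    @given(
        k=st.floats(0.1, 100.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=25, deadline=None)
    def test_scaling_homogeneity(self, k, seed):
        s = np.random.default_rng(seed).standard_normal(64)
        base = time_domain_features(s)
        scaled = time_domain_features(k * s)
        for key in ("mean", "std", "iqr", "rms"):
            assert scaled[key] == pytest.approx(k * base[key], rel=1e-9, abs=1e-12)
        if abs(base["mean"]) > 1e-9:
            assert scaled["cv"] == pytest.approx(base["cv"], rel=1e-9)


class TestWelch:
    def test_sine_peak_within_one_bin(self):
        t = np.arange(1500) / FS
        f, p = welch_psd(np.sin(2 * np.pi * 5.0 * t), FS)
        assert abs(f[np.argmax(p)] - 5.0) <= f[1] - f[0]

    def test_white_noise_flat(self):
        ps = np.mean(
            [welch_psd(np.random.default_rng(s).standard_normal(1500), FS)[1] for s in range(20)],
            axis=0,
        )
        assert ps.max() / ps.min() < 10.0

    def test_parseval_energy_conservation(self):
        t = np.arange(1500) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        f, p = welch_psd(x, FS)
        assert np.sum(p) * (f[1] - f[0]) == pytest.approx(np.var(x), rel=0.05)
        ratios = []
        for s in range(10):
            w = np.random.default_rng(s).standard_normal(1500)
            f, p = welch_psd(w, FS)
            ratios.append(np.sum(p) * (f[1] - f[0]) / np.var(w))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            welch_psd(np.zeros(20), FS)


class TestFrequencyFeatures:
    def test_pure_tone(self):
        t = np.arange(1500) / FS
        out = frequency_features(np.sin(2 * np.pi * 5.0 * t), FS)
        assert out["band_ratio"] >= 0.9
        assert out["spec_entropy"] <= 0.3

    def test_white_noise_entropy_high(self):
        out = frequency_features(np.random.default_rng(1).standard_normal(1500), FS)
        assert out["spec_entropy"] >= 0.9

    def test_zero_power_conventions(self):
        out = frequency_features(np.zeros(1500), FS)
        assert out == {"dom_freq": 0.0, "band_ratio": 0.0, "spec_entropy": 0.0}

    def test_single_bin_spectrum_entropy_zero(self):
        # degenerate distribution: all power in one bin -> H = 0
        p = np.zeros(64)
        p[10] = 1.0
        nz = p[p > 0]
        assert -np.sum(nz * np.log2(nz)) == 0.0


class TestApproximateEntropy:
    def test_constant_series_zero(self):
        assert approximate_entropy(np.full(100, 2.0)) == 0.0

    @pytest.mark.parametrize("n", [10, 25, 50, 100])
    def test_matches_bruteforce_exactly(self, n):
        x = np.random.default_rng(n).standard_normal(n)
        r = 0.2 * np.std(x)
        assert approximate_entropy(x, 2, r) == apen_bruteforce(x, 2, r)

    def test_tiny_printed_series_matches_bruteforce(self):
        x = np.array([1.0, 2.0, 1.0, 3.0, 1.0, 2.0, 2.0, 1.0, 3.0, 2.0])
        assert approximate_entropy(x, 2, 0.5) == apen_bruteforce(x, 2, 0.5)

    def test_noise_more_irregular_than_sine(self):
        t = np.arange(1500) / FS
        sine_vals, noise_vals = [], []
        for s in range(20):
            rng = np.random.default_rng(s)
            sine_vals.append(
                approximate_entropy(np.sin(2 * np.pi * 5.0 * t + rng.uniform(0, 6)))
            )
            noise_vals.append(approximate_entropy(rng.standard_normal(1500)))
        assert np.mean(noise_vals) > np.mean(sine_vals)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            approximate_entropy(np.zeros(3), m=2, r=0.1)


class TestAutocorr:
    def test_sine_quarter_period(self):
        t = np.arange(1500) / FS
        lag = autocorr_zero_lag(np.sin(2 * np.pi * 5.0 * t), FS)
        assert abs(lag - 0.05) <= 1.0 / FS

    def test_white_noise_decorrelates_fast(self):
        lags = [
            autocorr_zero_lag(np.random.default_rng(s).standard_normal(1500), FS)
            for s in range(10)
        ]
        assert np.mean(lags) <= 3.0 / FS

    def test_constant_is_zero(self):
        assert autocorr_zero_lag(np.full(100, 5.0), FS) == 0.0


class TestExtractFeatures:
    def test_ninety_named_columns(self, small_windows):
        fm = extract_features(small_windows[:3])
        assert list(fm.columns[:-1]) == list(FEATURE_NAMES)
        assert len(FEATURE_NAMES) == 90
        assert fm.columns[-1] == LABEL_COLUMN

    def test_duplicate_window_identical_rows(self, small_windows):
        fm = extract_features([small_windows[0], small_windows[0]])
        assert np.array_equal(fm.iloc[0].to_numpy(), fm.iloc[1].to_numpy())

    def test_scale_consistency(self, small_windows):
        # doubling the raw window doubles amplitude features, leaves
        # scale-free ones unchanged
        from tremorkit.features import window_features

        w = small_windows[0]

        class Doubled:
            data = 2.0 * w.data
            fs = w.fs
            label = w.label

        b = window_features(w)
        d = window_features(Doubled())
        for name in FEATURE_NAMES:
            series, suffix = name.split("__")
            if suffix in ("mean", "std", "iqr", "rms"):
                assert d[name] == pytest.approx(2.0 * b[name], rel=1e-6, abs=1e-12), name
            elif suffix in ("cv", "dom_freq", "band_ratio", "spec_entropy", "ac_zero_lag"):
                assert d[name] == pytest.approx(b[name], rel=1e-6, abs=1e-9), name


@pytest.fixture(scope="module")
def toy_matrix():
    rng = np.random.default_rng(0)
    n = 1000
    y = rng.integers(0, 3, size=n)
    fm = pd.DataFrame(
        {
            "informative": y + 0.05 * rng.standard_normal(n),
            "noise": rng.standard_normal(n),
        }
    )
    fm[LABEL_COLUMN] = y
    return fm


@pytest.fixture(scope="module")
def full_ranking():
    rng = np.random.default_rng(2)
    n = 300
    y = rng.integers(0, 3, size=n)
    fm = pd.DataFrame(rng.standard_normal((n, 90)), columns=list(FEATURE_NAMES))
    fm[LABEL_COLUMN] = y
    return mutual_information_ranking(fm)


class TestMutualInformation:
    def test_noise_feature_near_zero_mi(self, toy_matrix):
        rank = mutual_information_ranking(toy_matrix)
        mi = rank.set_index("feature")["mi"]
        assert mi["noise"] <= 0.02

    def test_informative_feature_near_label_entropy(self, toy_matrix):
        y = toy_matrix[LABEL_COLUMN].to_numpy()
        p = np.bincount(y) / len(y)
        h = -np.sum(p * np.log(p))  # nats
        rank = mutual_information_ranking(toy_matrix)
        mi = rank.set_index("feature")["mi"]
        assert mi["informative"] >= 0.9 * h

    def test_permutation_destroys_mi(self, toy_matrix):
        fm = toy_matrix.copy()
        fm["informative"] = np.random.default_rng(1).permutation(
            fm["informative"].to_numpy()
        )
        rank = mutual_information_ranking(fm)
        assert rank.set_index("feature")["mi"]["informative"] <= 0.02

    def test_single_class_rejected(self):
        fm = pd.DataFrame({"a": np.arange(10.0), LABEL_COLUMN: np.zeros(10, int)})
        with pytest.raises(ValueError):
            mutual_information_ranking(fm)

    def test_ranking_deterministic(self, toy_matrix):
        r1 = mutual_information_ranking(toy_matrix)
        r2 = mutual_information_ranking(toy_matrix)
        assert r1.equals(r2)


class TestSelectTopK:
    def test_identity_selection(self, full_ranking):
        assert set(select_top_k(full_ranking, k=90)) == set(FEATURE_NAMES)

    def test_thirty_selected_sixty_discarded(self, full_ranking):
        sel = select_top_k(full_ranking, k=30)
        assert len(sel) == 30
        assert len(set(FEATURE_NAMES) - set(sel)) == 60
        assert full_ranking["selected"].sum() == 30

    def test_tie_break_by_name_order(self):
        rank = pd.DataFrame({"feature": ["b", "a", "c"], "mi": [0.5, 0.5, 0.1]})
        rank = rank.sort_values("feature", kind="stable")
        rank = rank.sort_values("mi", ascending=False, kind="stable").reset_index(drop=True)
        rank["rank"] = np.arange(1, 4)
        assert select_top_k(rank, k=1) == ["a"]

    def test_k_too_large_rejected(self, full_ranking):
        with pytest.raises(ValueError):
            select_top_k(full_ranking, k=91)
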