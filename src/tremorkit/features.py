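"""The 90-feature catalog, mutual-information ranking and top-k selection.

For each of the 9 derived series per window, 10 scalar features are
computed, giving the 9 x 10 = 90-dimensional feature space:

time-domain statistics
    mean, standard deviation (n-1 denominator), interquartile range,
    coefficient of variation (SD/|mean|, 0 when the mean vanishes),
    root-mean-square;
frequency-domain features (Welch PSD, 8 segments, 50% overlap, Hann)
    dominant frequency (PSD argmax, Hz), tremor-band power ratio
    (power in 3.5-7.5 Hz over total), normalized spectral entropy;
nonlinear / regularity features
    approximate entropy ApEn(m=2, r=0.2*SD) and the lag (s) of the first
    zero-crossing of the biased autocorrelation.

Feature columns are named ``<series>__<feature>`` in a fixed order, so
rankings and selections are reproducible. The mutual information between
each continuous feature and the discrete severity label is estimated with
a k-nearest-neighbour estimator (k=3) averaged over several estimator
seeds; the top 30 features by MI are retained for modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as _sig
from sklearn.feature_selection import mutual_info_classif

from .preprocess import SERIES_NAMES, TREMOR_BAND, derive_series

FEATURE_SUFFIXES = (
    "mean",
    "std",
    "iqr",
    "cv",
    "rms",
    "dom_freq",
    "band_ratio",
    "spec_entropy",
    "apen",
    "ac_zero_lag",
)

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{series}__{suffix}" for series in SERIES_NAMES for suffix in FEATURE_SUFFIXES
)

LABEL_COLUMN = "label"


# ---------------------------------------------------------------------------
# per-series features


def time_domain_features(s: np.ndarray) -> dict[str, float]:
    """Mean, SD, IQR, coefficient of variation and RMS of one series."""
    s = np.asarray(s, dtype=float)
    if s.size == 0:
        raise ValueError("empty series")
    mean = float(np.mean(s))
    sd = float(np.std(s, ddof=1)) if s.size > 1 else 0.0
    q75, q25 = np.percentile(s, [75, 25])  # linear-interpolation quantiles
    cv = sd / abs(mean) if abs(mean) >= 1e-12 else 0.0
    return {
        "mean": mean,
        "std": sd,
        "iqr": float(q75 - q25),
        "cv": cv,
        "rms": float(np.sqrt(np.mean(s**2))),
    }


def welch_psd(s: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with 8 half-overlapping Hann segments tiling the window.

    Segment length is floor(2n/9) so that 8 segments at 50% overlap cover
    the series; raises ``ValueError`` if the series is too short for that.
    """
    s = np.asarray(s, dtype=float)
    nperseg = int(2 * len(s) // 9)
    if nperseg < 8:
        raise ValueError(f"series of {len(s)} samples too short for 8 Welch segments")
    return _sig.welch(
        s, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )


def frequency_features(s: np.ndarray, fs: float) -> dict[str, float]:
    """Dominant frequency, tremor-band power ratio and normalized spectral entropy.

    A zero-power series maps to (0, 0, 0) by convention.
    """
    freqs, psd = welch_psd(s, fs)
    total = float(np.sum(psd))
    if total <= 0.0 or not np.isfinite(total):
        return {"dom_freq": 0.0, "band_ratio": 0.0, "spec_entropy": 0.0}
    band = (freqs >= TREMOR_BAND[0]) & (freqs <= TREMOR_BAND[1])
    p = psd / total
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)) / np.log2(len(p))) if len(p) > 1 else 0.0
    return {
        "dom_freq": float(freqs[np.argmax(psd)]),
        "band_ratio": float(np.sum(psd[band]) / total),
        "spec_entropy": entropy,
    }


@njit(cache=True)
def _apen_kernel(x: np.ndarray, m: int, r: float) -> float:  # pragma: no cover
    n = x.shape[0]
    phi = np.empty(2)
    for mi in range(2):
        mm = m + mi
        cnt_n = n - mm + 1
        log_sum = 0.0
        for i in range(cnt_n):
            count = 0
            for j in range(cnt_n):
                d = 0.0
                for k in range(mm):
                    diff = abs(x[i + k] - x[j + k])
                    if diff > d:
                        d = diff
                if d <= r:
                    count += 1
            log_sum += np.log(count / cnt_n)
        phi[mi] = log_sum / cnt_n
    return phi[0] - phi[1]


def approximate_entropy(s: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """ApEn(m, r) a la Pincus: Phi_m(r) - Phi_{m+1}(r).

    Chebyshev distance, self-matches included. ``r`` defaults to
    0.2 * SD(s) (population SD). A constant series returns 0 by convention.
    """
    s = np.asarray(s, dtype=float)
    if len(s) < m + 2:
        raise ValueError(f"series of {len(s)} samples too short for ApEn(m={m})")
    if r is None:
        sd = float(np.std(s))
        if sd == 0.0:
            return 0.0
        r = 0.2 * sd
    if r <= 0:
        raise ValueError("r must be positive")
    return float(_apen_kernel(s, m, r))


def autocorr_zero_lag(s: np.ndarray, fs: float) -> float:
    """Lag (s) of the first zero-crossing of the biased autocorrelation.

    A constant series returns 0 by convention.
    """
    s = np.asarray(s, dtype=float)
    x = s - np.mean(s)
    if np.allclose(x, 0.0):
        return 0.0
    n = len(x)
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    r = np.fft.irfft(fx * np.conj(fx), nfft)[:n] / n  # biased estimator
    neg = np.flatnonzero(r[1:] <= 0.0)
    return float((neg[0] + 1) / fs) if neg.size else float((n - 1) / fs)


def series_features(s: np.ndarray, fs: float) -> dict[str, float]:
    """All 10 features of one derived series, keyed by suffix."""
    out = time_domain_features(s)
    out.update(frequency_features(s, fs))
    out["apen"] = approximate_entropy(s)
    out["ac_zero_lag"] = autocorr_zero_lag(s, fs)
    return out


# ---------------------------------------------------------------------------
# window-level extraction


def window_features(window) -> dict[str, float]:
    """The 90 named features of one labelled window."""
    series = derive_series(window)
    fs = float(window.fs)
    out: dict[str, float] = {}
    for name in SERIES_NAMES:
        feats = series_features(series[name], fs)
        for suffix in FEATURE_SUFFIXES:
            out[f"{name}__{suffix}"] = feats[suffix]
    return out


def extract_features(windows) -> pd.DataFrame:
    """Feature matrix (n windows x 90 features) with a trailing label column."""
    if not windows:
        raise ValueError("no windows given")
    rows = [window_features(w) for w in windows]
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    df[LABEL_COLUMN] = [w.label for w in windows]
    bad = df.columns[~np.isfinite(df.to_numpy()).all(axis=0)]
    if len(bad):
        raise ValueError(f"non-finite features: {list(bad)}")
    return df


# ---------------------------------------------------------------------------
# mutual-information ranking and selection


def mutual_information_ranking(
    fm: pd.DataFrame,
    n_neighbors: int = 3,
    n_seeds: int = 5,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Rank features by mutual information with the severity label.

    Uses the k-nearest-neighbour continuous-feature / discrete-label MI
    estimator (k=3), averaged over ``n_seeds`` estimator seeds (the
    estimator jitters feature values to break ties). Run on the full,
    pre-resampling matrix. Returns a frame ``feature, mi, rank, selected``
    sorted by descending MI with ties broken by fixed feature-name order.
    """
    if LABEL_COLUMN not in fm.columns:
        raise ValueError(f"feature matrix must carry a '{LABEL_COLUMN}' column")
    y = fm[LABEL_COLUMN].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("MI ranking needs at least 2 classes")
    X = fm.drop(columns=[LABEL_COLUMN])
    scores = np.zeros(X.shape[1])
    for i in range(n_seeds):
        scores += mutual_info_classif(
            X.to_numpy(), y, n_neighbors=n_neighbors, random_state=base_seed + i
        )
    scores /= n_seeds
    rank = pd.DataFrame({"feature": X.columns, "mi": np.maximum(scores, 0.0)})
    # stable sort on name first makes descending-MI ties break by name order
    rank = rank.sort_values("feature", kind="stable")
    rank = rank.sort_values("mi", ascending=False, kind="stable").reset_index(drop=True)
    rank["rank"] = np.arange(1, len(rank) + 1)
    rank["selected"] = rank["rank"] <= 30
    return rank


def select_top_k(ranking: pd.DataFrame, k: int = 30) -> list[str]:
    """Names of the k best-ranked features (the rest are discarded downstream)."""
    if k > len(ranking):
        raise ValueError(f"k={k} exceeds the {len(ranking)} ranked features")
    return ranking.nsmallest(k, "rank")["feature"].tolist()
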