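"""The 36-feature vector computed on one observation window.

Five families, applied to the raw (unsmoothed) pressure window:

* **statistics** (9): mean, max, min, sample sd, skewness, excess kurtosis,
  RMS, RSS, IQR — location, dispersion and shape of the pressure
  distribution.
* **peak** (8): troughs of the waveform below the 65 mmHg hypotension
  threshold — count, inter-trough interval statistics (in samples), trough
  value statistics, and the crest factor max/RMS.
* **change** (3): binary indicators of a single changepoint in mean,
  variance, and mean+variance, by exhaustive single-split search with a
  BIC-style penalty.
* **fourier** (6): the three largest non-DC periodogram ordinates of the
  mean-removed window and their frequencies in Hz.
* **wavelet** (10): pseudo-periods (seconds) of the ten highest-energy
  scales of a Morlet continuous wavelet transform over a logarithmic scale
  grid spanning 0.1–10 s.

Feature names follow the clinical short names (``p_n``, ``cp1``, ``freq1``,
``scale1`` …) and their order is fixed and public in :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from numpy.typing import ArrayLike, NDArray
from scipy import signal as sps

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "statistical_features",
    "peak_features",
    "change_features",
    "fourier_features",
    "wavelet_features",
    "extract_all",
    "wavelet_period_grid",
]

STAT_NAMES = ("mean", "max", "min", "sd", "skewness", "kurtosis", "rms", "rss", "iqr")
PEAK_NAMES = ("p_n", "p_interval", "p_interval_std", "p_mean", "p_max", "p_min", "p_std", "cf")
CHANGE_NAMES = ("cp1", "cp2", "cp3")
FOURIER_NAMES = ("po1", "po2", "po3", "freq1", "freq2", "freq3")
WAVELET_NAMES = tuple(f"scale{i}" for i in range(1, 11))

#: fixed, public order of the 36 features
FEATURE_NAMES: tuple[str, ...] = (
    STAT_NAMES + PEAK_NAMES + CHANGE_NAMES + FOURIER_NAMES + WAVELET_NAMES
)
assert len(FEATURE_NAMES) == 36


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the feature families.

    ``rss_convention`` selects between the textbook root-sum-square
    ``sqrt(sum x^2)`` (default) and ``rms_times_n`` = RMS · n, an alternative
    scaling seen in some clinical feature tables.
    """

    peak_threshold: float = 65.0
    min_prominence: float = 1.0
    min_spacing_s: float = 0.3
    rss_convention: str = "sqrt_sum_sq"  # or "rms_times_n"
    cp_min_segment: int = 8
    cp_penalty_scale: float = 1.0
    wavelet_period_min_s: float = 0.1
    wavelet_period_max_s: float = 10.0
    wavelet_n_scales: int = 96

    def __post_init__(self) -> None:
        if self.rss_convention not in ("sqrt_sum_sq", "rms_times_n"):
            raise ValueError("rss_convention must be sqrt_sum_sq or rms_times_n")


def statistical_features(
    window: ArrayLike, rss_convention: str = "sqrt_sum_sq"
) -> dict[str, float]:
    """Nine descriptive statistics of the pressure window.

    sd is the sample standard deviation (ddof=1); skewness is the third
    standardized moment and kurtosis the excess (fourth standardized moment
    minus 3), both defined as 0 for a constant window; IQR uses
    linear-interpolation quantiles.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < 4:
        raise ValueError("window must have at least 4 samples")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    dev = x - mean
    m2 = float(np.mean(dev**2))
    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    rms = float(np.sqrt(np.mean(x**2)))
    if rss_convention == "rms_times_n":
        rss = rms * x.size
    else:
        rss = float(np.sqrt(np.sum(x**2)))
    q1, q3 = np.percentile(x, [25, 75])
    return {
        "mean": mean,
        "max": float(np.max(x)),
        "min": float(np.min(x)),
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "rms": rms,
        "rss": rss,
        "iqr": float(q3 - q1),
    }


def peak_features(
    window: ArrayLike,
    fs: float,
    threshold: float = 65.0,
    min_prominence: float = 1.0,
    min_spacing_s: float = 0.3,
) -> dict[str, float]:
    """Sub-threshold trough analysis plus crest factor.

    "Peaks" here are downward excursions: local minima of the waveform with
    prominence ≥ ``min_prominence`` and spacing ≥ ``min_spacing_s``, kept
    only when their value is below the hypotension threshold. Intervals are
    successive trough-index differences in samples at the native rate. With
    no troughs all trough statistics are 0; with one trough the interval
    statistics are 0. The crest factor is max(window)/RMS(window) over the
    whole window regardless of troughs.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    distance = max(1, int(round(min_spacing_s * fs)))
    idx, _ = sps.find_peaks(-x, prominence=min_prominence, distance=distance)
    idx = idx[x[idx] < threshold]
    vals = x[idx]
    out = dict.fromkeys(PEAK_NAMES, 0.0)
    out["p_n"] = float(idx.size)
    if idx.size >= 1:
        out["p_mean"] = float(np.mean(vals))
        out["p_max"] = float(np.max(vals))
        out["p_min"] = float(np.min(vals))
        out["p_std"] = float(np.std(vals, ddof=0)) if idx.size > 1 else 0.0
    if idx.size >= 2:
        gaps = np.diff(idx).astype(np.float64)
        out["p_interval"] = float(np.mean(gaps))
        out["p_interval_std"] = float(np.std(gaps, ddof=0)) if gaps.size > 1 else 0.0
    rms = float(np.sqrt(np.mean(x**2)))
    out["cf"] = float(np.max(x)) / rms if rms > 0 else 0.0
    return out


# ---------------------------------------------------------------------------
# single-changepoint search
# ---------------------------------------------------------------------------


def _segment_costs(x: NDArray[np.float64]) -> tuple[NDArray, NDArray, NDArray]:
    """Prefix machinery for O(n) evaluation of all single splits.

    Returns, for every split k (left = x[:k], right = x[k:]), the
    sum-of-squared-deviations of each part about its own mean.
    """
    n = x.size
    c1 = np.cumsum(x)
    c2 = np.cumsum(x**2)
    k = np.arange(1, n)  # split positions
    left_n = k.astype(np.float64)
    right_n = (n - k).astype(np.float64)
    left_s1, left_s2 = c1[k - 1], c2[k - 1]
    right_s1, right_s2 = c1[-1] - left_s1, c2[-1] - left_s2
    sse_left = np.maximum(left_s2 - left_s1**2 / left_n, 0.0)
    sse_right = np.maximum(right_s2 - right_s1**2 / right_n, 0.0)
    return k, sse_left, sse_right


def _gaussian_cost(sse: NDArray | float, n: NDArray | float, var_floor: float) -> NDArray | float:
    """n · log(variance) with a floor keeping near-constant segments finite."""
    return n * np.log(np.maximum(np.asarray(sse) / n, var_floor))


def change_features(
    window: ArrayLike,
    min_segment: int = 8,
    penalty_scale: float = 1.0,
) -> dict[str, float]:
    """Binary single-changepoint indicators for mean, variance, mean+variance.

    For each statistic the best split k (both segments ≥ ``min_segment``)
    minimizes a Gaussian segment cost: for **mean**, n·log(SSE/n) with SSE
    about segment means (variance shared); for **variance**, segment costs
    about the global mean (means shared); for **mean+variance**, both free
    per segment. The split is accepted when the cost drop versus the unsplit
    window exceeds a BIC penalty, ``penalty_scale · p · log(n)`` with p the
    number of freed parameters (2, 2, 3). At most one changepoint per
    statistic, so each indicator is 0 or 1.
    """
    x = np.asarray(window, dtype=np.float64)
    n = x.size
    if n < 8:
        raise ValueError("window must have at least 8 samples")
    out = {"cp1": 0.0, "cp2": 0.0, "cp3": 0.0}
    if n < 2 * min_segment:
        return out

    total_var = float(np.var(x))
    var_floor = max(total_var, 1.0) * 1e-10
    logn = np.log(n)

    k, sse_l, sse_r = _segment_costs(x)
    valid = (k >= min_segment) & (n - k >= min_segment)
    kv = k[valid]
    nl, nr = kv.astype(np.float64), (n - kv).astype(np.float64)

    # mean change: shared variance, SSE about segment means
    sse0 = float(np.sum((x - x.mean()) ** 2))
    sse1 = sse_l[valid] + sse_r[valid]
    gain_mean = _gaussian_cost(sse0, n, var_floor) - _gaussian_cost(sse1.min(), n, var_floor)
    if gain_mean > penalty_scale * 2.0 * logn:
        out["cp1"] = 1.0

    # variance change: segment variances about the global mean
    dev2 = np.cumsum((x - x.mean()) ** 2)
    sseg_l = dev2[kv - 1]
    sseg_r = dev2[-1] - sseg_l
    cost_var = _gaussian_cost(sseg_l, nl, var_floor) + _gaussian_cost(sseg_r, nr, var_floor)
    gain_var = _gaussian_cost(dev2[-1], n, var_floor) - float(np.min(cost_var))
    if gain_var > penalty_scale * 2.0 * logn:
        out["cp2"] = 1.0

    # mean+variance change: both free per segment
    cost_mv = _gaussian_cost(sse_l[valid], nl, var_floor) + _gaussian_cost(sse_r[valid], nr, var_floor)
    gain_mv = _gaussian_cost(sse0, n, var_floor) - float(np.min(cost_mv))
    if gain_mv > penalty_scale * 3.0 * logn:
        out["cp3"] = 1.0
    return out


def best_mean_split(window: ArrayLike, min_segment: int = 8) -> int:
    """Index of the best single mean-change split (for diagnostics/tests)."""
    x = np.asarray(window, dtype=np.float64)
    k, sse_l, sse_r = _segment_costs(x)
    valid = (k >= min_segment) & (x.size - k >= min_segment)
    tot = sse_l[valid] + sse_r[valid]
    return int(k[valid][int(np.argmin(tot))])


def fourier_features(window: ArrayLike, fs: float) -> dict[str, float]:
    """Top-three periodogram ordinates (excluding DC) and their frequencies.

    The window is mean-removed before the periodogram. Ties in power are
    broken toward the lower frequency; adjacent bins may all qualify, which
    is typical for a strong pulse line (freq1 ≈ freq2 ≈ freq3).
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < 64:
        raise ValueError("window must have at least 64 samples")
    f, p = sps.periodogram(x - x.mean(), fs=fs, detrend=False)
    f, p = f[1:], p[1:]  # drop DC
    order = np.lexsort((f, -p))[:3]
    out = {}
    for i, j in enumerate(order, start=1):
        out[f"po{i}"] = float(p[j])
        out[f"freq{i}"] = float(f[j])
    return {k: out[k] for k in FOURIER_NAMES}


def wavelet_period_grid(config: FeatureConfig = FeatureConfig()) -> NDArray[np.float64]:
    """The logarithmic pseudo-period grid (seconds) used by the scalogram."""
    return np.geomspace(
        config.wavelet_period_min_s, config.wavelet_period_max_s, config.wavelet_n_scales
    )


def wavelet_features(
    window: ArrayLike, fs: float, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Pseudo-periods of the ten highest-energy Morlet scales.

    The mean-removed window is transformed with the Morlet wavelet on a
    fixed log grid of scales whose pseudo-periods span 0.1–10 s; per-scale
    energy is the sum over time of squared coefficient magnitude. Reported
    values are pseudo-periods in seconds (scale grid calibrated via the
    Morlet center frequency so a pure sinusoid of period T scores scale1=T
    within grid resolution), ordered by descending energy.
    """
    x = np.asarray(window, dtype=np.float64)
    if x.size < 256:
        raise ValueError("window must have at least 256 samples")
    periods = wavelet_period_grid(config)
    fc = pywt.central_frequency("morl")
    scales = periods * fc * fs
    coef, _ = pywt.cwt(x - x.mean(), scales, "morl", method="fft")
    energy = np.sum(np.abs(coef) ** 2, axis=1)
    order = np.argsort(-energy, kind="stable")[:10]
    return {f"scale{i}": float(periods[j]) for i, j in enumerate(order, start=1)}


def extract_all(
    window: ArrayLike, fs: float, config: FeatureConfig = FeatureConfig()
) -> dict[str, float]:
    """Full 36-value feature vector, in :data:`FEATURE_NAMES` order."""
    out: dict[str, float] = {}
    out.update(statistical_features(window, config.rss_convention))
    out.update(
        peak_features(
            window,
            fs,
            threshold=config.peak_threshold,
            min_prominence=config.min_prominence,
            min_spacing_s=config.min_spacing_s,
        )
    )
    out.update(change_features(window, config.cp_min_segment, config.cp_penalty_scale))
    out.update(fourier_features(window, fs))
    out.update(wavelet_features(window, fs, config))
    assert tuple(out) == FEATURE_NAMES
    return out
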