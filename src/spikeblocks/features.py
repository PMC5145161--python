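"""Wavelet features and deviation-from-normality feature selection.

Each spike is decomposed with a four-level Haar wavelet transform, giving as
many coefficients as sampling points. To reduce dimensionality, the ten
coefficients whose empirical distributions deviate most from a normal
distribution (Lilliefors-style Kolmogorov-Smirnov statistic, normal
parameters estimated from the sample) are retained: multimodal coefficient
distributions are exactly the ones that separate spike classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .containers import SpikeSet

__all__ = ["wavelet_features", "ks_statistic", "select_features_ks", "FeatureMatrix"]

WAVELET_LEVELS = 4


def wavelet_features(spikes: SpikeSet | np.ndarray) -> np.ndarray:
    """Full four-level Haar decomposition coefficients, one row per spike.

    The transform is orthonormal ('haar' in PyWavelets with default
    periodization-free modes is orthogonal on power-of-two lengths); for
    waveform lengths not decomposable into 4 dyadic levels the waveforms are
    zero-padded to the next valid length with a warning, so the coefficient
    count can slightly exceed the sample count.
    """
    waves = spikes.waveforms if isinstance(spikes, SpikeSet) else np.atleast_2d(spikes)
    k = waves.shape[1]
    if k < 16:
        raise ValueError("need at least 16 samples for a 4-level decomposition")
    if k % (1 << WAVELET_LEVELS):
        target = ((k >> WAVELET_LEVELS) + 1) << WAVELET_LEVELS
        warnings.warn(
            f"waveform length {k} not divisible by {1 << WAVELET_LEVELS}; "
            f"zero-padding to {target}", stacklevel=2)
        waves = np.pad(waves, ((0, 0), (0, target - k)))
    coeffs = pywt.wavedec(waves, "haar", level=WAVELET_LEVELS, axis=1,
                          mode="periodization")
    return np.concatenate(coeffs, axis=1)


def ks_statistic(column: np.ndarray) -> float:
    """KS distance of a sample from a normal with its own mean and SD.

    Zero-variance columns get statistic 0 so they are never selected over
    varying coefficients.
    """
    from scipy.stats import norm

    x = np.sort(np.asarray(column, dtype=np.float64))
    n = x.size
    sd = x.std()
    if sd == 0 or n < 2:
        return 0.0
    cdf = norm.cdf(x, loc=x.mean(), scale=sd)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


@dataclass
class FeatureMatrix:
    """Selected wavelet coefficients ready for clustering."""

    values: np.ndarray            # (n_spikes, d)
    selected_indices: np.ndarray  # the d chosen coefficient columns
    ks_stats: np.ndarray          # statistic per original coefficient

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def select_features_ks(coeffs: np.ndarray, d: int = 10) -> FeatureMatrix:
    """Keep the ``d`` coefficients deviating most from normality.

    Ranking is by descending KS statistic with ties broken toward the lower
    coefficient index, which makes the selection deterministic.
    """
    coeffs = np.atleast_2d(coeffs)
    n, k = coeffs.shape
    if n < 10:
        raise ValueError("need at least 10 spikes for feature selection")
    d = min(d, k)
    stats = np.array([ks_statistic(coeffs[:, j]) for j in range(k)])
    # stable sort on -stat: equal statistics keep ascending column order
    order = np.argsort(-stats, kind="stable")
    selected = np.sort(order[:d])
    return FeatureMatrix(values=coeffs[:, selected],
                         selected_indices=selected, ks_stats=stats)
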