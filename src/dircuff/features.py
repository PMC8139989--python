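"""Twenty hand-crafted descriptors of a 41-sample spike window.

The canonical feature order is fixed by :data:`FEATURE_NAMES`. Definitions
(where the bare feature names admit several conventions, the one used here
is stated):

* ``variance`` — unbiased sample variance.
* ``skewness``/``kurtosis`` — standardised central moments (kurtosis is the
  plain fourth standardised moment, not excess); 0 for zero-variance windows.
* ``entropy`` — Shannon entropy (bits) of a 10-bin amplitude histogram over
  [min, max]; 0 for constant windows.
* ``max_abs_fft`` — maximum DFT magnitude over nonnegative frequencies.
* ``rms`` — root-mean-square of the raw window; ``rms_level`` — RMS of the
  mean-removed window (the two otherwise-duplicate names are deliberately
  distinguished this way).
* ``hjorth_mobility`` — sqrt(var(first difference)/var(window)); 0 when the
  window variance is 0.
* ``range`` — max minus min; ``avg_power`` — mean squared amplitude.
* ``mean_first_derivative`` — mean of the first difference times the
  sampling rate (µV/s).
* ``n_zero_crossings`` — strict sign changes between consecutive samples;
  zero samples inherit the previous sign.
* ``sign_of_max_peak`` — sign of the largest-|.| sample (ties → earliest,
  zero → +1); ``first_slope_direction`` — sign of the first difference
  (0 → +1). These two polarity-coded features carry the direction signal.
* ``geometric_mean``/``harmonic_mean`` — computed on |samples| + 1e-12 µV
  (signed values leave both undefined).
* ``avg_integrated_rectifier`` — mean absolute amplitude.
* ``avg_psd`` — mean periodogram PSD ordinate; ``avg_welch_power`` — mean
  Welch PSD (16-sample Hann segments, 50% overlap).
* ``n_slope_sign_changes_rectified`` — sign changes of the first difference
  of the rectified window.

No definition can produce NaN; degenerate (constant or all-zero) windows map
to the documented conventions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .pipeline import WINDOW_LEN, SpikeWindow

FEATURE_NAMES = (
    "variance",
    "skewness",
    "kurtosis",
    "entropy",
    "max_abs_fft",
    "rms",
    "hjorth_mobility",
    "range",
    "avg_power",
    "mean_first_derivative",
    "n_zero_crossings",
    "sign_of_max_peak",
    "geometric_mean",
    "harmonic_mean",
    "rms_level",
    "avg_integrated_rectifier",
    "avg_psd",
    "avg_welch_power",
    "first_slope_direction",
    "n_slope_sign_changes_rectified",
)

_EPS = 1e-12


def _fill_zero_signs(s: np.ndarray) -> np.ndarray:
    """Replace zeros in a sign array by the previous nonzero sign.

    Leading zeros take the first nonzero sign; an all-zero row becomes +1.
    """
    s = s.copy()
    n_cols = s.shape[1]
    for j in range(1, n_cols):
        z = s[:, j] == 0
        s[z, j] = s[z, j - 1]
    for j in range(n_cols - 2, -1, -1):
        z = s[:, j] == 0
        s[z, j] = s[z, j + 1]
    s[s == 0] = 1
    return s


def _sign_changes(x: np.ndarray) -> np.ndarray:
    s = _fill_zero_signs(np.sign(x))
    return (s[:, 1:] != s[:, :-1]).sum(axis=1).astype(float)


def feature_matrix(windows: np.ndarray, sampling_rate: float = 40_000.0) -> np.ndarray:
    """Vectorised extraction: (n, 41) window matrix → (n, 20) feature matrix."""
    W = np.atleast_2d(np.asarray(windows, dtype=float))
    n, m = W.shape
    if m != WINDOW_LEN:
        raise ValueError(f"windows must have {WINDOW_LEN} samples, got {m}")

    mean = W.mean(axis=1, keepdims=True)
    centred = W - mean
    m2 = (centred**2).mean(axis=1)
    nonzero = m2 > 0
    variance = (centred**2).sum(axis=1) / (m - 1)

    skewness = np.zeros(n)
    kurtosis = np.zeros(n)
    skewness[nonzero] = (centred**3).mean(axis=1)[nonzero] / m2[nonzero] ** 1.5
    kurtosis[nonzero] = (centred**4).mean(axis=1)[nonzero] / m2[nonzero] ** 2

    entropy = np.zeros(n)
    for i in range(n):
        lo, hi = W[i].min(), W[i].max()
        if hi > lo:
            counts, _ = np.histogram(W[i], bins=10, range=(lo, hi))
            p = counts[counts > 0] / m
            entropy[i] = -(p * np.log2(p)).sum()

    max_abs_fft = np.abs(np.fft.rfft(W, axis=1)).max(axis=1)
    rms = np.sqrt((W**2).mean(axis=1))

    diff = np.diff(W, axis=1)
    var_diff = diff.var(axis=1, ddof=1)
    hjorth = np.zeros(n)
    hjorth[nonzero] = np.sqrt(var_diff[nonzero] / variance[nonzero])

    rng_ = W.max(axis=1) - W.min(axis=1)
    avg_power = (W**2).mean(axis=1)
    mean_first_derivative = diff.mean(axis=1) * sampling_rate
    n_zero_crossings = _sign_changes(W)

    absW = np.abs(W)
    peak_idx = absW.argmax(axis=1)  # argmax ties → earliest index
    peak_val = W[np.arange(n), peak_idx]
    sign_of_max_peak = np.where(peak_val < 0, -1.0, 1.0)

    shifted = absW + _EPS
    geometric_mean = np.exp(np.log(shifted).mean(axis=1))
    harmonic_mean = m / (1.0 / shifted).sum(axis=1)
    rms_level = np.sqrt(m2)
    avg_integrated_rectifier = absW.mean(axis=1)

    _, pxx = _signal.periodogram(W, fs=sampling_rate, axis=1, detrend=False)
    avg_psd = pxx.mean(axis=1)
    _, wxx = _signal.welch(
        W, fs=sampling_rate, window="hann", nperseg=16, noverlap=8, axis=1, detrend=False
    )
    avg_welch_power = wxx.mean(axis=1)

    first_slope_direction = np.where(W[:, 1] - W[:, 0] < 0, -1.0, 1.0)
    n_slope_sign_changes = _sign_changes(np.diff(absW, axis=1))

    out = np.column_stack(
        [
            variance,
            skewness,
            kurtosis,
            entropy,
            max_abs_fft,
            rms,
            hjorth,
            rng_,
            avg_power,
            mean_first_derivative,
            n_zero_crossings,
            sign_of_max_peak,
            geometric_mean,
            harmonic_mean,
            rms_level,
            avg_integrated_rectifier,
            avg_psd,
            avg_welch_power,
            first_slope_direction,
            n_slope_sign_changes,
        ]
    )
    assert out.shape == (n, len(FEATURE_NAMES))
    if not np.all(np.isfinite(out)):
        raise AssertionError("feature extraction produced non-finite values")
    return out


def hjorth_mobility(window: np.ndarray) -> float:
    """sqrt(var(diff)/var(window)) with unbiased variances; 0 when flat."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ValueError("window must have at least 2 samples")
    v = x.var(ddof=1)
    if v == 0:
        return 0.0
    return float(np.sqrt(np.diff(x).var(ddof=1) / v))


def extract_features(window: np.ndarray | SpikeWindow, sampling_rate: float = 40_000.0) -> pd.Series:
    """The 20-feature descriptor of one window, in canonical order."""
    samples = window.samples if isinstance(window, SpikeWindow) else np.asarray(window, dtype=float)
    if samples.size != WINDOW_LEN:
        raise ValueError(f"window must have {WINDOW_LEN} samples")
    row = feature_matrix(samples[None, :], sampling_rate)[0]
    return pd.Series(row, index=list(FEATURE_NAMES))


def batch_extract(
    windows: list[SpikeWindow] | np.ndarray,
    sampling_rate: float = 40_000.0,
    labels: list[str] | np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per window: the 20 canonical feature columns plus ``label``."""
    if len(windows) == 0:
        return pd.DataFrame(columns=list(FEATURE_NAMES) + ["label"])
    if isinstance(windows[0], SpikeWindow):
        mat = np.stack([w.samples for w in windows])
        if labels is None:
            labels = [w.label for w in windows]
    else:
        mat = np.atleast_2d(np.asarray(windows, dtype=float))
    feats = feature_matrix(mat, sampling_rate)
    df = pd.DataFrame(feats, columns=list(FEATURE_NAMES))
    df["label"] = list(labels) if labels is not None else "unknown"
    return df
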