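"""Obstruction-response quantification in 15-s bins and rank-sum statistics.

Heart rate, blood pressure, genioglossus EMG activity and the respiratory
nerve profile are each reduced to per-bin values (bins start at epoch
boundaries; a partial trailing bin is dropped), compared between baseline
and obstruction epochs as a percent change of means, and tested with a
two-sided Wilcoxon rank-sum. The rank-sum p-value is computed by exhaustive
enumeration for combined sample sizes up to 12 and by a tie-corrected,
continuity-corrected normal approximation beyond that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy.stats import rankdata

from .classify import TrainedModel, predict_afferent_fraction
from .construct import RnPTrace

BIN_S = 15.0
EPOCH_TAGS = ("baseline", "obstruction", "recovery", "post")


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


def make_bins(
    total_s: float,
    obstruction_intervals: list[tuple[float, float]],
    baseline_s: float,
    bin_s: float = BIN_S,
) -> pd.DataFrame:
    """15-s bins tagged baseline/obstruction/recovery/post.

    Epoch boundaries (baseline end, each obstruction start/stop, end of the
    last gap) delimit segments; each segment is tiled with ``bin_s`` bins
    starting at its left edge, dropping any partial trailing bin.
    """
    edges: list[tuple[float, float, str]] = [(0.0, baseline_s, "baseline")]
    for i, (lo, hi) in enumerate(obstruction_intervals):
        edges.append((lo, hi, "obstruction"))
        nxt = (
            obstruction_intervals[i + 1][0]
            if i + 1 < len(obstruction_intervals)
            else total_s
        )
        tag = "recovery" if i + 1 < len(obstruction_intervals) else "post"
        if nxt > hi:
            edges.append((hi, nxt, tag))
    rows = []
    for lo, hi, tag in edges:
        t = lo
        while t + bin_s <= hi + 1e-9:
            rows.append({"start": t, "duration": bin_s, "epoch": tag})
            t += bin_s
    return pd.DataFrame(rows)


def _bin_slice(n: int, fs: float, start: float, duration: float) -> slice:
    i0 = int(round(start * fs))
    i1 = min(int(round((start + duration) * fs)), n)
    return slice(i0, i1)


# ---------------------------------------------------------------------------
# per-channel reductions
# ---------------------------------------------------------------------------


def heart_rate(ecg: np.ndarray, sampling_rate: float, bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin heart rate (beats/min) from R-peak intervals.

    R peaks: amplitude threshold at 50% of the global maximum with a 100-ms
    refractory period. Bins with fewer than 2 peaks get a null value.
    """
    x = np.asarray(ecg, dtype=float)
    peaks, _ = _signal.find_peaks(
        x, height=0.5 * x.max(), distance=max(int(0.1 * sampling_rate), 1)
    )
    peak_t = peaks / sampling_rate
    out = bins.copy()
    values = []
    for _, b in bins.iterrows():
        sel = peak_t[(peak_t >= b.start) & (peak_t < b.start + b.duration)]
        if sel.size < 2:
            warnings.warn(f"bin at {b.start:.0f}s has <2 R-peaks; heart rate undefined")
            values.append(np.nan)
        else:
            values.append(60.0 / np.mean(np.diff(sel)))
    out["value"] = values
    return out


def mean_bp(bp: np.ndarray, sampling_rate: float, bins: pd.DataFrame) -> pd.DataFrame:
    """Per-bin arithmetic mean pressure (mmHg)."""
    x = np.asarray(bp, dtype=float)
    out = bins.copy()
    out["value"] = [
        float(np.mean(x[_bin_slice(x.size, sampling_rate, b.start, b.duration)]))
        for _, b in bins.iterrows()
    ]
    return out


def ggemg_activity(
    ggemg: np.ndarray,
    sampling_rate: float,
    bins: pd.DataFrame,
    threshold_mv: float = 0.2,
    bartlett_s: float = 0.3,
) -> pd.DataFrame:
    """Per-bin genioglossus activity (mV·s).

    Rectify, smooth with a normalised 300-ms Bartlett (triangular) moving
    average, detect peaks above 0.2 mV, and sum the trapezoidal area of the
    smoothed signal over each peak's contiguous supra-threshold extent
    (each extent counted once, assigned to the bin containing its peak).
    """
    x = np.abs(np.asarray(ggemg, dtype=float))
    w = _signal.windows.bartlett(max(int(round(bartlett_s * sampling_rate)), 3))
    smooth = _signal.convolve(x, w / w.sum(), mode="same")
    peaks, _ = _signal.find_peaks(smooth, height=threshold_mv)

    above = smooth > threshold_mv
    # contiguous supra-threshold regions
    step = np.diff(above.astype(int))
    starts = np.flatnonzero(step == 1) + 1
    stops = np.flatnonzero(step == -1) + 1
    if above.size and above[0]:
        starts = np.concatenate([[0], starts])
    if above.size and above[-1]:
        stops = np.concatenate([stops, [above.size]])

    region_area = {}
    region_peak_t = {}
    for p in peaks:
        j = np.searchsorted(starts, p, side="right") - 1
        if j < 0 or p >= stops[j]:
            continue
        if j not in region_area:
            seg = smooth[starts[j] : stops[j]]
            region_area[j] = float(np.trapezoid(seg, dx=1.0 / sampling_rate))
            region_peak_t[j] = (starts[j] + int(np.argmax(seg))) / sampling_rate

    out = bins.copy()
    values = np.zeros(len(bins))
    for j, area in region_area.items():
        t = region_peak_t[j]
        hit = (bins["start"] <= t) & (t < bins["start"] + bins["duration"])
        values[hit.to_numpy()] += area
    out["value"] = values
    return out


def rnp_response(rnp: RnPTrace | np.ndarray, bins: pd.DataFrame,
                 sampling_rate: float | None = None) -> pd.DataFrame:
    """Per-bin mean of the respiratory nerve profile (µV²)."""
    if isinstance(rnp, RnPTrace):
        x, fs = rnp.values, rnp.sampling_rate
    else:
        if sampling_rate is None:
            raise ValueError("sampling_rate required for a bare array")
        x, fs = np.asarray(rnp, dtype=float), sampling_rate
    out = bins.copy()
    out["value"] = [
        float(np.mean(x[_bin_slice(x.size, fs, b.start, b.duration)]))
        for _, b in bins.iterrows()
    ]
    return out


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


@dataclass
class ObstructionResponse:
    """Baseline-vs-obstruction summary for one variable."""

    variable: str
    baseline_mean: float
    baseline_se: float
    obstruction_mean: float
    obstruction_se: float
    percent_change: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "baseline_mean": self.baseline_mean,
            "baseline_se": self.baseline_se,
            "obstruction_mean": self.obstruction_mean,
            "obstruction_se": self.obstruction_se,
            "percent_change": self.percent_change,
            "p_value": self.p_value,
            "n": self.n,
        }


def wilcoxon_rank_sum(x, y, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum of x, p).

    Exact p by enumeration of all C(n, m) group assignments for combined
    n <= 12 (the two-sided p is the probability of a rank sum at least as
    far from its null mean as observed); otherwise a normal approximation
    with continuity correction, tie-corrected variance and an Edgeworth
    kurtosis term (the rank-sum null is platykurtic at small n). ``method``
    forces ``'exact'`` or ``'approx'``. Identical pooled values give p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n_y = x.size, y.size
    if m < 2 or n_y < 2:
        raise ValueError("each sample needs at least 2 observations")
    pooled = np.concatenate([x, y])
    N = m + n_y
    ranks = rankdata(pooled)
    w = float(ranks[:m].sum())
    mu = m * (N + 1) / 2.0
    if np.ptp(pooled) == 0:
        return w, 1.0
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")

    if method == "exact" or (method == "auto" and N <= 12):
        dev = abs(w - mu)
        count = 0
        for idx in combinations(range(N), m):
            s = ranks[list(idx)].sum()
            if abs(s - mu) >= dev - 1e-9:
                count += 1
        return w, count / comb(N, m)

    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = ((t_counts**3 - t_counts).sum()) / (N * (N - 1))
    var = m * n_y / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    z = max((abs(w - mu) - 0.5) / sqrt(var), 0.0)
    # excess kurtosis of the tie-free rank-sum null (platykurtic)
    gamma2 = -1.2 * (m * m + n_y * n_y + m * n_y + m + n_y) / (m * n_y * (N + 1))
    phi_z = np.exp(-z * z / 2.0) / sqrt(2.0 * np.pi)
    tail = 0.5 * (1.0 - erf(z / sqrt(2.0))) + gamma2 / 24.0 * (z**3 - 3.0 * z) * phi_z
    return w, float(np.clip(2.0 * tail, 0.0, 1.0))


def percent_change(
    baseline: np.ndarray, obstruction: np.ndarray, variable: str = ""
) -> ObstructionResponse:
    """Percent change of means plus SE of each sample and a rank-sum p.

    ``baseline`` and ``obstruction`` are replicate-level values (per bin or
    per animal, depending on the design); SE = std/sqrt(n) of each sample.
    """
    b = np.asarray(baseline, dtype=float)
    o = np.asarray(obstruction, dtype=float)
    b, o = b[np.isfinite(b)], o[np.isfinite(o)]
    if b.size == 0 or o.size == 0:
        raise ValueError("baseline and obstruction samples must be nonempty")
    bm, om = float(b.mean()), float(o.mean())
    if bm == 0:
        warnings.warn("baseline mean is zero; percent change undefined")
        pct = float("nan")
    else:
        pct = (om - bm) / bm * 100.0
    _, p = wilcoxon_rank_sum(b, o) if (b.size >= 2 and o.size >= 2) else (np.nan, np.nan)
    return ObstructionResponse(
        variable=variable,
        baseline_mean=bm,
        baseline_se=float(b.std(ddof=1) / np.sqrt(b.size)) if b.size > 1 else 0.0,
        obstruction_mean=om,
        obstruction_se=float(o.std(ddof=1) / np.sqrt(o.size)) if o.size > 1 else 0.0,
        percent_change=pct,
        p_value=float(p),
        n=min(b.size, o.size),
    )


def afferent_suppression_estimate(
    rnp: RnPTrace,
    baseline_interval: tuple[float, float],
    obstruction_intervals: list[tuple[float, float]],
    noise_rnp_level: float,
    margin_s: float = 1.5,
) -> float:
    """Estimate the obstruction suppression factor from epoch RnP levels.

    For a superposition of independent spike trains the mean ENG power is
    linear in firing rate plus a constant noise floor, so subtracting the
    floor (measured from a no-signal recording processed identically) and
    taking the obstruction/baseline ratio recovers the fraction of afferent
    firing retained during obstruction. ``margin_s`` trims epoch edges to
    keep the 2-Hz low-pass transition out of the averages.
    """
    x, fs = rnp.values, rnp.sampling_rate

    def _mean(lo: float, hi: float) -> float:
        i0, i1 = int(round((lo + margin_s) * fs)), int(round((hi - margin_s) * fs))
        if i1 <= i0:
            raise ValueError("interval shorter than twice the trim margin")
        return float(x[i0:i1].mean())

    base = _mean(*baseline_interval)
    obs = float(np.mean([_mean(lo, hi) for lo, hi in obstruction_intervals]))
    denom = base - noise_rnp_level
    if denom <= 0:
        raise ValueError("baseline RnP does not exceed the noise floor")
    return (obs - noise_rnp_level) / denom


def epoch_values(binned: pd.DataFrame, epoch: str) -> np.ndarray:
    return binned.loc[binned["epoch"] == epoch, "value"].to_numpy(dtype=float)


def afferent_fraction_test(
    model: TrainedModel,
    epoch_features: list[tuple[pd.DataFrame, pd.DataFrame]],
    variable: str = "afferent_fraction",
) -> ObstructionResponse:
    """Baseline-vs-obstruction comparison of the predicted afferent fraction.

    ``epoch_features`` holds one (baseline_features, obstruction_features)
    pair of window-feature tables per replicate animal/run; replicates with
    an empty epoch are excluded with a warning. The rank-sum compares the
    per-replicate fractions.
    """
    base, obst = [], []
    for fb, fo in epoch_features:
        a = predict_afferent_fraction(model, fb) if len(fb) else None
        b = predict_afferent_fraction(model, fo) if len(fo) else None
        if a is None or b is None:
            warnings.warn("replicate with an empty epoch excluded from afferent-fraction test")
            continue
        base.append(a)
        obst.append(b)
    return percent_change(np.asarray(base), np.asarray(obst), variable=variable)
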