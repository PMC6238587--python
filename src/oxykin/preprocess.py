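"""Trace preprocessing: normalization, binomial smoothing, differentiation,
electrode-background estimation and injection detection.

The processing chain mirrors standard practice for Clark-electrode progress
curves: normalize the calibration zero, smooth with a binomial kernel,
differentiate to a consumption-rate series, exclude the first 20 s after
injection (mixing artifacts), and estimate the electrode's intrinsic
background consumption from 60 s of pre-injection data.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.special import comb
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .trace import OxygenTrace, RateSeries

__all__ = [
    "normalize_trace",
    "smooth_binomial",
    "differentiate",
    "estimate_background",
    "detect_injection",
    "BinomialSmoother",
    "POST_INJECTION_EXCLUSION",
    "BACKGROUND_WINDOW",
]

#: seconds excluded after injection because of mixing artifacts
POST_INJECTION_EXCLUSION = 20.0
#: seconds of pre-injection data used for the background linear fit
BACKGROUND_WINDOW = 60.0


def _noise_sd(oxygen: np.ndarray) -> float:
    """Robust per-sample noise estimate from lag-1 differences (MAD-based)."""
    d = np.diff(oxygen)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def normalize_trace(trace: OxygenTrace, method: str = "plateau") -> OxygenTrace:
    """Set the lowest oxygen concentration to zero (calibration correction).

    ``method="min"`` subtracts the pointwise sample minimum.  The default
    ``method="plateau"`` estimates the lowest oxygen *level* robustly: on a
    noisy trace the pointwise minimum is an extreme-value statistic biased
    low by several noise standard deviations, which would shift the whole
    concentration axis.  When a depleted trailing plateau exists its mean is
    used as the zero level; otherwise the minimum of a heavily smoothed copy
    is used.  Both reduce to the exact minimum on noise-free data.
    """
    oxy = trace.oxygen
    if method == "min":
        zero = float(np.min(oxy))
    elif method == "plateau":
        sigma = _noise_sd(oxy)
        dt = trace.sample_interval
        w = max(3, int(round(10.0 / dt)))
        if sigma == 0.0 or len(oxy) < 4 * w:
            zero = float(np.min(oxy))
        else:
            sm = uniform_filter1d(oxy, size=w, mode="nearest")
            lo = float(np.min(sm))
            # mean over a fixed trailing window: free of the extreme-value
            # selection bias that any minimum-anchored block would inherit
            n60 = max(5 * w, int(round(60.0 / dt)))
            if len(oxy) >= 2 * n60:
                t_tail = trace.times[-n60:]
                tail = oxy[-n60:]
                slope, _ = np.polyfit(t_tail, tail, 1)
                se = sigma * np.sqrt(12.0 / n60) / (np.ptp(t_tail) + 1e-12)
                flat = abs(slope) <= 4.0 * se
                lowest = (float(np.mean(sm[-n60:]))
                          <= float(np.quantile(sm, 0.25)) + 3.0 * sigma / np.sqrt(w))
                zero = float(np.mean(tail)) if (flat and lowest) else lo
            else:  # trace too short for a trailing-plateau estimate
                zero = lo
    else:
        raise ValueError(f"unknown normalization method: {method!r}")
    return trace.with_oxygen(oxy - zero, f"normalize(method={method}, zero={zero:.6g})")


def binomial_kernel(order: int) -> np.ndarray:
    """Normalized binomial-coefficient kernel of a given even order.

    Order m gives the m+1 coefficients C(m, k) / 2^m; order 2 is the
    classic [1/4, 1/2, 1/4] smoother.
    """
    if order < 2 or order % 2 != 0:
        raise ValueError("binomial kernel order must be an even integer >= 2")
    k = comb(order, np.arange(order + 1))
    return k / k.sum()


def _smooth_array(values: np.ndarray, order: int, passes: int) -> np.ndarray:
    kernel = binomial_kernel(order)
    half = order // 2
    if len(values) <= order:
        raise ValueError("trace shorter than the smoothing kernel")
    out = np.asarray(values, dtype=float)
    for _ in range(passes):
        padded = np.pad(out, half, mode="reflect")
        out = np.convolve(padded, kernel, mode="valid")
    return out


def smooth_binomial(trace: OxygenTrace, order: int = 4, passes: int = 1) -> OxygenTrace:
    """Binomial smoothing of the oxygen channel (reflection-padded, so the
    output has the input's length); ``passes`` repeated applications."""
    if passes < 1:
        raise ValueError("passes must be a positive integer")
    smoothed = _smooth_array(trace.oxygen, order, passes)
    return trace.with_oxygen(smoothed, f"smooth_binomial(order={order}, passes={passes})")


class BinomialSmoother(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying binomial smoothing column-wise.

    Stateless (``fit`` only validates); composes with sklearn pipelines for
    array data.  ``smooth_binomial`` is the trace-level convenience wrapper.
    """

    def __init__(self, order: int = 4, passes: int = 1):
        self.order = order
        self.passes = passes

    def fit(self, X, y=None):
        check_array(X, ensure_2d=False)
        binomial_kernel(self.order)
        if self.passes < 1:
            raise ValueError("passes must be a positive integer")
        self.n_features_in_ = 1 if np.ndim(X) == 1 else np.shape(X)[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, ensure_2d=False, copy=True)
        if X.ndim == 1:
            return _smooth_array(X, self.order, self.passes)
        for j in range(X.shape[1]):
            X[:, j] = _smooth_array(X[:, j], self.order, self.passes)
        return X


def differentiate(trace: OxygenTrace,
                  exclusion: float = POST_INJECTION_EXCLUSION) -> RateSeries:
    """Differentiate a processed trace into a consumption-rate series.

    Three-point central differences on the interior (exact for locally
    quadratic signals), one-sided differences at the two endpoints (which the
    mask excludes anyway).  The rate is stored consumption-positive
    (-d[O2]/dt).  The mask excludes every pre-injection point and the first
    ``exclusion`` seconds after injection.
    """
    ti = trace.metadata.injection_time
    if ti is None:
        raise ValueError(
            "injection_time is unknown; run detect_injection or supply metadata")
    rate = -np.gradient(trace.oxygen, trace.times)
    mask = trace.times >= ti + exclusion
    mask[0] = mask[-1] = False  # one-sided endpoint differences
    return RateSeries(times=trace.times.copy(), oxygen=trace.oxygen.copy(),
                      rate=rate, mask=mask, metadata=trace.metadata)


def estimate_background(trace: OxygenTrace,
                        window: float = BACKGROUND_WINDOW) -> float:
    """Electrode background coefficient x (s^-1) from pre-injection drift.

    Least-squares slope of [O2] vs time over the last ``window`` seconds
    before injection, converted to the proportional form used by the rate
    model: background rate = x*[O2], so x = consumption slope / mean [O2]
    over the window, clipped at zero.
    """
    ti = trace.metadata.injection_time
    if ti is None:
        raise ValueError("injection_time required to locate pre-injection data")
    sel = (trace.times >= ti - window) & (trace.times < ti)
    if sel.sum() < 10 or trace.times[sel][0] > ti - 0.95 * window:
        raise ValueError(
            f"insufficient pre-injection data for a {window:.0f} s background fit")
    t, o = trace.times[sel], trace.oxygen[sel]
    slope = float(np.polyfit(t, o, 1)[0])
    consumption = max(-slope, 0.0)
    mean_o2 = float(np.mean(o))
    if mean_o2 <= 0:
        return 0.0
    return consumption / mean_o2


def detect_injection(trace: OxygenTrace,
                     slope_window: float = 5.0,
                     baseline_fraction: float = 0.25,
                     min_drop_rate: float = 0.01) -> float:
    """Estimate the injection time from the trace itself.

    Looks for the first time the rolling consumption rate (slope over
    ``slope_window`` seconds of a lightly smoothed trace) persistently
    exceeds the pre-injection drift by a wide margin.  Intended for traces
    whose metadata lacks ``injection_time``; the fitted model can still
    refine t_i afterwards.  Works best for sharp onsets; a slow lag-phase
    onset is detected at the point where consumption becomes resolvable.
    """
    dt = trace.sample_interval
    n = len(trace)
    L = max(2, int(round(slope_window / dt)))
    if n < 4 * L:
        raise ValueError("trace too short for injection detection")
    sm = uniform_filter1d(trace.oxygen, size=max(3, int(round(1.0 / dt))),
                          mode="nearest")
    slope = np.full(n, np.nan)
    slope[L:] = (sm[L:] - sm[:-L]) / (L * dt)
    nb = max(2 * L, int(round(baseline_fraction * n)))
    base = slope[L:nb]
    b0 = float(np.median(base))
    sd = float(1.4826 * np.median(np.abs(base - b0)))
    if b0 < -5 * min_drop_rate:
        raise ValueError("no pre-injection plateau: trace begins mid-consumption")
    threshold = b0 - max(8.0 * sd, 5.0 * abs(b0), min_drop_rate)
    below = slope < threshold
    persist = max(2, int(round(1.0 / dt)))
    run = 0
    for i in range(nb, n):
        run = run + 1 if below[i] else 0
        if run >= persist:
            coarse = i - run + 1
            return _refine_breakpoint(trace.times, sm, coarse, L)
    raise ValueError("no detectable injection transition in trace")


def _refine_breakpoint(times: np.ndarray, smoothed: np.ndarray,
                       coarse: int, L: int) -> float:
    """Refine an onset estimate by a continuous hinge (two-segment linear)
    least-squares fit over a window around the coarse crossing."""
    lo = max(0, coarse - 4 * L)
    hi = min(len(times), coarse + 2 * L)
    t, o = times[lo:hi], smoothed[lo:hi]
    best_rss, best_c = np.inf, times[coarse]
    for c in t[L // 2: -L // 2]:
        A = np.column_stack([np.ones_like(t), t - c, np.maximum(t - c, 0.0)])
        coef, _, _, _ = np.linalg.lstsq(A, o, rcond=None)
        rss = float(np.sum((A @ coef - o) ** 2))
        if rss < best_rss:
            best_rss, best_c = rss, float(c)
    return best_c
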