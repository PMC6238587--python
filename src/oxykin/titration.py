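"""Secondary analyses across runs: titration curves and gel-band kinetics.

Plots of k_cat, activation rate constants or halftime of activation versus
substrate concentration are fitted to a single pseudo-first-order process
(a saturating exponential).  The fit is parameterised by its half-maximal
concentration ("midpoint"), the only summary independent of how the
exponential is written.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .models import KineticParameters, ModelSpec, activation_two_step, \
    halftime_of_activation
from .fitting import FitResult

__all__ = ["TitrationCurve", "SaturatingExponentialRegressor",
           "fit_saturating_exponential", "fit_band_kinetics",
           "summarize_replicates"]


@dataclass
class TitrationCurve:
    """(concentration, response) pairs for one titration series.

    ``response_kind`` is free text naming the response ("kcat", "halftime",
    "k1", ...); ``errors`` optional per-point standard deviations.  ``fit``
    is populated by :func:`fit_saturating_exponential`.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    response_kind: str = "kcat"
    errors: np.ndarray | None = None
    fit: dict | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.concentrations) != len(self.responses):
            raise ValueError("concentrations and responses must match in length")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if len(self.errors) != len(self.responses):
                raise ValueError("errors must match responses in length")


class SaturatingExponentialRegressor(RegressorMixin, BaseEstimator):
    """Single pseudo-first-order saturating law in concentration.

    Increasing responses are fitted to
    ``baseline + amplitude * (1 - 2^(-c/midpoint))`` and decreasing ones
    (e.g. halftime of activation versus substrate) to
    ``baseline + amplitude * 2^(-c/midpoint)``; ``midpoint`` is the
    concentration at half-maximal change in either case.  ``direction`` is
    "auto" (from the Spearman rank correlation), "increasing" or
    "decreasing".

    Fitted attributes: ``amplitude_``, ``midpoint_``, ``baseline_``,
    ``direction_``, ``monotone_warning_`` (True when |Spearman rho| < 0.5).
    """

    def __init__(self, direction: str = "auto"):
        self.direction = direction

    @staticmethod
    def _model(c, baseline, amplitude, midpoint, decreasing):
        e = np.exp(-c * np.log(2.0) / midpoint)
        return baseline + amplitude * (e if decreasing else 1.0 - e)

    def fit(self, X, y):
        X, y = check_X_y(X, y, ensure_min_samples=4)
        c = X[:, 0]
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")

        rho = spearmanr(c, y).statistic if np.ptp(y) > 0 else 0.0
        self.monotone_warning_ = bool(abs(rho) < 0.5) if np.isfinite(rho) else True
        if self.direction == "auto":
            decreasing = bool(rho < 0)
        elif self.direction in ("increasing", "decreasing"):
            decreasing = self.direction == "decreasing"
        else:
            raise ValueError(f"unknown direction: {self.direction!r}")

        span = float(np.ptp(y))
        cpos = c[c > 0]
        mid0 = float(np.median(cpos)) if len(cpos) else 1.0
        if decreasing:
            theta0 = [float(np.min(y)), span, mid0]
        else:
            theta0 = [float(np.min(y)), span, mid0]
        scale = max(span, abs(float(np.mean(y))), 1e-12)
        lo = [-10.0 * scale, 0.0, 1e-6]
        hi = [10.0 * scale, 100.0 * scale, 1e6]
        theta0 = np.clip(theta0, np.array(lo) + 1e-12, np.array(hi) - 1e-12)

        sol = least_squares(
            lambda th: self._model(c, *th, decreasing) - y,
            theta0, bounds=(lo, hi), method="trf")
        self.baseline_, self.amplitude_, self.midpoint_ = map(float, sol.x)
        self.direction_ = "decreasing" if decreasing else "increasing"
        self.rss_ = float(2.0 * sol.cost)
        self.converged_ = bool(sol.status > 0)
        self.n_features_in_ = 1
        # amplitude indistinguishable from zero: midpoint has no meaning
        self.identifiable_ = bool(self.amplitude_ > 1e-6 * scale and span > 0)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return self._model(X[:, 0], self.baseline_, self.amplitude_,
                           self.midpoint_, self.direction_ == "decreasing")


def fit_saturating_exponential(curve: TitrationCurve,
                               direction: str = "auto") -> TitrationCurve:
    """Fit a titration curve to the single pseudo-first-order law; returns a
    new curve with ``fit`` populated (and flags for non-monotone data or an
    unidentifiable midpoint)."""
    if len(curve.concentrations) < 4:
        raise ValueError("titration fit requires at least 4 concentration points")
    reg = SaturatingExponentialRegressor(direction=direction)
    reg.fit(curve.concentrations.reshape(-1, 1), curve.responses)
    flags = list(curve.flags)
    if reg.monotone_warning_:
        flags.append("non-monotone data")
    if not reg.identifiable_:
        flags.append("midpoint unidentifiable (amplitude ~ 0)")
    fit = {"amplitude": reg.amplitude_, "midpoint": reg.midpoint_,
           "baseline": reg.baseline_, "direction": reg.direction_,
           "rss": reg.rss_, "converged": reg.converged_}
    return TitrationCurve(curve.concentrations, curve.responses,
                          response_kind=curve.response_kind,
                          errors=curve.errors, fit=fit, flags=flags)


def fit_band_kinetics(times, intensities, scheme: str = "disappearance") -> dict:
    """Two-step exponential fit of gel-densitometry band kinetics.

    Appearance bands follow the two-step sequential activation profile
    (terminal state), disappearance bands its complement; both are scaled by
    an amplitude over a baseline.  ``times`` in seconds.  Returns the two
    rate constants (min^-1), the halftime (min), amplitude and baseline.
    """
    t = np.asarray(times, dtype=float) / 60.0  # minutes
    y = np.asarray(intensities, dtype=float)
    if len(t) != len(y):
        raise ValueError("times and intensities must match in length")
    if len(t) < 6:
        raise ValueError("band kinetics fit requires at least 6 time points")
    if np.any(y < 0):
        raise ValueError("intensities must be non-negative")
    if np.ptp(y) == 0:
        raise ValueError("intensities carry no kinetic signal")
    if scheme not in ("appearance", "disappearance"):
        raise ValueError(f"unknown scheme: {scheme!r}")

    span = float(np.ptp(y))
    half_level = 0.5 if scheme == "appearance" else 0.5
    # crude halftime guess from the half-change crossing
    yn = (y - y.min()) / span
    prog = yn if scheme == "appearance" else 1.0 - yn
    above = np.nonzero(prog >= half_level)[0]
    t_half0 = float(t[above[0]]) if len(above) else float(np.median(t))
    k0 = max(1.6783 / max(t_half0, 1e-3), 1e-3)  # equal-rate two-step guess

    def model(theta):
        amp, base, k1, dk = theta
        frac = activation_two_step(t, k1, k1 + dk)
        f = frac if scheme == "appearance" else 1.0 - frac
        return base + amp * f

    lo = [1e-12, -span, 1e-4, 0.0]
    hi = [100 * span, y.max() + span, 1e3, 1e3]
    # small deterministic multistart: the (k1, k2) likelihood has a shallow
    # ridge toward a one-step-like solution (k2 -> inf) on noisy data
    sol = None
    for k_start in (k0, 0.5 * k0, 2.0 * k0):
        for dk_start in (0.05 * k_start, 0.5 * k_start, 2.0 * k_start):
            theta0 = np.clip([span, float(y.min()), k_start, dk_start], lo, hi)
            cand = least_squares(lambda th: model(th) - y, theta0,
                                 bounds=(lo, hi), method="trf")
            if sol is None or cand.cost < sol.cost:
                sol = cand
    amp, base, k1, dk = sol.x
    k2 = k1 + dk
    params = KineticParameters(vmax=1.0, km=1.0, n=1.0, k1=float(k1), k2=float(k2))
    halftime = halftime_of_activation(params, ModelSpec("two_step"))
    return {"k1": float(k1), "k2": float(k2), "halftime": halftime,
            "amplitude": float(amp), "baseline": float(base),
            "converged": bool(sol.status > 0), "rss": float(2.0 * sol.cost)}


_PARAM_COLS = ("vmax", "km", "n", "x", "k1", "k2", "k3", "ti")


def summarize_replicates(results: list[FitResult]) -> pd.DataFrame:
    """Mean +/- sd table per parameter over replicate fits of one model.

    All results must share the same model structure; derived quantities
    (kcat, halftime) are included when present on every result.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 replicate results to summarize")
    spec0 = results[0].spec
    if any(r.spec != spec0 for r in results[1:]):
        raise ValueError("mixed model specs cannot be summarized together")
    rows = []
    for r in results:
        row = {c: getattr(r.params, c) for c in _PARAM_COLS}
        row.update(r.derived)
        rows.append(row)
    df = pd.DataFrame(rows).dropna(axis=1, how="any")
    return df.agg(["mean", "std", "count"]).T.rename(columns={"count": "n"})
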