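"""Nonlinear least-squares fitting of differentiated oxygen traces.

The estimator regresses the observed consumption rate on (time, [O2]) pairs
using the full rate law (electrode background + activation-gated
Hill-Michaelis-Menten term).  Fitting is ordinary least squares on the rate,
with deterministic Latin-hypercube multistart plus a data-driven start, and
an internal (k1, delta = k2 - k1 >= 0) parameterisation that removes the
swap symmetry of the two-step activation scheme.

Model selection follows the rule "the simplest function that gave a good fit
to the data and had random residuals": candidates are tried simplest first
and the first one whose fit converges with a passing Wald-Wolfowitz runs
test on (decorrelated) residual signs is kept; if none passes, the
minimum-AIC fit is returned flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .models import (KineticParameters, ModelSpec, halftime_of_activation,
                     kcat_from_vmax, observed_rate)
from .trace import AssayMetadata, OxygenTrace, RateSeries

__all__ = [
    "KineticRateRegressor",
    "FitResult",
    "fit_trace",
    "runs_test",
    "select_model",
    "integrate_model",
    "default_candidates",
]

# fitting bounds, in reporting units (rate constants min^-1, KM uM)
DEFAULT_BOUNDS = {
    "vmax": (1e-6, 1e3),
    "km": (1e-2, 1e3),
    "n": (0.3, 15.0),
    "k1": (1e-4, 1e3),
    "dk": (0.0, 1e3),
    "k3": (1e-4, 1e3),
    "x": (0.0, 1.0),
}


def runs_test(residuals) -> float:
    """Two-sided Wald-Wolfowitz runs test p-value on residual signs.

    Zeros are dropped; the normal approximation to the runs distribution is
    used.  All-one-sign sequences return p ~ 0 (a single run is the extreme
    of non-randomness), not an error.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0.0])
    m = len(signs)
    if m < 20:
        raise ValueError("runs test requires at least 20 nonzero residuals")
    n1 = int(np.sum(signs > 0))
    n2 = m - n1
    if n1 == 0 or n2 == 0:
        return 0.0
    runs = int(np.sum(signs[1:] != signs[:-1])) + 1
    mean = 1.0 + 2.0 * n1 * n2 / m
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - m) / (m ** 2 * (m - 1.0))
    if var <= 0:
        return 0.0
    z = (runs - mean) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def _aic(rss: float, n: int, n_free: int) -> float:
    # Gaussian log-likelihood profile; +1 for the residual variance
    return n * np.log(max(rss, 1e-300) / n) + 2.0 * (n_free + 1)


class KineticRateRegressor(RegressorMixin, BaseEstimator):
    """Sklearn-style regressor for the observed oxygen-consumption rate.

    Parameters
    ----------
    activation : {"none", "one_step", "two_step"}
        Activation scheme gating the enzymatic term.
    inactivation : bool
        Add a first-order loss of activity after a one-step activation.
    hill_fixed_to_one : bool
        Clamp the Hill coefficient to 1 (classical Michaelis-Menten).
    background : float
        Electrode background coefficient x (s^-1); held fixed unless
        ``fit_background`` is True.  Estimate it with
        ``preprocess.estimate_background``.
    ti : float
        Injection time (s); held fixed unless ``fit_ti`` is True, in which
        case it is bounded within ``ti_window`` seconds of the given value.
    n_starts : int
        Number of deterministic Latin-hypercube multistart points, in
        addition to one data-driven start.
    random_state : int
        Seed for the (deterministic) Latin-hypercube start generator.
    bounds : dict or None
        Per-parameter (lo, hi) overrides of the default fitting bounds.

    Fitted attributes: ``vmax_``, ``km_``, ``n_``, ``k1_``, ``k2_``,
    ``k3_`` (min^-1, None when absent), ``x_``, ``ti_``, ``params_``
    (KineticParameters), ``stderr_`` (dict), ``rss_``, ``aic_``,
    ``residuals_``, ``converged_``, ``n_points_``.

    ``fit(X, y)`` takes X of shape (n, 2) with columns (time s, [O2] uM) and
    y the consumption-positive rate in uM/s.
    """

    def __init__(self, activation: str = "two_step", inactivation: bool = False,
                 hill_fixed_to_one: bool = False, background: float = 0.0,
                 fit_background: bool = False, ti: float = 0.0,
                 fit_ti: bool = False, ti_window: float = 10.0,
                 n_starts: int = 8, random_state: int = 0,
                 bounds: dict | None = None, max_nfev: int | None = None):
        self.activation = activation
        self.inactivation = inactivation
        self.hill_fixed_to_one = hill_fixed_to_one
        self.background = background
        self.fit_background = fit_background
        self.ti = ti
        self.fit_ti = fit_ti
        self.ti_window = ti_window
        self.n_starts = n_starts
        self.random_state = random_state
        self.bounds = bounds
        self.max_nfev = max_nfev

    # -- internal parameter vector ------------------------------------------
    def _spec(self) -> ModelSpec:
        return ModelSpec(activation=self.activation,
                         inactivation=self.inactivation,
                         hill_fixed_to_one=self.hill_fixed_to_one)

    def _free_names(self) -> list[str]:
        spec = self._spec()
        names = ["vmax", "km"]
        if not spec.hill_fixed_to_one:
            names.append("n")
        if spec.activation in ("one_step", "two_step"):
            names.append("k1")
        if spec.activation == "two_step":
            names.append("dk")
        if spec.inactivation:
            names.append("k3")
        if self.fit_background:
            names.append("x")
        if self.fit_ti:
            names.append("ti")
        return names

    def _theta_to_params(self, theta: np.ndarray,
                         names: list[str]) -> KineticParameters:
        d = dict(zip(names, theta))
        spec = self._spec()
        k1 = d.get("k1")
        k2 = k1 + d["dk"] if "dk" in d else None
        return KineticParameters(
            vmax=d["vmax"], km=d["km"],
            n=1.0 if spec.hill_fixed_to_one else d["n"],
            x=d.get("x", self.background),
            k1=k1, k2=k2, k3=d.get("k3"),
            ti=d.get("ti", self.ti),
        )

    def _bounds(self, names: list[str]) -> tuple[np.ndarray, np.ndarray]:
        table = dict(DEFAULT_BOUNDS)
        if self.bounds:
            table.update(self.bounds)
        table["ti"] = (self.ti - self.ti_window, self.ti + self.ti_window)
        lo = np.array([table[n][0] for n in names], dtype=float)
        hi = np.array([table[n][1] for n in names], dtype=float)
        return lo, hi

    def _data_driven_start(self, t, O2, y, names: list[str]) -> np.ndarray:
        """Heuristic initial values from coarse features of the rate series."""
        from scipy.ndimage import uniform_filter1d
        w = max(3, len(y) // 100)
        ys = uniform_filter1d(y, size=w, mode="nearest")
        vmax0 = max(float(np.percentile(ys, 98)), 1e-3)
        half_band = (ys > 0.35 * vmax0) & (ys < 0.65 * vmax0) & (O2 < 0.8 * O2.max())
        km0 = float(np.median(O2[half_band])) if half_band.any() else 10.0
        km0 = min(max(km0, 0.1), 500.0)
        rising = np.nonzero(ys > 0.5 * vmax0)[0]
        tau_half = max(float(t[rising[0]] - self.ti), 5.0) if len(rising) else 60.0
        k1_0 = float(np.clip(60.0 * np.log(2.0) / tau_half, 1e-3, 100.0))
        defaults = {"vmax": vmax0, "km": km0, "n": 2.5, "k1": k1_0,
                    "dk": 0.25 * k1_0, "k3": 0.1, "x": max(self.background, 1e-6),
                    "ti": self.ti}
        return np.array([defaults[n] for n in names], dtype=float)

    def _starts(self, t, O2, y, names, lo, hi) -> np.ndarray:
        starts = [self._data_driven_start(t, O2, y, names)]
        if self.n_starts > 0:
            sampler = qmc.LatinHypercube(d=len(names), seed=self.random_state)
            unit = sampler.random(self.n_starts)
            # sample scale parameters in log space
            log_scaled = np.array([n in ("vmax", "km", "k1", "k3") for n in names])
            lo_s = np.where(log_scaled, np.log(np.maximum(lo, 1e-6)), lo)
            hi_s = np.where(log_scaled, np.log(np.maximum(hi, 1e-6)), hi)
            pts = qmc.scale(unit, lo_s, hi_s)
            pts[:, log_scaled] = np.exp(pts[:, log_scaled])
            starts.extend(pts)
        eps = 1e-10
        return [np.clip(s, lo + eps, hi - eps) for s in starts]

    # -- sklearn API --------------------------------------------------------
    def fit(self, X, y):
        from scipy.optimize import least_squares

        X, y = check_X_y(X, y, ensure_min_samples=5)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (time s, [O2] uM)")
        spec = self._spec()
        t = X[:, 0]
        O2 = np.maximum(X[:, 1], 0.0)  # normalization noise can dip below zero
        names = self._free_names()
        if len(y) < 10 * len(names):
            warnings.warn("fewer than 10 points per free parameter; "
                          "estimates may be unstable", stacklevel=2)
        lo, hi = self._bounds(names)

        def resid(theta):
            p = self._theta_to_params(theta, names)
            return observed_rate(t, O2, p, spec) - y

        best = None
        for start in self._starts(t, O2, y, names, lo, hi):
            try:
                sol = least_squares(resid, start, bounds=(lo, hi),
                                    max_nfev=self.max_nfev, method="trf")
            except Exception:  # singular starts etc.
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None:
            raise RuntimeError("all optimisation starts failed")

        self._finalize(best, names, len(y))
        return self

    def _finalize(self, sol, names: list[str], n: int) -> None:
        self.free_names_ = names
        self.params_ = self._theta_to_params(sol.x, names)
        self.converged_ = bool(sol.status > 0 and np.isfinite(sol.cost))
        self.residuals_ = sol.fun.copy()
        self.rss_ = float(2.0 * sol.cost)
        self.n_points_ = n
        self.aic_ = float(_aic(self.rss_, n, len(names)))

        # covariance from the Jacobian at the optimum
        stderr: dict[str, float | None] = {nm: None for nm in names}
        dof = n - len(names)
        if dof > 0:
            JTJ = sol.jac.T @ sol.jac
            try:
                cov = np.linalg.pinv(JTJ) * self.rss_ / dof
                diag = np.diag(cov)
                if np.all(np.isfinite(diag)) and np.all(diag >= 0):
                    for i, nm in enumerate(names):
                        stderr[nm] = float(np.sqrt(diag[i]))
                    if "k1" in names and "dk" in names:
                        i, j = names.index("k1"), names.index("dk")
                        v = cov[i, i] + cov[j, j] + 2.0 * cov[i, j]
                        stderr["k2"] = float(np.sqrt(max(v, 0.0)))
            except np.linalg.LinAlgError:
                pass
        self.stderr_ = stderr

        p = self.params_
        self.vmax_, self.km_, self.n_ = p.vmax, p.km, p.n
        self.k1_, self.k2_, self.k3_ = p.k1, p.k2, p.k3
        self.x_, self.ti_ = p.x, p.ti

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != 2:
            raise ValueError("X must have two columns: (time s, [O2] uM)")
        return observed_rate(X[:, 0], np.maximum(X[:, 1], 0.0),
                             self.params_, self._spec())


@dataclass
class FitResult:
    """Outcome of fitting one rate series to one model structure."""

    spec: ModelSpec
    params: KineticParameters
    stderrs: dict
    residuals: np.ndarray
    rss: float
    aic: float
    runs_test_p: float
    converged: bool
    n_points: int
    derived: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def label(self) -> str:
        return self.spec.describe()


def _thin_stride(smoothing_order: int, smoothing_passes: int) -> int:
    """Residual decorrelation stride for a given binomial smoothing setting.

    Iterated binomial smoothing is near-Gaussian with kernel sd
    sqrt(passes * order / 4) samples; differentiated smoothed noise has an
    anticorrelation lobe that only dies out around 5-6 kernel sd, so thinned
    residuals are taken that far apart (plus the difference support).
    """
    sd = np.sqrt(smoothing_passes * smoothing_order / 4.0)
    return int(np.ceil(5.5 * sd)) + 3


def consumption_phase_end(rate: np.ndarray, frac: float = 0.02,
                          window: int = 501) -> int:
    """Index (into the masked rate series) where active consumption ends:
    the first point after the peak where the heavily smoothed rate stays
    below ``frac`` of its maximum.  Points beyond it are depleted-plateau
    noise carrying no kinetic information."""
    from scipy.ndimage import uniform_filter1d
    ys = uniform_filter1d(np.asarray(rate, float),
                          size=min(window, max(len(rate) // 2, 1)),
                          mode="nearest")
    ipk = int(np.argmax(ys))
    idx = np.nonzero(ys[ipk:] < frac * ys.max())[0]
    return ipk + int(idx[0]) if len(idx) else len(rate)


def _residual_randomness(residuals: np.ndarray, oxygen: np.ndarray,
                         rate: np.ndarray, stride: int,
                         low_frac: float = 0.25) -> float:
    """Combined runs-test p for residual randomness.

    Two Wald-Wolfowitz runs tests on decorrelation-thinned residual signs —
    one over the whole consumption phase, one over its low-oxygen quarter,
    where removing cooperativity leaves its signature — combined by
    Bonferroni.  The depleted plateau is excluded: it is structureless by
    construction and only dilutes the statistic.
    """
    stride = max(int(stride), 1)
    end = consumption_phase_end(rate)
    p1 = runs_test(residuals[:end][::stride])
    O2c = oxygen[:end]
    low = np.nonzero(O2c <= np.quantile(O2c, low_frac))[0]
    r_low = residuals[low][::stride]
    if len(r_low) < 25 and len(low) >= 25:
        r_low = residuals[low][::max(1, len(low) // 25)]
    if len(r_low) >= 20:
        p2 = runs_test(r_low)
        return min(1.0, 2.0 * min(p1, p2))
    return p1


def fit_trace(series: RateSeries, spec: ModelSpec, x: float = 0.0,
              fit_background: bool = False, init: KineticParameters | None = None,
              fit_ti: bool = False, n_starts: int = 8, random_state: int = 0,
              runs_stride: int = _thin_stride(4, 25), min_signal: float = 1e-3,
              retry_free_ti: bool = True) -> FitResult:
    """Fit a masked rate series to a model structure; see
    :class:`KineticRateRegressor` for the optimisation details.

    ``x`` is the electrode background coefficient from
    ``preprocess.estimate_background`` (held fixed by default).  The
    residual-randomness p-value combines consumption-phase and low-oxygen
    runs tests on residuals thinned by ``runs_stride`` so that
    smoothing/differentiation-induced short-range correlation does not
    invalidate the randomness assessment; the default stride matches the
    pipeline's default smoothing.
    """
    ti = series.metadata.injection_time
    if ti is None:
        raise ValueError("rate series metadata lacks injection_time")
    t, O2, y = series.masked()
    reg = KineticRateRegressor(
        activation=spec.activation, inactivation=spec.inactivation,
        hill_fixed_to_one=spec.hill_fixed_to_one, background=x,
        fit_background=fit_background, ti=float(ti), fit_ti=fit_ti,
        n_starts=n_starts, random_state=random_state)
    X = np.column_stack([t, O2])
    reg.fit(X, y)
    if not reg.converged_ and retry_free_ti and not fit_ti:
        retry = KineticRateRegressor(**{**reg.get_params(), "fit_ti": True})
        retry.fit(X, y)
        if retry.converged_:
            reg = retry

    try:
        p_runs = _residual_randomness(reg.residuals_, O2, y, runs_stride)
    except ValueError:  # too few points for a meaningful runs test
        p_runs = float("nan")

    flags: list[str] = []
    vs = reg.stderr_.get("vmax")
    if reg.vmax_ < min_signal or (vs is not None and reg.vmax_ < 2.0 * vs):
        flags.append("no enzymatic signal")
    if not reg.converged_:
        flags.append("non-convergence")

    derived: dict[str, float] = {}
    meta = series.metadata
    if meta.enzyme_conc:
        derived["kcat"] = kcat_from_vmax(reg.vmax_, meta.enzyme_conc)
    if spec.activation != "none":
        try:
            derived["halftime"] = halftime_of_activation(reg.params_, spec)
        except ValueError:
            flags.append("never reaches half-activation")

    return FitResult(spec=spec, params=reg.params_, stderrs=reg.stderr_,
                     residuals=reg.residuals_, rss=reg.rss_, aic=reg.aic_,
                     runs_test_p=p_runs, converged=reg.converged_,
                     n_points=reg.n_points_, derived=derived, flags=flags)


def default_candidates(hill_free: bool = True,
                       include_inactivation: bool = True) -> list[ModelSpec]:
    """Candidate model structures ordered simplest first."""
    fixed = not hill_free
    out = [ModelSpec("one_step", hill_fixed_to_one=fixed),
           ModelSpec("two_step", hill_fixed_to_one=fixed)]
    if include_inactivation:
        out.append(ModelSpec("one_step", inactivation=True, hill_fixed_to_one=fixed))
    return out


def select_model(series: RateSeries, candidates: list[ModelSpec] | None = None,
                 x: float = 0.0, alpha: float = 0.05, **fit_kwargs) -> FitResult:
    """Choose the simplest model with a converged fit and random residuals.

    Candidates are tried in the given order (default:
    one-step < two-step < one-step + inactivation); the first whose runs-test
    p exceeds ``alpha`` wins.  If none passes, the minimum-AIC fit is
    returned with a ``"no-candidate-random"`` flag.
    """
    if candidates is None:
        candidates = default_candidates()
    if not candidates:
        raise ValueError("candidate list is empty")
    fits: list[FitResult] = []
    for spec in candidates:
        res = fit_trace(series, spec, x=x, **fit_kwargs)
        fits.append(res)
        if res.converged and np.isfinite(res.runs_test_p) and res.runs_test_p > alpha:
            return res
    best = min(fits, key=lambda r: r.aic)
    best.flags.append("no-candidate-random")
    return best


def integrate_model(params: KineticParameters, spec: ModelSpec,
                    O2_start: float, t_span: np.ndarray,
                    rtol: float = 1e-8, atol: float = 1e-10) -> OxygenTrace:
    """Integrate d[O2]/dt = -observed_rate forward from ``O2_start`` and
    sample the solution on ``t_span`` (s)."""
    t_span = np.asarray(t_span, dtype=float)
    params.validate_for(spec)

    def rhs(t, y):
        return [-observed_rate(t, max(y[0], 0.0), params, spec)]

    sol = solve_ivp(rhs, (t_span[0], t_span[-1]), [float(O2_start)],
                    t_eval=t_span, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}; "
                           "consider loosening rtol/atol")
    oxy = np.minimum.accumulate(np.maximum(sol.y[0], 0.0))
    meta = AssayMetadata(injection_time=params.ti,
                         sample_interval=float(np.median(np.diff(t_span))))
    return OxygenTrace(times=t_span, oxygen=oxy, metadata=meta,
                       processing_log=[f"integrate_model({spec.describe()})"])
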