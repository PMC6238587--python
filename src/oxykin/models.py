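"""Kinetic rate laws for sulfhydryl-oxidase oxygen consumption.

The observed oxygen-consumption rate of an Ero1-type enzyme is modelled as a
Hill-modified Michaelis-Menten dependence on dissolved oxygen, multiplied by
the fraction of enzyme in the catalytically active state (the lag phase), plus
an electrode background proportional to [O2]:

    f([O2], t) = x*[O2] + a(t - ti) * Vmax * [O2]^n / ([O2]^n + KM^n)

where the activation profile ``a`` is one of

* ``none``      -- a = 1 (no lag; Erv1p-like behaviour),
* ``one_step``  -- A -> B, only B active: a = 1 - exp(-k1*tau),
* ``two_step``  -- A -> B -> C, only C active (sequential first-order steps),
* ``one_step`` + inactivation -- A -> B -> C with only B active, so activity
  rises and then decays with rate constant k3.

Conventions: time in seconds and concentrations in micromolar everywhere;
activation/inactivation rate constants are carried in min^-1 (the unit in
which they are conventionally reported) and converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KineticParameters",
    "ModelSpec",
    "ActivationProfile",
    "rate_hill_mm",
    "oxygen_at_relative_rate",
    "activation_one_step",
    "activation_two_step",
    "active_fraction_with_inactivation",
    "active_fraction",
    "observed_rate",
    "halftime_of_activation",
    "kcat_from_vmax",
    "fad_corrected_concentration",
]

#: molar absorptivity of protein-bound FAD at 454 nm (M^-1 cm^-1)
EPS_FAD_454 = 12_500.0
#: molar absorptivity of free FAD at 280 nm (M^-1 cm^-1)
EPS_FAD_280 = 21_300.0

# relative k1/k2 (or k1/k3) separation below which the degenerate equal-rate
# closed form is used instead of the generic expression
_DEGENERATE_RTOL = 1e-7

ActivationKind = Literal["none", "one_step", "two_step"]


@dataclass(frozen=True)
class ModelSpec:
    """Structural identity of a rate model: which activation scheme, whether an
    inactivation step follows it, and whether the Hill coefficient is clamped
    to 1 (classical Michaelis-Menten oxygen dependence)."""

    activation: ActivationKind = "two_step"
    inactivation: bool = False
    hill_fixed_to_one: bool = False

    def __post_init__(self) -> None:
        if self.activation not in ("none", "one_step", "two_step"):
            raise ValueError(f"unknown activation kind: {self.activation!r}")
        if self.inactivation and self.activation != "one_step":
            # A -> B -> C with B active: the single activation step is k1,
            # the decay step is k3.  Other combinations are not defined.
            raise ValueError("inactivation requires one_step activation")

    @property
    def n_kinetic_constants(self) -> int:
        k = {"none": 0, "one_step": 1, "two_step": 2}[self.activation]
        return k + (1 if self.inactivation else 0)

    def describe(self) -> str:
        parts = {"none": "no lag", "one_step": "one-step activation",
                 "two_step": "two-step activation"}[self.activation]
        if self.inactivation:
            parts += " + inactivation"
        if self.hill_fixed_to_one:
            parts += ", Hill n fixed to 1"
        return parts


@dataclass
class KineticParameters:
    """Full parameter vector of the observed-rate model.

    Attributes
    ----------
    x : float
        Electrode background coefficient (s^-1); background rate = x*[O2].
    k1, k2, k3 : float or None
        Activation (k1, k2) and inactivation (k3) rate constants in min^-1.
        ``k2`` is None for one-step models, ``k3`` is None unless the model
        has an inactivation step.
    ti : float
        Injection time (s).  Model time is tau = t - ti.
    vmax : float
        Maximal consumption rate (uM/s, positive).
    km : float
        Half-saturation oxygen concentration (uM).
    n : float
        Hill coefficient (dimensionless).
    """

    vmax: float
    km: float
    n: float = 1.0
    x: float = 0.0
    k1: float | None = None
    k2: float | None = None
    k3: float | None = None
    ti: float = 0.0

    def __post_init__(self) -> None:
        if self.vmax < 0:
            raise ValueError("vmax must be non-negative")
        if self.km <= 0:
            raise ValueError("km must be positive")
        if self.n <= 0:
            raise ValueError("Hill coefficient must be positive")
        if self.x < 0:
            raise ValueError("background coefficient x must be non-negative")
        for name in ("k1", "k2", "k3"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present")

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)

    def validate_for(self, spec: ModelSpec) -> None:
        """Raise if this parameter set does not match a model structure."""
        if spec.activation in ("one_step", "two_step") and self.k1 is None:
            raise ValueError(f"{spec.activation} activation requires k1")
        if spec.activation == "two_step" and self.k2 is None:
            raise ValueError("two_step activation requires k2")
        if spec.inactivation and self.k3 is None:
            raise ValueError("inactivation model requires k3")


@dataclass
class ActivationProfile:
    """Active-enzyme fraction over time; values lie in [0, 1]."""

    times: np.ndarray
    active_fraction: np.ndarray


def rate_hill_mm(S, vmax: float, km: float, n: float):
    """Hill-modified Michaelis-Menten rate: vmax * S^n / (S^n + km^n).

    ``S`` is the substrate (oxygen) concentration in uM; scalar or array.
    Reduces to classical Michaelis-Menten at n = 1 and returns 0 at S = 0.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    if vmax < 0 or km <= 0 or n <= 0:
        raise ValueError("require vmax >= 0, km > 0, n > 0")
    # (S/km)^n avoids overflow for large S and n
    r = np.power(S / km, n)
    out = vmax * r / (r + 1.0)
    return out if out.ndim else float(out)


def oxygen_at_relative_rate(f: float, km: float, n: float) -> float:
    """Oxygen concentration at which the rate is a fraction ``f`` of Vmax.

    Closed-form inverse of the Hill curve: S = km * (f/(1-f))^(1/n).
    """
    if not 0.0 < f < 1.0:
        raise ValueError("relative rate f must lie strictly in (0, 1)")
    if km <= 0 or n <= 0:
        raise ValueError("require km > 0, n > 0")
    return float(km * (f / (1.0 - f)) ** (1.0 / n))


def _tau(t, ti: float):
    tau = np.asarray(t, dtype=float) - ti
    return np.maximum(tau, 0.0)


def activation_one_step(t, k1: float, ti: float = 0.0):
    """Active fraction of an A -> B scheme with only B active.

    ``1 - exp(-k1*(t-ti))``; zero for t < ti by the pre-injection convention.
    ``k1`` and ``t`` must use consistent units.
    """
    if k1 <= 0:
        raise ValueError("k1 must be positive")
    out = -np.expm1(-k1 * _tau(t, ti))
    return out if np.ndim(out) else float(out)


def activation_two_step(t, k1: float, k2: float, ti: float = 0.0):
    """Active fraction of a sequential A -> B -> C scheme, only C active.

    ``(k2*(1-exp(-k1*tau)) - k1*(1-exp(-k2*tau))) / (k2 - k1)`` with
    ``tau = t - ti``.  Symmetric in (k1, k2); the removable singularity at
    k1 == k2 is evaluated through its analytic limit
    ``1 - exp(-k*tau)*(1 + k*tau)``.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    tau = _tau(t, ti)
    if abs(k2 - k1) <= _DEGENERATE_RTOL * max(k1, k2):
        k = 0.5 * (k1 + k2)
        out = 1.0 - np.exp(-k * tau) * (1.0 + k * tau)
    else:
        out = (k2 * -np.expm1(-k1 * tau) - k1 * -np.expm1(-k2 * tau)) / (k2 - k1)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


def active_fraction_with_inactivation(t, k1: float, k3: float, ti: float = 0.0):
    """Active fraction of A -> B -> C with only the intermediate B active.

    ``k1*(exp(-k1*tau) - exp(-k3*tau)) / (k3 - k1)``: activity rises with k1,
    then decays with k3, with a single interior maximum at
    ``tau* = ln(k3/k1)/(k3 - k1)``.  The k1 == k3 limit is
    ``k*tau*exp(-k*tau)``.
    """
    if k1 <= 0 or k3 <= 0:
        raise ValueError("rate constants must be positive")
    tau = _tau(t, ti)
    if abs(k3 - k1) <= _DEGENERATE_RTOL * max(k1, k3):
        k = 0.5 * (k1 + k3)
        out = k * tau * np.exp(-k * tau)
    else:
        out = k1 * (np.exp(-k1 * tau) - np.exp(-k3 * tau)) / (k3 - k1)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(out) else float(out)


def active_fraction(t, params: KineticParameters, spec: ModelSpec,
                    time_unit: Literal["s", "min"] = "s"):
    """Active fraction for any model structure, at time ``t``.

    ``params`` carries rate constants in min^-1; ``time_unit`` says whether
    ``t`` (and ``params.ti``) are in seconds (default) or minutes.
    """
    params.validate_for(spec)
    scale = 1.0 / 60.0 if time_unit == "s" else 1.0  # min^-1 -> per time unit
    if spec.activation == "none":
        # enzyme appears at injection: step from 0 to fully active
        out = np.where(np.asarray(t, float) >= params.ti, 1.0, 0.0)
        return out if out.ndim else float(out)
    if spec.inactivation:
        return active_fraction_with_inactivation(
            t, params.k1 * scale, params.k3 * scale, params.ti)
    if spec.activation == "one_step":
        return activation_one_step(t, params.k1 * scale, params.ti)
    return activation_two_step(t, params.k1 * scale, params.k2 * scale, params.ti)


def observed_rate(t, O2, params: KineticParameters, spec: ModelSpec):
    """Observed oxygen-consumption rate (uM/s) at time ``t`` (s) and
    oxygen concentration ``O2`` (uM).

    Background ``x*[O2]`` applies at all times; the enzymatic term is gated
    by the activation profile (zero before injection for lagged models).
    """
    params.validate_for(spec)
    t = np.asarray(t, dtype=float)
    O2 = np.asarray(O2, dtype=float)
    hill = rate_hill_mm(O2, params.vmax, params.km,
                        1.0 if spec.hill_fixed_to_one else params.n)
    frac = active_fraction(t, params, spec, time_unit="s")
    out = params.x * O2 + np.asarray(frac) * hill
    return out if out.ndim else float(out)


def halftime_of_activation(params: KineticParameters, spec: ModelSpec) -> float:
    """Time (min) after injection at which the active fraction reaches 0.5.

    Closed form ln2/k1 for one-step activation; bisection to 1e-6 relative
    tolerance otherwise.  For inactivation models whose peak active fraction
    never reaches 0.5, raises ``ValueError``.
    """
    params.validate_for(spec)
    if spec.activation == "none":
        raise ValueError("model without activation has no halftime")
    if spec.inactivation:
        k1, k3 = params.k1, params.k3
        if abs(k3 - k1) <= _DEGENERATE_RTOL * max(k1, k3):
            tau_peak = 1.0 / (0.5 * (k1 + k3))
        else:
            tau_peak = np.log(k3 / k1) / (k3 - k1)
        f = lambda tau: active_fraction_with_inactivation(tau, k1, k3) - 0.5
        if f(tau_peak) < 0:
            raise ValueError("never reaches half-activation")
        return float(brentq(f, 0.0, tau_peak, rtol=1e-9))
    if spec.activation == "one_step":
        return float(np.log(2.0) / params.k1)
    f = lambda tau: activation_two_step(tau, params.k1, params.k2) - 0.5
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - unreachable for positive rates
            raise RuntimeError("failed to bracket halftime")
    return float(brentq(f, 0.0, hi, rtol=1e-9))


def kcat_from_vmax(vmax: float, enzyme_conc: float) -> float:
    """Turnover number (s^-1): Vmax (uM/s) per enzyme concentration (uM),
    assuming one O2 consumed per catalytic turnover."""
    if enzyme_conc <= 0:
        raise ValueError("enzyme concentration must be positive")
    return vmax / enzyme_conc


def fad_corrected_concentration(A454: float, A280: float,
                                eps280_protein: float,
                                path_cm: float = 1.0) -> tuple[float, float]:
    """FAD and protein concentrations (uM) from A454 / A280 absorbances.

    FAD is quantified at 454 nm (eps 12,500 M^-1 cm^-1); its contribution at
    280 nm (eps 21,300 M^-1 cm^-1) is subtracted before converting the
    remaining A280 with the protein's own extinction coefficient.
    """
    if A454 < 0 or A280 < 0:
        raise ValueError("absorbances must be non-negative")
    if eps280_protein <= 0 or path_cm <= 0:
        raise ValueError("extinction coefficient and path length must be positive")
    fad_molar = A454 / (EPS_FAD_454 * path_cm)
    a280_fad = fad_molar * EPS_FAD_280 * path_cm
    corrected = A280 - a280_fad
    if corrected < -1e-12:
        raise ValueError("FAD absorbance exceeds total A280")
    protein_molar = max(corrected, 0.0) / (eps280_protein * path_cm)
    return fad_molar * 1e6, protein_molar * 1e6
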