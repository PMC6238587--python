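"""Unit tests for the pure kinetic rate laws and derived quantities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxykin.models import (
    KineticParameters, ModelSpec, activation_one_step, activation_two_step,
    active_fraction_with_inactivation, fad_corrected_concentration,
    halftime_of_activation, kcat_from_vmax, observed_rate,
    oxygen_at_relative_rate, rate_hill_mm,
)

positive_rates = st.floats(min_value=0.05, max_value=50.0)


class TestHillRateLaw:
    @pytest.mark.parametrize("S, vmax, km, n, expected, tol", [
        # cooperative Ero1a oxygen dependence retains 90% activity at 7.6 uM
        (7.6, 1.0, 5.0, 5.2, 0.90, 0.005),
        # without cooperativity 90% requires 45 uM
        (45.0, 1.0, 5.0, 1.0, 0.90, 0.005),
        (5.0, 2.0, 5.0, 3.7, 1.0, 1e-12),      # S = KM -> Vmax/2 for any n
        (0.0, 1.0, 5.0, 2.0, 0.0, 0.0),         # no substrate, no rate
    ])
    def test_reference_values(self, S, vmax, km, n, expected, tol):
        assert rate_hill_mm(S, vmax, km, n) == pytest.approx(
            expected * vmax / (2.0 if S == km else 1.0), abs=tol)

    def test_negative_substrate_rejected(self):
        with pytest.raises(ValueError):
            rate_hill_mm(-1.0, 1.0, 5.0, 2.0)

    def test_reduces_to_michaelis_menten_at_n_one(self):
        S = np.linspace(0.0, 300.0, 50)
        np.testing.assert_allclose(rate_hill_mm(S, 0.41, 89.0, 1.0),
                                   0.41 * S / (S + 89.0), rtol=1e-12)

    def test_strictly_increasing_in_substrate(self):
        S = np.linspace(0.01, 200.0, 500)
        r = rate_hill_mm(S, 1.0, 5.0, 5.2)
        assert np.all(np.diff(r) > 0)

    def test_activity_window_narrows_with_cooperativity(self):
        widths = [oxygen_at_relative_rate(0.9, 5.0, n)
                  - oxygen_at_relative_rate(0.1, 5.0, n)
                  for n in (1.0, 2.0, 3.1, 5.2, 8.0)]
        assert np.all(np.diff(widths) < 0)


class TestOxygenAtRelativeRate:
    @pytest.mark.parametrize("f, km, n, expected, decimals", [
        (0.10, 5.0, 5.2, 3.3, 1),   # cooperative shutoff concentration
        (0.10, 5.0, 1.0, 0.56, 2),  # non-cooperative comparison
        (0.90, 5.0, 5.2, 7.6, 1),
        (0.90, 5.0, 1.0, 45.0, 1),
    ])
    def test_reference_concentrations(self, f, km, n, expected, decimals):
        assert round(oxygen_at_relative_rate(f, km, n), decimals) == expected

    def test_half_maximal_at_km(self):
        assert oxygen_at_relative_rate(0.5, 37.0, 4.4) == pytest.approx(37.0)

    @given(f=st.floats(min_value=0.01, max_value=0.99),
           km=st.floats(min_value=0.1, max_value=200.0),
           n=st.floats(min_value=0.4, max_value=12.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_of_rate_law(self, f, km, n):
        S = oxygen_at_relative_rate(f, km, n)
        assert rate_hill_mm(S, 1.0, km, n) == pytest.approx(f, rel=1e-9)

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.1, 1.5])
    def test_domain_errors(self, f):
        with pytest.raises(ValueError):
            oxygen_at_relative_rate(f, 5.0, 5.2)


class TestActivationProfiles:
    def test_one_step_halftime_identity(self):
        k1 = 0.77
        assert activation_one_step(np.log(2) / k1, k1) == pytest.approx(0.5)

    def test_one_step_reference_points(self):
        assert activation_one_step(0.0, 1.0) == 0.0
        assert activation_one_step(2.0, 1.0) == pytest.approx(1 - np.exp(-2), rel=1e-12)
        assert activation_one_step(-5.0, 1.0) == 0.0  # pre-injection

    @given(k1=positive_rates, k2=positive_rates,
           t=st.floats(min_value=0.0, max_value=50.0))
    @settings(max_examples=60, deadline=None)
    def test_two_step_symmetric_in_rate_constants(self, k1, k2, t):
        assert activation_two_step(t, k1, k2) == pytest.approx(
            activation_two_step(t, k2, k1), rel=1e-12, abs=1e-15)

    @given(k=positive_rates, t=st.floats(min_value=0.01, max_value=30.0))
    @settings(max_examples=60, deadline=None)
    def test_two_step_continuous_at_equal_rates(self, k, t):
        # the function genuinely changes by eps * df/dk2 = eps * k t^2
        # exp(-kt)/2 across the diagonal; only the numerical error beyond
        # that first-order term must vanish
        eps = 1e-6 * k
        exact = activation_two_step(t, k, k)
        perturbed = activation_two_step(t, k, k + eps)
        first_order = 0.5 * eps * k * t * t * np.exp(-k * t)
        assert abs(perturbed - exact - first_order) < 1e-8

    def test_two_step_ero1a_halftime_point(self):
        # at the fitted Ero1a activation constants the active fraction
        # crosses one half close to 1.56 min after injection
        assert activation_two_step(1.56, 1.04, 1.12) == pytest.approx(0.5, abs=0.01)

    def test_two_step_limits(self):
        assert activation_two_step(0.0, 1.0, 1.3) == 0.0
        assert activation_two_step(500.0, 1.0, 1.3) == pytest.approx(1.0)
        # very fast second step reduces to one-step kinetics
        t = np.linspace(0.0, 5.0, 40)
        np.testing.assert_allclose(activation_two_step(t, 1.0, 1e6),
                                   activation_one_step(t, 1.0), atol=1e-4)

    def test_two_step_monotone_in_unit_interval(self):
        t = np.linspace(0.0, 20.0, 2000)
        f = activation_two_step(t, 0.9, 1.1)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f <= 1))

    def test_inactivation_profile_peak_location(self):
        # d/dt of the active-intermediate fraction vanishes at
        # ln(k3/k1)/(k3-k1); with k1=1, k3=2 that is ln 2
        t = np.linspace(0.0, 10.0, 200001)
        f = active_fraction_with_inactivation(t, 1.0, 2.0)
        assert t[np.argmax(f)] == pytest.approx(np.log(2.0), abs=1e-3)
        assert f[0] == 0.0
        assert f[-1] == pytest.approx(0.0, abs=1e-3)

    def test_inactivation_reduces_to_one_step_for_slow_loss(self):
        t = np.linspace(0.0, 5.0, 50)
        np.testing.assert_allclose(
            active_fraction_with_inactivation(t, 1.0, 1e-9),
            activation_one_step(t, 1.0), atol=1e-6)


class TestHalftime:
    def test_one_step_closed_form(self):
        p = KineticParameters(vmax=1, km=1, k1=np.log(2.0))
        assert halftime_of_activation(p, ModelSpec("one_step")) == pytest.approx(1.0)

    def test_two_step_ero1a_rate_constants(self):
        p = KineticParameters(vmax=1, km=1, k1=1.04, k2=1.12)
        assert halftime_of_activation(p, ModelSpec("two_step")) == pytest.approx(
            1.56, abs=0.02)

    def test_two_step_equal_rates_bisection(self):
        # 1 - e^{-k tau}(1 + k tau) = 0.5  =>  k tau ~ 1.67835
        k = 1.08
        p = KineticParameters(vmax=1, km=1, k1=k, k2=k)
        assert halftime_of_activation(p, ModelSpec("two_step")) == pytest.approx(
            1.67835 / k, rel=1e-4)

    def test_inactivation_never_reaching_half(self):
        p = KineticParameters(vmax=1, km=1, k1=0.1, k3=10.0)
        with pytest.raises(ValueError, match="half-activation"):
            halftime_of_activation(p, ModelSpec("one_step", inactivation=True))

    def test_no_activation_model_has_no_halftime(self):
        p = KineticParameters(vmax=1, km=1)
        with pytest.raises(ValueError):
            halftime_of_activation(p, ModelSpec("none"))


class TestObservedRate:
    def test_fully_activated_equals_hill_rate(self):
        p = KineticParameters(vmax=0.64, km=5.0, n=5.2, x=0.0, k1=1.04, k2=1.12,
                              ti=240.0)
        late = observed_rate(1e7, 100.0, p, ModelSpec("two_step"))
        assert late == pytest.approx(rate_hill_mm(100.0, 0.64, 5.0, 5.2), rel=1e-9)

    def test_zero_vmax_is_pure_background(self):
        p = KineticParameters(vmax=0.0, km=5.0, n=1.0, x=3e-5, ti=0.0)
        O2 = np.array([10.0, 100.0, 250.0])
        np.testing.assert_allclose(
            observed_rate(np.full(3, 100.0), O2, p, ModelSpec("none")), 3e-5 * O2)

    def test_background_only_before_injection(self):
        p = KineticParameters(vmax=0.64, km=5.0, n=5.2, x=2e-5, k1=1.04, k2=1.12,
                              ti=240.0)
        assert observed_rate(100.0, 250.0, p, ModelSpec("two_step")) == \
            pytest.approx(2e-5 * 250.0)

    def test_spec_params_mismatch_rejected(self):
        p = KineticParameters(vmax=1.0, km=5.0, n=2.0, k1=1.0)  # no k2
        with pytest.raises(ValueError, match="k2"):
            observed_rate(10.0, 50.0, p, ModelSpec("two_step"))


class TestDerivedQuantities:
    def test_kcat_reference_value(self):
        assert kcat_from_vmax(0.64, 1.0) == 0.64

    def test_kcat_scaling_and_errors(self):
        # doubling the enzyme concentration halves the turnover number
        assert kcat_from_vmax(0.5, 2.0) == pytest.approx(kcat_from_vmax(0.5, 1.0) / 2.0)
        assert kcat_from_vmax(0.0, 1.0) == 0.0
        with pytest.raises(ValueError):
            kcat_from_vmax(0.5, 0.0)

    def test_fad_concentration_from_a454(self):
        fad, protein = fad_corrected_concentration(0.125, 0.5, 40000.0)
        assert fad == pytest.approx(10.0)

    def test_fad_zero_gives_uncorrected_protein(self):
        fad, protein = fad_corrected_concentration(0.0, 0.4, 40000.0)
        assert fad == 0.0
        assert protein == pytest.approx(0.4 / 40000.0 * 1e6)

    def test_all_a280_from_fad(self):
        # 10 uM FAD contributes exactly 0.213 at 280 nm
        fad, protein = fad_corrected_concentration(0.125, 0.213, 40000.0)
        assert protein == pytest.approx(0.0, abs=1e-9)

    def test_fad_exceeding_a280_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            fad_corrected_concentration(0.125, 0.1, 40000.0)


class TestModelSpecValidation:
    def test_inactivation_requires_one_step(self):
        with pytest.raises(ValueError):
            ModelSpec("two_step", inactivation=True)

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            KineticParameters(vmax=1.0, km=-1.0)
        with pytest.raises(ValueError):
            KineticParameters(vmax=1.0, km=1.0, n=0.0)
        with pytest.raises(ValueError):
            KineticParameters(vmax=1.0, km=1.0, x=-1e-5)
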