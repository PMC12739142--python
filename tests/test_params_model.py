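"""Parameter validation, vector-field definitions and forcing admissibility."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from sirforce import (
    DEFAULT_FORCING,
    ForcingSpec,
    FullParams,
    ParameterError,
    ReducedParams,
    endemic_equilibrium,
    rhs_extended,
    rhs_full,
    rhs_reduced,
    transmission_rate,
    validate_forcing,
)


class TestParameterValidation:
    @pytest.mark.parametrize("field, value", [
        ("lam", -1.0), ("beta", 0.0), ("alpha", -0.5), ("delta", 0.0),
        ("gamma", -0.1),
    ])
    def test_invalid_reduced_parameter_names_constraint(self, field, value):
        kwargs = dict(lam=0.9, beta=0.6, alpha=0.1, delta=1.1)
        kwargs[field] = value
        with pytest.raises(ParameterError, match=field):
            ReducedParams(**kwargs)

    def test_forced_system_requires_positive_frequency(self):
        with pytest.raises(ParameterError, match="omega"):
            ReducedParams(lam=0.9, beta=0.6, alpha=0.1, delta=1.1,
                          gamma=0.1, omega=0.0)

    def test_reduction_absorbs_death_rate(self):
        fp = FullParams(lam=0.9, beta=0.6, a_raw=0.05, g=1.05, mu=0.05)
        rp = fp.reduced()
        assert rp.alpha == pytest.approx(0.1)
        assert rp.delta == pytest.approx(1.1)
        assert rp.delta > fp.mu


class TestTransmissionRate:
    def test_unforced_rate_is_constant_beta(self):
        p = ReducedParams(lam=0.9, beta=0.6722, alpha=0.1, delta=1.1)
        for t in (0.0, 1.7, 300.0):
            assert transmission_rate(t, p) == 0.6722

    def test_forced_rate_at_phase_zero(self):
        # default profile has psi(0) = 2
        p = ReducedParams(lam=0.9, beta=0.6722, alpha=0.1, delta=1.1,
                          gamma=0.001, omega=5.0)
        assert transmission_rate(0.0, p) == pytest.approx(0.6722 * 1.002,
                                                          rel=1e-14)

    @given(t=st.floats(0.0, 1e3), omega=st.sampled_from([0.1, 0.5, 1.0, 5.0]))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_forced_rate_is_periodic(self, t, omega):
        p = ReducedParams(lam=0.9, beta=0.6722, alpha=0.1, delta=1.1,
                          gamma=0.02, omega=omega)
        T = 2.0 * math.pi / omega
        assert transmission_rate(t + T, p) == pytest.approx(
            transmission_rate(t, p), rel=1e-9, abs=1e-12)


class TestFullField:
    def test_susceptible_axis_inflow(self, full_params):
        # on the S = 0 face the susceptible derivative is the bare inflow
        d = rhs_full(0.0, (0.0, 0.7, 0.3), full_params)
        assert d[0] == pytest.approx(full_params.lam)

    def test_no_disease_free_dynamics_on_axis(self, full_params):
        # with I = 0 the infective class is replenished environmentally
        d = rhs_full(0.0, (2.0, 0.0, 0.0), full_params)
        assert d[1] == pytest.approx(full_params.a_raw * 2.0)
        assert d[1] > 0

    def test_population_balance_identity(self, full_params, rng):
        # components must sum to lam - mu * (S + I + R) for any state
        for _ in range(100):
            x = rng.uniform(0.0, 5.0, size=3)
            d = rhs_full(0.0, x, full_params)
            assert d.sum() == pytest.approx(
                full_params.lam - full_params.mu * x.sum(), rel=1e-12, abs=1e-12)

    def test_reduction_identity(self, full_params, rng):
        # S' agrees exactly under alpha = a_raw + mu; I' differs by exactly
        # mu * S (the reduced system redefines the environmental gain)
        rp = full_params.reduced()
        for _ in range(100):
            x = rng.uniform(0.0, 5.0, size=3)
            d3 = rhs_full(0.0, x, full_params)
            d2 = rhs_reduced(0.0, x[:2], rp)
            assert d2[0] == pytest.approx(d3[0], rel=1e-12, abs=1e-14)
            assert d2[1] - d3[1] == pytest.approx(full_params.mu * x[0],
                                                  rel=1e-9, abs=1e-12)


class TestReducedField:
    def test_vanishes_at_endemic_equilibrium(self, mid_params):
        P = endemic_equilibrium(mid_params)
        d = rhs_reduced(0.0, P.point, mid_params)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_no_equilibrium_on_disease_free_axis(self, mid_params):
        # at (lam/alpha, 0) the S equation balances but I' = lam != 0
        d = rhs_reduced(0.0, (mid_params.lam / mid_params.alpha, 0.0),
                        mid_params)
        assert d[0] == pytest.approx(0.0, abs=1e-12)
        assert d[1] == pytest.approx(mid_params.lam)

    def test_rejects_negative_state(self, mid_params):
        with pytest.raises(ValueError, match="negative"):
            rhs_reduced(0.0, (-0.5, 0.3), mid_params)


class TestExtendedField:
    def test_unforced_field_independent_of_phase(self, mid_params):
        for theta in (0.0, 1.0, 3.0):
            d = rhs_extended((1.5, 0.8, theta), mid_params)
            assert np.allclose(d[:2], rhs_reduced(0.0, (1.5, 0.8), mid_params))
            assert d[2] == mid_params.omega

    def test_phase_advances_linearly(self, beta_mid):
        p = ReducedParams(lam=0.9, beta=beta_mid, alpha=0.1, delta=1.1,
                          gamma=0.01, omega=0.7)
        sol = solve_ivp(lambda t, x: rhs_extended(x, p), (0.0, 20.0),
                        (1.5, 0.8, 0.3), rtol=1e-10, atol=1e-12,
                        t_eval=np.linspace(0.0, 20.0, 21))
        assert np.allclose(sol.y[2], 0.3 + 0.7 * sol.t, atol=1e-7)

    def test_extended_matches_nonautonomous_formulation(self, beta_mid):
        # projecting the autonomous extension onto (S, I) reproduces the
        # non-autonomous trajectory started at the matching phase
        p = ReducedParams(lam=0.9, beta=beta_mid, alpha=0.1, delta=1.1,
                          gamma=0.05, omega=0.9)
        t0 = 2.2
        theta0 = (p.omega * t0) % (2.0 * math.pi)
        x0 = (1.4, 0.9)
        t_eval = np.linspace(0.0, 40.0, 81)
        ext = solve_ivp(lambda t, x: rhs_extended(x, p), (0.0, 40.0),
                        (*x0, theta0), rtol=1e-10, atol=1e-12, t_eval=t_eval)
        nonaut = solve_ivp(lambda t, x: rhs_reduced(t, x, p),
                           (t0, t0 + 40.0), x0, rtol=1e-10, atol=1e-12,
                           t_eval=t0 + t_eval)
        assert np.allclose(ext.y[:2], nonaut.y, atol=1e-6)


class TestForcingValidation:
    def test_default_profile_passes(self, mid_params):
        rep = validate_forcing(DEFAULT_FORCING, mid_params)
        assert rep.ok
        assert rep.n_critical_points == 2

    def test_constant_profile_fails_critical_points(self, mid_params):
        flat = ForcingSpec(psi=lambda x: np.ones_like(np.asarray(x, float)),
                           name="flat")
        rep = validate_forcing(flat, mid_params)
        assert not rep.critical_points_ok

    def test_nonperiodic_profile_fails(self, mid_params):
        ramp = ForcingSpec(psi=lambda x: np.asarray(x, float), name="ramp")
        rep = validate_forcing(ramp, mid_params)
        assert not rep.periodic

    def test_nonfinite_profile_raises(self, mid_params):
        bad = ForcingSpec(psi=lambda x: np.full_like(np.asarray(x, float),
                                                     np.nan), name="nan")
        with pytest.raises(ValueError, match="non-finite"):
            validate_forcing(bad, mid_params)
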