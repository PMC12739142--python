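"""Endemic equilibrium, Jacobian structure, trace thresholds, stability."""

import numpy as np
import pytest
from scipy.optimize import brentq, fsolve

from sirforce import (
    ReducedParams,
    classify_equilibrium,
    cubic_equilibrium_roots,
    endemic_equilibrium,
    hopf_thresholds,
    jacobian_at,
    rhs_reduced,
    trace_at_equilibrium,
)


class TestEndemicEquilibrium:
    def test_closed_form_values(self, mid_params):
        P = endemic_equilibrium(mid_params)
        assert P.I_star == pytest.approx(0.9 / 1.1, abs=1e-12)
        assert P.S_star == pytest.approx(
            1.1 ** 2 * 0.9 / (0.1 * 1.1 ** 2 + mid_params.beta * 0.9 ** 2),
            abs=1e-12)

    def test_is_a_fixed_point(self, mid_params):
        P = endemic_equilibrium(mid_params)
        assert np.max(np.abs(rhs_reduced(0.0, P.point, mid_params))) < 1e-12

    def test_unique_admissible_equilibrium(self, mid_params, rng):
        # multi-start root search over the trapping box finds a single
        # admissible fixed point
        p = mid_params
        found = []
        for _ in range(100):
            x0 = rng.uniform([0.0, 0.0], [p.lam / p.alpha, 3.0 * p.lam / p.delta])
            sol, info, ier, _ = fsolve(
                lambda x: rhs_reduced(0.0, np.abs(x), p), x0, full_output=True)
            sol = np.abs(sol)
            if ier == 1 and np.max(np.abs(info["fvec"])) < 1e-10:
                if not any(np.allclose(sol, f, atol=1e-6) for f in found):
                    found.append(sol)
        P = endemic_equilibrium(p)
        assert len(found) == 1
        assert np.allclose(found[0], P.point, atol=1e-6)


class TestEquilibriumCubic:
    def test_real_root_is_lam_over_delta(self, mid_params):
        roots, mask = cubic_equilibrium_roots(mid_params)
        assert mask.sum() == 1
        assert roots[mask][0].real == pytest.approx(0.9 / 1.1, abs=1e-9)

    def test_complex_pair_is_purely_imaginary(self, rng):
        for _ in range(20):
            lam, beta, alpha, delta = rng.uniform(0.1, 3.0, size=4)
            p = ReducedParams(lam=lam, beta=beta, alpha=alpha, delta=delta)
            roots, mask = cubic_equilibrium_roots(p)
            pair = roots[~mask]
            assert len(pair) == 2
            assert np.max(np.abs(pair.real)) < 1e-8
            assert np.allclose(np.abs(pair.imag),
                               np.sqrt(alpha * beta) / beta, atol=1e-8)

    def test_roots_reconstruct_polynomial(self, mid_params):
        # Vieta / brute-force check: multiplying out the computed roots must
        # reproduce the cubic's coefficients
        p = mid_params
        roots, _ = cubic_equilibrium_roots(p)
        lead = -p.beta * p.delta
        rebuilt = lead * np.poly(roots)
        expected = np.array([-p.beta * p.delta, p.beta * p.lam,
                             -p.alpha * p.delta, p.alpha * p.lam])
        assert np.allclose(rebuilt.real, expected, rtol=1e-10)
        assert np.max(np.abs(rebuilt.imag)) < 1e-12


class TestJacobian:
    def test_matches_finite_differences(self, mid_params, rng):
        h = 1e-6
        for _ in range(20):
            x = rng.uniform(0.1, 3.0, size=2)
            jac = jacobian_at(x, mid_params)
            fd = np.empty((2, 2))
            for j in range(2):
                e = np.zeros(2)
                e[j] = h
                fd[:, j] = (rhs_reduced(0.0, x + e, mid_params)
                            - rhs_reduced(0.0, x - e, mid_params)) / (2 * h)
            assert np.allclose(jac.entries, fd, rtol=1e-6, atol=1e-8)

    def test_trace_closed_form_at_equilibrium(self, mid_params):
        p = mid_params
        P = endemic_equilibrium(p)
        expected = ((-p.alpha * p.delta ** 2 - p.beta * p.lam ** 2) / p.delta ** 2
                    + p.delta * (-p.alpha * p.delta ** 2 + p.beta * p.lam ** 2)
                    / (p.alpha * p.delta ** 2 + p.beta * p.lam ** 2))
        assert jacobian_at(P.point, p).trace == pytest.approx(expected,
                                                              rel=1e-12)
        assert trace_at_equilibrium(p) == pytest.approx(expected, rel=1e-12)

    def test_trace_vanishes_at_thresholds(self, base_params, thresholds):
        for b in (thresholds.beta1, thresholds.beta2):
            p = base_params.with_beta(b)
            P = endemic_equilibrium(p)
            assert abs(jacobian_at(P.point, p).trace) < 1e-10


class TestHopfThresholds:
    def test_reference_values(self, thresholds):
        assert thresholds.beta1 == pytest.approx(0.2431530, abs=1e-6)
        assert thresholds.beta2 == pytest.approx(1.1012914, abs=1e-6)
        assert 0 < thresholds.beta1 < thresholds.beta2

    def test_coincide_when_delta_is_eight_alpha(self):
        th = hopf_thresholds(ReducedParams(lam=0.9, beta=1.0, alpha=0.1,
                                           delta=0.8))
        assert th.exists
        assert th.beta1 == pytest.approx(th.beta2, rel=1e-12)

    def test_absent_when_alpha_too_large(self):
        th = hopf_thresholds(ReducedParams(lam=0.9, beta=1.0, alpha=0.2,
                                           delta=1.1))
        assert not th.exists
        assert th.beta1 is None and th.beta2 is None

    def test_closed_forms_match_independent_root_finding(self, rng):
        # bracket sign changes of the trace on a coarse grid, refine with
        # brentq, and compare against the closed forms
        n_checked = 0
        while n_checked < 50:
            lam = rng.uniform(0.3, 2.0)
            delta = rng.uniform(0.3, 2.0)
            alpha = rng.uniform(0.01, delta / 8.0 * 0.95)
            p = ReducedParams(lam=lam, beta=1.0, alpha=alpha, delta=delta)
            th = hopf_thresholds(p)
            grid = np.linspace(1e-6, 3.0 * th.beta2, 400)
            tr = np.array([trace_at_equilibrium(p, b) for b in grid])
            idx = np.nonzero(tr[:-1] * tr[1:] < 0)[0]
            assert len(idx) == 2
            roots = [brentq(lambda b: trace_at_equilibrium(p, b),
                            grid[i], grid[i + 1], xtol=1e-12) for i in idx]
            assert roots[0] == pytest.approx(th.beta1, abs=1e-8)
            assert roots[1] == pytest.approx(th.beta2, abs=1e-8)
            n_checked += 1

    def test_trace_sign_pattern(self, base_params, thresholds):
        b1, b2 = thresholds.beta1, thresholds.beta2
        p = base_params
        assert trace_at_equilibrium(p, 0.5 * b1) < 0
        assert trace_at_equilibrium(p, 0.5 * (b1 + b2)) > 0
        assert trace_at_equilibrium(p, 2.0 * b2) < 0


class TestStabilityClassification:
    def test_focus_pattern_across_the_band(self, base_params, thresholds):
        b1, b2 = thresholds.beta1, thresholds.beta2
        assert classify_equilibrium(base_params.with_beta(b1 - 0.1)) \
            == "stable_focus"
        assert classify_equilibrium(base_params.with_beta((b1 + b2) / 2)) \
            == "unstable_focus"
        assert classify_equilibrium(base_params.with_beta(b2 + 0.1)) \
            == "stable_focus"

    def test_nonhyperbolic_at_threshold(self, base_params, thresholds):
        assert classify_equilibrium(base_params.with_beta(thresholds.beta1)) \
            == "nonhyperbolic"
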