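"""Tests of the Heun recurrences, closed-form series, evaluation and the
ODE-residual oracle (which is also the arbiter for the coefficient groupings)."""

from fractions import Fraction

import numpy as np
import pytest

from recspec import (
    ConfluentHeunParameters,
    ConvergenceDomainError,
    GeneralHeunParameters,
    confluent_heun_recurrence,
    forward_substitution,
    general_heun_recurrence,
    heun_eval,
    heun_series,
    ode_residual,
)
from recspec.fixtures import FixtureSpec, random_heun_params
from recspec.heun import HeunSeries, convergence_radius, heun_params_from_json, heun_params_to_json

from conftest import heun_ivp_oracle


def general_params(seed):
    return random_heun_params(FixtureSpec("heun_params", seed=seed))


def confluent_params(seed):
    return random_heun_params(FixtureSpec("heun_params", seed=seed,
                                          extra={"kind": "confluent"}))


class TestParameterInvariants:
    def test_fuchs_relation_closed_automatically(self):
        p = GeneralHeunParameters(a=2.0, q=0.1, alpha=0.3, beta=0.7, gamma=1.1, delta=-0.2)
        assert abs(p.alpha + p.beta + 1 - p.gamma - p.delta - p.epsilon) < 1e-12

    def test_fuchs_violation_rejected(self):
        with pytest.raises(ValueError, match="Fuchs"):
            GeneralHeunParameters(a=2.0, q=0.1, alpha=0.3, beta=0.7, gamma=1.1,
                                  delta=-0.2, epsilon=99.0)

    @pytest.mark.parametrize("gamma", [0, -1, -3])
    def test_nonpositive_integer_gamma_rejected(self, gamma):
        with pytest.raises(ValueError, match="gamma"):
            GeneralHeunParameters(a=2.0, q=0.1, alpha=0.3, beta=0.7, gamma=gamma, delta=0.0)
        with pytest.raises(ValueError, match="gamma"):
            ConfluentHeunParameters(q=0.1, alpha=0.3, gamma=gamma, delta=0.0, epsilon=1.0)

    def test_degenerate_a_rejected(self):
        with pytest.raises(ValueError, match="a = 0"):
            GeneralHeunParameters(a=0, q=0.1, alpha=0.3, beta=0.7, gamma=1.1, delta=0.0)


class TestRecurrenceFamilies:
    def test_general_first_coefficient(self):
        # C_1 = q/(a gamma) from the j = 0 row
        p = GeneralHeunParameters(a=Fraction(3, 2), q=Fraction(2, 5), alpha=Fraction(1, 3),
                                  beta=Fraction(-1, 4), gamma=Fraction(5, 6), delta=Fraction(1, 2))
        rec = general_heun_recurrence(p, mode="exact")
        C = forward_substitution(rec, 1)
        assert C[1] == Fraction(2, 5) / (Fraction(3, 2) * Fraction(5, 6))

    def test_confluent_first_coefficient(self):
        p = ConfluentHeunParameters(q=Fraction(1, 2), alpha=Fraction(1, 3),
                                    gamma=Fraction(6, 5), delta=Fraction(-2, 5),
                                    epsilon=Fraction(4, 5))
        rec = confluent_heun_recurrence(p, mode="exact")
        assert forward_substitution(rec, 1)[1] == Fraction(1, 2) / Fraction(6, 5)

    def test_p0_never_used(self):
        """P_0 multiplies C_{-1} = 0, so the j = 0 row ignores it."""
        p = general_params(0)
        rec = general_heun_recurrence(p)
        C = forward_substitution(rec, 3)
        assert np.isfinite(C).all()  # no dependence on P(0) blowing anything up

    def test_confluent_limit_of_general_family(self):
        """General family divided by a converges rowwise to the confluent one
        under a->oo with eps/a -> -eps', q/a -> q', alpha*beta/a -> alpha'."""
        epsp, qp, alphap = 0.7, -0.3, 0.45
        ga, de = 1.2, -0.4
        conf = ConfluentHeunParameters(q=qp, alpha=alphap, gamma=ga, delta=de, epsilon=epsp)
        crec = confluent_heun_recurrence(conf)
        for a in (1e6, 1e8):
            eps = -epsp * a
            q = qp * a
            alpha_beta = alphap * a
            # split alpha*beta with alpha+beta fixed by Fuchs
            s = ga + de + eps - 1  # alpha + beta
            disc = np.sqrt(s * s - 4 * alpha_beta + 0j)
            al, be = (s + disc) / 2, (s - disc) / 2
            gen = GeneralHeunParameters(a=a, q=q, alpha=al, beta=be, gamma=ga, delta=de)
            grec = general_heun_recurrence(gen)
            tol = 100.0 / a  # the limit is approached at rate O(1/a)
            for j in range(6):
                assert abs(grec.coeff_P(j) / a - crec.coeff_P(j)) < tol
                assert abs(grec.coeff_Qt(j) / a - crec.coeff_Qt(j)) < tol
                assert abs(grec.coeff_R(j) / a - crec.coeff_R(j)) < tol


class TestHeunSeries:
    @pytest.mark.parametrize("kind", ["general", "confluent"])
    def test_closed_form_equals_forward(self, kind):
        for seed in range(6):
            p = general_params(seed) if kind == "general" else confluent_params(seed)
            s_cf = heun_series(p, 25, method="closed_form")
            s_fw = heun_series(p, 25, method="forward")
            a = np.array(s_cf.coefficients, dtype=float)
            b = np.array(s_fw.coefficients, dtype=float)
            scale = np.maximum(1.0, np.abs(b))
            assert (np.abs(a - b) / scale).max() < 1e-9

    def test_exact_mode_identity(self):
        p = GeneralHeunParameters(a=Fraction(2), q=Fraction(1, 3), alpha=Fraction(1, 2),
                                  beta=Fraction(-1, 3), gamma=Fraction(3, 4), delta=Fraction(1, 5))
        cf = heun_series(p, 20, mode="exact", method="closed_form").coefficients
        fw = heun_series(p, 20, mode="exact", method="forward").coefficients
        assert cf == fw

    def test_leading_coefficient_is_one(self):
        assert heun_series(general_params(3), 5).coefficients[0] == 1.0


class TestHeunEval:
    def test_value_at_origin(self):
        assert heun_eval(general_params(1), 0.0)[0] == 1.0

    def test_zero_accessory_flattens_first_order(self):
        """q = 0 kills C_1, so y = 1 + O(z^2) near the origin."""
        p0 = general_params(2)
        p = GeneralHeunParameters(a=p0.a, q=0.0, alpha=p0.alpha, beta=p0.beta,
                                  gamma=p0.gamma, delta=p0.delta)
        z = 1e-5 * convergence_radius(p)
        val, _ = heun_eval(p, z)
        # |val - 1| = O(z^2): the linear term vanishes with q
        assert abs(val - 1.0) < 10 * z**2 * max(1.0, abs(p.alpha * p.beta))

    def test_outside_disc_raises(self):
        p = general_params(4)
        with pytest.raises(ConvergenceDomainError):
            heun_eval(p, 1.5 * convergence_radius(p))

    @pytest.mark.parametrize("kind", ["general", "confluent"])
    def test_matches_ivp_oracle(self, kind):
        """Series evaluation agrees with adaptive integration of the ODE
        started from y(0) = 1, y'(0) = C_1.  The comparison draws gamma > 1
        so the initial-value problem is well conditioned (for gamma < 1 the
        second Frobenius solution vanishes at 0 and forward integration
        amplifies seed error; the residual oracle covers that regime)."""
        for seed in range(5):
            extra = {"min_gamma": 1.1}
            if kind == "confluent":
                extra["kind"] = "confluent"
            p = random_heun_params(FixtureSpec("heun_params", seed=seed + 20, extra=extra))
            z = 0.3 * convergence_radius(p)
            val, info = heun_eval(p, z, tol=1e-13, n_max=300)
            ref = heun_ivp_oracle(p, z)
            assert abs(val - ref) < 1e-8 * max(1.0, abs(ref))


class TestOdeResidual:
    def test_trivial_constant_solution(self):
        """With q = 0 and alpha = 0 the constant y = 1 solves the equation."""
        p = GeneralHeunParameters(a=2.0, q=0.0, alpha=0.0, beta=0.7, gamma=1.1, delta=-0.2)
        s = HeunSeries(params=p, coefficients=[1.0] + [0.0] * 12, n=12)
        assert ode_residual(s, [0.1, 0.3, -0.2]) == 0.0

    @pytest.mark.parametrize("kind", ["general", "confluent"])
    def test_residual_small_at_order_forty(self, kind):
        for seed in range(6):
            p = general_params(seed + 50) if kind == "general" else confluent_params(seed + 50)
            s = heun_series(p, 40, method="forward")
            r = 0.2 * convergence_radius(p)
            assert ode_residual(s, [r, -r, r * 1j]) < 1e-10

    def test_residual_decays_geometrically_with_order(self):
        p = general_params(8)
        r = 0.3 * convergence_radius(p)
        res = [ode_residual(heun_series(p, n, method="forward"), [r]) for n in (10, 20, 30)]
        assert res[1] < res[0] * 1e-2 or res[1] < 1e-12
        assert res[2] < res[1] or res[2] < 1e-12

    def test_corruption_inflates_residual(self):
        """Perturbing C_2 by 1e-3 must inflate the residual by orders of
        magnitude — establishes the oracle's discriminating power."""
        p = general_params(9)
        s = heun_series(p, 40, method="forward")
        base = ode_residual(s, [0.2 * convergence_radius(p)])
        bad = list(s.coefficients)
        bad[2] += 1e-3
        corrupted = HeunSeries(params=p, coefficients=bad, n=s.n)
        inflated = ode_residual(corrupted, [0.2 * convergence_radius(p)])
        assert inflated > max(1e3 * base, 1e-6)

    def test_point_outside_disc_rejected(self):
        p = general_params(10)
        s = heun_series(p, 20, method="forward")
        with pytest.raises(ConvergenceDomainError):
            ode_residual(s, [2.0 * convergence_radius(p)])


class TestPolynomialReduction:
    def test_alpha_negative_integer_with_quantized_q_truncates(self):
        """alpha = -N plus a quantized accessory value gives a degree-N
        polynomial: C_j = 0 for all j > N (exact arithmetic)."""
        from recspec import BinaryChoiceModel, binary_choice_heun_map, quantization_polynomial
        from recspec.models import binary_choice_recurrence

        m = BinaryChoiceModel(N=5, eps1=1.0, eps2=2.0, mu1=0.5, mu2=0.75)
        rec = binary_choice_recurrence(m, exact=True)
        pol = quantization_polynomial(rec, m.N)
        # q = q(0) is always a root: the stationary mode truncates
        q0 = binary_choice_heun_map(m, exact=True).q_of_rate(0)
        val = sum(c * q0**k for k, c in enumerate(pol))
        assert val == 0
        C = forward_substitution(rec.with_accessory(q0), m.N + 3)
        assert C[m.N + 1] == 0 and C[m.N + 2] == 0


def test_params_json_roundtrip():
    for p in (general_params(30), confluent_params(31)):
        back = heun_params_from_json(heun_params_to_json(p))
        assert type(back) is type(p)
        assert abs(back.q - p.q) == 0
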