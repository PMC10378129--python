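"""Tests of the binary-choice and vacillating-voter model constructions,
their generators, stationary laws and stochastic oracles."""

import numpy as np
import pytest

from recspec import (
    BinaryChoiceModel,
    BirthDeathGenerator,
    ReducibleChainError,
    VacillatingVoterModel,
    binary_choice_generator,
    binary_choice_heun_map,
    gillespie_simulate,
    stationary_distribution,
    vacillating_generator,
    vacillating_recurrence,
    vacillating_rule_simulate,
)
from recspec.models import (
    model_from_dict,
    model_to_dict,
    vacillating_q_of_rate,
)
from recspec.recurrence import forward_substitution


class TestBinaryChoiceGenerator:
    def test_boundary_rates(self):
        m = BinaryChoiceModel(N=7, eps1=1.3, eps2=0.6, mu1=0.4, mu2=0.9)
        g = binary_choice_generator(m)
        assert g.birth[0] == m.N * m.eps1  # only spontaneous switching from n=0
        assert g.death[0] == 0
        assert g.birth[m.N] == 0  # nobody left to recruit or switch right
        assert g.death[m.N] == m.N * m.eps2

    def test_column_sums_vanish(self):
        """Probability conservation: column sums vanish to within one ulp of
        the total outflow rate (the diagonal is assembled from the same
        floats as the off-diagonal entries)."""
        m = BinaryChoiceModel(N=9, eps1=0.77, eps2=1.21, mu1=0.33, mu2=0.91)
        A = binary_choice_generator(m).matrix()
        assert np.abs(A.sum(axis=0)).max() <= 4e-16 * np.abs(A).max()

    def test_rate_symmetry_under_label_swap(self):
        """Swapping (eps1, mu1) <-> (eps2, mu2) mirrors the chain n <-> N-n."""
        m1 = BinaryChoiceModel(N=6, eps1=1.0, eps2=2.0, mu1=0.5, mu2=0.8)
        m2 = BinaryChoiceModel(N=6, eps1=2.0, eps2=1.0, mu1=0.8, mu2=0.5)
        g1, g2 = binary_choice_generator(m1), binary_choice_generator(m2)
        assert np.allclose(g1.birth, g2.death[::-1])
        assert np.allclose(g1.death, g2.birth[::-1])

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            BinaryChoiceModel(N=1, eps1=1, eps2=1, mu1=1, mu2=1)
        with pytest.raises(ValueError):
            BinaryChoiceModel(N=5, eps1=1, eps2=1, mu1=0, mu2=1)


class TestBinaryChoiceHeunMap:
    def test_delta_always_zero(self):
        m = BinaryChoiceModel(N=5, eps1=0.9, eps2=1.7, mu1=0.3, mu2=1.2)
        assert binary_choice_heun_map(m).delta == 0

    def test_symmetric_rates_merge_singularities(self):
        m = BinaryChoiceModel(N=5, eps1=1.0, eps2=1.0, mu1=0.7, mu2=0.7)
        assert binary_choice_heun_map(m).a == 1.0

    def test_alpha_is_minus_N(self):
        m = BinaryChoiceModel(N=11, eps1=1.0, eps2=2.0, mu1=0.5, mu2=0.75)
        hm = binary_choice_heun_map(m)
        assert hm.alpha == -11
        # Fuchs relation holds for the assembled parameters
        assert abs(hm.alpha + hm.beta + 1 - hm.gamma - hm.delta - hm.epsilon) < 1e-12

    def test_q_map_inverts(self):
        m = BinaryChoiceModel(N=5, eps1=0.9, eps2=1.7, mu1=0.3, mu2=1.2)
        hm = binary_choice_heun_map(m)
        for lam in (0.0, 1.7, 12.3):
            assert abs(hm.rate_of_q(hm.q_of_rate(lam)) - lam) < 1e-12


class TestVacillatingGenerator:
    def test_consensus_boundaries_only_spontaneous(self):
        m = VacillatingVoterModel(N=12, pd=0.25)
        g = vacillating_generator(m)
        assert g.birth[0] == pytest.approx(m.pd * m.N)
        assert g.death[0] == 0
        assert g.birth[m.N] == 0
        assert g.death[m.N] == pytest.approx(m.pd * m.N)

    def test_flip_symmetry(self):
        """The model is symmetric under n <-> N-n."""
        g = vacillating_generator(VacillatingVoterModel(N=9, pd=0.4))
        assert np.allclose(g.birth, g.death[::-1])

    def test_pd_one_limit_is_pure_random_flip(self):
        """As p_d -> 1 the interaction terms vanish: b(n) -> p_d (N-n)."""
        m = VacillatingVoterModel(N=8, pd=1 - 1e-12)
        g = vacillating_generator(m)
        n = np.arange(9.0)
        assert np.allclose(g.birth, (8 - n), atol=1e-9)
        assert np.allclose(g.death, n, atol=1e-9)

    def test_column_sums_vanish(self):
        A = vacillating_generator(VacillatingVoterModel(N=15, pd=0.3)).matrix()
        assert np.abs(A.sum(axis=0)).max() <= 4e-16 * np.abs(A).max()

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            VacillatingVoterModel(N=2, pd=0.5)
        with pytest.raises(ValueError):
            VacillatingVoterModel(N=5, pd=0.0)


class TestVacillatingRecurrence:
    def test_boundary_row_matches_explicit_condition(self):
        """C_1 = q(lam) / [(N-1)((N-1)p_d + N(1-p_d))] from the j=0 row."""
        m = VacillatingVoterModel(N=7, pd=0.35)
        lam = 0.9
        q = vacillating_q_of_rate(m, lam)
        rec = vacillating_recurrence(m).with_accessory(q)
        C = forward_substitution(rec, 1)
        N, pd = m.N, m.pd
        expected = q / ((N - 1) * ((N - 1) * pd + N * (1 - pd)))
        assert C[1] == pytest.approx(expected, rel=1e-13)

    def test_override_row_equals_generic_row(self):
        """The explicit boundary row coincides with the generic j=0
        coefficients of the derived family (no special casing is needed)."""
        m = VacillatingVoterModel(N=9, pd=0.2)
        rec = vacillating_recurrence(m, exact=True)
        no_override = type(rec)(rec.P, rec.Qt, rec.R, None, "exact")
        assert rec.coeff_R(0) == no_override.coeff_R(0)
        assert rec.coeff_Qt(0) == no_override.coeff_Qt(0)

    @pytest.mark.parametrize("pd", [0.1, 0.5, 0.9])
    def test_series_truncates_at_dense_eigenvalues(self, pd):
        """The spectral arbiter: at every dense-generator decay rate the
        recurrence solution satisfies C_{N+1} = 0 and reproduces the
        eigenvector after the (N-1)^n variable rescaling."""
        m = VacillatingVoterModel(N=8, pd=pd)
        g = vacillating_generator(m)
        A = g.matrix()
        w, V = np.linalg.eig(A)
        for k in np.argsort(-w.real):
            lam = -w[k].real
            rec = vacillating_recurrence(m).with_accessory(vacillating_q_of_rate(m, lam))
            C = np.array(forward_substitution(rec, m.N + 1), dtype=float)
            scaled = C[: m.N + 1] * (m.N - 1.0) ** np.arange(m.N + 1)
            v = V[:, k].real
            v = v / v[0]
            assert abs(C[m.N + 1]) < 1e-8 * np.abs(C).max()
            assert np.abs(scaled - v).max() < 1e-8 * np.abs(v).max()


class TestStationaryDistribution:
    def test_normalized_and_stationary(self):
        m = BinaryChoiceModel(N=100, eps1=1.2, eps2=0.8, mu1=0.05, mu2=0.07)
        g = binary_choice_generator(m)
        pi = stationary_distribution(g)
        assert pi.sum() == pytest.approx(1.0, abs=1e-14)
        assert np.abs(g.matrix() @ pi).max() < 1e-12 * np.abs(g.matrix()).max()

    def test_symmetric_model_symmetric_law(self):
        m = BinaryChoiceModel(N=20, eps1=1.0, eps2=1.0, mu1=0.5, mu2=0.5)
        pi = stationary_distribution(binary_choice_generator(m))
        assert np.allclose(pi, pi[::-1], rtol=1e-10)

    def test_reducible_chain_names_cut_state(self):
        g = BirthDeathGenerator(N=4, birth=np.array([1.0, 0.0, 1.0, 1.0, 0.0]),
                                death=np.array([0.0, 1.0, 1.0, 1.0, 1.0]))
        with pytest.raises(ReducibleChainError) as exc:
            stationary_distribution(g)
        assert exc.value.state == 1


class TestGillespie:
    def test_absorbing_chain_never_moves(self):
        g = BirthDeathGenerator(N=3, birth=np.zeros(4), death=np.zeros(4))
        states = gillespie_simulate(g, 2, t_end=5.0, n_traj=50, seed=0)
        assert (states == 2).all()

    def test_negative_time_rejected(self):
        g = BirthDeathGenerator(N=3, birth=np.array([1.0, 1, 1, 0]),
                                death=np.array([0.0, 1, 1, 1]))
        with pytest.raises(ValueError):
            gillespie_simulate(g, 0, -1.0, 10, seed=0)

    def test_long_time_reaches_stationarity(self):
        m = BinaryChoiceModel(N=6, eps1=1.5, eps2=1.0, mu1=0.3, mu2=0.4)
        g = binary_choice_generator(m)
        states = gillespie_simulate(g, 0, t_end=30.0, n_traj=20000, seed=7)
        emp = np.bincount(states, minlength=7) / 20000
        pi = stationary_distribution(g)
        assert 0.5 * np.abs(emp - pi).sum() < 0.02

    def test_seed_reproducibility(self):
        m = BinaryChoiceModel(N=5, eps1=1.0, eps2=1.0, mu1=0.5, mu2=0.5)
        g = binary_choice_generator(m)
        a = gillespie_simulate(g, 0, 1.0, 500, seed=11)
        b = gillespie_simulate(g, 0, 1.0, 500, seed=11)
        assert (a == b).all()


class TestVacillatingRuleSimulation:
    def test_pd_one_limit_matches_random_flip_chain(self):
        """With p_d -> 1 every event is a spontaneous flip, so the sampler
        must reproduce the symmetric binomial stationary law."""
        m = VacillatingVoterModel(N=10, pd=1 - 1e-9)
        samples = vacillating_rule_simulate(m, 40000, seed=3)
        emp = np.bincount(samples, minlength=11) / len(samples)
        from scipy.stats import binom

        ref = binom.pmf(np.arange(11), 10, 0.5)
        assert 0.5 * np.abs(emp - ref).sum() < 0.02

    def test_stationary_matches_generator(self):
        """Cross-oracle: the agent-rule sampler agrees with the detailed
        balance law of the propensity generator."""
        m = VacillatingVoterModel(N=15, pd=0.3)
        samples = vacillating_rule_simulate(m, 60000, seed=5)
        emp = np.bincount(samples, minlength=16) / len(samples)
        pi = stationary_distribution(vacillating_generator(m))
        assert 0.5 * np.abs(emp - pi).sum() < 0.02

    def test_trimodality_in_low_flip_regime(self):
        """For N = 20 and small p_d the stationary law has three local
        maxima: both consensus states plus the mixed state."""
        pi = stationary_distribution(vacillating_generator(VacillatingVoterModel(N=20, pd=0.05)))
        maxima = [i for i in range(21)
                  if (i == 0 or pi[i] >= pi[i - 1]) and (i == 20 or pi[i] >= pi[i + 1])]
        assert len(maxima) >= 3
        assert 0 in maxima and 20 in maxima and 10 in maxima


def test_model_serialization_roundtrip():
    for m in (BinaryChoiceModel(N=5, eps1=1.0, eps2=2.0, mu1=0.5, mu2=0.75),
              VacillatingVoterModel(N=9, pd=0.4)):
        assert model_from_dict(model_to_dict(m)) == m
    with pytest.raises(ValueError):
        model_from_dict({"model": "bogus"})
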