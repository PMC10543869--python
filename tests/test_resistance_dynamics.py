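from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bednetopt import (
    Environment,
    EvolutionParams,
    LocusState,
    PopulationState,
    advance_generation,
    resistance_phenotype,
)
from bednetopt.resistance_dynamics import (
    allele_fitnesses,
    apply_mutation_rule,
    fitness_table,
    genotype_fitness,
    mean_fitness,
    next_allele_frequency,
    next_population_size,
)


def make_state(f1=0.5, f2=0.5, N=1000.0, steps=(1, 0)):
    locus = LocusState(f_R=f1, steps_R=steps[0], steps_S=steps[1])
    locus2 = LocusState(f_R=f2, steps_R=steps[0], steps_S=steps[1])
    return PopulationState(N=N, locus1=locus, locus2=locus2)


class TestPhenotype:
    @pytest.mark.parametrize(
        "steps, d_q, expected",
        [(0, 0.3, 1.0), (2, 0.3, 0.49), (3, 0.5, 0.125)],
    )
    def test_examples(self, steps, d_q, expected):
        assert resistance_phenotype(steps, d_q) == pytest.approx(expected)

    def test_negative_steps_rejected(self):
        with pytest.raises(ValueError):
            resistance_phenotype(-1, 0.3)


class TestFitness:
    @pytest.mark.parametrize(
        "V, P, M, expected",
        [(1.0, 1.0, 1.0, 0.0), (0.0, 0.7, 0.9, 1.0), (0.5, 0.8, 0.5, 0.8)],
    )
    def test_genotype_fitness(self, V, P, M, expected):
        assert genotype_fitness(V, P, M) == pytest.approx(expected)

    def test_allele_fitness_is_weighted_mean(self):
        w = np.array([[0.9, 0.7], [0.6, 0.4]])
        w_R, w_S = allele_fitnesses(0.5, w)
        assert w_R == pytest.approx(0.8)
        assert w_S == pytest.approx(0.5)
        # other locus fixed for its resistant allele
        w_R, _ = allele_fitnesses(1.0, w)
        assert w_R == pytest.approx(w[0, 0])

    def test_equal_fitnesses_collapse(self):
        w = np.full((2, 2), 0.42)
        assert allele_fitnesses(0.3, w) == pytest.approx((0.42, 0.42))
        assert mean_fitness(0.1, 0.9, w) == pytest.approx(0.42)

    def test_mean_fitness_equal_weights(self):
        w = np.array([[1.0, 0.8], [0.6, 0.4]])
        assert mean_fitness(0.5, 0.5, w) == pytest.approx(0.7)

    def test_mean_fitness_monomorphic(self):
        w = np.array([[1.0, 0.8], [0.6, 0.4]])
        assert mean_fitness(1.0, 1.0, w) == pytest.approx(w[0, 0])


class TestFrequencyRecursion:
    def test_neutral_fixed(self):
        assert next_allele_frequency(0.5, 0.3, 0.3) == pytest.approx(0.5)

    @pytest.mark.parametrize("f", [0.0, 1.0])
    def test_boundary_fixed_points(self, f):
        assert next_allele_frequency(f, 0.9, 0.2) == pytest.approx(f)

    def test_selection_example(self):
        assert next_allele_frequency(0.5, 0.6, 0.4) == pytest.approx(0.6)

    def test_zero_total_fitness_leaves_frequency(self):
        assert next_allele_frequency(0.5, 0.0, 0.0) == 0.5


class TestPopulationUpdate:
    def test_carrying_capacity_equilibrium(self):
        assert next_population_size(1e4, 1.0, r=0.8, K=1e4) == pytest.approx(1e4)

    def test_total_kill(self):
        assert next_population_size(1e4, 0.0, r=0.8, K=1e4) == 0.0

    def test_logistic_growth_below_capacity(self):
        K = 1e4
        assert next_population_size(K / 2, 1.0, r=0.5, K=K) == pytest.approx(0.625 * K)

    def test_never_negative(self):
        # overshoot far above K with large r still floors at zero
        assert next_population_size(1e5, 1.0, r=20.0, K=1e3) == 0.0


class TestMutationRule:
    def test_below_threshold_unchanged(self):
        locus = LocusState(f_R=0.5, steps_R=1, steps_S=0)
        out = apply_mutation_rule(locus, N=1e6, mu=1e-6)
        assert out == locus

    def test_clock_accumulates_then_fires(self):
        mu, N = 1e-6, 4e5
        locus = LocusState(f_R=0.995, steps_R=1, steps_S=0)
        # 1/mu = 1e6 individuals: fires on the third generation
        locus = apply_mutation_rule(locus, N, mu)
        assert locus.cum_individuals == pytest.approx(4e5)
        locus = apply_mutation_rule(locus, N, mu)
        assert locus.steps_R == 1
        locus = apply_mutation_rule(locus, N, mu)
        assert locus.steps_R == 2
        assert locus.steps_S == 1  # old resistant allele becomes susceptible
        assert locus.f_R == pytest.approx(1 / N)
        assert locus.cum_individuals == 0.0

    def test_new_allele_phenotype_steps_down(self):
        # one more step multiplies the phenotype by (1 - d_q)
        d_q = 0.4
        locus = LocusState(f_R=0.999, steps_R=2, steps_S=1, cum_individuals=1e9)
        out = apply_mutation_rule(locus, N=1e5, mu=1e-6)
        q_old = resistance_phenotype(locus.steps_R, d_q)
        q_new = resistance_phenotype(out.steps_R, d_q)
        assert q_new == pytest.approx(q_old * (1 - d_q))

    def test_dropping_below_threshold_resets_clock(self):
        locus = LocusState(f_R=0.5, steps_R=1, steps_S=0, cum_individuals=500.0)
        assert apply_mutation_rule(locus, 100.0, 1e-6).cum_individuals == 0.0


class TestAdvanceGeneration:
    def test_no_nets_no_selection(self, evo):
        state = make_state(f1=0.3, f2=0.7, N=evo.K / 2)
        env = Environment(V=0.0, P=0.8, M=np.full((2, 2), 0.9))
        out = advance_generation(state, env, evo)
        assert out.locus1.f_R == pytest.approx(0.3)
        assert out.locus2.f_R == pytest.approx(0.7)
        # population relaxes toward K
        assert evo.K / 2 < out.N <= evo.K

    def test_matches_textbook_single_locus_recursion(self, evo):
        # independently coded haploid selection + logistic growth oracle,
        # with locus 2 neutral (mortality independent of its allele)
        evo = replace(evo, mu=1e-12)  # mutation clock cannot fire here
        V, P = 0.6, 0.8
        m_R, m_S = 0.2, 0.9
        env = Environment(V=V, P=P, M=np.array([[m_R, m_R], [m_S, m_S]]))

        f, N = 0.01, evo.K
        w_R, w_S = 1 - V * P * m_R, 1 - V * P * m_S
        traj = []
        for _ in range(50):
            wbar = f * w_R + (1 - f) * w_S
            f = f * w_R / wbar
            N = max(0.0, N * wbar * (1 + evo.r * (1 - N * wbar / evo.K)))
            traj.append((f, N))

        state = make_state(f1=0.01, f2=0.4, N=evo.K)
        for f_exp, N_exp in traj:
            state = advance_generation(state, env, evo)
            assert state.locus1.f_R == pytest.approx(f_exp, abs=1e-10)
            assert state.N == pytest.approx(N_exp, rel=1e-10)
        # the neutral locus never moves
        assert state.locus2.f_R == pytest.approx(0.4)

    def test_determinism(self, evo):
        env = Environment(V=0.5, P=0.7, M=np.array([[0.1, 0.3], [0.5, 0.9]]))
        a = b = make_state(f1=0.2, f2=0.8, N=0.9 * evo.K)
        for _ in range(20):
            a = advance_generation(a, env, evo)
            b = advance_generation(b, env, evo)
        assert a == b

    @settings(derandomize=True, max_examples=50)
    @given(
        f1=st.floats(0.0, 1.0),
        f2=st.floats(0.0, 1.0),
        V=st.floats(0.0, 1.0),
        P=st.floats(0.0, 1.0),
        m=st.tuples(*[st.floats(0.0, 1.0)] * 4),
    )
    def test_frequencies_stay_in_unit_interval(self, f1, f2, V, P, m, evo):
        env = Environment(V=V, P=P, M=np.array(m).reshape(2, 2))
        state = make_state(f1=f1, f2=f2, N=evo.K)
        for _ in range(5):
            state = advance_generation(state, env, evo)
        assert 0.0 <= state.locus1.f_R <= 1.0
        assert 0.0 <= state.locus2.f_R <= 1.0
        assert state.N >= 0.0

    def test_selection_favours_resistant_allele(self, evo):
        # lower mortality for the resistant allele and V*P > 0 implies a
        # non-decreasing resistant-allele frequency
        evo = replace(evo, mu=1e-12)  # isolate selection from new mutations
        env = Environment(V=0.8, P=0.9, M=np.array([[0.2, 0.2], [0.8, 0.8]]))
        state = make_state(f1=0.05, f2=0.5, N=evo.K)
        prev = state.locus1.f_R
        for _ in range(30):
            state = advance_generation(state, env, evo)
            assert state.locus1.f_R >= prev - 1e-15
            prev = state.locus1.f_R
        assert prev > 0.05

    def test_neutrality_when_mortality_equal(self, evo):
        # equal kill across genotypes leaves frequencies invariant forever
        env = Environment(V=0.9, P=0.9, M=np.full((2, 2), 0.6))
        state = make_state(f1=0.123, f2=0.456, N=evo.K)
        for _ in range(40):
            state = advance_generation(state, env, evo)
        assert state.locus1.f_R == pytest.approx(0.123)
        assert state.locus2.f_R == pytest.approx(0.456)


class TestValidation:
    def test_locus_invariants(self):
        with pytest.raises(ValueError):
            LocusState(f_R=1.2, steps_R=1)
        with pytest.raises(ValueError):
            LocusState(f_R=0.5, steps_R=1, steps_S=1)

    def test_evolution_params(self):
        with pytest.raises(ValueError):
            EvolutionParams(r=0.0, K=1e6, mu=1e-6, d_q=0.5, f_init=1e-3)
        with pytest.raises(ValueError):
            EvolutionParams(r=1.0, K=1e6, mu=0.0, d_q=0.5, f_init=1e-3)

    def test_environment_table_shape(self):
        with pytest.raises(ValueError):
            Environment(V=0.5, P=0.5, M=np.zeros((3, 2)))
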