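"""Two-locus haploid resistance evolution with density-dependent dynamics.

One biallelic haploid locus per insecticide, under random mating and
linkage equilibrium.  Each generation:

1. Genotype fitness ``w = 1 - V * P * M`` — a mosquito dies only if it
   encounters a covered host (coverage ``V``), the net is in use and
   physically intact (barrier ``P``), and the insecticide kills it
   (effective mortality ``M`` for its genotype under the deployment
   strategy).
2. Genotype fitnesses are decomposed into allelic fitnesses by averaging
   over the other locus, and allele frequencies follow the standard haploid
   replicator recursion.
3. Population size follows discrete logistic growth with density
   dependence applied after insecticide mortality:
   ``N' = N * wbar * (1 + r * (1 - N * wbar / K))``.
4. A deterministic mutation clock introduces the next mutational step in
   resistance: once the resident resistant allele exceeds 0.99 frequency,
   post-selection population sizes are summed generation by generation;
   when the sum reaches ``1 / mu`` individuals, a new allele with one more
   step replaces it at frequency ``1/N`` and the old resistant allele
   becomes the new susceptible allele.

Each mutational step multiplies mortality by ``(1 - d_q)``, so a genotype
with ``s`` steps has resistance phenotype ``q = (1 - d_q) ** s``.

Population size is tracked as a continuous quantity to keep the model
deterministic and smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LocusState",
    "PopulationState",
    "EvolutionParams",
    "Environment",
    "resistance_phenotype",
    "genotype_fitness",
    "fitness_table",
    "allele_fitnesses",
    "next_allele_frequency",
    "mean_fitness",
    "next_population_size",
    "apply_mutation_rule",
    "advance_generation",
    "mean_phenotype",
]

#: frequency a resident resistant allele must exceed before the mutation
#: clock for the next step starts running
MUTATION_FREQ_THRESHOLD = 0.99


@dataclass(frozen=True)
class LocusState:
    """Allelic state at one resistance locus.

    ``f_R`` is the frequency of the more-resistant allele (``steps_R``
    mutational steps); the less-resistant allele carries ``steps_S``
    steps.  ``cum_individuals`` is the deterministic mutation clock.
    """

    f_R: float
    steps_R: int
    steps_S: int = 0
    cum_individuals: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_R <= 1.0:
            raise ValueError("allele frequency must lie in [0, 1]")
        if self.steps_S >= self.steps_R:
            raise ValueError("the resistant allele must carry more steps")
        if self.steps_S < 0:
            raise ValueError("mutational steps must be >= 0")
        if self.cum_individuals < 0:
            raise ValueError("mutation clock must be >= 0")


@dataclass(frozen=True)
class PopulationState:
    """Adult mosquitoes setting out to blood-feed, plus both loci."""

    N: float
    locus1: LocusState
    locus2: LocusState

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("population size must be >= 0")


@dataclass(frozen=True)
class EvolutionParams:
    """Ecological and genetic constants of the vector population.

    r : intrinsic growth rate per generation (> 0)
    K : carrying capacity (> 0)
    mu : nominal mutation rate; 1/mu individuals must occur before the
        next resistance step arrives
    d_q : proportional mortality reduction per mutational step, in (0, 1)
    f_init : starting frequency of the rare resistant allele
    """

    r: float
    K: float
    mu: float
    d_q: float
    f_init: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("growth rate r must be > 0")
        if self.K <= 0:
            raise ValueError("carrying capacity K must be > 0")
        if not 0.0 < self.mu < 1.0:
            raise ValueError("mutation rate mu must lie in (0, 1)")
        if not 0.0 < self.d_q < 1.0:
            raise ValueError("per-step mortality decay d_q must lie in (0, 1)")
        if not 0.0 < self.f_init < 1.0:
            raise ValueError("initial resistant frequency must lie in (0, 1)")


@dataclass(frozen=True)
class Environment:
    """One generation's deployment environment.

    ``M`` is the 2x2 table of strategy-effective mortalities indexed by
    (allele at locus 1, allele at locus 2) with index 0 = the
    more-resistant allele, 1 = the less-resistant allele.
    """

    V: float
    P: float
    M: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.V <= 1.0:
            raise ValueError("coverage V must lie in [0, 1]")
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("barrier P must lie in [0, 1]")
        M = np.asarray(self.M, dtype=float)
        if M.shape != (2, 2):
            raise ValueError("mortality table must be 2x2")
        if np.any((M < 0) | (M > 1)):
            raise ValueError("mortalities must lie in [0, 1]")
        object.__setattr__(self, "M", M)


def resistance_phenotype(steps, d_q):
    """Phenotype ``(1 - d_q) ** steps``; 1 for the susceptible reference."""
    steps = np.asarray(steps)
    if np.any(steps < 0):
        raise ValueError("mutational steps must be >= 0")
    if not 0.0 < d_q < 1.0:
        raise ValueError("d_q must lie in (0, 1)")
    out = (1.0 - d_q) ** steps
    return out if out.ndim else float(out)


def mean_phenotype(locus: LocusState, d_q: float) -> float:
    """Frequency-weighted mean resistance phenotype at one locus."""
    q_r = resistance_phenotype(locus.steps_R, d_q)
    q_s = resistance_phenotype(locus.steps_S, d_q)
    return locus.f_R * q_r + (1.0 - locus.f_R) * q_s


def genotype_fitness(V, P, M_effective):
    """Survival probability ``1 - V * P * M`` of one genotype.

    ``M_effective`` is already combined across insecticides for the
    deployment strategy (mixture product rule, mosaic average, or the
    rotation cycle-active AI) with the genotype's phenotypes.
    """
    V = np.asarray(V, dtype=float)
    P = np.asarray(P, dtype=float)
    M = np.asarray(M_effective, dtype=float)
    for name, val in (("V", V), ("P", P), ("M", M)):
        if np.any((val < 0) | (val > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")
    out = 1.0 - V * P * M
    return out if out.ndim else float(out)


def fitness_table(env: Environment) -> np.ndarray:
    """2x2 genotype fitnesses ``1 - V * P * M`` from an environment."""
    return 1.0 - env.V * env.P * env.M


def allele_fitnesses(f_other_R: float, w: np.ndarray) -> tuple[float, float]:
    """Marginal fitnesses of the two alleles at one locus.

    ``w`` is the 2x2 genotype fitness table with this locus on the first
    axis and the other locus on the second (index 0 = resistant allele);
    ``f_other_R`` is the resistant-allele frequency at the other locus.
    Under linkage equilibrium the allelic fitness is the genotype-frequency
    weighted average over the other locus.
    """
    w = np.asarray(w, dtype=float)
    w_R = f_other_R * w[0, 0] + (1.0 - f_other_R) * w[0, 1]
    w_S = f_other_R * w[1, 0] + (1.0 - f_other_R) * w[1, 1]
    return float(w_R), float(w_S)


def next_allele_frequency(f_R: float, w_R: float, w_S: float) -> float:
    """Haploid replicator update ``f w_R / (f w_R + (1 - f) w_S)``.

    With total fitness zero and an interior frequency the population is
    headed for extinction; the frequency is left unchanged (the paired
    population update drives N to zero).
    """
    if not 0.0 <= f_R <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    if w_R < 0 or w_S < 0:
        raise ValueError("fitnesses must be >= 0")
    denom = f_R * w_R + (1.0 - f_R) * w_S
    if denom == 0.0:
        return f_R
    return f_R * w_R / denom


def mean_fitness(f1_R: float, f2_R: float, w: np.ndarray) -> float:
    """Population mean fitness over the four genotypes at linkage equilibrium."""
    w = np.asarray(w, dtype=float)
    p1 = np.array([f1_R, 1.0 - f1_R])
    p2 = np.array([f2_R, 1.0 - f2_R])
    return float(p1 @ w @ p2)


def next_population_size(N: float, wbar: float, r: float, K: float) -> float:
    """Discrete logistic update with density dependence after mortality."""
    if N < 0:
        raise ValueError("population size must be >= 0")
    if not 0.0 <= wbar <= 1.0:
        raise ValueError("mean fitness must lie in [0, 1]")
    survivors = N * wbar
    out = survivors * (1.0 + r * (1.0 - survivors / K))
    return max(0.0, out)


def apply_mutation_rule(locus: LocusState, N: float, mu: float) -> LocusState:
    """Advance the deterministic mutation clock and, if due, introduce the
    next resistance step.

    Below the frequency threshold the clock stays at zero.  Above it, this
    generation's ``N`` is added; once the accumulated number of individuals
    reaches ``1 / mu``, a new allele with one more mutational step enters
    at frequency ``1/N``, the old resistant allele becomes the new
    susceptible allele at ``(N - 1)/N``, and the clock resets.  No
    introduction happens in a population of one individual or fewer.
    """
    if locus.f_R <= MUTATION_FREQ_THRESHOLD:
        if locus.cum_individuals != 0.0:
            return replace(locus, cum_individuals=0.0)
        return locus
    cum = locus.cum_individuals + N
    if cum >= 1.0 / mu and N > 1.0:
        return LocusState(
            f_R=1.0 / N,
            steps_R=locus.steps_R + 1,
            steps_S=locus.steps_R,
            cum_individuals=0.0,
        )
    return replace(locus, cum_individuals=cum)


def advance_generation(
    state: PopulationState, env: Environment, params: EvolutionParams
) -> PopulationState:
    """One deterministic generation: selection, growth, then mutation.

    The mean fitness entering the population update is computed from the
    pre-update allele frequencies; the mutation clock runs on the
    post-update population size.
    """
    w = fitness_table(env)
    f1 = state.locus1.f_R
    f2 = state.locus2.f_R

    w1_R, w1_S = allele_fitnesses(f2, w)
    w2_R, w2_S = allele_fitnesses(f1, w.T)
    wbar = mean_fitness(f1, f2, w)

    f1_new = next_allele_frequency(f1, w1_R, w1_S)
    f2_new = next_allele_frequency(f2, w2_R, w2_S)
    N_new = next_population_size(state.N, wbar, params.r, params.K)

    locus1 = replace(state.locus1, f_R=f1_new)
    locus2 = replace(state.locus2, f_R=f2_new)
    if N_new > 0:
        locus1 = apply_mutation_rule(locus1, N_new, params.mu)
        locus2 = apply_mutation_rule(locus2, N_new, params.mu)
    return PopulationState(N=N_new, locus1=locus1, locus2=locus2)
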