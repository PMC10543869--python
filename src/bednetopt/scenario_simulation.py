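"""Deployment-scenario simulation and the factorial design grid.

A scenario runs the resistance/population model for a fixed horizon
(default 12 years) at a fixed number of generations per year (default 12,
roughly monthly mosquito generations).  Nets are redeployed every
``lifespan`` years: net age resets to zero, and under a rotation the
active insecticide alternates by deployment cycle (AI 1 in even cycles).
Coverage is constant within a run (it depends only on price, budget and
lifespan); the barrier and mortalities are evaluated at each generation's
start age (left endpoint).

``run_scenario`` advances a single design generation by generation through
:func:`bednetopt.resistance_dynamics.advance_generation` and records a
full trace.  ``run_grid`` sweeps the complete factorial of loading
concentrations and lifespans for each usage variant with a vectorised
engine that advances every design simultaneously; the two paths implement
the same recursion and are cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .net_properties import (
    Economics,
    InsecticideProfile,
    NetDesign,
    NetPhysicalProfile,
    bioassay_mortality,
    coverage,
    net_price,
    physical_barrier_at,
)
from .resistance_dynamics import (
    MUTATION_FREQ_THRESHOLD,
    Environment,
    EvolutionParams,
    LocusState,
    PopulationState,
    advance_generation,
    mean_phenotype,
    resistance_phenotype,
)

__all__ = [
    "ScenarioConfig",
    "SimulationTrace",
    "GridSpec",
    "GridResult",
    "deployment_age",
    "run_scenario",
    "trace_summaries",
    "run_grid",
    "initial_state",
]

#: net age (years) at which the WHO cone-test bioefficacy is evaluated
PQ_AGE = 3.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything except the design variables needed to run a scenario."""

    ins1: InsecticideProfile
    ins2: InsecticideProfile
    phys: NetPhysicalProfile
    econ: Economics
    evo: EvolutionParams
    duration: float = 12.0
    generations_per_year: int = 12
    strategy: str = "mixture"
    bioassay_reference: str = "initial_population"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.generations_per_year < 1:
            raise ValueError("generations_per_year must be >= 1")
        if self.bioassay_reference not in ("initial_population", "susceptible"):
            raise ValueError(
                "bioassay_reference must be 'initial_population' or 'susceptible'"
            )

    @property
    def n_generations(self) -> int:
        return int(round(self.duration * self.generations_per_year))


@dataclass
class SimulationTrace:
    """Per-generation series plus the summary metrics used by the optimizer.

    ``frame`` holds one row per generation (post-update state); control is
    ``1 - N/K``.  Bioefficacy is the forced-exposure cone-test mortality of
    the net at its current age against the current population-mean
    phenotypes.  ``relative_change`` is end/start bioefficacy at the
    3-year test age and reflects resistance evolution; it is ``None`` when
    the starting bioefficacy is zero.
    """

    design: NetDesign
    frame: pd.DataFrame
    avg_control: float
    start_bioefficacy: float
    end_bioefficacy: float
    relative_change: float | None
    coverage: float
    price: float


@dataclass(frozen=True)
class GridSpec:
    """Factorial search ranges: loadings from 0 to ``loading_max`` in steps
    of ``loading_interval`` (shared by both AIs); lifespans from
    ``lifespan_interval`` to ``lifespan_max`` (zero would mean no
    deployment)."""

    loading_max: float
    loading_interval: float
    lifespan_max: float
    lifespan_interval: float

    def __post_init__(self) -> None:
        if self.loading_interval <= 0 or self.lifespan_interval <= 0:
            raise ValueError("grid intervals must be > 0")
        if self.loading_max < self.loading_interval:
            raise ValueError("loading_max must be >= loading_interval")
        if self.lifespan_max < self.lifespan_interval:
            raise ValueError("lifespan_max must be >= lifespan_interval")

    def loading_values(self) -> np.ndarray:
        n = int(round(self.loading_max / self.loading_interval))
        return np.round(np.arange(n + 1) * self.loading_interval, 10)

    def lifespan_values(self) -> np.ndarray:
        n = int(round(self.lifespan_max / self.lifespan_interval))
        return np.round(np.arange(1, n + 1) * self.lifespan_interval, 10)


@dataclass
class GridResult:
    """Long-format table of summary metrics for every design x usage."""

    table: pd.DataFrame
    spec: GridSpec
    strategy: str


def deployment_age(t_abs: float, lifespan: float) -> tuple[float, int]:
    """Net age within the current deployment cycle, and the cycle index."""
    if t_abs < 0:
        raise ValueError("absolute time must be >= 0")
    if lifespan <= 0:
        raise ValueError("lifespan must be > 0")
    cycle = math.floor(t_abs / lifespan + 1e-12)
    age = t_abs - cycle * lifespan
    if age < 0:
        age = 0.0
    return age, cycle


def initial_state(cfg: ScenarioConfig) -> PopulationState:
    """Population at carrying capacity with one rare resistant allele per locus.

    The rare allele carries the profile's ``initial_steps`` (at least 1)
    and the resident allele one step fewer — for pyrethroids this puts the
    widespread background resistance in the resident allele.
    """

    def locus(ins: InsecticideProfile) -> LocusState:
        steps_r = max(1, ins.initial_steps)
        return LocusState(f_R=cfg.evo.f_init, steps_R=steps_r, steps_S=steps_r - 1)

    return PopulationState(N=cfg.evo.K, locus1=locus(cfg.ins1), locus2=locus(cfg.ins2))


def _allele_mortalities(
    age: float, design: NetDesign, cfg: ScenarioConfig, state: PopulationState
) -> tuple[np.ndarray, np.ndarray]:
    """Per-allele single-AI mortalities (index 0 = resistant allele)."""
    d_q = cfg.evo.d_q
    out = []
    for ins, c, locus in (
        (cfg.ins1, design.c1, state.locus1),
        (cfg.ins2, design.c2, state.locus2),
    ):
        q = resistance_phenotype(np.array([locus.steps_R, locus.steps_S]), d_q)
        if c > 0:
            x = -math.log(c) / ins.d_c
            m = q * expit(ins.d_m * (age + x) + ins.h_m)
        else:
            m = np.zeros(2)
        out.append(m)
    return out[0], out[1]


def _effective_mortality(
    m1: np.ndarray, m2: np.ndarray, strategy: str, cycle: int
) -> np.ndarray:
    """2x2 strategy-effective mortality table from per-allele mortalities."""
    M1 = m1[:, None] * np.ones((1, 2))
    M2 = np.ones((2, 1)) * m2[None, :]
    if strategy == "mixture":
        return 1.0 - (1.0 - M1) * (1.0 - M2)
    if strategy == "mosaic":
        return 0.5 * (M1 + M2)
    return M1 if cycle % 2 == 0 else M2


def _reference_phenotypes(
    state: PopulationState, cfg: ScenarioConfig
) -> tuple[float, float]:
    if cfg.bioassay_reference == "susceptible":
        return 1.0, 1.0
    d_q = cfg.evo.d_q
    return mean_phenotype(state.locus1, d_q), mean_phenotype(state.locus2, d_q)


def run_scenario(design: NetDesign, cfg: ScenarioConfig) -> SimulationTrace:
    """Simulate one design over the full horizon and summarise it."""
    if design.strategy != cfg.strategy:
        raise ValueError(
            f"design strategy {design.strategy!r} != scenario strategy {cfg.strategy!r}"
        )
    price = net_price(design, cfg.ins1, cfg.ins2, cfg.phys)
    V = coverage(design, cfg.econ, price)
    state = initial_state(cfg)
    start = state
    gpy = cfg.generations_per_year
    n_gen = cfg.n_generations

    rows = []
    for g in range(n_gen):
        t_abs = g / gpy
        age, cycle = deployment_age(t_abs, design.lifespan)
        P = physical_barrier_at(age, cfg.phys)
        m1, m2 = _allele_mortalities(age, design, cfg, state)
        M = _effective_mortality(m1, m2, design.strategy, cycle)
        env = Environment(V=V, P=P, M=M)
        state = advance_generation(state, env, cfg.evo)
        q1, q2 = _reference_phenotypes(state, cfg)
        rows.append(
            {
                "generation": g + 1,
                "time": (g + 1) / gpy,
                "net_age": age,
                "cycle": cycle,
                "N": state.N,
                "control": 1.0 - state.N / cfg.evo.K,
                "f_R1": state.locus1.f_R,
                "f_R2": state.locus2.f_R,
                "steps_R1": state.locus1.steps_R,
                "steps_R2": state.locus2.steps_R,
                "bioefficacy": bioassay_mortality(
                    design, age, q1, q2, cfg.ins1, cfg.ins2, cycle
                ),
            }
        )
    frame = pd.DataFrame(rows)

    q1_0, q2_0 = _reference_phenotypes(start, cfg)
    q1_T, q2_T = _reference_phenotypes(state, cfg)
    start_bio = bioassay_mortality(design, PQ_AGE, q1_0, q2_0, cfg.ins1, cfg.ins2, 0)
    end_bio = bioassay_mortality(design, PQ_AGE, q1_T, q2_T, cfg.ins1, cfg.ins2, 0)
    rel = end_bio / start_bio if start_bio > 0 else None
    return SimulationTrace(
        design=design,
        frame=frame,
        avg_control=float(frame["control"].mean()),
        start_bioefficacy=float(start_bio),
        end_bioefficacy=float(end_bio),
        relative_change=None if rel is None else float(rel),
        coverage=V,
        price=price,
    )


def trace_summaries(
    trace: SimulationTrace,
) -> tuple[float, float, float, float | None, float]:
    """(avg control, start bioefficacy, end bioefficacy, relative change, coverage)."""
    return (
        trace.avg_control,
        trace.start_bioefficacy,
        trace.end_bioefficacy,
        trace.relative_change,
        trace.coverage,
    )


# ---------------------------------------------------------------------------
# vectorised factorial sweep


class _BatchState:
    """State arrays for simultaneously advanced designs (one row each)."""

    def __init__(self, n: int, cfg: ScenarioConfig):
        init = initial_state(cfg)
        self.N = np.full(n, cfg.evo.K)
        self.f1 = np.full(n, cfg.evo.f_init)
        self.f2 = np.full(n, cfg.evo.f_init)
        self.sR1 = np.full(n, init.locus1.steps_R, dtype=np.int64)
        self.sS1 = np.full(n, init.locus1.steps_S, dtype=np.int64)
        self.sR2 = np.full(n, init.locus2.steps_R, dtype=np.int64)
        self.sS2 = np.full(n, init.locus2.steps_S, dtype=np.int64)
        self.cum1 = np.zeros(n)
        self.cum2 = np.zeros(n)


def _batch_allele_mortality(age, c, sR, sS, ins, d_q):
    """(m_R, m_S) arrays for one AI; age, c and steps are per-row arrays."""
    pos = c > 0
    safe_c = np.where(pos, c, 1.0)
    x = -np.log(safe_c) / ins.d_c
    logistic = expit(ins.d_m * (age + x) + ins.h_m)
    m_R = np.where(pos, (1.0 - d_q) ** sR * logistic, 0.0)
    m_S = np.where(pos, (1.0 - d_q) ** sS * logistic, 0.0)
    return m_R, m_S


def _batch_mutation(f, sR, sS, cum, N, mu):
    """Vectorised deterministic mutation clock (in place on copies)."""
    below = f <= MUTATION_FREQ_THRESHOLD
    cum = np.where(below, 0.0, cum + N)
    fire = (~below) & (cum >= 1.0 / mu) & (N > 1.0)
    sS = np.where(fire, sR, sS)
    sR = np.where(fire, sR + 1, sR)
    f = np.where(fire, 1.0 / N, f)
    cum = np.where(fire, 0.0, cum)
    return f, sR, sS, cum


def _simulate_batch(
    c1: np.ndarray,
    c2: np.ndarray,
    lifespan: np.ndarray,
    V: np.ndarray,
    cfg: ScenarioConfig,
    strategy: str,
) -> dict[str, np.ndarray]:
    """Advance every design simultaneously; return summary state arrays."""
    n = len(c1)
    st = _BatchState(n, cfg)
    evo = cfg.evo
    gpy = cfg.generations_per_year
    sum_control = np.zeros(n)
    n_gen = cfg.n_generations

    for g in range(n_gen):
        t_abs = g / gpy
        cycle = np.floor(t_abs / lifespan + 1e-12)
        age = np.maximum(t_abs - cycle * lifespan, 0.0)
        P = cfg.phys.u * expit(cfg.phys.d_p * age + cfg.phys.h_p)

        m1R, m1S = _batch_allele_mortality(age, c1, st.sR1, st.sS1, cfg.ins1, evo.d_q)
        m2R, m2S = _batch_allele_mortality(age, c2, st.sR2, st.sS2, cfg.ins2, evo.d_q)

        if strategy == "mixture":
            def comb(a, b):
                return 1.0 - (1.0 - a) * (1.0 - b)
        elif strategy == "mosaic":
            def comb(a, b):
                return 0.5 * (a + b)
        else:  # rotation: AI 1 active in even cycles, per-row cycle parity
            even = cycle % 2 == 0

            def comb(a, b):
                return np.where(even, a, b)

        # genotype fitnesses, index order (locus1 allele, locus2 allele)
        w_Rr = 1.0 - V * P * comb(m1R, m2R)
        w_Rs = 1.0 - V * P * comb(m1R, m2S)
        w_Sr = 1.0 - V * P * comb(m1S, m2R)
        w_Ss = 1.0 - V * P * comb(m1S, m2S)

        f1, f2 = st.f1, st.f2
        w1R = f2 * w_Rr + (1.0 - f2) * w_Rs
        w1S = f2 * w_Sr + (1.0 - f2) * w_Ss
        w2R = f1 * w_Rr + (1.0 - f1) * w_Sr
        w2S = f1 * w_Rs + (1.0 - f1) * w_Ss
        wbar = f1 * w1R + (1.0 - f1) * w1S

        d1 = f1 * w1R + (1.0 - f1) * w1S
        d2 = f2 * w2R + (1.0 - f2) * w2S
        f1n = np.where(d1 > 0, f1 * w1R / np.where(d1 > 0, d1, 1.0), f1)
        f2n = np.where(d2 > 0, f2 * w2R / np.where(d2 > 0, d2, 1.0), f2)

        survivors = st.N * wbar
        Nn = np.maximum(survivors * (1.0 + evo.r * (1.0 - survivors / evo.K)), 0.0)

        st.f1, st.f2, st.N = f1n, f2n, Nn
        alive = Nn > 0
        f1m, sR1, sS1, cum1 = _batch_mutation(
            st.f1, st.sR1, st.sS1, st.cum1, st.N, evo.mu
        )
        f2m, sR2, sS2, cum2 = _batch_mutation(
            st.f2, st.sR2, st.sS2, st.cum2, st.N, evo.mu
        )
        st.f1 = np.where(alive, f1m, st.f1)
        st.sR1 = np.where(alive, sR1, st.sR1)
        st.sS1 = np.where(alive, sS1, st.sS1)
        st.cum1 = np.where(alive, cum1, st.cum1)
        st.f2 = np.where(alive, f2m, st.f2)
        st.sR2 = np.where(alive, sR2, st.sR2)
        st.sS2 = np.where(alive, sS2, st.sS2)
        st.cum2 = np.where(alive, cum2, st.cum2)

        sum_control += 1.0 - st.N / evo.K

    d_q = evo.d_q
    return {
        "avg_control": sum_control / n_gen,
        "N_end": st.N,
        "f1_end": st.f1,
        "f2_end": st.f2,
        "sR1_end": st.sR1,
        "sS1_end": st.sS1,
        "sR2_end": st.sR2,
        "sS2_end": st.sS2,
        "qbar1_end": st.f1 * (1 - d_q) ** st.sR1 + (1 - st.f1) * (1 - d_q) ** st.sS1,
        "qbar2_end": st.f2 * (1 - d_q) ** st.sR2 + (1 - st.f2) * (1 - d_q) ** st.sS2,
        "mean_steps1_end": st.f1 * st.sR1 + (1 - st.f1) * st.sS1,
        "mean_steps2_end": st.f2 * st.sR2 + (1 - st.f2) * st.sS2,
    }


def _batch_bioassay(age, c1, c2, q1, q2, cfg, strategy, usage, cycle=0):
    """Vectorised whole-net cone-test mortality (same rules as
    :func:`bednetopt.net_properties.bioassay_mortality`)."""

    def single(c, q, ins):
        pos = c > 0
        safe_c = np.where(pos, c, 1.0)
        x = -np.log(safe_c) / ins.d_c
        return np.where(pos, q * expit(ins.d_m * (age + x) + ins.h_m), 0.0)

    m1 = single(c1, q1, cfg.ins1)
    m2 = single(c2, q2, cfg.ins2)
    if usage == "solo_1":
        return m1
    if usage == "solo_2":
        return m2
    if strategy == "mixture":
        return 1.0 - (1.0 - m1) * (1.0 - m2)
    if strategy == "mosaic":
        return 0.5 * (m1 + m2)
    return m1 if cycle % 2 == 0 else m2


def _usage_designs(grid: GridSpec, usage: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design arrays for one usage variant.  Joint usage sweeps the full
    (c1, c2, lifespan) factorial; solo usage sweeps the used AI's loading
    with the partner fixed at zero."""
    cs = grid.loading_values()
    ls = grid.lifespan_values()
    if usage == "joint":
        c1, c2, lf = np.meshgrid(cs, cs, ls, indexing="ij")
    elif usage == "solo_1":
        c1, lf = np.meshgrid(cs, ls, indexing="ij")
        c2 = np.zeros_like(c1)
    else:
        c2, lf = np.meshgrid(cs, ls, indexing="ij")
        c1 = np.zeros_like(c2)
    return c1.ravel(), c2.ravel(), lf.ravel()


def run_grid(
    cfg: ScenarioConfig,
    grid: GridSpec,
    usages: tuple[str, ...] = ("joint", "solo_1", "solo_2"),
) -> GridResult:
    """Sweep the complete factorial design grid for each usage variant.

    Returns one row per design x usage with price, coverage, average
    control, cone-test bioefficacies at the 3-year test age (start and end
    of the simulation) and the population-mean resistance steps reached.
    """
    if not usages:
        raise ValueError("at least one usage variant is required")
    init = initial_state(cfg)
    q1_0, q2_0 = _reference_phenotypes(init, cfg)

    frames = []
    for usage in usages:
        c1, c2, lf = _usage_designs(grid, usage)
        if cfg.strategy == "mixture":
            price = cfg.phys.a + c1 * cfg.ins1.k + c2 * cfg.ins2.k
        else:
            price = cfg.phys.a + 0.5 * (c1 * cfg.ins1.k + c2 * cfg.ins2.k)
        V = np.minimum(
            1.0, lf * cfg.econ.budget / (cfg.econ.reference_lifespan * price)
        )
        res = _simulate_batch(c1, c2, lf, V, cfg, cfg.strategy)

        start_bio = _batch_bioassay(
            PQ_AGE, c1, c2, q1_0, q2_0, cfg, cfg.strategy, usage
        )
        if cfg.bioassay_reference == "susceptible":
            q1_T = np.ones_like(c1)
            q2_T = np.ones_like(c1)
        else:
            q1_T, q2_T = res["qbar1_end"], res["qbar2_end"]
        end_bio = _batch_bioassay(PQ_AGE, c1, c2, q1_T, q2_T, cfg, cfg.strategy, usage)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(start_bio > 0, end_bio / np.where(start_bio > 0, start_bio, 1.0), np.nan)

        frames.append(
            pd.DataFrame(
                {
                    "usage": usage,
                    "c1": c1,
                    "c2": c2,
                    "lifespan": lf,
                    "price": price,
                    "coverage": V,
                    "avg_control": res["avg_control"],
                    "start_bioefficacy": start_bio,
                    "end_bioefficacy": end_bio,
                    "relative_change": rel,
                    "mean_steps1_end": res["mean_steps1_end"],
                    "mean_steps2_end": res["mean_steps2_end"],
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return GridResult(table=table, spec=grid, strategy=cfg.strategy)
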