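"""Closed-form properties of long-lasting insecticidal nets (LLINs).

An LLIN is characterised by four idealised curves in net age ``t`` (years
since deployment):

* chemical decay of each active ingredient — negative exponential,
  ``L(t) = c * exp(-d_c * t)`` with loading concentration ``c`` in relative
  units (1 = the insecticide's standard solo dose);
* mortality decay — negative logistic in time.  Changing the loading shifts
  the logistic midpoint by ``x = -ln(c) / d_c`` so that equal residual
  concentrations always produce equal mortality;
* physical decay of the netting — negative logistic scaled by the
  proportional use rate ``u``;
* a linear pricing model from which bed-net coverage of the human
  population follows, normalised so that a budget equal to the net price at
  the standard 3-year lifespan buys universal (100%) coverage.

Sign convention: the logistic slopes ``d_m`` and ``d_p`` are stored signed;
decay over time requires them to be negative.  The time of half-maximal
effect is ``-h / d`` (the ``h`` constants are logistic intercepts, not
half-lives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "STRATEGIES",
    "USAGES",
    "InsecticideProfile",
    "NetPhysicalProfile",
    "NetDesign",
    "Economics",
    "concentration_at",
    "loading_shift",
    "mortality_at",
    "combined_mortality",
    "physical_barrier_at",
    "net_price",
    "coverage",
    "bioassay_mortality",
    "property_table",
]

STRATEGIES = ("mixture", "mosaic", "rotation")
USAGES = ("joint", "solo_1", "solo_2")


@dataclass(frozen=True)
class InsecticideProfile:
    """Decay, potency, price and starting-resistance constants for one AI.

    Parameters
    ----------
    name
        Label used in configs and reports.
    d_c
        Chemical decay rate, per year; must be positive.
    d_m
        Mortality-logistic slope, per year.  Negative for decaying
        mortality (a warning is emitted otherwise; exploration of
        non-decaying curves is permitted).
    h_m
        Mortality-logistic intercept (dimensionless).
    k
        Price per relative unit of loading concentration, in budget
        currency units.
    initial_steps
        Mutational steps of the rare, more-resistant allele present at the
        start of a simulation (1 for a fresh mode of action; pyrethroids
        default to 3, with the background population already carrying the
        first two steps).
    """

    name: str
    d_c: float
    d_m: float
    h_m: float
    k: float
    initial_steps: int = 1

    def __post_init__(self) -> None:
        if self.d_c <= 0:
            raise ValueError(f"{self.name}: chemical decay rate d_c must be > 0")
        if self.k < 0:
            raise ValueError(f"{self.name}: price per unit k must be >= 0")
        if self.initial_steps < 0:
            raise ValueError(f"{self.name}: initial_steps must be >= 0")
        if self.d_m >= 0:
            warnings.warn(
                f"{self.name}: mortality slope d_m = {self.d_m} is not negative; "
                "mortality will not decay over time",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NetPhysicalProfile:
    """Fabric use, physical-decay and base-price constants shared by all nets."""

    u: float
    d_p: float
    h_p: float
    a: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.u <= 1.0:
            raise ValueError("use rate u must lie in [0, 1]")
        if self.a < 0:
            raise ValueError("base fabric price a must be >= 0")
        if self.d_p >= 0:
            warnings.warn(
                f"physical slope d_p = {self.d_p} is not negative; "
                "the barrier will not decay over time",
                stacklevel=2,
            )


@dataclass(frozen=True)
class NetDesign:
    """The optimisation variables: two loadings, a lifespan, a strategy.

    ``usage`` distinguishes the joint deployment of both insecticides from
    the solo deployment of either one; solo usage forces the partner's
    loading to zero.
    """

    c1: float
    c2: float
    lifespan: float
    strategy: str = "mixture"
    usage: str = "joint"

    def __post_init__(self) -> None:
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("loading concentrations must be >= 0")
        if self.lifespan <= 0:
            raise ValueError("deployment lifespan must be > 0")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.usage not in USAGES:
            raise ValueError(f"unknown usage {self.usage!r}")
        # solo deployment of one AI means the other is simply absent
        if self.usage == "solo_1" and self.c2 != 0.0:
            object.__setattr__(self, "c2", 0.0)
        if self.usage == "solo_2" and self.c1 != 0.0:
            object.__setattr__(self, "c1", 0.0)


@dataclass(frozen=True)
class Economics:
    """Public-health budget per person per standard 3-year purchase cycle."""

    budget: float
    reference_lifespan: float = 3.0

    def __post_init__(self) -> None:
        if self.budget < 0:
            raise ValueError("budget must be >= 0")
        if self.reference_lifespan <= 0:
            raise ValueError("reference lifespan must be > 0")


def concentration_at(c, d_c, t):
    """Residual concentration ``c * exp(-d_c * t)`` at net age ``t`` years."""
    c = np.asarray(c, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(c < 0):
        raise ValueError("loading concentration must be >= 0")
    if d_c <= 0:
        raise ValueError("chemical decay rate must be > 0")
    if np.any(t < 0):
        raise ValueError("net age must be >= 0")
    out = c * np.exp(-d_c * t)
    return out if out.ndim else float(out)


def loading_shift(c, d_c):
    """Midpoint shift ``x = -ln(c) / d_c`` induced by a non-standard loading.

    Undefined at ``c = 0``; callers treat an unloaded panel as killing
    nothing rather than evaluating the shift.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise ValueError("loading shift requires c > 0")
    out = -np.log(c) / d_c
    return out if out.ndim else float(out)


def mortality_at(t, c, q, ins: InsecticideProfile):
    """Mortality of one AI at net age ``t`` against phenotype ``q``.

    Returns ``q * sigmoid(d_m * (t + x) + h_m)`` with the loading shift
    ``x = -ln(c)/d_c``; an unloaded panel (``c = 0``) kills nothing.  ``q``
    is the resistance phenotype in [0, 1] (1 = fully susceptible).
    """
    t = np.asarray(t, dtype=float)
    c_arr = np.asarray(c, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(t < 0):
        raise ValueError("net age must be >= 0")
    if np.any(c_arr < 0):
        raise ValueError("loading concentration must be >= 0")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("resistance phenotype must lie in [0, 1]")
    pos = c_arr > 0
    # evaluate the shift only where the AI is present
    safe_c = np.where(pos, c_arr, 1.0)
    x = -np.log(safe_c) / ins.d_c
    m = q * expit(ins.d_m * (t + x) + ins.h_m)
    out = np.where(pos, m, 0.0)
    return out if out.ndim else float(out)


def combined_mortality(m1, m2):
    """Mortality of a two-AI mixture: ``1 - (1 - m1)(1 - m2)``."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if np.any((m1 < 0) | (m1 > 1)) or np.any((m2 < 0) | (m2 > 1)):
        raise ValueError("mortalities must lie in [0, 1]")
    out = 1.0 - (1.0 - m1) * (1.0 - m2)
    return out if out.ndim else float(out)


def physical_barrier_at(t, phys: NetPhysicalProfile):
    """Probability that a net of age ``t`` is in use and physically intact."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("net age must be >= 0")
    out = phys.u * expit(phys.d_p * t + phys.h_p)
    return out if out.ndim else float(out)


def net_price(
    design: NetDesign,
    ins1: InsecticideProfile,
    ins2: InsecticideProfile,
    phys: NetPhysicalProfile,
) -> float:
    """Price of one net under the linear pricing model.

    Mixtures carry both AIs on every net; mosaics and rotations split the
    two single-AI net types half-and-half across purchases, so the AI cost
    is averaged.
    """
    ai_cost = design.c1 * ins1.k + design.c2 * ins2.k
    if design.strategy == "mixture":
        return phys.a + ai_cost
    return phys.a + 0.5 * ai_cost


def coverage(design: NetDesign, econ: Economics, price: float) -> float:
    """Proportion of the at-risk population covered, capped at 1.

    ``lifespan * budget / (3 * price)``: a budget equal to the net price at
    the standard 3-year lifespan buys exactly universal coverage.
    """
    if price <= 0:
        raise ValueError("net price must be > 0")
    v = design.lifespan * econ.budget / (econ.reference_lifespan * price)
    return min(1.0, v)


def bioassay_mortality(
    design: NetDesign,
    t,
    q1,
    q2,
    ins1: InsecticideProfile,
    ins2: InsecticideProfile,
    cycle: int = 0,
):
    """Whole-net mortality in a forced-exposure cone bioassay at net age ``t``.

    The cone test presses mosquitoes against intact netting, so neither the
    physical barrier nor coverage enters.  Solo usage tests the single
    treated net type; a mixture combines both AIs on the panel; a mosaic
    averages the two single-AI net types; a rotation tests the
    cycle-active net type (AI 1 in even cycles).
    """
    m1 = mortality_at(t, design.c1, q1, ins1)
    m2 = mortality_at(t, design.c2, q2, ins2)
    if design.usage == "solo_1":
        return m1
    if design.usage == "solo_2":
        return m2
    if design.strategy == "mixture":
        return combined_mortality(m1, m2)
    if design.strategy == "mosaic":
        return 0.5 * (np.asarray(m1) + np.asarray(m2)) if np.ndim(m1) else 0.5 * (m1 + m2)
    # rotation
    return m1 if cycle % 2 == 0 else m2


def property_table(
    design: NetDesign,
    ins1: InsecticideProfile,
    ins2: InsecticideProfile,
    phys: NetPhysicalProfile,
    times,
    q1: float = 1.0,
    q2: float = 1.0,
) -> pd.DataFrame:
    """Tidy table of the property curves over ``times`` (years of net age)."""
    times = np.asarray(times, dtype=float)
    return pd.DataFrame(
        {
            "time": times,
            "concentration_1": concentration_at(design.c1, ins1.d_c, times),
            "concentration_2": concentration_at(design.c2, ins2.d_c, times),
            "mortality_1": mortality_at(times, design.c1, q1, ins1),
            "mortality_2": mortality_at(times, design.c2, q2, ins2),
            "barrier": physical_barrier_at(times, phys),
        }
    )
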