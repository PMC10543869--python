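"""Fitting the decay constants from bioassay time-series.

Mortality and physical-integrity series are binomial counts over time and
are fitted by maximum-likelihood binomial logistic regression of outcome
on net age, giving the signed slope ``d`` (per year) and intercept ``h``
used by the logistic property curves.  Chemical series (residual
concentration over time) are fitted by least squares on the log scale,
which is exact for a noiseless exponential.

Mortality series are assumed to be taken at the reference loading
(``c = 1``), so no loading shift is estimated; the shift is applied
downstream from the fitted chemical decay rate.

A seeded fixture generator draws synthetic bioassay tables from the model
curves for parameter-recovery testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "BioassayTimeSeries",
    "FittedDecay",
    "fit_exponential_decay",
    "fit_logistic_decay",
    "generate_decay_fixture",
]


@dataclass(frozen=True)
class BioassayTimeSeries:
    """One study's observations over net age.

    ``frame`` has a ``time`` column (years) plus either binomial columns
    (``tested``, ``killed`` — or ``intact`` for physical-integrity data)
    or a positive ``concentration`` column for chemical data.
    """

    frame: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = self.frame
        if "time" not in df.columns:
            raise ValueError("series must have a 'time' column")
        if (df["time"] < 0).any():
            raise ValueError("times must be >= 0")
        if df["time"].nunique() < 3:
            raise ValueError("at least 3 distinct time points are required")
        if self.kind == "proportion":
            outcome = self.outcome_column
            if (df["tested"] <= 0).any():
                raise ValueError("tested counts must be > 0")
            if ((df[outcome] < 0) | (df[outcome] > df["tested"])).any():
                raise ValueError(f"'{outcome}' must lie in [0, tested]")
        elif (df["concentration"] <= 0).any():
            raise ValueError("concentrations must be > 0")

    @property
    def kind(self) -> str:
        return "chemical" if "concentration" in self.frame.columns else "proportion"

    @property
    def outcome_column(self) -> str:
        for col in ("killed", "intact"):
            if col in self.frame.columns:
                return col
        raise ValueError("proportion series needs a 'killed' or 'intact' column")


@dataclass(frozen=True)
class FittedDecay:
    """Fitted decay constants with standard errors and diagnostics.

    For logistic fits, ``d`` and ``h`` are the signed slope and intercept
    of the linear predictor in net age; for exponential fits ``d`` is the
    chemical decay rate ``d_c`` (positive for decay) and ``h`` the log of
    the starting level.
    """

    kind: str
    d: float
    h: float
    se_d: float
    se_h: float
    deviance: float = np.nan
    separation: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d) and np.isfinite(self.h)):
            raise ValueError("fitted constants must be finite")
        if self.se_d < 0 or self.se_h < 0:
            raise ValueError("standard errors must be >= 0")


def fit_exponential_decay(series: BioassayTimeSeries) -> FittedDecay:
    """Least-squares fit of ``log(concentration) = h - d * time``.

    Closed form and exact on noiseless exponential input; ``d`` is
    returned as a positive decay rate for a decaying series.
    """
    if series.kind != "chemical":
        raise ValueError("exponential fitting needs a chemical series")
    df = series.frame
    X = sm.add_constant(df["time"].to_numpy(dtype=float))
    res = sm.OLS(np.log(df["concentration"].to_numpy(dtype=float)), X).fit()
    h, slope = res.params
    se_h, se_slope = res.bse
    if not np.isfinite(se_h):  # saturated fits (e.g. 2 parameters, exact data)
        se_h, se_slope = 0.0, 0.0
    return FittedDecay(
        kind="exponential",
        d=float(-slope),
        h=float(h),
        se_d=float(se_slope),
        se_h=float(se_h),
        deviance=float(res.ssr),
    )


def fit_logistic_decay(series: BioassayTimeSeries) -> FittedDecay:
    """Binomial logistic regression of outcome proportion on net age.

    Returns the signed slope ``d`` and intercept ``h`` of
    ``logit(p) = d * t + h``, matching the mortality- and physical-decay
    parameterisations.  Complete separation is flagged (estimates are then
    boundary values and their errors unreliable).
    """
    if series.kind != "proportion":
        raise ValueError("logistic fitting needs a proportion (count) series")
    df = series.frame
    outcome = series.outcome_column
    successes = df[outcome].to_numpy(dtype=float)
    failures = df["tested"].to_numpy(dtype=float) - successes
    if successes.sum() == 0 or failures.sum() == 0:
        raise ValueError("both outcome classes must be observed overall")
    X = sm.add_constant(df["time"].to_numpy(dtype=float))
    model = sm.GLM(np.column_stack([successes, failures]), X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    h, d = res.params
    se_h, se_d = res.bse
    # heuristic separation flag: fitted proportions pinned to 0/1 everywhere
    mu = res.fittedvalues
    separation = bool(np.all((mu < 1e-8) | (mu > 1 - 1e-8))) or abs(d) > 1e3
    if separation:
        warnings.warn(
            "possible complete separation: logistic estimates are unreliable",
            stacklevel=2,
        )
    return FittedDecay(
        kind="logistic",
        d=float(d),
        h=float(h),
        se_d=float(se_d),
        se_h=float(se_h),
        deviance=float(res.deviance),
        separation=separation,
    )


def generate_decay_fixture(
    kind: str,
    d: float,
    h: float,
    times,
    tested: int = 100,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> BioassayTimeSeries:
    """Draw a synthetic bioassay table from a decay curve.

    ``kind='logistic'`` draws binomial kills from ``p = expit(d t + h)``
    with ``tested`` mosquitoes per time point; ``kind='exponential'``
    draws concentrations ``exp(h - d t)`` with multiplicative lognormal
    noise of log-scale SD ``noise_sd``.  The same seed reproduces the same
    table exactly.
    """
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    if kind == "logistic":
        p = expit(d * times + h)
        killed = rng.binomial(tested, p)
        frame = pd.DataFrame(
            {"time": times, "tested": tested, "killed": killed}
        )
    elif kind == "exponential":
        conc = np.exp(h - d * times) * rng.lognormal(0.0, noise_sd, size=times.shape)
        frame = pd.DataFrame({"time": times, "concentration": conc})
    else:
        raise ValueError("kind must be 'logistic' or 'exponential'")
    return BioassayTimeSeries(frame=frame, label=f"synthetic-{kind}")
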