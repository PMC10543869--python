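"""Configuration loading, validation, batch running and report writing.

Configs are YAML, deep-merged over the packaged default registry
(:mod:`bednetopt.data`).  A run is fully reproducible from its resolved
config: every report directory records the resolved config and its hash,
and the log states for every constant whether it came from the packaged
defaults or a user override.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .net_properties import (
    Economics,
    InsecticideProfile,
    NetDesign,
    NetPhysicalProfile,
    STRATEGIES,
)
from .optimizer import OptimalityCriterion, OptimaTable, summarize_optima, CRITERIA
from .resistance_dynamics import EvolutionParams
from .scenario_simulation import (
    GridResult,
    GridSpec,
    ScenarioConfig,
    run_grid,
    run_scenario,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "BatchSpec",
    "load_params",
    "load_and_validate",
    "run_batch",
    "write_report",
]

logger = logging.getLogger("bednetopt")


class ConfigError(ValueError):
    """Raised with every validation problem listed, one per line."""


def _default_registry() -> dict:
    text = (resources.files("bednetopt") / "data/defaults.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val, f"{path}{key}.")
        else:
            logger.debug("config override: %s%s = %r", path, key, val)
            out[key] = val
    return out


def load_params(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Resolved parameter registry: packaged defaults, then the user file,
    then in-memory overrides."""
    registry = _default_registry()
    user: dict = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
    merged = _deep_merge(registry, user)
    if overrides:
        merged = _deep_merge(merged, overrides)
    for section in ("insecticides", "physical", "economics", "evolution"):
        for key in merged.get(section, {}):
            origin = "override" if key in user.get(section, {}) else "default"
            logger.info("parameter %s.%s: %s", section, key, origin)
    return merged


@dataclass
class RunConfig:
    """A fully validated, runnable configuration."""

    name: str
    scenario: ScenarioConfig
    grid: GridSpec
    criteria: list[OptimalityCriterion]
    usages: tuple[str, ...]
    resolved: dict = field(default_factory=dict, repr=False)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.resolved, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _build_profile(name: str, raw: dict, errors: list[str]) -> InsecticideProfile | None:
    try:
        return InsecticideProfile(
            name=name,
            d_c=float(raw["d_c"]),
            d_m=float(raw["d_m"]),
            h_m=float(raw["h_m"]),
            k=float(raw["k"]),
            initial_steps=int(raw.get("initial_steps", 1)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"insecticide {name!r}: {exc}")
        return None


def load_and_validate(
    path: str | Path | None = None, overrides: dict | None = None
) -> RunConfig:
    """Build a :class:`RunConfig`, reporting every violation at once."""
    merged = load_params(path, overrides)
    errors: list[str] = []

    scen = merged.get("scenario", {})
    registry = merged.get("insecticides", {})

    def resolve(slot: str) -> InsecticideProfile | None:
        ref = scen.get(slot)
        if ref is None or ref == "none":
            ref = "none"
        if isinstance(ref, dict):
            return _build_profile(slot, ref, errors)
        if ref not in registry:
            errors.append(f"scenario.{slot}: unknown insecticide {ref!r}")
            return None
        return _build_profile(str(ref), registry[ref], errors)

    ins1 = resolve("insecticide_1")
    ins2 = resolve("insecticide_2")

    phys = econ = evo = None
    try:
        phys = NetPhysicalProfile(**{k: float(v) for k, v in merged["physical"].items()})
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"physical: {exc}")
    try:
        econ = Economics(**{k: float(v) for k, v in merged["economics"].items()})
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"economics: {exc}")
    try:
        evo = EvolutionParams(**{k: float(v) for k, v in merged["evolution"].items()})
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"evolution: {exc}")

    grid = None
    try:
        grid = GridSpec(**{k: float(v) for k, v in merged["grid"].items()})
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"grid: {exc}")

    strategy = scen.get("strategy", "mixture")
    if strategy not in STRATEGIES:
        errors.append(f"scenario.strategy: unknown strategy {strategy!r}")

    scenario = None
    if not errors:
        try:
            scenario = ScenarioConfig(
                ins1=ins1,
                ins2=ins2,
                phys=phys,
                econ=econ,
                evo=evo,
                duration=float(scen.get("duration", 12.0)),
                generations_per_year=int(scen.get("generations_per_year", 12)),
                strategy=strategy,
                bioassay_reference=scen.get("bioassay_reference", "initial_population"),
            )
        except (TypeError, ValueError) as exc:
            errors.append(f"scenario: {exc}")

    codes = merged.get("criteria", list(CRITERIA))
    criteria = []
    for code in codes:
        try:
            criteria.append(OptimalityCriterion(code=code))
        except ValueError as exc:
            errors.append(f"criteria: {exc}")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    return RunConfig(
        name=str(scen.get("name", merged.get("name", "scenario"))),
        scenario=scenario,
        grid=grid,
        criteria=criteria,
        usages=tuple(merged.get("usages", ("joint", "solo_1", "solo_2"))),
        resolved=merged,
    )


@dataclass
class BatchSpec:
    """A sweep over budgets and insecticide pairings sharing one base config."""

    budgets: list[float]
    pairs: list[tuple[str, str | None]]
    base: RunConfig

    def __post_init__(self) -> None:
        if not self.budgets or not self.pairs:
            raise ValueError("batch needs at least one budget and one pair")
        if any(b < 0 for b in self.budgets):
            raise ValueError("budgets must be >= 0")


def _slug(text: str) -> str:
    return "".join(ch if ch.isalnum() else "-" for ch in text.lower()).strip("-")


def run_batch(batch: BatchSpec, outdir: str | Path) -> pd.DataFrame:
    """Run grid + optima for every budget x pairing; write per-cell files
    and a combined index keyed by budget, pair and criterion.

    A failing cell is logged and flagged in the index; remaining cells
    still complete.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    index_rows = []
    for ins1_name, ins2_name in batch.pairs:
        for budget in batch.budgets:
            overrides = {
                "economics": {"budget": float(budget)},
                "scenario": {
                    "insecticide_1": ins1_name,
                    "insecticide_2": ins2_name if ins2_name else "none",
                },
            }
            if not ins2_name:
                overrides["usages"] = ["solo_1"]
            cell = f"{_slug(ins1_name)}__{_slug(ins2_name or 'none')}__b{budget:g}"
            try:
                cfg = load_and_validate(overrides=_deep_merge(batch.base.resolved, overrides))
                result = run_grid(cfg.scenario, cfg.grid, cfg.usages)
                optima = summarize_optima(result, cfg.criteria, cfg.usages)
                result.table.to_csv(outdir / f"{cell}_grid.csv", index=False)
                optima.table.to_csv(outdir / f"{cell}_optima.csv", index=False)
                for _, row in optima.table.iterrows():
                    index_rows.append(
                        {
                            "insecticide_1": ins1_name,
                            "insecticide_2": ins2_name or "none",
                            "budget": budget,
                            **row.to_dict(),
                            "status": "ok",
                        }
                    )
            except Exception as exc:  # keep the rest of the batch alive
                logger.error("batch cell %s failed: %s", cell, exc)
                index_rows.append(
                    {
                        "insecticide_1": ins1_name,
                        "insecticide_2": ins2_name or "none",
                        "budget": budget,
                        "status": f"failed: {exc}",
                    }
                )
    index = pd.DataFrame(index_rows)
    index.to_csv(outdir / "batch_index.csv", index=False)
    return index


def write_report(
    optima: OptimaTable,
    traces: dict[str, "object"],
    grid: GridResult | None,
    cfg: RunConfig,
    outdir: str | Path,
) -> list[Path]:
    """Write tidy, plotting-ready report tables.

    ``optima.csv`` keeps explicit no-solution rows; each trace becomes a
    per-generation CSV; the full grid becomes a long-format landscape
    table of control, coverage and cost.  The resolved config and its
    hash accompany the tables for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    optima_out = optima.table.copy()
    if "feasible" in optima_out.columns:
        optima_out["solution"] = np.where(optima_out["feasible"], "ok", "no-solution")
    path = outdir / "optima.csv"
    optima_out.to_csv(path, index=False)
    written.append(path)

    for label, trace in traces.items():
        path = outdir / f"trace_{_slug(label)}.csv"
        trace.frame.to_csv(path, index=False)
        written.append(path)

    if grid is not None:
        path = outdir / "landscape.csv"
        grid.table.to_csv(path, index=False)
        written.append(path)

    meta = {"name": cfg.name, "config_hash": cfg.config_hash}
    path = outdir / "run_config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump({**meta, "resolved": cfg.resolved}, fh, sort_keys=False)
    written.append(path)
    return written
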