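"""Multi-response desirability scoring and genetic-algorithm optimization.

A desirability spec maps one response onto [0, 1] through a piecewise-linear
shape — UP (one-sided ramp) or TENT (two-sided with plateau) — defined by
four breakpoints (min, mid1, mid2, max) and carries a weight.  The overall
score is the weighted arithmetic mean of the per-response desirabilities
(geometric mode available), reported on the percent scale.

The GA searches the six-variable design space for the settings maximizing
the overall desirability of the predicted responses: elitist replacement,
tournament selection, uniform crossover, and Gaussian mutation on the unit
cube with reflection at bounds; the categorical nozzle channel mutates by
level resampling.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset_io import DESIGN_BOUNDS, NOZZLE_LEVELS, ProcessSettings
from .errors import DomainError

CONTINUOUS_VARS = ("kgm_conc", "alg_conc", "p_outer", "p_inner", "airflow")


@dataclass(frozen=True)
class DesirabilitySpec:
    property_name: str
    weight: float
    shape: str  # "UP" or "TENT"
    min: float
    mid1: float
    mid2: float
    max: float

    def __post_init__(self):
        if self.shape not in ("UP", "TENT"):
            raise DomainError(f"shape must be UP or TENT, got {self.shape!r}")
        if not (self.min <= self.mid1 <= self.mid2 <= self.max):
            raise DomainError(
                f"breakpoints must satisfy min <= mid1 <= mid2 <= max, got "
                f"({self.min}, {self.mid1}, {self.mid2}, {self.max})"
            )
        if self.weight <= 0:
            raise DomainError(f"weight must be positive, got {self.weight}")


def desirability(spec: DesirabilitySpec, x: float, up_ramp: str = "to_mid1") -> float:
    """Evaluate one desirability function at ``x``; always in [0, 1].

    UP (default ``up_ramp="to_mid1"``): 0 at/below min, linear ramp to 1 at
    mid1, 1 from mid1 onwards (values beyond max keep scoring 1 but trigger
    an out-of-range warning).  The alternative ``up_ramp="to_mid2"`` places
    the ramp on [mid1, mid2] instead.  TENT: 0 outside [min, max], ramp up
    on [min, mid1], plateau 1 on [mid1, mid2], ramp down on [mid2, max].
    """
    if not np.isfinite(x):
        raise DomainError(f"desirability input must be finite, got {x}")

    def ramp(lo, hi):
        if x <= lo:
            return 0.0
        if x >= hi:
            return 1.0
        return (x - lo) / (hi - lo)

    if spec.shape == "UP":
        if x > spec.max:
            warnings.warn(
                f"{spec.property_name}: value {x} beyond the UP max breakpoint "
                f"{spec.max}; scored 1 but out of the calibrated range",
                stacklevel=2,
            )
        if up_ramp == "to_mid1":
            return ramp(spec.min, spec.mid1) if spec.mid1 > spec.min else float(x >= spec.mid1)
        if up_ramp == "to_mid2":
            return ramp(spec.mid1, spec.mid2) if spec.mid2 > spec.mid1 else float(x >= spec.mid2)
        raise DomainError(f"unknown up_ramp convention {up_ramp!r}")
    # TENT
    if x <= spec.min or x >= spec.max:
        return 0.0
    if x < spec.mid1:
        return (x - spec.min) / (spec.mid1 - spec.min)
    if x <= spec.mid2:
        return 1.0
    return (spec.max - x) / (spec.max - spec.mid2)


def overall_desirability(specs, values: dict, up_ramp: str = "to_mid1",
                         aggregation: str = "arithmetic") -> float:
    """Weighted aggregate of per-property desirabilities, percent scale."""
    ds, ws = [], []
    for spec in specs:
        if spec.property_name not in values:
            raise DomainError(f"missing value for property {spec.property_name!r}")
        ds.append(desirability(spec, values[spec.property_name], up_ramp))
        ws.append(spec.weight)
    ds, ws = np.asarray(ds), np.asarray(ws)
    if aggregation == "arithmetic":
        return float(np.average(ds, weights=ws) * 100.0)
    if aggregation == "geometric":
        if (ds <= 0).any():
            return 0.0
        return float(np.exp(np.average(np.log(ds), weights=ws)) * 100.0)
    raise DomainError(f"unknown aggregation {aggregation!r}")


def load_desirability_csv(source) -> list[DesirabilitySpec]:
    """Read specs from a CSV with columns property,weight,shape,min,mid1,mid2,max."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    required = {"property", "weight", "shape", "min", "mid1", "mid2", "max"}
    missing = required - set(df.columns)
    if missing:
        raise DomainError(f"desirability table missing column(s) {sorted(missing)}")
    return [
        DesirabilitySpec(
            property_name=str(r["property"]), weight=float(r["weight"]),
            shape=str(r["shape"]).upper(), min=float(r["min"]), mid1=float(r["mid1"]),
            mid2=float(r["mid2"]), max=float(r["max"]),
        )
        for _, r in df.iterrows()
    ]


def load_reference_desirability() -> list[DesirabilitySpec]:
    """The packaged five-response desirability table used for the reference study."""
    with resources.files("prillopt.data").joinpath("desirability.csv").open("r") as fh:
        return load_desirability_csv(fh)


@dataclass(frozen=True)
class DesignSpace:
    """Box bounds for the continuous variables plus the nozzle levels."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DESIGN_BOUNDS)
    )
    nc_levels: tuple[str, ...] = NOZZLE_LEVELS

    def __post_init__(self):
        if not self.nc_levels:
            raise DomainError("design space needs at least one nozzle level")
        for name in CONTINUOUS_VARS:
            if name not in self.bounds:
                raise DomainError(f"design space missing bounds for {name!r}")
            lo, hi = self.bounds[name]
            if hi <= lo:
                raise DomainError(f"bounds for {name!r} must satisfy max > min")

    def decode(self, unit: np.ndarray, nc_idx: int) -> ProcessSettings:
        vals = {}
        for j, name in enumerate(CONTINUOUS_VARS):
            lo, hi = self.bounds[name]
            vals[name] = lo + float(unit[j]) * (hi - lo)
        return ProcessSettings(nc=self.nc_levels[nc_idx], **vals)

    def frame(self, unit: np.ndarray, nc_idx: np.ndarray) -> pd.DataFrame:
        cols = {"nc": [self.nc_levels[i] for i in nc_idx]}
        for j, name in enumerate(CONTINUOUS_VARS):
            lo, hi = self.bounds[name]
            cols[name] = lo + unit[:, j] * (hi - lo)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class GaConfig:
    populations: int = 1
    iterations: int = 100
    population_size: int = 100
    replacement_rate: float = 0.5
    mutation_sd: float = 0.1
    seed: int = 1
    crossover: bool = True

    def __post_init__(self):
        if self.population_size < 2:
            raise DomainError("population_size must be >= 2")
        if not 0.0 < self.replacement_rate <= 1.0:
            raise DomainError("replacement_rate must lie in (0, 1]")
        if self.mutation_sd < 0:
            raise DomainError("mutation_sd must be >= 0")


@dataclass
class OptimizationResult:
    best_settings: ProcessSettings
    predicted_responses: dict[str, float]
    per_property_desirability: dict[str, float]
    overall_desirability: float
    trace: list[float]  # best-so-far overall desirability per iteration

    def as_dict(self) -> dict:
        return {
            "best_settings": {"nc": self.best_settings.nc, **{
                k: getattr(self.best_settings, k) for k in CONTINUOUS_VARS
            }},
            "predicted_responses": self.predicted_responses,
            "per_property_desirability": self.per_property_desirability,
            "overall_desirability": self.overall_desirability,
            "trace": self.trace,
        }


def _reflect(u: np.ndarray) -> np.ndarray:
    # reflect into [0,1]; handles overshoot up to one period
    u = np.mod(u, 2.0)
    return np.where(u > 1.0, 2.0 - u, np.abs(u))


def ga_optimize(predictor, specs, space: DesignSpace = DesignSpace(),
                config: GaConfig = GaConfig(), up_ramp: str = "to_mid1",
                aggregation: str = "arithmetic") -> OptimizationResult:
    """Maximize overall desirability of predicted responses over the design space.

    ``predictor`` maps a settings DataFrame (columns nc + the five continuous
    variables, one row per candidate) to ``{response_name: array}`` covering
    every property named in ``specs``.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.population_size, len(CONTINUOUS_VARS)
    n_elite = max(1, int(round(n * (1.0 - config.replacement_rate))))
    n_elite = min(n_elite, n - 1) if config.replacement_rate > 0 else n

    unit = rng.random((n, d))
    nc_idx = rng.integers(0, len(space.nc_levels), size=n)

    def fitness(unit, nc_idx):
        frame = space.frame(unit, nc_idx)
        try:
            preds = predictor(frame)
        except Exception as exc:
            raise DomainError(
                f"predictor failed on candidate settings {frame.iloc[0].to_dict()}: {exc}"
            ) from exc
        scores = np.empty(len(frame))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(len(frame)):
                values = {r: float(preds[r][i]) for r in preds}
                scores[i] = overall_desirability(specs, values, up_ramp, aggregation)
        return scores, preds

    scores, preds = fitness(unit, nc_idx)
    best_i = int(np.argmax(scores))
    best = (scores[best_i], unit[best_i].copy(), int(nc_idx[best_i]))
    trace = [float(best[0])]

    for _ in range(config.iterations):
        order = np.argsort(-scores, kind="stable")
        elite_u, elite_nc = unit[order[:n_elite]], nc_idx[order[:n_elite]]
        n_new = n - n_elite
        # tournament of 2 over the whole current population
        cand = rng.integers(0, n, size=(n_new, 2, 2))
        pick = np.where(
            scores[cand[:, 0, 0]] >= scores[cand[:, 0, 1]], cand[:, 0, 0], cand[:, 0, 1]
        )
        pick2 = np.where(
            scores[cand[:, 1, 0]] >= scores[cand[:, 1, 1]], cand[:, 1, 0], cand[:, 1, 1]
        )
        if config.crossover:
            mask = rng.random((n_new, d)) < 0.5
            child_u = np.where(mask, unit[pick], unit[pick2])
            child_nc = np.where(rng.random(n_new) < 0.5, nc_idx[pick], nc_idx[pick2])
        else:
            child_u, child_nc = unit[pick].copy(), nc_idx[pick].copy()
        child_u = _reflect(child_u + rng.normal(0.0, config.mutation_sd, size=(n_new, d)))
        resample = rng.random(n_new) < config.mutation_sd
        child_nc = np.where(
            resample, rng.integers(0, len(space.nc_levels), size=n_new), child_nc
        )
        unit = np.vstack([elite_u, child_u])
        nc_idx = np.concatenate([elite_nc, child_nc])
        scores, preds = fitness(unit, nc_idx)
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best[0]:
            best = (scores[gen_best], unit[gen_best].copy(), int(nc_idx[gen_best]))
        trace.append(float(best[0]))

    best_settings = space.decode(best[1], best[2])
    frame = space.frame(best[1][None, :], np.array([best[2]]))
    final_preds = predictor(frame)
    values = {r: float(final_preds[r][0]) for r in final_preds}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_prop = {s.property_name: desirability(s, values[s.property_name], up_ramp)
                    for s in specs}
        overall = overall_desirability(specs, values, up_ramp, aggregation)
    return OptimizationResult(
        best_settings=best_settings,
        predicted_responses=values,
        per_property_desirability=per_prop,
        overall_desirability=overall,
        trace=trace,
    )
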