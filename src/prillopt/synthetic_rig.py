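"""Virtual prilling rig: a synthetic data generator with known ground truth.

The rig evaluates smooth low-order response surfaces over the six-variable
design space (with one nozzle-by-pressure interaction), adds Gaussian
measurement noise, and blanks out batches falling in a configurable failure
region — emulating nozzle blockage.  A log-normal particle-population
sampler accompanies it.  Because the ground truth is known in closed form,
the rig supports parameter-recovery tests and brute-force grid oracles for
the optimization pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .dataset_io import (
    DESIGN_BOUNDS,
    NOZZLE_LEVELS,
    RESPONSE_COLUMNS,
    BatchOutcome,
    FormulationDataset,
    FormulationRecord,
    ProcessSettings,
)
from .desirability_ga import CONTINUOUS_VARS, DesignSpace, overall_desirability
from .errors import DomainError
from .particle_metrics import ParticlePopulation

NC_ORD = {"A": 0.0, "B": 0.5, "C": 1.0}


@dataclass(frozen=True)
class RigConfig:
    """Ground-truth coefficients, per-response noise, failure rule and seed.

    Surfaces act on unit-scaled continuous variables; scores are produced by
    clipping latent surfaces to their ordinal scales.  The defaults echo the
    ranges of real batches (Feret ~1.1-3.0 mm, coating up to ~0.4 mm) and
    place the nozzle-configuration interaction on the outer pressure of the
    particle-size response.
    """

    feret_pout_coef: dict[str, float] = field(
        default_factory=lambda: {"A": 0.15, "B": 0.95, "C": 0.55}
    )
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {
            "prilling_score": 0.15,
            "feret_mm": 0.05,
            "circularity": 0.02,
            "core_score": 0.3,
            "coating_mm": 0.015,
        }
    )
    # batches fail (all responses missing) in this region of the space
    fail_nc: str = "A"
    fail_alg_above: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.noise_sd.values()):
            raise DomainError("noise_sd must be >= 0 for every response")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RigConfig":
        text = source.read() if hasattr(source, "read") else open(source).read()
        return cls(**yaml.safe_load(text))


def _unit(frame: pd.DataFrame) -> dict[str, np.ndarray]:
    u = {}
    for name in CONTINUOUS_VARS:
        lo, hi = DESIGN_BOUNDS[name]
        x = frame[name].to_numpy(dtype=float)
        if (x < lo - 1e-9).any() or (x > hi + 1e-9).any():
            raise DomainError(f"settings outside design bounds for {name!r}")
        u[name] = (x - lo) / (hi - lo)
    return u


def rig_response_frame(config: RigConfig, frame: pd.DataFrame) -> dict[str, np.ndarray]:
    """Noiseless ground-truth responses for each settings row (vectorized)."""
    u = _unit(frame)
    nc = frame["nc"].to_numpy(dtype=object)
    if not set(nc) <= set(NOZZLE_LEVELS):
        raise DomainError(f"unknown nozzle level(s) {sorted(set(nc) - set(NOZZLE_LEVELS))}")
    nc_ord = np.array([NC_ORD[v] for v in nc])
    not_a = (nc != "A").astype(float)
    pout_coef = np.array([config.feret_pout_coef[v] for v in nc])

    clip01 = lambda x: np.clip(x, 0.0, 1.0)
    return {
        "prilling_score": 2.0 * clip01(
            0.25 + 0.85 * nc_ord - 0.45 * u["alg_conc"] + 0.2 * u["p_inner"]
        ),
        "feret_mm": 1.35 + pout_coef * u["p_outer"] - 0.35 * u["airflow"]
        + 0.15 * (1.0 - u["kgm_conc"]),
        "circularity": clip01(
            0.96 - 0.25 * u["p_outer"] + 0.1 * u["p_inner"] - 0.06 * (nc == "A")
        ),
        "core_score": 5.0 * clip01(
            0.08 + 0.6 * not_a + 0.33 * u["p_outer"] - 0.3 * u["p_inner"]
        ),
        "coating_mm": 0.02 + 0.26 * u["kgm_conc"] + 0.13 * (1.0 - u["airflow"]),
    }


def rig_failure_mask(config: RigConfig, frame: pd.DataFrame) -> np.ndarray:
    return (
        (frame["nc"].to_numpy(dtype=object) == config.fail_nc)
        & (frame["alg_conc"].to_numpy(dtype=float) > config.fail_alg_above)
    )


def rig_response(config: RigConfig, settings: ProcessSettings) -> dict[str, float] | None:
    """Ground truth for one settings point; None when the batch fails."""
    frame = pd.DataFrame([settings.as_dict()])
    if bool(rig_failure_mask(config, frame)[0]):
        return None
    return {k: float(v[0]) for k, v in rig_response_frame(config, frame).items()}


def rig_predictor(config: RigConfig):
    """Frame-vectorized truth predictor usable directly by the GA (ignores failure)."""

    def predict(frame: pd.DataFrame) -> dict[str, np.ndarray]:
        return rig_response_frame(config, frame)

    return predict


def random_design(n: int, seed: int = 0,
                  space: DesignSpace = DesignSpace()) -> list[ProcessSettings]:
    """Uniform random settings within the design space."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        vals = {
            name: rng.uniform(*space.bounds[name]) for name in CONTINUOUS_VARS
        }
        out.append(ProcessSettings(nc=str(rng.choice(space.nc_levels)), **vals))
    return out


def sample_batch(config: RigConfig, design: list[ProcessSettings],
                 seed: int | None = None) -> FormulationDataset:
    """Noisy rig outcomes for a design, in the standard dataset schema.

    Scores are rounded to their ordinal scales, circularity clipped to
    [0, 1], lengths floored at small positive values; failed rows carry
    all-missing outcomes.
    """
    if not design:
        raise DomainError("design must be non-empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frame = pd.DataFrame([s.as_dict() for s in design])
    truth = rig_response_frame(config, frame)
    failed = rig_failure_mask(config, frame)
    records = []
    for i, settings in enumerate(design):
        if failed[i]:
            records.append(FormulationRecord(i + 1, settings, BatchOutcome()))
            continue
        noisy = {
            k: truth[k][i] + rng.normal(0.0, config.noise_sd[k]) for k in RESPONSE_COLUMNS
        }
        outcome = BatchOutcome(
            prilling_score=float(np.clip(np.rint(noisy["prilling_score"]), 0, 2)),
            feret_mm=float(max(noisy["feret_mm"], 1e-3)),
            circularity=float(np.clip(noisy["circularity"], 0.0, 1.0)),
            core_score=float(np.clip(np.rint(noisy["core_score"]), 0, 5)),
            coating_mm=float(max(noisy["coating_mm"], 0.0)),
        )
        records.append(FormulationRecord(i + 1, settings, outcome))
    return FormulationDataset(records)


def grid_true_optimum(config: RigConfig, specs, points_per_dim: int = 9,
                      space: DesignSpace = DesignSpace(), up_ramp: str = "to_mid1",
                      aggregation: str = "arithmetic"):
    """Brute-force grid maximum of the rig's true overall desirability.

    Returns (best overall desirability in percent, best ProcessSettings).
    """
    axes = [np.linspace(*space.bounds[name], points_per_dim) for name in CONTINUOUS_VARS]
    mesh = np.meshgrid(*axes, indexing="ij")
    flat = np.column_stack([m.ravel() for m in mesh])
    best_score, best_settings = -np.inf, None
    import warnings as _warnings

    for nc in space.nc_levels:
        frame = pd.DataFrame(flat, columns=list(CONTINUOUS_VARS))
        frame.insert(0, "nc", nc)
        truth = rig_response_frame(config, frame)
        scores = np.empty(len(frame))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            for i in range(len(frame)):
                scores[i] = overall_desirability(
                    specs, {k: float(truth[k][i]) for k in truth}, up_ramp, aggregation
                )
        j = int(np.argmax(scores))
        if scores[j] > best_score:
            best_score = float(scores[j])
            best_settings = ProcessSettings(
                nc=nc, **{name: float(flat[j, k]) for k, name in enumerate(CONTINUOUS_VARS)}
            )
    return best_score, best_settings


def true_overall_desirability(config: RigConfig, settings: ProcessSettings, specs,
                              up_ramp: str = "to_mid1",
                              aggregation: str = "arithmetic") -> float:
    """Rig-truth overall desirability of one settings point, percent."""
    frame = pd.DataFrame([settings.as_dict()])
    truth = rig_response_frame(config, frame)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return overall_desirability(
            specs, {k: float(v[0]) for k, v in truth.items()}, up_ramp, aggregation
        )


@dataclass(frozen=True)
class PopulationConfig:
    geometric_mean: float = 1.57
    geometric_sd: float = 1.16
    n: int = 300
    circularity_mean: float | None = 0.9
    circularity_concentration: float = 80.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if self.geometric_sd < 1.0:
            raise DomainError("geometric_sd must be >= 1")
        if self.geometric_mean <= 0:
            raise DomainError("geometric_mean must be > 0")


def sample_population(config: PopulationConfig) -> ParticlePopulation:
    """Log-normal diameters (ln-mean = ln GM, ln-sd = ln GSD) + beta circularities."""
    rng = np.random.default_rng(config.seed)
    ln_sd = np.log(config.geometric_sd)
    if ln_sd == 0.0:
        d = np.full(config.n, config.geometric_mean)
    else:
        d = np.exp(rng.normal(np.log(config.geometric_mean), ln_sd, size=config.n))
    circ = None
    if config.circularity_mean is not None:
        a = config.circularity_mean * config.circularity_concentration
        b = (1.0 - config.circularity_mean) * config.circularity_concentration
        circ = tuple(rng.beta(a, b, size=config.n))
    return ParticlePopulation(diameters=tuple(d), circularities=circ)
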