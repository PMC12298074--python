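"""Particle-population statistics and drug-loading calculators.

The size distribution is characterized by the Probit method: cumulative
fractions at Hazen plotting positions (i - 0.5)/n are probit-transformed
and regressed on ln(diameter).  For log-normal data the regression is
linear; the geometric mean and geometric standard deviation follow from the
fitted line (GM = exp(-intercept/slope), GSD = exp(1/slope)).  Moment-based
estimates are reported alongside, since different estimators can disagree
on finite samples.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    MassBalanceError,
)


@dataclass(frozen=True)
class ParticlePopulation:
    diameters: tuple[float, ...]
    circularities: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.diameters) < 1:
            raise DomainError("population needs at least one particle")
        if any(d <= 0 for d in self.diameters):
            raise DomainError("all diameters must be > 0")
        if self.circularities is not None:
            if len(self.circularities) != len(self.diameters):
                raise DomainError("circularities must match diameters in length")
            if any(not 0.0 <= c <= 1.0 for c in self.circularities):
                raise DomainError("circularities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.diameters)


def read_population_csv(source) -> ParticlePopulation:
    """Read a population from an image-analysis CSV (feret_mm, optional circularity)."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source)
    if "feret_mm" not in df.columns:
        raise DomainError("population table must have a 'feret_mm' column")
    circ = None
    if "circularity" in df.columns and not df["circularity"].isna().all():
        circ = tuple(df["circularity"].astype(float))
    return ParticlePopulation(diameters=tuple(df["feret_mm"].astype(float)),
                              circularities=circ)


@dataclass(frozen=True)
class SizeDistributionSummary:
    n: int
    mean_mm: float
    geometric_mean_mm: float
    geometric_sd: float
    q25_mm: float
    q50_mm: float
    q75_mm: float
    probit_r2: float
    # secondary, moment-based estimates (log-space mean/sd of the sample)
    geometric_mean_moment_mm: float
    geometric_sd_moment: float

    def as_dict(self) -> dict:
        return asdict(self)


def probit_fit(population: ParticlePopulation) -> SizeDistributionSummary:
    """Fit a log-normal size distribution by probit regression."""
    d = np.sort(np.asarray(population.diameters, dtype=float))
    n = d.size
    if n < 5:
        raise InsufficientDataError(f"probit fit needs n >= 5 particles, got {n}")
    if np.unique(d).size < 2:
        raise DegenerateInputError("all diameters equal; size distribution degenerate")
    frac = (np.arange(1, n + 1) - 0.5) / n  # Hazen plotting positions
    probit = stats.norm.ppf(frac)
    lnx = np.log(d)
    res = stats.linregress(lnx, probit)
    slope, intercept = float(res.slope), float(res.intercept)
    if slope <= 0:
        raise DegenerateInputError("non-positive probit slope; diameters not increasing in rank")
    gm = float(np.exp(-intercept / slope))
    gsd = float(np.exp(1.0 / slope))
    q25, q50, q75 = (float(q) for q in np.quantile(d, [0.25, 0.5, 0.75]))
    return SizeDistributionSummary(
        n=n,
        mean_mm=float(d.mean()),
        geometric_mean_mm=gm,
        geometric_sd=gsd,
        q25_mm=q25, q50_mm=q50, q75_mm=q75,
        probit_r2=float(res.rvalue**2),
        geometric_mean_moment_mm=float(np.exp(lnx.mean())),
        geometric_sd_moment=float(np.exp(lnx.std(ddof=1))),
    )


def drug_loading(m_drug_in_aerogel: float, m_loaded_aerogel: float) -> float:
    """Drug mass per loaded-carrier mass, percent."""
    if m_loaded_aerogel <= 0:
        raise DomainError("loaded aerogel mass must be > 0")
    if m_drug_in_aerogel < 0:
        raise DomainError("drug mass must be >= 0")
    if m_drug_in_aerogel > m_loaded_aerogel:
        raise DomainError("drug mass cannot exceed the loaded aerogel mass")
    return m_drug_in_aerogel / m_loaded_aerogel * 100.0


def encapsulation_efficiency(m_drug_in_aerogel: float, m_drug_dropped: float) -> float:
    """Drug retained per drug fed, percent."""
    if m_drug_dropped <= 0:
        raise DomainError("dropped drug mass must be > 0")
    if m_drug_in_aerogel < 0:
        raise DomainError("drug mass must be >= 0")
    return m_drug_in_aerogel / m_drug_dropped * 100.0


def indirect_ee(m_dropped: float, losses: dict[str, float]) -> dict:
    """Mass-balance estimate of encapsulation efficiency.

    ``losses`` maps processing-bath names to drug masses recovered there;
    the residual drug in the particles is inferred by difference.
    """
    if m_dropped <= 0:
        raise DomainError("dropped drug mass must be > 0")
    if any(v < 0 for v in losses.values()):
        raise DomainError("losses must be >= 0")
    total_loss = sum(losses.values())
    if total_loss > m_dropped * (1 + 1e-12):
        raise MassBalanceError(
            f"losses ({total_loss}) exceed the dropped drug mass ({m_dropped})"
        )
    residual = m_dropped - total_loss
    return {
        "ee_percent": residual / m_dropped * 100.0,
        "residual_mass": residual,
        "loss_percent_by_bath": {k: v / m_dropped * 100.0 for k, v in losses.items()},
    }


@dataclass(frozen=True)
class LoadingResult:
    dl_percent: float
    ee_percent: float
    m_drug_in_aerogel: float
    m_loaded_aerogel: float
    m_drug_dropped: float


def loading_result(m_drug_in_aerogel: float, m_loaded_aerogel: float,
                   m_drug_dropped: float) -> LoadingResult:
    return LoadingResult(
        dl_percent=drug_loading(m_drug_in_aerogel, m_loaded_aerogel),
        ee_percent=encapsulation_efficiency(m_drug_in_aerogel, m_drug_dropped),
        m_drug_in_aerogel=m_drug_in_aerogel,
        m_loaded_aerogel=m_loaded_aerogel,
        m_drug_dropped=m_drug_dropped,
    )


def shape_summary(population: ParticlePopulation) -> dict:
    """Mean +/- sample SD of Feret diameter and (when present) circularity."""
    if population.n < 2:
        raise InsufficientDataError("shape summary needs n >= 2 particles")
    d = np.asarray(population.diameters, dtype=float)
    out = {"n": population.n,
           "feret_mean_mm": float(d.mean()),
           "feret_sd_mm": float(d.std(ddof=1))}
    if population.circularities is not None:
        c = np.asarray(population.circularities, dtype=float)
        out["circularity_mean"] = float(c.mean())
        out["circularity_sd"] = float(c.std(ddof=1))
    return out
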