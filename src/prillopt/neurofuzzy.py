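"""Interpretable additive fuzzy-spline response models.

Each response is modelled as an intercept plus a sum of submodels of at most
two inputs.  A submodel expands its inputs into triangular (order-2 B-spline)
fuzzy membership bases — a tensor product when it has two inputs — and its
coefficients are fitted by ridge least squares.  Model structure (which
inputs, which set densities) is selected by a structural-risk criterion, and
a fitted model can be rendered as IF-THEN rules.

Categorical inputs enter as one singleton set per level, i.e. exact one-hot
encoding inside the spline framework; no ordering is imposed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import model_quality
from .dataset_io import FormulationDataset, usable_records
from .errors import DegenerateInputError, DomainError

_LABELS3 = ("LOW", "MID", "HIGH")

DEFAULT_RIDGE_FACTOR = 1e-6
DEFAULT_C1 = 0.75

#: submodel input sets used for the five responses of the reference dataset
REFERENCE_STRUCTURES: dict[str, list[tuple[str, ...]]] = {
    "prilling_score": [("nc",), ("alg_conc",), ("p_outer",)],
    "feret_mm": [("nc", "p_outer"), ("kgm_conc", "p_inner"), ("airflow",)],
    "circularity": [("nc", "p_outer"), ("p_inner",), ("p_outer",)],
    "core_score": [("nc", "p_inner"), ("p_outer",)],
    "coating_mm": [("alg_conc",), ("kgm_conc", "airflow"), ("p_outer", "p_inner")],
}


def set_labels(n: int) -> list[str]:
    if n == 1:
        return ["ALL"]
    if n == 2:
        return ["LOW", "HIGH"]
    if n == 3:
        return list(_LABELS3)
    return [f"LEVEL_{i + 1}" for i in range(n)]


@dataclass(frozen=True)
class FuzzyPartition:
    """Fuzzy sets over one input: triangular hats on nodes, or one singleton per level."""

    input_name: str
    nodes: tuple = ()          # sorted node positions (continuous input)
    levels: tuple = ()         # category levels (categorical input)

    def __post_init__(self):
        if bool(self.nodes) == bool(self.levels):
            raise DomainError("partition needs either nodes (continuous) or levels (categorical)")
        if self.nodes:
            arr = np.asarray(self.nodes, dtype=float)
            if len(arr) < 2:
                raise DomainError("continuous partition needs at least 2 nodes")
            if not np.all(np.diff(arr) > 0):
                raise DomainError("nodes must be strictly increasing")

    @property
    def categorical(self) -> bool:
        return bool(self.levels)

    @property
    def n_sets(self) -> int:
        return len(self.levels) if self.categorical else len(self.nodes)

    @property
    def labels(self) -> list[str]:
        if self.categorical:
            return [str(v) for v in self.levels]
        return set_labels(self.n_sets)

    def memberships(self, x) -> np.ndarray:
        """(n, n_sets) membership matrix; rows sum to 1 (clamped outside the node span)."""
        if self.categorical:
            x = np.asarray(x, dtype=object)
            out = np.zeros((len(x), self.n_sets))
            for j, level in enumerate(self.levels):
                out[:, j] = x == level
            if not np.allclose(out.sum(axis=1), 1.0):
                bad = sorted(set(x) - set(self.levels))
                raise DomainError(f"unknown categorical level(s) {bad} for input {self.input_name!r}")
            return out
        t = np.asarray(self.nodes, dtype=float)
        x = np.clip(np.asarray(x, dtype=float), t[0], t[-1])
        out = np.zeros((len(x), self.n_sets))
        for j in range(self.n_sets):
            m = np.zeros_like(x)
            if j > 0:
                left = (x >= t[j - 1]) & (x <= t[j])
                m[left] = (x[left] - t[j - 1]) / (t[j] - t[j - 1])
            if j < self.n_sets - 1:
                right = (x >= t[j]) & (x < t[j + 1])
                m[right] = (t[j + 1] - x[right]) / (t[j + 1] - t[j])
            else:
                m[x >= t[-1]] = 1.0
            if j == 0:
                m[x <= t[0]] = 1.0
            out[:, j] = m
        return out


def adapted_nodes(values, density: int) -> np.ndarray:
    """Node positions at data quantiles (node adaptation), deduplicated.

    Falls back to fewer nodes when the data carry fewer distinct quantiles
    than requested.
    """
    v = np.asarray(values, dtype=float)
    qs = np.quantile(v, np.linspace(0.0, 1.0, density))
    nodes = np.unique(np.round(qs, 12))
    if len(nodes) < 2:
        raise DegenerateInputError(
            f"cannot build a partition: fewer than 2 distinct values (density {density})"
        )
    return nodes


def build_partition(name: str, values, density: int, categorical: bool) -> FuzzyPartition:
    if categorical:
        levels = tuple(sorted({str(v) for v in values}))
        return FuzzyPartition(input_name=name, levels=levels)
    return FuzzyPartition(input_name=name, nodes=tuple(adapted_nodes(values, density)))


@dataclass(frozen=True)
class Submodel:
    """One additive term: 1 or 2 inputs, their partitions, and basis coefficients."""

    inputs: tuple[str, ...]
    partitions: tuple[FuzzyPartition, ...]
    coefficients: np.ndarray | None = None

    def __post_init__(self):
        if not 1 <= len(self.inputs) <= 2:
            raise DomainError("a submodel takes 1 or 2 inputs")
        if len(self.partitions) != len(self.inputs):
            raise DomainError("one partition per input required")

    @property
    def n_basis(self) -> int:
        return int(np.prod([p.n_sets for p in self.partitions]))

    def basis(self, data: pd.DataFrame) -> np.ndarray:
        mats = [p.memberships(data[p.input_name].to_numpy()) for p in self.partitions]
        if len(mats) == 1:
            return mats[0]
        # tensor product basis, row-wise
        n = mats[0].shape[0]
        return (mats[0][:, :, None] * mats[1][:, None, :]).reshape(n, -1)

    def contribution(self, data: pd.DataFrame) -> np.ndarray:
        if self.coefficients is None:
            raise DomainError("submodel has no fitted coefficients")
        return self.basis(data) @ self.coefficients

    def basis_labels(self) -> list[tuple[tuple[str, str], ...]]:
        """Antecedent (input, label) tuples, one per basis function, in basis order."""
        per_input = [[(p.input_name, lab) for lab in p.labels] for p in self.partitions]
        return [tuple(combo) for combo in itertools.product(*per_input)]


@dataclass
class NflModel:
    response_name: str
    submodels: list[Submodel]
    intercept: float
    ridge_factor: float
    srm_score: float
    n_records: int
    densities: dict[str, int] = field(default_factory=dict)
    training_r2_percent: float | None = None
    ill_posed: bool = False

    @property
    def n_coefficients(self) -> int:
        return 1 + sum(s.n_basis for s in self.submodels)

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        data = _as_frame(data)
        out = np.full(len(data), self.intercept, dtype=float)
        for s in self.submodels:
            out += s.contribution(data)
        return out

    @property
    def training_r2(self) -> float:
        if self.training_r2_percent is None:
            raise DegenerateInputError("training R2 undefined (constant response)")
        return self.training_r2_percent

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "intercept": float(self.intercept),
            "ridge_factor": float(self.ridge_factor),
            "srm_score": float(self.srm_score),
            "n_records": int(self.n_records),
            "densities": {k: int(v) for k, v in self.densities.items()},
            "training_r2_percent": None
            if self.training_r2_percent is None
            else float(self.training_r2_percent),
            "ill_posed": bool(self.ill_posed),
            "submodels": [
                {
                    "inputs": list(s.inputs),
                    "partitions": [
                        {
                            "input": p.input_name,
                            "nodes": [float(v) for v in p.nodes],
                            "levels": list(p.levels),
                        }
                        for p in s.partitions
                    ],
                    "coefficients": [float(c) for c in s.coefficients],
                }
                for s in self.submodels
            ],
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "NflModel":
        subs = []
        for sd in d["submodels"]:
            parts = tuple(
                FuzzyPartition(
                    input_name=pd_["input"],
                    nodes=tuple(pd_["nodes"]),
                    levels=tuple(pd_["levels"]),
                )
                for pd_ in sd["partitions"]
            )
            subs.append(
                Submodel(
                    inputs=tuple(sd["inputs"]),
                    partitions=parts,
                    coefficients=np.asarray(sd["coefficients"], dtype=float),
                )
            )
        return cls(
            response_name=d["response"],
            submodels=subs,
            intercept=d["intercept"],
            ridge_factor=d["ridge_factor"],
            srm_score=d["srm_score"],
            n_records=d["n_records"],
            densities=dict(d.get("densities", {})),
            training_r2_percent=d.get("training_r2_percent"),
            ill_posed=d.get("ill_posed", False),
        )

    @classmethod
    def from_yaml(cls, source) -> "NflModel":
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = open(source).read()
        return cls.from_dict(yaml.safe_load(text))


def srm_score(mse: float, n_coefficients: int, n_records: int, c1: float = DEFAULT_C1,
              eps: float = 1e-9) -> float:
    """Structural-risk score: penalized mean squared error, lower is better.

    mse / max(eps, 1 - sqrt(c1*(p/n)*(1 + ln(n/p)) + ln(n)/(2n))); +inf when
    the penalty argument reaches 1 (model inadmissible at this sample size).
    """
    if n_records <= 0:
        raise DomainError("n_records must be positive")
    if mse < 0:
        raise DomainError("mse must be non-negative")
    p, n = n_coefficients, n_records
    if p >= n:
        return math.inf
    h = c1 * (p / n) * (1.0 + math.log(n / p)) + math.log(n) / (2.0 * n)
    if h >= 1.0:
        return math.inf
    return mse / max(eps, 1.0 - math.sqrt(h))


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, FormulationDataset):
        return data.to_frame()
    return data


def _categorical_columns(frame: pd.DataFrame) -> set[str]:
    return {c for c in frame.columns if frame[c].dtype == object}


def _design_matrix(frame: pd.DataFrame, submodels: Sequence[Submodel]) -> np.ndarray:
    cols = [np.ones((len(frame), 1))]
    cols += [s.basis(frame) for s in submodels]
    return np.hstack(cols)


def _ridge_solve(X: np.ndarray, y: np.ndarray, ridge_factor: float) -> np.ndarray:
    # intercept column included in X; the tiny ridge also keeps rank-deficient
    # partition-of-unity bases solvable
    p = X.shape[1]
    A = X.T @ X + ridge_factor * np.eye(p)
    return np.linalg.solve(A, X.T @ y)


def _build_submodels(frame: pd.DataFrame, structure: Sequence[Sequence[str]],
                     densities: dict[str, int]) -> list[Submodel]:
    categorical = _categorical_columns(frame)
    subs = []
    for inputs in structure:
        parts = []
        for name in inputs:
            if name not in frame.columns:
                raise DomainError(f"unknown input name {name!r}")
            parts.append(
                build_partition(
                    name, frame[name].to_numpy(), densities.get(name, 2), name in categorical
                )
            )
        subs.append(Submodel(inputs=tuple(inputs), partitions=tuple(parts)))
    return subs


def _fit_given(frame: pd.DataFrame, y: np.ndarray, structure, densities,
               ridge_factor: float, c1: float):
    subs = _build_submodels(frame, structure, densities)
    X = _design_matrix(frame, subs)
    w = _ridge_solve(X, y, ridge_factor)
    resid = y - X @ w
    mse = float(np.mean(resid**2))
    p = X.shape[1]
    score = srm_score(mse, p, len(y), c1)
    fitted = []
    k = 1
    for s in subs:
        fitted.append(Submodel(inputs=s.inputs, partitions=s.partitions,
                               coefficients=w[k:k + s.n_basis].copy()))
        k += s.n_basis
    return float(w[0]), fitted, mse, score, p


def _density_grid(frame: pd.DataFrame, structure, candidate_densities):
    """All per-input density assignments for the continuous inputs of a structure."""
    categorical = _categorical_columns(frame)
    cont = sorted({n for inputs in structure for n in inputs if n not in categorical})
    feasible = {}
    for name in cont:
        n_distinct = frame[name].nunique()
        ds = [d for d in candidate_densities if d <= n_distinct]
        feasible[name] = ds or [min(candidate_densities)]
    for combo in itertools.product(*(feasible[n] for n in cont)):
        yield dict(zip(cont, combo))


def prepare_training_frame(data, response: str):
    """Usable-record input frame + response vector for one response."""
    if isinstance(data, FormulationDataset):
        frame = usable_records(data, response).to_frame()
    else:
        frame = _as_frame(data)
        frame = frame.loc[~frame[response].isna()].reset_index(drop=True)
    y = frame[response].to_numpy(dtype=float)
    return frame, y


def fit_fixed_structure(data, response: str, structure: Sequence[Sequence[str]],
                        densities="srm", ridge_factor: float = DEFAULT_RIDGE_FACTOR,
                        c1: float = DEFAULT_C1,
                        candidate_densities: tuple[int, ...] = (2, 3)) -> NflModel:
    """Fit a model with a fixed submodel structure by ridge least squares.

    ``densities`` may be a per-input dict, a single int, or ``"srm"`` to pick
    the per-input set densities from ``candidate_densities`` minimizing the
    structural-risk score.  Categorical inputs always get one set per level.
    """
    frame, y = prepare_training_frame(data, response)
    if len(frame) == 0:
        raise DomainError(f"no usable records for response {response!r}")
    for inputs in structure:
        for name in inputs:
            if name not in frame.columns:
                raise DomainError(f"unknown input name {name!r}")

    if isinstance(densities, int):
        cands = [{n: densities for inputs in structure for n in inputs}]
    elif isinstance(densities, dict):
        cands = [densities]
    elif densities == "srm":
        cands = list(_density_grid(frame, structure, candidate_densities))
        if not cands:
            cands = [{}]
    elif densities == "max":
        # largest candidate density each input's data can support
        categorical = _categorical_columns(frame)
        cont = {n for inputs in structure for n in inputs if n not in categorical}
        dmax = max(candidate_densities)
        cands = [{n: min(dmax, frame[n].nunique()) for n in cont}]
    else:
        raise DomainError(
            f"densities must be 'srm', 'max', an int or a dict, got {densities!r}"
        )

    best = None
    for dens in cands:
        intercept, subs, mse, score, p = _fit_given(frame, y, structure, dens,
                                                    ridge_factor, c1)
        key = (score, p)
        if best is None or key < best[0]:
            best = (key, dens, intercept, subs, mse, p)
    (score, p), dens, intercept, subs, mse, p = best

    try:
        r2 = model_quality.r_squared(y, np.full_like(y, intercept) +
                                     sum(s.contribution(frame) for s in subs))
    except DegenerateInputError:
        r2 = None
    return NflModel(
        response_name=response,
        submodels=subs,
        intercept=intercept,
        ridge_factor=ridge_factor,
        srm_score=score,
        n_records=len(y),
        densities=dens,
        training_r2_percent=r2,
        ill_posed=p > len(y),
    )


@dataclass(frozen=True)
class AsmodConfig:
    candidate_densities: tuple[int, ...] = (2, 3)
    max_inputs_per_submodel: int = 2
    max_nodes: int = 15
    c1: float = DEFAULT_C1
    ridge_factor: float = DEFAULT_RIDGE_FACTOR
    max_moves: int = 50
    min_records: int = 6


def fit_asmod(data, response: str, config: AsmodConfig = AsmodConfig(),
              inputs: Sequence[str] | None = None) -> NflModel:
    """Greedy grow/prune structure search scored by the structural-risk criterion.

    Starting from the intercept-only model, candidate moves are: add a
    univariate submodel on an unused input, merge two univariate submodels
    into a tensor submodel, raise one partition's density, or delete a
    submodel.  The best strictly-improving move is accepted; ties prefer
    fewer inputs, then fewer coefficients, then lexical order.  The selected
    model's score therefore never exceeds the intercept-only score.
    """
    frame, y = prepare_training_frame(data, response)
    if len(frame) < config.min_records:
        raise DomainError(
            f"need at least {config.min_records} usable records, got {len(frame)}"
        )
    if inputs is None:
        inputs = [c for c in frame.columns if c not in ("sample", response)]
        # drop other response columns if a full formulation frame was passed
        from .dataset_io import RESPONSE_COLUMNS

        inputs = [c for c in inputs if c not in RESPONSE_COLUMNS]
    categorical = _categorical_columns(frame)
    d0 = min(config.candidate_densities)

    def fit(structure, densities):
        intercept, subs, mse, score, p = _fit_given(
            frame, y, structure, densities, config.ridge_factor, config.c1
        )
        return intercept, subs, mse, score, p

    # current state: list of input tuples + density map
    structure: list[tuple[str, ...]] = []
    densities: dict[str, int] = {}
    base_mse = float(np.mean((y - y.mean()) ** 2))
    current_score = srm_score(base_mse, 1, len(y), config.c1)
    intercept, subs = float(np.mean(y)), []

    for _ in range(config.max_moves):
        candidates = []  # (score, n_inputs, p, lexical, structure, densities)
        used = {n for tup in structure for n in tup}

        def consider(new_structure, new_densities):
            try:
                i2, s2, mse2, score2, p2 = fit(new_structure, new_densities)
            except (DegenerateInputError, DomainError):
                return
            lex = tuple(sorted(tuple(t) for t in new_structure))
            n_inputs = len({n for t in new_structure for n in t})
            candidates.append((score2, n_inputs, p2, lex, new_structure, new_densities, i2, s2))

        for name in inputs:
            if name in used:
                continue
            if name not in categorical and frame[name].nunique() < 2:
                continue
            if name in categorical:
                consider(structure + [(name,)], densities)
                continue
            # try every admissible initial density: a weak linear trend can
            # hide a strong mid-range effect that only 3 nodes expose
            for d in config.candidate_densities:
                if d <= frame[name].nunique():
                    consider(structure + [(name,)], {**densities, name: d})
        for i, j in itertools.combinations(range(len(structure)), 2):
            a, b = structure[i], structure[j]
            if len(a) + len(b) > config.max_inputs_per_submodel:
                continue
            merged = [t for k, t in enumerate(structure) if k not in (i, j)]
            merged.append(tuple(sorted(a + b)))
            consider(merged, densities)
        for name in sorted(used):
            if name in categorical:
                continue
            higher = [d for d in config.candidate_densities
                      if d > densities.get(name, d0) and d <= config.max_nodes
                      and d <= frame[name].nunique()]
            if higher:
                consider(structure, {**densities, name: min(higher)})
        for i in range(len(structure)):
            consider([t for k, t in enumerate(structure) if k != i], densities)

        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))
        best = candidates[0]
        if best[0] >= current_score - 1e-12:
            break
        current_score = best[0]
        structure, densities = best[4], best[5]
        intercept, subs = best[6], best[7]

    pred = np.full_like(y, intercept) + sum(
        (s.contribution(frame) for s in subs), np.zeros_like(y)
    )
    try:
        r2 = model_quality.r_squared(y, pred)
    except DegenerateInputError:
        r2 = None
    return NflModel(
        response_name=response,
        submodels=list(subs),
        intercept=intercept,
        ridge_factor=config.ridge_factor,
        srm_score=current_score,
        n_records=len(y),
        densities=densities,
        training_r2_percent=r2,
    )


@dataclass(frozen=True)
class LinguisticRule:
    antecedent: tuple[tuple[str, str], ...]  # (input, label) pairs
    consequent_level: str
    confidence: float

    def render(self, response: str) -> str:
        cond = " AND ".join(f"{name} IS {label}" for name, label in self.antecedent)
        return f"IF {cond} THEN {response} IS {self.consequent_level} ({self.confidence:.2f})"


def extract_rules(model: NflModel) -> list[LinguisticRule]:
    """One rule per basis function; confidence is the coefficient's normalized
    position within its submodel, mapped to LOW/MID/HIGH consequent levels."""
    rules = []
    for s in model.submodels:
        w = np.asarray(s.coefficients, dtype=float)
        lo, hi = float(w.min()), float(w.max())
        span = hi - lo
        for antecedent, coef in zip(s.basis_labels(), w):
            conf = 1.0 if span == 0 else (float(coef) - lo) / span
            level = "LOW" if conf < 1 / 3 else ("MID" if conf < 2 / 3 else "HIGH")
            rules.append(LinguisticRule(antecedent=antecedent,
                                        consequent_level=level, confidence=conf))
    return rules
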