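"""Feed-forward surrogate networks for the five batch responses.

One network per response: six inputs, one hidden layer of two nodes with
asymmetric sigmoid activation, and a linear or sigmoid output node.  Inputs
and outputs are affinely scaled to [0.1, 0.9]; the nozzle configuration is
encoded on a single channel (A=0, B=0.5, C=1) so the network keeps exactly
six inputs (a one-hot mode is available).  Training is full-batch RPROP
with optional early stopping on an inner validation slice ("smart stop").

The momentum and learning-rate fields in :class:`TrainConfig` are accepted
for configuration-file compatibility but are inert: RPROP adapts per-weight
steps from gradient signs and uses neither.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset_io import (
    FormulationDataset,
    RESPONSE_COLUMNS,
    SETTING_COLUMNS,
)
from .errors import DomainError, TrainingDivergenceError

NC_ORDINAL = {"A": 0.0, "B": 0.5, "C": 1.0}

#: default output activation per reference response; bounded responses get
#: the sigmoid, open-ended lengths stay linear
DEFAULT_OUTPUT_ACTIVATION = {
    "prilling_score": "sigmoid",
    "feret_mm": "linear",
    "circularity": "sigmoid",
    "core_score": "sigmoid",
    "coating_mm": "linear",
}


def sigmoid(x):
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ScalingSpec:
    """Invertible affine map of each variable onto a target interval."""

    mins: dict[str, float]
    maxs: dict[str, float]
    target: tuple[float, float] = (0.1, 0.9)

    def __post_init__(self):
        for k in self.mins:
            if self.maxs[k] <= self.mins[k]:
                raise DomainError(f"scaling for {k!r} needs max > min")

    def scale(self, name: str, x):
        lo, hi = self.target
        return lo + (np.asarray(x, dtype=float) - self.mins[name]) / (
            self.maxs[name] - self.mins[name]
        ) * (hi - lo)

    def unscale(self, name: str, z):
        lo, hi = self.target
        return self.mins[name] + (np.asarray(z, dtype=float) - lo) / (hi - lo) * (
            self.maxs[name] - self.mins[name]
        )


@dataclass(frozen=True)
class TrainConfig:
    target_mse: float = 1e-4
    max_iterations: int = 1000
    split_fraction: float = 0.8
    seed: int = 10_000
    smart_stop: bool = True
    patience: int = 50
    validation_fraction: float = 0.2
    rprop_step_init: float = 0.1
    rprop_increase: float = 1.2
    rprop_decrease: float = 0.5
    rprop_step_min: float = 1e-6
    rprop_step_max: float = 50.0
    nc_encoding: str = "ordinal"  # or "onehot"
    # accepted for config-file fidelity; not used by RPROP
    momentum: float = 0.8
    learning_rate: float = 0.7

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise DomainError("split_fraction must lie in (0, 1)")
        if self.max_iterations < 1:
            raise DomainError("max_iterations must be >= 1")


def encode_settings(frame: pd.DataFrame, nc_encoding: str = "ordinal") -> np.ndarray:
    """Settings DataFrame -> raw input matrix (before scaling)."""
    cont = frame[list(SETTING_COLUMNS[1:])].to_numpy(dtype=float)
    if nc_encoding == "ordinal":
        nc = frame["nc"].map(NC_ORDINAL)
        if nc.isna().any():
            raise DomainError("unknown nozzle configuration in data")
        return np.column_stack([nc.to_numpy(dtype=float), cont])
    if nc_encoding == "onehot":
        onehot = np.column_stack([(frame["nc"] == lvl).to_numpy(dtype=float) for lvl in "ABC"])
        return np.hstack([onehot, cont])
    raise DomainError(f"unknown nc encoding {nc_encoding!r}")


@dataclass
class AnnModel:
    response_name: str
    w1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    scaling: ScalingSpec
    output_activation: str = "linear"
    nc_encoding: str = "ordinal"
    seed: int = 0
    training_log: list = field(default_factory=list)  # (epoch, train mse) pairs

    @property
    def architecture(self) -> tuple[int, int, int]:
        return (self.w1.shape[1], self.w1.shape[0], 1)

    def _input_names(self) -> list[str]:
        if self.nc_encoding == "onehot":
            return ["nc_A", "nc_B", "nc_C", *SETTING_COLUMNS[1:]]
        return ["nc_ord", *SETTING_COLUMNS[1:]]

    def _scale_inputs(self, raw: np.ndarray, warn_extrapolation: bool = True) -> np.ndarray:
        names = self._input_names()
        cols = []
        extrapolating = False
        for j, name in enumerate(names):
            x = raw[:, j]
            if (x < self.scaling.mins[name] - 1e-12).any() or (
                x > self.scaling.maxs[name] + 1e-12
            ).any():
                extrapolating = True
            cols.append(self.scaling.scale(name, x))
        if extrapolating and warn_extrapolation:
            warnings.warn(
                f"inputs outside the fitted range of model {self.response_name!r}; "
                "prediction is an extrapolation",
                stacklevel=2,
            )
        return np.column_stack(cols)

    def _forward_scaled(self, X: np.ndarray) -> np.ndarray:
        h = sigmoid(X @ self.w1.T + self.b1)
        z = h @ self.w2 + self.b2
        return sigmoid(z) if self.output_activation == "sigmoid" else z

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Predict the response, in engineering units, for each settings row."""
        raw = encode_settings(frame, self.nc_encoding)
        z = self._forward_scaled(self._scale_inputs(raw))
        return self.scaling.unscale(self.response_name, z)

    def predict(self, settings) -> float:
        """Predict for a single ProcessSettings."""
        frame = pd.DataFrame([settings.as_dict()])
        return float(self.predict_frame(frame)[0])

    # -- persistence ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "architecture": list(self.architecture),
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": float(self.b2),
            "output_activation": self.output_activation,
            "nc_encoding": self.nc_encoding,
            "seed": int(self.seed),
            "scaling": {
                "mins": self.scaling.mins,
                "maxs": self.scaling.maxs,
                "target": list(self.scaling.target),
            },
            "training_log": [[int(e), float(m)] for e, m in self.training_log],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "AnnModel":
        return cls(
            response_name=d["response"],
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            scaling=ScalingSpec(
                mins=dict(d["scaling"]["mins"]),
                maxs=dict(d["scaling"]["maxs"]),
                target=tuple(d["scaling"]["target"]),
            ),
            output_activation=d["output_activation"],
            nc_encoding=d["nc_encoding"],
            seed=d["seed"],
            training_log=[tuple(x) for x in d["training_log"]],
        )

    @classmethod
    def from_json(cls, source) -> "AnnModel":
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = open(source).read()
        return cls.from_dict(json.loads(text))


def split_dataset(dataset: FormulationDataset, fraction: float = 0.8,
                  seed: int = 0) -> tuple[FormulationDataset, FormulationDataset]:
    """Random disjoint/exhaustive train-test split, sizes rounded to nearest."""
    if not 0.0 < fraction < 1.0:
        raise DomainError("split fraction must lie strictly in (0, 1)")
    n = len(dataset)
    if n < 5:
        raise DomainError(f"need at least 5 records to split, got {n}")
    n_train = int(round(n * fraction))
    n_train = min(max(n_train, n - n_train), n - 1)  # train >= test, test non-empty
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = sorted(order[:n_train])
    test_idx = sorted(order[n_train:])
    recs = dataset.records
    return (
        FormulationDataset([recs[i] for i in train_idx]),
        FormulationDataset([recs[i] for i in test_idx]),
    )


def _rprop_train(X, y, w0, config: TrainConfig, forward_loss_grad):
    """Generic full-batch RPROP- loop on a flat parameter vector.

    Epoch-level backtracking keeps the recorded loss non-increasing: an
    epoch whose update raises the loss is reverted and its steps shrunk.
    """
    w = w0.copy()
    steps = np.full_like(w, config.rprop_step_init)
    prev_grad = np.zeros_like(w)
    loss, grad = forward_loss_grad(w)
    log = [(0, loss)]
    for epoch in range(1, config.max_iterations + 1):
        if not np.isfinite(loss):
            raise TrainingDivergenceError("non-finite training loss", epoch=epoch)
        if loss <= config.target_mse:
            break
        sign_change = grad * prev_grad
        steps = np.where(
            sign_change > 0,
            np.minimum(steps * config.rprop_increase, config.rprop_step_max),
            np.where(
                sign_change < 0,
                np.maximum(steps * config.rprop_decrease, config.rprop_step_min),
                steps,
            ),
        )
        update_grad = np.where(sign_change < 0, 0.0, grad)
        w_new = w - np.sign(update_grad) * steps
        new_loss, new_grad = forward_loss_grad(w_new)
        if new_loss <= loss:
            w = w_new
            prev_grad = update_grad
            loss, grad = new_loss, new_grad
        else:  # revert and shrink all steps
            steps = np.maximum(steps * config.rprop_decrease, config.rprop_step_min)
            prev_grad = np.zeros_like(w)
        log.append((epoch, loss))
    return w, log


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(w, n_in, hidden):
    k = hidden * n_in
    w1 = w[:k].reshape(hidden, n_in)
    b1 = w[k:k + hidden]
    w2 = w[k + hidden:k + 2 * hidden]
    b2 = w[-1]
    return w1, b1, w2, b2


def _loss_grad_factory(X, y, hidden, output_activation):
    n, n_in = X.shape

    def loss_grad(w):
        w1, b1, w2, b2 = _unpack(w, n_in, hidden)
        a = X @ w1.T + b1
        h = sigmoid(a)
        z = h @ w2 + b2
        out = sigmoid(z) if output_activation == "sigmoid" else z
        err = out - y
        loss = float(np.mean(err**2))
        dout = 2.0 * err / n
        dz = dout * out * (1.0 - out) if output_activation == "sigmoid" else dout
        g_w2 = h.T @ dz
        g_b2 = float(dz.sum())
        dh = np.outer(dz, w2) * h * (1.0 - h)
        g_w1 = dh.T @ X
        g_b1 = dh.sum(axis=0)
        return loss, _pack(g_w1, g_b1, g_w2, g_b2)

    return loss_grad


def build_scaling(frame: pd.DataFrame, response: str, nc_encoding: str,
                  target=(0.1, 0.9)) -> ScalingSpec:
    raw = encode_settings(frame, nc_encoding)
    names = (["nc_A", "nc_B", "nc_C"] if nc_encoding == "onehot" else ["nc_ord"]) + list(
        SETTING_COLUMNS[1:]
    )
    mins = {nm: float(raw[:, j].min()) for j, nm in enumerate(names)}
    maxs = {nm: float(raw[:, j].max()) for j, nm in enumerate(names)}
    for nm in names:  # guard constant columns
        if maxs[nm] <= mins[nm]:
            maxs[nm] = mins[nm] + 1.0
    yv = frame[response].to_numpy(dtype=float)
    ylo, yhi = float(yv.min()), float(yv.max())
    if yhi <= ylo:
        yhi = ylo + 1.0
    mins[response], maxs[response] = ylo, yhi
    return ScalingSpec(mins=mins, maxs=maxs, target=target)


def train_ann(train, response: str, config: TrainConfig = TrainConfig(),
              hidden: int = 2, output_activation: str | None = None,
              scaling: ScalingSpec | None = None) -> AnnModel:
    """Train one network on the usable records of ``train`` for one response."""
    if isinstance(train, FormulationDataset):
        frame = train.to_frame()
    else:
        frame = train
    frame = frame.loc[~frame[response].isna()].reset_index(drop=True)
    if len(frame) == 0:
        raise DomainError(f"no usable records for response {response!r}")
    if output_activation is None:
        output_activation = DEFAULT_OUTPUT_ACTIVATION.get(response, "linear")
    if scaling is None:
        scaling = build_scaling(frame, response, config.nc_encoding)

    raw = encode_settings(frame, config.nc_encoding)
    names = (["nc_A", "nc_B", "nc_C"] if config.nc_encoding == "onehot" else ["nc_ord"]) + list(
        SETTING_COLUMNS[1:]
    )
    X = np.column_stack([scaling.scale(nm, raw[:, j]) for j, nm in enumerate(names)])
    y = scaling.scale(response, frame[response].to_numpy(dtype=float))

    rng = np.random.default_rng(config.seed)
    n_in = X.shape[1]
    w0 = _pack(
        rng.normal(0.0, 0.5, size=(hidden, n_in)),
        rng.normal(0.0, 0.5, size=hidden),
        rng.normal(0.0, 0.5, size=hidden),
        float(rng.normal(0.0, 0.5)),
    )

    if config.smart_stop and len(X) >= 5:
        n_val = max(1, int(round(len(X) * config.validation_fraction)))
        order = rng.permutation(len(X))
        val_idx, fit_idx = order[:n_val], order[n_val:]
        lg_fit = _loss_grad_factory(X[fit_idx], y[fit_idx], hidden, output_activation)
        lg_val = _loss_grad_factory(X[val_idx], y[val_idx], hidden, output_activation)

        best_w, best_val, since = w0.copy(), np.inf, 0
        w = w0.copy()
        steps = np.full_like(w, config.rprop_step_init)
        prev_grad = np.zeros_like(w)
        loss, grad = lg_fit(w)
        log = [(0, loss)]
        for epoch in range(1, config.max_iterations + 1):
            if not np.isfinite(loss):
                raise TrainingDivergenceError("non-finite training loss", epoch=epoch)
            val_loss, _ = lg_val(w)
            if val_loss < best_val - 1e-12:
                best_val, best_w, since = val_loss, w.copy(), 0
            else:
                since += 1
                if since >= config.patience:
                    break
            if loss <= config.target_mse:
                best_w = w.copy()
                break
            sign_change = grad * prev_grad
            steps = np.where(
                sign_change > 0,
                np.minimum(steps * config.rprop_increase, config.rprop_step_max),
                np.where(
                    sign_change < 0,
                    np.maximum(steps * config.rprop_decrease, config.rprop_step_min),
                    steps,
                ),
            )
            update_grad = np.where(sign_change < 0, 0.0, grad)
            w_new = w - np.sign(update_grad) * steps
            new_loss, new_grad = lg_fit(w_new)
            if new_loss <= loss:
                w = w_new
                prev_grad = update_grad
                loss, grad = new_loss, new_grad
            else:
                steps = np.maximum(steps * config.rprop_decrease, config.rprop_step_min)
                prev_grad = np.zeros_like(w)
            log.append((epoch, loss))
        w_final = best_w
    else:
        lg = _loss_grad_factory(X, y, hidden, output_activation)
        w_final, log = _rprop_train(X, y, w0, config, lg)

    w1, b1, w2, b2 = _unpack(w_final, n_in, hidden)
    return AnnModel(
        response_name=response,
        w1=w1.copy(), b1=b1.copy(), w2=w2.copy(), b2=float(b2),
        scaling=scaling,
        output_activation=output_activation,
        nc_encoding=config.nc_encoding,
        seed=config.seed,
        training_log=log,
    )


def split_fit_r2(dataset: FormulationDataset, response: str,
                 config: TrainConfig) -> tuple[AnnModel, float | None, float | None]:
    """Split, train, and score one network; R2 values on the fraction scale.

    Returns (model, train_r2, test_r2); an R2 is None when that split's
    observed values are constant (undefined coefficient of determination).
    """
    from .errors import DegenerateInputError
    from .model_quality import r_squared

    train, test = split_dataset(dataset, config.split_fraction, config.seed)
    model = train_ann(train, response, config)

    def _r2(part):
        frame = part.to_frame()
        y = frame[response].to_numpy(dtype=float)
        try:
            return r_squared(y, model.predict_frame(frame)) / 100.0
        except DegenerateInputError:
            return None

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        return model, _r2(train), _r2(test)


def best_over_seeds(dataset: FormulationDataset, response: str, seeds,
                    config_base: TrainConfig | None = None,
                    stop_at: float | None = None) -> dict:
    """Best split/seed by min(train R2, test R2) over a fixed seed set.

    Seeds whose test slice is constant (undefined R2) are skipped.  When
    ``stop_at`` is given the scan ends early once both R2 reach it.
    """
    from dataclasses import replace

    if config_base is None:
        config_base = TrainConfig(smart_stop=False)
    best = None
    for seed in seeds:
        config = replace(config_base, seed=seed)
        model, train_r2, test_r2 = split_fit_r2(dataset, response, config)
        if train_r2 is None or test_r2 is None:
            continue
        score = min(train_r2, test_r2)
        if best is None or score > best["score"]:
            best = {"score": score, "seed": seed, "train_r2": train_r2,
                    "test_r2": test_r2, "model": model}
        if stop_at is not None and best["score"] >= stop_at:
            break
    if best is None:
        raise DomainError(
            f"no seed produced a well-defined train/test R2 for {response!r}"
        )
    return best
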