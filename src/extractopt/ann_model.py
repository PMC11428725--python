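"""Feed-forward MLP (3 inputs -> H hidden -> 3 outputs) trained by
Levenberg-Marquardt with a 70/15/15 split and validation-based early stopping.

The network uses a logistic sigmoid transfer on both the hidden and the
output layer, so inputs and targets are min-max scaled into [0.1, 0.9]
(avoiding output-saturation at the observed extremes).  Training minimizes
the squared error on the training subset with damped Gauss-Newton updates

    (J'J + mu I) delta = J' e

where J is the backpropagated Jacobian of the residuals; mu shrinks after an
accepted step and grows after a rejected one.  After every epoch the
validation MSE is recorded and the weights at the epoch with minimum
validation MSE are the ones reported (early stopping).

For a 27-run factorial dataset the 70/15/15 split gives 19 training, 4
validation and 4 test runs; membership is randomized by seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ResponseTable

__all__ = [
    "TrainingFailure",
    "MinMaxScaler",
    "MLPParams",
    "TrainConfig",
    "TrainHistory",
    "MLPModel",
    "forward",
    "jacobian",
    "train_lm",
    "topology_search",
    "error_histogram",
]

MU_MAX = 1e10


class TrainingFailure(RuntimeError):
    """Raised when no damped step is ever accepted (mu overflow at epoch 1)."""

    def __init__(self, message: str, history: "TrainHistory | None" = None):
        super().__init__(message)
        self.history = history


@dataclass
class MinMaxScaler:
    """Per-column min-max scaling onto a fixed output range."""

    mins: np.ndarray
    maxs: np.ndarray
    lo: float = 0.1
    hi: float = 0.9

    @classmethod
    def fit(cls, X: np.ndarray, lo: float = 0.1, hi: float = 0.9) -> "MinMaxScaler":
        X = np.asarray(X, dtype=float)
        mins, maxs = X.min(axis=0), X.max(axis=0)
        if np.any(maxs <= mins):
            raise ValueError("constant column: min-max scaling undefined")
        return cls(mins=mins, maxs=maxs, lo=lo, hi=hi)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.lo + (X - self.mins) / (self.maxs - self.mins) * (self.hi - self.lo)

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        return self.mins + (Z - self.lo) / (self.hi - self.lo) * (self.maxs - self.mins)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


_ACTS = {
    "logistic": (_sigmoid, lambda a: a * (1.0 - a)),  # derivative in terms of output
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass
class MLPParams:
    """Weights and biases of a single-hidden-layer network.

    Shapes: ``w_ih`` (H, n_in), ``b_h`` (H,), ``w_ho`` (n_out, H),
    ``b_o`` (n_out,).
    """

    w_ih: np.ndarray
    b_h: np.ndarray
    w_ho: np.ndarray
    b_o: np.ndarray
    hidden_activation: str = "logistic"
    output_activation: str = "logistic"

    def __post_init__(self) -> None:
        H, n_in = self.w_ih.shape
        n_out = self.w_ho.shape[0]
        if self.b_h.shape != (H,) or self.w_ho.shape != (n_out, H) or self.b_o.shape != (n_out,):
            raise ValueError("inconsistent parameter shapes")

    @property
    def hidden_size(self) -> int:
        return self.w_ih.shape[0]

    @classmethod
    def init_random(
        cls,
        n_in: int,
        hidden: int,
        n_out: int,
        rng: np.random.Generator,
        hidden_activation: str = "logistic",
        output_activation: str = "logistic",
    ) -> "MLPParams":
        # bounded uniform init suits the saturating sigmoid layers
        return cls(
            w_ih=rng.uniform(-0.5, 0.5, size=(hidden, n_in)),
            b_h=rng.uniform(-0.5, 0.5, size=hidden),
            w_ho=rng.uniform(-0.5, 0.5, size=(n_out, hidden)),
            b_o=rng.uniform(-0.5, 0.5, size=n_out),
            hidden_activation=hidden_activation,
            output_activation=output_activation,
        )

    def pack(self) -> np.ndarray:
        return np.concatenate([self.w_ih.ravel(), self.b_h, self.w_ho.ravel(), self.b_o])

    def with_vector(self, theta: np.ndarray) -> "MLPParams":
        H, n_in = self.w_ih.shape
        n_out = self.w_ho.shape[0]
        i = 0
        w_ih = theta[i : i + H * n_in].reshape(H, n_in); i += H * n_in
        b_h = theta[i : i + H]; i += H
        w_ho = theta[i : i + n_out * H].reshape(n_out, H); i += n_out * H
        b_o = theta[i : i + n_out]
        return MLPParams(w_ih, b_h, w_ho, b_o, self.hidden_activation, self.output_activation)


def forward(params: MLPParams, X: np.ndarray) -> np.ndarray:
    """Network outputs for scaled inputs ``X`` of shape (n, n_in)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    act_h, _ = _ACTS[params.hidden_activation]
    act_o, _ = _ACTS[params.output_activation]
    hidden = act_h(X @ params.w_ih.T + params.b_h)
    return act_o(hidden @ params.w_ho.T + params.b_o)


def jacobian(params: MLPParams, X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals e = (Y - f(X)).ravel() and their Jacobian de/dtheta.

    Backpropagated analytically; shape of J is (n * n_out, n_params) in the
    parameter order of :meth:`MLPParams.pack`.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n, n_in = X.shape
    H = params.hidden_size
    n_out = params.w_ho.shape[0]
    act_h, dact_h = _ACTS[params.hidden_activation]
    act_o, dact_o = _ACTS[params.output_activation]

    hidden = act_h(X @ params.w_ih.T + params.b_h)          # (n, H)
    out = act_o(hidden @ params.w_ho.T + params.b_o)        # (n, n_out)
    e = (Y - out).ravel()

    go = dact_o(out)                                        # (n, n_out) s'(o_k)
    gh = dact_h(hidden)                                     # (n, H)     s'(z_i)

    eye_o = np.eye(n_out)
    # d out[n,k] / d w_ho[j,i] = go[n,k] * delta_kj * hidden[n,i]
    J_who = np.einsum("nk,kj,ni->nkji", go, eye_o, hidden)  # (n, n_out, n_out, H)
    J_bo = np.einsum("nk,kj->nkj", go, eye_o)               # d out[n,k]/d b_o[j]
    # chain to the hidden layer: d out[n,k]/d z[n,i] = go[n,k] w_ho[k,i] gh[n,i]
    delta = np.einsum("nk,ki,ni->nki", go, params.w_ho, gh)  # (n, n_out, H)
    J_wih = np.einsum("nki,nm->nkim", delta, X)             # (n, n_out, H, n_in)
    J_bh = delta                                            # (n, n_out, H)

    n_params = params.pack().size
    J = np.empty((n * n_out, n_params))
    i = 0
    J[:, i : i + H * n_in] = J_wih.reshape(n * n_out, H * n_in); i += H * n_in
    J[:, i : i + H] = J_bh.reshape(n * n_out, H); i += H
    J[:, i : i + n_out * H] = J_who.reshape(n * n_out, n_out * H); i += n_out * H
    J[:, i : i + n_out] = J_bo.reshape(n * n_out, n_out)
    # residual is target minus output, so de/dtheta = -dout/dtheta
    return e, -J


@dataclass
class TrainConfig:
    """Levenberg-Marquardt training settings."""

    hidden_size: int = 10
    seed: int = 0
    mu_init: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    max_epochs: int = 1000
    patience: int = 6
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    hidden_activation: str = "logistic"
    output_activation: str = "logistic"
    scale_range: tuple[float, float] = (0.1, 0.9)


@dataclass
class TrainHistory:
    """Per-epoch MSE traces (scaled units) and the early-stopping outcome."""

    mse_train: list[float] = field(default_factory=list)
    mse_val: list[float] = field(default_factory=list)
    mse_test: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0
    subset_r: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self.mse_train) + 1),
                "mse_train": self.mse_train,
                "mse_val": self.mse_val,
                "mse_test": self.mse_test,
            }
        )


def split_indices(n: int, fractions: tuple[float, float, float], rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random train/validation/test membership; 27 runs -> 19/4/4."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    perm = rng.permutation(n)
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


@dataclass
class MLPModel:
    """A trained network with its scalers, configuration and history."""

    params: MLPParams
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    config: TrainConfig
    history: TrainHistory
    factor_names: tuple[str, ...]
    response_names: tuple[str, ...]
    split: dict[str, np.ndarray] = field(default_factory=dict)

    def predict(self, X_natural: np.ndarray) -> np.ndarray:
        """Predict responses (natural assay units) from natural-unit inputs."""
        Z = self.x_scaler.transform(np.atleast_2d(X_natural))
        return self.y_scaler.inverse(forward(self.params, Z))

    def save(self, path: str | Path) -> None:
        doc = {
            "factor_names": list(self.factor_names),
            "response_names": list(self.response_names),
            "config": asdict(self.config),
            "params": {
                "w_ih": self.params.w_ih.tolist(),
                "b_h": self.params.b_h.tolist(),
                "w_ho": self.params.w_ho.tolist(),
                "b_o": self.params.b_o.tolist(),
                "hidden_activation": self.params.hidden_activation,
                "output_activation": self.params.output_activation,
            },
            "x_scaler": {"mins": self.x_scaler.mins.tolist(), "maxs": self.x_scaler.maxs.tolist(),
                         "lo": self.x_scaler.lo, "hi": self.x_scaler.hi},
            "y_scaler": {"mins": self.y_scaler.mins.tolist(), "maxs": self.y_scaler.maxs.tolist(),
                         "lo": self.y_scaler.lo, "hi": self.y_scaler.hi},
            "split": {k: v.tolist() for k, v in self.split.items()},
            "history": {
                "mse_train": self.history.mse_train,
                "mse_val": self.history.mse_val,
                "mse_test": self.history.mse_test,
                "best_epoch": self.history.best_epoch,
                "stopped_epoch": self.history.stopped_epoch,
                "subset_r": self.history.subset_r,
            },
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        doc = json.loads(Path(path).read_text())
        p = doc["params"]
        cfg = doc["config"]
        cfg["split"] = tuple(cfg["split"])
        cfg["scale_range"] = tuple(cfg["scale_range"])
        hist = doc["history"]
        return cls(
            params=MLPParams(
                np.array(p["w_ih"]), np.array(p["b_h"]), np.array(p["w_ho"]), np.array(p["b_o"]),
                p["hidden_activation"], p["output_activation"],
            ),
            x_scaler=MinMaxScaler(np.array(doc["x_scaler"]["mins"]), np.array(doc["x_scaler"]["maxs"]),
                                  doc["x_scaler"]["lo"], doc["x_scaler"]["hi"]),
            y_scaler=MinMaxScaler(np.array(doc["y_scaler"]["mins"]), np.array(doc["y_scaler"]["maxs"]),
                                  doc["y_scaler"]["lo"], doc["y_scaler"]["hi"]),
            config=TrainConfig(**cfg),
            history=TrainHistory(hist["mse_train"], hist["mse_val"], hist["mse_test"],
                                 hist["best_epoch"], hist["stopped_epoch"], hist["subset_r"]),
            factor_names=tuple(doc["factor_names"]),
            response_names=tuple(doc["response_names"]),
            split={k: np.array(v, dtype=int) for k, v in doc["split"].items()},
        )


def _mse(params: MLPParams, X: np.ndarray, Y: np.ndarray) -> float:
    if len(X) == 0:
        return float("nan")
    return float(np.mean((Y - forward(params, X)) ** 2))


def _pooled_r(params: MLPParams, X: np.ndarray, Y: np.ndarray) -> float:
    out = forward(params, X).ravel()
    tgt = np.asarray(Y).ravel()
    if tgt.size < 2 or np.std(tgt) == 0 or np.std(out) == 0:
        return float("nan")
    return float(np.corrcoef(tgt, out)[0, 1])


DEFAULT_ANN_RESPONSES: tuple[str, ...] = ("dpph", "frap", "tpc")


def train_lm(
    table: ResponseTable,
    responses: Sequence[str] = DEFAULT_ANN_RESPONSES,
    config: TrainConfig | None = None,
) -> MLPModel:
    """Train the network on a run table by Levenberg-Marquardt.

    Inputs are the natural-unit factor settings; targets are the named
    response means.  Both are min-max scaled into the configured range.
    Returns the model with the weights of the best-validation epoch.
    """
    config = config or TrainConfig()
    if len(table) < 9:
        raise ValueError("need at least 9 runs to split and train")
    lo, hi = config.scale_range
    X_nat = table.data[list(table.factor_names)].to_numpy(dtype=float)
    Y_nat = np.column_stack([table.response(r) for r in responses])
    x_scaler = MinMaxScaler.fit(X_nat, lo, hi)
    y_scaler = MinMaxScaler.fit(Y_nat, lo, hi)
    X = x_scaler.transform(X_nat)
    Y = y_scaler.transform(Y_nat)

    rng = np.random.default_rng(config.seed)
    i_train, i_val, i_test = split_indices(len(table), config.split, rng)
    Xtr, Ytr = X[i_train], Y[i_train]

    params = MLPParams.init_random(
        X.shape[1], config.hidden_size, Y.shape[1], rng,
        config.hidden_activation, config.output_activation,
    )
    theta = params.pack()
    mu = config.mu_init
    history = TrainHistory()
    best_val = np.inf
    best_theta = theta.copy()
    best_epoch = 0
    epochs_since_best = 0
    any_accepted = False

    e, J = jacobian(params.with_vector(theta), Xtr, Ytr)
    sse = float(e @ e)
    n_params = theta.size
    eye = np.eye(n_params)

    epoch = 0
    while epoch < config.max_epochs:
        accepted = False
        while mu <= MU_MAX:
            try:
                delta = np.linalg.solve(J.T @ J + mu * eye, -J.T @ e)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            cand = theta + delta
            e_new, _ = jacobian(params.with_vector(cand), Xtr, Ytr)
            sse_new = float(e_new @ e_new)
            if sse_new < sse:
                theta = cand
                sse = sse_new
                mu = max(mu * config.mu_dec, 1e-20)
                accepted = True
                any_accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            if not any_accepted:
                raise TrainingFailure(
                    "Levenberg-Marquardt damping overflowed before any step was accepted",
                    history,
                )
            break  # mu saturated: converged on the training subset
        epoch += 1
        cur = params.with_vector(theta)
        history.mse_train.append(_mse(cur, Xtr, Ytr))
        history.mse_val.append(_mse(cur, X[i_val], Y[i_val]))
        history.mse_test.append(_mse(cur, X[i_test], Y[i_test]))
        val = history.mse_val[-1]
        if not np.isfinite(val):  # no validation subset: stop on training MSE
            val = history.mse_train[-1]
        if val < best_val:
            best_val = val
            best_theta = theta.copy()
            best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best > config.patience:
                break
        e, J = jacobian(cur, Xtr, Ytr)

    history.best_epoch = best_epoch
    history.stopped_epoch = epoch
    final = params.with_vector(best_theta)
    history.subset_r = {
        "train": _pooled_r(final, Xtr, Ytr),
        "validation": _pooled_r(final, X[i_val], Y[i_val]),
        "test": _pooled_r(final, X[i_test], Y[i_test]),
        "all": _pooled_r(final, X, Y),
    }
    return MLPModel(
        params=final,
        x_scaler=x_scaler,
        y_scaler=y_scaler,
        config=config,
        history=history,
        factor_names=table.factor_names,
        response_names=tuple(responses),
        split={"train": i_train, "validation": i_val, "test": i_test},
    )


def _val_r2(model: MLPModel, table: ResponseTable) -> float:
    """Pooled R^2 on the validation subset, scaled units."""
    X = model.x_scaler.transform(table.data[list(model.factor_names)].to_numpy(dtype=float))
    Y = model.y_scaler.transform(
        np.column_stack([table.response(r) for r in model.response_names])
    )
    i = model.split["validation"]
    out = forward(model.params, X[i]).ravel()
    tgt = Y[i].ravel()
    sst = float(((tgt - tgt.mean()) ** 2).sum())
    if sst == 0:
        return float("nan")
    return 1.0 - float(((tgt - out) ** 2).sum()) / sst


def topology_search(
    table: ResponseTable,
    responses: Sequence[str] = DEFAULT_ANN_RESPONSES,
    hidden_sizes: Sequence[int] = range(8, 13),
    seeds: Sequence[int] = range(5),
    base_config: TrainConfig | None = None,
) -> tuple[int, pd.DataFrame]:
    """Train each hidden-layer size over several seeds and pick the best.

    Scores each size by its best validation R^2 across seeds; ties go to the
    smallest network.  Reproducible for fixed seeds.
    """
    base = base_config or TrainConfig()
    rows = []
    for h in hidden_sizes:
        scores = []
        for s in seeds:
            cfg = TrainConfig(**{**asdict(base), "hidden_size": int(h), "seed": int(s)})
            cfg.split = tuple(cfg.split)
            cfg.scale_range = tuple(cfg.scale_range)
            model = train_lm(table, responses, cfg)
            scores.append(_val_r2(model, table))
        rows.append({"hidden_size": int(h), "val_r2_best": float(np.nanmax(scores)),
                     "val_r2_mean": float(np.nanmean(scores))})
    frame = pd.DataFrame(rows)
    best = int(frame.sort_values(["val_r2_best", "hidden_size"], ascending=[False, True])
               .iloc[0]["hidden_size"])
    return best, frame


def error_histogram(
    model: MLPModel,
    table: ResponseTable,
    bins: int = 20,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Residuals (target - output, natural units) binned by data subset.

    Residuals are pooled across the model's responses, so counts across the
    train/validation/test subsets sum to ``n_runs * n_responses``.
    Returns ``(bin_edges, {subset: counts})``.
    """
    X = table.data[list(model.factor_names)].to_numpy(dtype=float)
    Y = np.column_stack([table.response(r) for r in model.response_names])
    resid = Y - model.predict(X)
    edges = np.histogram_bin_edges(resid.ravel(), bins=bins)
    counts = {}
    for subset, idx in model.split.items():
        counts[subset], _ = np.histogram(resid[idx].ravel(), bins=edges)
    return edges, counts
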