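"""Classifier families and their transfer mechanisms.

Two families are supported:

* ``ann`` — a small feed-forward dense network (ReLU hidden layers,
  sigmoid output, dropout between hidden layers, L2 weight decay, Adam,
  binary cross-entropy), implemented here in numpy so that layer freezing
  is a first-class, inspectable operation: frozen layers are simply
  excluded from the update step and remain bitwise identical.
* ``xgb`` — gradient-boosted trees (xgboost); transfer is boosting
  continuation ("partial fit"): the source ensemble is preserved verbatim
  and new trees are fitted on the target chunk starting from the source
  margins.

Both produce a :class:`TransferModel` whose predictions are positive-class
probabilities; with no target observations the transfer model is exactly
the source model.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb

from .records import FeatureTable

ANN = "ann"
XGB = "xgb"


class TrainingError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnConfig:
    """Architecture and optimisation settings for the dense network.

    ``layer_widths`` lists all dense layers including the 1-unit output;
    ``dropout_rates`` apply after the corresponding hidden activations.
    ``frozen_layers`` (0-based dense-layer indices) only matters in the
    transfer phase.
    """

    layer_widths: Tuple[int, ...] = (64, 32, 1)
    dropout_rates: Tuple[float, ...] = (0.2, 0.2)
    l2_strength: float = 1e-4
    epochs: int = 100
    optimizer_name: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 64
    early_stopping_patience: int = 10
    frozen_layers: frozenset = frozenset()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_widths[-1] != 1:
            raise ValueError("output layer width must be 1")
        if any(not (0.0 <= d < 1.0) for d in self.dropout_rates):
            raise ValueError("dropout rates must be in [0,1)")
        if len(self.dropout_rates) > len(self.layer_widths) - 1:
            raise ValueError("more dropout rates than hidden layers")
        if self.l2_strength < 0:
            raise ValueError("l2_strength must be >= 0")
        if self.optimizer_name not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer_name!r}")

    @property
    def n_layers(self) -> int:
        return len(self.layer_widths)


DEFAULT_XGB_PARAMS: Dict[str, object] = {
    "max_depth": 4,
    "eta": 0.1,
    "min_child_weight": 1,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
    "lambda": 1.0,
    "objective": "binary:logistic",
    "eval_metric": "logloss",
    "tree_method": "exact",
    "nthread": 1,
    "seed": 0,
}
DEFAULT_XGB_ROUNDS = 150
DEFAULT_NEW_TREES = 50


# --------------------------------------------------------------------------
# dense network internals
# --------------------------------------------------------------------------

class _Scaler:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        self.std = np.maximum(X.std(axis=0), 1e-8)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


class _DenseNet:
    """Plain numpy MLP with per-layer freezing."""

    def __init__(self, d_in: int, cfg: AnnConfig):
        rng = np.random.default_rng(cfg.rng_seed)
        widths = [d_in] + list(cfg.layer_widths)
        self.W: List[np.ndarray] = []
        self.b: List[np.ndarray] = []
        for a, b in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (a + b))  # Glorot uniform
            self.W.append(rng.uniform(-limit, limit, (a, b)))
            self.b.append(np.zeros(b))
        self.cfg = cfg

    # forward returning logits and caches for backprop
    def _forward(self, X, rng=None, dropout=False):
        h = X
        caches = []
        n_hidden = len(self.W) - 1
        for l in range(n_hidden):
            z = h @ self.W[l] + self.b[l]
            a = np.maximum(z, 0.0)
            mask = None
            rate = (self.cfg.dropout_rates[l]
                    if l < len(self.cfg.dropout_rates) else 0.0)
            if dropout and rate > 0.0:
                mask = (rng.random(a.shape) >= rate) / (1.0 - rate)
                a = a * mask
            caches.append((h, z, mask))
            h = a
        logits = (h @ self.W[-1] + self.b[-1]).ravel()
        caches.append((h, None, None))
        return logits, caches

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X)
        return 1.0 / (1.0 + np.exp(-logits))

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        logits, _ = self._forward(X)
        # numerically stable BCE with logits
        return float(np.mean(
            np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
        ))

    def _gradients(self, X, y, rng):
        n = len(X)
        logits, caches = self._forward(X, rng=rng, dropout=True)
        p = 1.0 / (1.0 + np.exp(-logits))
        delta = ((p - y) / n)[:, None]
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        h_last = caches[-1][0]
        gW[-1] = h_last.T @ delta + self.cfg.l2_strength * self.W[-1]
        gb[-1] = delta.sum(axis=0)
        grad_h = delta @ self.W[-1].T
        for l in range(len(self.W) - 2, -1, -1):
            h_in, z, mask = caches[l]
            if mask is not None:
                grad_h = grad_h * mask
            grad_z = grad_h * (z > 0)
            gW[l] = h_in.T @ grad_z + self.cfg.l2_strength * self.W[l]
            gb[l] = grad_z.sum(axis=0)
            grad_h = grad_z @ self.W[l].T
        return gW, gb

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: Optional[np.ndarray] = None,
        y_val: Optional[np.ndarray] = None,
        frozen: frozenset = frozenset(),
    ) -> None:
        cfg = self.cfg
        if frozen and len(frozen) >= len(self.W):
            raise ValueError("all layers frozen: nothing to train")
        rng = np.random.default_rng([cfg.rng_seed, 1])
        lr = cfg.learning_rate
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        best_val = np.inf
        best_params = None
        patience_left = cfg.early_stopping_patience
        n = len(X)
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                gW, gb = self._gradients(X[idx], y[idx], rng)
                t += 1
                for l in range(len(self.W)):
                    if l in frozen:
                        continue
                    if cfg.optimizer_name == "sgd":
                        self.W[l] -= lr * gW[l]
                        self.b[l] -= lr * gb[l]
                        continue
                    mW[l] = beta1 * mW[l] + (1 - beta1) * gW[l]
                    vW[l] = beta2 * vW[l] + (1 - beta2) * gW[l] ** 2
                    mb[l] = beta1 * mb[l] + (1 - beta1) * gb[l]
                    vb[l] = beta2 * vb[l] + (1 - beta2) * gb[l] ** 2
                    mh = mW[l] / (1 - beta1 ** t)
                    vh = vW[l] / (1 - beta2 ** t)
                    self.W[l] -= lr * mh / (np.sqrt(vh) + eps)
                    mhb = mb[l] / (1 - beta1 ** t)
                    vhb = vb[l] / (1 - beta2 ** t)
                    self.b[l] -= lr * mhb / (np.sqrt(vhb) + eps)
            train_loss = self.loss(X[order[:min(n, 512)]],
                                   y[order[:min(n, 512)]])
            if not np.isfinite(train_loss):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={lr}, l2={cfg.l2_strength})"
                )
            if X_val is not None and cfg.early_stopping_patience > 0:
                val_loss = self.loss(X_val, y_val)
                if val_loss < best_val - 1e-6:
                    best_val = val_loss
                    best_params = ([w.copy() for w in self.W],
                                   [b.copy() for b in self.b])
                    patience_left = cfg.early_stopping_patience
                else:
                    patience_left -= 1
                    if patience_left <= 0:
                        break
        if best_params is not None:
            self.W, self.b = best_params


# --------------------------------------------------------------------------
# the transfer model container
# --------------------------------------------------------------------------

@dataclass
class TransferModel:
    """A fitted classifier with an optional fine-tuned transfer phase."""

    family: str
    source_state: dict
    transfer_state: Optional[dict] = None
    mechanism: str = "freeze_layers"
    provenance: dict = field(default_factory=dict)

    def _predict_with(self, state: dict, X: np.ndarray) -> np.ndarray:
        if self.family == ANN:
            net: _DenseNet = state["net"]
            return net.predict_proba(state["scaler"](X))
        booster: xgb.Booster = state["booster"]
        return booster.predict(xgb.DMatrix(X))

    def _as_X(self, data) -> np.ndarray:
        if isinstance(data, FeatureTable):
            return data.X
        return np.asarray(data, dtype=float)

    def predict(self, data) -> np.ndarray:
        """Positive-class probabilities of the current (transferred) model."""
        state = self.transfer_state or self.source_state
        return self._predict_with(state, self._as_X(data))

    def predict_source(self, data) -> np.ndarray:
        """Probabilities of the untouched source-phase model."""
        return self._predict_with(self.source_state, self._as_X(data))

    @property
    def n_target_observations(self) -> int:
        return int(self.provenance.get("n_target_observations", 0))


def _check_trainable(table: FeatureTable) -> None:
    y = table.y
    if len(np.unique(y)) < 2:
        raise TrainingError("degenerate training set: single-class labels")


# --------------------------------------------------------------------------
# ANN family
# --------------------------------------------------------------------------

def train_ann(
    table: FeatureTable,
    cfg: AnnConfig,
    validation: Optional[FeatureTable] = None,
    provenance: Optional[dict] = None,
) -> TransferModel:
    """Fit the dense network on a (balanced) training table."""
    _check_trainable(table)
    if validation is not None:
        table.require_same_schema(validation)
    X, y = table.X, table.y.astype(float)
    scaler = _Scaler(X)
    net = _DenseNet(X.shape[1], cfg)
    Xv = yv = None
    if validation is not None and len(validation):
        Xv, yv = scaler(validation.X), validation.y.astype(float)
    net.fit(scaler(X), y, Xv, yv)
    prov = {"source_species": table.df["species"].iloc[0],
            "n_source_observations": len(table),
            "n_target_observations": 0}
    prov.update(provenance or {})
    return TransferModel(
        family=ANN,
        source_state={"net": net, "scaler": scaler, "cfg": cfg,
                      "feature_names": table.feature_names},
        mechanism="freeze_layers",
        provenance=prov,
    )


def transfer_ann(
    model: TransferModel,
    target_chunk: FeatureTable,
    cfg: Optional[AnnConfig] = None,
    validation: Optional[FeatureTable] = None,
) -> TransferModel:
    """Fine-tune on a target chunk with the configured layers frozen.

    The source model's parameters are never mutated; the returned model
    carries both phases.  Feature standardisation re-uses the source
    training statistics so frozen layers keep their meaning.  When a
    (target-domain) validation table is given, fine-tuning early-stops on
    its loss, which curbs forgetting of the source phase.
    """
    if model.family != ANN:
        raise ValueError("transfer_ann requires an ANN model")
    src = model.source_state
    if target_chunk.feature_names != src["feature_names"]:
        raise ValueError("target chunk schema differs from source model")
    cfg = cfg if cfg is not None else src["cfg"]
    if len(cfg.frozen_layers) >= len(src["net"].W):
        raise ValueError("all layers frozen: nothing to train")
    net = copy.deepcopy(src["net"])
    net.cfg = cfg
    if len(target_chunk) and cfg.epochs > 0:
        _check_trainable(target_chunk)
        X = src["scaler"](target_chunk.X)
        Xv = yv = None
        if validation is not None and len(validation):
            Xv = src["scaler"](validation.X)
            yv = validation.y.astype(float)
        net.fit(X, target_chunk.y.astype(float), Xv, yv,
                frozen=cfg.frozen_layers)
    prov = dict(model.provenance)
    prov.update({
        "target_species": (target_chunk.df["species"].iloc[0]
                           if len(target_chunk) else None),
        "n_target_observations": len(target_chunk),
    })
    return TransferModel(
        family=ANN,
        source_state=src,
        transfer_state={"net": net, "scaler": src["scaler"], "cfg": cfg,
                        "feature_names": src["feature_names"]},
        mechanism="freeze_layers",
        provenance=prov,
    )


# --------------------------------------------------------------------------
# XGB family
# --------------------------------------------------------------------------

def train_xgb(
    table: FeatureTable,
    params: Optional[Dict[str, object]] = None,
    validation: Optional[FeatureTable] = None,
    num_boost_round: int = DEFAULT_XGB_ROUNDS,
    early_stopping_rounds: Optional[int] = None,
    provenance: Optional[dict] = None,
) -> TransferModel:
    """Fit a gradient-boosted tree ensemble."""
    _check_trainable(table)
    if validation is not None:
        table.require_same_schema(validation)
    merged = dict(DEFAULT_XGB_PARAMS)
    merged.update(params or {})
    dtrain = xgb.DMatrix(table.X, label=table.y)
    evals = []
    if validation is not None and len(validation):
        evals = [(xgb.DMatrix(validation.X, label=validation.y), "val")]
    booster = xgb.train(
        merged, dtrain, num_boost_round=num_boost_round,
        evals=evals if early_stopping_rounds else [],
        early_stopping_rounds=early_stopping_rounds,
        verbose_eval=False,
    )
    prov = {"source_species": table.df["species"].iloc[0],
            "n_source_observations": len(table),
            "n_target_observations": 0}
    prov.update(provenance or {})
    return TransferModel(
        family=XGB,
        source_state={"booster": booster, "params": merged,
                      "feature_names": table.feature_names},
        mechanism="boosting_continuation",
        provenance=prov,
    )


def transfer_xgb(
    model: TransferModel,
    target_chunk: FeatureTable,
    n_new_trees: int = DEFAULT_NEW_TREES,
) -> TransferModel:
    """Boosting continuation on a target chunk.

    The source trees are preserved verbatim; ``n_new_trees`` additional
    trees are fitted on the chunk starting from the source ensemble's
    margins, with the learning rate halved for low-variance updates.
    """
    if model.family != XGB:
        raise ValueError("transfer_xgb requires an XGB model")
    if len(target_chunk) == 0:
        raise ValueError("empty target chunk")
    src = model.source_state
    if target_chunk.feature_names != src["feature_names"]:
        raise ValueError("target chunk schema differs from source model")
    params = dict(src["params"])
    params["eta"] = float(params.get("eta", 0.3)) / 2.0
    dchunk = xgb.DMatrix(target_chunk.X, label=target_chunk.y)
    continued = xgb.train(
        params, dchunk, num_boost_round=n_new_trees,
        xgb_model=src["booster"].copy(), verbose_eval=False,
    )
    prov = dict(model.provenance)
    prov.update({
        "target_species": target_chunk.df["species"].iloc[0],
        "n_target_observations": len(target_chunk),
        "n_new_trees": n_new_trees,
    })
    return TransferModel(
        family=XGB,
        source_state=src,
        transfer_state={"booster": continued, "params": params,
                        "feature_names": src["feature_names"]},
        mechanism="boosting_continuation",
        provenance=prov,
    )


def tree_count(model: TransferModel, which: str = "target") -> int:
    state = (model.transfer_state if which == "target" and model.transfer_state
             else model.source_state)
    return state["booster"].num_boosted_rounds()


# --------------------------------------------------------------------------
# grid search
# --------------------------------------------------------------------------

def grid_search(
    family: str,
    table: FeatureTable,
    validation: FeatureTable,
    grid: Dict[str, Sequence],
    base: Optional[object] = None,
    on_fit: Optional[Callable[[dict], None]] = None,
) -> Tuple[dict, pd.DataFrame]:
    """Exhaustive hyperparameter search scored by validation accuracy.

    Ties break to the first point in declared grid order.  Returns the
    best parameter dict and the full results table.
    """
    if not grid:
        raise ValueError("empty grid")
    keys = list(grid)
    rows = []
    best: Optional[dict] = None
    best_acc = -np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        point = dict(zip(keys, combo))
        if on_fit is not None:
            on_fit(point)
        if family == ANN:
            cfg = replace(base or AnnConfig(), **point)
            mdl = train_ann(table, cfg, validation)
        elif family == XGB:
            params = dict(base or {})
            params.update(point)
            mdl = train_xgb(table, params, validation)
        else:
            raise ValueError(f"unknown family {family!r}")
        pred = mdl.predict(validation) >= 0.5
        acc = float((pred == validation.y.astype(bool)).mean())
        rows.append({**point, "validation_accuracy": acc})
        if acc > best_acc:
            best_acc = acc
            best = point
    return best, pd.DataFrame(rows)
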