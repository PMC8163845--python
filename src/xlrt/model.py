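"""Siamese multi-task network for crosslinked-peptide retention times.

The model takes the label-encoded sequences of the two peptides of a
crosslink.  Both branches share one embedding layer and one recurrent
layer (GRU or LSTM); the branch outputs are merged — additively by
default, which makes every prediction invariant to the order of the two
peptides — and feed one subnetwork per prediction task.  Each subnetwork
is a pyramid of three fully connected layers with dropout and batch
normalization between them.  The reversed-phase (RP) head has a linear
output trained with mean squared error; fraction heads (SCX, hSAX) emit
one sigmoid per fraction position and are trained with binary
cross-entropy against the cumulative ordinal encoding.  The overall
training loss is the weighted sum of the per-task losses.

In ``linear`` mode a single branch feeds the subnetworks directly, so the
same weights also predict retention of individual (linear) peptides — this
is what provides the alpha/beta single-peptide predictions used as
rescoring features.
"""

from __future__ import annotations

import copy
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import (
    Adam,
    BatchNorm,
    Dense,
    Dropout,
    Embedding,
    GRU,
    LSTM,
    Tensor,
    bce_with_logits,
    combine,
    mse_loss,
)
from .encoding import decode_ordinal, encode_ordinal

__all__ = ["SiameseRTRegressor", "ModelConfig", "total_loss"]

DEFAULT_N_FRACTIONS = {"scx": 9, "hsax": 10}

ORDINAL_TASKS = ("scx", "hsax")


def total_loss(
    predictions: Mapping[str, np.ndarray],
    truths: Mapping[str, np.ndarray],
    task_weights: Mapping[str, float],
) -> float:
    """Weighted sum of per-task losses: ``w_rp*MSE + w_scx*BCE + w_hsax*BCE``.

    ``predictions['rp']`` and ``truths['rp']`` are retention times; ordinal
    tasks are given as per-position probability matrices (predictions) and
    integer fractions or encoded matrices (truths).  Tasks absent from
    either mapping contribute zero.
    """
    for task, w in task_weights.items():
        if w < 0:
            raise ValueError(f"negative weight for task {task!r}")
    loss = 0.0
    for task, w in task_weights.items():
        if task not in predictions or task not in truths:
            continue
        pred = np.asarray(predictions[task], dtype=np.float64)
        truth = np.asarray(truths[task])
        if task == "rp":
            loss += w * float(np.mean((pred - truth.astype(np.float64)) ** 2))
        else:
            if truth.ndim == 1:  # integer fractions -> cumulative encoding
                truth = np.stack([encode_ordinal(int(f), pred.shape[1]) for f in truth])
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(truth >= 0.5, -np.log(pred), -np.log(1.0 - pred))
            term = np.where(
                (truth >= 0.5) & (pred == 1.0) | (truth < 0.5) & (pred == 0.0), 0.0, term
            )
            loss += w * float(np.mean(term))
    return loss


@dataclass
class ModelConfig:
    """All architecture and training hyper-parameters in one place."""

    max_len: int = 30
    embedding_dim: int = 50
    recurrent_type: str = "GRU"
    recurrent_units: int = 50
    use_batch_norm: bool = True
    combination: str = "add"
    tasks: tuple[str, ...] = ("rp", "scx", "hsax")
    n_fractions: dict = field(default_factory=lambda: dict(DEFAULT_N_FRACTIONS))
    subnet_layer_sizes: tuple[int, ...] = (50, 20, 10)
    dropout_rate: float = 0.1
    task_weights: dict = field(default_factory=dict)
    learning_rate: float = 2e-3
    epochs: int = 50
    batch_size: int = 128
    seed: int = 0
    mode: str = "crosslink"

    def build(self, vocab_size: int) -> "SiameseRTRegressor":
        return SiameseRTRegressor(vocab_size=vocab_size, **self.__dict__)


class _Network:
    """Layer container; separates the shared trunk from the task heads."""

    def __init__(self, params: dict, rng: np.random.Generator):
        p = params
        self.embedding = Embedding(p["vocab_size"], p["embedding_dim"], rng)
        rec_cls = {"GRU": GRU, "LSTM": LSTM}[p["recurrent_type"]]
        self.recurrent = rec_cls(p["embedding_dim"], p["recurrent_units"], rng)
        self.bn_recurrent = BatchNorm(p["recurrent_units"]) if p["use_batch_norm"] else None
        head_in = p["recurrent_units"] * (2 if p["combination"] == "concatenate" else 1)
        self.heads: dict[str, list] = {}
        self.out_layers: dict[str, Dense] = {}
        for task in p["tasks"]:
            layers, n_in = [], head_in
            for size in p["subnet_layer_sizes"]:
                layers.append(
                    (
                        Dense(n_in, size, rng),
                        BatchNorm(size) if p["use_batch_norm"] else None,
                        Dropout(p["dropout_rate"]),
                    )
                )
                n_in = size
            self.heads[task] = layers
            n_out = 1 if task == "rp" else p["n_fractions"][task]
            self.out_layers[task] = Dense(n_in, n_out, rng)

    # -- traversal --------------------------------------------------------
    def shared_layers(self) -> dict:
        out = {"embedding": self.embedding, "recurrent": self.recurrent}
        if self.bn_recurrent is not None:
            out["bn_recurrent"] = self.bn_recurrent
        return out

    def named_layers(self) -> dict:
        out = dict(self.shared_layers())
        for task, layers in self.heads.items():
            for i, (dense, bn, _) in enumerate(layers):
                out[f"{task}.dense{i}"] = dense
                if bn is not None:
                    out[f"{task}.bn{i}"] = bn
            out[f"{task}.out"] = self.out_layers[task]
        return out

    def parameters(self):
        params = []
        for layer in self.named_layers().values():
            params.extend(layer.parameters())
        return params

    def state(self) -> dict[str, np.ndarray]:
        out = {}
        for lname, layer in self.named_layers().items():
            for pname, arr in layer.state_arrays().items():
                out[f"{lname}/{pname}"] = arr.copy()
        return out

    def load_state(self, state: Mapping[str, np.ndarray], strict: bool = True) -> None:
        for lname, layer in self.named_layers().items():
            for pname, arr in layer.state_arrays().items():
                key = f"{lname}/{pname}"
                if key not in state:
                    if strict:
                        raise KeyError(f"missing weight {key}")
                    continue
                src = np.asarray(state[key])
                if src.shape != arr.shape:
                    if strict:
                        raise ValueError(f"shape mismatch for {key}")
                    continue
                layer.load_state_arrays({pname: src})

    # -- forward ----------------------------------------------------------
    def branch(self, idx: np.ndarray, training: bool) -> Tensor:
        mask = (idx > 0).astype(np.float64)
        h = self.recurrent(self.embedding(idx), mask)
        if self.bn_recurrent is not None:
            h = self.bn_recurrent(h, training)
        return h

    def forward_heads(self, merged: Tensor, training: bool, rng) -> dict[str, Tensor]:
        out = {}
        for task, layers in self.heads.items():
            h = merged
            for dense, bn, drop in layers:
                h = dense(h).relu()
                if bn is not None:
                    h = bn(h, training)
                h = drop(h, training, rng)
            out[task] = self.out_layers[task](h)
        return out


class SiameseRTRegressor(BaseEstimator):
    """Multi-task retention-time predictor for peptide pairs.

    Parameters
    ----------
    vocab_size:
        Size of the embedding table (``alphabet.vocab_size``; integer 0 is
        the padding token).
    max_len:
        Fixed encoded sequence length.
    tasks:
        Subset of ``{"rp", "scx", "hsax"}``; ``rp`` is a regression head,
        the others ordinal-fraction heads of size ``n_fractions[task]``.
    combination:
        How the two branch outputs are merged: ``add`` (default, order
        invariant), ``multiply`` or ``concatenate``.
    task_weights:
        Per-task weights of the combined loss (default 1.0 each; with a
        single task its weight is effectively 1).
    mode:
        ``crosslink`` (two-peptide input) or ``linear`` (single peptide).
    warm_start:
        Reuse the existing network weights in :meth:`fit` (used after
        :meth:`transfer` for fine-tuning).
    """

    def __init__(
        self,
        vocab_size: int = 32,
        max_len: int = 30,
        embedding_dim: int = 50,
        recurrent_type: str = "GRU",
        recurrent_units: int = 50,
        use_batch_norm: bool = True,
        combination: str = "add",
        tasks: Sequence[str] = ("rp", "scx", "hsax"),
        n_fractions: Mapping[str, int] | None = None,
        subnet_layer_sizes: Sequence[int] = (50, 20, 10),
        dropout_rate: float = 0.1,
        task_weights: Mapping[str, float] | None = None,
        learning_rate: float = 2e-3,
        epochs: int = 50,
        batch_size: int = 128,
        seed: int = 0,
        mode: str = "crosslink",
        warm_start: bool = False,
    ):
        self.vocab_size = vocab_size
        self.max_len = max_len
        self.embedding_dim = embedding_dim
        self.recurrent_type = recurrent_type
        self.recurrent_units = recurrent_units
        self.use_batch_norm = use_batch_norm
        self.combination = combination
        self.tasks = tasks
        self.n_fractions = n_fractions
        self.subnet_layer_sizes = subnet_layer_sizes
        self.dropout_rate = dropout_rate
        self.task_weights = task_weights
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        self.mode = mode
        self.warm_start = warm_start

    # -- configuration helpers -------------------------------------------
    def _resolved(self) -> dict:
        tasks = tuple(self.tasks)
        if not tasks:
            raise ValueError("at least one task required")
        for t in tasks:
            if t != "rp" and t not in ORDINAL_TASKS:
                raise ValueError(f"unknown task {t!r}")
        sizes = tuple(self.subnet_layer_sizes)
        if any(b > a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("subnet_layer_sizes must be non-increasing (pyramid)")
        nf = dict(DEFAULT_N_FRACTIONS)
        nf.update(self.n_fractions or {})
        weights = {t: 1.0 for t in tasks}
        weights.update({t: float(w) for t, w in (self.task_weights or {}).items() if t in tasks})
        if any(w < 0 for w in weights.values()):
            raise ValueError("task weights must be positive")
        if self.mode not in ("crosslink", "linear"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.combination not in ("add", "multiply", "concatenate"):
            raise ValueError(f"unknown combination {self.combination!r}")
        return {
            "vocab_size": self.vocab_size,
            "max_len": self.max_len,
            "embedding_dim": self.embedding_dim,
            "recurrent_type": self.recurrent_type,
            "recurrent_units": self.recurrent_units,
            "use_batch_norm": self.use_batch_norm,
            "combination": self.combination,
            "tasks": tasks,
            "n_fractions": {t: int(nf[t]) for t in tasks if t != "rp"},
            "subnet_layer_sizes": sizes,
            "dropout_rate": self.dropout_rate,
            "task_weights": weights,
            "mode": self.mode,
        }

    # -- input handling ---------------------------------------------------
    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X)
        if not np.issubdtype(X.dtype, np.integer):
            raise ValueError("X must contain integer-encoded sequences")
        expected = 3 if self.mode == "crosslink" else 2
        if X.ndim != expected:
            raise ValueError(
                f"{self.mode} mode expects X of ndim {expected}, got shape {X.shape}"
            )
        if X.shape[-1] != self.max_len:
            raise ValueError(f"sequence length {X.shape[-1]} != max_len {self.max_len}")
        if X.min() < 0 or X.max() >= self.vocab_size:
            raise ValueError("token integer outside the model's alphabet")
        if self.mode == "crosslink" and X.shape[1] != 2:
            raise ValueError("crosslink mode expects X of shape (n, 2, max_len)")
        if self.mode == "crosslink" and not (X[:, 1, :].max(axis=1) > 0).all():
            raise ValueError("crosslink mode requires a non-empty second peptide")
        return X

    def _check_y(self, y, n: int, cfg: dict) -> dict[str, np.ndarray]:
        out = {}
        for task in cfg["tasks"]:
            if task not in y:
                raise ValueError(f"missing target for task {task!r}")
            arr = np.asarray(y[task])
            if arr.shape[0] != n:
                raise ValueError(f"target length mismatch for task {task!r}")
            if task == "rp":
                out[task] = arr.astype(np.float64)
            else:
                nf = cfg["n_fractions"][task]
                arr = arr.astype(np.int64)
                if arr.min() < 1 or arr.max() > nf:
                    raise ValueError(
                        f"{task} fractions outside [1, {nf}]; check n_fractions"
                    )
                out[task] = arr
        return out

    # -- loss -------------------------------------------------------------
    def _batch_losses(self, preds: dict, targets: dict, sl: slice | np.ndarray, cfg) -> dict:
        losses = {}
        for task in cfg["tasks"]:
            if task == "rp":
                t = (targets["rp"][sl] - self._rp_mean) / self._rp_std
                losses[task] = mse_loss(preds[task], t.reshape(-1, 1))
            else:
                enc = targets[f"_{task}_enc"][sl]
                losses[task] = bce_with_logits(preds[task], enc)
        return losses

    def _forward(self, X: np.ndarray, training: bool, rng) -> dict[str, Tensor]:
        net = self.network_
        if self.mode == "crosslink":
            merged = combine(
                net.branch(X[:, 0, :], training),
                net.branch(X[:, 1, :], training),
                self.combination,
            )
        else:
            merged = net.branch(X, training)
        return net.forward_heads(merged, training, rng)

    # -- API --------------------------------------------------------------
    def fit(self, X, y, validation_data=None):
        """Train the network; the returned model carries the weights of the
        epoch with the lowest total validation loss.

        ``y`` maps task names to target arrays (``rp``: retention times in
        minutes; ordinal tasks: 1-based fraction integers).  When
        ``validation_data`` is omitted, 10% of the rows are held out for
        epoch selection.
        """
        cfg = self._resolved()
        X = self._check_X(X)
        targets = self._check_y(y, X.shape[0], cfg)
        rng = np.random.default_rng(self.seed)

        if validation_data is None:
            n = X.shape[0]
            n_val = int(np.ceil(0.1 * n))
            perm = rng.permutation(n)
            val_ix, train_ix = perm[:n_val], perm[n_val:]
            Xv = X[val_ix]
            yv = {t: targets[t][val_ix] for t in cfg["tasks"]}
            X = X[train_ix]
            targets = {t: targets[t][train_ix] for t in cfg["tasks"]}
        else:
            Xv, yv = validation_data
            if np.asarray(Xv).shape[0] == 0:
                raise ValueError("validation set is empty; epoch selection undefined")
            Xv = self._check_X(Xv)
            yv = self._check_y(yv, Xv.shape[0], cfg)
        if X.shape[0] == 0:
            raise ValueError("empty training set")

        if self.warm_start and hasattr(self, "network_"):
            net = self.network_
        else:
            net = _Network(cfg, np.random.default_rng(self.seed))
            self.network_ = net
        # target standardization keeps the regression head in a well-scaled range
        if "rp" in cfg["tasks"]:
            self._rp_mean = float(np.mean(targets["rp"]))
            self._rp_std = float(np.std(targets["rp"])) or 1.0
        else:
            self._rp_mean, self._rp_std = 0.0, 1.0
        for task in cfg["tasks"]:
            if task == "rp":
                continue
            nf = cfg["n_fractions"][task]
            targets[f"_{task}_enc"] = np.stack(
                [encode_ordinal(int(f), nf) for f in targets[task]]
            )
            yv[f"_{task}_enc"] = np.stack([encode_ordinal(int(f), nf) for f in yv[task]])

        opt = Adam(net.parameters(), lr=self.learning_rate)
        weights = cfg["task_weights"]
        history: list[dict] = []
        best = (np.inf, -1, None)
        n = X.shape[0]
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            train_acc = {t: 0.0 for t in cfg["tasks"]}
            n_batches = 0
            for start in range(0, n, self.batch_size):
                ix = order[start : start + self.batch_size]
                preds = self._forward(X[ix], True, rng)
                losses = self._batch_losses(preds, targets, ix, cfg)
                loss = None
                for task, l in losses.items():
                    term = weights[task] * l
                    loss = term if loss is None else loss + term
                opt.zero_grad()
                loss.backward()
                opt.step()
                for task, l in losses.items():
                    train_acc[task] += float(l.data)
                n_batches += 1
            row = {"epoch": epoch}
            total_train = 0.0
            for task in cfg["tasks"]:
                row[f"train_{task}"] = train_acc[task] / n_batches
                total_train += weights[task] * row[f"train_{task}"]
            row["train_total"] = total_train
            val_losses = self._eval_losses(Xv, yv, cfg)
            total_val = 0.0
            for task in cfg["tasks"]:
                row[f"val_{task}"] = val_losses[task]
                total_val += weights[task] * val_losses[task]
            row["val_total"] = total_val
            history.append(row)
            if total_val < best[0]:
                best = (total_val, epoch, net.state())
        self.history_ = pd.DataFrame(history)
        self.best_epoch_ = best[1]
        self.best_val_loss_ = best[0]
        if best[2] is not None:
            net.load_state(best[2])
        self._cfg = cfg
        return self

    def _eval_losses(self, X, targets, cfg, chunk: int = 512) -> dict[str, float]:
        rng = np.random.default_rng(0)  # unused in eval mode
        acc = {t: 0.0 for t in cfg["tasks"]}
        n = X.shape[0]
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            preds = self._forward(X[sl], False, rng)
            losses = self._batch_losses(preds, targets, sl, cfg)
            w = (sl.stop - sl.start) / n
            for task, l in losses.items():
                acc[task] += w * float(l.data)
        return acc

    def _predict_from_merged_batches(self, X, single: bool, chunk: int = 1024) -> dict:
        cfg = self._cfg
        rng = np.random.default_rng(0)
        outs: dict[str, list] = {t: [] for t in cfg["tasks"]}
        n = X.shape[0]
        for start in range(0, n, chunk):
            part = X[start : start + chunk]
            if single:
                merged = self.network_.branch(part, False)
                preds = self.network_.forward_heads(merged, False, rng)
            else:
                preds = self._forward(part, False, rng)
            for t in cfg["tasks"]:
                outs[t].append(preds[t].data)
        result: dict[str, np.ndarray] = {}
        for task in cfg["tasks"]:
            raw = np.concatenate(outs[task], axis=0)
            if task == "rp":
                result["rp"] = raw.ravel() * self._rp_std + self._rp_mean
            else:
                probs = 1.0 / (1.0 + np.exp(-raw))
                result[f"{task}_probs"] = probs
                result[task] = np.array([decode_ordinal(p) for p in probs])
        return result

    def predict(self, X) -> dict[str, np.ndarray]:
        """Predict all tasks; ordinal heads return both per-position
        probabilities (``<task>_probs``) and decoded fractions."""
        self._require_fitted()
        X = self._check_X(X)
        return self._predict_from_merged_batches(X, single=False)

    def predict_single(self, X) -> dict[str, np.ndarray]:
        """Predict from a single peptide through one shared branch.

        With the additive merge the heads see one branch output in place of
        the sum of two, which yields the alpha/beta single-peptide
        predictions used for feature engineering.
        """
        self._require_fitted()
        if self.mode == "crosslink" and self.combination == "concatenate":
            raise ValueError("single-peptide prediction undefined for concatenation merge")
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.max_len:
            raise ValueError(f"expected (n, {self.max_len}) int array")
        if X.min() < 0 or X.max() >= self.vocab_size:
            raise ValueError("token integer outside the model's alphabet")
        return self._predict_from_merged_batches(X, single=True)

    def _require_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("model is not fitted")

    # -- transfer learning -------------------------------------------------
    def transfer(self, **overrides) -> "SiameseRTRegressor":
        """New estimator sharing this model's trunk weights.

        Heads whose output shape is unchanged are copied; heads whose shape
        changed (e.g. a different number of fractions) are freshly
        initialized.  The clone has ``warm_start=True`` so a subsequent
        :meth:`fit` fine-tunes rather than re-initializes.
        """
        self._require_fitted()
        if "vocab_size" in overrides and overrides["vocab_size"] != self.vocab_size:
            raise ValueError("transfer requires the same alphabet (vocab_size)")
        params = self.get_params()
        params.update(overrides)
        params["warm_start"] = True
        new = SiameseRTRegressor(**params)
        cfg = new._resolved()
        new.network_ = _Network(cfg, np.random.default_rng(new.seed))
        new.network_.load_state(self.network_.state(), strict=False)
        new._rp_mean, new._rp_std = self._rp_mean, self._rp_std
        new._cfg = cfg
        new.history_ = pd.DataFrame()
        new.best_epoch_ = -1
        return new

    # -- persistence -------------------------------------------------------
    def save(self, directory) -> None:
        self._require_fitted()
        os.makedirs(directory, exist_ok=True)
        np.savez(os.path.join(directory, "weights.npz"), **self.network_.state())
        meta = {
            "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.get_params().items()
            },
            "rp_mean": self._rp_mean,
            "rp_std": self._rp_std,
            "best_epoch": int(getattr(self, "best_epoch_", -1)),
        }
        with open(os.path.join(directory, "model.json"), "w") as fh:
            json.dump(meta, fh, indent=1)
        if hasattr(self, "history_") and len(self.history_):
            self.history_.to_csv(os.path.join(directory, "history.csv"), index=False)

    @classmethod
    def load(cls, directory) -> "SiameseRTRegressor":
        with open(os.path.join(directory, "model.json")) as fh:
            meta = json.load(fh)
        params = meta["params"]
        for key in ("tasks", "subnet_layer_sizes"):
            if isinstance(params.get(key), list):
                params[key] = tuple(params[key])
        est = cls(**params)
        cfg = est._resolved()
        est.network_ = _Network(cfg, np.random.default_rng(est.seed))
        with np.load(os.path.join(directory, "weights.npz")) as npz:
            est.network_.load_state(dict(npz))
        est._rp_mean = meta["rp_mean"]
        est._rp_std = meta["rp_std"]
        est._cfg = cfg
        est.best_epoch_ = meta.get("best_epoch", -1)
        hist = os.path.join(directory, "history.csv")
        est.history_ = pd.read_csv(hist) if os.path.exists(hist) else pd.DataFrame()
        return est

    def n_parameters(self) -> int:
        self._require_fitted()
        return int(sum(p.data.size for p in self.network_.parameters()))
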