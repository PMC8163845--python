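"""Cross-validation strategy for retention-time learning.

Confident CSMs (target-target matches passing the configured FDR cutoff,
deduplicated by peptide-pair identity) are split into *k* folds.  In each
iteration two folds train the network — with 10% of the training material
held out as a validation set that selects the best epoch — and the third
fold receives predictions, so no confident CSM is ever predicted by a
model that saw it.  All remaining CSMs (below-cutoff targets and all
decoys, which never enter training) are predicted by the fold model with
the lowest total validation loss.

The canonical split arithmetic, with ``N`` unique CSMs and ``k`` folds:
test = floor(N/k), validation = ceil(0.1 * (N - test)), train = rest.
For N = 6453 this gives (3871, 431, 2151); for N = 645 (387, 43, 215);
for N = 3226 (1935, 216, 1075).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score

from .dataset import alphabet_from_records, encode_pairs, targets_from_records
from .fdr import q_values, unique_csm_key
from .io import CSMRecord


__all__ = [
    "CVSplit",
    "TaskMetrics",
    "split_sizes",
    "make_cv_splits",
    "compute_metrics",
    "run_cv",
    "learning_curve",
    "CVResult",
]


@dataclass(frozen=True)
class CVSplit:
    fold_id: int
    train_ids: tuple
    validation_ids: tuple
    test_ids: tuple


@dataclass(frozen=True)
class TaskMetrics:
    accuracy: float
    relaxed_accuracy: float
    r2: float
    mse: float


def split_sizes(n: int, k: int = 3, val_frac: float = 0.1) -> tuple[int, int, int]:
    """(train, validation, test) counts for one CV iteration."""
    if k < 2:
        raise ValueError("k must be >= 2")
    test = n // k
    val = int(np.ceil(val_frac * (n - test)))
    return n - test - val, val, test


def make_cv_splits(csm_ids, k: int = 3, val_frac: float = 0.1, seed: int = 0) -> list[CVSplit]:
    """Random fold assignment; the k test sets partition ``csm_ids``.

    When ``len(csm_ids)`` is not divisible by ``k`` the remainder items go
    to the test sets of the first folds, so each id is predicted exactly
    once.
    """
    ids = list(csm_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < 2 * k:
        raise ValueError(f"{len(ids)} CSMs are too few for k={k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    chunks = np.array_split(perm, k)
    splits = []
    for fold, test_ix in enumerate(chunks):
        rest = np.concatenate([c for f, c in enumerate(chunks) if f != fold])
        n_val = int(np.ceil(val_frac * rest.size))
        rest = rng.permutation(rest)
        val_ix, train_ix = rest[:n_val], rest[n_val:]
        splits.append(
            CVSplit(
                fold_id=fold,
                train_ids=tuple(ids[i] for i in train_ix),
                validation_ids=tuple(ids[i] for i in val_ix),
                test_ids=tuple(ids[i] for i in test_ix),
            )
        )
    return splits


def compute_metrics(preds, truths, task: str = "rp") -> TaskMetrics:
    """Accuracy, relaxed accuracy (error <= |1| fraction), R² and MSE."""
    preds = np.asarray(preds, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if preds.size == 0 or preds.shape != truths.shape:
        raise ValueError("empty or mismatched prediction/truth vectors")
    err = preds - truths
    return TaskMetrics(
        accuracy=float(np.mean(err == 0)),
        relaxed_accuracy=float(np.mean(np.abs(err) <= 1)),
        r2=float(r2_score(truths, preds)),
        mse=float(np.mean(err**2)),
    )


@dataclass
class CVResult:
    predictions: pd.DataFrame
    metrics: pd.DataFrame
    models: list
    best_fold: int
    splits: list
    alphabet: object


def _confident_mask(records, fdr_cutoff: float) -> np.ndarray:
    """TT records passing the q-value cutoff, estimated per link class."""
    scores = np.array([r.score for r in records])
    classes = np.array([r.td_class for r in records])
    link = np.array([r.link_class for r in records])
    q = np.full(len(records), np.inf)
    for lc in np.unique(link):
        m = link == lc
        if (classes[m] == "TT").any():
            q[m] = q_values(scores[m], classes[m])
    return (classes == "TT") & (q <= fdr_cutoff), q


def run_cv(
    records: list[CSMRecord],
    model_config,
    fdr_cutoff: float = 0.01,
    k: int = 3,
    val_frac: float = 0.1,
    seed: int = 0,
    alphabet=None,
) -> CVResult:
    """Full CV training/prediction pass over a CSM table.

    ``model_config`` is a :class:`~xlrt.model.ModelConfig` (or estimator
    params dict).  Decoy matches never enter the training material.
    """
    from .model import ModelConfig

    if isinstance(model_config, dict):
        model_config = ModelConfig(**model_config)
    tasks = tuple(model_config.tasks)
    confident, q = _confident_mask(records, fdr_cutoff)
    if not confident.any():
        raise ValueError("no confident CSMs at the requested FDR cutoff")

    if alphabet is None:
        alphabet = alphabet_from_records(records)

    # deduplicate confident CSMs by peptide-pair identity; the best-scoring
    # record represents each unique CSM during training
    best_by_key: dict = {}
    for i in np.nonzero(confident)[0]:
        key = unique_csm_key(records[i], "rt_learning")
        if key not in best_by_key or records[i].score > records[best_by_key[key]].score:
            best_by_key[key] = i
    keys = sorted(best_by_key)  # deterministic order before shuffling
    splits = make_cv_splits(keys, k=k, val_frac=val_frac, seed=seed)
    rep_index = best_by_key

    X_all = encode_pairs(records, alphabet, model_config.max_len)

    models, fold_rows, metric_rows = [], {}, []
    for split in splits:
        est = model_config.build(alphabet.vocab_size)
        tr = [rep_index[kk] for kk in split.train_ids]
        va = [rep_index[kk] for kk in split.validation_ids]
        te = [rep_index[kk] for kk in split.test_ids]
        est.fit(
            X_all[tr],
            targets_from_records([records[i] for i in tr], tasks),
            validation_data=(X_all[va], targets_from_records([records[i] for i in va], tasks)),
        )
        models.append(est)
        preds = est.predict(X_all[te])
        truths = targets_from_records([records[i] for i in te], tasks)
        for task in tasks:
            m = compute_metrics(preds[task], truths[task], task)
            metric_rows.append(
                {
                    "fold": split.fold_id,
                    "task": task,
                    "accuracy": m.accuracy,
                    "relaxed_accuracy": m.relaxed_accuracy,
                    "r2": m.r2,
                    "mse": m.mse,
                }
            )
        for kk in split.test_ids:
            fold_rows[kk] = split.fold_id

    best_fold = int(
        np.lexsort(
            (np.arange(len(models)), [m.best_val_loss_ for m in models])
        )[0]
    )

    # predict every record: confident ones by their test fold, the rest by
    # the best fold model
    pred_rows = []
    key_of = [unique_csm_key(r, "rt_learning") for r in records]
    by_fold: dict[int, list[int]] = {}
    for i, r in enumerate(records):
        fold = fold_rows.get(key_of[i], best_fold) if confident[i] else best_fold
        by_fold.setdefault(fold, []).append(i)
    results = {}
    for fold, idxs in by_fold.items():
        p = models[fold].predict(X_all[idxs])
        for j, i in enumerate(idxs):
            row = {
                "csm_id": records[i].csm_id,
                "fold": fold,
                "confident": bool(confident[i]),
                "q_value": q[i],
            }
            for task in tasks:
                row[f"pred_{task}"] = p[task][j]
            results[i] = row
    pred_rows = [results[i] for i in range(len(records))]
    return CVResult(
        predictions=pd.DataFrame(pred_rows),
        metrics=pd.DataFrame(metric_rows),
        models=models,
        best_fold=best_fold,
        splits=splits,
        alphabet=alphabet,
    )


def learning_curve(
    records,
    fractions_of_data,
    model_config,
    seed: int = 0,
    k: int = 3,
    fdr_cutoff: float = 0.01,
) -> pd.DataFrame:
    """Re-run the CV on nested subsamples of the CSM table.

    Reports, per subsample, the canonical split sizes and the combined
    score R²(RP) + Acc(hSAX) + Acc(SCX) averaged over folds (tasks absent
    from the model contribute zero).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions_of_data:
        if not 0 < frac <= 1:
            raise ValueError("fractions must lie in (0, 1]")
        n = int(round(frac * len(records)))
        sub = [records[i] for i in rng.choice(len(records), size=n, replace=False)]
        try:
            res = run_cv(sub, model_config, fdr_cutoff=fdr_cutoff, k=k, seed=seed)
        except ValueError as exc:
            warnings.warn(f"fraction {frac}: skipped ({exc})")
            continue
        n_unique = sum(len(s.test_ids) for s in res.splits)
        train, val, test = split_sizes(n_unique, k)
        per_task = res.metrics.groupby("task").mean(numeric_only=True)
        combined = 0.0
        if "rp" in per_task.index:
            combined += per_task.loc["rp", "r2"]
        for t in ("hsax", "scx"):
            if t in per_task.index:
                combined += per_task.loc[t, "accuracy"]
        row = {
            "fraction": frac,
            "n_csms": n_unique,
            "n_train": train,
            "n_validation": val,
            "n_test": test,
            "combined_score": combined,
        }
        for t in per_task.index:
            row[f"r2_{t}"] = per_task.loc[t, "r2"]
            row[f"accuracy_{t}"] = per_task.loc[t, "accuracy"]
            row[f"relaxed_accuracy_{t}"] = per_task.loc[t, "relaxed_accuracy"]
        rows.append(row)
    return pd.DataFrame(rows)
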