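"""Semi-supervised SVM rescoring of crosslink spectrum matches.

Target-target matches passing the initial FDR cutoff are positive
training examples; target-decoy and decoy-decoy matches (passing or not)
are negatives.  The labeled CSMs are split into k folds stratified by
search-score percentile; per fold, a linear SVM (regularization chosen by
internal cross-validation, features standardized on the training folds
only, optional SMOTE balancing inside the fold) is trained on the other
folds and scores the held-out fold.  Below-cutoff target-target matches
are scored by the average of all k models.  The final score combines the
search-engine score with the SVM margin:

    rescored = score + score * svm_score
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV
from sklearn.neighbors import NearestNeighbors
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .fdr import q_values
from .io import CSMRecord

__all__ = [
    "assemble_training_set",
    "stratified_folds_by_score",
    "balance_with_smote",
    "rescore",
    "RescoreResult",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class RescoreResult:
    csm_id: str
    svm_score: float
    xi_score: float
    xi_rescored: float
    fold_of_scoring: int | str


def compute_q_per_link_class(records) -> np.ndarray:
    scores = np.array([r.score for r in records])
    classes = np.array([r.td_class for r in records])
    link = np.array([r.link_class for r in records])
    q = np.full(len(records), np.inf)
    for lc in np.unique(link):
        m = link == lc
        if (classes[m] == "TT").any():
            q[m] = q_values(scores[m], classes[m])
    return q


def assemble_training_set(
    records: list[CSMRecord], fdr_cutoff: float = 0.01, q: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of (positives, negatives).

    Positives: TT CSMs at or below the q-value cutoff (entrapment targets
    included).  Negatives: every TD and DD CSM.  Below-cutoff TTs belong to
    neither class; they are scored but never trained on.
    """
    if q is None:
        q = compute_q_per_link_class(records)
    classes = np.array([r.td_class for r in records])
    pos = np.nonzero((classes == "TT") & (q <= fdr_cutoff))[0]
    neg = np.nonzero(classes != "TT")[0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both positive (confident TT) and negative (TD/DD) examples")
    return pos, neg


def stratified_folds_by_score(scores, k: int = 3, seed: int = 0) -> np.ndarray:
    """Fold labels such that every fold spans the score range.

    CSMs are binned into k score percentiles; within each bin they are
    dealt round-robin (in shuffled order) across the folds.
    """
    scores = np.asarray(scores, dtype=float)
    if k > scores.size:
        raise ValueError(f"k={k} exceeds the number of CSMs ({scores.size})")
    rng = np.random.default_rng(seed)
    ranks = np.argsort(np.argsort(scores, kind="stable"), kind="stable")
    bins = np.minimum((ranks * k) // scores.size, k - 1)
    folds = np.empty(scores.size, dtype=int)
    offset = 0
    for b in range(k):
        ix = rng.permutation(np.nonzero(bins == b)[0])
        folds[ix] = (np.arange(ix.size) + offset) % k
        offset += ix.size
    return folds


def balance_with_smote(
    features: np.ndarray, labels: np.ndarray, seed: int = 0, k_neighbors: int = 5
):
    """Synthetic minority oversampling to equal class counts.

    New minority rows are convex combinations of a minority sample and one
    of its k nearest minority neighbours.  When the minority class is too
    small for neighbour interpolation, plain duplication is used instead.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE balancing expects exactly two classes")
    if counts[0] == counts[1]:
        return features, labels
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    need = int(abs(counts[0] - counts[1]))
    m_ix = np.nonzero(labels == minority)[0]
    Xm = features[m_ix]
    if Xm.shape[0] <= k_neighbors:
        warnings.warn("minority class smaller than neighbour count; duplicating instead")
        dup = Xm[rng.integers(0, Xm.shape[0], size=need)]
        synth = dup
    else:
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
        _, neigh = nn.kneighbors(Xm)
        base = rng.integers(0, Xm.shape[0], size=need)
        pick = neigh[base, rng.integers(1, k_neighbors + 1, size=need)]
        gamma = rng.random(size=(need, 1))
        synth = Xm[base] + gamma * (Xm[pick] - Xm[base])
    features_out = np.vstack([features, synth])
    labels_out = np.concatenate([labels, np.full(need, minority, dtype=labels.dtype)])
    return features_out, labels_out


def _fit_svm(X, y, c_grid, seed):
    svc = LinearSVC(dual=False, max_iter=5000, random_state=seed)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold lost one of the classes")
    grid = GridSearchCV(svc, {"C": list(c_grid)}, cv=3, scoring="roc_auc", n_jobs=1)
    grid.fit(X, y)
    return grid.best_estimator_


def rescore(
    records: list[CSMRecord],
    features: pd.DataFrame,
    k: int = 3,
    use_smote: bool = False,
    seed: int = 0,
    fdr_cutoff: float = 0.01,
    c_grid=DEFAULT_C_GRID,
) -> pd.DataFrame:
    """Score every CSM and combine with the search-engine score.

    ``features`` is the matrix from :func:`xlrt.features.feature_matrix`
    (indexed by csm_id, aligned with ``records``).  Returns a DataFrame
    with svm_score, xi_score, xi_rescored and fold bookkeeping.
    """
    ids = [r.csm_id for r in records]
    if list(features.index) != ids:
        features = features.loc[ids]
    X = features.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")

    q = compute_q_per_link_class(records)
    pos, neg = assemble_training_set(records, fdr_cutoff, q)
    labeled = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(pos.size, dtype=int), np.zeros(neg.size, dtype=int)])
    scores = np.array([r.score for r in records])

    folds = stratified_folds_by_score(scores[labeled], k=k, seed=seed)
    svm_score = np.zeros(len(records))
    fold_of = np.full(len(records), "averaged", dtype=object)
    models = []
    for f in range(k):
        train_m = folds != f
        scaler = StandardScaler().fit(X[labeled[train_m]])
        Xtr = scaler.transform(X[labeled[train_m]])
        ytr = y[train_m]
        if use_smote:
            Xtr, ytr = balance_with_smote(Xtr, ytr, seed=seed + f)
        model = _fit_svm(Xtr, ytr, c_grid, seed)
        models.append((scaler, model))
        test_ix = labeled[folds == f]
        svm_score[test_ix] = model.decision_function(scaler.transform(X[test_ix]))
        for i in test_ix:
            fold_of[i] = f
    unlabeled = np.setdiff1d(np.arange(len(records)), labeled)
    if unlabeled.size:
        preds = np.stack(
            [m.decision_function(s.transform(X[unlabeled])) for s, m in models]
        )
        svm_score[unlabeled] = preds.mean(axis=0)

    xi_rescored = scores + scores * svm_score
    return pd.DataFrame(
        {
            "csm_id": ids,
            "svm_score": svm_score,
            "xi_score": scores,
            "xi_rescored": xi_rescored,
            "fold_of_scoring": fold_of,
            "labeled": np.isin(np.arange(len(records)), labeled),
            "q_initial": q,
        }
    )
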