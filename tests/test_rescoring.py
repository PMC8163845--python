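
import numpy as np
import pandas as pd
import pytest

from xlrt.io import CSMRecord
from xlrt.rescoring import (
    assemble_training_set,
    balance_with_smote,
    rescore,
    stratified_folds_by_score,
)


def _rec(i, score, td="TT", link_class="heteromeric", entrapment=False):
    ta, tb = {"TT": (True, True), "TD": (True, False), "DD": (False, False)}[td]
    return CSMRecord(
        csm_id=f"c{i}",
        peptide_a="PEPKTIDER",
        peptide_b="KAR",
        link_pos_a=4,
        link_pos_b=1,
        score=score,
        is_target_a=ta,
        is_target_b=tb,
        is_entrapment_a=entrapment,
        link_class=link_class,
    )


class TestAssembleTrainingSet:
    def toy(self):
        # 5 high-scoring TT (q = 0), decoys, then 5 more TT below the cutoff
        recs = [_rec(i, 100 - i) for i in range(5)]
        recs += [_rec(5, 90, "TD"), _rec(6, 89, "TD"), _rec(7, 88, "TD")]
        recs += [_rec(8, 87, "DD"), _rec(9, 86, "DD")]
        recs += [_rec(10 + i, 80 - i) for i in range(5)]
        return recs

    def test_label_rules_on_toy_set(self):
        pos, neg = assemble_training_set(self.toy(), fdr_cutoff=0.01)
        assert pos.size == 5 and neg.size == 5
        recs = self.toy()
        assert all(recs[i].td_class == "TT" for i in pos)
        assert all(recs[i].td_class != "TT" for i in neg)

    def test_below_cutoff_tts_in_neither_class(self):
        recs = self.toy()
        pos, neg = assemble_training_set(recs, fdr_cutoff=0.01)
        low_tt = {i for i, r in enumerate(recs) if r.td_class == "TT" and r.score < 85}
        assert not (low_tt & set(pos)) and not (low_tt & set(neg))

    def test_entrapment_tts_passing_cutoff_are_positives(self):
        recs = self.toy()
        recs[0] = _rec(0, 100, "TT", entrapment=True)
        pos, _ = assemble_training_set(recs, fdr_cutoff=0.01)
        assert 0 in pos

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            assemble_training_set([_rec(0, 10), _rec(1, 9)], fdr_cutoff=0.01)


class TestStratifiedFolds:
    def test_each_fold_covers_each_tertile(self):
        scores = np.array([1, 2, 3, 10, 11, 12, 20, 21, 22], dtype=float)
        folds = stratified_folds_by_score(scores, k=3, seed=0)
        for f in range(3):
            fold_scores = scores[folds == f]
            assert fold_scores.size == 3
            assert (fold_scores < 10).sum() == 1
            assert ((fold_scores >= 10) & (fold_scores < 20)).sum() == 1
            assert (fold_scores >= 20).sum() == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=50)
        assert np.array_equal(
            stratified_folds_by_score(scores, seed=3), stratified_folds_by_score(scores, seed=3)
        )

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds_by_score([1.0, 2.0], k=3)

    def test_stratification_tightens_fold_score_means(self):
        """Across 100 seeds, per-fold mean scores spread less than with
        unstratified random assignment."""
        rng = np.random.default_rng(42)
        strat_spread, random_spread = [], []
        for seed in range(100):
            scores = rng.normal(size=60)
            folds = stratified_folds_by_score(scores, k=3, seed=seed)
            strat_spread.append(np.std([scores[folds == f].mean() for f in range(3)]))
            rand = np.random.default_rng(seed).permutation(60) % 3
            random_spread.append(np.std([scores[rand == f].mean() for f in range(3)]))
        assert np.mean(strat_spread) < np.mean(random_spread)


class TestSmote:
    def test_balanced_input_unchanged(self):
        X = np.arange(20.0).reshape(10, 2)
        y = np.array([0] * 5 + [1] * 5)
        Xb, yb = balance_with_smote(X, y, seed=0)
        assert Xb.shape == X.shape and np.array_equal(yb, y)

    def test_counts_equalized(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(size=(20, 3)), rng.normal(5, 1, size=(8, 3))])
        y = np.array([0] * 20 + [1] * 8)
        Xb, yb = balance_with_smote(X, y, seed=1)
        assert (yb == 0).sum() == (yb == 1).sum() == 20

    def test_synthetic_points_inside_minority_bounds(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(size=(30, 4)), rng.uniform(2, 3, size=(10, 4))])
        y = np.array([0] * 30 + [1] * 10)
        Xb, yb = balance_with_smote(X, y, seed=3)
        new = Xb[40:]
        minority = X[30:]
        assert (new >= minority.min(axis=0) - 1e-9).all()
        assert (new <= minority.max(axis=0) + 1e-9).all()

    def test_tiny_minority_falls_back_to_duplication(self):
        X = np.vstack([np.zeros((10, 2)), np.ones((3, 2))])
        y = np.array([0] * 10 + [1] * 3)
        with pytest.warns(UserWarning, match="duplicat"):
            Xb, yb = balance_with_smote(X, y, seed=4)
        assert (yb == 1).sum() == 10
        assert np.array_equal(np.unique(Xb[13:]), np.array([1.0]))


@pytest.fixture(scope="module")
def toy_rescored():
    rng = np.random.default_rng(7)
    n_pos, n_neg, n_low = 40, 40, 20
    recs, rows = [], []
    for i in range(n_pos):
        recs.append(_rec(i, 30 + rng.normal()))
        rows.append(rng.normal(0, 1, size=4))
    for i in range(n_neg):
        recs.append(_rec(n_pos + i, 13 + rng.normal(), "DD" if i % 4 == 0 else "TD"))
        rows.append(rng.normal(3, 1, size=4))
    for i in range(n_low):
        recs.append(_rec(n_pos + n_neg + i, 12 + rng.normal()))
        rows.append(rng.normal(1.5, 1, size=4))
    fm = pd.DataFrame(rows, index=[r.csm_id for r in recs],
                      columns=[f"f{j}" for j in range(4)])
    return recs, rescore(recs, fm, seed=0, fdr_cutoff=0.05)


class TestRescore:
    def test_final_score_identity_exact(self, toy_rescored):
        _, out = toy_rescored
        assert np.array_equal(
            out["xi_rescored"].to_numpy(),
            out["xi_score"].to_numpy() + out["xi_score"].to_numpy() * out["svm_score"].to_numpy(),
        )

    def test_labeled_csms_scored_by_their_test_fold(self, toy_rescored):
        recs, out = toy_rescored
        labeled = out[out["labeled"]]
        assert set(labeled["fold_of_scoring"]) <= {0, 1, 2}

    def test_below_cutoff_tts_scored_by_average(self, toy_rescored):
        recs, out = toy_rescored
        rest = out[~out["labeled"]]
        assert (rest["fold_of_scoring"] == "averaged").all()
        assert len(rest) == 20

    def test_informative_features_separate_classes(self, toy_rescored):
        recs, out = toy_rescored
        classes = np.array([r.td_class for r in recs])
        assert out["svm_score"][classes == "TT"].mean() > out["svm_score"][classes != "TT"].mean()

    def test_misaligned_features_rejected(self, toy_rescored):
        recs, _ = toy_rescored
        fm = pd.DataFrame(np.zeros((3, 2)), index=["a", "b", "c"])
        with pytest.raises(KeyError):
            rescore(recs, fm, seed=0)
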