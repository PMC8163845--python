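import numpy as np
import pytest

from xlrt.cv import compute_metrics
from xlrt.dataset import encode_pairs, targets_from_records
from xlrt.model import SiameseRTRegressor, total_loss

TINY = dict(
    vocab_size=25,
    max_len=20,
    embedding_dim=8,
    recurrent_units=8,
    subnet_layer_sizes=(8, 4, 2),
    batch_size=32,
    epochs=3,
)


def random_pairs(rng, n, vocab=25, max_len=20):
    X = np.zeros((n, 2, max_len), dtype=np.int64)
    for i in range(n):
        for j in range(2):
            length = rng.integers(5, max_len + 1)
            X[i, j, :length] = rng.integers(1, vocab, size=length)
    return X


def fit_tiny(X, y, **kw):
    params = {**TINY, **kw}
    return SiameseRTRegressor(**params).fit(X, y)


class TestTotalLoss:
    def test_perfect_predictions_give_zero(self):
        preds = {"rp": [1.0, 2.0], "scx": np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])}
        truths = {"rp": [1.0, 2.0], "scx": np.array([2, 1])}
        assert total_loss(preds, truths, {"rp": 1, "scx": 1}) == 0.0

    def test_single_weight_reduces_to_plain_mse(self):
        preds = {"rp": [1.0, 3.0], "scx": np.array([[0.7, 0.2]])}
        truths = {"rp": [0.0, 0.0], "scx": np.array([2])}
        got = total_loss(preds, truths, {"rp": 1, "scx": 0, "hsax": 0})
        assert got == pytest.approx(5.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        preds = {"rp": rng.normal(size=6), "hsax": rng.uniform(0.05, 0.95, size=(6, 4))}
        truths = {"rp": rng.normal(size=6), "hsax": rng.integers(1, 5, size=6)}
        w1 = {"rp": 1.0, "hsax": 0.5}
        w2 = {"rp": 2.0, "hsax": 1.0}
        assert total_loss(preds, truths, w2) == pytest.approx(2 * total_loss(preds, truths, w1))

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            total_loss({"rp": [1.0]}, {"rp": [1.0]}, {"rp": -1})

    def test_missing_task_contributes_zero(self):
        preds = {"rp": [2.0]}
        truths = {"rp": [0.0]}
        assert total_loss(preds, truths, {"rp": 1, "scx": 5}) == pytest.approx(4.0)


class TestArchitecture:
    def test_single_task_model_has_one_output_head(self):
        rng = np.random.default_rng(0)
        X = random_pairs(rng, 40)
        y = {"rp": rng.normal(size=40)}
        est = fit_tiny(X, y, tasks=("rp",), epochs=1)
        preds = est.predict(X[:5])
        assert set(preds) == {"rp"}
        assert set(est.network_.out_layers) == {"rp"}

    def test_order_invariance_of_additive_combination(self):
        rng = np.random.default_rng(1)
        X = random_pairs(rng, 60)
        y = {"rp": rng.normal(size=60), "scx": rng.integers(1, 10, size=60),
             "hsax": rng.integers(1, 11, size=60)}
        est = fit_tiny(X, y, epochs=2)
        swapped = X[:, ::-1, :]
        p1, p2 = est.predict(X), est.predict(swapped)
        for key in ("rp", "scx_probs", "hsax_probs"):
            assert np.array_equal(p1[key], p2[key])

    def test_branches_share_all_weights(self):
        """The two inputs flow through one embedding/recurrent stack, so a
        linear-mode network with the same config has the same parameters."""
        rng = np.random.default_rng(2)
        X = random_pairs(rng, 40)
        y = {"rp": rng.normal(size=40)}
        cross = fit_tiny(X, y, tasks=("rp",), epochs=1)
        linear = fit_tiny(X[:, 0, :], y, tasks=("rp",), epochs=1, mode="linear")
        assert cross.n_parameters() == linear.n_parameters()

    def test_pyramid_constraint_enforced(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SiameseRTRegressor(subnet_layer_sizes=(8, 16, 4))._resolved()

    def test_empty_second_peptide_rejected_in_crosslink_mode(self):
        rng = np.random.default_rng(3)
        X = random_pairs(rng, 10)
        X[0, 1, :] = 0
        with pytest.raises(ValueError, match="second peptide"):
            fit_tiny(X, {"rp": np.zeros(10)}, tasks=("rp",), epochs=1)

    def test_fraction_label_outside_configured_range_rejected(self):
        rng = np.random.default_rng(4)
        X = random_pairs(rng, 10)
        y = {"rp": np.zeros(10), "scx": np.full(10, 12), "hsax": np.ones(10)}
        with pytest.raises(ValueError, match="n_fractions"):
            fit_tiny(X, y, epochs=1)


class TestFit:
    def test_same_seed_gives_identical_history(self):
        rng = np.random.default_rng(5)
        X = random_pairs(rng, 80)
        y = {"rp": rng.normal(size=80)}
        a = fit_tiny(X, y, tasks=("rp",), seed=9)
        b = fit_tiny(X, y, tasks=("rp",), seed=9)
        assert a.history_.equals(b.history_)

    def test_history_length_equals_epochs(self):
        rng = np.random.default_rng(6)
        X = random_pairs(rng, 50)
        est = fit_tiny(X, {"rp": rng.normal(size=50)}, tasks=("rp",), epochs=4)
        assert len(est.history_) == 4
        assert {"train_rp", "val_rp", "val_total"} <= set(est.history_.columns)

    def test_empty_validation_set_rejected(self):
        rng = np.random.default_rng(7)
        X = random_pairs(rng, 30)
        y = {"rp": rng.normal(size=30)}
        with pytest.raises(ValueError, match="validation"):
            SiameseRTRegressor(**TINY, tasks=("rp",)).fit(
                X, y, validation_data=(X[:0], {"rp": y["rp"][:0]})
            )

    def test_best_checkpoint_is_restored(self):
        rng = np.random.default_rng(8)
        X = random_pairs(rng, 60)
        est = fit_tiny(X, {"rp": rng.normal(size=60)}, tasks=("rp",), epochs=5)
        best = est.history_["val_total"].idxmin()
        assert est.best_epoch_ == best
        assert est.best_val_loss_ == pytest.approx(est.history_["val_total"].min())


class TestRecoveryAndTransfer:
    def test_parameter_recovery_on_additive_data(self, small_trained):
        """Held-out predictions recover the additive retention structure."""
        est = small_trained["model"]
        X, y, n = small_trained["X"], small_trained["y"], small_trained["n_train"]
        preds = est.predict(X[n:])
        assert compute_metrics(preds["rp"], y["rp"][n:]).r2 > 0.75
        assert compute_metrics(preds["scx"], y["scx"][n:]).relaxed_accuracy > 0.6

    def test_single_peptide_prediction_path(self, small_trained):
        est = small_trained["model"]
        X = small_trained["X"]
        single = est.predict_single(X[:8, 0, :])
        assert single["rp"].shape == (8,)
        assert (1 <= single["scx"]).all() and (single["scx"] <= 9).all()

    def test_transfer_same_shapes_is_a_pure_copy(self, small_trained):
        est = small_trained["model"]
        X = small_trained["X"][:10]
        moved = est.transfer()
        p1, p2 = est.predict(X), moved.predict(X)
        assert np.array_equal(p1["rp"], p2["rp"])

    def test_transfer_changed_fractions_reinitializes_only_that_head(self, small_trained):
        est = small_trained["model"]
        moved = est.transfer(n_fractions={"scx": 5, "hsax": 10})
        assert moved.network_.out_layers["scx"].weight.data.shape[1] == 5
        for key, arr in est.network_.shared_layers().items():
            for name, val in arr.state_arrays().items():
                assert np.array_equal(val, moved.network_.named_layers()[key].state_arrays()[name])
        X = small_trained["X"][:10]
        assert moved.predict(X)["scx_probs"].shape == (10, 5)

    def test_transfer_rejects_alphabet_change(self, small_trained):
        with pytest.raises(ValueError, match="alphabet"):
            small_trained["model"].transfer(vocab_size=99)

    def test_save_load_round_trip(self, small_trained, tmp_path):
        est = small_trained["model"]
        X = small_trained["X"][:12]
        est.save(tmp_path / "ckpt")
        back = SiameseRTRegressor.load(tmp_path / "ckpt")
        p1, p2 = est.predict(X), back.predict(X)
        assert np.array_equal(p1["rp"], p2["rp"])
        assert np.array_equal(p1["hsax_probs"], p2["hsax_probs"])

    def test_fine_tuning_beats_training_from_scratch(self, small_dataset, small_trained):
        """Pre-trained shared layers give a head start on a small dataset."""
        records = small_dataset["records"]
        truth = small_dataset["truth"]
        conf = [r for r in records if r.td_class == "TT" and truth.loc[r.csm_id, "is_true"]]
        rng = np.random.default_rng(0)
        ix = rng.permutation(len(conf))[:150]
        sub = [conf[i] for i in ix]
        X = encode_pairs(sub, small_trained["alphabet"], 30)
        y = targets_from_records(sub, ("rp", "scx", "hsax"))
        cut = 100
        Xtr, ytr = X[:cut], {k: v[:cut] for k, v in y.items()}
        fine = small_trained["model"].transfer(epochs=8)
        fine.fit(Xtr, ytr)
        from conftest import SMALL_MODEL_KW

        scratch = SiameseRTRegressor(
            vocab_size=small_trained["alphabet"].vocab_size, epochs=8, seed=4, **SMALL_MODEL_KW
        ).fit(Xtr, ytr)
        r2_fine = compute_metrics(fine.predict(X[cut:])["rp"], y["rp"][cut:]).r2
        r2_scratch = compute_metrics(scratch.predict(X[cut:])["rp"], y["rp"][cut:]).r2
        assert r2_fine > r2_scratch
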