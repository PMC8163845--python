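"""Shared fixtures: small synthetic datasets and a quickly trained model.

Everything is generated at test time from the synthetic-data module with
fixed seeds; nothing is read from disk.
"""

from __future__ import annotations

import pytest

from xlrt.dataset import alphabet_from_records, encode_pairs, targets_from_records
from xlrt.model import SiameseRTRegressor
from xlrt.synthetic import SimulationConfig, simulate_dataset

SMALL_MODEL_KW = dict(
    max_len=30,
    embedding_dim=24,
    recurrent_units=24,
    subnet_layer_sizes=(24, 12, 6),
    batch_size=64,
    learning_rate=4e-3,
)


@pytest.fixture(scope="session")
def small_dataset():
    """~1200 CSMs with the default class mix; returns records and truth."""
    config = SimulationConfig(n_csms=1200, n_proteins=80)
    records, truth, proteins, retention_model = simulate_dataset(config, seed=11)
    return {
        "config": config,
        "records": records,
        "truth": truth.set_index("csm_id"),
        "proteins": proteins,
        "retention_model": retention_model,
    }


@pytest.fixture(scope="session")
def small_trained(small_dataset):
    """A small Siamese model trained on the latent-true TT records."""
    records = small_dataset["records"]
    truth = small_dataset["truth"]
    conf = [r for r in records if r.td_class == "TT" and truth.loc[r.csm_id, "is_true"]]
    alphabet = alphabet_from_records(records)
    X = encode_pairs(conf, alphabet, 30)
    y = targets_from_records(conf, ("rp", "scx", "hsax"))
    n_train = int(0.8 * len(conf))
    est = SiameseRTRegressor(
        vocab_size=alphabet.vocab_size, epochs=80, seed=4, **SMALL_MODEL_KW
    )
    est.fit(X[:n_train], {k: v[:n_train] for k, v in y.items()})
    return {
        "model": est,
        "alphabet": alphabet,
        "confident": conf,
        "X": X,
        "y": y,
        "n_train": n_train,
    }
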