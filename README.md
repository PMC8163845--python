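# xlrt — retention-time-aided identification of crosslinked peptides

Crosslinking mass spectrometry (crosslinking MS) identifies pairs of
covalently linked peptides from fragmentation spectra. Because two
peptides share one spectrum, fragmentation evidence is often lopsided and
the combinatorial search space — especially for heteromeric links between
different proteins — makes random matches common. Chromatographic
retention, however, depends on *both* peptides of a crosslink. `xlrt`
exploits that: it learns to predict multi-dimensional retention
coordinates of crosslinked peptides and folds the prediction errors into
the match score, yielding more identifications at the same confidence.

The package targets computational proteomicists working with
crosslink search-engine output (CSM tables from e.g. xiSEARCH or pLink2
exports) and provides:

- **A Siamese multi-task recurrent network** (`xlrt.model.SiameseRTRegressor`,
  an sklearn-style estimator). Both peptides pass through one shared
  embedding + GRU/LSTM stack; the branch outputs are combined additively
  (making predictions invariant to peptide order) and feed one subnetwork
  per chromatographic dimension. Reversed-phase retention time (RP) is a
  regression head (linear output, MSE loss); fraction numbers from strong
  cation exchange (SCX) and hydrophilic strong anion exchange (hSAX) are
  ordinal heads: fraction *f* of *n* is encoded as *f−1* leading ones
  (`f1=[0,0,0]`, `f2=[1,0,0]`, `f3=[1,1,0]` for *n*=3), trained with
  per-position sigmoid + binary cross-entropy, decoded as the first
  position with probability < 0.5. The total loss is the weighted sum
  `w_RP·MSE + w_SCX·BCE + w_hSAX·BCE`. The network runs on a compact
  numpy autodiff engine bundled with the package (`xlrt._nn`).
- **Cross-validated training** (`xlrt.cv`): confident CSMs (TT matches at
  ≤ 1% FDR, deduplicated by peptide pair) are split into *k*=3 folds; two
  folds train (minus 10% validation used for best-epoch selection), the
  third is predicted, so no CSM is predicted by a model that saw it.
  Everything else — including all decoys, which never enter training — is
  predicted by the fold model with the lowest validation loss.
- **Feature engineering** (`xlrt.features`): per dimension, predictions
  for the pair, the alpha and the beta peptide plus signed/absolute/squared
  errors — 13 features per dimension, 43 for RP+SCX+hSAX.
- **Semi-supervised SVM rescoring** (`xlrt.rescoring`): confident TTs are
  positives, TD/DD decoy matches negatives; score-percentile-stratified
  3-fold CV, per-fold standardization, optional SMOTE, linear SVM with
  internally cross-validated regularization. Final score:
  `rescored = score + score · svm_score`.
- **Target-decoy + entrapment FDR** (`xlrt.fdr`): `FDR = (TD − DD) / TT`,
  monotonized q-values, separate estimation for self and heteromeric
  links, and roll-ups CSM → peptide pair → residue pair → PPI.
- **Entrapment database construction** (`xlrt.entrapment`): tryptic
  digest, homology exclusion, greedy nearest-neighbour pairing of one
  irrelevant protein per target by K/R count + length (or amino-acid
  composition), doubling the database size.
- **A synthetic-data generator** (`xlrt.synthetic`) with additive
  per-residue retention models and ground-truth labels, so the entire
  pipeline is testable without any external data.

## Worked example

Simulate a small crosslinking study and run the cross-validated
retention-time training:

```python
from xlrt.synthetic import SimulationConfig, simulate_dataset
from xlrt.cv import run_cv
from xlrt.model import ModelConfig

records, truth, proteins, rmodel = simulate_dataset(
    SimulationConfig(n_csms=1200, n_proteins=80), seed=11
)
config = ModelConfig(embedding_dim=24, recurrent_units=24,
                     subnet_layer_sizes=(24, 12, 6), epochs=80,
                     learning_rate=4e-3, seed=4)
result = run_cv(records, config, fdr_cutoff=0.01, k=3, seed=4)
print(result.metrics.groupby("task")[["r2", "accuracy", "relaxed_accuracy", "mse"]]
      .mean().round(3))
```

Output (about two minutes on one CPU):

```
         r2  accuracy  relaxed_accuracy     mse
task
hsax  0.529     0.230             0.647   3.231
rp    0.936     0.000             0.121  62.347
scx   0.304     0.209             0.578   4.087
```

Held-out RP retention times are predicted with R² = 0.94 even from this
small training set, while the ordinal fraction tasks (relaxed accuracy:
fraction of predictions within ±1 fraction) are data-hungrier — they keep
improving with more CSMs, which is exactly what the learning-curve helper
(`xlrt.cv.learning_curve`) shows. `result.predictions` carries one row
per CSM with its fold assignment, q-value and per-dimension predictions,
ready for `xlrt.features.feature_matrix` and `xlrt.rescoring.rescore`.

The same workflows are available from the shell:

```bash
xlrt simulate --seed 1 --out-dir sim
xlrt rescore --config config.yaml --seed 1 --out-dir out
```

where `config.yaml` points `csm_table` at the simulated (or real) table.

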