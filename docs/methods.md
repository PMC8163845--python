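# Methods

This note documents the models, conventions and numerical choices behind
`xlrt`, and what the synthetic benchmarks do and do not demonstrate.

## Retention-time model

A crosslinked peptide is represented as two token sequences. Tokens are
residues, modified residues (`Mox`, `Ccm`, …) or crosslinked residues
(`K_xl`), each mapped to its own positive integer; 0 pads sequences to a
fixed length (`max_len`, default 30). Distinct modification states never
share a token, so e.g. oxidized and plain methionine receive different
embeddings.

Both sequences flow through one shared embedding layer (default dimension
50) and one shared recurrent layer (GRU by default, LSTM optional, 50
units; padded positions are masked so they cannot influence the hidden
state). The two branch outputs are merged — `add` by default, `multiply`
and `concatenate` are available — and feed one subnetwork per prediction
task: three dense layers in a pyramid (50, 20, 10) with batch
normalization and dropout (rate 0.1) between them.

Heads and losses:

- **RP** (reversed-phase retention time, minutes): linear output, mean
  squared error. Targets are internally standardized during training and
  de-standardized at prediction, which keeps the optimizer well-scaled
  regardless of the gradient length.
- **SCX / hSAX** (fraction numbers): ordinal regression. Fraction *f* of
  *n* is encoded as a length-*n* binary vector with *f−1* leading ones;
  the head emits *n* sigmoids trained with binary cross-entropy. Decoding
  returns the 1-based index of the first probability below 0.5; when no
  entry falls below the threshold, fraction *n* is returned — the encoded
  vectors never set the last position, so this cap makes encode/decode an
  exact round trip. The structurally-zero last position is kept in the
  loss (harmless under BCE).

The total loss is `w_RP·MSE + w_SCX·BCE + w_hSAX·BCE` with all weights
defaulting to 1 (with a single task the weight is effectively 1). With
the additive merge, predictions are exactly invariant to the order of the
two peptides, because the branches share every weight and addition
commutes.

Training uses Adam (learning rate 2e-3 by default; the desk-scale
benchmarks below use 60–80 epochs, batch 128) with one master seed
fanning out to weight initialization, shuffling and dropout — two runs
with the same seed produce identical histories. After every epoch the
total validation loss is evaluated; the returned model carries the
weights of the best epoch.

Single-peptide predictions reuse the trained pair model: one branch
output is passed directly to the heads. In the additive merge the heads
then see one contribution instead of the sum of two, which is exactly
what makes the alpha/beta single-peptide errors informative for
rescoring: for a genuine crosslink the *pair* prediction fits the
observation better than either single-peptide prediction.

Transfer learning copies the shared trunk into a new estimator; task
heads keep their weights where shapes match and are re-initialized where
the fraction count changed. The clone fine-tunes on `fit` (warm start)
instead of re-initializing.

The network runs on a small reverse-mode autodiff engine over numpy
arrays (`xlrt._nn`), gradient-checked against finite differences in the
test suite.

## Cross-validation

Confident CSMs are TT matches with q ≤ 1% (self and heteromeric links
estimated separately), deduplicated by the retention-time identity key —
the unordered peptide-pair (with modifications), ignoring link sites and
charge, since retention does not depend on them. With *N* unique CSMs and
*k* = 3 folds the canonical arithmetic is: prediction fold ⌊N/k⌋,
validation ⌈0.1·(N − ⌊N/k⌋)⌉, training the rest — e.g. (3871, 431, 2151)
for N = 6453. When *k* does not divide *N*, the remainder items are
spread over the first test folds so the folds still partition the
confident set and every confident CSM is predicted exactly once. Decoys
and below-cutoff CSMs are predicted by the fold model with the lowest
total validation loss (ties: lowest fold id). Folds are not stratified.

Metrics: accuracy, relaxed accuracy (|error| ≤ 1 fraction), R², MSE. The
learning-curve helper subsamples the CSM table uniformly without
replacement and reports the combined score R²(RP) + Acc(hSAX) + Acc(SCX).

## Feature schema (v1)

Per available dimension *d*: `pred_pair_d`, `pred_alpha_d`, `pred_beta_d`,
signed errors (observed − predicted) for the three, their absolute
values, `sq_err_pair_d`, and the alpha/beta aggregates sum/min/max of
absolute errors — 13 features. With all three dimensions, four
cross-dimension aggregates (summed absolute and squared pair errors,
summed alpha/beta absolute errors, Euclidean norm of the pair-error
vector) bring the total to 43. Alpha is the longer peptide (ties broken
lexicographically — deterministic and order-free). Fraction-valued
dimensions use decoded fractions, so their errors are in fraction units.
The exact published feature list is not printed in full anywhere; this
schema satisfies both printed counts, uses only the named transform
families, and is versioned so alternatives can be plugged in.

## Rescoring

Positives: TT CSMs at ≤ 1% CSM-FDR (entrapment targets included — their
behaviour after rescoring is the overfitting control). Negatives: all TD
and DD matches. Below-cutoff TTs are scored but never trained on. The
labeled set is binned into *k* score percentiles and dealt round-robin
into folds, so every fold spans the score range. Per fold:
standardization fitted on the training folds only, optional SMOTE (off by
default; hand-rolled convex-combination oversampling with a duplication
fallback for tiny minorities), and a linear SVM with C selected from
{0.01, 0.1, 1, 10} by internal 3-fold CV. Labeled CSMs are scored by
their held-out fold's model; unlabeled TTs by the mean of all fold
models. The final score is the exact identity
`rescored = score + score·svm_score`.

## FDR

`FDR = (TD − DD)/TT`, clamped at zero (the raw estimator can go negative
when DD > TD). q-values are the running minimum of the FDR over all
thresholds accepting an item; at tied scores decoys are counted before
targets (conservative) and tied items share the best q. Self and
heteromeric populations are thresholded independently. Roll-ups go CSM →
peptide pair → residue pair → PPI; each level keeps the best-scoring
member per group and filters at its threshold (defaults 5%/5%/5%/1%)
before the next aggregation. Group score is the maximum member score.

## Entrapment database

Candidates sharing any identical tryptic peptide (1 missed cleavage,
maximum length 100, minimum length 7 — the usual search-engine minimum,
below which fragments are shared by essentially every protein) with any
target are excluded; each target, processed in descending length order
(ties by accession), takes its nearest unused candidate by Euclidean
distance on z-scored (K/R count, length), or on the 20-dim amino-acid
composition for small target sets. The combined database interleaves each
target with its match: exactly twice the target count. Exact
tryptic-peptide identity stands in for a 100%-identity local-alignment
screen; shared peptides are precisely what creates ambiguous spectrum
matches.

## Synthetic data

The generator emulates the statistical structure the method relies on,
with ground truth retained:

- Proteins: random sequences from a fixed (roughly bacterial) residue
  frequency table, uniform lengths 80–400; an equal-sized pool is flagged
  as entrapment. True crosslinks are drawn only from non-entrapment
  targets; random matches from everything, with decoy peptides as
  pseudo-reversed sequences.
- Retention: each dimension has an additive per-residue model. RP uses a
  hydrophobicity-like scale; SCX weights K/R/H with the crosslinked K
  attenuated (the linker consumes charge); hSAX weights D/E/Y/F/W. The
  pair coordinate is the sum of both peptides' contributions. For RP the
  sum is mapped through a logistic "gradient curve" onto a bounded
  110-minute elution window: LC gradients are designed (often run
  partially exponentially) to spread peptides roughly uniformly over the
  run, and a bounded, near-uniform elution distribution is also what
  makes a relative noise specification meaningful — with heavy-tailed
  latents, "noise = 5% of range" is dominated by the extremes. The curve
  constants (midpoint 72, scale 15) were calibrated once to the default
  peptide pool's pair-sum distribution. Fraction dimensions are
  quantile-binned by rank (9 SCX, 10 hSAX fractions), so the transform is
  irrelevant there.
- Noise: Gaussian, sd = 5% of the clean range per dimension.
- False matches (TD, DD, random/entrapment TT): half receive the
  coordinate of a pair in which one peptide is correct and the partner is
  random, half a uniform draw over the observed range — mimicking the
  typical failure mode where one peptide of a CSM is right and the other
  wrong.
- Scores: Gaussians, true N(12, 3.5) vs false N(7, 2), overlapping so
  that a meaningful set of true matches falls below the 1% cutoff.
  Random-match classes TT:TD:DD = 1:2:1, which makes E[TD − DD] equal the
  number of false TTs — the decoy estimator is unbiased by construction,
  so calibration failures indicate implementation errors, not simulation
  quirks.

What the synthetic benchmarks show: that the implementation learns an
additive-plus-monotone retention structure from ~2–3k training pairs,
that the CV bookkeeping prevents self-prediction, that the decoy-based
q-values track the realized false proportion, and that rescoring recovers
true matches without inflating entrapment hits. What they do not show:
performance on real elution behaviour (peptides eluting across multiple
fractions, sequence–position interactions the additive model lacks,
batch effects between runs), realistic score distributions, or spectrum-
level effects. Real-data accuracy must be established per dataset via the
built-in CV metrics.

## Problem sizes and defaults used in the shipped benchmarks

The acceptance script and end-to-end tests use 5,000 CSMs (60% true
matches), train on two thirds of the ~2,400 confident unique CSMs for 60
epochs, and evaluate on the held-out third; the negative control uses
five 1,500-CSM replicates. These sizes were chosen to exercise the full
pipeline at desk scale. The entrapment benchmark builds the combined
database for 2,850 targets from a 3,400-candidate pool.

## Known limitations

- The recurrent stack is plain numpy; it is adequate for 10³–10⁴ CSMs
  but not for proteome-scale linear-peptide pretraining corpora.
- Ordinal heads assume a fixed fraction count per dimension; mixed
  fractionation schemes need transfer learning with re-initialized heads.
- `grouped_fdr` implements max-score aggregation only; boosting and
  protein-group levels are out of scope.
- SMOTE falls back to duplication for minorities smaller than the
  neighbour count.
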