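# Methods

## The stacking procedure

Given training data (X, Y) with n samples and p features, `Nfold` folds and
L base-learner configurations, training proceeds as:

1. **Fold assignment.** A uniform random partition of the n samples into
   `Nfold` folds whose sizes differ by at most one, drawn with a fixed seed
   (scikit-learn `KFold(shuffle=True)`). For classification an optional
   stratified assignment (`StratifiedKFold`) preserves label frequencies per
   fold; the default is unstratified, and the flag exists for heavily
   imbalanced labels.
2. **Base training.** For every (fold f, learner ℓ) cell, learner ℓ is fitted
   on the complement of fold f. All `Nfold × L` fits are independent and run
   in parallel via joblib up to `cores` workers.
3. **Out-of-fold table.** Cell (i, ℓ) of the n × L meta-feature table is the
   prediction for sample i by the fold model of ℓ trained without fold(i).
   Each training sample is predicted exactly once per learner by a model that
   never saw it; tests verify this by refitting every cell from scratch.
   For classification the cells are predicted class labels (not
   probabilities): per-learner aggregation at prediction time is a vote over
   categories, and label meta-features keep training and prediction on the
   same representation.
4. **Meta training.** Pooled mode (default): one meta-fit on all n rows.
   Per-fold mode: `Nfold` meta-fits, fit f using exactly the rows of fold f.
   The rows of the per-fold fits partition the training set. (A defensible
   alternative reading would train each meta-fit on the *complement* of fold
   f; the literal per-fold variant is implemented, and the pooled default
   sidesteps the ambiguity.)
5. **Prediction.** New samples go to all `Nfold × L` fold models — fold
   models are deliberately never refit on the full training data, so the
   ensemble averages over fold perturbations. Per learner: arithmetic mean of
   the `Nfold` outputs (regression) or modal category (classification). The
   m × L aggregated table, encoded exactly as at training, feeds the
   meta-model(s); per-fold meta-outputs are averaged (regression) or
   majority-voted (classification).

### Classification encoding

The meta design expands each selected label column into indicator variables,
dropping the first (lexicographically sorted) observed category as the
reference level. The category set per column is frozen at training time; a
category first seen at prediction maps to the all-zero encoding with a
warning rather than an error, since a rare label from one base learner should
not abort an otherwise valid prediction.

### Determinism and parallelism

Every fitted model derives its own 31-bit seed from the global seed and its
grid coordinates through a `SeedSequence` with namespaced spawn keys (base
cells, meta fits, simulation draws and benchmark replicates live in disjoint
namespaces). Serial and parallel training are therefore bit-identical, which
the test suite asserts at cores ∈ {1, 4}.

### Failure policy

A base-learner fit that raises is recorded as a per-cell failure and training
continues: a large learner grid should survive one fragile method. A learner
whose every fold fails — or whose out-of-fold column is incomplete — is
dropped from the meta-feature table with a warning. At prediction, failed
cells are simply absent from the per-learner average; if a learner required
by the meta-model produced no predictions at all, prediction fails loudly.
Conservation (cells fitted + cells failed = `Nfold · L`) is tested.

### Ties and degenerate inputs

Modal-category ties break to the lexicographically smallest label, making
classification prediction deterministic. Pearson correlation and Cohen's
kappa raise an explicit undefined-metric error on zero-variance input or
identical constant labels instead of returning 0 or NaN; constancy is
detected by max−min = 0, not by a standard-deviation threshold, because a
constant vector's floating-point standard deviation can be ~1e−17 rather
than exactly zero. Feature alignment at prediction is by column name with
order normalization when names are available, and mismatches are rejected
with the missing/extra names listed — silent positional misalignment is the
classic stacking bug.

## Base learners and hyperparameter grids

One base learner = one method + one complete hyperparameter setting; a
G-row table contributes G learners, and `cartesian_grid` is the explicit
helper that builds the full combination table from per-parameter value
lists. Keeping rows-as-settings separate from product expansion means the
number of learners L is always visible in the configuration. Hyperparameter
names pass through to the backing scikit-learn estimators verbatim
(`n_estimators`, `alpha`, `C`, `gamma`, `n_components`, ...), so the registry
needs no translation table and any estimator argument is reachable. The
shipped adapters cover random forest, gradient boosting, SVM (RBF and
polynomial kernels), elastic net (coordinate-descent for regression,
saga-solver logistic for classification), partial least squares
(regression only), unpenalized linear/logistic baselines and
mean/median/majority dummies; `register_adapter` accepts new ones at
runtime. Re-implementing any learner's internal fitting is out of scope by
design.

## The synthetic generator

`simulate_regression(n, p, n_causal, snr, seed)` draws X as n × p independent
standard normals, sets unit coefficients on the first `n_causal` variables,
adds unit-coefficient products of neighboring causal variables
(x₁x₂, x₂x₃, …, i.e. `n_causal − 1` pairs), and adds Gaussian noise with
`noise_sd = sd(signal)/√snr`, so the realized variance ratio equals `snr` by
construction and corr(signal, Y) → √(snr/(1+snr)). Interactions are
restricted to the causal block because all other coefficients are zero by
definition; a flag (`interactions="all"`) extends them to all p−1 adjacent
pairs for sensitivity checks. "Signal-to-noise ratio = s" is interpreted as
var(signal)/var(noise) = s — the only reading with a checkable invariant.
The defaults (n=1000, p=200, n_causal=20, snr=4) are the generator's
reference design.

`simulate_classification` quantile-bins the noisy latent into ordered
categories with unequal widths (default probabilities proportional to
1..K, e.g. 0.1/0.2/0.3/0.4 for K=4), so minor classes exist and the
classification path is exercised where kernel methods tend to miss rare
categories.

What the generator does **not** emulate: real marker genotypes (discrete
dosages, linkage disequilibrium, allele-frequency spectra), correlated or
heavy-tailed features, batch structure, missingness. Passing tests on this
generator show the pipeline's mechanics and ordering of methods on a clean
sparse-interaction signal; they do not certify accuracy on any real dataset.

## Benchmark harness

`run_benchmark` races stacking against each base method family run
standalone. Per replicate, paired seeds generate one fresh train/test pair
that every method sees identically. Standalone comparators are ordinary
single-model fits on the full training set; a family with a multi-row grid
selects its row by internal cross-validation over the rows (refit on the
full training set), mirroring how a practitioner would tune a single model.
Method failures mark their cell failed and the run continues.

The reference scenario (`reference_scenario()`) scales the generator's
reference design down to 400 train / 400 test samples and p = 100 — chosen
so a 10-replicate race finishes in a few minutes on one CPU while preserving
the qualitative ordering — with five families (elastic net, random forest,
gradient boosting, RBF-kernel SVM, PLS) at two compact settings each and an
elastic-net meta-learner. At this scale stacking's mean test correlation
exceeds the average of the standalone families' means and tracks the best
single family within a small margin; the acceptance script recomputes these
numbers.

## Persistence

A trained stack is saved as a single zip archive: `manifest.json` (package
and library versions, task, fold count, learner roster with hyperparameters,
failed cells, seed, feature names) next to the pickled fitted states. The
manifest makes archives auditable without unpickling; the round trip is
bitwise-exact in prediction. Archives are pickle-based and should only be
loaded from trusted sources.

## Known limitations

- No repeated/nested CV, no leave-one-out, no prediction intervals.
- Classification meta-features are hard labels; probability stacking is not
  implemented.
- Per-fold meta-training follows the literal per-fold reading (above);
  users comparing against other stacking implementations should check which
  variant those use.
- The benchmark's internal row selection for comparators uses the scenario's
  fold count; with very small n this can be optimistic for large grids.
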