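# Methods

## Setting and model

`poolbo` performs Bayesian optimization over a *finite, enumerated* pool of
molecules: there is no continuous design space, so "optimization" means
deciding which untested pool members to evaluate next. The objective is any
scalar the caller can supply per molecule; the built-in
`LookupObjective`-style table replays precomputed datasets (retrospective
screening), and a synthetic closed-form landscape supports development and
testing. Docking-style scores are lower-is-better; the package works in a
maximization convention internally and negates raw scores exactly once, at
evaluation, which keeps every downstream component (incumbent, acquisition,
metrics) sign-bug-free.

The surrogate's job is ranking, not calibrated affinity prediction: batched
acquisition only needs the relative order of the predicted means (plus a
variance for the uncertainty-aware metrics). This is why fingerprint
regressors with modest accuracy still produce large enrichments.

## Molecular representation

Molecules are canonicalized with RDKit at load; duplicate detection and
score lookup both operate on canonical SMILES, so the same molecule written
two ways cannot enter a pool twice or miss its score. Features are
2048-bit atom-pair fingerprints — binary presence of hashed (atom type,
atom type, topological distance) pairs with bond distances 1–3 — computed
once per pool member and cached (optionally on disk, keyed by file
checksum), because full-pool inference every iteration is the dominant
recurring cost. Hydrogen-suppressed graphs feed the fingerprint (the RDKit
default; explicit hydrogens add no atom pairs at these distances beyond
their heavy-atom context).

## Surrogates

**Random forest** (`rf`): scikit-learn `RandomForestRegressor`, 100 trees,
depth cap 8, trained on raw targets. The predictive variance is the
variance of the individual trees' predictions — the standard ensemble
estimator. The depth cap keeps per-iteration retraining cheap and acts as
regularization at the few-hundred-sample training sizes typical of early
iterations.

**Feedforward network** (`nn`): implemented in NumPy with manual
backpropagation. Two hidden layers of 100 ReLU units, dropout p = 0.2
after each hidden layer, Adam at learning rate 0.01, mean-squared-error
loss with an L2 penalty of 0.01 on the weights, batch size 4096 (clipped to
the training-set size), at most 50 epochs with early stopping at patience 5
on a seeded random 80/20 validation split, re-drawn at each retraining.
Targets are standardized to zero mean and unit variance on the current
training set and predictions un-standardized, which keeps the fixed
learning rate stable as the score scale varies; the forest does not need
this. When the training targets are all identical the validation split is
meaningless, so the model falls back to fixed-epoch training with a
warning.

Uncertainty for the network comes from Monte-Carlo dropout: 10 stochastic
forward passes with dropout active, predictive mean and variance across
passes. With p = 0 the passes coincide and the variance is exactly zero
(computed as such, avoiding float jitter). Alternatively a
mean–variance-estimation (MVE) head outputs (μ, raw σ²) with a softplus
(plus a 1e-6 floor) enforcing σ² > 0, trained with the Gaussian negative
log-likelihood L = ½log(2πσ²) + (y − μ)²/(2σ²).

A directed message-passing architecture is not provided; the package's
surrogate interface (`fit`/`predict` → mean, variance) is the extension
seam, and `architecture="mpn"` raises `NotImplementedError` rather than
silently substituting.

Retraining is from scratch on all acquired data at the start of each
iteration (`retrain_mode="full"`, the default — empirically the more
reliable choice); `"online"` fine-tunes the existing network on only the
newly acquired batch for callers who need cheaper updates.

## Acquisition

Utilities are computed for every pool member (already-tested members are
masked out of selection but still logged) and the batch is the top-b
untested candidates. Parameters default to β = 2 and ξ = 0.01. The
improvement margin is γ = μ̂ − f\* − ξ with ξ *signed and configurable*: the
conventional form subtracts ξ (a penalty encouraging exploration), and a
negative ξ recovers the additive variant some references print. On
docking-score scales the difference (0.02) is negligible. f\* is the best
*observed* objective value, never a prediction.

σ = 0 is handled by the continuous limits of the closed forms: EI →
max(γ, 0), PI → 1{γ > 0}, TS → μ̂ exactly. Thompson sampling draws one
independent normal sample per candidate per iteration. Ties at the batch
boundary — common once scores are quantized to 0.1 — are broken uniformly
at random with the run RNG, so a fixed seed reproduces the batch exactly.
The random baseline is the same loop with prediction-independent uniform
utilities (no surrogate is fit, since nothing would consume it), which
guarantees identical budget accounting to the model-guided runs.

Batch sizes and initialization sizes given as fractions are converted to
counts by ceiling (minimum 1): 1% of a 10,560-molecule pool is 106
molecules, of 50,240 is 503, of 2,141,514 is 21,416.

## Stopping

Besides a fixed iteration budget (default five exploration batches, i.e. a
6% total budget at 1% batches), a convergence rule is available: stop when
|current top-k average − rolling mean of the previous *w* iterations| /
|rolling mean| < threshold, with threshold 0.01 and w = 3 by default. At
least w completed prior iterations are required, a zero rolling mean falls
back to an absolute-difference test, and a signed variant (counting
regressions as convergence) is exposed as an option since the magnitude
convention is a genuine design choice.

## Evaluation metrics

Against a full ground-truth table, a run is scored by:

- **Average**: mean of the k best found scores divided by the mean of the
  true top-k, computed in the raw-score domain with its sign preserved —
  sensitive to near-misses, scale-dependent.
- **SMILES**: |found top-k ∩ true top-k| / k on SMILES sets — strict, and
  brittle when ties straddle rank k.
- **Scores**: multiset intersection of the two k-length score lists / k —
  the tie-robust headline metric. Score values are compared exactly as
  parsed (no epsilon): datasets carry fixed printed precision, and the
  multiset form is precisely what absorbs tied molecules.

The true top-k under ties at rank k is fixed by a stable sort on
(score, canonical SMILES); the Scores metric is insensitive to this rule by
construction. Molecules evaluated as MISSING are excluded from "found" but
counted in the budget when choosing the random-baseline comparison. The
enrichment factor is the ratio of model-guided to random recovery at equal
budget, undefined when the baseline recovery is zero. The repeat-overlap
trace counts cumulative unique SMILES across repeated trials per iteration
against two bounds: all trials disjoint (maximum) and all trials identical
after their own initializations (minimum).

## Synthetic landscapes

The fixture generator enumerates heteroatom-substituted alkyl chains (with
small branch/ring decorations) from a fixed deterministic grammar —
hundreds to tens of thousands of valid, unique, chemically plausible
molecules with no external data. Raw scores are
−(w·φ(x) [+ sparse bit-interaction term]) + 𝒩(0, σ_noise), where φ(x) is
the same 2048-bit fingerprint the surrogates see and w ~ 𝒩(0, I). Placing
the signal in fingerprint space makes the landscape learnable by
construction, emulating the smooth structure–score relationships of real
docking datasets. Optional knobs emulate their warts: quantizing raw
scores to a 0.1 grid (tie-heavy, Vina-style) and blanking a fraction of
scores (failed-dock molecules).

What passing on fixtures shows: the loop's accounting, determinism, and
the *relative* advantage of model-guided over random acquisition when a
learnable structure–score relationship exists. What it does not show:
absolute recovery rates on real docking data, whose landscapes are rougher,
whose score distributions are heavy-tailed, and whose chemical spaces are
vastly more diverse than a chain grammar.

## Benchmark problem sizes

The bundled benchmark (`scripts/acceptance.py`, mirrored by the enrichment
acceptance test) uses a 5,000-molecule linear landscape with noise at 10%
of the signal sd, k = 50 (the top 1%), greedy random-forest acquisition at
1% init + five 1% batches (a 300-molecule budget), five seeds per
condition. These sizes give stable means on a single CPU in about a
minute while leaving the greedy-vs-random contrast far from marginal
(observed enrichment factors ≈ 10–19 across seeds).

## Numerical and degenerate-input choices

- Variance is validated non-negative at the `Prediction` boundary; means
  must be finite, so no NaN reaches acquisition.
- `select_batch` truncates (with a warning) when fewer untested candidates
  remain than the batch size — the final-iteration edge case; the run then
  terminates cleanly on pool exhaustion.
- Empty pools, missing columns, unparseable lookup tables and n > pool
  subsamples are fatal errors; unparseable SMILES rows and duplicate
  molecules are skipped and counted in load reports.
- All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; fixed-seed runs are byte-identical including
  tie-breaks, MC-dropout passes, and synthetic-data generation.

## Known limitations

- No message-passing surrogate (see above); fingerprint models underperform
  learned-representation models on very large, diverse libraries.
- No batch-diversity construction: batches are the plain top-b, which can
  be homogeneous on landscapes with a single dominant basin.
- The RF online mode refits on the supplied rows rather than incrementally
  growing trees (forests do not fine-tune); only the network truly trains
  online.
- The lookup objective is deterministic; stochastic objectives would need
  repeated-evaluation bookkeeping the explorer does not implement.
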