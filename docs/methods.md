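# Methods

## Problem and model

The package predicts the probability that a subject dies within a fixed
horizon (days), given mixed-type covariates, follow-up time and an event
indicator with right censoring. The fixed-horizon view turns survival
prediction into binary classification: a subject who died at or before the
horizon is a positive; a subject observed past the horizon (even if
censored later) is a confirmed negative; a subject censored before the
horizon carries no label and is excluded from binary training and from AUC
evaluation (the censoring discard rule). Risk scores are oriented so that
1 = certain death within the horizon; AUC treats death as the positive
class. One tree is built per horizon, so the learner selected at the root
and every split can differ across horizons.

### Base learner class R

Each cluster's model comes from R = {COX, LINEAR, LOGISTIC}, in that
canonical order (used for tie-breaking):

* **COX** — proportional-hazards regression fitted by Newton-Raphson on
  the Breslow partial likelihood (ties handled by Breslow's method), with a
  small ridge term (1e-4) for stability on near-degenerate risk sets, and
  a Newton step capped at max-norm 10 to survive monotone-likelihood
  clusters. Horizon risk is `1 − S0(h)^exp(βᵀz)` with the Breslow baseline
  survival S0 evaluated at the horizon. Censored subjects participate
  natively, so COX trains on every subject of its cluster. The solver is
  implemented in `tops._cox` because the split search performs hundreds of
  Cox fits per node and needs millisecond fits; its coefficients are
  cross-checked against lifelines in the test suite.
* **LINEAR** — the "linear perceptron" of the method's description is
  under-specified (no update rule is given anywhere); it is implemented as
  a least-squares linear probability model on the 0/1 labels with output
  clipped to [0, 1]: deterministic, convex, and usable both as a node
  scorer and for ranking.
* **LOGISTIC** — L2-regularized logistic regression at inverse strength
  C = 1e4 (near-unregularized; the penalty only guarantees convergence on
  near-separable small clusters).

Binary learners train on horizon-included subjects only and require both
classes. Continuous covariates are standardized to mean 0 / variance 1 on
the training subset inside each learner (binary {0,1} columns pass
through); the transform is stored and reused at scoring time, so the Cox
baseline refers to the training-mean covariate profile.

### Tree construction

The development set is split once, before construction, into a training
part and a validation part (default 80/20, stratified by label;
deterministic given the seed). Subjects censored before the horizon have
no label and join the training side, where Cox can still use them. All
split selection and weight fitting uses validation members only.

Stage 0 trains every learner in R on the full training part and assigns
the one with the highest validation AUC to the root. Then terminal nodes
are processed in creation (FIFO) order; for each, the candidate grid is
every combination of

* split feature (every encoded column),
* threshold (per-node empirical quantiles — default deciles — of the
  feature over the node's training members, de-duplicated),
* learner for each side (from R), and
* training cluster for each side: any node on the root path, or the
  prospective child itself (the set-containment reading of "weakly
  preceding": exactly the clusters containing the child's region).

Candidates are inadmissible if either child would fall below 50 training
members or 5 validation members per class. A candidate is scored by the
AUC, over all validation members of the node, of the combined scorer
(left model on the left members, right model on the right); the argmax is
accepted only if it exceeds the incumbent node model's validation AUC by
more than ε = 1e-4 **and** does not decrease the overall validation AUC of
the working tree predictor (each validation subject scored by its current
terminal node's model). The second condition is this package's own
acceptance rule: local AUC improvement on a subset does not mathematically
imply improvement of the pooled AUC, and the global guard makes the
monotonicity of the build log a construction invariant rather than an
empirical accident. A node whose best candidate fails either condition is
closed permanently; construction halts when every terminal node is closed
(guaranteed by the size floors, ε, and a depth cap of 10).

Ties in the candidate search are broken deterministically: higher AUC,
then lower feature column index, then smaller threshold, then learner
order COX < LINEAR < LOGISTIC (left side then right), then shallower
training node. Node models are frozen once fitted; splitting a child never
refits an ancestor. Within one build, models are cached per (training
node, learner), so ancestor scorers are fitted once.

### Path weights and prediction

For each terminal node, the binary labels of its validation members are
regressed on the score columns of the models along its root path under a
non-negativity constraint (NNLS), and the solution is normalized to sum
to 1, making the prediction a convex combination and hence in [0, 1].
"Linear regression" and "linear perceptron" are both named for this step
in the method's description; NNLS plus simplex normalization is chosen for
the range guarantee. Degenerate cases fall back to uniform weights: fewer
than 10 validation members, identical score columns (within 1e-12), or an
all-zero NNLS solution.

A survival curve for one subject is assembled from trees at ≥ 2 horizons:
survival 1 − H_h(x) per horizon, made non-increasing by
pool-adjacent-violators, anchored at S(0) = 1, and linearly interpolated
between horizons.

## Preprocessing

Features missing in strictly more than 10% of fitting subjects are dropped
(a feature at exactly the threshold is kept). Categorical features with k
levels become k one-vs-rest indicators ("A / not-A"); two-level features
become a single 0/1 column; continuous features pass through. Missing
entries are filled by the column mean (continuous) or mode (binary,
ties → 0), computed on the fitting subset and reused on held-out data.
This deliberate single-pass deterministic imputation replaces multiple
imputation by chained equations: it removes stochastic imputation variance
from the algorithmic test surface, and the `strategy` enum leaves a hook
for richer imputers. Feature relevance (reported per node, top 3) is the
absolute Pearson correlation between each encoded column and the binary
label over the cluster's included subjects.

## Metrics

* **AUC** — tie-aware Mann-Whitney estimate (½ credit for ties); a single
  implementation serves both evaluation and the split search.
* **C-index** — Harrell's convention: a pair is comparable when the
  shorter time belongs to an event (censored subjects enter only as the
  longer member); score ties earn ½; equal times with both events count as
  comparable with ½ credit. No subjects are discarded.
* **Calibration** — equal-frequency bins (default deciles; duplicate
  edges merged), per-bin normal-approximation 95% binomial CI, and
  ρ = RMSE of (mean predicted, observed rate) points from the identity.
* **Operating points** — sensitivity at fixed specificity (smallest
  cutoff reaching the target) with raw correct-positive/negative counts,
  and the mirrored specificity at fixed sensitivity.
* **Cross-validation** — k random folds (default 5); per fold the whole
  pipeline (encoder fitted on the training folds, one tree per horizon) is
  rebuilt and AUC (discard rule), per-horizon C-index and their mean are
  evaluated on the held-out fold; reported as mean ± std across folds. Era
  mode replaces the fold loop with a single train-on-one-date-range,
  test-on-another pass over an explicit date column.

## Synthetic cohorts

The generator emulates the statistical structure of a heterogeneous
registry cohort: continuous covariates ~ N(0,1), binary ~ Bernoulli(0.5);
clusters defined by ordered covariate thresholds (bit pattern of the
threshold indicators); event times exponential or Weibull with per-cluster
baseline rate λ_k (events/year, year = 365 days) and proportional-hazards
effect exp(β_kᵀx); censoring uniform on [0, censoring_max] and independent
of covariates, keeping the mechanism ignorable. The closed-form risk
P(T ≤ h | x) = 1 − exp(−λ_k e^{β_kᵀx} (h/365)^shape) is exposed per
subject and horizon.

Three named scenarios define the study conditions (parameters chosen once
as a realistic desk-scale cohort: d = 4 continuous + 2 binary covariates,
λ = 0.25/year, censoring_max = 3650 days, primary horizon 1095 days):

* **homogeneous** — one global model (n = 4000); nothing to discover, so
  the stopping rule should keep ToPs within noise of a global learner.
* **single-split** — two regimes split at x1 = 0 with distinct
  coefficient vectors and zero direct x1 effect (n = 4000), so first-split
  recovery is driven purely by the regime change.
* **four-cluster** — nested thresholds at x1 = 0 and x2 = 0 with
  sign-flipped per-cluster effects (n = 8000): globally the effects cancel
  and a single model is near-uninformative (held-out AUC ≈ 0.55), while
  the cluster-specific truth is strongly predictive (oracle AUC ≈ 0.91).
  Because the clusters' hazards differ, the correlation between each
  feature and the horizon label — and hence the per-node top-relevant
  features — varies with the horizon, qualitatively echoing
  horizon-dependent feature importance in real cohorts.

What passing these tests does *not* show about real data: the generator's
covariates are independent and its censoring is uninformative, so the
tests say nothing about correlated predictors, informative censoring,
era/cohort drift, or covariate-dependent missingness.

### A note on the discard rule and calibration

Under censoring, inclusion is informative in one direction: deaths are
never discarded, while early-censored survivors-to-be are. Among included
subjects the observed event rate therefore sits above the unconditional
risk (≈ +0.03 at the default censoring level). The oracle-calibration
check (oracle risks as scores, ρ < 0.02 at n = 20000) is accordingly run
in the uncensored regime, where inclusion is unbiased and the closed-form
risks are calibrated by construction; the ToPs calibration check (ρ < 0.1)
keeps the default censoring and absorbs this bias.

## Numerical choices and degenerate inputs

* Improvement threshold ε = 1e-4 on validation AUC; size floors 50
  training / 5 validation-per-class per child; depth cap 10. The method's
  trees are intentionally shallow; these floors encode that while leaving
  room for real structure.
* Candidate learners that fail to fit (single-class child, Cox without
  events, non-convergence) are silently skipped within the search; direct
  calls to `fit_base_learner` raise instead.
* Thresholds use `np.quantile` linear interpolation on training members;
  duplicate quantiles are collapsed.
* Constant columns get relevance 0; empty calibration bins are merged;
  an entirely missing column is an error (the missingness filter should
  have dropped it).
* Determinism: the only randomness is the stratified development split
  and fold assignment, both driven by the seed; given identical inputs and
  seed, tree serializations are byte-identical.

## Known limitations

* No multiple-imputation pooling, competing risks, informative-censoring
  correction, or time-dependent AUC.
* The global acceptance guard can close a node whose split would have
  become beneficial after other regions split; in practice this is rare
  (the local and global criteria almost always agree).
* `search_best_split` and `fit_path_weights` as standalone operations
  need a tree fitted in the current session (the builder state is not
  serialized); deserialized trees support prediction, description and
  survival curves.
* O(n²) C-index; fine for desk-scale held-out folds, not for full
  registry-scale cohorts.
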