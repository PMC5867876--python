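# Methods

## Problem and model

`xenodiff` identifies genes whose expression separates original human tumor
cells from their patient-derived xenograft (PDX) counterparts, and expresses
the separation as human-readable threshold rules. The input is a cells ×
genes table of continuous log-scale expression (single-cell qPCR-style
measurements) with a binary class label per cell; the emulated study shape
is 831 cells (174 human, 657 PDX) × 69 genes. The pipeline has three
stages:

1. **Monte Carlo feature selection (MCFS).** Draw `s` random projections of
   `m` genes; on each projection train `t` binary decision trees
   (information-gain splits, grown to purity, no pruning), each on an
   independent stratified train/test split of the cells. Gene `g`
   accumulates relative importance

   ```
   RI_g = Σ_trees  wAcc^u · Σ_{nodes splitting on g} IG(node) · (n_node / n_tree)^v
   ```

   where `wAcc` is the mean of per-class recalls of that tree on its
   *held-out* cells, and `IG` is base-2 information gain. Measuring `wAcc`
   on the training cells would be uninformative for grown-to-purity trees
   (always 1), so held-out weighting is the only meaningful choice.
   Genes are ranked by descending RI; ties break by ascending column index.

2. **Incremental forward selection (IFS).** Nested candidate sets
   F1 ⊂ F2 ⊂ … (ranking prefixes) are each scored by stratified 10-fold
   cross-validated random-forest classification; the score is the mean
   per-fold Matthews correlation coefficient. One fold assignment is shared
   by all candidates, so the curve's differences reflect features rather
   than fold noise. The optimum is the smallest prefix attaining the
   maximum mean MCC.

3. **Rough-set rule learning.** The matrix restricted to the optimal genes
   is viewed as a decision system (U, A ∪ {d}). Each gene is discretized by
   supervised entropy minimization with the MDL stopping criterion
   (Fayyad–Irani); the generalized decision ∂A unions the labels of objects
   with identical discretized attribute vectors. The discernibility matrix
   holds, for each object pair with differing ∂A, the set of attributes on
   which they differ; the global discernibility function (simplified by
   idempotence and absorption) feeds a greedy Johnson reducer, producing a
   single near-minimal reduct. RIPPER then learns ordered IF–THEN rules
   for the minority class over the reduct genes, on the *raw continuous*
   values with midpoint thresholds, and a condition-free default rule
   assigns the majority class.

## Scoring

The MCC is computed in covariance form: with one-hot indicator matrices X
(prediction) and Y (truth) over N classes,
`MCC = cov(X,Y) / sqrt(cov(X,X)·cov(Y,Y))` where
`cov(X,Y) = (1/N) Σ_k Σ_i (x_ik − x̄_k)(y_ik − ȳ_k)`. The 1/N prefactors
cancel in the ratio and are omitted in code. For two classes this is
algebraically the classical `(TP·TN − FP·FN)/√(…)` formula (asserted to
1e-12 in the tests against that formula and scikit-learn). A constant
prediction or constant truth makes a self-covariance zero; the convention
MCC = 0 (with a warning) keeps IFS curves finite. MCC is used because the
classes are ~1:3.8 imbalanced — raw accuracy of a majority-class predictor
would already be 0.79. Because "positive class" is a convention, the
companion sensitivity/specificity are reported as the recalls of an
explicitly named class (default: the minority class) and its complement.
The reported MCC is the mean of per-fold MCCs (a pooled-prediction variant
is a one-line change in `evaluate_candidate`).

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `s`, `t` | 1000, 5 | projections and trees per projection; canonical MCFS-practice ensemble size |
| `m` | max(⌈0.05·d⌉, 2) | genes per projection (`m ≪ d`) |
| `u`, `v` | 1, 1 | exponents on wAcc and node fraction |
| `train_fraction` | 0.66 | stratified train share per tree |
| `n_folds` | 10 | IFS cross-validation folds |
| RF trees | 500 | IFS evaluator size; √d features per split |
| `gene_frac`, `cell_frac` | 0.5, 0.5 | missingness filters: drop genes, then cells, missing in strictly more than half (ties kept) |
| `k` (imputation) | 10 | neighbors for nearest-neighbor averaging |
| `grow_fraction` | 2/3 | RIPPER grow:prune split, stratified |
| `dl_budget` | 64 bits | MDL slack before rule generation stops |
| `k_optimize` | 2 | RIPPER optimization passes |

All randomness flows from a single seed; per-tree seeds derive
deterministically from (seed, projection index, tree index), so results are
independent of execution order, and adding trees only adds non-negative RI
terms.

## Numerical and design choices

- **Imputation distance.** Distance between cells is the *mean* squared
  difference over genes observed in both, not the raw Euclidean sum —
  unequal observed support would otherwise bias distances toward sparsely
  observed pairs. Neighbor ties break by input row order. A missing entry
  is filled from the k nearest cells that observe that gene (walking past
  neighbors that do not), falling back to the gene's observed mean.
- **Tree induction** uses scikit-learn's CART with `criterion="entropy"`
  (base-2, verified), which matches the information-gain weighting in the
  RI sum; split contributions are read off the fitted tree structure.
- **Permutation cutoff.** The RI significance threshold is the 0.95
  quantile of per-permutation *maximum* RI over label-permuted copies —
  a family-wise control appropriate when any gene may be reported.
- **Generalized-decision collapse.** When few genes receive MDL cuts and
  label noise is present, whole discretized patterns can contain both
  classes, making every pair's ∂A equal — the discernibility function is
  then empty and no reduct exists. The classifier falls back to all
  attributes with a warning. This is a property of the rough-set
  definitions on coarse noisy data, not an implementation artifact.
- **RIPPER description length.** Rule cost is
  `0.5·(log2(k+1) + k·log2(#conditions))` (the standard halving corrects
  for redundant condition encodings); exception cost is the binomial code
  `log2 C(n_cov, fp) + log2 C(n_unc, fn)` plus the two count terms. A
  grown-and-pruned rule is kept only if its prune-set value (p−n)/(p+n) is
  positive and total description length stays within `dl_budget` bits of
  the best seen; a final global pruning keeps the description-length-
  minimal prefix of the rule list and drops any rule with zero support.
  On label-permuted data this leaves the default rule alone.
- **Tie-breaks.** Equal RI → lower column index; equal IFS MCC → fewer
  features (parsimony); equal Johnson frequency → earlier attribute;
  equal FOIL gain → earlier attribute, `<=` before `>=`.

## Synthetic data

The generator emulates the statistical shape of the target study: Gaussian
background (mean 2, SD 1 by default — continuous log-scale expression),
two classes at the 174:657 imbalance, 15 informative genes shifted by
`effect_size·SD` (default 1.5) in the human class, optional planted
threshold-rule conjunctions (satisfying values placed an exponentially
distributed margin past the threshold, so the boundary is dense and
recoverable), optional correlated gene blocks (mimicking co-expressed
keratins), and missingness completely at random. It does **not** simulate
qPCR chemistry, expression-dependent dropout, patient/batch structure, or
heavy-tailed noise; passing recovery tests therefore demonstrates
correctness of the algorithms under the stated statistical model, not
robustness to those real-data complications.

Values can be clipped to a bounded window (off by default) to mimic the
instrument's dynamic range.

## Problem sizes used in the test and acceptance runs

The shipped checks run MCFS at s = 200, t = 5 and the IFS evaluator at 100
random-forest trees on the default 831 × 69 study shape; the end-to-end
determinism check uses s = 50, t = 2 and 30 trees (determinism does not
depend on ensemble size). Property tests that need convergence (RI-profile
stability across seeds) use graded effect sizes so every gene has a
distinct expected RI; with uniform background genes the background portion
of the ranking is exchangeable noise and no finite ensemble stabilizes it.

## Known limitations

- Discernibility is quadratic in cells; beyond ~5000 cells the rough-set
  stage should be subsampled or given the reduct directly.
- Rule induction is two-class only (matching the PDX-vs-human design).
- The published reference rule set is reproduced for *application*
  (classification of new cells); its exact thresholds cannot be re-derived
  without the original study's cell-level data.
- `ri_cutoff` re-runs the full ensemble per permutation; use a reduced
  `s` for exploratory thresholds.
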