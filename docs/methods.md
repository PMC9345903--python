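# Methods

This note documents the models behind `slscreen`, the defaults and why they
were chosen, what the synthetic benchmark does and does not establish, and
the package's known limitations.

## The screening model

The screen treats a synthetic-lethal (SL) interaction between a driver
gene D and a druggable partner P as a conjunction of four observable
signatures, each tested independently on an analysis-ready cohort
(log2(TPM+1) expression for tumors and adjacent normals, a binary
functional-mutation matrix, clinical follow-up, study labels):

* **Compensatory up-regulation.** If D's loss of function makes the cell
  depend on P, P should be expressed higher in D-mutant tumors. Tested
  with a two-sided Wilcoxon rank-sum per candidate, BH-corrected within
  each driver's candidate family, combined with a direction rule
  (log2 fold change > 0, computed as the difference of group means on the
  log2(TPM+1) scale). The significance cut (p_adj < 0.05) is this
  package's choice; only the direction rule is intrinsic to the model.
* **Functional coupling in normal tissue.** SL partners tend to work in
  the same processes, so their transcripts co-vary where neither is
  mutated. Spearman ρ with average-rank ties; the t-approximation is
  replaced by full permutation enumeration for n ≤ 9 normals. Pass
  requires both ρ > 0.1 and BH p_adj < 0.05 — the coefficient threshold
  binds even when p is tiny.
* **Ontological proximity.** Wang-method semantic similarity: the S-value
  of an ancestor t of term A is the maximum product of edge weights
  (is_a 0.8, part_of 0.6) along paths from A up to t; term similarity is
  the shared-ancestor mass normalized by both terms' total masses;
  gene-level similarity is the best-match average over annotation sets.
  The functional similarity score is the geometric mean of the molecular-
  function and cellular-component gene similarities,
  FSS = √(Ss_MF · Ss_CC), passed when strictly above 0.45. A gene with no
  annotation in either namespace has undefined FSS and fails — absence of
  evidence is treated as failure to demonstrate similarity. The
  biological-process namespace is parsed and stored but never enters FSS.
* **Mutual exclusivity.** If losing both genes kills the clone, tumors
  carrying both mutations should be depleted. Raw co-mutation counts
  confound per-gene frequency and per-sample burden, so the null model
  conditions on both: p_ij = logistic(u_i + v_j) fit by alternating
  per-coordinate Newton steps until expected row and column sums match
  the observed margins to 1e-6. The null co-mutation count of a pair is
  then Poisson-binomial with per-sample success q_i = p_{a,i} p_{b,i};
  the one-sided lower tail P(C ≤ observed) is computed by exact truncated
  convolution (O(n·k)), BH-corrected across all tested pairs. The pass
  threshold defaults to p_adj < 0.15, with 0.1 available as the stricter
  documented alternative; both options are deliberately preserved rather
  than reconciled.

The four flags are computed independently and conjoined, so execution
order is irrelevant and tightening any single threshold can only shrink
the final set.

### Rank aggregation

Survivors are ordered by how concordantly they rank across the four
criteria (FSS, log2FC, ρ descending; exclusivity p_adj ascending). With
normalized ranks r₁ ≤ … ≤ r_m (ties = average ranks, r = rank/n), the
Stuart joint order-statistic probability P(U₍ₖ₎ ≤ r_k for all k) is
evaluated by the alternating recursion V_k = Σᵢ (−1)^(i−1) (V_{k−i}/i!)
r_{m−k+1}^i, p = m!·V_m, which is numerically stable for m ≤ 20. The rank
aggregation score is RAS = −log2(p), higher = more concordant; the raw
Stuart probability is used without any multiplicity rescaling, and p is
floored at 1e-300 before the logarithm. Ranked tables break RAS ties by
pair identifier so output order is deterministic.

### Drug-response imputation

Per-compound ridge regressions map cell-line expression to dose-response
AUC (lower = more sensitive). Panel preparation removes haematopoietic/
lymphoid lines, drops compounds missing in > 20% of the remaining lines,
and imputes leftover gaps by averaging the k = 10 nearest compound
profiles (Euclidean distance over co-observed AUCs). Predictors are
standardized on the training lines; λ is selected from 13 log-spaced
values in 10⁻³…10³ by ten-fold CV mean squared error. A model is applied
to tumors only if its cross-validated R² exceeds 0.05: an expression-
uninformative compound scores ≈ 0 or below, and applying such a model
would compare structured noise between mutant and wild-type groups —
empirically this gate is what keeps the decoy flag rate near zero.
Tumor-side genes absent from a model are imputed at the training mean
(zero after standardization), with at least half the model genes required.
A compound is SL-associated with a driver when its estimated AUC is lower
in mutants: logFC = log2(mean AUC_mut / mean AUC_WT) < 0 and two-sided
Wilcoxon p < 0.05. logFC is computed on the AUC scale (ratio of
arithmetic means); the alternative log-AUC convention changes no flag
because the direction rule and the rank test are scale-robust.

### Mutation-status classification

For cohorts without mutation calls, driver status is predicted from
expression. Genes with |log2FC| > 1.5 and BH-adjusted two-sided Wilcoxon
p < 0.05 feed a binomial elastic net with mixing parameter α = 0.9
(mostly-lasso); the regularization strength is selected by stratified
cross-validated deviance. The Wilcoxon engine replaces the moderated-t
fit a typical microarray pipeline would use; the contract is the
threshold rule, not the test engine, and on the strong-signal benchmark
the selected sets coincide. Generalization is measured by
leave-one-study-out cross-validation with gene selection redone inside
each fold — the held-out study contributes nothing to selection or
fitting, which the no-leakage test asserts by hashing coefficients.
Accuracy uses probability cut 0.5; ROC AUC is the normalized Mann-Whitney
U with ties counted ½.

### Survival validation and the network

Within driver-mutant patients, partner expression strictly above the
median defines the active group (ties go inactive, so "> median" and
"< median" partition exactly); groups are compared by log-rank test and a
univariate Cox model with Breslow tie handling, reporting the active-vs-
inactive hazard ratio with 95% CI. The tripartite network contains `sl`
edges (driver → partner, carrying RAS and procedure statistics),
`targets` edges (drug → partner) and `effective` edges (driver → drug),
the last only for flagged compounds whose target is that driver's SL
partner — every effective edge is structurally supported by a
driver → partner → drug path, and no drug node exists without a target
edge. Both invariants are re-checked at every export.

## The synthetic benchmark

The generator plants all four signatures at once and nothing else:

* Expression is Gaussian on the log2(TPM+1) scale, per-gene baselines
  Uniform(3, 8), unit noise sd, clipped at 0.01 to keep the TPM scale
  positive. Rank-based downstream tests make the distributional family
  immaterial; what matters is the ordering structure.
* Planted partner genes shift by `de_shift` = 2 log2-units in
  driver-mutant tumors.
* In normals, each planted pair shares a Gaussian latent factor whose
  loading is calibrated in closed form to a target Spearman correlation
  (ρ_S = 0.6) via the bivariate-normal conversion ρ_S = (6/π)·asin(r/2),
  so the planted effect size is exactly targetable.
* Mutations follow a per-gene rate (Uniform(0.1, 0.3)) × per-sample
  burden (lognormal, σ = 0.25) product model — deliberately the same
  family the exclusivity null fits, so calibration tests are well-posed.
  Planted pairs are resampled jointly with P(both) = 0.1 × the
  independence product, preserving both marginals.
* GO trees (depth 5, branching 3 per namespace) give each planted pair
  its own anchor node three levels below the root: the driver is
  annotated to a leaf below the anchor, the partner to that leaf plus a
  sibling (FSS ≈ 0.82–0.91); decoys are annotated only under anchors no
  pair uses, which at depth 5 caps decoy-pair FSS near 0.34 — below the
  0.45 threshold by construction of the tree depth, not by tuning.
* Cell-line AUCs respond linearly to the target gene's expression
  (AUC = 10 − 0.5·expr + noise). Noise sd defaults to 0.3: with signal
  sd 0.5 this leaves an oracle ceiling of ~0.86 Spearman for held-out
  recovery — a noise sd equal to the signal sd would cap even a perfect
  model near 0.71 and make recovery unobservable in principle.
* Identifiers are synthetic (G0001, T0001, CL0001, CP0001); no real gene
  symbols appear, so nothing here reads as a biological claim.

What passing the benchmark shows: the statistics are implemented
correctly, the thresholds compose as specified, and planted effects of
realistic size are recovered with high precision. What it does not show:
robustness to RNA-seq count noise, batch effects needing explicit
correction, copy-number confounding, annotation incompleteness, or any
property of real tumor cohorts — none of these are modeled.

### Operating characteristics worth knowing

* The exclusivity procedure is the screen's power bottleneck. A planted
  pair whose drawn frequencies land near 0.1 expects only ~3 co-mutations
  in 300 tumors; its raw lower-tail p (~0.005–0.13) can be lifted past
  0.15 by BH across the 1,500-pair family. Benchmark recall is therefore
  seed-dependent (1.0 at seed 42; 0.6 at seed 1) while precision stays at
  1.0 — the conjunction makes false positives vanishingly rare.
* The exact discrete lower tail makes the exclusivity test conservative:
  with the true generative background the type-I error at α = 0.05 is
  ~0.031–0.038 (the attainable size of a discrete test), and with a
  background refit to the realized matrix it drops further (~0.01–0.02)
  because refitting conditions on realized margins and the conditional
  null variance is smaller than the product-model variance. Screening
  conclusions are therefore conservative, never anti-conservative.
* The curveball permutation oracle conditions on exact margins, the
  analytic test only on expected margins. On matrices with few genes the
  two nulls genuinely differ (same-column competition shifts the permuted
  co-count down by O(1/n_genes)); agreement within Monte-Carlo error
  holds at realistic panel sizes (≥ ~200 genes), which is where the
  oracle comparison is run.

## Numerical and degenerate-input choices

* Background fit: all-zero/all-one rows and columns are dropped with a
  warning (their margin constraints are infinite); non-convergence after
  `max_iter` raises with the achieved residuals.
* Poisson-binomial DP truncates above the observed count; escaped mass
  never returns, so retained probabilities are exact.
* Constant expression vectors make Spearman ρ undefined: the pair fails
  co-expression with a warning rather than erroring the run.
* Wilcoxon p-values use scipy's exact method where it applies (small
  tie-free samples) and the normal approximation with tie correction
  otherwise.
* Stuart p is clamped to [0, 1] against floating-point drift and floored
  at 1e-300 before RAS.
* The burden filter ("fewer than ten mutations") counts all recorded
  mutations before the functional-class filter; counting after is a
  switch (`burden_before_class_filter=False`) since the convention is
  ambiguous in the field.
* Functional classes default to frameshift + nonsense
  ({Frame_Shift_Del, Frame_Shift_Ins, Nonsense_Mutation}); splice-site or
  missense inclusion is configuration, not code.
* "Penalty 0.9" for the classifier is interpreted as the elastic-net
  mixing parameter α (the regularization strength λ is CV-selected, so it
  cannot be the fixed 0.9); the DE log2FC cut is 1.5 by default with 1.0
  available.
* Samples exactly at the survival median go to the inactive group.
* KNN imputation k is reduced with a warning when fewer compound
  neighbors exist.
* BH families: per-driver for differential expression, all-pairs for
  co-expression and exclusivity; recorded in the run manifest because
  family choice materially changes p_adj.

## Determinism

Every stochastic step takes an explicit seed; component RNGs derive from
(seed, stream-id) pairs so adding a stage never perturbs another stage's
draws. Fixture sets, result tables and manifests are written with fixed
formatting and sorted keys; the run manifest excludes the output path, so
two runs with the same config and seed are byte-identical wherever they
land.

## Limitations

Pairwise interactions only (no higher-order exclusivity); no co-occurrence
testing; no driver discovery (the driver list is an input); no batch
correction beyond optional per-batch median centering; no copy-number
variation; survival validation is univariate by design. The drug-response
model is linear in expression — compounds with non-monotone dose-response
relationships to their target's expression would need a different learner.
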