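# Methods

## Coordination via normalized eigen-spectra

Given an expression matrix restricted to a gene set of interest, each gene
is Z-scored across the samples of its group (mean 0, SD 1, divisor m−ddof,
ddof = 1 by default). The Gram matrix R = Z Zᵀ of the standardized rows is,
up to the constant factor m−ddof, the sample correlation matrix of the gene
set; its entries are the pairwise inner products Σ_s z_is z_js. Because R
is symmetric PSD by construction we use a symmetric eigensolver
(`numpy.linalg.eigvalsh`), so the eigenbasis is orthogonal and the inverse
in R = Q Λ Q⁻¹ is simply Qᵀ. Eigenvalues are divided by their sum to give a
unit-sum spectrum, sorted descending.

Why this is the right normalization:

* **Scale invariance.** Multiplying the data by any c > 0 multiplies every
  eigenvalue by c², which cancels in the ratio.
* **Divisor invariance.** Switching the SD divisor between m and m−1
  rescales R by a constant; the normalized spectrum is identical. The
  divisor is exposed anyway (`ddof`) for anyone inspecting raw Gram
  entries, whose diagonal equals m−ddof.
* **Interpretability.** λ₁ ≈ 1 means one latent factor drives the whole
  set; λ flat at 1/n means independence. For an equicorrelated set the map
  is exact: λ₁ = (1+(n−1)ρ)/n and the remaining n−1 values are (1−ρ)/n.

**Group comparison.** Spectra are computed per group and differenced rank
by rank, case minus baseline. Both spectra sum to 1, so the deltas sum to
0: increased coordination at the top of the spectrum is necessarily paid
for lower down. We report the full delta vector plus the rank-1
(`largest_delta`) and rank-n (`smallest_delta`) entries. No significance
test is attached to the deltas — none is defined for this statistic here; a
permutation test over group labels would be the natural extension but is
deliberately not implemented.

**Numerical policy.** Eigenvalues in [−10⁻⁸·trace, 0) are clamped to zero
(floating-point PSD violations of rank-deficient Gram matrices, e.g. when
n > m); anything more negative raises. A zero spectrum sum (all-zero
matrix) is a degenerate-input error. Input to the Gram construction is
checked to be standardized (|row mean| < 10⁻⁶) unless explicitly
overridden, because an un-centered matrix silently changes the statistic's
meaning.

**Z-scoring scope.** Default is within-group standardization (each group's
matrix is standardized on its own samples), matching the construction of
separate per-group correlation matrices; a `global` scope (standardize
once, then split) is exposed as a sensitivity flag, since with real
microarray data either convention is defensible and they do not coincide.

## Synthetic data generator

The generator is the package's ground-truth instrument, not a fixture: it
draws log2-scale expression from a multivariate normal whose correlation
is block-diagonal. Each module of k genes is equicorrelated with a
group-specific ρ (valid range ρ > −1/(k−1) for PSD); genes in different
modules and all background genes are independent; a configurable subset of
genes receives an additive mean shift in one designated group; `noise_sd`
scales the unit-variance blocks. The multivariate normal is the minimal
model consistent with Z-scoring and inner products — the statistic consumes
normalized expression, so no count-level (negative-binomial, library-size)
simulation is attempted, and conclusions from passing tests transfer to
real data only insofar as real normalized expression is approximately
elliptical with the assumed block structure. Real data also violate block
independence (background co-expression), have heavier tails, and have
per-gene variances that differ; none of these are emulated.

Sampling uses one global seed; each group draws from a deterministic
substream (`SeedSequence(seed, spawn_key=(group_index,))` in sorted group
order), so datasets are bit-for-bit reproducible and groups can be resized
independently without reshuffling the other group's draws. The eigh-based
multivariate-normal method is used so singular blocks (ρ = 1) sample
cleanly.

Default study design: one 4-gene module (three hub genes plus the MAPT
anchor) with ρ_AD = 0.5627 and ρ_CON = 0.3907 — back-solved from the
population rank-1 eigenvalues 0.672 and 0.543 via λ₁ = (1+3ρ)/4 — so the
default simulation reproduces the magnitude of coordination change the
method is meant to detect. An equicorrelated design constrains the rest of
the spectrum to be flat, so it cannot simultaneously prescribe the smallest
eigenvalue; for that, `sample_from_correlation` accepts an arbitrary
per-group correlation matrix (e.g. one built by `scipy.stats.
random_correlation` from a fully specified spectrum), which is how the
acceptance script emulates spectra whose largest *and* smallest eigenvalues
both rise in the case group.

The edge-list generator plants named hubs with exact degrees: hubs are
wired greedily to the lowest-degree filler nodes (hub–hub edges only when a
degree request exceeds the filler pool), background filler–filler edges are
added at low probability with degrees capped strictly below the smallest
planted hub degree, and the construction re-verifies every requested degree
before attaching uniform [0.5, 1] confidence scores. Infeasible requests
raise rather than silently degrade.

## Differential expression stand-in

The DEG stage is deliberately simple: per-gene log2 fold change as the
difference of group means (inputs are assumed already log2), a Welch
unequal-variance t-test with Satterthwaite degrees of freedom (via
`scipy.stats.ttest_ind`), and a hand-rolled Benjamini–Hochberg step-up
(p_adj at ascending rank i is min over j ≥ i of m·p_(j)/j, capped at 1) that
the tests verify exactly against a brute-force implementation and against
statsmodels. It is a transparent stand-in for a moderated-t pipeline
(voom/eBayes-style variance moderation and covariate design matrices are
out of scope); with n = 50 per group and 3-SD shifts, moderation is
immaterial and the planted genes are recovered exactly. Thresholds are
strict inequalities (|logFC| > 1.5, p < 0.05), applied to the BH-adjusted
p by default with a flag for raw p, since published workflows are often
ambiguous about which they used.

## Hub ranking

Edge lists are parsed from 2- or 3-column TSV with undirected
deduplication and self-loop removal. Confidence scores are accepted on
either the [0,1] or the STRING export [0,1000] scale (auto-detected: any
score > 1 divides the whole column by 1000). Filtering keeps scores ≥ the
threshold. Degree is the unweighted count of retained incident edges; ties
break lexicographically by node ID so rankings are deterministic.

## Classifier ensemble

The contribution implemented here is the aggregation and evaluation, not
the learners: any object with `fit(X, y)` / `predict_proba(X)`
participates. Defaults are scikit-learn's RandomForest (Gini, 200 trees),
RBF-kernel SVC with probability outputs, a logistic-regression linear
model, and a per-class Gaussian density classifier written in this package
(class-conditional multivariate normal with regularized covariance, Bayes
posterior with training priors) filling the mixture-model slot — the
supervised reading of a "GMM" when one Gaussian component per class is
fitted. A least-squares scorer clipped to [0,1] is available as an
alternative linear model. The soft vote is Σ w_k p_k / Σ w_k per sample
and class, default weights RF 2, SVM 2, GMM 1, LM 1; it is invariant to
rescaling all weights. Hard labels use threshold 0.5 with exact ties going
to the negative class. The train/test split is 80/20, stratified and
seeded by default (both exposed, since real studies rarely state either).

ROC is computed from first principles — descending sweep over distinct
scores, cumulative TP/FP counts, (0,0) prepended — and AUC as the
trapezoidal area, which equals the Mann–Whitney pair statistic (ties count
½); the tests enforce that identity to 10⁻¹⁰ and cross-check against
scikit-learn. The "nomogram" use-case is covered by exporting the per-
sample ensemble probability table; graphical rendering is out of scope.

## Problem sizes

Simulation-based checks use 10,000 samples/group for moment and
eigenvalue recovery (tolerances 0.05 and 0.02), 1,000/group for direction
and null tests, 2,000/group in the acceptance script's spectrum recovery,
and 250/group (50/50 in the default pipeline run) for ensemble evaluation;
these sizes put Monte-Carlo error well inside each stated tolerance while
keeping the full suite in seconds.

## Known limitations

* The Welch-based DEG stage ignores covariates and variance moderation;
  it is not a limma replacement.
* Equicorrelated modules cannot represent spectra with structured middle
  eigenvalues; use explicit correlation matrices for those designs.
* The coordination comparison is descriptive — no inferential error
  control is provided on spectrum deltas.
* With n genes > m samples the Gram matrix is rank-deficient; trailing
  normalized eigenvalues are exactly 0 and should not be over-read.
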