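# Methods

## The model

A count table `X` (p OTUs or gene/reaction groups × n samples) is modelled
entry-wise as independent Poisson draws,

    X_ij ~ Poisson((T W)_ij),

where `T` (p × k) holds k non-negative *types* — subcommunity composition
vectors constrained to column sum 1 — and `W` (k × n) holds non-negative
per-sample mixing weights.  Because each type is a composition, the
per-sample sequencing depth is carried entirely by `W`: at the maximum
likelihood solution each raw weight column sums to the corresponding
column sum of `X`.  Working on raw counts (not proportions) lets deeper
samples contribute more information, and the sample-to-sample variation in
the latent mean `T W` produces the overdispersion of observed proportions
typical of microbiome data.

Maximizing the Poisson log-likelihood
`L(T, W) = Σ_ij [X_ij log(TW)_ij − (TW)_ij]` is equivalent to minimizing
the generalized Kullback–Leibler divergence between `X` and `TW`, so the
fit uses the classical multiplicative updates for that divergence.  Each
sweep updates `W` then `T`, renormalizes the columns of `T` to unit sum
(absorbing the scale into `W`), and rescales every `W` column to the
sample depth.  With unit-sum `T` the depth rescale is exactly the
per-column likelihood-optimal scale, so the whole sweep is monotone: the
likelihood trace never decreases (asserted to 1e-9 per step in tests).

Numerical choices:

* initial entries of `T` and `W` are drawn uniform on (0, 1], scaled so
  the initial `TW` total matches the total count; the seed is a required,
  logged parameter;
* `(TW)` is floored at 1e-12 inside logarithms only; no pseudocounts are
  added to the data;
* convergence at relative log-likelihood change < 1e-6 (default), capped
  at 2000 sweeps;
* the factorization is not always unique, so `fit_multistart` /
  `loglik_curve` take the best of (default) 10 seeded restarts rather
  than adding penalties;
* all-zero feature rows are retained (they carry zero mass in every
  type); all-zero sample columns are rejected at load, since a zero-depth
  sample has undefined weights.

## Projecting samples onto fixed types

For fixed `T`, the weights of each sample are the coefficients of an
identity-link, intercept-free Poisson regression of the sample's counts
on the columns of `T`, constrained non-negative.  The objective is
concave in the weights, and the constrained optimum is found by a
backwards–forwards procedure: fit the unconstrained regression
(initialized from linear least squares), batch-drop variables with
negative coefficients and refit until all are positive, then test every
dropped variable for re-entry by placing a tiny coefficient ε = 1e-7 on
it (rescaling the coefficient vector so its sum equals the sample depth)
and re-admitting it only if the likelihood increases.  The ε move is a
discrete directional-derivative test, so at termination every zero-weight
variable has a non-positive likelihood gradient (checked on random
instances in the test suite).

The inner unconstrained fit is Fisher scoring with step-halving that
keeps all fitted means non-negative.  When the optimum presses against
the mean-validity boundary the scoring steps can stall; a stalled iterate
whose coefficients are all non-negative is polished with monotone
multiplicative updates (same optimum, by concavity), while a stalled
iterate with negative coefficients is returned as-is — the outer loop
only consumes its sign pattern.  A sample whose support is disjoint from
every active type has constrained MLE w = 0 and infinite deviance; this
is returned honestly rather than rescaled.

Per-sample fit is scored by the Poisson deviance
`2 Σ [x log(x/μ) − (x − μ)]` (twice the log-likelihood gap to the
saturated model), with 0·log 0 = 0 and deviance +inf when a zero mean
meets a positive count.

## Supervised decomposition and classification

For labelled data the types are fitted separately within each class and
concatenated, `T = (T⁽¹⁾ | … | T⁽ᵍ⁾)`, so class-specific subcommunity
signatures survive rather than being averaged away.  All samples are then
projected onto the combined `T`; the weight columns are normalized to sum
1 (removing depth) and a logistic regression on the normalized weights
performs classification.  Per-class observation weights (e.g. 4× for a
minority class) enter only the classifier, never the factorization.  An
L2 penalty of 1e-8 (iteration cap 1000) guards against divergence on
separable weight matrices while being statistically negligible; with more
than two classes a one-vs-rest scheme is used.  Cross-validation refits
the types inside every training fold; folds are stratified-random by
default or contiguous blocks in sample order for time series.

## Choosing the number of types

For each candidate k, k types are fitted on training folds of the target
class; the held-out own-class fold and a paired fold of the other
class(es) are projected onto them and their per-sample deviances compared
with a Wilcoxon rank-sum test (midranks, tie-corrected variance, no
continuity correction; Z > 0 when the other class fits worse).  The fold
statistics combine into `Z_all = Σ Z_f / √r`, whose spread is estimated
by the sample standard deviation of the fold Z values — not the null
value 1, because the aim is separation, not hypothesis testing.  The
chosen k is the smallest candidate whose `Z_all` is within one such
standard deviation of the maximum.  The other class is split into r
folds with the same seed and paired fold-for-fold (with several other
classes, their paired-fold deviances are pooled).  When the curve is not
clear-cut for some class, its k can instead be refined by minimizing
cross-validated classification error with the easy classes' k fixed,
ties broken toward the smaller k.

Saturation note: when the two classes' deviances separate totally at
*every* candidate (e.g. the other class's support is disjoint from the
fitted types, making its deviances +inf for all k), the fold Z values are
identical across k and the smallest-k rule returns the smallest
candidate.  The regime in which the procedure is informative is the one
where separation *emerges* as k reaches the true type count — see the
generator below.

## Synthetic data

`related_class_types` generates the per-class true type matrices for the
two-class benchmark.  Both classes share a latent pool of max(k)
heavy-tailed profiles (log-normal σ = 1.5 across features); each class
anchors its types on a random subset of pool profiles (anchor weight
0.65, remainder a Dirichlet blend of the pool) and applies a small
log-normal distortion (σ = 0.1) per type.  This emulates types fitted
separately to two classes of real metagenomes: the classes share most of
their community building blocks and differ modestly, while types within
a class are well separated.  Two failure modes motivated this design and
are worth knowing: independently drawn sparse types make the classes
near-orthogonal, so even one fitted type separates them totally and the
selection question degenerates; and types with hard zero supports give
cross-class samples infinite deviances, with the same effect.

The generative sampler draws `W` uniform on (0, 1) (columns scaled to the
requested depths), optionally perturbs the mean `TW` with Gaussian noise
whose per-row standard deviation is sd(T row)/SNR for SNR ∈ {4, 2, 1}
(zero for SNR = ∞; negative means are clamped at 0 — the model leaves
negativity unaddressed, and clamping preserves non-negativity with
negligible mass at these SNRs), and samples Poisson counts.  The
zero-inflated variant draws weight columns from Dirichlet(0.005, …,
0.005), concentrating nearly all depth on very few types; gamma draws
that underflow to exact zero at this tiny shape are kept (they are the
intended sparsity).  The outlier generator flips exactly
round(fraction·n) uniformly chosen binary training labels.  The
clustering benchmark mixes two base compositions in ratios 1:s and s:1
(s ≥ 1) and draws multinomial samples of fixed depth.

Desk-scale study conditions (used by the end-to-end tests and by
`scripts/acceptance.py`): p = 200 features, true type counts (2, 3),
depth 5000, 200 samples per class (first half training), SNR = ∞,
k grid 1–5, 10-fold cross-validation, 5 replicates with a fresh type
draw per replicate.  These sizes keep a full pipeline replicate at a few
seconds while preserving the qualitative regime; what passing shows is
that the machinery recovers structure *generated by its own model
family* (plus the ecological generator below) — not that real
microbiomes satisfy the model.

## Holling type II community dynamics

The ecological generator integrates, per sample,

    dM_i/dt = M_i ( r_i (1 − c_i M_i) + Σ_{j≠i} b_ij a_ij M_j / (1 + a_ij TH_ij M_j) )

with explicit Euler (default 10⁶ steps of 0.001; the benchmark uses 10⁵
steps at its larger sample counts).  Parameters follow the stated
ranges: b_ij uniform on (0, 0.008) for mutualistic (black) edges,
(−0.002, 0.008) for mixed (blue), (−0.08, 0) for inhibitory (red);
1/TH_ij ~ 10⁵·Beta(5, 1); attack rates a_ij default to 1 (no
distribution is prescribed; only the products a·TH and b·a matter at
these scales); per-sample environments r_i ~ U(0, 1) and
1/c_i − 1 ~ 99·Beta(1, 2); initial abundances U(0.1, 10).  Samples that
diverge past 10¹² (or come out empty) are flagged and redrawn.  Final
abundances are rounded to integers for the count container.

The ground-truth network has three overlapping ten-member clusters
(indices 1–10, 9–18, 17–26) plus four isolated OTUs.  The default edge
plan wires each cluster as a sparse circulant (every member linked to its
two followers around the cluster ring) with 6 blue and 3 red
between-cluster edges.  Sparsity matters: each incoming saturating
interaction contributes up to b/TH (a few hundred) to the growth term, so
dense wiring inflates the equilibria until the Euler step is unstable
(dt·relaxation rate > 2) and the subcommunity covariation dissolves into
numerical oscillation.  The published figure of the reference network is
similarly sparse but its exact edge list is not recoverable, so all
benchmark comparisons built on this plan are directional, not exact.

Recovery is scored by a per-subcommunity loss: 1 per true member missing
from the chosen union of clusters, 1 per non-member included, and 1 per
cluster beyond the first.  NMF candidates are the top-j sets of each
fitted type (sweeping an abundance threshold); co-occurrence candidates
are the connected components of the permutation-tested Spearman
correlation network (1000 permutations per pair, two-sided empirical
p-values with the +1 correction, Benjamini–Hochberg across pairs) at
every attained significance level, plus singletons.  The minimum over
unions is exact (bitmask enumeration) up to 20 candidates, otherwise a
width-100 beam search with a warning.  The middle cluster (9–18) is
recovered worst by both methods — its members' interactions are spread
across the two overlaps — matching the benchmark's reported pattern.

## Evaluation utilities

Weight-space distances are plain Euclidean distances between normalized
weight columns.  PAM (k-medoids) is implemented with the classic build +
swap phases on a precomputed distance matrix; tie-breaks are by lowest
index, making it deterministic.  Mis-clustering error minimizes the
misassignment fraction over cluster-to-class matchings (Hungarian
assignment).  The static projection places the k types at fixed planar
positions (default: vertices of a regular k-gon) and each sample at the
convex combination of those positions given by its normalized weights;
the layout is exported as TSV, with optional matplotlib rendering.

## Known limitations

* The selection procedure inherits the smallest-k rule's degeneracy
  under total separation (above); on very easy problems it reports the
  smallest candidate, which is the correct reading of the rule.
* Identity-link Poisson regression near the mean-validity boundary
  relies on the multiplicative-update fallback; likelihoods are then
  accurate to the update tolerance (1e-12 relative) rather than Newton
  precision.
* The Euler integrator is fixed-step; extreme parameter draws are
  handled by redraw rather than adaptive stepping.
* BIOM input is not supported — convert to TSV first.
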