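# Methods

## The estimator

For a predictor block X (N × p) and target block Y (N × q) the CID is
computed in three steps.

1. **Subgrouping.**  The N samples are partitioned into K subgroups by
   agglomerative hierarchical clustering of the rows of X with complete
   linkage on Euclidean distances, cutting the dendrogram at K clusters
   (scipy's implementation; deterministic given the input order).  Clusters
   are relabelled 1..K in order of first appearance so runs are reproducible
   across platforms.  K-means and a minimal 1-D batch self-organizing map
   are available as explicitly seeded alternative backends; they are
   conveniences for robustness checks, not separately validated paths.
   The conditioning partition is the only way X enters the statistic.

2. **Empirical CDFs.**  The multivariate ecdf counts rows componentwise
   `<=` the evaluation point, non-strict in every coordinate and including
   the point itself.  Evaluation points are the observed target rows y_i.
   Internally a single N × N dominance matrix L[j, i] = 1{y_j ≤ y_i} is
   built once; marginal and conditional ecdf values are column means of L
   (over all rows, or rows of one subgroup).

3. **Aggregation.**  D_i = Σ_s (n_s/N)(Ĝ_s(y_i) − Ĝ(y_i))², and
   CID = mean(D_i)/C(N) with C(N) = (N² − 1)/(6N²).  Subgroup-size weights
   n_s/N are used because Σ_s (n_s/N) Ĝ_s(y) = Ĝ(y) identically, making D_i
   the weighted variance of the conditional CDF values around the marginal —
   the decomposition reported as `per_subgroup_share` is exact under this
   weighting and underlies the per-sample discrepancy bars used to inspect
   hits.

**The normalizer and the range of the statistic.**  C(N) is fixed by the
requirement that full dependence attains exactly 1: for a univariate target
with distinct values and singleton subgroups, D_i = Ĝ(y_i)(1 − Ĝ(y_i)) and
the mean over the ranks i/N equals (N² − 1)/(6N²) identically, so CID = 1.
Its large-N limit is ∫F(1 − F)dF = 1/6.  For univariate targets CID ∈ [0, 1]
always.  For multivariate targets the bound can fail in a regime the method
never operates in: when K approaches N and many target rows are pairwise
incomparable (an antichain under the componentwise order), mean Ĝ(1 − Ĝ) can
exceed C(N) and the ratio can reach ≈ 6/(N + 1) at singleton subgroups
(above 1 for N < 5; supremum ≈ 1.5).  Empirically the statistic stays well
inside [0, 1] whenever K ≤ N/2 (max ≈ 0.7 over thousands of random
instances) and far inside it at the working settings K = 3–5, N ≥ 25
(max ≈ 0.4).  We do not clip: the reported value is always exactly
mean(D_i)/C(N), and the property suite quantifies the unit-interval bound
over K ≤ N/2 (all K for univariate targets).

The CID is asymmetric by design; `symmetric_cid` averages the two directed
values, each with its own clustering of its own predictor.

## Dimension reduction for large gene sets

At microarray sample sizes the q-dimensional componentwise ecdf becomes
uninformative quickly: most pairs of rows are incomparable, Ĝ hugs 1/N, and
even perfect dependence yields small discrepancies.  Blocks with p ≥ 10 or
q ≥ 10 (configurable) are therefore replaced by their first
min(3, p, q) pairs of regularized canonical variates.  Columns are first
standardized (mean 0, variance 1, denominator N − 1; constant columns are an
error naming the offending index).  With S_XX, S_YY, S_XY the sample
(cross-)covariances, the variates solve the symmetric eigenproblem of

    (S_XX + λ₁I)^(−1/2) S_XY (S_YY + λ₂I)^(−1) S_YX (S_XX + λ₁I)^(−1/2),

eigenvalues being squared canonical correlations; coefficients have unit
variance in the regularized metric, successive pairs are uncorrelated in
that metric, and the ridge makes the solve well-posed when N < p.  Sign
convention: each predictor coefficient vector is flipped so its
largest-magnitude entry is positive, and the target vector is aligned so the
score correlation is non-negative — eigenvectors are otherwise
sign-ambiguous and downstream heatmaps need determinism.

λ₁, λ₂ are selected on the grid {10⁻⁴, 10⁻³, 10⁻², 10⁻¹, 1} (per-axis,
full product — a shared λ is not assumed) by leave-one-out cross-validation:
the first variate pair is refit on N − 1 samples, the held-out sample is
scored, and the criterion is the correlation of the N held-out score pairs.
Ties break toward the smallest λ₁ + λ₂; a grid cell whose held-out scores
are degenerate ranks below all others.  Pipelines may pass a smaller grid or
fixed λ's when runtime matters.

## Significance

**Permutation test.**  For the CID the subgroup *labels* are randomly
reassigned across samples (the observed partition sizes are kept; the
clustering is not re-run), the statistic is recomputed, and
p = #{null ≥ observed}/B.  Conditioning on the observed partition sizes
keeps the null comparable to the observed statistic, and reusing the fixed
dominance matrix lets all B permutations be evaluated in one einsum.  For
CanCor/KLD/HD/PPR the rows of X are permuted and the full statistic is
recomputed, including re-clustering where it applies; PPR counts
#{null ≤ observed} since a smaller residual sum of squares means stronger
association.  No +1 correction is applied to either count, and ties count
against the observed value (conservative).  All randomness flows from one
integer seed.

**Adjusted-CID screen.**  For an all-pairs screen with G sets, permutations
for G(G − 1) pairs are wasteful; instead each predictor column of the raw
CID matrix is standardized by its off-diagonal median and median absolute
deviation, and adjusted values above 3.5 are called significant — the
modified z-score outlier rule.  The MAD is used unscaled by default; a
`mad_scale` toggle (0.6745) reproduces the textbook consistency convention,
which tightens calls.  Zero-MAD columns are flagged degenerate, logged, and
make no calls.  Only high outliers are called; low outliers are reported but
not flagged.

## Rival measures

CanCor is the largest classical canonical correlation (QR/SVD; a singular
within-block covariance raises an error pointing to the regularized path).
KLD and HD discretize each target dimension into r = 3 bins at its sample
quantiles (type-7 interpolation; ties go to the lower bin), form joint cells,
and compare conditional cell probabilities within each predictor-derived
subgroup against the *global* marginal cells — never re-binned per subgroup,
so occupied conditional cells always have positive marginal mass.  Both
aggregate with n_s/N weights, mirroring the CID; KLD is in nats.  PPR is a
deliberately reduced-scope projection pursuit regression: greedy forward
terms, direction initialized from the least-squares coefficient map,
a LOWESS local-linear smoother (frac = 0.6) along the projection, alternating
loading/direction refinement, and a term kept only if it lowers the RSS (so
RSS is non-increasing in the number of terms).  Its contract is a monotone
proxy for fit quality under permutation, not bit-compatibility with any
legacy smoother stack.

## Simulation models

**Linear (multivariate normal).**  X is N × p standard normal,
u = X·1/√p is the predictor-set signal, and Y = ρ·u·1ᵀ + √(1 − ρ²)·E with
rows of E drawn N(0, (1 − s)I + sJ) via an independent part plus a shared
scalar.  This placement makes ρ exactly the population correlation between
every target gene and the predictor signal (each Y column has unit
variance), ρ = 0 the independence null, and s = 1 the degenerate case of
identical error components.  Defaults: N = 100, p = 5, q = 2,
ρ ∈ {0, 0.2, …, 1}, s ∈ {0, 0.6, 1}.

**Nonlinear.**  Six iid Uniform(0, 1) predictors, two targets:

    Y1 = 20·(X1 + X2 − 1)² + ε1
    Y2 = exp(10·(X3 + X4 − 1))·ε2,     ε1, ε2 iid N(0, 1).

The three channels exercise three qualitatively different alternatives.
(X1, X2) move the mean of Y1 through a quadratic ridge whose linear
projection on each predictor is exactly zero by the symmetry
E[(U − ½)³] = 0, so correlation-based tests are blind to it while the
ridge is smooth at the spatial scale of the predictor clusters — which is
what the CID's conditioning needs.  (X3, X4) modulate only the spread of Y2
(log-sd linear in X3 + X4; a pure scale family, also linearly invisible
since E[ε2] = 0).  (X5, X6) are independent of Y and provide the null
channel.  The amplitude 20 and rate 10 were chosen when the generator was
designed so that, at N = 100 with K = 5 and 1000 permutations, the CID's
power on the mean channel is ≈ 1 and on the variance channel as high as the
statistic permits, while canonical correlation stays below 0.4 on both —
the regime the method is meant to showcase.

One structural fact is worth recording: every conditional CDF of a scale
family crosses the marginal at zero, which caps the per-sample
discrepancies of the variance channel when Y is evaluated *jointly* with
the independent Y1 coordinate.  Testing Y2 alone gives power 1.0; testing
(Y1, Y2) jointly plateaus near 0.9 at these settings regardless of how
extreme the variance modulation is made.  Reported variance-channel powers
around 0.9 reflect this ceiling of the bivariate componentwise ecdf, not an
implementation defect.

**Study runner.**  `run_power_study` draws R replicates (replicate-level RNG
substreams spawned from one seed), computes each requested method's
permutation p-value, and reports rejection fractions at the nominal level
with Wilson 95% intervals; for the nonlinear model it also records the
intersection event (both the mean and variance channels rejecting in the
same replicate).  Benchmarks use R = 100 replicates and B = 1000
permutations with K = 5; the package's own test suite uses the same sizes
for the headline checks and R = 30, B = 200–250 for auxiliary monotonicity
and comparison checks.

## What the generators do and do not emulate

The generators produce exchangeable samples with exactly known dependence
structure, which is what calibrating a permutation test requires.  They do
not emulate microarray realities: heavy-tailed and skewed log-ratios,
probe-level noise, missingness, batch effects, correlated samples (paired
tumor/normal designs), or gene sets that overlap.  Passing tests therefore
demonstrate calibration and power under clean dependence, not robustness to
array artifacts; the I/O layer's missing-value policies (drop-gene per the
complete-probe convention, drop-sample, reject) are tested separately on
constructed fixtures.

## Numerical and interface conventions

- Expression files default to genes-in-rows (samples in columns), the
  microarray convention, with an orientation flag; missing token "NA".
  Gene identifiers are opaque strings; genes listed in a set but absent from
  the matrix are dropped and logged, and no overlap correction is applied to
  overlapping sets.
- Supervised K rule: K = floor(N/10 + 0.5) clipped to [2, N]
  (60 → 6, 48 → 5, 152 → 15); cohorts under 20 samples trigger a warning.
- Duplicate predictor rows simply co-cluster; K = 1 yields CID = 0 exactly
  and K = N singletons are handled without special cases.
- Unsupervised runs process ordered pairs in deterministic collection
  order; reruns with the same seed are bit-identical.
- The all-pairs screen needs G ≥ 3 sets; the table always carries the raw
  value, the adjusted value, the significance call, and whether canonical
  reduction was applied (reduction iff p ≥ 10 or q ≥ 10, auditable per row).

## Known limitations

- The CID's raw magnitude is not comparable across targets of different
  dimension or internal correlation; only the per-predictor adjusted screen
  or the permutation p-value should be used for calls.  Gene-set modules
  with a dominant shared factor are the favorable regime; nearly isotropic
  multivariate targets compress the statistic's dynamic range.
- The multivariate unit-interval bound holds in the operating regime
  (K ≤ N/2) but not universally (see the normalizer discussion above).
- PPR is a reduced-scope stand-in adequate for permutation ranking only.
- The adjusted-CID screen controls nothing family-wise; it is an outlier
  rule, and the 3.5 cutoff with an unscaled MAD is a convention, not a
  calibrated error rate.
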