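# Methods

## Model

A target region with k CpGs measured in n samples is tested as a
multivariate outcome. Beta values β ∈ (0,1) are clipped to
[ε, 1−ε] (default ε = 10⁻⁶) and transformed to M-values
M = log₂ β/(1−β), on which the Gaussian/linear working model is far more
reasonable than on the bounded beta scale. The M-value matrix **Y**
(n × k) is centered per CpG (covariance-based RDA; per-CpG unit-variance
scaling is available with `scale=True` but is not the default, since
M-value variances carry information about probe informativeness).

Redundancy analysis then proceeds in two steps: (1) each CpG column of
**Y** is regressed on all predictor columns of the centered design
**X** (n × m), giving the fitted matrix **Ŷ** (the orthogonal projection
of **Y** onto the column space of **X**, computed via QR) and residuals;
(2) the SVD of **Ŷ** supplies the RDA components. Component
eigenvalues are s²/(n−1), their count is min(m, k, n−1), and component
signs are fixed by making each component's largest-magnitude CpG loading
positive, so output is reproducible. Sample scores (U·s) and CpG
loadings (V) feed the biplot coordinates; group centroids are the means
of member samples' scores.

With conditioning covariates **Z** (n × q) — age, batch, surrogate
variables supplied as ordinary columns — both **Y** and **X** are first
residualized on the centered **Z** (partial RDA). The variance identity
ss_conditioned + ss_fitted + ss_residual = ss_total holds on every fit
(enforced in tests at 10⁻⁸ relative).

**R² convention.** R² = ss_fitted / ss_total with ss_total the *total*
centered variance, including the conditioned-out part. This makes
adjusted models' R² directly comparable to (and no larger than) crude
models' — the behaviour one observes when adjusting a strong crude
association for surrogate variables. The alternative convention
(denominator after removing the conditioned variance) is exposed as
`r2_denominator="conditioned"`.

## Inference

* **Permutation pseudo-F.** F = (ss_fitted/m) / (ss_residual/(n−m−q−1)),
  strictly increasing in R² at fixed dimensions. Samples are treated as
  freely exchangeable: predictor rows are permuted jointly while the
  outcome and conditioning covariates stay attached to their samples.
  Default B = 10,000 permutations; p = (1 + #{F\* ≥ F}) / (B+1) (add-one
  formula, ties counted conservatively), so p ≥ 1/(B+1) — at the default
  B the reporting floor is 1/10001 < 10⁻⁴. Without conditioning, row
  permutation commutes with the QR factorization, so each permutation
  costs one small matrix product (the observed and permuted statistics
  share one decomposition); with conditioning the model is re-fitted per
  permutation. Whether residual permutation under the reduced model
  would be preferable for partial models is a genuinely open choice; the
  simple scheme was chosen because it directly matches "shuffle the
  outcome variable" and is exact when q = 0.
* **Random-region R² null.** "A random region with the same number of
  CpGs" is realized as a run of k *consecutive* annotated probes on a
  single chromosome — this matches the CpG count exactly, whereas
  width-matched windows would not, given variable probe density.
  Windows overlapping the target are excluded by default (switchable) so
  the null is not contaminated by the tested signal; sampling is
  uniform, without replacement until the eligible windows are exhausted
  and with replacement (logged) beyond that. The exceedance p-value uses
  the same add-one formula, and every null window goes through the same
  fit path as the target.

Under a global null E[R²] = 1/(n−1) exactly for any sample-exchangeable
outcome (permutation argument per CpG), which is the analytic anchor for
the ~0.026 null level at n = 40.

## Synthetic data

The simulator emulates chromosome-22 450K data: 8432 CpGs placed
uniformly at random on a 51 Mb pseudo-chromosome, each with beta values
drawn i.i.d. across samples from Beta(a_j, b_j). The per-CpG parameters
of the reference cohort behind the original design are not published, so
`default_cpg_parameters` draws a declared synthetic stand-in: per-CpG
means from a three-component mixture (hypomethylated ~ Beta(2,18),
weight 0.45; hypermethylated ~ Beta(18,2), weight 0.40; intermediate
~ Beta(5,5), weight 0.15) reproducing the bimodal array marginal, and
precision ν = a+b log-uniform on [50, 500], covering tight extreme
probes and noisier intermediate ones. `fit_cpg_parameters` provides a
method-of-moments fit (ν floored at 2, zero-variance guarded) for users
with their own reference beta matrix.

A DMR is injected by placing a region of the requested width uniformly
at random (re-drawn until it contains ≥ 3 CpGs), selecting
round-half-up(fraction × k) DMP positions uniformly without replacement
inside it, and shifting each DMP's mean beta by ±d in group 2 with the
precision ν preserved. The shift direction is random per DMP by default
(large regions plausibly mix hyper- and hypo-methylation; `--direction
up|down` forces one sign), feasibility-checked and clamped to
[0.02, 0.98] so Beta parameters stay well conditioned. Non-DMP CpGs are
identically distributed in both groups, which is what makes the
benchmark's "random region" rows a genuine null.

Default grid: region widths 500/300/100/50 kb × n ∈ {10, 40, 100}
(two equal groups) × mean-difference d ∈ {0.3, 0.1, 0.05} × DMP fraction
∈ {30%, 10%}, 200 replicates per cell, 10,000 permutations. Seeds are
hierarchical (master → scenario → replicate → stream) so any cell
reruns independently and bit-identically.

**What the simulation does and does not show.** Samples are i.i.d. given
group, CpGs are independent given their Beta parameters, and there are
no probe-chemistry, batch or cell-composition effects — so passing
benchmarks demonstrates the statistical behaviour of the test (null
level, exactness of the permutation p, power ordering), not robustness
to correlated probes or technical structure in real arrays (covariates/
surrogate variables are the intended handle for the latter). Absolute
R² magnitudes under signal depend on the synthetic Beta baseline and are
treated as qualitative: what is invariant, and what the tests assert, is
that mean R² increases with d and with the DMP fraction, does not trend
with region width, and sits at 1/(n−1) under the null.

## Numerical and validation choices

* Rank checks via the QR diagonal at 10⁻¹⁰ relative tolerance; constant
  design columns and collinear encodings raise errors rather than being
  silently dropped.
* Dummy coding uses the first lexicographic level as reference; only the
  span of the contrasts affects R², so this is a reproducibility
  convention, not a modelling choice.
* Missing betas: CpG rows with any missing value are dropped (count
  logged), no imputation. Regions with fewer than 3 CpGs are refused
  (a 1–2 CpG "region" is a probe test, not a regional one).
* Zero residual variance yields an infinite pseudo-F with a warning.
* The implementation is cross-checked in the test suite against an
  independent constrained-ordination implementation (R vegan's `rda`,
  crude and partial models: R², pseudo-F and eigenvalues agree to
  10⁻⁸), and against per-CpG OLS oracles.
* Validation problem sizes (chosen to keep the whole suite at a few
  minutes while leaving Monte-Carlo error well below the tested
  margins): 200 windows for the null R² level; 400 null permutation
  tests at B = 199 for the type-I binomial check; 1000 null tests for
  p-value uniformity (KS at the 1% level); 20 replicates/cell for the
  grid-structure checks; 50 replicates for the strong-scenario power
  bound.

## Limitations

* No modelling of Infinium I/II probe chemistry, spatial correlation
  between neighbouring CpGs, batch effects or cell-composition
  heterogeneity.
* The tool answers the *targeted* question only; it does not scan the
  genome for candidate DMRs.
* The random-region null draws windows from the chromosomes present in
  the annotation — with a single-chromosome annotation it is a
  chromosome-wide, not genome-wide, null.
* Linearity between predictors and M-values is assumed; for categorical
  designs this is automatic, for continuous predictors it should be
  checked.
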