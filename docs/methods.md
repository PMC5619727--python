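# Methods

## The model space

A candidate model is a partition of the J observed cell types into
disjoint groups sharing a mean β-value. Rather than enumerating all set
partitions (Bell(6) = 203 for six cell types), the model space is tied to
the hematopoietic lineage: the dendrogram of per-cell-type mean
methylation profiles (agglomerative clustering, Euclidean distance;
complete linkage by default, with single/UPGMA/WPGMA available) proposes
one model per leaf and one per internal non-root node. In a node's model
every member cell type receives its own mean and all non-members are
pooled into a single *reference* partition; the root is skipped because
its model coincides with the saturated one. Together with the null model
(one common mean) and the saturated model (all means distinct), the
canonical six-population lineage — (CD14 Mono, CD16 Neu) myeloid branch;
((CD4 T, CD8 T), CD56 NK), then CD19 B on the lymphoid branch — yields
twelve distinct models. Models whose set partitions coincide (which
happens for small J) are deduplicated with the canonical name kept, so a
two-leaf tree collapses to just {null, saturated}. Users can also supply
an explicit model list, bypassing clustering entirely; clustering ties
are broken deterministically by sorting cell types lexicographically
before linkage.

## Likelihood, priors, closed-form marginal

Per CpG and sex, the n×J observations follow
y_i ~ N_J(X μ, σ² I) with a common residual variance across cell types
(an identifiability choice at these sample sizes). The g-prior
μ | g, σ² ~ N_P(b₀1, g σ²/n (XᵀX)⁻¹) is, after stacking the n
replicates into the design Z = 1_n ⊗ X, exactly the textbook Zellner
prior g σ² (ZᵀZ)⁻¹ centred at the global mean b₀. With p(σ²) ∝ 1/σ²,
writing w = y − b₀, F = Σ_p (Σ_{ij∈p} w_ij)²/(n c_p) for group sizes
c_p, and TSS = Σ w²,

    log p(y | m, g) = log Γ(N/2) − (P/2) log(1+g) − (N/2) log π
                      − (N/2) log Q,     Q = TSS − F·g/(1+g),  N = nJ.

The derivation is standard normal–inverse-gamma conjugacy; the test
suite checks it against an independent oracle that integrates μ through
explicit N×N covariance algebra and σ² by adaptive quadrature on
log σ², to 1e-6 relative error. The marginal is proper only when
N > P (enforced) and degenerates if the data equal b₀ exactly (raised
as an error).

Posterior moments used downstream:

* μ | y has mean b₀ + g/(1+g)(μ_OLS − b₀), the partition sample means
  shrunk toward b₀. The b₀ term cancels from every difference of
  components, so all differential and sex-effect quantities are
  unaffected by the choice of centre.
* σ² | y ~ InvGamma(N/2, Q/2); the plug-in point estimate is the
  posterior mean Q/(N−2) (the mode Q/(N+2) is used, with a warning, in
  the N ≤ 2 corner that assembled datasets cannot reach). The mean was
  chosen over the mode because the estimate is used as a conventional
  plug-in in the downstream normal posteriors.

Posterior model probabilities use equal priors and log-sum-exp
normalisation, so log marginals of magnitude up to ~1e4 cause no
overflow.

## Empirical-Bayes estimation of g

g is shared by all CpGs of a sex and estimated by maximising the
model-averaged marginal likelihood Σ_k log Σ_m p(y_k|m,g) Pr(m). The EM
algorithm treats each CpG's model indicator as latent: the E-step
computes responsibilities Pr(m|y_k,g), the M-step maximises the
expected complete-data log likelihood by bounded scalar optimisation on
log g (bounds e^±~18, Brent, xatol 1e-10). Defaults: init g = 1,
relative-objective tolerance 1e-6, at most 200 iterations;
non-convergence returns the best iterate with a warning. The objective
is ascent-monotone (asserted with 1e-8 slack), and on simulated data
the EM typically converges in well under ten iterations to the same
maximiser as a grid search with local refinement. Note that the
maximiser can be large (ĝ in the thousands when between-cell-type
effects dwarf the noise); a grid capped at 1e3 will sit on its upper
edge, which is why the test-suite grid oracle expands its refinement
bracket past a boundary argmax.

Separate sexes are fitted separately: own b₀ (grand mean of that sex's
β-values by default), own ĝ, same candidate models.

## Marker panels and downstream posteriors

For each model, CpGs are ranked by posterior probability and the Bayes
FDR of the top-r set is estimated by the mean of (1 − probability) over
the set — non-decreasing in r, so the panel is the longest admissible
prefix at the level (default 5%); tied probabilities enter all-in or
all-out. An empty panel is valid and carries realized FDR 0 by
convention.

Differential methylation within model m compares each cell-specific
partition p with the reference partition: the posterior of
μ_p − μ_ref is normal with mean μ̂_p − μ̂_ref and variance
g/(1+g) · σ̂²/n · (1/c_p + 1/c_ref). It is summarised by the mean, a
95% CI (±1.959964 sd), probabilities that |difference| falls in the
left-closed bins [0,0.10), [0.10,0.20), …, [0.50,∞), and a state:
hypomethylated when the mean is negative, hypermethylated when
positive, unclassified at exactly zero (a measure-zero tie; no
arbitrary sign is imposed). The saturated model has no reference and is
excluded from differential summaries unless a baseline partition is
designated explicitly; the null model has nothing to compare.

Sex effects are assessed on common markers (same model selected in both
sexes). Per cell-specific partition, the female−male difference is
normal with mean μ̂_F,p − μ̂_M,p and variance
σ̂²_F·ĝ_F/((1+ĝ_F)n_F c_p) + σ̂²_M·ĝ_M/((1+ĝ_M)n_M c_p) — the sum of
the two sexes' posterior variances for that partition mean, the
diagonal form consistent with the differential-methylation variance. A
marker is declared sex-specific when Pr(|Δ| ≥ δ) > τ for some
partition (defaults δ = 0.10, τ = 0.95). The probability is two-sided
in |Δ|, so swapping the sexes negates the mean and preserves the
declaration.

Validation recomputes, in an independent dataset, the mean difference
between each summarised partition and its reference, restricted to the
cell types the validation data actually contains (the multivariate
normal marginalises coordinate-wise); it reports the percentage of
training 95% CIs covering the validation difference, the percentage of
sign-concordant states, and — for multi-partition models — joint
(all-partitions) rates alongside per-partition ones. CI coverage is
sensitive to an underestimated σ̂², which is why state concordance is
reported alongside it.

## Synthetic data

The generator mirrors the likelihood: per CpG it draws a model from a
mixture (uniform over the twelve models by default), a reference
baseline (uniform on [0.2, 0.8] by default, keeping boundary clipping
rare at σ ≤ 0.05), an offset for every cell-specific partition, and
i.i.d. N(0, σ²) noise per subject and cell type, clipping to [0,1] and
counting clip events (a clip fraction above 10% warns that the
configuration is unrealistic). Defaults emulate the six-population
sorted-leukocyte design: J = 6, five female and six male subjects,
σ = 0.02, effects around 0.3 on the β-scale.

Two deliberate design choices:

* A scalar effect size e draws each partition's offset magnitude
  uniformly from [0.75e, 1.25e] with a random sign. A constant
  magnitude would let two same-sign partitions of a multi-partition
  model coincide exactly, collapsing the realized pattern onto a
  coarser partition that may not be in the candidate set; the jitter
  keeps partition means distinct almost surely while preserving the
  nominal effect scale. Saturated-model probes draw an independent
  offset per cell type.
* Sex effects are additive mean shifts applied to one randomly chosen
  cell-specific partition of the male copy (probability 0.05, magnitude
  0.2 by default), matching the object of the sex-effect posterior;
  null-model probes carry none.

What the generator does *not* emulate: probe-type chemistry biases,
batch effects, beta-distributed (heteroscedastic) noise, spatial
correlation along the genome, or SNP artefacts. Passing tests therefore
demonstrate correctness of the inferential machinery under the model's
own assumptions plus boundary clipping, not robustness to array
artefacts. Clipping at the [0,1] boundary slightly attenuates large
effects and large sex shifts near the boundary, which depresses
sex-effect sensitivity in configurations with baseline + effect + shift
near 1.

## Calibration of the Bayes FDR, and a known limitation

When data are generated from the model's own law (models uniform,
partition means drawn from the g-prior), the realized false-discovery
proportion of the 5% panels matches the nominal level (≈ 0.05 in the
test suite's self-generated check). Under point-effect simulation truth
— effects essentially fixed at 0.3 ≈ 15σ with a 90% null / 10% signal
mixture — the realized FDP of the mean-rule panels is materially higher
(≈ 0.10–0.11): true signal probes then carry posterior probabilities
within 1e-8 of 1, and the mean-of-(1−p) rule lets them subsidise
moderate-probability entries which, in a null-dominated mixture with
point effects, are almost exclusively null. This is a property of
posterior-probability-based FDR estimates under prior misspecification
(both the equal model prior vs the 90/10 mixture and the continuous
g-prior vs point effects), not of the implementation; the achieved
*estimated* Bayes FDR is ≤ the level by construction. Users who need
frequentist FDP control under sparse strong signals should treat the
nominal level as an estimate, not a guarantee.

## Numerical and procedural choices

* Probes are intersected across sexes before common-marker and
  sex-effect computation; missing data are dropped (subjects lacking a
  cell type, probes with any missing value) with logged counts — the
  model has no missing-data mechanism.
* Cell-type order is lexicographic unless a lineage ordering is given;
  assembly is invariant to input row/column permutations up to that
  ordering.
* β-value validation is strict at load time: duplicate probe ids and
  values outside [0,1] are hard errors naming the offending cells.
* All randomness flows through a single integer seed per simulation;
  identical seeds give identical datasets.
* Problem sizes used by the test suite and the acceptance script
  (K ≤ 2000 CpGs, 20 replicates) were chosen as the smallest scales at
  which the Monte-Carlo error of the reported proportions is a few
  tenths of a percent; the vectorised fit handles hundreds of thousands
  of probes (per-probe work is O(M·J) on sufficient statistics).
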