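# Methods

This note documents the models implemented in `multigwas`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
can and cannot say about real cohorts.

## Estimators and their relative efficiency

For a biallelic variant with dosage `g_ij ∈ {0,1,2}` in group `j` of size
`n_j`, phenotype `y_ij = β g_ij + ε_ij` with `ε ~ N(0, σ²)` and a constant
allelic effect across groups:

* the within-group OLS slope is `β̂_j = S_xy,j / S_xx,j` with variance
  `σ²/S_xx,j`, where `S_xx,j` is the centered genotype sum of squares in
  group `j`;
* the pooled slope replaces within-group sums with totals:
  `β̂_P = S_xy / S_xx`, variance `σ²/S_xx`;
* the IVW fixed-effect meta estimate with weights `w_j = 1/Var(β̂_j)`
  reduces to `β̂_M = Σ_j S_xy,j / Σ_j S_xx,j`, variance `σ²/Σ_j S_xx,j`.

The ANOVA decomposition `S_xx = Σ_j S_xx,j + Σ_j n_j (ḡ_j − ḡ)²` then gives

```
ARE = Var(β̂_M)/Var(β̂_P) = S_xx / Σ_j S_xx,j ≥ 1.
```

`theory.are_asymptotic` evaluates the population version by substituting
`E[S_xx,j] = n_j · 2 f_j (1−f_j)` and `E[ḡ_j] = 2 f_j`;
`theory.are_empirical` computes the realized decomposition from a panel.
The variance-ratio convergence is verified by Monte-Carlo in the test
suite (500 replicates, 5,000 per group, ratio within 10%).

`σ²` is treated as shared across groups in the variance formulas, matching
the derivation above; empirical comparisons of estimator variance use
Monte-Carlo over replicates rather than per-group variance estimates. The
derivation is covariate-free; covariate-adjusted behaviour is studied
empirically through the association engines.

## Synthetic genotypes

**Allele frequencies.** Balding–Nichols: group frequency
`f_j ~ Beta(p(1−F_j)/F_j, (1−p)(1−F_j)/F_j)` around an ancestral `p ~
U(0.05, 0.95)`, so `E[f_j] = p`, `Var(f_j) = F_j p(1−p)`. Default F_ST per
group (AFR 0.15, AMR 0.10, EAS 0.12, EUR 0.08, SAS 0.10) are round values
in the range typically estimated between continental groups and a shared
ancestral population. Variants that come out numerically monomorphic are
dropped with a logged count.

**Within-group substructure.** Real continental ancestry groups are not
homogeneous: they carry admixture gradients and fine-scale structure, which
is precisely what ancestry-group-specific PCs capture in biobank data.
Optionally (`n_subpops`, `sub_fst`), each group is therefore composed of
subpopulations whose frequencies are a second Balding–Nichols draw around
the group frequency. Without this feature, group-specific PCs of a
simulated panel are pure sampling noise and the group-specific
stratification scenario below would be vacuous — no method could inflate.
Scenario runs default to 3 subpopulations per group at sub-F_ST 0.02, a
mild level of internal differentiation. Group labels, group-level
frequencies, and all MAF rules are unaffected.

**Linkage disequilibrium.** Haplotypes are first-order Markov chains along
the variant sequence: within a physical block (default 100 kb), adjacent
alleles target correlation ρ (default 0.8), with the joint probability
clipped to the Fréchet bounds so the marginal frequency of every variant is
honoured exactly; blocks are independent. This is the simplest structure
that makes LD pruning, LD clumping and the ±500 kb LD-based power metric
meaningful. It does not reproduce empirical LD decay, haplotype sharing
across groups, or long-range LD. Default variant spacing is 5 kb.

**Admixture.** Two-way admixed haplotypes are generated by drawing ancestry
switch points as a Poisson process along the genetic map with rate equal to
the number of generations per Morgan (default 10), assigning each segment's
ancestry i.i.d. with the target proportion, and sampling alleles from the
segment-ancestry group frequency (or copying from supplied source haplotype
pools). The genetic map is uniform at 1 cM/Mb by default. Segment
ancestries are drawn independently, which ignores the drift of individual
admixture fractions around the target proportion; local-ancestry tracts
have the correct exponential length scale but alleles within a tract are in
linkage equilibrium unless haplotype pools are supplied.

## Population structure estimation

LD pruning is the standard greedy left-to-right scan (r² > 0.1 within
500 kb removes the later variant), run once on the pooled panel; whether
per-group PCA should re-prune with within-group r² is ambiguous in the
workflow this mirrors, so the pruned set is an explicit argument and can be
recomputed per scope by the caller.

PCA standardizes dosage columns by `(g − 2f̂)/√(2f̂(1−f̂))` with `f̂`
estimated from the samples the PCA runs on (pooled-sample frequency for the
cross-group scope, within-group frequency per group), skipping monomorphic
columns. Eigenvalues are those of the sample covariance; each component's
sign is fixed so its largest-magnitude loading is positive. For matrices
above ~4 million entries the top-k decomposition uses a seeded randomized
SVD with 10 power iterations rather than a full decomposition: it is
deterministic, and the leading components — the well-separated ancestry
axes that all downstream modelling consumes — agreed with a Lanczos solver
to print precision on representative panels; only bulk (noise) components
differ at the percent level. Smaller problems use exact LAPACK SVD.

Variance explained by a PC set uses the two-step procedure: residualize
the trait on age and sex within each group, then ΔR² between the full model
(both PC sets, group-specific scores stacked sample-wise) and the reduced
model with only the other set, with percentile bootstrap CIs (default 1,000
replicates; configurable upward — the procedure this mirrors used 10,000).

## Phenotype generators

All generators target total within-group variance 1.

**Null phenotypes.** `y = Σ_{k≤10} δ_k PC_k + ε`, `ε ~ N(0, 1−α)`, with
`δ_k = √(w_k α / Var(PC_k))` and `w_k = λ_k/Σλ` the eigenvalue share.
This is the unique allocation that (i) splits the stratification variance
α across PCs proportionally to their eigenvalues and (ii) preserves unit
phenotype variance, which pins down the otherwise ambiguous placement of
the square root. The grid α ∈ {0, 0.2%, 0.5%, 1%, 2%, 5%} spans observed
values through hypothetical extremes.

**Continuous traits.** `y = γ_j + Σ_l X_l u_l + Σ_k δ_k PC_k + ε` with
`X = (G − 2f_j)/√(2f_j(1−f_j))` standardized by the sample's own group
frequency (the explicit centering enforces the stated mean-0/variance-1
scale), shared standardized effects `u_l ~ N(0, h²/L)` (default h² = 0.4),
group intercepts `γ_j ~ N(0,1)`, and `ε ~ N(0, 1 − h² − Σδ²Var(PC))` so
the unit-variance budget closes. Shared standardized effects imply
per-allele effects that scale as `1/√(2f_j(1−f_j))` — groups where the
variant is rarer have larger per-allele effects. Power scenarios add a
small group-specific PC component (α = 0.26%, two PCs per group), the
median group-specific PC variance observed in the large cohort this
emulates.

**Binary traits.** The same linear predictor on the logit scale with
logit-scale genetic variance h² = 0.57 (a breast-cancer-like architecture);
the group intercept α_j is found by root bracketing so that
`mean(expit(α_j + liability))` matches the target prevalence within 1e-4
(monotone, hence unique). Case-control sampling keeps all cases and draws
controls without replacement at the configured ratio (default 1:1).
Scenario runs simulate a configurable pool and sample from it rather than
simulating millions of subjects. Liability-threshold (probit) models and
effect-size heterogeneity across groups are out of scope.

## Association engines and combination

The linear engine residualizes the phenotype and all dosage columns on the
covariates once (QR projection) and computes per-variant slope, standard
error (residual variance at full OLS degrees of freedom) and a two-sided
normal Wald p — exactly the full per-variant OLS by Frisch–Waugh–Lovell,
verified against a matrix-inversion oracle at 1e-8. The logistic engine is
per-variant IRLS (max 25 iterations, |Δloglik| < 1e-8); separation or
non-convergence is reported (`converged=False`), not repaired (no Firth
correction). Zero-variance dosages yield unconverged rows with no p-value.

Variant inclusion follows the asymmetric MAF rules: pooled analysis and
IVW meta-analysis cover variants with MAF > 1% in *at least one* ancestry
group (per-group analyses test their own common variants; the union feeds
the meta-analysis), while the meta-regression restricts to MAF > 1% in
*all* groups, so its output is a subset. The effect allele is ALT
throughout. Groups below 50 samples (configurable) are skipped.

IVW combination: `β̂_M = Σw_jβ̂_j/Σw_j`, `se = (Σw_j)^{-1/2}`, `w_j =
1/se_j²`, z-test p-value.

The meta-regression combiner regresses per-group effects on T axes of
genetic variation (weights `1/se_j²`). The axes are classical (Torgerson)
MDS coordinates of the J×J matrix of mean squared allele-frequency
differences — implemented directly via double-centering and
eigendecomposition since the dissimilarity is already squared-Euclidean in
form. Per variant, with X = [1, axes]:

* association: χ² = RSS(empty) − RSS(full), df T+1 (at T = 0 this equals
  the IVW z², which the tests assert at 1e-8);
* ancestry-correlated heterogeneity: χ² = RSS(intercept-only) − RSS(full),
  df T;
* residual heterogeneity: χ² = RSS(full), df J−T−2.

The axis count follows T = J−3 for J ≥ 4 groups (3 axes at six groups, 2 at
five); below four groups the method is reported not-applicable, with an
explicit T override available. This component reimplements the published
meta-regression framework it is named after; it is not an original method
of this package.

## Evaluation layer

Power against a known causal set is measured two ways: exact recovery (the
causal variant itself reaches p ≤ 5×10⁻⁸) and LD-based recovery (some
significant same-chromosome variant within ±500 kb — the window is a
radius, and cross-chromosome hits never count). Type-I error is the
exceedance rate at nominal levels with Wilson 95% intervals; `flag` marks
two-sided miscalibration and `inflated` marks the directional failure
(interval entirely above nominal), since a conservative method should not
be labelled inflated. Genomic inflation is the median-χ² λ (constant
0.4549, p-values clipped at the smallest positive float), with
λ₁₀₀₀ = 1 + (λ−1)(1/n_cases + 1/n_controls)/(2/1000) for binary traits and
the `2/n` analogue for quantitative ones. LD clumping greedily takes the
most significant remaining variant (position tie-break) and removes
significant neighbours with r² > 0.1 within a 500 kb radius, matching the
pruning window since no separate clumping radius is standard.

## Scenario designs and scale

`pipeline.run_scenario` wires everything end to end for five designs:
equal group sizes, fixed reference-group size, fixed total size, a
four-group admixed design (100% EUR, 100% AFR, 50/50 and 20/80 EUR/AFR —
the text description of this design and its summary table disagree on one
group; the table's EUR+AFR reading is implemented), and a type-I null
grid. Replicates redraw phenotypes (and analyses) on a single fixed
genotype panel with PCs computed once, matching the repeated-phenotype
design the scenarios emulate; `refresh_genotypes_each_replicate=True`
resimulates genotypes per replicate. All randomness descends from
`base_seed` through tagged `SeedSequence`s; identical configs give
bit-identical aggregates, and each run writes a manifest (config, version,
aggregate checksum).

Default scenario scale is five groups × 2,000 samples and 20,000 variants —
thousands of times smaller than the biobank-scale settings the designs
emulate. Power levels at this scale are not comparable to published
full-scale percentages; only orderings and calibration properties are, and
those are what the acceptance tests assert (pooled LD-based power ≥ IVW
and ≥ meta-regression in ≥8/10 replicates; calibrated type-I at α = 0;
pooled-only inflation under group-specific stratification at α = 5%).
Biobank-scale sizes remain reachable through the config.

## Known limitations

* LD is block-stationary and within-group only in the admixed simulator's
  frequency mode; no realistic recombination maps.
* Fixed-effect engines only: whole-genome ridge / mixed-model machinery is
  out of scope, though the strategy interfaces accept externally computed
  summary statistics.
* No rare-variant, interaction, or X-chromosome handling; no
  random-effects meta-analysis or fine-mapping.
* Effect sizes are homogeneous across groups on the standardized scale by
  construction; the comparison does not speak to settings with genuine
  effect heterogeneity.
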