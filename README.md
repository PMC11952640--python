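# multigwas

Simulation and comparison of **multi-ancestry GWAS strategies**: pooled
analysis, inverse-variance-weighted (IVW) fixed-effect meta-analysis, and
MR-MEGA-style meta-regression on axes of genetic variation.

When a genome-wide association study spans several ancestry groups, the
analyst must choose between pooling everyone into one regression (adjusting
for cross-ancestry principal components) or running one GWAS per group and
combining the summary statistics. `multigwas` provides the machinery to
study that choice quantitatively: a synthetic multi-population genotype
simulator, phenotype generators with controlled population stratification,
per-variant association engines, both combination methods, and an
evaluation layer (power, type-I error, genomic inflation, LD clumping). It
is aimed at statistical geneticists who want to probe when pooling beats
meta-analysis — and when population stratification breaks either — without
access to biobank-scale data.

## The core result

For a variant with allele frequency `f_j` in group `j` (size `n_j`) and a
constant allelic effect, the pooled estimator β̂_P uses the *total* genotype
sum of squares while the IVW meta estimator β̂_M uses only the *within-group*
part. The ANOVA identity

```
SS_total = SS_within + Σ_j n_j (ḡ_j − ḡ)²
```

gives the asymptotic relative efficiency

```
ARE(β̂_P, β̂_M) = Var(β̂_M) / Var(β̂_P) = SS_total / SS_within ≥ 1,
```

with equality only when all group dosage means coincide: pooled analysis is
never less efficient, and its advantage grows with the sample-size-weighted
variance of allele frequencies across groups. The package verifies this
analytically, by Monte-Carlo, and in end-to-end simulated GWAS.

## Worked example

```python
import numpy as np
from multigwas import (
    simulate_frequencies, simulate_panel, LDBlockSpec,
    ld_prune, compute_pcs, simulate_continuous,
    run_strategy_pooled, run_strategy_pergroup, ivw_meta, are_asymptotic,
)

# 1. Two diverged populations, 2,000 variants with block LD
vt = simulate_frequencies(2000, ["AFR", "EUR"], {"AFR": 0.15, "EUR": 0.08}, seed=1)
panel = simulate_panel(vt, {"AFR": 1500, "EUR": 1500}, LDBlockSpec(rho=0.8), seed=2)

# 2. PCs at both scopes on the LD-pruned panel
pruned = ld_prune(panel, r2_threshold=0.1, window_bp=500_000)
pcs = compute_pcs(panel, 10, "cross_group", pruned)
pcs_g = {g: compute_pcs(panel, 10, f"per_group:{g}", pruned) for g in panel.groups}

# 3. A continuous trait with 50 causal variants, h2 = 0.4
pheno = simulate_continuous(panel, h2=0.4, seed=3, n_causal=50)

# 4. Pooled GWAS vs per-group GWAS + IVW meta-analysis
pooled = run_strategy_pooled(panel, pheno, pcs)
studies = run_strategy_pergroup(panel, pheno, pcs_g)
meta = ivw_meta(studies)

print(pooled.summary(threshold=1e-5))
print("IVW significant:", (meta["p"] <= 1e-5).sum())
print("closed-form ARE at f=(0.1,0.5):", round(are_asymptotic([1500, 1500], [0.1, 0.5]), 4))
```

Output from this exact script:

```
GWAS results [pooled] (continuous trait)
  variants tested : 1990  (converged 1990)
  significant (p <= 1e-05) : 30
  top hits:
           1:1400000  beta=-0.4644  se=0.0375  p=3.415e-35
           1:6450000  beta=+0.2683  se=0.0274  p=1.304e-22
           1:2825000  beta=-0.3874  se=0.0402  p=4.955e-22
           1:1760000  beta=-0.2721  se=0.0284  p=1.104e-21
           1:7845000  beta=-0.6955  se=0.0739  p=5.071e-21
IVW significant: 29
closed-form ARE at f=(0.1,0.5): 1.4706
```

The pooled analysis finds 30 signals to the meta-analysis' 29 at the same
threshold, and the closed-form ARE says the meta estimator's variance is
47% larger than the pooled one at strongly diverged frequencies — the two
observations are the same phenomenon.

A command-line interface mirrors the library
(`multigwas simulate-genotypes | simulate-phenotypes | pca | gwas | meta |
mrmega | evaluate | are | run-scenario`); see `multigwas --help`.

## Layout

| Module | Contents |
| --- | --- |
| `multigwas.popsim` | Balding–Nichols frequencies, block-LD haplotype panels, two-way admixture |
| `multigwas.structure` | LD pruning, PCA (cross-group / per-group), variance explained by PC sets |
| `multigwas.phenosim` | null / continuous / binary phenotype generators, prevalence calibration |
| `multigwas.assoc` | `LinearGWAS` / `LogisticGWAS` models, MAF inclusion rules, strategy runners |
| `multigwas.combine` | IVW meta-analysis, axes of genetic variation, MR-MEGA meta-regression |
| `multigwas.theory` | estimator algebra, asymptotic relative efficiency |
| `multigwas.evalmetrics` | exact/LD power, type-I tables, λ / λ₁₀₀₀, LD clumping |
| `multigwas.pipeline` | scenario configs and end-to-end orchestration |

Model assumptions, parameter choices and known limitations are documented
in [docs/methods.md](docs/methods.md).
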