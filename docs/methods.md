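# Methods

This note documents the models, algorithms, numerical choices and
limitations of the package. It is written for a reader who wants to
know exactly what each stage computes and what the passing test suite
does and does not demonstrate about real data.

## Study design being modeled

The package targets exome-array case-control studies of a late-onset
disease: several thousand cases and controls recruited in a handful of
countries, genotyped on a fixed chip of a couple hundred thousand
mostly rare coding sites. Two properties of this design drive
everything else:

1. **Most sites are monomorphic or near-monomorphic in any one
   cohort.** A chip designed from sequencing of other cohorts carries
   many sites whose minor allele simply does not appear in a given
   sample, and many more with one or two carriers. Single-variant tests
   at such sites are grossly underpowered, which *deflates* the genomic
   inflation factor (λ_GC well below 1 is expected, not evidence of
   over-correction).
2. **Case-control imbalance interacts with "set-unique" definitions.**
   A variant observed only in cases may be group-unique merely because
   the case group is larger and therefore reveals more of the rare
   spectrum. Any statistic built on group-unique variants inherits this
   artifact under the null; the balanced-cohort reanalysis is the
   control.

## Synthetic-data generator

`simulate_study` draws a population forward from a logistic disease
model and then samples the requested numbers of cases and controls per
country (retrospective/ascertained sampling). This matters: it is the
ascertainment, not the disease model, that produces the set-unique
imbalance artifact, so the generator must sample case/control quotas
rather than a random cohort.

Sites are drawn from a five-class frequency mixture — monomorphic,
"singleton", rare (MAF < 0.005), low-frequency (0.005–0.05), common
(> 0.05). The singleton class is defined relative to a reference cohort
scale (`singleton_reference_n`, default 7,350): a site in this class
has expected minor-allele count 1 in a cohort of that size, so a
scaled-down simulated sample sees proportionally fewer carriers. This
reflects how a fixed array behaves when a smaller cohort is genotyped,
and it is what makes scaled-down artifact simulations behave like the
full-scale study, where per-individual set-unique counts imply that the
typical set-unique variant has on the order of one carrier.

Other structure: genes with shifted-Poisson variant counts; functional
classes (synonymous/missense/LoF); deleteriousness scores drawn from a
Beta distribution on [0,1] with a labeling threshold, with only LoF
variants allowed to be unscored (exercising the unscored-LoF imputation
rule); reference-panel MAFs equal to the generating MAF perturbed on
the logit scale; per-gene causal architectures in which exactly
`round(causal_fraction·m)` variants get |β| = c·|log10 MAF| (default
c = 0.4) and `round(protective_fraction·n_causal)` of them are
risk-decreasing; sex and country log-odds offsets; flat or
phenotype-dependent genotype missingness.

Default sizes are the full-scale design (4,244/3,106 samples from six
countries, 14,488 genes, ≈233k sites, ≈57% monomorphic); tests and the
acceptance suite run scaled-down configurations (see below). For
ultra-rare sites genotypes are generated sparsely — the site's total
allele count is drawn first and alleles are placed on random chromosome
slots — which is distribution-identical to per-individual binomial
draws and much faster.

What the generator does **not** emulate: linkage disequilibrium between
sites (sites are independent), sequencing/genotyping error and batch
effects, X-chromosome transmission, and realistic gene length/site
density variation. Passing tests therefore demonstrate correctness of
the statistics under independent-site sampling, not robustness to LD
or differential genotyping artifacts.

## Quality control

Thresholds default to conventional exome-array practice: sample missing
rate > 5%; heterozygosity beyond 4 SD; pi-hat > 0.2; pruning subset =
non-AT/CG autosomal SNPs with MAF > 0.05, call rate > 99%, HWE p >
1e-3, pairwise r² < 0.05 (greedy windowed pruning, 50-variant windows,
step 5, ascending position — a deterministic PLINK-like convention);
variant call rate < 98%, HWE in controls p < 1e-6, differential
missingness p < 5e-3 (Fisher exact on the 2×2 missing × phenotype
table). The exact HWE test sums the probabilities of heterozygote
counts no more probable than observed, conditional on allele counts;
log-space evaluation keeps it exact to floating precision for any table
(verified against exact-rational enumeration for all tables with ≤ 12
minor-allele copies).

Relatedness uses the classical method-of-moments IBD estimator from
identity-by-state counts and cohort allele frequencies, with IBD-state
probabilities clamped to [0,1] and renormalized. Within a flagged pair
the member with the higher missing rate is removed (ties by sample id)
— deterministic and data-preserving. Genotypic sex is an optional input
column; without it the sex-discordance step is skipped with a warning,
since the chip's X content is not modeled.

The "non-monomorphic in cases and controls" filter defaults to the
pooled reading (MAC ≥ 1 in the combined sample); a flag applies the
stricter per-group reading.

## Single-variant testing

Standard logistic regression is fit by IRLS with step-halving
(relative log-likelihood tolerance 1e-8, 100 iterations max); the
genotype coefficient's Wald p is reported, matching the convention of
the common GWAS toolchain. Separation (diverging coefficients or
non-convergence) flags the variant instead of reporting a p-value.

Firth regression maximizes the Jeffreys-penalized likelihood
l(β) + ½ log det I(β) by Newton steps on the modified score
U*(β) = X'(y − μ + h(½ − μ)), h the weighted-design leverages. The
p-value is the penalized likelihood-ratio test in which the null fit
constrains the tested coefficient to zero *within the full-design
penalty* — the same convention as the R `logistf` package; refitting a
smaller design instead would shift the deviance by a dimension-
dependent penalty offset and miscalibrate the test (this is checked by
a null-uniformity test and a brute-force grid-search oracle).

λ_GC is median(χ²₁ quantile of 1−p)/median(χ²₁). Covariates default to
five principal components, sex and country (country as K−1 indicators
against the largest cohort); the number of PCs is a parameter since
published descriptions of comparable analyses vary between five and
six.

## Gene-based testing

Variant selection: missense + LoF variants with sample MAF < 0.01 and
MAC ≥ 2; genes with fewer than two qualifying variants are excluded.
Weights are the Beta(1,25) density at the MAF (the field's default,
exposed as a parameter).

The statistic family Q_ρ interpolates between the variance-component
kernel test (ρ=0) and the weighted burden test (ρ=1) on the default
grid {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}. Under the
covariate-only logistic null model the score vector s = (GW)'(y−μ̂) is
asymptotically N(0, Σ) with Σ = (GW)'P₀(GW) computed from the weighted
projection residual; Q_ρ = s'R_ρs is then a mixture of χ²₁ with the
eigenvalues of R_ρ^{1/2} Σ R_ρ^{1/2}.

Per-ρ tail probabilities use moment matching (modified Liu) as a first
pass, refined by Imhof's exact inversion integral when the first pass
reports p < 0.05. The p-value of the minimum-p statistic across the
grid is computed in one of two ways:

- **moderate p** (Bonferroni bound over the grid ≥ 5e-4): direct
  evaluation of P(min_ρ p_ρ ≤ observed) under s ~ N(0, Σ) by a seeded,
  deterministic Monte-Carlo sample of the m-dimensional score vector
  (default 2¹⁶ draws), applying the identical per-ρ map to observed and
  sampled statistics so the map's approximation error cancels;
- **far tail**: the standard one-dimensional integral over the shared
  burden component, with Imhof quantiles per ρ and the variance-
  rescaled kernel tail inside the integrand.

Permutation-exact p-values recompute the full minimum-p statistic for
B label permutations, stratified within country by default (unstrati-
fied label permutation is anti-conservative under stratification), and
report (r+1)/(B+1). Without covariates the null model is permutation-
invariant and the recomputation is fully vectorized; with covariates
the null model is refit per permutation. The permutation machinery is
the package's authoritative oracle: the test suite requires analytic
and permutation p-values to agree within Monte-Carlo error on null
genes.

Degenerate genes whose statistic is invariant to labels (score variance
numerically zero) report p = 1 by convention.

The Firth burden test regresses phenotype on the per-sample minor-
allele count across qualifying variants (carrier coding available as a
flag); conditional analysis adds a named variant's dosage to the null
model and removes it from the tested set.

## ISUB

Set-unique variants are those with MAC > 0 in one phenotype group and
MAC = 0 in the other; variants with reference-panel MAF > 0.5% are
removed (missing reference MAF ⇒ retained: absence from a large
reference implies rarity). NS = set-unique missense + LoF; DEL = the
deleterious-labeled subset; unscored LoF variants receive the
deleterious label and the maximum score observed in their own
set-unique group (pooled-maximum available as a flag). Scores sum once
per carried variant (dominant model). Group comparison is logistic
regression of phenotype on the score plus covariates (five PCs +
country by default; sex is not included, matching the description of
the published procedure this follows). Diagnostics are two-sided
Wilcoxon rank-sum tests on per-individual counts and on per-variant
scores; sensitivity analyses rerun the comparison with >5 SD score
outliers removed and on log(S+1) (the offset accommodates zero scores,
which occur by construction).

The balanced-subset analysis restricts to named cohorts and recomputes
*everything* — set-uniqueness included — within the subset.

A caveat the test suite quantifies: with multi-carrier set-unique
variants, individual scores are positively correlated within groups
(one variant boosts several individuals), and ordinary logistic
regression is mildly anti-conservative under a strict exchangeable
null. In the singleton-dominated regime of a real exome array the
effect is small; the acceptance suite's generator operates in that
regime.

## Power

Single-variant power: genotype odds odds₀·OR^g (additive log-odds),
odds₀ solved so the HWE-weighted penetrance equals the prevalence
(default 1/350, the lifetime risk of the modeled disease); expected
risk-allele frequencies in cases and controls follow, and power is the
non-central χ²₁ tail of the allelic trend test, with the non-centrality
from the expected frequency difference at the given sample sizes. An
option treats controls as unselected population draws. The analytic
calculator is validated against brute-force simulation from the exact
retrospective genotype distributions. At the reference design point
(4,244/3,106, MAF 1%, OR 2.3, α = 5×10⁻⁷, prevalence 1/350) it returns
78.6% — an OR of 2.3 sits at the edge of 80% detectability, with power
crossing 80% near OR 2.33.

Gene-test power simulates single-gene studies from the generator over a
(causal fraction, protective fraction) grid and reports rejection
fractions with Wilson intervals.

## Problem sizes used by the test and acceptance suites

All sizes are the package's own scaled-down analogs of the full design:

- **Imbalance-artifact suite**: 100 replicates at 1,000/730
  (≈1.37:1) and 100 at 500/500; 5,600 genes × ~16 variants (≈90k
  sites); spectrum 25% monomorphic / 75% singleton-class with
  `singleton_reference_n = 3555`, so the typical polymorphic site has
  ~0.5 expected carriers in the larger arm — the singleton-dominated
  regime discussed above. The directional artifact check is one-sided
  (the hypothesis is directional: the larger group's burden is
  higher); the 1:1 calibration check is two-sided.
- **Permutation-agreement suite**: 50 null genes, n = 1,000, 4–12
  variants each, B = 10,000 permutations; agreement is assessed
  against the combined Monte-Carlo error of both estimates, with the
  expected ~5% of genes allowed outside 2 SE.
- **Calibration suite**: λ_GC on 10,000 uniform p-values; a
  rare-variant spectrum at n = 2,000 for the deflation direction;
  ≥2,000 common null variants for single-variant type-I error; 1,000
  null genes (n = 2,000, 10 rare variants each) for gene-based type-I
  error.
- **Recovery suite**: 200 replicates of a single variant with allelic
  OR 2.0 at MAF 0.05, 2,000/2,000 samples, drawn from the exact
  retrospective genotype distributions.

## Known limitations

- No LD model: pruning and conditional analysis are exercised on
  independent-site data only.
- The Gaussian score reference for the gene test's Monte-Carlo min-p
  evaluation is asymptotic; at very small n with very rare variants the
  permutation p-value is the authoritative one (and is what the
  package reports as `exact_p`).
- Analytic power uses the normal approximation of the trend test;
  at extreme α and tiny expected counts it can deviate by ~1 point
  from simulation.
- The pipeline stages communicate through files and recompute pruning
  for PCA; on very large studies an in-memory path would be faster.
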