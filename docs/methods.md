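# Methods

## Models

**Linear ridge.** For a continuous phenotype y (n × 1) and a standardised
genotype matrix X (n × m of minor-allele counts, each column centred and
scaled to unit SD), the ridge estimator is β̂_λ = (X′X + λP)⁻¹X′y with
P a diagonal 0/1 penalty mask (1 for SNPs, 0 for unpenalised covariates).
The response is centred and the intercept recovered as mean(y); with a
column-centred design the intercept is orthogonal to the coefficients, so
this is exact. With a uniform penalty everything is computed from one thin
SVD X = U D V′, reused across λ:

* coefficients      V diag(dᵢ/(dᵢ² + λ)) U′y
* model edf         tr(H) = Σ dᵢ²/(dᵢ² + λ)
* residual edf      ν = n − Σ [2dᵢ²/(dᵢ² + λ) − dᵢ⁴/(dᵢ² + λ)²]
* covariance        σ̂² V diag(dᵢ²/(dᵢ² + λ)²) V′,  σ̂² = RSS/ν

so no m × m matrix is formed when m > n. The residual sum of squares uses
the ridge residuals at the working λ: the test is built entirely from the
ridge fit, and in the m > n regime there is no unpenalised alternative.
When m < n an OLS-based residual mean square RSS/(n − m) is available via
`sigma2_method="ols"`. Singular values below 1e-12 × max(d) are treated
as zero; λ = 0 on a rank-deficient design is an error rather than a
pseudoinverse fit, because the test is then undefined.

**Logistic ridge.** The penalised log-likelihood ℓ(β) = Σ[yᵢxᵢβ −
log(1 + e^{xᵢβ})] − λβ′Pβ is maximised by Newton–Raphson; each step solves
(X′WX + 2λP)β = X′Wz with W = diag p̂ᵢ(1 − p̂ᵢ) and working response
z = Xβ + W⁻¹(y − p̂). Writing the penalty as λβ′β (not λ/2·β′β) makes the
Hessian contribute 2λP, which is the convention the covariance
(X′WX + 2λP)⁻¹X′WX(X′WX + 2λP)⁻¹ assumes; mixing the two conventions is a
classic source of silently wrong standard errors. The intercept is always
present and never penalised — in case-control data it absorbs prevalence,
and shrinking it would bias every test. Safeguards: initialisation at
β = 0 with the intercept at logit(ȳ); step-halving (≤ 20 halvings)
whenever a Newton step would decrease the penalised log-likelihood;
weights floored at 1e-10 when forming z. Convergence is max |Δβ| < 1e-8
(default) within 50 iterations; the covariance is refused for
non-converged fits.

**Tests.** T_λ = β̂_jλ/se(β̂_jλ) with se from the covariance diagonal,
referred to N(0,1), or to t with n − tr(H) df for the linear model (the
variants coincide as n grows; both are exposed). Two-sided p-values
throughout; no multiplicity adjustment by default. The permutation
benchmark permutes y, refits at the same λ (λ is an input, not
re-estimated per permutation), and reports per-coefficient
p_j = #{b : |β*_jb| ≥ |β̂_j|}/B, B = 1000 by default. The denominator is B,
so p = 0 is possible and is printed as "< 1/B". For the linear model the
ridge solution is linear in y, so all B refits collapse into one matrix
product; the observed coefficients are computed through the same linear
map so that exact ties (e.g. the identity permutation) count consistently.
Logistic permutations refit Newton per permutation; non-converged refits
are dropped with a warning, > 10 % failures is an error.

**Shrinkage diagnostics.** λ_HKB = mσ̂²_OLS/(β̂′_OLS β̂_OLS) requires m < n
(OLS quantities), computed on the column-centred design. The ridge trace
(coefficient paths) and p-value trace (raw p per SNP per λ; −log₁₀
transform applied only at the presentation layer, base recorded in the
output metadata) are emitted over a default grid of 25 log-spaced points
in [1e-2, 1e4], covering the practically useful shrinkage range with
margin. No automatic "stabilisation" detection is attempted: the traces
are decision aids, and picking λ off them is a judgement call.

## Synthetic data

The simulator emulates sampling genotypes from a large sequence-like
haplotype population:

* **Panel.** The default panel is a neutral coalescent simulation
  (msprime): 21,000 haplotypes over 1 Mb with effective population size
  10,500, recombination 1e-8 /bp/gen and mutation 2.5e-8 /bp/gen, giving
  ~10,000 segregating sites, a realistic site-frequency spectrum (most
  SNPs rare; ~4 % in the 0.10–0.15 MAF band) and genealogy-driven LD in
  which r² between a focal SNP and its neighbours ranges from ~0 to
  exactly 1 (shared tree branches). Alleles are recoded so 1 is the minor
  allele. A first-order Markov copying generator
  (`build_haplotype_panel`: copy the previous allele with probability
  `ld_decay`, else redraw from a Beta-shaped MAF spectrum, plus a fraction
  of exact duplicate columns) is kept as a dependency-light alternative;
  note its r² between neighbours concentrates at intermediate values
  rather than the bimodal near-0/near-1 pattern of sequence data, which
  matters for weak-shrinkage power (see Limitations).
* **Genotypes.** Each individual sums two haplotypes drawn with
  replacement (Hardy–Weinberg). Study designs use a random contiguous
  window of m SNPs; single-causal designs pick a causal SNP uniformly
  among those with population MAF in 0.10–0.15 and a uniformly random
  window containing it; multi-causal designs pick uniformly among all
  windows holding at least the required number of eligible SNPs.
* **Phenotypes.** Continuous: null Yᵢ ~ N(0,1); single-causal
  Yᵢ ~ N(1 + 2k, 1) with k the causal minor-allele count; multi-causal
  Y = Xβ + ε, ε ~ N(0, I) with β = effect size at causal columns. Binary:
  null Yᵢ ~ Binom(1, 0.5); case-control via the additive penetrance model
  f₀ = K/(1 − 2p + 2pr), f₁ = rf₀, f₂ = 2rf₀ − f₀ (K prevalence, r the
  genotype relative risk f₁/f₀, p the causal MAF), ascertaining until n/2
  cases and n/2 controls. K defaults to 0.10 and r to 2.0, typical values
  for a common complex disease; both are configurable. The expected
  number of draws per retained individual is bounded by ~max(1/K,
  1/(1−K)), so the ascertainment loop terminates quickly for any valid
  penetrances.
* **Preprocessing.** Mean imputation of missing calls, removal of
  sample-invariant SNPs (their indices are kept so a dropped causal SNP
  counts as undetected), then per-column standardisation using the
  n-denominator SD (any consistent convention works; this one is recorded
  so results are bit-stable).
* **Seeding.** One scenario seed feeds a `numpy` SeedSequence; each
  replicate spawns its own child streams (window, genotypes, phenotype),
  so any single table cell is reproducible in isolation.

Scoring: TPR/FPR are the proportions of causal/non-causal SNPs with
p < α (default 0.05), averaged over replicates as unweighted means of
per-replicate proportions (equal scenario sizes make this identical to
pooling). A non-causal SNP in perfect LD with the causal SNP still counts
as a false positive — with heavy shrinkage, correlated neighbours absorb
part of the signal, which is why FPR can exceed α at large λ even for a
well-calibrated test. Ranks use minimum-rank ties. Bland–Altman agreement
plots compare two p-value vectors on the −log₁₀ scale (difference =
permutation − approximate), flooring exact zeros at 1/(10B).

Default problem sizes in the reproduction script — 25 replicates for the
n = 1000 × m = 1000 null scenarios and 10–25 for the power scenarios —
keep a full run to about a minute on one CPU while holding the Monte
Carlo error of each reported rate near 0.003 (null) and 0.01–0.05
(power).

## What the simulations do and do not show

The generator reproduces the LD spectrum, frequency spectrum and
ascertainment of an idealised, neutrally evolving panel. It does not
model genotyping error, imputation uncertainty, population structure or
relatedness, selection, or covariate confounding — so passing calibration
here shows the test is sound under its own assumptions, not that it is
robust to those complications.

One behaviour deserves emphasis. The logistic approximate test's size at
weak shrinkage (λ ≈ 0.1 with m ≈ n) depends sharply on the *effective
rank* of the standardised genotype window. Under coalescent LD a
1000-SNP window holds only ~400 distinct genotype patterns, the penalised
fit stays far from separation, and the test is mildly conservative
(FPR ≈ 0.03–0.05 in our runs, against a permutation benchmark near
0.05). When predictors are closer to linearly independent (effective
rank → n), the weakly penalised logistic fit approaches separation, the
final-iteration weights collapse, and the same test becomes markedly
anti-conservative (we measure FPR ≈ 0.18 at rank ≈ 0.7n). Users applying
the logistic test at small λ to data with weak LD should therefore
confirm calibration with a permutation run; at strong shrinkage
(λ ≈ 100) the test is near-nominal in every regime we examined. The
linear test, whose residual variance is corrected through ν, stays close
to nominal throughout.

## Known limitations

* λ selection is left to the user (HKB, traces); no cross-validation.
* The logistic sandwich assumes a converged Newton fit; extremely
  separable data with λ → 0 is rejected rather than patched (no Firth
  correction).
* Genome-wide-scale streaming is out of scope: a window of a few thousand
  SNPs is the intended problem size.
* The copying-model panel is a caricature of LD; use the coalescent panel
  for anything quantitative.
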