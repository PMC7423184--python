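# Methods

This note documents the statistical models implemented in `exomod`,
their assumptions, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Study design the package targets

A cross-sectional exome cohort stratified into phenotype groups —
here: `random` sickle-cell-anemia patients (n = 56), patients with
overt `stroke` (n = 23), `long_survivor` patients over 40 years
(n = 26), and healthy HbAA `control` donors (n = 58).  Six pairwise
contrasts are standard: three case–case comparisons
(long_survivor:random, stroke:random, stroke:long_survivor) and three
case–control comparisons.  The three case–case contrasts are treated
as the primary hypotheses; results for them carry an additional
significance flag at the Bonferroni-adjusted level 0.05/3 ≈ 0.017.

## Variant prioritization

A variant is retained when all three hold:

* **Consensus deleteriousness.** At least `min_damaging` (default 17)
  of the 21 named predictors call it damaging.  Categorical codes `D`,
  `A` (MutationTaster's disease_causing_automatic) and `H` count as
  damaging; `T/N/B/P/L/M` as tolerated; anything unparseable is
  `unknown` and never counts toward the consensus.  For predictors
  whose raw output is a score (CADD, GERP++, DANN, PhyloP, SiPhy,
  Eigen, GenoCanyon, M-CAP) a config-exposed cutoff table converts
  scores to verdicts; the defaults (e.g. CADD ≥ 20, GERP++ ≥ 4) follow
  common practice and are deliberately visible rather than baked in.
* **Functional class** in {nonsynonymous, stopgain, stoploss} by
  default.  Whether stop variants should bypass the predictor
  consensus is genuinely open; here they do not — the conjunction is
  uniform across classes, and the class set is configurable.
* **Rarity.** Every reference-panel frequency *present* must be at or
  below `max_pop_freq` (default 0.01).  A variant with no reference
  frequency at all is treated as rare — absence of evidence of
  commonness, which matches how novel variants are handled in
  practice.  The exact threshold used by comparable studies is rarely
  stated; 0.01 is the conventional "rare" line and is config-exposed.

Raising `min_damaging` can only shrink the retained set; raising
`max_pop_freq` can only grow it (tested as a property).

### SiPhy aggregation

Per gene, SiPhy 29-way scores of the retained variants are
standardized against the mean/sd of **all** scored variants in the
dataset and combined as a Stouffer z, `Σ s_j / √k`.  The combination
rule behind published per-gene conservation z-scores is not uniquely
determined by the score itself, so this aggregation is a documented
reconstruction: Stouffer was chosen because its null variance is
k-stable (a plain standardized sum is available via
`siphy_aggregation: sum`).  Absolute z-values are therefore comparable
within one dataset, not across publications.  Genes with no scored
retained variant yield no row, never a zero.

## Burden test against a neutral null

The observed statistic is the number of **distinct** qualifying
variants of a gene present in a phenotype group (allele counts are
not summed; recurrent mutation of a gene is the signal of interest).
The null allocates the group's total count `T` across genes in
proportion to the flanked gene length: `E_g = T · L_g / Σ L` with
`L_g = (end + flank) − (start − flank) + 1`.  This is the
mutational-target logic of de novo burden testing, calibrated so that
`Σ E_g = T` exactly.  Significance is the upper Poisson tail
`P(Poisson(E_g) ≥ obs)` with BH adjustment across genes within a
group.

Assumptions and scope:

* Qualifying variants arrive independently at a rate proportional to
  the region length.  Sequence-context mutability, coverage
  heterogeneity and selection are not modeled; the null is isolated
  behind `estimate_null_expectations` precisely so that a per-gene
  mutability table can be swapped in.
* The Poisson tail is discrete, so its p-values are stochastically
  larger than uniform at small expectations.  Calibration is therefore
  verified through the randomized probability integral transform
  `p' = P(X > obs) + U·P(X = obs)`, which is exactly Uniform(0,1) iff
  the Poisson null holds; the reported test statistic remains the
  plain (conservative) tail.

## Allele-frequency differentiation

Per biallelic site and group pair (A, B):

```
z = (p̂_A − p̂_B) / sqrt( p̄ (1 − p̄) · (1/c_A + 1/c_B + 2F) )
```

where `p̂` are sample alt-allele frequencies, `c` the called allele
counts (2 × called samples; missing genotypes drop out of both
numerator and denominator), `p̄` the pooled frequency, and `F` the
aggregate drift factor of a stepwise-constant `N_e` schedule,
`F = 1 − exp(−Σ t_k/(2N_k))`.  Sites fixed in the pooled sample
(p̄ ∈ {0,1}) contribute z = 0; sites with zero called alleles in a
group are skipped.  `F` defaults to 0: the contrast groups are
contemporaneous samples from one population, so binomial sampling is
the exact null and drift variance is optional inflation for users who
want the demographic null instead.

Per gene, `T = Σ z_j²` over every site within ±40 kb of the gene
interval (closed at both ends; "40 kb upstream and downstream" is
boundary-ambiguous and the inclusive reading was adopted).  The flank
is anchored to the transcript interval, not the exon union — the
alternative reading is noted as open.  Linkage disequilibrium between
the sites inflates the variance of T relative to a χ²_k; rather than
an analytic effective-number-of-tests correction, the null is obtained
by permuting **sample** labels within the contrast, which preserves LD
exactly and makes the empirical p-value
`(1 + #{T* ≥ T_obs}) / (1 + B)` exact under label exchangeability.
For tiny cohorts the full label-assignment set is enumerated instead
(`exhaustive=True`), giving the exact exceedance fraction.  A gamma
tail moment-matched to the permutation sample is reported as
`p_analytic` — a fast pre-screen, never the calibrated result.

Site inclusion is fixed by the observed labelling; within a
permutation a group left with zero called alleles at a site simply
contributes 0.  Swapping the two group labels leaves both T and the
p-value unchanged: the statistic is symmetric, samples are put in a
canonical order, and the per-gene random stream is derived from the
*sorted* contrast tokens.

## SKAT-O rare-variant association

For a contrast with n individuals, variants qualify when their call
rate is ≥ 0.9 (the missingness cutoff; variants below are dropped) and
their minor allele frequency over called alleles in the contrast is
positive and below the adaptive threshold `1/√(2n)`.  Remaining
missing dosages are mean-imputed within the contrast and coding is
flipped to the minor allele.  Genes with fewer than 2 qualifying rare
variants are excluded.

With Beta(1,25)-density weights `w_j = f_Beta(MAF_j; 1, 25)` and null
residuals `r = y − μ̂` from a logistic regression of the group
indicator on intercept + covariates:

```
Q_skat   = Σ_j w_j² (G_jᵀ r)²          (variance component, ρ = 0)
Q_burden = (Σ_j w_j G_jᵀ r)²           (collapsing burden, ρ = 1)
Q_ρ      = (1 − ρ) Q_skat + ρ Q_burden
```

over the 11-point grid ρ ∈ {0, 0.1², …, 0.9², 1}.  "Linear weighted
kernel" does not pin down the weights; Beta(1,25) is the canonical
weighted-linear choice and both the weights and the grid are config
keys.  The reported statistic is the **minimum over the grid of the
per-ρ empirical p**, and its p-value is the permutation p of that
minimum with the min re-taken inside every permutation — this nulls
the grid search correctly without any Davies/Liu mixture machinery
(permutation is the calibration route throughout).  Per-ρ p-values use
pooled exceedance ranks over the observed + permuted ensemble, so the
observed statistic is exchangeable with the permutations under the
null and the final p is uniform on {1/(B+1), …, 1}.

Permutation schemes: the default permutes phenotype labels and refits
the null per permutation when covariates are present (exact under the
strong null); because the refitted ensemble is identical for every
gene of a contrast it is computed once per contrast and shared.
`permute: residual` permutes the residual vector per gene instead — an
approximation that is exact when there are no covariates (μ̂ is then
constant) and is the fast path for large permutation counts.

**Covariates.** Age and the top genotype principal components.  PCA
standardizes dosage columns by `√(2p(1−p))` after mean imputation;
scores are deterministic with the sign fixed by making each
component's largest-magnitude loading positive.  Note that when a
group is *defined* by age (long survivors are >40 by construction),
age separates the phenotype perfectly and the logistic null is fit by
a ridge-stabilized fallback (warned); residual signal then has to
come from genotypes orthogonal to age, which is the honest consequence
of adjusting for a defining covariate.

## Gene-set enrichment

Hit lists are tested against GMT collections with the upper-tail
hypergeometric probability of the observed overlap given
(|universe|, |set|, |hits|), plus fold-enrichment observed/expected,
BH-adjusted across sets.  The universe defaults to all genes of the
gene-model table and is overridable, since the appropriate background
depends on what the hit list could in principle have contained.  Hits
outside the universe are dropped with a log message; sets empty after
harmonization are dropped with a warning.

## Synthetic cohort generator

The generator produces data with exactly the structure the tests
assume, which is what makes the calibration results meaningful:

* **Site frequencies** are drawn by inverse-CDF sampling of the
  neutral law (mass ∝ 1/i for derived count i on a 2N-point grid,
  default 2000) — the standing distribution under the Wright–Fisher
  model with selective neutrality.  A stepwise `N_e` schedule enters
  through the single drift factor F as a Beta perturbation with
  variance `F·p(1−p)`; the default schedule is effectively drift-free
  (one epoch, N_e = 10⁶), because no demographic parameters are
  canonical for this design — all are config-exposed.
* **Per-region site counts** are Poisson with mean
  `θ · L_g / mean(L)` over the *flanked* region length, clipped to a
  configured range, and positions are uniform in the flanked region.
  This makes qualifying counts proportional to flanked length — the
  same proportionality the burden null assumes — so burden p-values
  are calibrated by construction under the neutral configuration.
* **Genotypes** are two binomial draws per sample from the
  group-specific frequency; planted differentiation shifts one group's
  frequency by +δ (δ ≤ 0.5, clipped to [0,1]); missingness is injected
  independently at a configured rate and stored as a sentinel distinct
  from 0.
* **Predictor verdicts** are exchangeably correlated Bernoullis via a
  shared latent Gaussian per variant (sensitivity 0.95, specificity
  0.95, correlation 0.3 by default — predictors trained on overlapping
  features agree more than independence would predict).  SiPhy scores
  come from separated normals (deleterious ~ N(12, 2²), benign
  ~ N(4, 2²), on the score's natural 0–20ish scale); deleterious
  variants are nonsynonymous/stop and rare-or-absent in the reference
  panels.
* **Planted burden** multiplies the per-variant deleterious
  probability (default 0.05) by an excess factor for chosen genes.

What it does **not** emulate: haplotype structure and recombination
(LD exists only through shared gene-block frequencies), selection,
sequencing error, batch effects, coverage variation, population
admixture.  Tests passing on this generator therefore demonstrate the
*statistical* correctness of the machinery (calibration,
exchangeability, power against the planted effect classes), not
robustness to every artifact of real exome data.

## Numerical conventions

* All random streams derive from a master seed via SHA-256 hashing of
  (seed, stage, gene, contrast) tokens: results are independent of
  evaluation order and reproducible across processes; re-running a
  pipeline config reproduces output tables byte-for-byte.
* Empirical p-values are never 0: `(1 + exceedances)/(1 + B)`, with
  ties counted as exceedances.  Exhaustive enumerations report the
  exact exceedance fraction (the observed assignment counts itself).
* In exhaustive mode the observed residual vector is computed through
  the identical code path as the enumerated ensemble so that
  knife-edge floating-point ties resolve consistently.
* Missing genotypes are a distinct sentinel (−1), never 0; half-calls
  (one missing allele) are treated as fully missing.
* Multi-allelic VCF records are split into biallelic sites with
  allele-specific counts.  Internal coordinates are 1-based inclusive;
  BED is converted at the boundary.  Readers sort records internally,
  so results are independent of input row order.

## Problem sizes used in the bundled checks

The calibration and power checks run at sizes chosen to make their
statistical assertions sharp while remaining desk-scale: 300 genes ×
2000 permutations for the two permutation-test calibrations (25 vs 25
samples), 500 genes for burden calibration/recovery (θ = 100,
p_deleterious = 0.1, giving ≥5 expected qualifying variants per gene),
200 replicate cohorts for differentiation power (δ = 0.25 at five
MAF-0.2 sites, 25 per group), and 100 replicate spectra of ≥10 000
sites for the SFS shape.  The acceptance script mirrors these
conditions and recomputes everything from its `--seed`.

## Known limitations

* The burden null ignores per-gene mutability differences; on real
  data a mutability table should replace the length-proportional
  allocation (the interface anticipates this).
* The differentiation statistic is a reconstruction honoring the
  stated ingredients (Wright–Fisher neutrality, stepwise N_e, pairwise
  frequency differences, large-value rejection, ±40 kb aggregation,
  LD-aware calibration); the original study's exact supplementary
  statistic is not recoverable from its main text, so numerical
  per-gene p-values are not expected to match published tables.
* Whether published per-comparison analyses shuffled phenotypes or
  residuals, and which weight function their "linear weighted kernel"
  used, is unstated; both are config keys here, neither is asserted as
  ground truth.
* Permutation p-value resolution is 1/(1+B); genome-wide use needs B
  large enough for the multiplicity actually faced (the study-scale
  default is 100 000).
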