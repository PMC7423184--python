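# exomod

Exome-wide discovery of genetic modifiers in phenotypically stratified
cohorts — built around the study design used for sickle cell anemia
(SCA) severity: three case groups ("random" SCA patients, patients with
overt **stroke**, and **long survivors** past age 40) plus healthy HbAA
controls.  The package implements the full statistical chain from a
multi-sample VCF and a dbNSFP-style annotation table to per-gene
association results:

1. **Consensus deleteriousness prioritization** — a variant is retained
   when at least 17 of 21 in-silico predictors (SIFT, LRT,
   MutationTaster, …, PhyloP, SiPhy) call it damaging, it is
   nonsynonymous or a stop variant, and it is rare (reference-panel
   frequency ≤ 0.01 by default).
2. **Mutational-burden testing** — each gene's count of distinct
   qualifying variants, per phenotype group, is tested against a
   neutral null that allocates the group total in proportion to the
   flanked gene length:
   `E[X_g] = T · L_g / Σ L`, `p = P(Poisson(E[X_g]) ≥ obs)`,
   Benjamini–Hochberg across genes.
3. **Gene-level allele-frequency differentiation** — per SNP,
   `z = (p̂_A − p̂_B) / sqrt( p̄(1−p̄)(1/c_A + 1/c_B + 2F) )`
   with called-allele counts `c` and an optional Wright–Fisher drift
   factor `F` derived from a stepwise-constant `N_e` schedule; per gene
   the statistic is `T = Σ_j z_j²` over all SNPs within ±40 kb of the
   gene, calibrated by permuting sample labels (which preserves LD).
4. **SKAT-O rare-variant association** — the optimal ρ-combination of
   the Beta(1,25)-weighted variance-component and burden scores,
   `Q_ρ = (1−ρ) Σ w_j²(G_jᵀr)² + ρ (Σ w_j G_jᵀr)²`, with the adaptive
   per-comparison rarity threshold `MAF < 1/√(2n)`, a 0.9 call-rate
   cutoff, logistic null models with age/PC covariates, and empirical
   p-values from label permutation with the min-p-over-grid statistic
   re-minimized inside every permutation.
5. **SiPhy aggregation and gene-set enrichment** — per-gene Stouffer
   z-scores of SiPhy 29-way conservation over retained variants, and
   upper-tail hypergeometric over-representation against GMT pathway
   collections.

Because real patient exomes of this kind are not publicly deposited,
the package ships a first-class **synthetic cohort generator**
(`exomod.simulate`) that reproduces the statistical structure the
analysis assumes — neutral 1/i site-frequency spectra, binomial
genotypes for the four groups at the study's sample sizes
(26/23/56 + 58), planted per-gene burden excess and frequency shifts,
and correlated 21-predictor verdicts — and writes standard formats
(VCF 4.2, annotation TSV, cohort TSV, BED, GMT) that round-trip through
the package's own readers.

## Worked example

The bundled demo config simulates a 163-sample cohort over 30 genes,
plants a 4× deleterious-variant excess in genes `G05` and `G12` and a
0.3 allele-frequency shift in `G20` for the stroke group, then runs
every stage:

```bash
exomod run-all --config configs/demo.yaml --out demo_run
```

prints the per-stage row counts

```
variants        1761
retained        96
burden          120
differentiation 90
skato           180
```

and writes `retained.tsv`, `siphy.tsv`, `burden.tsv`,
`differentiation.tsv`, `skato.tsv`, `enrichment.tsv` and a provenance
`manifest.json`.  The planted signals surface where they should: `G05`
leads the burden ranking in every group (e.g. in the random SCA group,
6 qualifying variants against 1.92 expected, p = 0.014; in controls
8 against 1.80, p = 5.7×10⁻⁴, q = 0.017), and the differentiation
table's strongest hits are the stroke contrasts of the shifted gene:

```
          comparison gene  n_variants   statistic  p_empirical
stroke:long_survivor  G20          64  945.263953     0.001996
       stroke:random  G20          64 1619.906624     0.001996
```

with `p_empirical = 1/(1+B)` pinned at the permutation resolution
(B = 500 in the demo).  Re-running the same config reproduces every
table byte-for-byte; seeds for each stage are derived from the master
seed by hashing, so per-gene results do not depend on evaluation order.

Individual stages are also available as subcommands (`simulate`,
`prioritize`, `burden`, `differentiate`, `skato`, `enrich`) operating
on the on-disk formats, so any stage can be re-run from its
predecessors' outputs.

## Layout

```
src/exomod/
  datatypes.py        shared containers (GenotypeMatrix, GeneRegion, ...)
  simulate.py         synthetic exome-cohort generator
  io.py               VCF / annotation / BED / cohort readers and writers
  prioritize.py       21-predictor consensus filter, SiPhy aggregation
  burden.py           length-proportional Poisson burden null
  differentiation.py  drift-aware frequency z and permutation test
  skat.py             SKAT-O, null models, genotype PCA
  enrichment.py       hypergeometric gene-set over-representation
  pipeline.py         validated YAML config and stage orchestration
  cli.py              `exomod` command-line interface
```

See `docs/methods.md` for the statistical model, its assumptions, and
the reconstruction choices behind each null.
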