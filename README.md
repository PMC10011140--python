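# eqtlkit

Multi-cohort expression quantitative trait locus (eQTL) analysis in Python:
cis- and trans-eQTL discovery by sample-size-weighted z-score meta-analysis,
permutation-based gene-level significance, iterative conditional mapping,
cross-dataset replication metrics, cell-type deconvolution with interaction
eQTLs, and single-SNP Mendelian randomization (MR) with colocalization.

It is written for statistical geneticists who want a tested, transparent,
desk-scale implementation of the full brain-eQTL-style analysis stack — every
stage can be exercised end to end on the built-in synthetic study generator,
whose planted effects provide exact ground truth.

## The model

Within each cohort *i*, a variant–gene pair is scored by the Spearman
correlation ρ between genotype dosage and expression, converted to a z-score
through the t approximation. Cohorts are combined as

    z_meta = Σᵢ √nᵢ · zᵢ / √(Σᵢ nᵢ)

which is robust to cross-cohort heterogeneity in expression scale because
only ranks enter per cohort. An approximate allelic effect is reconstructed
from the meta z-score with the allele frequency *f* and total sample size
*n*:

    d = √(2·f·(1−f)·(n + z²)),   β = z / d,   SE = 1 / d.

Gene-level significance follows the permutation scheme used by the
FastQTL family: sample labels are permuted within cohorts, the minimum
p-value per permutation is collected, a Beta(a, b) distribution is fitted to
those minima by maximum likelihood, the nominal top p-value is adjusted
through the fitted CDF, and Storey q-values over genes call significance at
q < 0.05. Trans associations (SNP–TSS distance > 5 Mb or different
chromosome) use an empirical FDR over ten genome-wide permutations.
Conditional rounds regress the dosages of prior lead variants out of
expression per cohort (OLS) and re-scan.

Further stages: allelic concordance, π₁, the noise-corrected slope
correlation R_b and the correlation of log₂ allelic fold change for
cross-dataset agreement; non-negative least squares (NNLS) on a single-cell
signature for cell-type proportions with a Decon-QTL-style all-non-negative
interaction model tested by a one-sided F-test; Wald-ratio MR
(β_GWAS / β_eQTL) with LD clumping, proxy search and forward-strand
harmonization; and Wakefield approximate-Bayes-factor colocalization with
PP4 > 0.7 under either the default or region-size priors.

## Worked example

```python
import numpy as np
import eqtlkit as ek

cfg = ek.SimConfig(seed=7, n_cohorts=2, n_per_cohort=(400, 300),
                   n_variants=200, n_genes=60, cis_effect_sd=0.8,
                   n_cis_effects=5, n_secondary_effects=2,
                   n_trans_effects=2, n_interaction_effects=2)
study = ek.simulate_study(cfg)

qc = ek.variant_qc_table([c.genotypes for c in study.cohorts])
keep, dropped = ek.filter_variants(qc, maf_min=0.01, hwe_min=1e-4,
                                   max_missing=0.1)
print(f"variants passing QC: {len(keep)} / {len(qc)}")

pairs = ek.cis_pairs(study.variants.loc[keep], study.genes)
genes_df, nulls = ek.cis_gene_level(study.cohorts, pairs, n_perm=100, seed=7)
print(f"cis-eQTL genes (q < 0.05): {int(genes_df.significant.sum())}"
      f" of {len(genes_df)} tested")

cond = ek.run_conditional(study.cohorts, pairs, max_rank=3, n_perm=100, seed=7)
print("independent signals per rank:",
      {int(k): int(v) for k, v in cond.groupby('rank').size().items()})

c0 = study.cohorts[0]
props = ek.predict_proportions(c0.expression, study.signature)
mae = float(np.abs(props[c0.proportions.columns].to_numpy()
                   - c0.proportions.to_numpy()).mean())
print(f"cell-type proportion MAE vs truth: {mae:.3f}")
```

Output:

```
variants passing QC: 200 / 200
cis-eQTL genes (q < 0.05): 5 of 57 tested
independent signals per rank: {1: 5, 2: 1}
cell-type proportion MAE vs truth: 0.023
```

Three of the five q < 0.05 genes carry planted cis effects strong enough to
detect at this sample size (the generator draws slopes around
`cis_effect_sd`, so some planted effects are intentionally weak); one is a
planted cell-type interaction showing its marginal effect, and the
conditional pass finds one secondary signal. The deconvolution recovers the
true mixing proportions to about two percentage points per cell type.

A thin CLI covers the simulate/scan/agree path:

```bash
eqtlkit simulate --out study/ --seed 7
eqtlkit scan --study study/ --out cis.tsv --perm 100
eqtlkit agree --a stats_a.tsv --b stats_b.tsv
```

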