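"""Shared fixtures: small synthetic studies with hand-planted effects."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from eqtlkit import synth


def build_custom_study(planted_cis=(), planted_secondary=(), planted_trans=(),
                       planted_interactions=(), n_per_cohort=(300, 300),
                       n_variants=120, n_genes=30, seed=0, noise_sd=1.0,
                       missing_rate=0.0, allele_flip_rate=0.0,
                       batch_effect_sd=0.0, ld_block_size=10, ld_switch=0.25,
                       n_cell_types=5, maf_range=(0.1, 0.5)):
    """A study whose planted effects are given explicitly (variant index,
    gene index, slope) instead of drawn by the generator, so tests control
    effect sizes exactly. Variant/gene indices are resolved against the
    panel; cis effects are planted on the variant nearest the gene's TSS
    plus the given offset (in variants)."""
    cfg = synth.SimConfig(
        n_cohorts=len(n_per_cohort), n_per_cohort=tuple(n_per_cohort),
        n_variants=n_variants, n_genes=n_genes, seed=seed, noise_sd=noise_sd,
        missing_rate=missing_rate, allele_flip_rate=allele_flip_rate,
        batch_effect_sd=batch_effect_sd, ld_block_size=ld_block_size,
        ld_switch=ld_switch, n_cell_types=n_cell_types, maf_range=maf_range,
        n_cis_effects=0, n_secondary_effects=0, n_trans_effects=0,
        n_interaction_effects=0)
    master = synth.simulate_genotypes(
        n=2, n_variants=cfg.n_variants, maf_range=cfg.maf_range,
        ld_blocks=[(cfg.ld_block_size, cfg.ld_switch)], seed=cfg.seed,
        n_chromosomes=cfg.n_chromosomes, bp_per_variant=cfg.bp_per_variant)
    markers_per_type = max(1, min(10, cfg.n_genes // (2 * cfg.n_cell_types)))
    signature = synth.make_signature(cfg.n_cell_types,
                                     markers_per_type=markers_per_type,
                                     seed=cfg.seed + 3)
    genes = synth.make_gene_annotation(cfg.n_genes, master.variants,
                                       marker_genes=signature.marker_genes,
                                       seed=cfg.seed + 5)
    truth = synth.GroundTruth(
        cis=[synth.PlantedEffect(*t) for t in planted_cis],
        secondary=[synth.PlantedEffect(*t) for t in planted_secondary],
        trans=[synth.PlantedEffect(*t) for t in planted_trans],
        interactions=[synth.PlantedInteraction(*t)
                      for t in planted_interactions])
    cohorts = []
    for c in range(cfg.n_cohorts):
        g = synth.simulate_genotypes(
            n=cfg.n_per_cohort[c], n_variants=cfg.n_variants,
            missing_rate=cfg.missing_rate, seed=cfg.seed + 101 * (c + 1),
            sample_prefix=f"C{c + 1}_", variant_meta=master.variants)
        if c > 0 and cfg.allele_flip_rate > 0:
            synth._flip_recorded_alleles(
                g, cfg.allele_flip_rate,
                np.random.default_rng(cfg.seed + 211 * c))
        expr, props, covs = synth.simulate_cohort_expression(
            g, truth, signature, cfg, c, genes=genes)
        cohorts.append(synth.CohortDataset(
            name=f"cohort{c + 1}", genotypes=g, expression=expr,
            covariates=covs, proportions=props))
    return synth.Study(config=cfg, variants=master.variants, genes=genes,
                       signature=signature, truth=truth, cohorts=cohorts)


def nearest_variant(study, gene, offset=0, exclude_block_of=None):
    """Variant id near the gene's TSS (offset in panel order), optionally
    from a different LD block than a given variant."""
    grow = study.genes.loc[gene]
    v = study.variants[study.variants.chrom == grow.chrom]
    order = (v.pos - grow.tss).abs().sort_values().index
    if exclude_block_of is not None:
        bad = study.variants.loc[exclude_block_of, "block"]
        order = [x for x in order if study.variants.loc[x, "block"] != bad]
    return order[offset]


@pytest.fixture(scope="session")
def default_study():
    """One generator-default study reused by read-only tests."""
    return synth.simulate_study(synth.SimConfig(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
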