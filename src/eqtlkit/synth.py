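"""Synthetic multi-cohort eQTL study generator.

Everything downstream of this module (meta-analysis, conditional mapping,
multiple-testing calibration, deconvolution, MR/coloc) is exercised against
data produced here, where the planted effects are known exactly.

The generator emulates:

* multi-cohort genotype panels sharing a variant set but drawn independently
  per cohort (differing realized MAF and missingness, occasional ref/alt
  swaps to exercise allele harmonization),
* LD through a haplotype-copy chain: within a block, each haplotype copies
  the previous variant's allele with probability ``1 - switch`` and redraws
  from the block MAF otherwise, so adjacent-variant r^2 ~ (1 - switch)^2,
* bulk expression as a non-negative mixture of cell-type signature profiles
  (marker genes) plus planted cis, trans and cell-type-interaction genetic
  effects, cohort batch structure, and Gaussian noise,
* GWAS summary statistics whose causal variant either is or is not the
  planted eQTL variant, for colocalization-positive/negative fixtures.

It does not model population structure, imputation uncertainty or read-level
noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

_NUCS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Dosage panel for one cohort.

    ``dosages`` is samples x variants with entries in {0, 1, 2} and NaN for
    missing calls. ``true_dosages`` keeps the pre-masking dosages used when
    generating phenotypes (never used by analysis code). ``variants`` carries
    id (index), chrom, pos, ref, alt plus the generative metadata
    (target_maf, block, switch) needed to resample a matched population.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    true_dosages: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_index(self, variant_id: str) -> int:
        return int(self.variants.index.get_loc(variant_id))

    def dosage_of(self, variant_id: str, complete: bool = False) -> np.ndarray:
        j = self.variant_index(variant_id)
        if complete and self.true_dosages is not None:
            return self.true_dosages[:, j]
        return self.dosages[:, j]

    def observed_maf(self) -> np.ndarray:
        """Minor-allele frequency per variant from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            af = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(af, 1.0 - af)

    def alt_allele_freq(self) -> np.ndarray:
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass
class SignatureMatrix:
    """Marker-gene x cell-type expression profile with optional subtype map."""

    values: pd.DataFrame
    merge_map: dict[str, str] | None = None

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def marker_genes(self) -> list[str]:
        return list(self.values.index)


@dataclass(frozen=True)
class PlantedEffect:
    variant: str
    gene: str
    slope: float


@dataclass(frozen=True)
class PlantedInteraction:
    variant: str
    gene: str
    cell_type: str
    slope: float


@dataclass
class GroundTruth:
    """Planted effects; every downstream recovery test reads from here."""

    cis: list[PlantedEffect] = field(default_factory=list)
    secondary: list[PlantedEffect] = field(default_factory=list)
    trans: list[PlantedEffect] = field(default_factory=list)
    interactions: list[PlantedInteraction] = field(default_factory=list)

    def all_genetic_effects(self) -> list[PlantedEffect]:
        return list(self.cis) + list(self.secondary) + list(self.trans)


@dataclass
class CohortDataset:
    """One cohort: aligned genotypes, expression, covariates, proportions."""

    name: str
    genotypes: GenotypeMatrix
    expression: pd.DataFrame          # genes x samples
    covariates: pd.DataFrame          # samples x covariates
    proportions: pd.DataFrame         # samples x cell types (ground truth)


@dataclass
class SimConfig:
    """Study conditions for the synthetic multi-cohort dataset.

    Defaults give three cohorts of 300/200/100 samples (total n = 600, all
    above the 30-sample cohort inclusion floor), a 400-variant panel in
    10-variant LD blocks on two toy chromosomes (50 kb spacing, so both the
    1 Mb cis window and the 5 Mb trans rule are exercisable), five brain cell
    types mixed through a Dirichlet prior, and unit-SD expression noise.
    """

    n_cohorts: int = 3
    n_per_cohort: tuple[int, ...] = (300, 200, 100)
    n_variants: int = 400
    n_genes: int = 120
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_effect_sd: float = 0.5
    n_cis_effects: int = 20
    n_secondary_effects: int = 8
    n_trans_effects: int = 6
    trans_effect_sd: float = 0.4
    n_interaction_effects: int = 6
    interaction_effect_sd: float = 1.5
    n_cell_types: int = 5
    dirichlet_alpha: tuple[float, ...] | None = None
    batch_effect_sd: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.02
    allele_flip_rate: float = 0.1
    ld_block_size: int = 10
    ld_switch: float = 0.25
    n_chromosomes: int = 2
    bp_per_variant: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_cohort) != self.n_cohorts:
            raise ValueError("n_per_cohort length must equal n_cohorts")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("n_variants", "n_genes", "n_cis_effects",
                     "n_secondary_effects", "n_trans_effects",
                     "n_interaction_effects", "n_cell_types"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dirichlet_alpha is None:
            base = (10.0, 6.0, 5.0, 4.0, 2.0, 1.5, 1.0, 0.8)
            self.dirichlet_alpha = base[: self.n_cell_types]
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha length must equal n_cell_types")


@dataclass
class Study:
    config: SimConfig
    variants: pd.DataFrame
    genes: pd.DataFrame
    signature: SignatureMatrix
    truth: GroundTruth
    cohorts: list[CohortDataset]


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _expand_blocks(n_variants: int, ld_blocks, maf_range, n_chromosomes: int,
                   rng: np.random.Generator):
    """Per-variant arrays: chrom, block id, switch prob, block target MAF.

    LD blocks never span a chromosome boundary (the copy chain restarts).
    """
    per_chrom = int(math.ceil(n_variants / n_chromosomes))
    chrom = np.array([f"chr{i // per_chrom + 1}" for i in range(n_variants)])
    if ld_blocks is None:
        ld_blocks = [(10, 0.25)]
    if isinstance(ld_blocks, tuple) and len(ld_blocks) == 2 and np.isscalar(ld_blocks[0]):
        ld_blocks = [ld_blocks]
    block_id = np.empty(n_variants, dtype=int)
    switch = np.empty(n_variants, dtype=float)
    target_maf = np.empty(n_variants, dtype=float)
    i = 0
    b = 0
    spec_i = 0
    while i < n_variants:
        size, s = ld_blocks[spec_i % len(ld_blocks)]
        spec_i += 1
        maf = rng.uniform(*maf_range)
        for _ in range(int(size)):
            if i >= n_variants:
                break
            if i > 0 and chrom[i] != chrom[i - 1]:
                # chromosome boundary: close the block and start a fresh one
                b += 1
                maf = rng.uniform(*maf_range)
            block_id[i] = b
            switch[i] = s
            target_maf[i] = maf
            i += 1
        b += 1
    return chrom, block_id, switch, target_maf


def _draw_haplotypes(n_hap: int, block_id: np.ndarray, switch: np.ndarray,
                     target_maf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    m = block_id.size
    haps = np.empty((n_hap, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(n_hap) < target_maf[j]
        if j == 0 or block_id[j] != block_id[j - 1]:
            haps[:, j] = fresh
        else:
            keep = rng.random(n_hap) >= switch[j]
            haps[:, j] = np.where(keep, haps[:, j - 1], fresh)
    return haps


def simulate_genotypes(n: int, n_variants: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       ld_blocks=None, missing_rate: float = 0.0,
                       seed: int = 0, n_chromosomes: int = 2,
                       bp_per_variant: int = 50_000,
                       sample_prefix: str = "S",
                       variant_meta: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Simulate a dosage panel under the haplotype-copy LD model.

    Parameters
    ----------
    ld_blocks
        Sequence of ``(block_size, switch_probability)`` tuples, cycled until
        the panel is covered. A switch probability ``s`` gives adjacent-variant
        r^2 of roughly ``(1 - s)^2`` within a block.
    variant_meta
        Reuse a previously generated variant table (shared panel across
        cohorts) instead of drawing a new block/MAF layout.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if n_variants < 1:
        raise ValueError("empty panel requested")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = np.random.default_rng(seed)

    if variant_meta is None:
        chrom, block_id, switch, target_maf = _expand_blocks(
            n_variants, ld_blocks, maf_range, n_chromosomes, rng)
        pos = np.empty(n_variants, dtype=int)
        ref = []
        alt = []
        counter: dict[str, int] = {}
        for j in range(n_variants):
            k = counter.get(chrom[j], 0) + 1
            counter[chrom[j]] = k
            pos[j] = k * bp_per_variant
            r, a = _NUCS[j % len(_NUCS)]
            ref.append(r)
            alt.append(a)
        ids = [f"rs{j + 1:06d}" for j in range(n_variants)]
        variants = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
             "target_maf": target_maf, "block": block_id, "switch": switch},
            index=pd.Index(ids, name="variant"),
        )
    else:
        variants = variant_meta.copy()
        block_id = variants["block"].to_numpy()
        switch = variants["switch"].to_numpy()
        target_maf = variants["target_maf"].to_numpy()

    haps = _draw_haplotypes(2 * n, block_id, switch, target_maf, rng)
    true_dos = (haps[:n] + haps[n:]).astype(float)
    dos = true_dos.copy()
    if missing_rate > 0:
        mask = rng.random(dos.shape) < missing_rate
        dos[mask] = np.nan
    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(dosages=dos, variants=variants, samples=samples,
                          true_dosages=true_dos)


def resample_dosages(gmat: GenotypeMatrix, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw a fresh population with the panel's LD structure (no missingness)."""
    block_id = gmat.variants["block"].to_numpy()
    switch = gmat.variants["switch"].to_numpy()
    target_maf = gmat.variants["target_maf"].to_numpy()
    haps = _draw_haplotypes(2 * n, block_id, switch, target_maf, rng)
    return (haps[:n] + haps[n:]).astype(float)


# ---------------------------------------------------------------------------
# signature and gene annotation
# ---------------------------------------------------------------------------

DEFAULT_CELL_TYPES = ("excitatory", "inhibitory", "astrocyte",
                      "oligodendrocyte", "microglia", "endothelial",
                      "opc", "pericyte")


def make_signature(cell_types: Sequence[str] | int = 5,
                   markers_per_type: int = 30, marker_high: float = 20.0,
                   marker_low: float = 1.0, seed: int = 0,
                   merge_map: dict[str, str] | None = None) -> SignatureMatrix:
    """Build a marker-gene signature: each cell type gets markers expressed
    ``marker_high`` in its own column and ``marker_low`` elsewhere (jittered,
    clipped at zero)."""
    if isinstance(cell_types, int):
        cell_types = DEFAULT_CELL_TYPES[:cell_types]
    cell_types = list(cell_types)
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for c, ct in enumerate(cell_types):
        for i in range(markers_per_type):
            prof = np.full(len(cell_types), marker_low, dtype=float)
            prof[c] = marker_high
            prof = np.clip(prof + rng.normal(0, 0.1 * marker_low + 1e-9,
                                             len(cell_types)), 0, None)
            prof[c] = max(prof[c], marker_high * 0.5)
            rows.append(prof)
            index.append(f"MK_{ct.upper()}_{i + 1:02d}")
    values = pd.DataFrame(rows, index=pd.Index(index, name="gene"),
                          columns=cell_types)
    return SignatureMatrix(values=values, merge_map=merge_map)


def make_gene_annotation(n_genes: int, variants: pd.DataFrame,
                         marker_genes: Sequence[str] = (),
                         protein_coding_fraction: float = 0.9,
                         seed: int = 0) -> pd.DataFrame:
    """Gene table (chrom, tss, strand, biotype) on the panel's toy genome.

    Marker genes come first and are always protein-coding; TSS positions are
    drawn uniformly over each chromosome's variant span so cis windows are
    populated.
    """
    rng = np.random.default_rng(seed)
    chroms = variants["chrom"].unique()
    spans = {c: (int(variants.loc[variants.chrom == c, "pos"].min()),
                 int(variants.loc[variants.chrom == c, "pos"].max()))
             for c in chroms}
    names = list(marker_genes) + [
        f"GENE{i + 1:04d}" for i in range(n_genes - len(marker_genes))]
    if len(names) != n_genes:
        raise ValueError("more marker genes than n_genes")
    rows = []
    for i, g in enumerate(names):
        c = chroms[i % len(chroms)]
        lo, hi = spans[c]
        tss = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        is_marker = i < len(marker_genes)
        biotype = ("protein_coding"
                   if is_marker or rng.random() < protein_coding_fraction
                   else "lncRNA")
        rows.append((g, c, tss, strand, biotype))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand",
                                       "biotype"]).set_index("gene")


# ---------------------------------------------------------------------------
# planting effects
# ---------------------------------------------------------------------------

def _pooled_dosage(cohort_genotypes: Sequence[GenotypeMatrix],
                   variant: str) -> np.ndarray:
    return np.concatenate([g.dosage_of(variant, complete=True)
                           for g in cohort_genotypes])


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def plant_effects(config: SimConfig, variants: pd.DataFrame,
                  genes: pd.DataFrame,
                  cohort_genotypes: Sequence[GenotypeMatrix],
                  cell_types: Sequence[str],
                  window: int = 1_000_000,
                  marker_genes: Sequence[str] = ()) -> GroundTruth:
    """Choose planted (variant, gene) effects consistent with the cis/trans
    geometry: cis pairs within the window, secondary variants with pooled
    r^2 < 0.05 against the primary, trans pairs >5 Mb away or cross-chromosome.

    Marker genes (whose variance is dominated by the cell-type mixture) are
    used for cis/trans effects only once the non-marker genes run out;
    interaction effects are planted on marker and non-marker genes alike.
    """
    rng = np.random.default_rng(config.seed + 17)
    truth = GroundTruth()
    coding = genes[genes.biotype == "protein_coding"]
    markers = set(marker_genes)
    plain = [g for g in coding.index if g not in markers]
    marked = [g for g in coding.index if g in markers]
    gene_order = (list(rng.permutation(np.asarray(plain, dtype=object)))
                  + list(rng.permutation(np.asarray(marked, dtype=object))))

    def cis_candidates(gene: str) -> pd.DataFrame:
        grow = genes.loc[gene]
        v = variants[(variants.chrom == grow.chrom)
                     & (np.abs(variants.pos - grow.tss) <= window)]
        return v

    used_genes: list[str] = []
    for gene in gene_order:
        if len(truth.cis) >= config.n_cis_effects:
            break
        cand = cis_candidates(gene)
        if len(cand) == 0:
            continue
        v = str(rng.choice(cand.index.to_numpy()))
        slope = _nonzero_normal(rng, config.cis_effect_sd)
        truth.cis.append(PlantedEffect(v, gene, slope))
        used_genes.append(gene)

    # secondary: second, LD-independent variant for a subset of cis genes
    for eff in truth.cis[: config.n_secondary_effects]:
        cand = cis_candidates(eff.gene)
        primary = _pooled_dosage(cohort_genotypes, eff.variant)
        pblock = variants.loc[eff.variant, "block"]
        options = [v for v in cand.index if variants.loc[v, "block"] != pblock]
        rng.shuffle(options)
        for v in options:
            if _r2(primary, _pooled_dosage(cohort_genotypes, v)) < 0.05:
                truth.secondary.append(
                    PlantedEffect(v, eff.gene,
                                  _nonzero_normal(rng, config.cis_effect_sd * 0.6)))
                break

    # trans: different chromosome or >5 Mb
    free_genes = [g for g in gene_order if g not in used_genes]
    for gene in free_genes[: config.n_trans_effects]:
        grow = genes.loc[gene]
        far = variants[(variants.chrom != grow.chrom)
                       | (np.abs(variants.pos - grow.tss) > 5_000_000)]
        if len(far) == 0:
            continue
        v = str(rng.choice(far.index.to_numpy()))
        truth.trans.append(
            PlantedEffect(v, gene, _nonzero_normal(rng, config.trans_effect_sd)))

    # interactions: cis variant whose slope scales with one cell type
    inter_genes = [g for g in gene_order if g not in used_genes][
        config.n_trans_effects: config.n_trans_effects + config.n_interaction_effects]
    for gene in inter_genes:
        cand = cis_candidates(gene)
        if len(cand) == 0:
            continue
        v = str(rng.choice(cand.index.to_numpy()))
        ct = str(rng.choice(np.asarray(cell_types)))
        slope = _nonzero_normal(rng, config.interaction_effect_sd)
        truth.interactions.append(PlantedInteraction(v, gene, ct, slope))
    return truth


def _nonzero_normal(rng: np.random.Generator, sd: float) -> float:
    """Effect size: normal magnitude bounded away from zero, random sign."""
    mag = abs(rng.normal(0.0, sd))
    return float(np.sign(rng.random() - 0.5) * max(mag, 0.3 * sd))


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_cohort_expression(genotypes: GenotypeMatrix, truth: GroundTruth,
                               signature: SignatureMatrix, config: SimConfig,
                               cohort_index: int,
                               genes: pd.DataFrame | None = None,
                               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one cohort's expression (genes x samples), true cell-type
    proportions, and technical covariates.

    Marker genes are the signature-weighted mixture of the true proportions;
    planted effects add ``slope * dosage`` (cis/trans) or
    ``slope * dosage * proportion_c`` (interaction); a per-cohort batch
    covariate with per-gene loadings and N(0, noise_sd) noise are added on top.
    """
    n = genotypes.n_samples
    if genes is None:
        gene_ids = list(signature.marker_genes)
    else:
        gene_ids = list(genes.index)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for eff in truth.all_genetic_effects():
        if eff.gene not in gene_pos:
            raise ValueError(f"planted gene {eff.gene!r} absent from panel")
    for it in truth.interactions:
        if it.gene not in gene_pos:
            raise ValueError(f"planted gene {it.gene!r} absent from panel")

    # per-gene baselines and batch loadings are shared across cohorts
    base_rng = np.random.default_rng(config.seed + 1009)
    baseline = base_rng.uniform(1.0, 6.0, len(gene_ids))
    batch_loading = base_rng.normal(0.0, 1.0, len(gene_ids))

    rng = np.random.default_rng(config.seed + 7919 * (cohort_index + 1))
    props = rng.dirichlet(config.dirichlet_alpha, size=n)
    props_df = pd.DataFrame(props, index=genotypes.samples,
                            columns=signature.cell_types)

    expr = np.tile(baseline[:, None], (1, n))
    # signature mixture for marker genes
    mk = [g for g in signature.marker_genes if g in gene_pos]
    mk_rows = [gene_pos[g] for g in mk]
    expr[mk_rows, :] = signature.values.loc[mk].to_numpy() @ props.T

    for eff in truth.all_genetic_effects():
        d = genotypes.dosage_of(eff.variant, complete=True)
        expr[gene_pos[eff.gene], :] += eff.slope * d
    for it in truth.interactions:
        d = genotypes.dosage_of(it.variant, complete=True)
        expr[gene_pos[it.gene], :] += (it.slope * d
                                       * props_df[it.cell_type].to_numpy())

    batch = rng.normal(float(cohort_index), 1.0, n)
    rna_quality = rng.normal(0.0, 1.0, n)
    expr += config.batch_effect_sd * np.outer(batch_loading, batch)
    expr += 0.2 * config.batch_effect_sd * np.outer(
        base_rng.normal(0, 1, len(gene_ids)), rna_quality)
    expr += rng.normal(0.0, config.noise_sd, expr.shape)

    expr_df = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene"),
                           columns=genotypes.samples)
    covs = pd.DataFrame({"batch": batch, "rna_quality": rna_quality},
                        index=genotypes.samples)
    return expr_df, props_df, covs


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> Study:
    """End-to-end synthetic study: shared variant panel, per-cohort genotype
    draws (with per-cohort ref/alt swaps for harmonization testing), gene
    annotation, planted effects, and per-cohort expression."""
    rng = np.random.default_rng(config.seed)
    master = simulate_genotypes(
        n=2, n_variants=config.n_variants, maf_range=config.maf_range,
        ld_blocks=[(config.ld_block_size, config.ld_switch)],
        missing_rate=0.0, seed=config.seed,
        n_chromosomes=config.n_chromosomes,
        bp_per_variant=config.bp_per_variant)
    markers_per_type = max(1, min(10, config.n_genes // (2 * config.n_cell_types)))
    signature = make_signature(config.n_cell_types,
                               markers_per_type=markers_per_type,
                               seed=config.seed + 3)
    genes = make_gene_annotation(config.n_genes, master.variants,
                                 marker_genes=signature.marker_genes,
                                 seed=config.seed + 5)

    cohort_genos: list[GenotypeMatrix] = []
    for c in range(config.n_cohorts):
        g = simulate_genotypes(
            n=config.n_per_cohort[c], n_variants=config.n_variants,
            missing_rate=config.missing_rate, seed=config.seed + 101 * (c + 1),
            sample_prefix=f"C{c + 1}_", variant_meta=master.variants)
        if c > 0 and config.allele_flip_rate > 0:
            _flip_recorded_alleles(g, config.allele_flip_rate,
                                   np.random.default_rng(config.seed + 211 * c))
        cohort_genos.append(g)

    truth = plant_effects(config, master.variants, genes, cohort_genos,
                          signature.cell_types,
                          marker_genes=signature.marker_genes)

    cohorts = []
    for c, g in enumerate(cohort_genos):
        expr, props, covs = simulate_cohort_expression(
            g, truth, signature, config, c, genes=genes)
        cohorts.append(CohortDataset(name=f"cohort{c + 1}", genotypes=g,
                                     expression=expr, covariates=covs,
                                     proportions=props))
    return Study(config=config, variants=master.variants, genes=genes,
                 signature=signature, truth=truth, cohorts=cohorts)


def _flip_recorded_alleles(g: GenotypeMatrix, rate: float,
                           rng: np.random.Generator) -> None:
    """Swap ref/alt bookkeeping (and recode dosage as 2 - d) for a random
    subset of variants; the underlying genotypes are unchanged, so a correct
    harmonization step must undo this exactly."""
    flip = rng.random(g.n_variants) < rate
    idx = np.where(flip)[0]
    if idx.size == 0:
        return
    v = g.variants
    ref = v["ref"].to_numpy().copy()
    alt = v["alt"].to_numpy().copy()
    ref[idx], alt[idx] = alt[idx], ref[idx].copy()
    g.variants = v.assign(ref=ref, alt=alt)
    g.dosages[:, idx] = 2.0 - g.dosages[:, idx]
    if g.true_dosages is not None:
        g.true_dosages[:, idx] = 2.0 - g.true_dosages[:, idx]


# ---------------------------------------------------------------------------
# GWAS summaries
# ---------------------------------------------------------------------------

def simulate_gwas_summary(genotypes: GenotypeMatrix, causal_variant: str,
                          h2_locus: float, n_gwas: int, shared: bool = True,
                          seed: int = 0, binary: bool = False,
                          case_fraction: float = 0.5) -> pd.DataFrame:
    """Per-variant GWAS summary statistics from a simulated phenotype.

    A fresh population with the panel's LD structure is drawn. When
    ``shared`` is False the phenotype is driven by an alternative variant in
    low LD (pooled r^2 < 0.05) with ``causal_variant``, producing a
    colocalization-negative locus. Continuous traits use a linear model;
    binary traits use a logistic link on the genetic liability, with
    per-variant effects estimated by (vectorized) logistic regression.

    Returns a DataFrame (snp, chr, pos, ea, oa, beta, se, p, n); the effect
    allele is the panel's alt allele. ``df.attrs`` records the causal variant
    actually used.
    """
    if causal_variant not in genotypes.variants.index:
        raise ValueError(f"{causal_variant!r} not in panel")
    if n_gwas < 50:
        raise ValueError("n_gwas < 50 gives unstable standard errors")
    if not (0.0 <= h2_locus < 1.0):
        raise ValueError("h2_locus must be in [0, 1)")
    rng = np.random.default_rng(seed)
    G = resample_dosages(genotypes, n_gwas, rng)
    v = genotypes.variants
    cidx = genotypes.variant_index(causal_variant)

    if not shared:
        g0 = G[:, cidx]
        order = np.argsort(np.abs(v["pos"].to_numpy()
                                  - int(v.iloc[cidx]["pos"])))
        alt_idx = None
        for j in order:
            if j == cidx or v.iloc[j]["chrom"] != v.iloc[cidx]["chrom"]:
                continue
            if v.iloc[j]["block"] == v.iloc[cidx]["block"]:
                continue
            if _r2(g0, G[:, j]) < 0.05:
                alt_idx = int(j)
                break
        if alt_idx is None:
            raise ValueError("no low-LD alternative causal variant available")
        cidx = alt_idx
    g = G[:, cidx]

    var_g = g.var()
    beta_true = math.sqrt(h2_locus / var_g) if (h2_locus > 0 and var_g > 0) else 0.0
    liability = beta_true * g
    if binary:
        from scipy.special import expit
        alpha = math.log(case_fraction / (1 - case_fraction))
        y = (rng.random(n_gwas)
             < expit(alpha + liability + rng.normal(0, math.sqrt(max(1 - h2_locus, 1e-12)), n_gwas))
             ).astype(float)
        beta, se = _logistic_scan(G, y)
    else:
        y = liability + rng.normal(0, math.sqrt(1 - h2_locus), n_gwas)
        beta, se = _linear_scan(G, y)
    from scipy import stats as sps
    z = np.where(se > 0, beta / se, 0.0)
    p = 2 * sps.norm.sf(np.abs(z))
    out = pd.DataFrame({
        "snp": v.index, "chr": v["chrom"].to_numpy(), "pos": v["pos"].to_numpy(),
        "ea": v["alt"].to_numpy(), "oa": v["ref"].to_numpy(),
        "beta": beta, "se": se, "p": p, "n": n_gwas,
    }).reset_index(drop=True)
    out.attrs["causal_variant"] = str(v.index[cidx])
    out.attrs["shared"] = shared
    return out


def _linear_scan(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Marginal OLS of y on each variant (vectorized)."""
    n = y.size
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc ** 2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = gc.T @ yc / sxx
    resid_var = ((yc ** 2).sum() - beta ** 2 * sxx) / (n - 2)
    se = np.sqrt(np.maximum(resid_var, 0) / sxx)
    return np.nan_to_num(beta), np.where(np.isfinite(se) & (se > 0), se, np.inf)


def _logistic_scan(G: np.ndarray, y: np.ndarray,
                   n_iter: int = 25) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant logistic regression (intercept + dosage) via IRLS,
    vectorized across variants."""
    from scipy.special import expit
    n, m = G.shape
    b0 = np.full(m, math.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9)))
    b1 = np.zeros(m)
    for _ in range(n_iter):
        eta = b0[None, :] + G * b1[None, :]
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        r = y[:, None] - mu
        s0 = r.sum(axis=0)
        s1 = (G * r).sum(axis=0)
        w00 = w.sum(axis=0)
        w01 = (w * G).sum(axis=0)
        w11 = (w * G * G).sum(axis=0)
        det = np.clip(w00 * w11 - w01 ** 2, 1e-12, None)
        db0 = (w11 * s0 - w01 * s1) / det
        db1 = (w00 * s1 - w01 * s0) / det
        b0 += db0
        b1 += db1
        if np.max(np.abs(db1)) < 1e-10:
            break
    eta = b0[None, :] + G * b1[None, :]
    mu = expit(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    w00 = w.sum(axis=0)
    w01 = (w * G).sum(axis=0)
    w11 = (w * G * G).sum(axis=0)
    det = np.clip(w00 * w11 - w01 ** 2, 1e-12, None)
    se = np.sqrt(w00 / det)
    return b1, se


def simulate_summary_pair(n_eqtl: int, seed: int = 0, slope_corr: float = 0.0,
                          slope_sd: float = 0.5,
                          se_range: tuple[float, float] = (0.03, 0.08),
                          sig_threshold: float = 5e-8,
                          allele_swap_rate: float = 0.3
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two eQTL summary-statistic tables for agreement analyses.

    Per record the two datasets' true slopes are bivariate normal with
    correlation ``slope_corr`` (0 = fully independent effects); observed
    betas add N(0, se) noise with per-record SEs drawn from ``se_range``
    (heteroskedastic), p-values follow beta/se, and significance is each
    dataset's own p < ``sig_threshold``. A fraction of the second dataset's
    records has ref/alt recorded swapped (beta negated), exercising
    harmonization.
    """
    rng = np.random.default_rng(seed)
    cov = slope_corr * slope_sd ** 2
    true = rng.multivariate_normal(
        [0.0, 0.0], [[slope_sd ** 2, cov], [cov, slope_sd ** 2]], size=n_eqtl)
    from scipy import stats as sps

    def one(col: int) -> pd.DataFrame:
        se = rng.uniform(*se_range, n_eqtl)
        beta = true[:, col] + rng.normal(0, se)
        p = 2 * sps.norm.sf(np.abs(beta / se))
        return pd.DataFrame({
            "gene": [f"G{i:05d}" for i in range(n_eqtl)],
            "variant": [f"rs{i:06d}" for i in range(n_eqtl)],
            "assessed_allele": "A", "other_allele": "G",
            "beta": beta, "se": se, "p": p,
            "significant": p < sig_threshold})

    a, b = one(0), one(1)
    swap = rng.random(n_eqtl) < allele_swap_rate
    b.loc[swap, ["assessed_allele", "other_allele"]] = ["G", "A"]
    b.loc[swap, "beta"] = -b.loc[swap, "beta"]
    return a, b


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------

def write_vcf(gmat: GenotypeMatrix, path: str) -> None:
    """Minimal VCF v4.2: GT from rounded dosage plus a DS field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gmat.samples) + "\n")
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (vid, row) in enumerate(gmat.variants.iterrows()):
            fields = [str(row["chrom"]).removeprefix("chr"), str(int(row["pos"])),
                      str(vid), row["ref"], row["alt"], ".", "PASS", ".", "GT:DS"]
            for i in range(gmat.n_samples):
                d = gmat.dosages[i, j]
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gts[int(round(d))]}:{d:.3f}")
            fh.write("\t".join(fields) + "\n")


def write_dosage_tsv(gmat: GenotypeMatrix, path: str) -> None:
    df = pd.DataFrame(gmat.dosages.T, index=gmat.variants.index,
                      columns=gmat.samples)
    df.to_csv(path, sep="\t", na_rep="NA")


def write_expression_tsv(expr: pd.DataFrame, path: str) -> None:
    expr.to_csv(path, sep="\t")


def write_annotation_bed(genes: pd.DataFrame, path: str) -> None:
    out = genes.reset_index()[["chrom", "tss", "strand", "gene", "biotype"]]
    out.to_csv(path, sep="\t", index=False)


def write_gwas_tsv(gwas: pd.DataFrame, path: str) -> None:
    gwas.to_csv(path, sep="\t", index=False)
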