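"""Per-cohort rank association and sample-size-weighted z-score meta-analysis.

The scan correlates genotype dosage with expression by Spearman correlation
within each cohort, converts each cohort's correlation to a z-score through
the t approximation, and combines cohorts as

    z_meta = sum_i sqrt(n_i) * z_i / sqrt(sum_i n_i)

i.e. weights w_i = sqrt(n_i), z_meta = sum w_i z_i / sqrt(sum w_i^2). This is
robust to between-cohort heterogeneity in expression scale because only ranks
enter per cohort. Meta z-scores are converted back to an approximate
allelic effect and standard error on the standardized-expression scale using
the allele frequency and sample size:

    d = sqrt(2 * maf * (1 - maf) * (n + z^2)),  beta = z / d,  se = 1 / d.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtri

from .synth import CohortDataset, GenotypeMatrix

logger = logging.getLogger(__name__)

Z_CAP = 40.0
MIN_COHORT_N = 30


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _hwe_distribution(n: int, rare: int) -> tuple[tuple[int, ...], dict]:
    """Exact-integer heterozygote-count distribution conditional on allele
    counts: unnormalized weight of het count h is C(n; hom_r, h, hom_c) 2^h
    (the common denominator C(2n, rare) cancels). Returns the weights per het
    (parity-stepped from rare % 2) and a map het -> exact tail probability
    (sum of weights <= the observed weight, over the total)."""
    hets = list(range(rare % 2, rare + 1, 2))
    h0 = hets[0]
    hom_r0 = (rare - h0) // 2
    w = (math.factorial(n)
         // (math.factorial(hom_r0) * math.factorial(h0)
             * math.factorial(n - h0 - hom_r0))) * (2 ** h0)
    weights = [w]
    for h in hets[:-1]:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # exact integer recurrence: w(h+2) = w(h) * 4 hom_r hom_c / ((h+1)(h+2))
        w = w * 4 * hom_r * hom_c // ((h + 1) * (h + 2))
        weights.append(w)
    total = sum(weights)
    order = sorted(range(len(weights)), key=weights.__getitem__)
    cum = 0
    tail: dict[int, float] = {}
    i = 0
    while i < len(order):
        j = i
        block = 0
        while j < len(order) and weights[order[j]] == weights[order[i]]:
            block += weights[order[j]]
            j += 1
        cum += block
        p = min(cum / total, 1.0)
        for k in range(i, j):
            tail[hets[order[k]]] = p
        i = j
    return tuple(weights), tail


def hwe_exact_p(n_AA: int, n_AB: int, n_BB: int) -> float:
    """Exact two-sided Hardy-Weinberg test.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote configurations no more probable than the observed one.
    Exact integer arithmetic throughout; ties in configuration probability
    are exact, not float-rounded.
    """
    if min(n_AA, n_AB, n_BB) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_AB + n_BB
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = 2 * n_AA + n_AB
    rare = min(n_a, 2 * n - n_a)
    _, tail = _hwe_distribution(n, rare)
    return tail[n_AB]


def hwe_exact_all(n: int, rare_alleles: int) -> tuple[np.ndarray, np.ndarray]:
    """All heterozygote counts compatible with ``rare_alleles`` minor alleles
    in ``n`` samples, with their exact test p-values. Returns (hets, ps)."""
    if not (0 <= rare_alleles <= n):
        raise ValueError("rare allele count must be in [0, n]")
    _, tail = _hwe_distribution(n, rare_alleles)
    hets = np.array(sorted(tail))
    return hets, np.array([tail[h] for h in hets])


# ---------------------------------------------------------------------------
# variant-level QC
# ---------------------------------------------------------------------------

def genotype_counts(dosage: np.ndarray) -> tuple[int, int, int]:
    """(hom-ref, het, hom-alt) from rounded non-missing dosages."""
    d = dosage[~np.isnan(dosage)]
    g = np.clip(np.round(d), 0, 2).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def variant_qc_table(cohorts: Sequence[GenotypeMatrix]) -> pd.DataFrame:
    """Per-variant joint MAF (sample-size-weighted mean of cohort MAFs),
    worst-cohort HWE exact p, and worst-cohort missingness."""
    base = cohorts[0].variants
    mafs = np.zeros(len(base))
    wsum = 0.0
    hwe_min = np.ones(len(base))
    miss_max = np.zeros(len(base))
    for g in cohorts:
        n = g.n_samples
        mafs += n * np.nan_to_num(g.observed_maf())
        wsum += n
        miss = np.isnan(g.dosages).mean(axis=0)
        miss_max = np.maximum(miss_max, miss)
        for j in range(g.n_variants):
            aa, ab, bb = genotype_counts(g.dosages[:, j])
            if aa + ab + bb >= 1:
                hwe_min[j] = min(hwe_min[j], hwe_exact_p(aa, ab, bb))
    return pd.DataFrame({"maf": mafs / wsum, "hwe_p": hwe_min,
                         "missingness": miss_max}, index=base.index)


def filter_variants(qc: pd.DataFrame, maf_min: float = 0.01,
                    hwe_min: float = 1e-4,
                    max_missing: float = 0.05) -> tuple[pd.Index, pd.DataFrame]:
    """Apply MAF > maf_min, HWE p > hwe_min, missingness <= max_missing.

    Returns the surviving variant index plus a per-dropped-variant reason
    table. Variants at HWE p <= hwe_min are excluded everywhere (the
    joint-analysis convention used by both the cis and interaction scans).
    """
    reasons = []
    keep = np.ones(len(qc), dtype=bool)
    for i, (vid, row) in enumerate(qc.iterrows()):
        why = []
        if not row.maf > maf_min:
            why.append(f"maf={row.maf:.4f}<= {maf_min}")
        if not row.hwe_p > hwe_min:
            why.append(f"hwe_p={row.hwe_p:.2e}<= {hwe_min}")
        if row.missingness > max_missing:
            why.append(f"missingness={row.missingness:.3f}> {max_missing}")
        if why:
            keep[i] = False
            reasons.append((vid, "; ".join(why)))
    dropped = pd.DataFrame(reasons, columns=["variant", "reason"])
    for _, r in dropped.iterrows():
        logger.debug("dropped %s: %s", r.variant, r.reason)
    return qc.index[keep], dropped


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

def cis_pairs(variants: pd.DataFrame, genes: pd.DataFrame,
              window: int = 1_000_000,
              biotype_filter: str | None = "protein_coding") -> pd.DataFrame:
    """All (gene, variant) pairs with |pos - tss| <= window on the same
    chromosome. Distance is signed: negative means upstream of the TSS with
    respect to the gene's strand."""
    gsel = genes if biotype_filter is None else genes[genes.biotype == biotype_filter]
    rows = []
    for gene, grow in gsel.iterrows():
        v = variants[(variants.chrom == grow.chrom)
                     & (np.abs(variants.pos - grow.tss) <= window)]
        sign = 1 if grow.strand == "+" else -1
        for vid, vrow in v.iterrows():
            rows.append((gene, vid, sign * int(vrow.pos - grow.tss)))
    return pd.DataFrame(rows, columns=["gene", "variant", "distance"])


def trans_pairs(variants: pd.DataFrame, genes: pd.DataFrame,
                variant_shortlist: Sequence[str],
                min_distance: int = 5_000_000,
                biotype_filter: str | None = "protein_coding") -> pd.DataFrame:
    """(gene, variant) pairs for the trans scan: variant restricted to the
    shortlist and SNP-TSS distance > min_distance or different chromosome."""
    gsel = genes if biotype_filter is None else genes[genes.biotype == biotype_filter]
    vsel = variants.loc[[v for v in variant_shortlist if v in variants.index]]
    rows = []
    for gene, grow in gsel.iterrows():
        for vid, vrow in vsel.iterrows():
            if (vrow.chrom != grow.chrom
                    or abs(int(vrow.pos - grow.tss)) > min_distance):
                rows.append((gene, vid, int(vrow.pos - grow.tss)))
    return pd.DataFrame(rows, columns=["gene", "variant", "distance"])


# ---------------------------------------------------------------------------
# association statistics
# ---------------------------------------------------------------------------

def _rho_to_z(rho: np.ndarray, n) -> np.ndarray:
    """Spearman rho -> two-sided p via the t approximation (n-2 df) -> signed
    standard-normal z, capped at |z| <= Z_CAP."""
    rho = np.clip(np.asarray(rho, dtype=float), -1.0, 1.0)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), np.maximum(n - 2, 1))
    with np.errstate(divide="ignore"):
        z = -ndtri(p / 2.0)  # p underflow -> +inf, capped below
    z = np.sign(rho) * np.minimum(z, Z_CAP)
    return z


def cohort_assoc(dosage: np.ndarray, expr: np.ndarray,
                 min_n: int = MIN_COHORT_N) -> tuple[int, float, float] | None:
    """Spearman association of one variant with one gene in one cohort.

    Pairwise-complete observations; returns (n, rho, z) or None when the
    cohort is unusable (too few samples or a constant vector).
    """
    ok = ~(np.isnan(dosage) | np.isnan(expr))
    n = int(ok.sum())
    if n < min_n:
        return None
    d, e = dosage[ok], expr[ok]
    if np.all(d == d[0]) or np.all(e == e[0]):
        logger.debug("constant vector; cohort skipped for this pair")
        return None
    rho = sps.spearmanr(d, e).statistic
    if not np.isfinite(rho):
        return None
    z = float(_rho_to_z(np.array([rho]), n)[0])
    return n, float(rho), z


def meta_z(per_cohort: Sequence[tuple[int, float]]) -> tuple[float, float, int]:
    """Sample-size-weighted z-score meta-analysis.

    z_meta = sum(sqrt(n_i) z_i) / sqrt(sum n_i); two-sided normal p.
    """
    if len(per_cohort) == 0:
        raise ValueError("need at least one cohort")
    # canonical summation order + fsum: cohort permutation is exactly neutral
    pairs = sorted((float(n), float(z)) for n, z in per_cohort)
    num = math.fsum(math.sqrt(n) * z for n, z in pairs)
    den = math.sqrt(math.fsum(n for n, _ in pairs))
    z = num / den
    p = float(2.0 * sps.norm.sf(abs(z)))
    return z, p, int(sum(n for n, _ in pairs))


def zscore_to_beta_se(z: float, maf: float, n: float) -> tuple[float, float]:
    """Approximate allelic effect and SE from a z-score, MAF and sample size:
    d = sqrt(2 maf (1-maf) (n + z^2)); beta = z/d; se = 1/d."""
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if n <= 0:
        raise ValueError("n must be positive")
    d = math.sqrt(2.0 * maf * (1.0 - maf) * (n + z * z))
    return z / d, 1.0 / d


# ---------------------------------------------------------------------------
# vectorized per-gene machinery (shared with the permutation engine)
# ---------------------------------------------------------------------------

def _rank(a: np.ndarray) -> np.ndarray:
    """Average ranks along axis 0 (columns ranked independently)."""
    return sps.rankdata(a, axis=0)


def assoc_block(dosages: np.ndarray, expr: np.ndarray,
                min_n: int = MIN_COHORT_N
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spearman rho/z of every dosage column against one expression vector.

    Complete columns are ranked once and correlated by matrix algebra; columns
    with missing dosages fall back to pairwise-complete per-column work.
    Returns (n, rho, z) arrays with NaN z where a column is untestable.
    """
    ns = np.full(dosages.shape[1], np.nan)
    rhos = np.full(dosages.shape[1], np.nan)
    miss = np.isnan(dosages).any(axis=0)
    eok = ~np.isnan(expr)
    if (~miss).any():
        D = dosages[:, ~miss][eok]
        y = expr[eok]
        n = y.size
        if n >= min_n:
            rd = _rank(D)
            ry = sps.rankdata(y)
            rd = rd - rd.mean(axis=0)
            ry = ry - ry.mean()
            denom = np.sqrt((rd ** 2).sum(axis=0) * (ry ** 2).sum())
            with np.errstate(invalid="ignore", divide="ignore"):
                r = rd.T @ ry / np.where(denom == 0, np.nan, denom)
            rhos[~miss] = r
            ns[~miss] = n
    for j in np.where(miss)[0]:
        res = cohort_assoc(dosages[:, j], expr, min_n=min_n)
        if res is not None:
            ns[j], rhos[j], _ = res
    with np.errstate(invalid="ignore"):
        zs = _rho_to_z(np.nan_to_num(rhos), np.nan_to_num(ns, nan=3.0))
    zs[~np.isfinite(rhos)] = np.nan
    ns[~np.isfinite(rhos)] = np.nan
    return ns, rhos, zs


def combine_block(ns: np.ndarray, zs: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Meta-analyze (cohorts x variants) arrays of n and z column-wise,
    ignoring NaN cohorts. Returns (meta_z, meta_p, total_n)."""
    ok = np.isfinite(zs) & np.isfinite(ns)
    w = np.where(ok, np.sqrt(np.where(ok, ns, 0.0)), 0.0)
    num = np.nansum(w * np.where(ok, zs, 0.0), axis=0)
    den = np.sqrt((w ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(den > 0, num / den, np.nan)
    p = 2.0 * sps.norm.sf(np.abs(z))
    return z, p, np.where(ok, ns, 0.0).sum(axis=0).astype(int)


# ---------------------------------------------------------------------------
# allele harmonization and gene-level data assembly
# ---------------------------------------------------------------------------

@dataclass
class GeneData:
    """Analysis-ready data for one gene: per cohort, the harmonized dosage
    submatrix (samples x variants, assessed allele = reference cohort's alt)
    and the expression vector."""

    gene: str
    variants: list[str]
    distances: list[int]
    cohort_dosages: list[np.ndarray] = field(default_factory=list)
    cohort_expr: list[np.ndarray] = field(default_factory=list)


def harmonize_dosages(cohorts: Sequence[GenotypeMatrix],
                      variant_ids: Sequence[str]) -> tuple[list[str], list[np.ndarray]]:
    """Align all cohorts to the first cohort's alt allele per variant.

    A cohort whose (ref, alt) is the swap of the reference pair has its
    dosages recoded 2 - d; identical pairs pass through; anything else is
    dropped from every cohort (and logged).
    """
    ref = cohorts[0].variants
    kept: list[str] = []
    per_cohort_cols: list[list[np.ndarray]] = [[] for _ in cohorts]
    for vid in variant_ids:
        ra, aa = ref.loc[vid, "ref"], ref.loc[vid, "alt"]
        cols = []
        ok = True
        for g in cohorts:
            if vid not in g.variants.index:
                cols.append(None)
                continue
            r2_, a2_ = g.variants.loc[vid, "ref"], g.variants.loc[vid, "alt"]
            d = g.dosages[:, g.variant_index(vid)]
            if (r2_, a2_) == (ra, aa):
                cols.append(d)
            elif (r2_, a2_) == (aa, ra):
                cols.append(2.0 - d)
            else:
                logger.warning("variant %s: irreconcilable alleles, dropped", vid)
                ok = False
                break
        if not ok:
            continue
        kept.append(vid)
        for c, col in enumerate(cols):
            per_cohort_cols[c].append(
                col if col is not None
                else np.full(cohorts[c].n_samples, np.nan))
    mats = [np.column_stack(cols) if cols else
            np.empty((cohorts[c].n_samples, 0))
            for c, cols in enumerate(per_cohort_cols)]
    return kept, mats


def build_gene_data(cohorts: Sequence[CohortDataset],
                    pairs: pd.DataFrame) -> list[GeneData]:
    """Group the pair list by gene and assemble harmonized per-cohort arrays."""
    out = []
    genos = [c.genotypes for c in cohorts]
    for gene, sub in pairs.groupby("gene", sort=True):
        vids = list(sub["variant"])
        kept, mats = harmonize_dosages(genos, vids)
        dist = dict(zip(sub["variant"], sub["distance"]))
        gd = GeneData(gene=str(gene), variants=kept,
                      distances=[dist[v] for v in kept])
        usable = False
        for c, mat in zip(cohorts, mats):
            if gene in c.expression.index:
                gd.cohort_dosages.append(mat)
                gd.cohort_expr.append(c.expression.loc[gene].to_numpy(float))
                usable = True
            else:
                gd.cohort_dosages.append(mat)
                gd.cohort_expr.append(np.full(mat.shape[0], np.nan))
        if usable and kept:
            out.append(gd)
    return out


def scan_gene(gd: GeneData, expr_override: list[np.ndarray] | None = None,
              min_n: int = MIN_COHORT_N) -> pd.DataFrame:
    """Meta-analyzed association of every variant of one gene.

    ``expr_override`` substitutes per-cohort expression vectors (used by the
    permutation and conditional machinery).
    """
    exprs = expr_override if expr_override is not None else gd.cohort_expr
    m = len(gd.variants)
    ns = np.full((len(exprs), m), np.nan)
    zs = np.full((len(exprs), m), np.nan)
    rhos = np.full((len(exprs), m), np.nan)
    for c, (D, y) in enumerate(zip(gd.cohort_dosages, exprs)):
        if np.all(np.isnan(y)):
            continue
        ns[c], rhos[c], zs[c] = assoc_block(D, y, min_n=min_n)
    mz, mp, tn = combine_block(ns, zs)
    return pd.DataFrame({
        "gene": gd.gene, "variant": gd.variants, "distance": gd.distances,
        "meta_z": mz, "p": mp, "n": tn,
        "n_cohorts": np.isfinite(zs).sum(axis=0),
    })


def run_scan(cohorts: Sequence[CohortDataset], pairs: pd.DataFrame,
             mode: str = "cis", qc: pd.DataFrame | None = None,
             min_n: int = MIN_COHORT_N) -> pd.DataFrame:
    """Full cis or trans scan over a pair list.

    Returns one row per testable (variant, gene) pair with per-pair meta z,
    p, total n, weighted MAF and reconstructed beta/se. The assessed allele
    is the first cohort's alt allele. Pairs with zero testable cohorts are
    omitted (counted in ``df.attrs['n_omitted']``).
    """
    if mode not in ("cis", "trans"):
        raise ValueError("mode must be 'cis' or 'trans'")
    if qc is None:
        qc = variant_qc_table([c.genotypes for c in cohorts])
    gene_data = build_gene_data(cohorts, pairs)
    frames = []
    for gd in gene_data:
        frames.append(scan_gene(gd, min_n=min_n))
    if not frames:
        out = pd.DataFrame({"gene": pd.Series(dtype=str),
                            "variant": pd.Series(dtype=str),
                            "distance": pd.Series(dtype=int),
                            "meta_z": pd.Series(dtype=float),
                            "p": pd.Series(dtype=float),
                            "n": pd.Series(dtype=int),
                            "n_cohorts": pd.Series(dtype=int)})
        out.attrs["n_omitted"] = 0
        for col in ("assessed_allele", "other_allele", "maf", "beta", "se"):
            out[col] = pd.Series(dtype=float)
        out["is_trans"] = pd.Series(dtype=bool)
        return out
    out = pd.concat(frames, ignore_index=True)
    n_before = len(out)
    out = out[np.isfinite(out["meta_z"])].reset_index(drop=True)
    out.attrs["n_omitted"] = n_before - len(out)

    ref = cohorts[0].genotypes.variants
    out["assessed_allele"] = ref.loc[out["variant"], "alt"].to_numpy()
    out["other_allele"] = ref.loc[out["variant"], "ref"].to_numpy()
    out["maf"] = qc.loc[out["variant"], "maf"].to_numpy()
    maf = np.clip(out["maf"].to_numpy(), 1e-6, 0.5)
    d = np.sqrt(2.0 * maf * (1.0 - maf)
                * (out["n"].to_numpy() + out["meta_z"].to_numpy() ** 2))
    out["beta"] = out["meta_z"] / d
    out["se"] = 1.0 / d
    out["is_trans"] = mode == "trans"
    return out
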