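"""Multiple-testing machinery for the eQTL scans.

cis significance follows the permutation / beta-distribution scheme: the
sample labels of the expression vector are shuffled within each cohort, the
full per-gene scan is repeated per permutation, and the per-permutation
minimum p-value is recorded. A Beta(a, b) distribution is fitted to those
minima by maximum likelihood (the minimum of m independent uniforms is
Beta(1, m), so b acts as an effective number of independent tests), and the
gene's nominal top p-value is adjusted through the fitted CDF. Storey
q-values over the adjusted top associations then control the FDR across
genes (q < 0.05 significant).

trans significance uses an empirical permutation FDR over a small number of
genome-wide permutations: FDR(t) = mean permuted discoveries at p <= t over
real discoveries at p <= t.

Numerical choices: inside the permutation engine, missing dosages are imputed
at the per-cohort column mean once per gene, so real and permuted scans see
the identical design and the null is exactly exchangeable; per-gene
permutation streams are seeded from the master seed plus a CRC32 hash of the
gene id, making results independent of gene evaluation order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .meta import GeneData, _rho_to_z, build_gene_data, combine_block
from .synth import CohortDataset

logger = logging.getLogger(__name__)


def gene_seed(master_seed: int, gene: str) -> int:
    return (master_seed * 1_000_003 + zlib.crc32(gene.encode())) % (2 ** 31)


@dataclass
class PermutationNull:
    gene: str
    min_p: np.ndarray
    a: float
    b: float
    loglik: float
    ks_distance: float


# ---------------------------------------------------------------------------
# fast per-gene scan engine
# ---------------------------------------------------------------------------

class GeneScanEngine:
    """Precomputed rank machinery for repeated scans of one gene.

    Dosage columns are mean-imputed per cohort and rank-transformed once;
    each evaluation then costs one rank of y plus a matrix product per
    cohort.
    """

    def __init__(self, gd: GeneData, min_n: int = 30):
        self.gd = gd
        self.min_n = min_n
        self._cohorts = []  # (Rd centered ranks, col_norm, n, expr)
        for D, y in zip(gd.cohort_dosages, gd.cohort_expr):
            n = D.shape[0]
            if n < min_n or np.all(np.isnan(y)) or D.shape[1] == 0:
                self._cohorts.append(None)
                continue
            Di = D.copy()
            mu = np.nanmean(Di, axis=0)
            ix = np.where(np.isnan(Di))
            Di[ix] = np.take(mu, ix[1])
            Rd = sps.rankdata(Di, axis=0)
            Rd = Rd - Rd.mean(axis=0)
            norm = np.sqrt((Rd ** 2).sum(axis=0))
            norm[norm == 0] = np.nan
            self._cohorts.append((Rd, norm, n, np.asarray(y, dtype=float)))

    @property
    def m(self) -> int:
        return len(self.gd.variants)

    def scan(self, perm: list[np.ndarray | None] | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
        """(meta_z, meta_p) per variant; ``perm`` holds per-cohort sample
        permutations of the expression labels (None = identity)."""
        m = self.m
        nrows = len(self._cohorts)
        ns = np.full((nrows, m), np.nan)
        zs = np.full((nrows, m), np.nan)
        for c, item in enumerate(self._cohorts):
            if item is None:
                continue
            Rd, norm, n, y = item
            yy = y if perm is None or perm[c] is None else y[perm[c]]
            ry = sps.rankdata(yy)
            ry = ry - ry.mean()
            ynorm = np.sqrt((ry ** 2).sum())
            if ynorm == 0:
                continue
            rho = Rd.T @ ry / (norm * ynorm)
            zs[c] = _rho_to_z(np.nan_to_num(rho), n)
            zs[c, ~np.isfinite(rho)] = np.nan
            ns[c] = np.where(np.isfinite(rho), n, np.nan)
        mz, mp, _ = combine_block(ns, zs)
        return mz, mp

    def min_p(self, perm=None) -> tuple[float, int]:
        _, p = self.scan(perm)
        if not np.isfinite(p).any():
            return 1.0, -1
        j = int(np.nanargmin(p))
        return float(p[j]), j


# ---------------------------------------------------------------------------
# permutation null + beta fit
# ---------------------------------------------------------------------------

def fit_beta(min_p: np.ndarray, m_variants: int) -> tuple[float, float, float, float]:
    """MLE Beta fit to permutation-minimum p-values (method-of-moments start),
    parameters clipped to a in [0.1, 10], b in [0.5, 10 m]. Returns
    (a, b, loglik, KS distance)."""
    x = np.clip(np.asarray(min_p, dtype=float), 1e-12, 1 - 1e-12)
    mean, var = x.mean(), x.var()
    if var <= 0:
        a0, b0 = 1.0, max(m_variants, 1.0)
    else:
        common = mean * (1 - mean) / var - 1.0
        a0, b0 = max(mean * common, 0.1), max((1 - mean) * common, 0.5)
    try:
        a, b, _, _ = sps.beta.fit(x, a0, b0, floc=0, fscale=1)
    except Exception:  # fall back to the moment estimate
        a, b = a0, b0
    a = float(np.clip(a, 0.1, 10.0))
    b = float(np.clip(b, 0.5, 10.0 * max(m_variants, 1)))
    loglik = float(sps.beta.logpdf(x, a, b).sum())
    ks = float(sps.kstest(x, "beta", args=(a, b)).statistic)
    return a, b, loglik, ks


def permute_gene_null(gd: GeneData, n_perm: int = 1000, seed: int = 0,
                      engine: GeneScanEngine | None = None,
                      expr_override: list[np.ndarray] | None = None
                      ) -> PermutationNull:
    """Permutation null for one gene: expression sample labels are shuffled
    within each cohort (genotype/covariate structure preserved, one
    permutation shared by all of the gene's variants), the scan is repeated,
    and the minimum p is recorded per permutation."""
    if n_perm < 10:
        raise ValueError("n_perm < 10 cannot support a beta fit")
    if n_perm < 50:
        logger.warning("n_perm=%d gives an unstable beta fit", n_perm)
    if engine is None:
        g2 = gd
        if expr_override is not None:
            g2 = GeneData(gene=gd.gene, variants=gd.variants,
                          distances=gd.distances,
                          cohort_dosages=gd.cohort_dosages,
                          cohort_expr=expr_override)
        engine = GeneScanEngine(g2)
    rng = np.random.default_rng(seed)
    mins = np.empty(n_perm)
    sizes = [D.shape[0] for D in gd.cohort_dosages]
    for k in range(n_perm):
        perm = [rng.permutation(n) for n in sizes]
        mins[k], _ = engine.min_p(perm)
    a, b, ll, ks = fit_beta(mins, len(gd.variants))
    return PermutationNull(gene=gd.gene, min_p=mins, a=a, b=b,
                           loglik=ll, ks_distance=ks)


def beta_adjust_p(p_nominal: float | np.ndarray,
                  null: PermutationNull) -> float | np.ndarray:
    """Gene-level adjusted p: regularized incomplete beta CDF of the nominal
    top p under the fitted permutation-minimum distribution."""
    return sps.beta.cdf(p_nominal, null.a, null.b)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_pi0(ps: np.ndarray,
               lambdas: np.ndarray | None = None) -> float:
    """Storey's pi0 on a lambda grid with cubic-smoother extrapolation to the
    largest lambda; clipped to (0, 1]. Fewer than 20 p-values falls back to
    pi0 = 1 (BH-equivalent)."""
    ps = np.asarray(ps, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.951, 0.05)
    m = ps.size
    if m < 20:
        logger.info("only %d p-values: pi0 fixed at 1", m)
        return 1.0
    pi0_l = np.array([(ps > lam).mean() / (1.0 - lam) for lam in lambdas])
    try:
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    except Exception:
        pi0 = float(pi0_l[-1])
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(ps: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_(i) = min_{j >= i} pi0 * m * p_(j) / j."""
    ps = np.asarray(ps, dtype=float)
    if pi0 is None:
        pi0 = storey_pi0(ps)
    m = ps.size
    order = np.argsort(ps, kind="mergesort")
    ranked = pi0 * m * ps[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# gene-level cis pipeline
# ---------------------------------------------------------------------------

def cis_gene_level(cohorts: Sequence[CohortDataset], pairs: pd.DataFrame,
                   n_perm: int = 100, seed: int = 0, alpha: float = 0.05,
                   gene_data: list[GeneData] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, PermutationNull]]:
    """Top association per gene with permutation/beta-adjusted p and Storey
    q-values; ``significant`` flags q < alpha."""
    if gene_data is None:
        gene_data = build_gene_data(cohorts, pairs)
    rows = []
    nulls: dict[str, PermutationNull] = {}
    for gd in gene_data:
        engine = GeneScanEngine(gd)
        p_min, j = engine.min_p()
        if j < 0:
            continue
        null = permute_gene_null(gd, n_perm=n_perm,
                                 seed=gene_seed(seed, gd.gene), engine=engine)
        nulls[gd.gene] = null
        rows.append({"gene": gd.gene, "top_variant": gd.variants[j],
                     "p": p_min, "adj_p": float(beta_adjust_p(p_min, null)),
                     "beta_a": null.a, "beta_b": null.b})
    out = pd.DataFrame(rows)
    if len(out):
        out["qval"] = qvalues(out["adj_p"].to_numpy())
        out["significant"] = out["qval"] < alpha
    return out, nulls


# ---------------------------------------------------------------------------
# empirical permutation FDR (trans)
# ---------------------------------------------------------------------------

def empirical_fdr(real_ps: np.ndarray, perm_ps: Sequence[np.ndarray],
                  thresholds: np.ndarray | None = None) -> np.ndarray:
    """Permutation FDR per record.

    FDR(t) = (mean permuted count at p <= t) / (real count at p <= t),
    evaluated on the grid of observed real p-values, made monotone
    non-decreasing in t by taking, for each record, the minimum estimate over
    all thresholds at or above its p-value. All-empty real discoveries give
    FDR = 1 everywhere.
    """
    real_ps = np.asarray(real_ps, dtype=float)
    if real_ps.size == 0:
        return real_ps.copy()
    if thresholds is None:
        thresholds = np.unique(real_ps)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    real_sorted = np.sort(real_ps)
    n_real = np.searchsorted(real_sorted, thresholds, side="right")
    n_perm = np.zeros_like(thresholds, dtype=float)
    for pp in perm_ps:
        pp = np.sort(np.asarray(pp, dtype=float))
        n_perm += np.searchsorted(pp, thresholds, side="right")
    n_perm /= max(len(perm_ps), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_t = np.where(n_real > 0, n_perm / n_real, 1.0)
    fdr_t = np.minimum(fdr_t, 1.0)
    # q-value style: min over thresholds >= t
    fdr_mono = np.minimum.accumulate(fdr_t[::-1])[::-1]
    idx = np.searchsorted(thresholds, real_ps, side="left")
    return fdr_mono[np.minimum(idx, len(thresholds) - 1)]


def trans_fdr(cohorts: Sequence[CohortDataset], pairs: pd.DataFrame,
              n_perm: int = 10, seed: int = 0) -> pd.DataFrame:
    """Trans scan with permutation FDR: the real scan plus ``n_perm``
    genome-wide permutations of the expression sample labels within cohorts
    over the identical pair set."""
    gene_data = build_gene_data(cohorts, pairs)
    engines = [GeneScanEngine(gd) for gd in gene_data]

    def full_scan(perms_by_cohort=None) -> pd.DataFrame:
        frames = []
        for gd, eng in zip(gene_data, engines):
            mz, mp = eng.scan(perms_by_cohort)
            frames.append(pd.DataFrame({"gene": gd.gene,
                                        "variant": gd.variants,
                                        "meta_z": mz, "p": mp}))
        df = pd.concat(frames, ignore_index=True)
        return df[np.isfinite(df["p"])]

    real = full_scan().reset_index(drop=True)
    rng = np.random.default_rng(seed % (2 ** 31))
    perm_ps = []
    sizes = [c.genotypes.n_samples for c in cohorts]
    for _ in range(n_perm):
        perms = [rng.permutation(n) for n in sizes]
        perm_ps.append(full_scan(perms)["p"].to_numpy())
    real["fdr"] = empirical_fdr(real["p"].to_numpy(), perm_ps)
    real["significant"] = real["fdr"] < 0.05
    return real
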