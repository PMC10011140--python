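"""Iterative conditional cis-eQTL discovery.

Round 1 is the standard per-gene scan with permutation/beta multiple-testing
correction. Each further round regresses the dosages of all previously
discovered lead variants out of the gene's expression per cohort (ordinary
least squares, missing dosages mean-imputed within cohort), re-scans an
LD-pruned candidate set on the residuals, re-runs the permutation null on the
residualized expression, and stops per gene once the round's q-value is no
longer significant or the maximum rank is reached. Conditioning on the lead
dosage rather than on meta-level summaries keeps the procedure valid under
per-cohort covariate structure.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .meta import GeneData, build_gene_data
from .mtc import (GeneScanEngine, beta_adjust_p, gene_seed, permute_gene_null,
                  qvalues)
from .synth import CohortDataset

logger = logging.getLogger(__name__)


def _impute(col: np.ndarray) -> np.ndarray:
    col = np.asarray(col, dtype=float).copy()
    bad = np.isnan(col)
    if bad.any():
        col[bad] = np.nanmean(col) if not bad.all() else 0.0
    return col


def regress_out_eqtl(expr: np.ndarray,
                     prior_dosages: Sequence[np.ndarray]) -> np.ndarray:
    """OLS residuals of one cohort's expression on all prior lead dosages
    jointly (plus intercept). Collinear leads (r^2 > 0.95 with an earlier
    lead within the cohort) are dropped with a log entry."""
    y = np.asarray(expr, dtype=float)
    cols: list[np.ndarray] = []
    for k, d in enumerate(prior_dosages):
        d = _impute(d)
        drop = False
        for prev in cols:
            sd = d.std()
            sp = prev.std()
            if sd == 0 or (sp > 0 and np.corrcoef(d, prev)[0, 1] ** 2 > 0.95):
                drop = True
                break
        if drop or d.std() == 0:
            logger.info("conditional: dropping collinear prior lead %d", k)
            continue
        cols.append(d)
    if not cols:
        return y.copy()
    X = np.column_stack([np.ones_like(y)] + cols)
    ok = ~np.isnan(y)
    coef, *_ = np.linalg.lstsq(X[ok], y[ok], rcond=None)
    resid = y.copy()
    resid[ok] = y[ok] - X[ok] @ coef
    return resid


def ld_prune(variant_ids: Sequence[str], dosages: np.ndarray,
             positions: np.ndarray, r2_max: float = 0.2,
             window: int = 1_000_000) -> list[str]:
    """Greedy position-order pruning: scan variants by position and drop any
    with r^2 > r2_max to an already retained variant within the window.
    ``dosages`` is pooled samples x variants (NaN allowed)."""
    order = np.argsort(positions, kind="mergesort")
    kept: list[int] = []
    for j in order:
        ok = True
        for k in kept:
            if abs(positions[j] - positions[k]) > window:
                continue
            a, b = dosages[:, j], dosages[:, k]
            m = ~(np.isnan(a) | np.isnan(b))
            if m.sum() < 3:
                continue
            aa, bb = a[m], b[m]
            if aa.std() == 0 or bb.std() == 0:
                continue
            if np.corrcoef(aa, bb)[0, 1] ** 2 > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    kept_set = sorted(kept)
    return [variant_ids[j] for j in kept_set]


def _prune_against_leads(gd: GeneData, leads: Sequence[str],
                         lead_dosages: np.ndarray, r2_max: float) -> GeneData:
    """Drop candidate variants in LD (r^2 > r2_max, pooled dosages) with any
    prior lead. Residual association at such variants after conditioning is
    dominated by cross-cohort missingness artifacts rather than independent
    signal, so they are removed from the rescan."""
    pooled = np.vstack(gd.cohort_dosages)
    keep_idx = []
    for j, v in enumerate(gd.variants):
        ok = True
        for k in range(lead_dosages.shape[1]):
            a, b = pooled[:, j], lead_dosages[:, k]
            m = ~(np.isnan(a) | np.isnan(b))
            if m.sum() < 3 or a[m].std() == 0 or b[m].std() == 0:
                continue
            if np.corrcoef(a[m], b[m])[0, 1] ** 2 > r2_max:
                ok = False
                break
        if ok:
            keep_idx.append(j)
    return GeneData(
        gene=gd.gene, variants=[gd.variants[i] for i in keep_idx],
        distances=[gd.distances[i] for i in keep_idx],
        cohort_dosages=[D[:, keep_idx] for D in gd.cohort_dosages],
        cohort_expr=gd.cohort_expr)


def run_conditional(cohorts: Sequence[CohortDataset], pairs: pd.DataFrame,
                    max_rank: int = 5, n_perm: int = 100, seed: int = 0,
                    alpha: float = 0.05, r2_prune: float = 0.2,
                    prune_window: int = 1_000_000) -> pd.DataFrame:
    """Primary and non-primary cis-eQTLs per gene.

    Returns one record per (gene, rank) with the round's lead variant, meta
    z/p, reconstructed beta/se and within-round q-value. A rank-r record
    exists only when rank r-1 was significant for that gene. Before each
    rescan, candidates in LD (r^2 > r2_prune) with any prior lead are dropped
    (the pruning exists to dodge cross-cohort missingness artifacts in the
    conditioning; LD-independent secondary signals are untouched).
    """
    from .meta import variant_qc_table, zscore_to_beta_se

    gene_data = build_gene_data(cohorts, pairs)
    qc = variant_qc_table([c.genotypes for c in cohorts])
    state = {gd.gene: {"gd": gd, "leads": [], "resid": list(gd.cohort_expr),
                       "active": True} for gd in gene_data}
    records: list[dict] = []

    for rank in range(1, max_rank + 1):
        round_rows = []
        for gene, st in state.items():
            if not st["active"]:
                continue
            gd = st["gd"]
            if rank > 1:
                lead_dos = np.column_stack(
                    [np.concatenate([c.genotypes.dosage_of(v)
                                     for c in cohorts])
                     for v in st["leads"]])
                gd = _prune_against_leads(st["gd"], st["leads"], lead_dos,
                                          r2_prune)
                if not gd.variants:
                    st["active"] = False
                    continue
                new_resid = []
                for c, y in enumerate(st["gd"].cohort_expr):
                    priors = [cohorts[c].genotypes.dosage_of(v)
                              for v in st["leads"]]
                    new_resid.append(regress_out_eqtl(y, priors))
                st["resid"] = new_resid
            work = GeneData(gene=gd.gene, variants=gd.variants,
                            distances=gd.distances,
                            cohort_dosages=gd.cohort_dosages,
                            cohort_expr=st["resid"])
            engine = GeneScanEngine(work)
            p_min, j = engine.min_p()
            if j < 0:
                st["active"] = False
                continue
            null = permute_gene_null(
                work, n_perm=n_perm,
                seed=gene_seed(seed + rank, gene), engine=engine)
            mz, _ = engine.scan()
            round_rows.append({
                "gene": gene, "rank": rank, "variant": gd.variants[j],
                "meta_z": float(mz[j]), "p": p_min,
                "adj_p": float(beta_adjust_p(p_min, null)),
            })
        if not round_rows:
            break
        rdf = pd.DataFrame(round_rows)
        rdf["qval"] = qvalues(rdf["adj_p"].to_numpy())
        for _, row in rdf.iterrows():
            st = state[row.gene]
            if row.qval < alpha:
                maf = float(np.clip(qc.loc[row.variant, "maf"], 1e-6, 0.5))
                n_tot = sum(c.genotypes.n_samples for c in cohorts)
                beta, se = zscore_to_beta_se(row.meta_z, maf, n_tot)
                records.append({**row.to_dict(), "beta": beta, "se": se})
                st["leads"].append(row.variant)
            else:
                st["active"] = False
    cols = ["gene", "rank", "variant", "meta_z", "p", "adj_p", "qval",
            "beta", "se"]
    return pd.DataFrame(records, columns=cols)
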