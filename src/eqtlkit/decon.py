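"""Cell-type deconvolution and interaction eQTLs.

Proportion prediction solves, per bulk sample e over the marker genes of a
single-cell signature S, the non-negative least-squares problem
min ||S w - e||_2 s.t. w >= 0, and reports proportions w / sum(w). Subtype
columns can be summed into major types through a merge map (entries mapped to
None are discarded, e.g. developmental signatures, and rows renormalized).

The interaction model, for one eQTL (gene g, variant with dosage G) and
predicted proportions P (samples x cell types), is

    y = sum_c beta_c P_c + sum_c gamma_c P_c G_c* ,   beta, gamma >= 0,

where per cell type the genotype encoding G_c* is either G or 2 - G,
whichever fits better — the flip is how a negative interaction is expressed
under the non-negativity constraint. Because the proportions sum to one the
main-effect terms absorb the intercept. Each cell type's interaction is
tested by a one-sided F-test of the full model against the model lacking its
interaction term, on (1, n - 2 C) degrees of freedom.

Expression enters after covariate correction and a per-gene rank-based
inverse normal transform (Blom offsets); the transformed values are mapped
back to the gene's original mean and standard deviation so they stay positive
and the all-non-negative model remains well posed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls
from statsmodels.stats.multitest import multipletests

from .synth import SignatureMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression preparation
# ---------------------------------------------------------------------------

def inverse_normal_transform(x: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets,
    (rank - 3/8) / (n + 1/4); ties get average ranks."""
    x = np.asarray(x, dtype=float)
    r = sps.rankdata(x)
    return sps.norm.ppf((r - offset) / (x.size + 1.0 - 2.0 * offset))


def prepare_expression_for_decon(expr_tpm: pd.DataFrame,
                                 covariates: pd.DataFrame | None = None
                                 ) -> pd.DataFrame:
    """log2(TPM + 1), OLS removal of technical covariates per gene, residuals
    rescaled to each gene's original log2 mean/SD, negatives clamped to 0."""
    logx = np.log2(expr_tpm.to_numpy(float) + 1.0)
    if covariates is None or covariates.shape[1] == 0:
        out = logx
    else:
        C = covariates.loc[expr_tpm.columns].to_numpy(float)
        X = np.column_stack([np.ones(C.shape[0]), C])
        coef, *_ = np.linalg.lstsq(X, logx.T, rcond=None)
        resid = logx.T - X @ coef
        mu = logx.mean(axis=1)
        sd = logx.std(axis=1)
        rsd = resid.std(axis=0)
        rsd[rsd == 0] = 1.0
        out = (resid / rsd * sd + mu).T
    return pd.DataFrame(np.clip(out, 0.0, None), index=expr_tpm.index,
                        columns=expr_tpm.columns)


# ---------------------------------------------------------------------------
# proportion prediction
# ---------------------------------------------------------------------------

def _nnls_weights(expr: pd.DataFrame, signature: SignatureMatrix
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    shared = [g for g in signature.marker_genes if g in expr.index]
    if not shared:
        raise ValueError("no shared marker genes between expression and signature")
    S = signature.values.loc[shared].to_numpy(float)
    for c, ct in enumerate(signature.cell_types):
        if not np.any(S[:, c] > 0):
            raise ValueError(f"cell type {ct!r} has no informative shared marker")
    E = expr.loc[shared].to_numpy(float)
    W = np.empty((E.shape[1], S.shape[1]))
    for i in range(E.shape[1]):
        W[i], _ = nnls(S, E[:, i])
    w_df = pd.DataFrame(W, index=expr.columns, columns=signature.cell_types)
    e_df = pd.DataFrame(E, index=shared, columns=expr.columns)
    return w_df, e_df


def predict_proportions(expr: pd.DataFrame, signature: SignatureMatrix
                        ) -> pd.DataFrame:
    """NNLS cell-type proportions per sample (rows sum to 1).

    Samples whose NNLS weights are all zero get uniform proportions and are
    listed in ``df.attrs['degenerate_samples']``. Subtypes are summed into
    major types per the signature's merge map.
    """
    W, _ = _nnls_weights(expr, signature)
    totals = W.sum(axis=1)
    degenerate = list(W.index[totals == 0])
    if degenerate:
        logger.warning("%d samples with all-zero NNLS fit set to uniform",
                       len(degenerate))
        W.loc[degenerate] = 1.0
        totals = W.sum(axis=1)
    props = W.div(totals, axis=0)
    if signature.merge_map:
        merged: dict[str, np.ndarray] = {}
        for ct in props.columns:
            target = signature.merge_map.get(ct, ct)
            if target is None:
                continue  # discarded subtype (e.g. developmental)
            merged[target] = merged.get(target, 0.0) + props[ct].to_numpy()
        props = pd.DataFrame(merged, index=props.index)
        props = props.div(props.sum(axis=1), axis=0)
    props.attrs["degenerate_samples"] = degenerate
    return props


def reconstruction_accuracy(expr: pd.DataFrame,
                            signature: SignatureMatrix) -> float:
    """Mean over samples of 1 - ||S w - e|| / ||e|| on the shared marker
    genes (relative reconstruction accuracy of the NNLS fit)."""
    W, E = _nnls_weights(expr, signature)
    S = signature.values.loc[E.index].to_numpy(float)
    fit = S @ W.to_numpy().T
    e = E.to_numpy(float)
    norms = np.linalg.norm(e, axis=0)
    norms[norms == 0] = 1.0
    rel = 1.0 - np.linalg.norm(fit - e, axis=0) / norms
    return float(rel.mean())


def exclude_proportion_outliers(props: pd.DataFrame,
                                z_max: float = 4.0) -> pd.Index:
    """Samples surviving the per-cell-type z-score filter (any z > z_max
    drops the sample; a constant column contributes z = 0)."""
    sd = props.std(axis=0, ddof=1).to_numpy()
    mu = props.mean(axis=0).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.abs((props.to_numpy() - mu) / np.where(sd == 0, np.inf, sd))
    keep = ~(z > z_max).any(axis=1)
    return props.index[keep]


# ---------------------------------------------------------------------------
# interaction eQTL model
# ---------------------------------------------------------------------------

@dataclass
class IeqtlFit:
    gene: str
    variant: str
    cell_type: str
    beta_inter: float
    p: float
    f_stat: float
    encoding: str                  # "g" or "2-g"
    group_correlations: tuple[float, float, float]


def _nnls_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, rnorm = nnls(X, y)
    return coef, float(rnorm ** 2)


def ieqtl_fit(expr_gene: np.ndarray, dosage: np.ndarray,
              props: pd.DataFrame, gene: str = "", variant: str = "",
              apply_int: bool = True) -> list[IeqtlFit]:
    """Cell-type interaction tests for one eQTL.

    Fits the all-non-negative interaction model, choosing per cell type the
    genotype encoding (g or 2-g) that minimizes the full-model RSS (ties keep
    g), then F-tests each cell type's interaction term one-sidedly against
    the model lacking it. The reported interaction beta is signed relative to
    the supplied dosage allele: a 2-g encoding flips the sign. Constant
    proportion columns are skipped.
    """
    y = np.asarray(expr_gene, dtype=float)
    g = np.asarray(dosage, dtype=float)
    P = props.to_numpy(float)
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g, P = y[ok], g[ok], P[ok]
    n = y.size
    if apply_int:
        sd = y.std()
        mu = y.mean()
        y = inverse_normal_transform(y) * (sd if sd > 0 else 1.0) + mu
    # canonical genotype orientation: makes the fit exactly invariant to
    # ref/alt relabeling (the encoding search absorbs the flip)
    flipped = False
    if g.std() > 0 and y.std() > 0 and np.corrcoef(g, y)[0, 1] < 0:
        g = 2.0 - g
        flipped = True
    cell_types = list(props.columns)
    C = len(cell_types)
    usable = [c for c in range(C) if P[:, c].std() > 0]
    for c in range(C):
        if c not in usable:
            logger.info("ieQTL: constant proportions for %s, skipped",
                        cell_types[c])

    k_full = 2 * C
    if n <= k_full + 1:
        raise ValueError("too few samples for the interaction model")

    def design(encodings: list[str]) -> np.ndarray:
        cols = [P[:, c] for c in range(C)]
        for c in range(C):
            gc = g if encodings[c] == "g" else 2.0 - g
            cols.append(P[:, c] * gc)
        return np.column_stack(cols)

    # greedy per-cell-type encoding search (ties keep g)
    encodings = ["g"] * C
    _, rss = _nnls_rss(design(encodings), y)
    for c in usable:
        trial = list(encodings)
        trial[c] = "2-g"
        _, rss_t = _nnls_rss(design(trial), y)
        if rss_t < rss:
            encodings, rss = trial, rss_t

    results = []
    df2 = n - k_full
    for c in usable:
        # re-choose the tested cell type's encoding with the others fixed, so
        # its interaction can express either sign (ties keep g)
        enc_c = "g"
        best_coef, best_rss = None, np.inf
        for trial_enc in ("g", "2-g"):
            trial = list(encodings)
            trial[c] = trial_enc
            coef_t, rss_t = _nnls_rss(design(trial), y)
            if rss_t < best_rss - 1e-12 or best_coef is None:
                best_coef, best_rss, enc_c = coef_t, rss_t, trial_enc
        trial = list(encodings)
        trial[c] = enc_c
        X_full = design(trial)
        keep = [j for j in range(2 * C) if j != C + c]
        _, rss_red = _nnls_rss(X_full[:, keep], y)
        f = max(rss_red - best_rss, 0.0) / (best_rss / df2)
        p = float(sps.f.sf(f, 1, df2))
        gamma = best_coef[C + c]
        # report relative to the dosage allele supplied by the caller
        enc_out = enc_c if not flipped else ("2-g" if enc_c == "g" else "g")
        beta_inter = float(gamma if enc_out == "g" else -gamma)
        results.append(IeqtlFit(
            gene=gene, variant=variant, cell_type=cell_types[c],
            beta_inter=beta_inter, p=p, f_stat=float(f), encoding=enc_out,
            group_correlations=_group_correlations(y, g, P[:, c])))
    return results


def _group_correlations(y: np.ndarray, g: np.ndarray,
                        prop: np.ndarray) -> tuple[float, float, float]:
    """Pearson r between expression and the cell-type proportion within each
    rounded genotype group (NaN where a group is too small)."""
    out = []
    gg = np.round(g)
    for k in (0, 1, 2):
        m = gg == k
        if m.sum() < 3 or y[m].std() == 0 or prop[m].std() == 0:
            out.append(float("nan"))
        else:
            out.append(float(np.corrcoef(y[m], prop[m])[0, 1]))
    return tuple(out)


def run_ieqtl(expr: pd.DataFrame, dosages: pd.DataFrame,
              eqtls: Sequence[tuple[str, str]], props: pd.DataFrame,
              maf_min: float = 0.05, max_missing: float = 0.95,
              apply_int: bool = True) -> pd.DataFrame:
    """Interaction tests over a list of (gene, variant) eQTLs.

    ``dosages`` is variants x samples aligned to ``expr`` columns and
    ``props`` rows. Variants failing MAF > maf_min or the missingness cap are
    skipped.
    """
    rows = []
    for gene, variant in eqtls:
        if gene not in expr.index or variant not in dosages.index:
            continue
        d = dosages.loc[variant].to_numpy(float)
        miss = np.isnan(d).mean()
        af = np.nanmean(d) / 2.0
        maf = min(af, 1 - af)
        if maf <= maf_min or miss >= max_missing:
            continue
        fits = ieqtl_fit(expr.loc[gene].to_numpy(float), d, props,
                         gene=gene, variant=variant, apply_int=apply_int)
        for f in fits:
            rows.append({"gene": f.gene, "variant": f.variant,
                         "cell_type": f.cell_type, "beta_inter": f.beta_inter,
                         "p": f.p, "encoding": f.encoding})
    return pd.DataFrame(rows)


def ieqtl_fdr(results: pd.DataFrame, method: str = "bh",
              data: Sequence[tuple[np.ndarray, np.ndarray, pd.DataFrame]] | None = None,
              n_perm: int = 20, seed: int = 0, alpha: float = 0.05
              ) -> pd.DataFrame:
    """FDR over the pooled (eQTL x cell type) interaction p-values.

    method='bh' applies Benjamini-Hochberg. method='permutation' shuffles the
    genotype against the joint (expression, proportions) and uses the
    empirical-FDR estimator; it requires ``data`` as (expr, dosage, props)
    triples matching the rows' eQTLs.
    """
    out = results.copy()
    if method == "bh":
        _, fdr, _, _ = multipletests(out["p"].to_numpy(), method="fdr_bh")
        out["fdr"] = fdr
    elif method == "permutation":
        if data is None:
            raise ValueError("permutation FDR needs the underlying data")
        from .mtc import empirical_fdr
        rng = np.random.default_rng(seed)
        perm_ps = []
        for _ in range(n_perm):
            ps = []
            for y, d, P in data:
                perm = rng.permutation(len(d))
                for f in ieqtl_fit(y, d[perm], P):
                    ps.append(f.p)
            perm_ps.append(np.asarray(ps))
        out["fdr"] = empirical_fdr(out["p"].to_numpy(), perm_ps)
    else:
        raise ValueError("method must be 'bh' or 'permutation'")
    out["significant"] = out["fdr"] < alpha
    return out
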