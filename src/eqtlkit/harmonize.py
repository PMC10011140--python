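"""Expression harmonization ahead of eQTL mapping.

Covers per-sample QC filtering on alignment metrics, TMM library-size
normalization, removal of the technical covariates most correlated with the
expression principal components, PCA over the sample correlation matrix
(with 4-SD iterative outlier flagging), k-NN brain-region classification on
the first two PCs, and regression of leading expression PCs out of every
gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

SCALES = ("counts", "tpm", "tmm", "log2", "residual")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with a scale tag and provenance notes."""

    values: pd.DataFrame
    scale: str = "counts"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

DEFAULT_QC_THRESHOLDS = {"pct_coding_bases": 0.10,
                         "pct_reads_aligned": 0.60,
                         "pct_unique_mapping": 0.60}


def qc_filter_samples(metrics: pd.DataFrame,
                      thresholds: dict[str, float] | None = None) -> pd.Index:
    """Samples passing every metric threshold.

    Exclusion is strictly-less-than the threshold (a sample exactly at 10%
    coding bases is retained). Raises on a missing metric column.
    """
    thresholds = dict(DEFAULT_QC_THRESHOLDS if thresholds is None else thresholds)
    for col in thresholds:
        if col not in metrics.columns:
            raise ValueError(f"QC metric column missing: {col!r}")
    keep = pd.Series(True, index=metrics.index)
    for col, t in thresholds.items():
        keep &= metrics[col] >= t
    return metrics.index[keep]


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_factor(obs: np.ndarray, ref: np.ndarray, trim_m: float,
                trim_a: float) -> float:
    n_obs, n_ref = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return 1.0
    o, r = obs[ok] / n_obs, ref[ok] / n_ref
    m = np.log2(o / r)
    a = 0.5 * np.log2(o * r)
    if np.abs(m).max() < 1e-10:
        return 1.0
    lo_m, hi_m = np.quantile(m, [trim_m, 1 - trim_m])
    lo_a, hi_a = np.quantile(a, [trim_a, 1 - trim_a])
    keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
    if not keep.any():
        return 1.0
    # asymptotic binomial variance weights, as in the TMM definition
    w = ((n_obs - obs[ok]) / (n_obs * obs[ok])
         + (n_ref - ref[ok]) / (n_ref * ref[ok]))
    w = 1.0 / w
    return float(2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))


def tmm_normalize(expr: ExpressionMatrix, trim_m: float = 0.3,
                  trim_a: float = 0.05,
                  ref_sample: str | None = None) -> ExpressionMatrix:
    """Trimmed-mean-of-M-values normalization.

    Per-sample scaling factors come from the doubly trimmed (M by trim_m, A
    by trim_a), precision-weighted mean of log-ratios against a reference
    sample (the highest-depth column by default); factors are rescaled to
    geometric mean 1 and counts divided by factor x library size (reported
    per million).
    """
    if expr.scale != "counts":
        raise ValueError("TMM expects raw counts")
    X = expr.values.to_numpy(float)
    if (X < 0).any():
        raise ValueError("negative counts")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = list(expr.samples[lib == 0])
        raise ValueError(f"all-zero samples: {bad}")
    if ref_sample is None:
        ref_idx = int(np.argmax(lib))
    else:
        ref_idx = int(expr.samples.get_loc(ref_sample))
    ref = X[:, ref_idx]
    factors = np.array([_tmm_factor(X[:, j], ref, trim_m, trim_a)
                        for j in range(X.shape[1])])
    factors /= np.exp(np.mean(np.log(factors)))
    norm = X / (lib * factors) * 1e6
    return ExpressionMatrix(
        values=pd.DataFrame(norm, index=expr.genes, columns=expr.samples),
        scale="tmm",
        provenance={**expr.provenance, "tmm_factors": factors.tolist(),
                    "tmm_ref": str(expr.samples[ref_idx])})


# ---------------------------------------------------------------------------
# covariate regression
# ---------------------------------------------------------------------------

def rank_covariates(expr: ExpressionMatrix, covs: pd.DataFrame,
                    n_pcs: int = 10) -> pd.Series:
    """Covariates ranked by max |Pearson r| against the leading expression
    PCs (descending)."""
    scores = pca_samples(expr, n_pcs=min(n_pcs, len(expr.samples) - 1))
    C = covs.loc[expr.samples]
    best = {}
    for name in C.columns:
        x = C[name].to_numpy(float)
        if np.std(x) == 0:
            best[name] = 0.0
            continue
        rs = [abs(np.corrcoef(x, scores[pc])[0, 1]) for pc in scores.columns]
        best[name] = float(np.nanmax(rs))
    return pd.Series(best).sort_values(ascending=False)


def regress_top_covariates(expr: ExpressionMatrix, covs: pd.DataFrame,
                           k: int = 20) -> ExpressionMatrix:
    """OLS-remove the k covariates most correlated with the expression PCs.

    Collinear covariate columns are dropped (rank-revealing QR on the design)
    with a warning; residuals keep each gene's mean.
    """
    ranked = rank_covariates(expr, covs)
    chosen = list(ranked.index[: min(k, len(ranked))])
    C = covs.loc[expr.samples, chosen].to_numpy(float)
    keep_cols = []
    for j in range(C.shape[1]):
        trial = C[:, keep_cols + [j]]
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(C)), trial])) \
                == len(keep_cols) + 2:
            keep_cols.append(j)
        else:
            logger.warning("dropping collinear covariate %r", chosen[j])
    X = np.column_stack([np.ones(C.shape[0])] + ([C[:, keep_cols]]
                                                 if keep_cols else []))
    Y = expr.values.to_numpy(float).T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef + Y.mean(axis=0)
    return ExpressionMatrix(
        values=pd.DataFrame(resid.T, index=expr.genes, columns=expr.samples),
        scale="residual",
        provenance={**expr.provenance,
                    "covariates_removed": [chosen[j] for j in keep_cols]})


# ---------------------------------------------------------------------------
# PCA on the sample correlation matrix
# ---------------------------------------------------------------------------

def pca_samples(expr: ExpressionMatrix, n_pcs: int = 10) -> pd.DataFrame:
    """Sample scores from the eigendecomposition of the sample x sample
    correlation matrix, ordered by decreasing eigenvalue, with a
    deterministic sign convention (the largest-magnitude loading of each PC
    is positive). Eigenvalues are stored in ``df.attrs['eigenvalues']``."""
    X = expr.values.to_numpy(float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = list(expr.samples[sd == 0])
        raise ValueError(f"constant sample vectors: {bad}")
    R = np.corrcoef(X, rowvar=False)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    n_pcs = min(n_pcs, len(vals))
    vecs = vecs[:, :n_pcs]
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = vecs * np.sqrt(np.maximum(vals[:n_pcs], 0.0))
    out = pd.DataFrame(scores, index=expr.samples,
                       columns=[f"PC{i + 1}" for i in range(n_pcs)])
    out.attrs["eigenvalues"] = vals
    return out


def flag_pca_outliers(scores: pd.DataFrame, n_pcs: int = 4,
                      sd_max: float = 4.0, n_iter: int = 2) -> pd.Index:
    """Iteratively flag samples more than sd_max SDs from the centroid on any
    of the first n_pcs PCs (two passes by default). Returns surviving ids."""
    keep = scores.index
    cols = scores.columns[: min(n_pcs, scores.shape[1])]
    for _ in range(n_iter):
        sub = scores.loc[keep, cols]
        z = (sub - sub.mean()) / sub.std(ddof=0).replace(0, np.inf)
        keep = keep[~(z.abs() > sd_max).any(axis=1).to_numpy()]
    return keep


def knn_classify_region(scores: pd.DataFrame, labeled_scores: pd.DataFrame,
                        labels: pd.Series, k: int = 7) -> pd.Series:
    """Majority vote among the k Euclidean-nearest labeled samples on the
    first two PCs; ties break by summed inverse distance, then
    lexicographically."""
    if len(labeled_scores) < k:
        raise ValueError("k exceeds the labeled set size")
    q = scores.iloc[:, :2].to_numpy(float)
    ref = labeled_scores.iloc[:, :2].to_numpy(float)
    lab = labels.loc[labeled_scores.index].to_numpy()
    D = cdist(q, ref)
    out = []
    for i in range(len(q)):
        nn = np.argsort(D[i], kind="mergesort")[:k]
        cand = {}
        for j in nn:
            c, w = cand.get(lab[j], (0, 0.0))
            cand[lab[j]] = (c + 1, w + 1.0 / max(D[i, j], 1e-12))
        best = sorted(cand.items(),
                      key=lambda kv: (-kv[1][0], -kv[1][1], kv[0]))[0][0]
        out.append(best)
    return pd.Series(out, index=scores.index, name="region")


# ---------------------------------------------------------------------------
# expression-PC correction
# ---------------------------------------------------------------------------

def expression_pcs(expr: ExpressionMatrix, n_pcs: int) -> pd.DataFrame:
    """Sample scores of the leading expression PCs (SVD of the gene-centered
    matrix, samples as observations)."""
    X = expr.values.to_numpy(float)
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x genes
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(n_pcs, S.size)
    scores = U[:, :n_pcs] * S[:n_pcs]
    for j in range(n_pcs):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=expr.samples,
                        columns=[f"PC{i + 1}" for i in range(n_pcs)])


def pc_correct_expression(expr: ExpressionMatrix,
                          n_pcs: int) -> ExpressionMatrix:
    """Regress the first n_pcs expression PCs out of every gene."""
    n = len(expr.samples)
    if n_pcs >= n:
        raise ValueError("n_pcs must be below the sample count")
    if n_pcs == 0:
        out = ExpressionMatrix(values=expr.values.copy(), scale=expr.scale,
                               provenance=dict(expr.provenance))
        out.provenance["n_pcs_removed"] = 0
        return out
    scores = expression_pcs(expr, n_pcs)
    X = np.column_stack([np.ones(n), scores.to_numpy(float)])
    Y = expr.values.to_numpy(float).T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef + Y.mean(axis=0)
    return ExpressionMatrix(
        values=pd.DataFrame(resid.T, index=expr.genes, columns=expr.samples),
        scale="residual",
        provenance={**expr.provenance, "n_pcs_removed": int(n_pcs)})


def select_n_pcs(expr: ExpressionMatrix, evaluate, grid=(0, 25, 50, 100)):
    """Pick the PC-removal depth maximizing ``evaluate`` (a callable mapping
    a corrected ExpressionMatrix to a score, e.g. significant genes on a
    held-out chromosome)."""
    best_n, best_score = None, -np.inf
    for n_pcs in grid:
        if n_pcs >= len(expr.samples):
            continue
        score = evaluate(pc_correct_expression(expr, n_pcs))
        if score > best_score:
            best_n, best_score = n_pcs, score
    return best_n, best_score
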