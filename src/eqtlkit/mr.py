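"""Single-SNP Mendelian randomization and colocalization.

Instruments are cis-eQTL variants at genome-wide significance (p < 5e-8),
LD-clumped greedily by ascending p (10,000 kb window, r^2 < 0.001 by
default). Instruments absent from the outcome GWAS can be replaced by the
highest-LD proxy at r^2 >= 0.8. Effect alleles are harmonized assuming
forward-stranded GWAS records: matching alleles pass, swapped alleles flip
the GWAS beta, strand complements are resolved, palindromic (A/T, C/G)
variants are retained without any frequency-based re-orientation, and
irreconcilable pairs are dropped.

The causal effect per s.d. of expression is the Wald ratio
wr = beta_gwas / beta_eqtl with first-order delta-method SE
|se_gwas / beta_eqtl| (a second-order option adds the exposure-error term).

Colocalization uses Wakefield approximate Bayes factors per variant and
trait (prior effect SD 0.15 for quantitative traits, 0.2 for case-control)
and the standard five-hypothesis posterior (PP0: neither trait has a causal
variant in the region; PP1/PP2: only one does; PP3: both, distinct variants;
PP4: both, shared variant), computed in log space. It is run under both the
default priors (p1 = p2 = 1e-4, p12 = 1e-5) and region-size-based priors
(p1 = p2 = 1/Q for Q shared variants, p12 = p1/10); loci colocalize when
either run gives PP4 > 0.7.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import logsumexp

from .synth import GenotypeMatrix

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
GENOME_WIDE_P = 5e-8


# ---------------------------------------------------------------------------
# instruments
# ---------------------------------------------------------------------------

def select_instruments(cis_stats: pd.DataFrame,
                       p_threshold: float = GENOME_WIDE_P) -> pd.DataFrame:
    """Per-gene instruments: cis associations with p < p_threshold."""
    return cis_stats[cis_stats["p"] < p_threshold].copy()


def _panel_r2(panel: GenotypeMatrix, v1: str, v2: str) -> float:
    a = panel.dosage_of(v1)
    b = panel.dosage_of(v2)
    m = ~(np.isnan(a) | np.isnan(b))
    if m.sum() < 3 or a[m].std() == 0 or b[m].std() == 0:
        return 0.0
    return float(np.corrcoef(a[m], b[m])[0, 1] ** 2)


def ld_clump(instruments: pd.DataFrame, panel: GenotypeMatrix,
             window_kb: int = 10_000, r2_max: float = 0.001) -> pd.DataFrame:
    """Greedy clumping by ascending p: keep the best remaining variant, drop
    every other instrument within the window at r^2 > r2_max, repeat.
    Instruments absent from the reference panel are dropped with a warning.
    """
    inpanel = instruments["variant"].isin(panel.variants.index)
    if (~inpanel).any():
        logger.warning("%d instruments absent from LD panel dropped",
                       int((~inpanel).sum()))
    work = instruments[inpanel].sort_values("p", kind="mergesort")
    v = panel.variants
    kept_rows = []
    remaining = list(work.index)
    while remaining:
        idx = remaining.pop(0)
        row = work.loc[idx]
        kept_rows.append(idx)
        chrom = v.loc[row.variant, "chrom"]
        pos = int(v.loc[row.variant, "pos"])
        still = []
        for j in remaining:
            other = work.loc[j, "variant"]
            if (v.loc[other, "chrom"] == chrom
                    and abs(int(v.loc[other, "pos"]) - pos) <= window_kb * 1000
                    and _panel_r2(panel, row.variant, other) > r2_max):
                continue
            still.append(j)
        remaining = still
    return work.loc[kept_rows]


def proxy_lookup(snp: str, outcome: pd.DataFrame, panel: GenotypeMatrix,
                 r2_min: float = 0.8) -> tuple[str, float] | None:
    """Replacement SNP for an instrument missing from the outcome GWAS: the
    highest-r^2 panel variant present in the outcome at r^2 >= r2_min.
    Returns (proxy id, r^2), or (snp, 1.0) when present, or None."""
    present = set(outcome["snp"])
    if snp in present:
        return snp, 1.0
    best = None
    best_r2 = 0.0
    for other in panel.variants.index:
        if other == snp or other not in present:
            continue
        r2 = _panel_r2(panel, snp, other)
        if r2 > best_r2:
            best, best_r2 = other, r2
    if best is not None and best_r2 >= r2_min:
        return best, best_r2
    logger.info("no proxy at r2 >= %.2f for %s; instrument dropped",
                r2_min, snp)
    return None


# ---------------------------------------------------------------------------
# harmonization (forward-strand / "Action 2" semantics)
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize_effects(eqtl: dict, gwas: dict) -> dict | None:
    """Align a GWAS record to the eQTL's assessed allele.

    Returns the merged record with the GWAS beta on the eQTL's assessed
    allele, a ``palindromic`` flag (retained, never frequency-filtered) and
    the action taken; None when the allele pairs are irreconcilable.
    """
    ea, oa = eqtl["assessed_allele"], eqtl["other_allele"]
    gea, goa = gwas["ea"], gwas["oa"]
    beta = float(gwas["beta"])
    action = "same"
    if (gea, goa) == (ea, oa):
        pass
    elif (gea, goa) == (oa, ea):
        beta = -beta
        action = "swap"
    elif (_COMPLEMENT.get(gea), _COMPLEMENT.get(goa)) == (ea, oa):
        action = "complement"
    elif (_COMPLEMENT.get(gea), _COMPLEMENT.get(goa)) == (oa, ea):
        beta = -beta
        action = "complement+swap"
    else:
        logger.info("irreconcilable alleles for %s: (%s/%s) vs (%s/%s)",
                    eqtl.get("variant", "?"), ea, oa, gea, goa)
        return None
    return {"variant": eqtl.get("variant"), "assessed_allele": ea,
            "beta_eqtl": float(eqtl["beta"]), "se_eqtl": float(eqtl["se"]),
            "beta_gwas": beta, "se_gwas": float(gwas["se"]),
            "p_gwas": float(gwas.get("p", np.nan)),
            "palindromic": _is_palindromic(ea, oa), "action": action}


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------

def wald_ratio(beta_gwas: float, se_gwas: float, beta_eqtl: float,
               se_eqtl: float, second_order: bool = False
               ) -> tuple[float, float, float, bool]:
    """(wr, se, p, weak_instrument_flag).

    wr = beta_gwas / beta_eqtl; first-order delta SE = |se_gwas / beta_eqtl|;
    the second-order option adds the exposure uncertainty term
    wr^2 se_eqtl^2 / beta_eqtl^2. Instruments with |beta/se| < 2 on the
    exposure side are flagged weak.
    """
    if beta_eqtl == 0:
        raise ValueError("beta_eqtl must be non-zero")
    wr = beta_gwas / beta_eqtl
    var = (se_gwas / beta_eqtl) ** 2
    if second_order:
        var += wr ** 2 * se_eqtl ** 2 / beta_eqtl ** 2
    se = math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(wr) / se)) if se > 0 else float("nan")
    weak = abs(beta_eqtl / se_eqtl) < 2 if se_eqtl > 0 else False
    return float(wr), float(se), p, bool(weak)


@dataclass
class MrResult:
    gene: str
    instrument: str
    proxy: str | None
    proxy_r2: float
    wr: float
    se: float
    p: float
    weak: bool
    action: str


def run_mr(cis_stats: pd.DataFrame, gwas: pd.DataFrame,
           panel: GenotypeMatrix, p_instrument: float = GENOME_WIDE_P,
           window_kb: int = 10_000, r2_clump: float = 0.001,
           r2_proxy: float = 0.8, suggestive_p: float = 5e-5,
           bonferroni_p: float | None = None) -> pd.DataFrame:
    """Wald-ratio MR of every eligible gene against one outcome GWAS.

    ``cis_stats`` needs gene, variant, assessed_allele, other_allele, beta,
    se, p. Bonferroni threshold defaults to 0.05 / number of ratios tested.
    """
    inst = select_instruments(cis_stats, p_instrument)
    results: list[MrResult] = []
    gwas_by_snp = gwas.set_index("snp")
    for gene, sub in inst.groupby("gene"):
        clumped = ld_clump(sub, panel, window_kb=window_kb, r2_max=r2_clump)
        for _, row in clumped.iterrows():
            found = proxy_lookup(row.variant, gwas, panel, r2_min=r2_proxy)
            if found is None:
                continue
            snp, r2 = found
            erec = row.to_dict()
            if snp != row.variant:
                # re-express the eQTL effect on the proxy variant
                proxy_stats = cis_stats[(cis_stats.gene == gene)
                                        & (cis_stats.variant == snp)]
                if len(proxy_stats) == 0:
                    continue
                erec = proxy_stats.iloc[0].to_dict()
            grec = gwas_by_snp.loc[snp].to_dict()
            merged = harmonize_effects(erec, grec)
            if merged is None or merged["beta_eqtl"] == 0:
                continue
            wr, se, p, weak = wald_ratio(merged["beta_gwas"],
                                         merged["se_gwas"],
                                         merged["beta_eqtl"],
                                         merged["se_eqtl"])
            results.append(MrResult(gene=str(gene), instrument=row.variant,
                                    proxy=None if snp == row.variant else snp,
                                    proxy_r2=r2, wr=wr, se=se, p=p, weak=weak,
                                    action=merged["action"]))
    out = pd.DataFrame([r.__dict__ for r in results])
    if len(out):
        if bonferroni_p is None:
            bonferroni_p = 0.05 / len(out)
        out["pass_suggestive"] = out["p"] < suggestive_p
        out["pass_bonferroni"] = out["p"] < bonferroni_p
        out.attrs["bonferroni_p"] = bonferroni_p
    return out


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

@dataclass
class ColocResult:
    n_snps: int
    priors: tuple[float, float, float]
    pp: np.ndarray                       # PP0..PP4
    colocalized: bool
    flags: list[str]

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


def wakefield_labf(beta: np.ndarray, se: np.ndarray,
                   prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor per variant."""
    beta = np.asarray(beta, dtype=float)
    var = np.asarray(se, dtype=float) ** 2
    z2 = beta ** 2 / var
    r = prior_sd ** 2 / (prior_sd ** 2 + var)
    return 0.5 * (np.log1p(-r) + r * z2)


def _logdiffexp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)) for a >= b."""
    if b >= a:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_abf(eqtl: pd.DataFrame, gwas: pd.DataFrame,
              p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
              sd_eqtl: float = 0.15, sd_gwas: float = 0.2) -> ColocResult:
    """Five-hypothesis colocalization over the shared variants of a region.

    Both tables need (snp, beta, se). Posterior probabilities PP0..PP4 are
    computed in log space from per-variant Wakefield log-ABFs, so the result
    is overflow-safe for |z| well beyond 50.
    """
    shared = sorted(set(eqtl["snp"]) & set(gwas["snp"]))
    if len(shared) == 0:
        raise ValueError("no shared variants in region")
    flags = []
    if len(shared) < 10:
        flags.append(f"only {len(shared)} shared variants")
    e = eqtl.set_index("snp").loc[shared]
    g = gwas.set_index("snp").loc[shared]
    l1 = wakefield_labf(e["beta"].to_numpy(), e["se"].to_numpy(), sd_eqtl)
    l2 = wakefield_labf(g["beta"].to_numpy(), g["se"].to_numpy(), sd_gwas)

    s1 = float(logsumexp(l1))
    s2 = float(logsumexp(l2))
    s12 = float(logsumexp(l1 + l2))
    lh = np.array([
        0.0,
        math.log(p1) + s1,
        math.log(p2) + s2,
        math.log(p1) + math.log(p2) + _logdiffexp(s1 + s2, s12),
        math.log(p12) + s12,
    ])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()
    return ColocResult(n_snps=len(shared), priors=(p1, p2, p12), pp=pp,
                       colocalized=bool(pp[4] > 0.7), flags=flags)


def coloc_both_priors(eqtl: pd.DataFrame, gwas: pd.DataFrame,
                      pp4_threshold: float = 0.7,
                      sd_eqtl: float = 0.15, sd_gwas: float = 0.2
                      ) -> tuple[ColocResult, ColocResult, bool]:
    """Run colocalization under the default priors and under region-size
    priors (p1 = p2 = 1/Q, p12 = p1/10); the locus colocalizes when either
    run exceeds the PP4 threshold."""
    default = coloc_abf(eqtl, gwas, sd_eqtl=sd_eqtl, sd_gwas=sd_gwas)
    q = default.n_snps
    sized = coloc_abf(eqtl, gwas, p1=1.0 / q, p2=1.0 / q, p12=0.1 / q,
                      sd_eqtl=sd_eqtl, sd_gwas=sd_gwas)
    decision = (default.pp4 > pp4_threshold) or (sized.pp4 > pp4_threshold)
    return default, sized, decision
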