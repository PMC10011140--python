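"""Cross-dataset eQTL agreement metrics.

Four complementary replication statistics between a discovery and a
replication set of eQTL summary statistics:

* AC (allelic concordance): % of eQTLs significant in both datasets whose
  effect signs match; 50% expected for unrelated effects.
* pi1: Storey's 1 - pi0 over the replication p-values of
  discovery-significant eQTLs — the estimated fraction of true effects in
  the replication set, direction-blind.
* Rb: correlation of the underlying effect slopes corrected for estimation
  noise: var_true_k = var(beta_k) - mean(se_k^2) and
  cov_true = cov(beta_1, beta_2) - overlap_corr * mean(se_1 * se_2), with
  rb = cov_true / sqrt(var_true_1 var_true_2) and a leave-one-out jackknife
  SE. overlap_corr = 0 for non-overlapping cohorts.
* caFC: Pearson correlation of per-eQTL log2 allelic fold changes, which
  requires genotype-level data. The aFC estimator here is the
  homozygote-contrast approximation (mean log2 expression of alt homozygotes
  minus ref homozygotes, slope-based fallback when a homozygote class is
  thin); exact nonlinear aFC fitting is out of scope, and every report flags
  this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mtc import storey_pi0

logger = logging.getLogger(__name__)

AFC_CAP = float(np.log2(100.0))


# ---------------------------------------------------------------------------
# harmonized summary pairs
# ---------------------------------------------------------------------------

def harmonize_pair(a: pd.DataFrame, b: pd.DataFrame,
                   on: tuple[str, str] = ("gene", "variant")) -> pd.DataFrame:
    """Join two summary-stat tables on (gene, variant) and align the assessed
    allele: swapped ref/alt in the replication set flips beta2 (and any z);
    irreconcilable allele pairs are dropped and counted in
    ``df.attrs['n_allele_dropped']``."""
    cols = list(on) + ["assessed_allele", "other_allele", "beta", "se", "p"]
    sig_a = a["significant"] if "significant" in a else pd.Series(False, index=a.index)
    sig_b = b["significant"] if "significant" in b else pd.Series(False, index=b.index)
    aa = a[cols].assign(sig=sig_a.to_numpy())
    bb = b[cols].assign(sig=sig_b.to_numpy())
    m = aa.merge(bb, on=list(on), suffixes=("1", "2"))
    same = ((m["assessed_allele1"] == m["assessed_allele2"])
            & (m["other_allele1"] == m["other_allele2"]))
    swapped = ((m["assessed_allele1"] == m["other_allele2"])
               & (m["other_allele1"] == m["assessed_allele2"]))
    n_drop = int((~same & ~swapped).sum())
    if n_drop:
        logger.warning("%d records with irreconcilable alleles dropped", n_drop)
    m = m[same | swapped].copy()
    flip = swapped[same | swapped].to_numpy()
    m.loc[flip, "beta2"] = -m.loc[flip, "beta2"]
    out = m.rename(columns={"sig1": "sig1", "sig2": "sig2"})[
        list(on) + ["assessed_allele1", "beta1", "se1", "p1", "sig1",
                    "beta2", "se2", "p2", "sig2"]]
    out = out.rename(columns={"assessed_allele1": "assessed_allele"})
    out.attrs["n_allele_dropped"] = n_drop
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def allelic_concordance(pair: pd.DataFrame) -> float:
    """Percentage of both-significant records with matching effect sign.
    Records with a zero beta on either side are excluded (and counted via the
    return's accompanying log). Undefined (NaN) for an empty set."""
    both = pair[pair["sig1"] & pair["sig2"]]
    nz = both[(both["beta1"] != 0) & (both["beta2"] != 0)]
    n_zero = len(both) - len(nz)
    if n_zero:
        logger.info("AC: %d zero-beta records excluded", n_zero)
    if len(nz) == 0:
        logger.warning("AC undefined: no both-significant records")
        return float("nan")
    conc = np.sign(nz["beta1"]) == np.sign(nz["beta2"])
    return 100.0 * float(conc.mean())


def pi1(replication_ps: np.ndarray) -> float:
    """Storey pi1 = 1 - pi0 over replication p-values of
    discovery-significant eQTLs."""
    ps = np.asarray(replication_ps, dtype=float)
    if ps.size < 20:
        logger.warning("pi1 on %d p-values is unstable", ps.size)
    return float(max(0.0, 1.0 - storey_pi0(ps)))


def rb(pair: pd.DataFrame, overlap_corr: float = 0.0,
       use: str = "discovery-significant") -> tuple[float, float]:
    """Noise-corrected correlation of effect slopes with jackknife SE.

    ``use`` selects the eQTL set: 'discovery-significant' (sig1),
    'both-significant' (sig1 & sig2) or 'all'.
    """
    sel = {"discovery-significant": pair["sig1"],
           "both-significant": pair["sig1"] & pair["sig2"],
           "all": pd.Series(True, index=pair.index)}[use]
    d = pair[sel]
    b1 = d["beta1"].to_numpy(float)
    b2 = d["beta2"].to_numpy(float)
    s1 = d["se1"].to_numpy(float)
    s2 = d["se2"].to_numpy(float)

    def _rb(b1, b2, s1, s2) -> float:
        v1 = b1.var() - np.mean(s1 ** 2)
        v2 = b2.var() - np.mean(s2 ** 2)
        if v1 <= 0 or v2 <= 0:
            return float("nan")
        cov = np.cov(b1, b2, bias=True)[0, 1] - overlap_corr * np.mean(s1 * s2)
        return float(np.clip(cov / np.sqrt(v1 * v2), -1.0, 1.0))

    point = _rb(b1, b2, s1, s2)
    if not np.isfinite(point):
        logger.warning("rb undefined: estimation noise exceeds slope variance")
        return float("nan"), float("nan")
    n = b1.size
    if n < 3:
        return point, float("nan")
    loo = np.array([
        _rb(np.delete(b1, i), np.delete(b2, i),
            np.delete(s1, i), np.delete(s2, i)) for i in range(n)])
    loo = loo[np.isfinite(loo)]
    k = loo.size
    se = float(np.sqrt((k - 1) / k * ((loo - loo.mean()) ** 2).sum())) if k > 2 else float("nan")
    return point, se


def afc(expr_log2: np.ndarray, dosage: np.ndarray,
        min_hom: int = 3) -> float:
    """log2 allelic fold change by homozygote contrast.

    aFC = mean log2 expression of alt homozygotes minus ref homozygotes;
    when either homozygote class has fewer than ``min_hom`` samples the
    slope-based fallback 2 x (per-allele log2 slope) is used. Capped at
    |aFC| <= log2(100).
    """
    e = np.asarray(expr_log2, dtype=float)
    d = np.asarray(dosage, dtype=float)
    ok = ~(np.isnan(e) | np.isnan(d))
    e, d = e[ok], d[ok]
    g = np.round(d)
    ref, alt = e[g == 0], e[g == 2]
    if len(ref) >= min_hom and len(alt) >= min_hom:
        val = float(alt.mean() - ref.mean())
    else:
        logger.debug("aFC: thin homozygote class, slope fallback")
        if d.std() == 0:
            return 0.0
        slope = float(np.cov(d, e)[0, 1] / d.var())
        val = 2.0 * slope
    return float(np.clip(val, -AFC_CAP, AFC_CAP))


def cafc(afc1: np.ndarray, afc2: np.ndarray) -> float:
    """Pearson correlation of the two datasets' aFC estimates over shared,
    allele-harmonized eQTLs. Undefined below 3 shared records."""
    a = np.asarray(afc1, dtype=float)
    b = np.asarray(afc2, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        logger.warning("caFC undefined: fewer than 3 shared eQTLs")
        return float("nan")
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    n_overlap: int
    n_both_sig: int
    ac: float
    pi1: float
    rb: float
    rb_se: float
    cafc: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_overlap": self.n_overlap, "n_both_sig": self.n_both_sig,
                "AC": self.ac, "pi1": self.pi1, "rb": self.rb,
                "rb_se": self.rb_se, "caFC": self.cafc, "flags": self.flags}


def compare(pair: pd.DataFrame, overlap_corr: float = 0.0,
            rb_set: str = "discovery-significant",
            afc1: np.ndarray | None = None,
            afc2: np.ndarray | None = None) -> AgreementReport:
    """All agreement metrics for a harmonized summary pair."""
    flags = ["aFC estimator: homozygote-contrast approximation"]
    both = int((pair["sig1"] & pair["sig2"]).sum())
    ac = allelic_concordance(pair)
    disc = pair[pair["sig1"]]
    p1 = pi1(disc["p2"].to_numpy()) if len(disc) else float("nan")
    if len(disc) < 20:
        flags.append("pi1 unstable: <20 discovery-significant records")
    r, r_se = rb(pair, overlap_corr=overlap_corr, use=rb_set)
    c = cafc(afc1, afc2) if afc1 is not None and afc2 is not None else None
    return AgreementReport(n_overlap=len(pair), n_both_sig=both, ac=ac,
                           pi1=p1, rb=r, rb_se=r_se, cafc=c, flags=flags)
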