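"""Post-hoc PIC annotation and cross-dataset replication statistics.

Annotation: per-sample RNA-quality proxy (correlation of each sample's
expression profile with the cohort-average profile), PIC-covariate and
PIC-gene Pearson correlations with BH-FDR.

Replication between a discovery and a replication set of ieQTL summary
statistics: allelic concordance (AC), Storey's pi1, and the error-corrected
slope correlation Rb, plus reconstruction of beta/SE from p-value, MAF and
sample size when a replication set ships without them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interactions import bh_fdr

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def rna_quality(expression) -> pd.Series:
    """Per-sample correlation with the across-sample mean expression profile.

    A standard RNA-seq quality proxy: degraded samples correlate less with the
    cohort-average gene-expression vector. Samples with a constant profile get
    NaN.
    """
    df = expression.values if not isinstance(expression, pd.DataFrame) else expression
    if df.shape[0] < 3 or df.shape[1] < 3:
        raise ValueError("need at least 3 genes and 3 samples")
    X = df.to_numpy(dtype=float)
    mean_profile = X.mean(axis=1)
    Xc = X - X.mean(axis=0, keepdims=True)
    mc = mean_profile - mean_profile.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (mc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * mc[:, None]).sum(axis=0) / denom
    r[X.std(axis=0) == 0] = np.nan
    return pd.Series(r, index=df.columns, name="rna_quality")


def _pearson_with_p(x: np.ndarray, y: np.ndarray):
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3 or x[mask].std() == 0 or y[mask].std() == 0:
        return np.nan, np.nan, n
    r, p = stats.pearsonr(x[mask], y[mask])
    return float(r), float(p), n


def correlate_pics(pics: pd.DataFrame, annotations: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise PIC x annotation Pearson correlations with pooled BH-FDR."""
    annotations = annotations.loc[pics.index]
    rows = []
    for pic in pics.columns:
        for var in annotations.columns:
            r, p, n = _pearson_with_p(pics[pic].to_numpy(float),
                                      annotations[var].to_numpy(float))
            if np.isnan(p):
                logger.info("skipping constant/short pair (%s, %s)", pic, var)
                continue
            rows.append((pic, var, n, r, p))
    table = pd.DataFrame(rows, columns=["pic", "variable", "n", "r", "p"])
    table["fdr"] = bh_fdr(table["p"].to_numpy()) if len(table) else []
    table["significant"] = table["fdr"] < alpha
    return table


def top_correlated_genes(pic, expression, k: int = 200, alpha: float = 0.05):
    """Top-k positively and negatively PIC-correlated genes (BH-FDR < alpha).

    Ranking is by the Fisher z-score of the correlation among significant
    genes; lists may be shorter than k.
    """
    df = expression.values if not isinstance(expression, pd.DataFrame) else expression
    c = np.asarray(pic, dtype=float) if not isinstance(pic, pd.Series) \
        else pic.loc[df.columns].to_numpy(float)
    X = df.to_numpy(dtype=float)
    mask = np.isfinite(c)
    Xm, cm = X[:, mask], c[mask]
    n = mask.sum()
    Xc = Xm - Xm.mean(axis=1, keepdims=True)
    cc = cm - cm.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=1) * (cc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ cc) / denom
    t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    valid = np.isfinite(r)
    fdr = np.ones_like(p)
    fdr[valid] = bh_fdr(p[valid])
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)) * np.sqrt(n - 3)
    sig = valid & (fdr < alpha)
    genes = df.index.to_numpy()
    pos = genes[sig & (r > 0)][np.argsort(-z[sig & (r > 0)])][:k]
    neg = genes[sig & (r < 0)][np.argsort(z[sig & (r < 0)])][:k]
    return list(pos), list(neg)


# ---------------------------------------------------------------------------
# Replication
# ---------------------------------------------------------------------------

@dataclass
class ReplicationStats:
    n_overlap: int
    ac: float
    pi0: float
    pi1: float
    rb: float
    rb_se: float


def harmonize(disc: pd.DataFrame, repl: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two summary-stat tables on (gene, variant), flipping the
    replication beta sign where the assessed alleles differ."""
    joined = disc.merge(repl, on=["gene", "variant"], suffixes=("_disc", "_repl"))
    if "allele_assessed_disc" in joined.columns:
        flip = joined["allele_assessed_disc"] != joined["allele_assessed_repl"]
        joined.loc[flip, "beta_repl"] *= -1.0
    return joined


def allelic_concordance(disc: pd.DataFrame, repl: pd.DataFrame) -> float:
    """Fraction of jointly-significant effects sharing the beta sign.

    NaN when no pair is significant in both sets.
    """
    joined = harmonize(disc, repl)
    both = joined["significant_disc"].astype(bool) & joined["significant_repl"].astype(bool)
    if both.sum() == 0:
        logger.warning("no jointly-significant pairs; AC undefined")
        return np.nan
    sub = joined.loc[both]
    return float((np.sign(sub["beta_disc"]) == np.sign(sub["beta_repl"])).mean())


def pi1(repl_pvalues, lambdas=None) -> float:
    """1 - Storey's pi0, the estimated fraction of true alternatives.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic
    smoother evaluated at the largest lambda, clamped to [0, 1].
    """
    p = np.asarray(repl_pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if p.size < 20:
        warnings.warn("fewer than 20 p-values: pi1 estimate is unstable",
                      stacklevel=2)
    lam = np.arange(0.05, 0.96, 0.05) if lambdas is None else np.asarray(lambdas)
    pi0_lam = np.array([(p > l).mean() / (1 - l) for l in lam])
    if p.size < 20 or np.allclose(pi0_lam, pi0_lam[0]):
        pi0 = pi0_lam[-1]
    else:
        coeffs = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = np.polyval(coeffs, lam[-1])
    pi0 = float(np.clip(pi0, 0.0, 1.0))
    return 1.0 - pi0


def rb(disc: pd.DataFrame, repl: pd.DataFrame,
       overlap_correction: bool = False) -> tuple[float, float]:
    """Error-corrected correlation of effect slopes between two datasets.

    The sample covariance of the betas is divided by each side's slope
    standard deviation after deflating the observed beta variance by the mean
    squared standard error:

        rb = cov(b_d, b_r) / sqrt((var(b_d) - mean(se_d^2)) (var(b_r) - mean(se_r^2)))

    With ``overlap_correction=False`` the error covariance between the two
    sides is taken as 0 (disjoint cohorts). The standard error of rb comes
    from a delete-one jackknife. Returns (nan, nan) if a corrected variance is
    non-positive.
    """
    joined = harmonize(disc, repl)
    b1 = joined["beta_disc"].to_numpy(float)
    b2 = joined["beta_repl"].to_numpy(float)
    s1 = joined["se_disc"].to_numpy(float)
    s2 = joined["se_repl"].to_numpy(float)
    mask = np.isfinite(b1) & np.isfinite(b2) & np.isfinite(s1) & np.isfinite(s2)
    b1, b2, s1, s2 = b1[mask], b2[mask], s1[mask], s2[mask]
    n = b1.size
    if n < 3:
        raise ValueError("need at least 3 overlapping records")
    if overlap_correction:
        raise NotImplementedError(
            "overlapping-sample error covariance is not supported; cohorts are "
            "assumed disjoint")

    def _rb(idx):
        x, y, sx, sy = b1[idx], b2[idx], s1[idx], s2[idx]
        cov = np.cov(x, y, ddof=1)[0, 1]
        vx = x.var(ddof=1) - np.mean(sx ** 2)
        vy = y.var(ddof=1) - np.mean(sy ** 2)
        if vx <= 0 or vy <= 0:
            return np.nan
        return cov / np.sqrt(vx * vy)

    full = _rb(np.arange(n))
    if not np.isfinite(full):
        logger.warning("corrected slope variance <= 0; Rb undefined")
        return np.nan, np.nan
    jack = np.array([_rb(np.delete(np.arange(n), i)) for i in range(n)])
    jack = jack[np.isfinite(jack)]
    m = jack.size
    se = float(np.sqrt((m - 1) / m * ((jack - jack.mean()) ** 2).sum())) if m > 1 else np.nan
    return float(full), se


def beta_se_from_p(p: float, n: int, maf: float, sign_source: float
                   ) -> tuple[float, float]:
    """Reconstruct (beta, se) from a p-value, sample size and MAF.

    The usual summary-statistic reconstruction: z = |Phi^-1(p/2)|,
    se = 1 / sqrt(2 maf (1 - maf) (n + z^2)), beta = sign(sign_source) * z * se.
    """
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if n <= 4:
        raise ValueError("n must exceed 4")
    if p <= 0:
        warnings.warn("p-value of 0 clamped to 1e-300", stacklevel=2)
        p = 1e-300
    if p > 1:
        raise ValueError("p-value above 1")
    z = abs(stats.norm.ppf(p / 2.0))
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * (n + z ** 2))
    beta = float(np.sign(sign_source)) * z * se
    return float(beta), float(se)


def replication_stats(disc: pd.DataFrame, repl: pd.DataFrame) -> ReplicationStats:
    """AC, pi1 and Rb for a discovery/replication pair of summary-stat tables.

    pi1 is computed over the replication p-values of the discovery-significant
    records (discovery-conditioned), with the replication-side FDR recomputed
    on that subset.
    """
    joined = harmonize(disc, repl)
    disc_sig = joined["significant_disc"].astype(bool)
    sub = joined.loc[disc_sig].copy()
    if len(sub):
        sub["fdr_repl"] = bh_fdr(sub["p_repl"].to_numpy())
        repl2 = repl.copy().merge(
            sub[["gene", "variant", "fdr_repl"]], on=["gene", "variant"], how="inner")
        repl2["significant"] = repl2["fdr_repl"] < 0.05
        repl2 = repl2.drop(columns=["fdr_repl"])
    else:
        repl2 = repl.iloc[0:0]
    ac = allelic_concordance(disc.loc[disc["significant"].astype(bool)], repl2) \
        if len(repl2) else np.nan
    p1 = pi1(sub["p_repl"].to_numpy()) if len(sub) >= 3 else np.nan
    r, se = rb(disc.loc[disc["significant"].astype(bool)], repl) \
        if {"se"} <= set(disc.columns) & set(repl.columns) else (np.nan, np.nan)
    return ReplicationStats(
        n_overlap=len(joined), ac=ac, pi0=1 - p1 if np.isfinite(p1) else np.nan,
        pi1=p1, rb=r, rb_se=se,
    )
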