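"""Variant QC, expression standardization, covariate residualization and the
per-dataset rank-based inverse-normal ("force-normal") transform.

QC follows the conventional single-variant filters: per-dataset genotype call
rate, minor allele frequency and Hardy-Weinberg equilibrium computed on
hard-called (rounded) dosages, plus a minimum count per genotype group.
Regression always uses the continuous dosages; hard calls are for QC only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .io import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "eqtl_p": 0.05,
    "call_rate": 0.95,
    "min_group_size": 2,
    "maf_threshold": 0.05,
    "hwe_threshold": 1e-4,
    "min_dataset_size": 30,
    "pseudocount": 1.0,
    "min_mean_log_expression": 1.0,
}


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium p-value.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all tables at most as probable as the
    observed one (no mid-p correction). Symmetric in (n0, n2); a monomorphic
    variant has p = 1.
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    if rare == 0:
        return 1.0
    probs = _hwe_het_distribution(n, rare)
    p_obs = probs[n1]
    # tolerance guards against float round-off when summing "<= observed"
    p = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))
    return min(1.0, p)


@lru_cache(maxsize=None)
def _hwe_het_distribution(n: int, rare: int) -> dict:
    """P(het count | n diploid samples, `rare` copies of the minor allele).

    Recurrence of the standard SNP exact test: going from h to h-2
    heterozygotes multiplies the table probability by
    h*(h-1) / (4*(hom_r+1)*(hom_c+1)).
    """
    if (2 * n - rare) < rare:
        raise ValueError("rare allele count exceeds half the alleles")
    # heterozygote count shares the parity of the rare-allele count; start from
    # the largest admissible value and recurse downwards
    h = rare
    if h > n:
        h -= 2 * ((h - n + 1) // 2)
    weights = {}
    w = 1.0
    weights[h] = w
    hh = h
    while hh >= 2:
        hom_r = (rare - hh) // 2
        hom_c = n - hh - hom_r
        w = w * hh * (hh - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        hh -= 2
        weights[hh] = w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


# ---------------------------------------------------------------------------
# Per-variant QC
# ---------------------------------------------------------------------------

@dataclass
class VariantQC:
    variant_id: str
    maf: float
    hwe_p: float
    call_rate_per_dataset: dict
    genotype_group_counts: tuple
    passed: bool
    fail_reasons: list = field(default_factory=list)
    masked_datasets: list = field(default_factory=list)


def variant_qc(
    dosages: pd.Series,
    datasets: pd.Series,
    eqtl_pvalue: float | None = None,
    thresholds: dict | None = None,
) -> VariantQC:
    """QC one variant: per-dataset call rate, MAF, HWE, genotype-group counts.

    Datasets whose call rate falls below the threshold have *all* their samples
    masked for this variant before MAF/HWE/group counts are computed. Dosages
    are hard-called by rounding for the QC statistics only.
    """
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    d = dosages.astype(float)
    call_rates = {}
    masked = []
    mask = np.isfinite(d.to_numpy())
    for label, idx in datasets.groupby(datasets).groups.items():
        sub = np.isfinite(d.loc[idx].to_numpy())
        rate = float(sub.mean()) if len(sub) else 0.0
        call_rates[label] = rate
        if rate < thr["call_rate"]:
            masked.append(label)
    if masked:
        in_masked = datasets.isin(masked).to_numpy()
        mask = mask & ~in_masked

    hard = np.clip(np.rint(d.to_numpy()[mask]), 0, 2).astype(int)
    n0 = int((hard == 0).sum())
    n1 = int((hard == 1).sum())
    n2 = int((hard == 2).sum())
    n = n0 + n1 + n2
    reasons = []
    if n == 0:
        return VariantQC(str(dosages.name), np.nan, np.nan, call_rates,
                         (0, 0, 0), False, ["no_calls"], masked)
    ac = n1 + 2 * n2
    maf = min(ac, 2 * n - ac) / (2 * n)
    hwe_p = hwe_exact_test(n0, n1, n2)

    if eqtl_pvalue is not None and not (eqtl_pvalue < thr["eqtl_p"]):
        reasons.append("eqtl_p")
    if not (maf > thr["maf_threshold"]):
        reasons.append("maf")
    if not (hwe_p > thr["hwe_threshold"]):
        reasons.append("hwe")
    if min(n0, n1, n2) <= thr["min_group_size"]:
        reasons.append("group_size")
    return VariantQC(str(dosages.name), float(maf), float(hwe_p), call_rates,
                     (n0, n1, n2), not reasons, reasons, masked)


def qc_filter_eqtls(data, thresholds: dict | None = None):
    """Apply variant QC to every eQTL record; return (filtered data, QC table).

    Samples of datasets failing the call-rate check are masked (set missing)
    in the retained genotype matrix, so downstream fits skip them.
    """
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    records = []
    keep = []
    dosages = data.genotype.dosages.copy()
    has_p = "pvalue" in data.eqtls.columns
    if not has_p:
        logger.warning("no eQTL p-value column; skipping the eQTL-p filter")
    for i, row in data.eqtls.iterrows():
        dos = dosages.loc[row["variant"]]
        qc = variant_qc(dos, data.datasets,
                        eqtl_pvalue=row["pvalue"] if has_p else None,
                        thresholds=thr)
        records.append(qc)
        keep.append(qc.passed)
        if qc.passed and qc.masked_datasets:
            cols = data.datasets.index[data.datasets.isin(qc.masked_datasets)]
            dosages.loc[row["variant"], cols] = np.nan
    qc_table = pd.DataFrame(
        {
            "gene": data.eqtls["gene"].values,
            "variant": data.eqtls["variant"].values,
            "maf": [q.maf for q in records],
            "hwe_p": [q.hwe_p for q in records],
            "n0": [q.genotype_group_counts[0] for q in records],
            "n1": [q.genotype_group_counts[1] for q in records],
            "n2": [q.genotype_group_counts[2] for q in records],
            "pass": keep,
            "fail_reasons": [";".join(q.fail_reasons) for q in records],
        }
    )
    filtered = replace(data, eqtls=data.eqtls.loc[keep].reset_index(drop=True),
                       genotype=GenotypeMatrix(dosages))
    n_fail = int((~np.asarray(keep)).sum())
    if n_fail:
        logger.info("variant QC removed %d of %d eQTLs", n_fail, len(keep))
    return filtered, qc_table


# ---------------------------------------------------------------------------
# Expression standardization
# ---------------------------------------------------------------------------

def standardize_expression(
    raw: ExpressionMatrix,
    pseudocount: float = 1.0,
    already_log: bool = False,
    min_mean_log_expression: float | None = 1.0,
) -> ExpressionMatrix:
    """log2(x + pseudocount) -> centre per gene -> z-transform per sample.

    Zero-variance genes are dropped (they carry no information and break the
    z-transform); lowly expressed genes (mean log2 below
    ``min_mean_log_expression``) are dropped as their interactions cannot be
    corrected for reliably.
    """
    if raw.state != "raw":
        raise ValueError(f"expected raw expression, got state {raw.state!r}")
    vals = raw.values.to_numpy(dtype=float)
    if not already_log:
        if (vals < 0).any():
            raise ValueError("negative values in raw expression; set already_log=True?")
        vals = np.log2(vals + pseudocount)
    genes = raw.values.index
    if min_mean_log_expression is not None and not already_log:
        keep = vals.mean(axis=1) >= min_mean_log_expression
        if not keep.all():
            logger.warning("dropping %d lowly expressed gene(s)", int((~keep).sum()))
            vals, genes = vals[keep], genes[keep]
    var = vals.var(axis=1)
    keep = var > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance gene(s)", int((~keep).sum()))
        vals, genes = vals[keep], genes[keep]
    vals = vals - vals.mean(axis=1, keepdims=True)  # centre per gene
    vals = (vals - vals.mean(axis=0, keepdims=True)) / vals.std(axis=0, keepdims=True)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=genes, columns=raw.values.columns),
        state="standardized",
    )


# ---------------------------------------------------------------------------
# Design matrix and residualization
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrix:
    """Samples x columns covariate design with per-column interaction flags.

    Columns flagged ``interaction`` additionally contribute a column * genotype
    term at fit time (the genotype being each gene's own eQTL variant).
    Dataset indicator columns are always interaction-flagged.
    """

    values: pd.DataFrame
    interaction_flags: pd.Series

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)


def build_design(
    covariates: pd.DataFrame | None,
    datasets: pd.Series,
    interaction_covariates: list | None = None,
) -> DesignMatrix:
    """Assemble covariates + dataset indicators (reference coding) into a design.

    One indicator per dataset minus a reference, only when more than one
    dataset is present; indicators are always interaction-flagged, user
    covariates only when listed in ``interaction_covariates``.
    """
    parts = []
    flags = {}
    if covariates is not None and covariates.shape[1]:
        cov = covariates.astype(float)
        arr = cov.to_numpy()
        centred = arr - arr.mean(axis=0)
        norms = np.linalg.norm(centred, axis=0)
        nz = norms > 0
        if nz.sum() >= 2:
            sub = centred[:, nz] / norms[nz]
            corr = sub.T @ sub
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
            if abs(corr[i, j]) > 1 - 1e-12:
                names = cov.columns[nz]
                raise ValueError(
                    f"covariates {names[i]!r} and {names[j]!r} are perfectly collinear"
                )
        parts.append(cov)
        inter = set(interaction_covariates or [])
        unknown = inter - set(cov.columns)
        if unknown:
            raise ValueError(f"unknown interaction covariates: {sorted(unknown)}")
        for c in cov.columns:
            flags[c] = c in inter
    labels = pd.unique(datasets)
    if len(labels) > 1:
        dummies = pd.get_dummies(datasets, prefix="dataset", dtype=float)
        dummies = dummies.iloc[:, 1:]  # reference coding: drop the first level
        parts.append(dummies)
        for c in dummies.columns:
            flags[c] = True  # dataset indicators always carry an interaction term
    if parts:
        values = pd.concat(parts, axis=1)
        values.index = datasets.index
    else:
        values = pd.DataFrame(index=datasets.index)
    return DesignMatrix(values, pd.Series(flags, dtype=bool))


def residualize(
    expression: ExpressionMatrix,
    design: DesignMatrix,
    genotype: GenotypeMatrix | None = None,
    eqtls: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """OLS-residualize every gene on the design (plus flagged genotype interactions).

    For interaction-flagged columns, the per-gene design gains column * g terms
    where g is that gene's own eQTL dosage; samples with missing g are excluded
    from the fit and their residuals stay missing for that gene.
    """
    if expression.state == "raw":
        raise ValueError("standardize expression before residualizing")
    Y = expression.values.to_numpy(dtype=float)
    n_genes, n = Y.shape
    base = np.column_stack([np.ones(n), design.values.to_numpy(dtype=float)]) \
        if design.values.shape[1] else np.ones((n, 1))
    flagged = [k for k, c in enumerate(design.column_names)
               if design.interaction_flags.get(c, False)]
    gene_to_variant = {}
    if eqtls is not None and genotype is not None and flagged:
        for _, row in eqtls.iterrows():
            gene_to_variant.setdefault(row["gene"], row["variant"])

    out = np.full_like(Y, np.nan)
    min_rows = base.shape[1] + len(flagged) + 1
    for gi, gene in enumerate(expression.values.index):
        y = Y[gi]
        X = base
        mask = np.isfinite(y)
        variant = gene_to_variant.get(gene)
        if variant is not None:
            g = genotype.dosages.loc[variant].to_numpy(dtype=float)
            mask = mask & np.isfinite(g)
            inter_cols = base[:, [1 + k for k in flagged]] * g[:, None]
            X = np.column_stack([base, inter_cols])
        if mask.sum() < min_rows:
            raise ValueError(f"gene {gene!r}: fewer samples than design columns")
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        out[gi, mask] = y[mask] - X[mask] @ beta
    return ExpressionMatrix(
        pd.DataFrame(out, index=expression.values.index, columns=expression.values.columns),
        state="residualized",
    )


# ---------------------------------------------------------------------------
# Force-normal transform
# ---------------------------------------------------------------------------

def force_normal(values, datasets: pd.Series | None = None) -> np.ndarray:
    """Rank-based inverse-normal transform applied within each dataset.

    Average ranks for ties, mapped to standard-normal quantiles at
    (rank - 0.5) / n_dataset. Missing entries stay missing. Requires >= 2
    non-missing values per dataset.
    """
    arr = np.asarray(values, dtype=float)
    out = np.full_like(arr, np.nan)
    if datasets is None:
        codes = np.zeros(arr.shape[-1], dtype=int)
    else:
        codes = pd.Categorical(datasets).codes
    for d in np.unique(codes):
        cols = codes == d
        sub = arr[..., cols]
        n_valid = np.isfinite(sub).sum(axis=-1)
        if np.any(n_valid < 2):
            raise ValueError("force_normal needs >= 2 non-missing values per dataset")
        ranks = stats.rankdata(sub, method="average", axis=-1, nan_policy="omit")
        quant = (ranks - 0.5) / np.expand_dims(n_valid, -1)
        out[..., cols] = ndtri(quant)
    return out


def force_normal_matrix(values: np.ndarray, dataset_codes: np.ndarray) -> np.ndarray:
    """Row-wise force-normal of a 2-D array given integer dataset codes."""
    out = np.full_like(values, np.nan)
    for d in np.unique(dataset_codes):
        cols = dataset_codes == d
        sub = values[:, cols]
        n_valid = np.isfinite(sub).sum(axis=1, keepdims=True)
        ranks = stats.rankdata(sub, method="average", axis=1, nan_policy="omit")
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, cols] = ndtri((ranks - 0.5) / n_valid)
    return out
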