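"""Genotype x context interaction-eQTL mapping.

For every eQTL the interaction test compares two nested OLS models,

    y = b1 + bg*g + bc*c            (null)
    y = b1 + bg*g + bc*c + bgxc*g*c (alternative)

by an F-test on the residual sums of squares with (1, n - 4) degrees of
freedom. Before the test, genotype and context main effects are regressed out
of the expression and both the expression residuals and the context are
force-normalized per dataset, so that only the interaction term can explain
variance. Benjamini-Hochberg FDR is applied per context.

Everything is vectorized across eQTLs: designs are per-eQTL 3/4-column
matrices solved through batched normal equations with missingness handled by
0/1 weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .preprocess import force_normal_matrix

CONDITION_LIMIT = 1e12  # designs beyond this are declared degenerate, not crashed


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Batched OLS
# ---------------------------------------------------------------------------

def _batch_ols(Y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Weighted least squares per row.

    Y: (m, n) responses, X: (m, n, k) designs, w: (m, n) 0/1 weights.
    Returns betas (m, k), rss (m,), ok (m,) with ok=False for designs whose
    normal-equation matrix is singular/ill-conditioned.
    """
    Yw = np.where(w > 0, Y, 0.0)
    Xw = X * w[:, :, None]
    XtX = np.einsum("mnk,mnl->mkl", Xw, X, optimize=True)
    XtY = np.einsum("mnk,mn->mk", Xw, Yw, optimize=True)
    # eigenvalue-based condition check on the (symmetric) normal matrix
    eig = np.linalg.eigvalsh(XtX)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = eig[:, -1] / eig[:, 0]
    ok = np.isfinite(cond) & (eig[:, 0] > 0) & (cond < CONDITION_LIMIT)
    safe = XtX.copy()
    safe[~ok] = np.eye(X.shape[2])
    betas = np.linalg.solve(safe, XtY[:, :, None])[:, :, 0]
    betas[~ok] = np.nan
    resid = Yw - np.einsum("mnk,mk->mn", X, np.nan_to_num(betas), optimize=True)
    rss = np.einsum("mn,mn->m", resid * w, resid, optimize=True)
    rss[~ok] = np.nan
    return betas, rss, ok


@dataclass
class InteractionFit:
    """Nested-model interaction fit for a single eQTL."""

    gene_id: str
    variant_id: str
    n_effective: int
    beta1: float
    beta_g: float
    beta_c: float
    beta_gxc: float
    rss0: float
    rss1: float
    f_stat: float
    p: float
    fdr: float = np.nan
    degenerate: bool = False


@dataclass
class InteractionResults:
    """Vectorized per-context mapping result.

    Arrays are aligned with ``eqtls`` rows. ``y_norm``, ``genotype`` and
    ``context_norm`` are the exact (force-normalized) values that produced the
    betas; the EM maximization step reuses them.
    """

    eqtls: pd.DataFrame
    betas: np.ndarray       # (m, 4): b1, bg, bc, bgxc
    rss0: np.ndarray
    rss1: np.ndarray
    f_stat: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    n_effective: np.ndarray
    ok: np.ndarray
    y_norm: np.ndarray      # (m, n)
    genotype: np.ndarray    # (m, n)
    context_norm: np.ndarray  # (m, n)
    mask: np.ndarray        # (m, n) joint non-missing indicator
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)

    @property
    def significant(self) -> np.ndarray:
        return self.ok & (self.fdr < self.alpha)

    @property
    def n_significant(self) -> int:
        return int(self.significant.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene": self.eqtls["gene"].values,
            "variant": self.eqtls["variant"].values,
            "n": self.n_effective,
            "beta1": self.betas[:, 0],
            "beta_g": self.betas[:, 1],
            "beta_c": self.betas[:, 2],
            "beta_gxc": self.betas[:, 3],
            "rss0": self.rss0,
            "rss1": self.rss1,
            "f_stat": self.f_stat,
            "p": self.p,
            "fdr": self.fdr,
            "significant": self.significant,
        })


def _interaction_scan(
    Y: np.ndarray,
    G: np.ndarray,
    c: np.ndarray,
    dataset_codes: np.ndarray,
    remove_main_effects: bool = True,
    normalize: bool = True,
) -> dict:
    """Shared engine: per-eQTL nested-model F-test, batched over all eQTLs.

    Significance (when ``remove_main_effects``) is assessed on expression with
    the genotype and context main effects regressed out, so only the
    interaction term can explain variance. The betas handed to the EM
    maximization come from a fresh full-model fit on the force-normalized
    expression *with* its main effects: the per-sample likelihood of Eq-style
    y = b1 + bg*g + bc*c + bgxc*g*c is written on that scale, and the main
    effects carry most of the per-sample information about c.
    """
    m, n = Y.shape
    mask = np.isfinite(Y) & np.isfinite(G) & np.isfinite(c)[None, :]
    w = mask.astype(float)
    n_eff = mask.sum(axis=1)
    ones = np.ones((m, n))
    Cm = np.where(mask, c[None, :], np.nan)
    Gm = np.where(mask, G, 0.0)

    if remove_main_effects:
        X3 = np.stack([ones, Gm, np.nan_to_num(Cm)], axis=2)
        b3, _, ok3 = _batch_ols(np.nan_to_num(Y), X3, w)
        fitted = np.einsum("mnk,mk->mn", X3, np.nan_to_num(b3), optimize=True)
        Yr = np.where(mask, Y - fitted, np.nan)
    else:
        ok3 = np.ones(m, dtype=bool)
        Yr = np.where(mask, Y, np.nan)

    if normalize:
        Yn = force_normal_matrix(Yr, dataset_codes)
        if mask.all():  # no missingness: every row of Cm is the same vector
            Cn = np.broadcast_to(
                force_normal_matrix(Cm[:1], dataset_codes), Cm.shape)
        else:
            Cn = force_normal_matrix(Cm, dataset_codes)
    else:
        Yn, Cn = Yr, Cm
    Yn0 = np.nan_to_num(Yn)
    Cn0 = np.nan_to_num(Cn)

    X0 = np.stack([ones, Gm, Cn0], axis=2)
    X1 = np.stack([ones, Gm, Cn0, Gm * Cn0], axis=2)
    _, rss0, ok0 = _batch_ols(Yn0, X0, w)
    betas, rss1, ok1 = _batch_ols(Yn0, X1, w)
    ok = ok3 & ok0 & ok1 & (n_eff >= 5)

    if remove_main_effects and normalize:
        # optimization-path fit: same model, main effects retained
        Yn_opt = force_normal_matrix(np.where(mask, Y, np.nan), dataset_codes)
        betas_opt, _, ok_opt = _batch_ols(np.nan_to_num(Yn_opt), X1, w)
        ok = ok & ok_opt
    else:
        Yn_opt, betas_opt = Yn, betas

    df2 = n_eff - 4
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss0 - rss1) / (rss1 / df2)
    # exact fits (rss0 ~ rss1 ~ 0) carry no interaction evidence: F = 0, p = 1
    exact = (rss0 - rss1) <= 1e-12 * np.maximum(rss0, 1.0)
    f = np.where(exact, 0.0, f)
    f = np.where(ok, np.clip(f, 0, None), np.nan)
    p = np.ones(m)
    p[ok] = stats.f.sf(f[ok], 1, df2[ok])
    return {
        "betas": betas_opt, "rss0": rss0, "rss1": rss1, "f": f, "p": p,
        "n_eff": n_eff, "ok": ok, "y_norm": Yn_opt,
        "genotype": np.where(mask, G, np.nan), "context_norm": Cn, "mask": mask,
    }


def fit_interaction(y, g, c, datasets: pd.Series | None = None,
                    remove_main_effects: bool = False,
                    normalize: bool = False) -> InteractionFit:
    """Nested-model interaction test for one eQTL.

    By default fits the supplied vectors as-is (they are assumed already
    force-normalized); set ``remove_main_effects``/``normalize`` to run the
    full per-eQTL pipeline used by :func:`map_ieqtls`.
    """
    y = np.asarray(y, dtype=float)[None, :]
    g = np.asarray(g, dtype=float)[None, :]
    c = np.asarray(c, dtype=float)
    codes = (pd.Categorical(datasets).codes if datasets is not None
             else np.zeros(y.shape[1], dtype=int))
    r = _interaction_scan(y, g, c, codes, remove_main_effects, normalize)
    ok = bool(r["ok"][0])
    b = r["betas"][0] if ok else np.full(4, np.nan)
    return InteractionFit(
        gene_id="", variant_id="", n_effective=int(r["n_eff"][0]),
        beta1=b[0], beta_g=b[1], beta_c=b[2], beta_gxc=b[3],
        rss0=float(r["rss0"][0]), rss1=float(r["rss1"][0]),
        f_stat=float(r["f"][0]) if ok else np.nan,
        p=float(r["p"][0]), degenerate=not ok,
    )


class HaltOptimization(RuntimeError):
    """Raised when fewer than two significant ieQTLs are available."""


def _context_array(context, sample_ids=None) -> np.ndarray:
    if isinstance(context, pd.Series):
        return (context.loc[sample_ids] if sample_ids is not None else context).to_numpy(float)
    return np.asarray(context, dtype=float)


def map_ieqtls(
    data,
    context,
    alpha: float = 0.05,
    remove_main_effects: bool = True,
    require_min: bool = False,
) -> InteractionResults:
    """Map significant genotype x context ieQTLs for one context vector.

    Per eQTL: regress genotype and context main effects out of the (already
    covariate-residualized) expression, force-normalize the residuals and the
    context per dataset, refit the nested models and F-test the interaction;
    BH-FDR across all eQTLs of this context.
    """
    c = _context_array(context, data.sample_ids)
    if np.nanstd(c) == 0:
        raise ValueError("context vector is constant")
    genes = data.eqtls["gene"].values
    variants = data.eqtls["variant"].values
    Y = data.expression.values.reindex(genes).to_numpy(dtype=float)
    G = data.genotype.dosages.reindex(variants).to_numpy(dtype=float)
    codes = pd.Categorical(data.datasets).codes
    r = _interaction_scan(Y, G, c, codes, remove_main_effects=remove_main_effects)
    fdr = np.ones_like(r["p"])
    fdr[r["ok"]] = bh_fdr(r["p"][r["ok"]])
    res = InteractionResults(
        eqtls=data.eqtls, betas=r["betas"], rss0=r["rss0"], rss1=r["rss1"],
        f_stat=r["f"], p=r["p"], fdr=fdr, n_effective=r["n_eff"], ok=r["ok"],
        y_norm=r["y_norm"], genotype=r["genotype"], context_norm=r["context_norm"],
        mask=r["mask"], alpha=alpha,
    )
    if require_min and res.n_significant < 2:
        raise HaltOptimization(
            f"only {res.n_significant} significant ieQTL(s); need at least 2"
        )
    return res


def select_start(data, starts, alpha: float = 0.05):
    """Pick the starting vector with the most significant ieQTLs.

    ``starts`` is a samples x vectors DataFrame or a list of vectors. Ties are
    broken by the lowest index. Returns (index, InteractionResults); raises
    :class:`HaltOptimization` when no start yields >= 2 ieQTLs.
    """
    if isinstance(starts, pd.DataFrame):
        vectors = [starts[c] for c in starts.columns]
    else:
        vectors = list(starts)
    if not vectors:
        raise ValueError("need at least one starting vector")
    counts, results = [], []
    for v in vectors:
        try:
            res = map_ieqtls(data, v, alpha=alpha)
        except ValueError:
            res = None
        counts.append(res.n_significant if res is not None else -1)
        results.append(res)
    best = int(np.argmax(counts))  # argmax keeps the lowest index on ties
    if counts[best] < 2:
        raise HaltOptimization("no starting vector yields >= 2 significant ieQTLs")
    return best, results[best]


def conditional_map(data, contexts, alpha: float = 0.05) -> list[InteractionResults]:
    """Conditional ieQTL mapping over an ordered list of contexts.

    Context k+1 is tested on expression from which contexts 1..k and their
    genotype interactions have been regressed out (per gene, using its own
    eQTL variant), so correlated contexts cannot inflate the ieQTL counts.
    Unlike :func:`map_ieqtls`, main effects are not pre-removed before the
    F-test.
    """
    if isinstance(contexts, pd.DataFrame):
        contexts = [contexts[c] for c in contexts.columns]
    genes = data.eqtls["gene"].values
    variants = data.eqtls["variant"].values
    Y = data.expression.values.reindex(genes).to_numpy(dtype=float)
    G = data.genotype.dosages.reindex(variants).to_numpy(dtype=float)
    codes = pd.Categorical(data.datasets).codes
    n = Y.shape[1]
    results = []
    fitted_contexts: list[np.ndarray] = []
    for context in contexts:
        c = _context_array(context, data.sample_ids)
        r = _interaction_scan(Y, G, c, codes, remove_main_effects=False)
        fdr = np.ones_like(r["p"])
        fdr[r["ok"]] = bh_fdr(r["p"][r["ok"]])
        results.append(InteractionResults(
            eqtls=data.eqtls, betas=r["betas"], rss0=r["rss0"], rss1=r["rss1"],
            f_stat=r["f"], p=r["p"], fdr=fdr, n_effective=r["n_eff"], ok=r["ok"],
            y_norm=r["y_norm"], genotype=r["genotype"], context_norm=r["context_norm"],
            mask=r["mask"], alpha=alpha,
        ))
        # regress this context + its genotype interaction out before the next one
        fitted_contexts.append(c)
        mask = np.isfinite(Y) & np.isfinite(G)
        for prev in fitted_contexts:
            mask &= np.isfinite(prev)[None, :]
        w = mask.astype(float)
        cols = [np.ones((Y.shape[0], n))]
        for prev in fitted_contexts:
            pm = np.nan_to_num(np.broadcast_to(prev, Y.shape))
            cols.extend([pm, pm * np.nan_to_num(G)])
        X = np.stack(cols, axis=2)
        b, _, okb = _batch_ols(np.nan_to_num(np.where(mask, Y, np.nan)), X, w)
        fitted = np.einsum("mnk,mk->mn", X, np.nan_to_num(b), optimize=True)
        Y = np.where(mask, Y - fitted, np.nan)
    return results


class InteractionMapper(BaseEstimator):
    """Estimator wrapper around ieQTL mapping.

    Parameters
    ----------
    alpha : BH-FDR significance threshold per context.
    conditional : run the ordered conditional analysis instead of independent
        per-context scans.
    remove_main_effects : pre-remove genotype/context main effects before the
        F-test (always off in conditional mode, matching the conditional
        analysis definition).
    """

    def __init__(self, alpha: float = 0.05, conditional: bool = False,
                 remove_main_effects: bool = True):
        self.alpha = alpha
        self.conditional = conditional
        self.remove_main_effects = remove_main_effects

    def fit(self, data, contexts):
        if isinstance(contexts, pd.Series):
            contexts = contexts.to_frame()
        if self.conditional:
            self.results_ = conditional_map(data, contexts, alpha=self.alpha)
        elif isinstance(contexts, pd.DataFrame):
            self.results_ = [
                map_ieqtls(data, contexts[c], alpha=self.alpha,
                           remove_main_effects=self.remove_main_effects)
                for c in contexts.columns
            ]
        else:
            self.results_ = [
                map_ieqtls(data, c, alpha=self.alpha,
                           remove_main_effects=self.remove_main_effects)
                for c in contexts
            ]
        self.n_significant_ = [r.n_significant for r in self.results_]
        return self
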