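"""Per-sample likelihood maximization and the outer EM loop.

With expression and context force-normalized each pass, the residual variance
is treated as constant, so maximizing the interaction log-likelihood equals
minimizing the residual sum of squares. For sample i under one ieQTL model
with betas (b1, bg, bc, bgxc) the squared residual is quadratic in the
sample's context value c:

    (y_i - b1 - bg*g_i - (bc + bgxc*g_i) * c)^2 = A_i c^2 + B_i c + const,
    A_i = k_i^2,  B_i = -2 k_i m_i,  k_i = bc + bgxc*g_i,  m_i = y_i - b1 - bg*g_i.

Summing (A, B) over all significant ieQTLs and taking the vertex -B/(2A)
gives each sample's joint maximum-likelihood update in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .interactions import HaltOptimization, InteractionResults, map_ieqtls
from .preprocess import force_normal

DEFAULT_EM_CONFIG = {
    "min_iterations": 5,
    "max_iterations": 100,
    "tolerance": 0.999,
    "alpha": 0.05,
}


def sample_quadratics(fit, y, g):
    """Quadratic coefficients (A_i, B_i) of one ieQTL model per sample.

    ``fit`` needs attributes beta1/beta_g/beta_c/beta_gxc; samples with missing
    y or g get (0, 0) and contribute nothing.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    mask = np.isfinite(y) & np.isfinite(g)
    k = np.where(mask, fit.beta_c + fit.beta_gxc * g, 0.0)
    m = np.where(mask, y - fit.beta1 - fit.beta_g * np.where(mask, g, 0.0), 0.0)
    return k ** 2, -2.0 * k * m


def _accumulate(results: InteractionResults, subset: np.ndarray):
    """Summed (A, B) per sample over the ieQTL models in ``subset``."""
    b = results.betas[subset]
    G = np.nan_to_num(results.genotype[subset])
    Y = np.nan_to_num(results.y_norm[subset])
    w = results.mask[subset].astype(float)
    k = (b[:, 2][:, None] + b[:, 3][:, None] * G) * w
    m = (Y - b[:, 0][:, None] - b[:, 1][:, None] * G) * w
    A = np.einsum("mn,mn->n", k, k)
    B = -2.0 * np.einsum("mn,mn->n", k, m)
    return A, B, k, m


def optimize_context(results: InteractionResults, current, subset=None):
    """One maximization step: vertex of the per-sample summed quadratics.

    Samples with A = 0 (no informative ieQTL) keep their current value.
    Returns (updated context array, info dict with pre/post RSS over the fixed
    ieQTL set and the flat-sample indicator).
    """
    subset = results.significant if subset is None else np.asarray(subset)
    if subset.dtype != bool:
        idx = np.zeros(len(results.p), dtype=bool)
        idx[subset] = True
        subset = idx
    if subset.sum() < 2:
        raise HaltOptimization("optimization requires at least two ieQTLs")
    current = np.asarray(current, dtype=float)
    A, B, k, m = _accumulate(results, subset)
    if not np.any(A > 0):
        raise ValueError("every sample has a flat likelihood (A = 0 for all)")
    with np.errstate(divide="ignore", invalid="ignore"):
        vertex = -B / (2.0 * A)
    updated = np.where(A > 0, vertex, current)
    rss_before = float(np.sum((m - k * np.nan_to_num(current)[None, :]) ** 2))
    rss_after = float(np.sum((m - k * updated[None, :]) ** 2))
    info = {"rss_before": rss_before, "rss_after": rss_after, "flat": A == 0}
    return updated, info


@dataclass
class EMState:
    """Trace of one EM run."""

    iteration: int = 0
    converged: bool = False
    oscillating: bool = False
    halted: bool = False
    n_ieqtls_history: list = field(default_factory=list)
    r_history: list = field(default_factory=list)
    rss_history: list = field(default_factory=list)  # (before, after) per M-step
    contexts: list = field(default_factory=list)

    def trace(self) -> pd.DataFrame:
        n = len(self.n_ieqtls_history)
        return pd.DataFrame({
            "iteration": np.arange(1, n + 1),
            "n_ieqtls": self.n_ieqtls_history,
            "r_with_previous": self.r_history,
            "rss_before": [r[0] for r in self.rss_history],
            "rss_after": [r[1] for r in self.rss_history],
        })


def _pairwise_r(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    if mask.sum() < 2:
        return np.nan
    return float(np.corrcoef(a[mask], b[mask])[0, 1])


def run_em(data, start, config: dict | None = None):
    """Full EM loop for one component: map ieQTLs, update, repeat to convergence.

    Convergence: iteration >= min_iterations and Pearson r between consecutive
    iterates >= tolerance. If an iterate matches ANY earlier iterate at
    |r| >= tolerance (oscillation), the iterate with the most ieQTLs among the
    detected cycle is returned. Raises :class:`HaltOptimization` via the
    ``halted`` flag only when the very first mapping already fails; later
    failures return the partial state.

    Returns (pic, state, final_results) where ``pic`` is the force-normalized
    context vector and ``final_results`` the mapping that produced it.
    """
    cfg = {**DEFAULT_EM_CONFIG, **(config or {})}
    datasets = data.datasets
    c = force_normal(np.asarray(_as_array(start, data.sample_ids)), datasets)
    state = EMState()
    results_history: list[InteractionResults] = []
    best = None

    for it in range(1, cfg["max_iterations"] + 1):
        state.iteration = it
        try:
            res = map_ieqtls(data, c, alpha=cfg["alpha"], require_min=True)
        except HaltOptimization:
            state.halted = True
            if it == 1:
                raise
            pic, res = best if best is not None else (c, None)
            return pic, state, res
        state.contexts.append(c)
        results_history.append(res)
        state.n_ieqtls_history.append(res.n_significant)
        if best is None or res.n_significant >= best[2]:
            best = (c, res, res.n_significant)

        c_raw, info = optimize_context(res, c)
        c_new = force_normal(c_raw, datasets)
        state.rss_history.append((info["rss_before"], info["rss_after"]))
        r = _pairwise_r(c_new, c)
        state.r_history.append(r)

        if it >= cfg["min_iterations"] and r >= cfg["tolerance"]:
            state.converged = True
            state.contexts.append(c_new)
            return c_new, state, res
        # oscillation: the new iterate reverts to some earlier one while still
        # differing from its immediate predecessor (r >= tolerance with the
        # predecessor is the convergence path above and just keeps iterating
        # until min_iterations is met)
        osc_candidates = [] if r >= cfg["tolerance"] else state.contexts[:-1]
        for j, old in enumerate(osc_candidates):
            if abs(_pairwise_r(c_new, old)) >= cfg["tolerance"]:
                state.oscillating = True
                state.converged = True
                cycle = range(j, len(state.contexts))
                kbest = max(cycle, key=lambda i: state.n_ieqtls_history[i])
                pic = state.contexts[kbest]
                return pic, state, results_history[kbest]
        c = c_new

    # hard stop: return the iterate with the most ieQTLs seen
    pic, res, _ = best
    return pic, state, res


def _as_array(vec, sample_ids):
    if isinstance(vec, pd.Series):
        return vec.loc[sample_ids].to_numpy(dtype=float)
    return np.asarray(vec, dtype=float)
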