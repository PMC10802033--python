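"""Sequential extraction of principal interaction components (PICs).

Each round selects the starting vector with the most significant ieQTLs, runs
the EM optimizer to convergence, appends the resulting PIC to the covariate
design with a genotype-interaction term, re-residualizes the expression and
repeats — until the requested number of components is reached or no starting
vector yields at least two significant ieQTLs.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .interactions import HaltOptimization, map_ieqtls, select_start
from .io import AlignedData, ExpressionMatrix
from .optimize import DEFAULT_EM_CONFIG, run_em
from .preprocess import DesignMatrix, build_design, residualize

logger = logging.getLogger(__name__)


class PICA(BaseEstimator):
    """Principal interaction component analysis.

    Infers per-sample hidden context vectors that maximize genotype x context
    interaction effects across a set of eQTLs, via expectation maximization.

    Parameters
    ----------
    n_components : maximum number of PICs to extract; ``None`` runs until no
        further component can be optimized.
    alpha : BH-FDR threshold for calling an ieQTL significant (per context).
    min_iterations, max_iterations : EM iteration bounds.
    tol : Pearson-correlation convergence tolerance between consecutive
        iterates (also the oscillation-detection tolerance).
    interaction_covariates : names of covariate columns whose genotype
        interaction is regressed out alongside the main effect.

    Attributes
    ----------
    pics_ : DataFrame (samples x PICs), force-normalized per dataset.
    ieqtls_ : list of per-PIC ieQTL summary DataFrames.
    states_ : list of per-PIC EM traces.
    n_components_ : number of PICs extracted.
    """

    def __init__(self, n_components=None, alpha=0.05, min_iterations=5,
                 max_iterations=100, tol=0.999, interaction_covariates=None):
        self.n_components = n_components
        self.alpha = alpha
        self.min_iterations = min_iterations
        self.max_iterations = max_iterations
        self.tol = tol
        self.interaction_covariates = interaction_covariates

    def _em_config(self):
        return {
            "min_iterations": self.min_iterations,
            "max_iterations": self.max_iterations,
            "tolerance": self.tol,
            "alpha": self.alpha,
        }

    def fit(self, data: AlignedData, starts: pd.DataFrame | None = None):
        """Extract PICs from aligned, QC-filtered, standardized data.

        ``starts`` defaults to ``data.starts``. Starting vectors are not
        consumed: all of them are re-evaluated every round, so one starting
        position may seed more than one PIC.
        """
        starts = data.starts if starts is None else starts
        if starts is None or starts.shape[1] == 0:
            raise ValueError("no starting vectors supplied")
        base_design = build_design(data.covariates, data.datasets,
                                   self.interaction_covariates)
        expr = data.expression
        if expr.state == "standardized" or base_design.values.shape[1]:
            expr = residualize(expr, base_design, data.genotype, data.eqtls)
        elif expr.state != "residualized":
            raise ValueError("expression must be standardized or residualized")

        pics, summaries, states = [], [], []
        design = base_design
        limit = self.n_components if self.n_components is not None else np.inf
        while len(pics) < limit:
            work = replace(data, expression=expr)
            try:
                idx, _ = select_start(work, starts, alpha=self.alpha)
                start_vec = starts.iloc[:, idx]
                pic, state, res = run_em(work, start_vec, self._em_config())
            except HaltOptimization:
                if not pics:
                    raise HaltOptimization("no optimizable context: every "
                                           "starting vector yields < 2 ieQTLs")
                break
            name = f"PIC{len(pics) + 1}"
            logger.info("%s: %d ieQTLs after %d iterations (start %s)",
                        name, res.n_significant, state.iteration, starts.columns[idx])
            pics.append(pd.Series(pic, index=data.sample_ids, name=name))
            summaries.append(res.to_frame())
            state.start_index = idx
            states.append(state)
            # augment the design with the PIC and its genotype interaction,
            # then re-residualize the expression jointly on all terms
            design = _augment_design(design, pics[-1])
            expr = residualize(
                replace(data.expression, state="standardized"),
                design, data.genotype, data.eqtls,
            )
        self.pics_ = pd.concat(pics, axis=1)
        self.ieqtls_ = summaries
        self.states_ = states
        self.n_components_ = len(pics)
        self.residual_expression_ = expr
        return self

    def transform(self, data: AlignedData) -> ExpressionMatrix:
        """Expression with all fitted PICs (and their genotype interactions)
        regressed out — technical-PIC correction for downstream analyses."""
        if not hasattr(self, "pics_"):
            raise RuntimeError("fit the model before calling transform")
        expr = data.expression
        for name in self.pics_.columns:
            expr = remove_pic_effects(expr, self.pics_[name], data.genotype, data.eqtls)
        return expr

    def fit_transform(self, data: AlignedData, starts=None) -> ExpressionMatrix:
        return self.fit(data, starts).transform(data)


def _augment_design(design: DesignMatrix, pic: pd.Series) -> DesignMatrix:
    values = pd.concat([design.values, pic], axis=1)
    flags = pd.concat([design.interaction_flags,
                       pd.Series({pic.name: True})]).astype(bool)
    return DesignMatrix(values, flags)


def extract_pics(data: AlignedData, n_components=None, alpha=0.05,
                 starts=None, **em_kwargs) -> PICA:
    """Functional wrapper over :class:`PICA`. Returns the fitted estimator."""
    cfg = {**DEFAULT_EM_CONFIG, **em_kwargs}
    model = PICA(
        n_components=n_components, alpha=alpha,
        min_iterations=cfg["min_iterations"],
        max_iterations=cfg["max_iterations"], tol=cfg["tolerance"],
    )
    return model.fit(data, starts=starts)


def remove_pic_effects(expression: ExpressionMatrix, pic, genotype, eqtls
                       ) -> ExpressionMatrix:
    """Regress one PIC and its genotype interaction out of every gene.

    Per gene the design is [1, pic, pic * g] with g the gene's own eQTL
    dosage; re-mapping the same PIC on the corrected expression yields no
    significant ieQTLs.
    """
    pic = pd.Series(np.asarray(pic, dtype=float) if not isinstance(pic, pd.Series)
                    else pic, index=expression.values.columns, name="pic")
    design = DesignMatrix(pic.to_frame(), pd.Series({"pic": True}))
    out = residualize(replace(expression, state="standardized"),
                      design, genotype, eqtls)
    return out


def verify_pic_removed(data: AlignedData, expression: ExpressionMatrix, pic,
                       alpha: float = 0.05) -> int:
    """Number of significant ieQTLs the removed PIC still has (should be 0)."""
    work = replace(data, expression=expression)
    return map_ieqtls(work, pic, alpha=alpha).n_significant
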