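"""Synthetic eQTL data with planted hidden contexts, plus evaluation helpers.

The generator emulates a bulk eQTL dataset: per eQTL a biallelic variant with
dosages drawn Binomial(2, MAF) under Hardy-Weinberg, hidden per-sample
contexts drawn N(0, 1), and expression

    y = b1 + bg*g + sum_contexts (bc*c + bgxc*g*c) + eps,   eps ~ N(0, noise_sd^2).

A configurable fraction of eQTLs carries each context's main + interaction
effect. Starting vectors with a chosen correlation rho to a context are built
as rho * z(context) + sqrt(1 - rho^2) * z(noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AlignedData, ExpressionMatrix, GenotypeMatrix


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults are a desk-scale stand-in for a large bulk cohort: 500 samples,
    1000 eQTLs, 3 hidden contexts each interacting with 20% of the eQTLs,
    interaction effect sizes |bgxc| ~ U(0.3, 0.6), unit noise.
    """

    n_samples: int = 500
    n_eqtls: int = 1000
    n_contexts: int = 3
    fraction_interacting: float = 0.20
    maf_range: tuple = (0.05, 0.5)
    beta_g_range: tuple = (0.3, 1.0)
    beta_c_range: tuple = (0.2, 0.5)
    beta_gxc_range: tuple = (0.3, 0.6)
    noise_sd: float = 1.0
    n_datasets: int = 1
    seed: int = 0
    maf_values: list | None = None   # optional empirical MAF table
    beta_g_values: list | None = None  # optional empirical main-effect table


@dataclass
class SimulationResult:
    assignment: dict          # pic name -> context name
    accuracy: dict            # context name -> |Pearson r|
    correlations: pd.DataFrame


def _signed_uniform(rng, low, high, size):
    return rng.uniform(low, high, size) * rng.choice([-1.0, 1.0], size)


def simulate_dataset(config: SimulationConfig | None = None, **kwargs):
    """Generate an :class:`AlignedData` bundle plus the true context matrix.

    Returns (data, truths) where ``truths`` is a samples x contexts DataFrame.
    The planted per-eQTL parameters are stored in ``data.extras["planted"]``.
    """
    cfg = config or SimulationConfig(**kwargs)
    if config is not None and kwargs:
        raise ValueError("pass either a config or keyword overrides, not both")
    if cfg.n_samples < 30:
        import warnings
        warnings.warn("fewer than 30 samples: interaction detection power "
                      "collapses at this size", stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_samples, cfg.n_eqtls, cfg.n_contexts

    samples = [f"sample{i:04d}" for i in range(n)]
    genes = [f"gene{j:04d}" for j in range(m)]
    variants = [f"rs{j:06d}" for j in range(m)]

    if cfg.maf_values is not None:
        maf = rng.choice(np.asarray(cfg.maf_values, dtype=float), size=m)
    else:
        maf = rng.uniform(*cfg.maf_range, size=m)
    G = rng.binomial(2, maf[:, None], size=(m, n)).astype(float)
    C = rng.standard_normal((n, k))
    contexts = [f"context{j + 1}" for j in range(k)]

    beta1 = rng.standard_normal(m) * 0.5
    if cfg.beta_g_values is not None:
        beta_g = rng.choice(np.asarray(cfg.beta_g_values, dtype=float), size=m)
    else:
        beta_g = _signed_uniform(rng, *cfg.beta_g_range, m)
    carries = rng.random((m, k)) < cfg.fraction_interacting
    beta_c = _signed_uniform(rng, *cfg.beta_c_range, (m, k)) * carries
    beta_gxc = _signed_uniform(rng, *cfg.beta_gxc_range, (m, k)) * carries

    Y = (beta1[:, None] + beta_g[:, None] * G
         + beta_c @ C.T + (beta_gxc @ C.T) * G
         + rng.normal(0.0, cfg.noise_sd, size=(m, n)))

    dataset_labels = np.repeat(
        [f"dataset{d}" for d in range(cfg.n_datasets)],
        np.diff(np.linspace(0, n, cfg.n_datasets + 1).astype(int)),
    )
    data = AlignedData(
        expression=ExpressionMatrix(
            pd.DataFrame(Y, index=genes, columns=samples), state="residualized"),
        genotype=GenotypeMatrix(pd.DataFrame(G, index=variants, columns=samples)),
        eqtls=pd.DataFrame({"gene": genes, "variant": variants}),
        datasets=pd.Series(dataset_labels, index=samples, name="dataset"),
        starts=None,
        extras={"planted": {
            "maf": maf, "beta1": beta1, "beta_g": beta_g,
            "beta_c": beta_c, "beta_gxc": beta_gxc, "carries": carries,
        }},
    )
    truths = pd.DataFrame(C, index=samples, columns=contexts)
    return data, truths


def make_correlated_start(context, rho: float, seed: int = 0,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Starting vector with expected Pearson correlation ``rho`` to ``context``."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must be in [0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    c = np.asarray(context, dtype=float)
    z = (c - c.mean()) / c.std()
    noise = rng.standard_normal(c.size)
    zn = (noise - noise.mean()) / noise.std()
    # orthogonalize the noise so the empirical correlation concentrates on rho
    zn = zn - (zn @ z) / (z @ z) * z
    zn /= zn.std()
    return rho * z + np.sqrt(1.0 - rho ** 2) * zn


def make_start_matrix(truths: pd.DataFrame, rho: float, seed: int = 0) -> pd.DataFrame:
    """One rho-correlated starting vector per true context."""
    rng = np.random.default_rng(seed)
    cols = {f"start_{c}": make_correlated_start(truths[c].to_numpy(), rho, rng=rng)
            for c in truths.columns}
    return pd.DataFrame(cols, index=truths.index)


def reconstruction_accuracy(pics: pd.DataFrame, truths: pd.DataFrame
                            ) -> SimulationResult:
    """Greedy highest-|r| assignment of PICs to contexts; accuracy = |Pearson r|.

    Sign-invariant: a PIC recovering the negated context scores the same. The
    assignment is injective (each context claimed by at most one PIC).
    """
    if pics.shape[1] == 0 or truths.shape[1] == 0:
        raise ValueError("need at least one PIC and one truth vector")
    corr = pd.DataFrame(
        np.abs(np.corrcoef(pics.to_numpy().T, truths.to_numpy().T)
               [: pics.shape[1], pics.shape[1]:]),
        index=pics.columns, columns=truths.columns,
    )
    remaining = corr.copy()
    assignment, accuracy = {}, {}
    while remaining.size and remaining.shape[0] and remaining.shape[1]:
        flat = remaining.stack()
        (pic, ctx) = flat.idxmax()
        assignment[pic] = ctx
        accuracy[ctx] = float(remaining.loc[pic, ctx])
        remaining = remaining.drop(index=pic, columns=ctx)
    return SimulationResult(assignment, accuracy, corr)


def reconstruction_sweep(
    rhos,
    seeds,
    config: SimulationConfig | None = None,
    em_config: dict | None = None,
) -> pd.DataFrame:
    """Starting-correlation robustness sweep.

    For every (rho, seed): simulate a dataset, build one rho-correlated
    starting vector per true context, run the EM optimizer from each start
    independently, and score the recovered components against the truths by
    greedy highest-|r| assignment. A start that halts (fewer than two
    significant ieQTLs at some iteration) contributes no component; contexts
    left unmatched score an accuracy of 0.

    Returns a long table with columns (rho, seed, context, accuracy).
    """
    from .interactions import HaltOptimization
    from .optimize import run_em

    rows = []
    for seed in seeds:
        cfg = SimulationConfig(**{**vars(config or SimulationConfig()), "seed": int(seed)})
        data, truths = simulate_dataset(cfg)
        for rho in rhos:
            starts = make_start_matrix(truths, float(rho), seed=int(seed) + 100)
            pics = {}
            for j, col in enumerate(starts.columns):
                try:
                    pic, _, _ = run_em(data, starts[col], em_config)
                except HaltOptimization:
                    continue
                pics[f"PIC{j + 1}"] = pic
            accuracy = dict.fromkeys(truths.columns, 0.0)
            if pics:
                result = reconstruction_accuracy(
                    pd.DataFrame(pics, index=truths.index), truths)
                accuracy.update(result.accuracy)
            for ctx, acc in accuracy.items():
                rows.append((float(rho), int(seed), ctx, acc))
    return pd.DataFrame(rows, columns=["rho", "seed", "context", "accuracy"])


def minimal_robust_rho(sweep: pd.DataFrame, threshold: float = 0.9) -> float:
    """Smallest starting correlation from which reconstruction is robust.

    Robust: the minimum accuracy over all contexts and seeds exceeds
    ``threshold`` at that rho and at every larger rho in the sweep.
    """
    by_rho = sweep.groupby("rho")["accuracy"].min().sort_index()
    passing = by_rho > threshold
    smallest = np.nan
    for rho in passing.index[::-1]:
        if not passing[rho]:
            break
        smallest = rho
    return float(smallest)


def downsample(data: AlignedData, n: int, seed: int = 0,
               min_dataset_size: int = 30) -> AlignedData:
    """Stratified random subset of ``n`` samples preserving dataset proportions.

    Largest-remainder rounding allocates the per-dataset counts; datasets that
    would fall below ``min_dataset_size`` are dropped with a warning.
    """
    total = data.n_samples
    if n > total:
        raise ValueError(f"requested {n} of {total} samples")
    rng = np.random.default_rng(seed)
    groups = data.datasets.groupby(data.datasets).groups
    labels = list(groups)
    sizes = np.array([len(groups[d]) for d in labels], dtype=float)
    exact = sizes / sizes.sum() * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    chosen = []
    for d, cnt in zip(labels, counts):
        if cnt < min_dataset_size and len(labels) > 1:
            import warnings
            warnings.warn(f"dataset {d} would keep {cnt} < {min_dataset_size} "
                          "samples; dropping it", stacklevel=2)
            continue
        ids = list(groups[d])
        pick = rng.choice(len(ids), size=cnt, replace=False)
        chosen.extend(ids[i] for i in sorted(pick))
    order_map = {s: i for i, s in enumerate(data.sample_ids)}
    chosen.sort(key=order_map.__getitem__)
    return data.subset_samples(chosen)
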