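"""Reading, writing and aligning the on-disk artifacts of an interaction-eQTL run.

All matrices are tab-delimited text (optionally gzip-compressed, autodetected by
the ``.gz`` extension): first row = sample identifiers, first column = row
identifiers (genes or variants). Genotypes are dosages in [0, 2]; missing
entries are encoded as ``NA``, an empty cell, or a configurable numeric
sentinel, and are stored internally as NaN (never as a magic number).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MISSING_SENTINELS = ("NA", "")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression matrix with a transformation-state tag.

    ``state`` is one of ``raw`` (counts/TMM scale), ``standardized``
    (log2 -> gene-centred -> per-sample z) or ``residualized`` (covariate
    effects removed by OLS).
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if self.state not in ("raw", "standardized", "residualized"):
            raise ValueError(f"unknown expression state {self.state!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GenotypeMatrix:
    """Variants x samples dosage matrix; missing dosages are NaN."""

    dosages: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "variant")
        _check_unique(self.dosages.columns, "sample")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            bad = finite[(finite < 0) | (finite > 2)][0]
            raise ValueError(f"dosage {bad} outside [0, 2]")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class AlignedData:
    """All inputs of one run on a single, shared sample ordering."""

    expression: ExpressionMatrix
    genotype: GenotypeMatrix
    eqtls: pd.DataFrame  # columns: gene, variant [, pvalue, allele_assessed]
    datasets: pd.Series  # sample_id -> dataset label
    covariates: pd.DataFrame | None = None  # samples x covariates
    starts: pd.DataFrame | None = None  # samples x starting vectors
    extras: dict = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.expression.values.columns)

    @property
    def n_samples(self) -> int:
        return self.expression.values.shape[1]

    def subset_samples(self, sample_ids: list[str]) -> "AlignedData":
        sample_ids = list(sample_ids)
        return AlignedData(
            expression=replace(self.expression, values=self.expression.values[sample_ids]),
            genotype=GenotypeMatrix(self.genotype.dosages[sample_ids]),
            eqtls=self.eqtls.copy(),
            datasets=self.datasets.loc[sample_ids],
            covariates=None if self.covariates is None else self.covariates.loc[sample_ids],
            starts=None if self.starts is None else self.starts.loc[sample_ids],
            extras=dict(self.extras),
        )


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dup = index[index.duplicated()][0]
        raise ValueError(f"duplicate {what} id: {dup!r}")


def read_matrix(
    path,
    kind: str = "expression",
    missing_sentinels=DEFAULT_MISSING_SENTINELS,
    numeric_missing_code: float | None = None,
) -> ExpressionMatrix | GenotypeMatrix:
    """Read a TSV matrix (row ids in the first column, sample ids in the header).

    Parameters
    ----------
    kind : "expression" or "genotype". For genotype matrices the entries listed
        in ``missing_sentinels`` (and, if given, ``numeric_missing_code``)
        become NaN; a non-numeric expression cell is an error.
    """
    na_values = list(missing_sentinels) if kind == "genotype" else None
    df = pd.read_csv(
        path, sep="\t", index_col=0,
        na_values=na_values, keep_default_na=kind == "genotype",
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    _check_unique(df.index, "gene" if kind == "expression" else "variant")
    _check_unique(df.columns, "sample")
    if kind == "expression":
        try:
            values = df.astype(float)
        except ValueError:
            obj = df.apply(pd.to_numeric, errors="coerce")
            bad = np.argwhere(obj.isna().to_numpy() & df.notna().to_numpy())[0]
            raise ValueError(
                f"non-numeric expression value at gene {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            ) from None
        if values.isna().any().any():
            loc = np.argwhere(values.isna().to_numpy())[0]
            raise ValueError(
                f"missing expression value at gene {values.index[loc[0]]!r}, "
                f"sample {values.columns[loc[1]]!r}"
            )
        return ExpressionMatrix(values, state="raw")
    values = df.astype(float)
    if numeric_missing_code is not None:
        values = values.mask(values == numeric_missing_code)
    return GenotypeMatrix(values)


def write_matrix(matrix, path, float_format: str | None = "%.6f") -> None:
    """Write an expression/genotype matrix (or bare DataFrame) back to TSV.

    ``float_format=None`` writes full precision. Missing genotype dosages are
    written as ``NA``.
    """
    df = getattr(matrix, "values", None)
    if not isinstance(df, pd.DataFrame):
        df = getattr(matrix, "dosages", matrix)
    df.to_csv(path, sep="\t", float_format=float_format, na_rep="NA")


def read_eqtl_table(
    path,
    gene_col: str = "gene",
    variant_col: str = "variant",
    pvalue_col: str = "pvalue",
    allele_col: str = "allele_assessed",
) -> pd.DataFrame:
    """Read the gene-variant eQTL table; order preserved, optional columns kept."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    missing = [c for c in (gene_col, variant_col) if c not in df.columns]
    if missing:
        raise ValueError(
            f"eQTL table misses mandatory column(s) {missing}; found {list(df.columns)}"
        )
    out = pd.DataFrame({
        "gene": df[gene_col].astype(str),
        "variant": df[variant_col].astype(str),
    })
    if pvalue_col in df.columns:
        out["pvalue"] = df[pvalue_col].astype(float)
    if allele_col in df.columns:
        out["allele_assessed"] = df[allele_col].astype(str)
    if out.empty:
        logger.warning("eQTL table %s contains no records", path)
    return out


def read_dataset_map(path) -> pd.Series:
    """Read the two-column sample<TAB>dataset assignment table."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("dataset map needs two columns: sample_id, dataset")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="dataset")
    _check_unique(ser.index, "sample")
    return ser


def align(
    expression: ExpressionMatrix,
    genotype: GenotypeMatrix,
    eqtls: pd.DataFrame,
    datasets: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    starts: pd.DataFrame | None = None,
    min_dataset_size: int = 30,
) -> AlignedData:
    """Intersect samples across all inputs and apply one canonical ordering.

    The ordering is the expression-file sample order restricted to the
    intersection. Datasets smaller than ``min_dataset_size`` are dropped with
    their samples; eQTL records whose gene or variant is absent are dropped
    with a logged count.
    """
    sample_sets = [set(expression.sample_ids), set(genotype.sample_ids)]
    if datasets is not None:
        sample_sets.append(set(datasets.index))
    if covariates is not None:
        sample_sets.append(set(covariates.index))
    if starts is not None:
        sample_sets.append(set(starts.index))
    common = set.intersection(*sample_sets)
    order = [s for s in expression.sample_ids if s in common]
    if not order:
        raise ValueError("no samples shared across all inputs")

    if datasets is None:
        datasets = pd.Series("dataset0", index=order, name="dataset")
    datasets = datasets.loc[order]
    sizes = datasets.value_counts()
    small = sizes[sizes < min_dataset_size].index
    if len(small):
        logger.warning(
            "dropping %d dataset(s) below %d samples: %s",
            len(small), min_dataset_size, list(small),
        )
        order = [s for s in order if datasets[s] not in set(small)]
        if not order:
            raise ValueError("all datasets below the minimum size")
        datasets = datasets.loc[order]

    expr = replace(expression, values=expression.values[order])
    geno = GenotypeMatrix(genotype.dosages[order])

    keep = eqtls["gene"].isin(expr.values.index) & eqtls["variant"].isin(geno.dosages.index)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d eQTL record(s) with absent gene/variant", n_dropped)
    eqtls = eqtls.loc[keep].reset_index(drop=True)

    return AlignedData(
        expression=expr,
        genotype=geno,
        eqtls=eqtls,
        datasets=datasets,
        covariates=None if covariates is None else covariates.loc[order],
        starts=None if starts is None else starts.loc[order],
    )


def write_run_info(path, settings: dict) -> None:
    with open(path, "w") as fh:
        json.dump(settings, fh, indent=2, default=str)
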