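"""Expression-matrix container, I/O, per-gene dispersion statistics and gene filters.

The whole pipeline operates on a genes x samples matrix of log-scale
expression values (log2 microarray intensities or log-TPM).  The container is
a thin validated wrapper over a :class:`pandas.DataFrame`; gene identifiers
are rows, sample identifiers are columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class AxisError(ValueError):
    """Duplicate or otherwise invalid gene/sample identifiers."""


class MatrixParseError(ValueError):
    """Non-numeric or missing cell encountered while loading a matrix."""


class EmptyFilterError(ValueError):
    """A gene filter retained fewer than 2 genes."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of finite log-scale expression values.

    Parameters
    ----------
    data:
        DataFrame with unique gene ids as index and unique sample ids as
        columns; every value finite. At least 2 genes and 2 samples.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise AxisError(
                f"expression matrix needs >=2 genes and >=2 samples, got shape {df.shape}"
            )
        for axis_name, idx in (("gene", df.index), ("sample", df.columns)):
            dup = idx[idx.duplicated()]
            if len(dup):
                raise AxisError(f"duplicate {axis_name} identifier(s): {sorted(set(dup.astype(str)))}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise MatrixParseError("expression matrix contains non-numeric values")
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise MatrixParseError(
                f"non-finite value at gene {df.index[bad[0]]!r}, sample {df.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        """(n_genes, n_samples) float array."""
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        missing = set(gene_ids) - set(self.gene_ids)
        if missing:
            raise AxisError(f"unknown gene id(s): {sorted(missing)}")
        return ExpressionMatrix(self.data.loc[gene_ids])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise AxisError(f"unknown sample id(s): {sorted(missing)}")
        return ExpressionMatrix(self.data[sample_ids])


def load_matrix(path, delimiter: str = "\t") -> ExpressionMatrix:
    """Read a delimited genes-x-samples matrix.

    First row holds sample ids, first column holds gene ids.  Duplicated
    identifiers and non-numeric cells are rejected; nothing is imputed.
    """
    raw = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if raw.index.duplicated().any() or raw.columns.duplicated().any():
        # delegate the error message to the container
        dup_idx = raw.index[raw.index.duplicated()].tolist() or raw.columns[raw.columns.duplicated()].tolist()
        raise AxisError(f"duplicate identifier(s): {sorted(set(map(str, dup_idx)))}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise MatrixParseError(
            f"non-numeric cell {raw.iat[r, c]!r} at gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise MatrixParseError(
            f"missing value at gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def write_matrix(matrix: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    """Write the matrix so that ``load_matrix`` round-trips bit-identically."""
    matrix.data.to_csv(path, sep=delimiter, float_format="%.17g")


def load_annotations(path, delimiter: str = "\t") -> pd.DataFrame:
    """Read a sample-annotation table (one row per sample, first column = sample id).

    An optional ``er_status`` column with values ``pos``/``neg`` supports
    pre-stratifying the training domain.
    """
    ann = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if ann.index.duplicated().any():
        raise AxisError("duplicate sample identifier(s) in annotation table")
    if "er_status" in ann.columns:
        bad = set(ann["er_status"].dropna().unique()) - {"pos", "neg"}
        if bad:
            raise MatrixParseError(f"er_status values must be 'pos'/'neg', got {sorted(bad)}")
    return ann


def mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Raw median absolute deviation ``median(|v_i - median(v)|)`` (no consistency scaling)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def gene_stats(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene dispersion statistics over samples.

    Returns a DataFrame indexed by gene id with columns ``mad``, ``variance``,
    ``sd``, ``iqr``, ``cv`` and ``variance_test_p``.

    Notes
    -----
    * ``mad`` is the raw (unscaled) median absolute deviation.
    * ``iqr`` uses linear interpolation between order statistics
      (numpy's default quantile convention).
    * ``cv`` is sd / |mean|; genes with zero mean get ``inf`` (and never pass
      a top-fraction CV filter ahead of finite genes only by accident — the
      caller sees them ranked first, which is the conventional behaviour for
      near-zero-mean log-ratio data).
    * ``variance_test_p`` is a one-sided chi-squared test of each gene's
      sample variance against the median of all per-gene variances
      (H0: sigma^2 <= median variance), the screening role this p-value
      plays in the variance-plus-CV gene filter.
    """
    X = matrix.values
    n = matrix.n_samples
    if n < 2:
        raise ValueError("gene_stats needs >=2 samples (variance degrees of freedom)")
    variance = X.var(axis=1, ddof=1)
    sd = np.sqrt(variance)
    med_var = float(np.median(variance))
    if med_var > 0:
        chi2_stat = (n - 1) * variance / med_var
        var_p = stats.chi2.sf(chi2_stat, df=n - 1)
    else:
        var_p = np.where(variance > 0, 0.0, 1.0)
    means = X.mean(axis=1)
    cv = np.divide(sd, np.abs(means), out=np.full_like(sd, np.inf), where=means != 0)
    cv = np.where(sd == 0, 0.0, cv)  # constant gene: no variation regardless of mean
    q75, q25 = np.percentile(X, [75, 25], axis=1)
    return pd.DataFrame(
        {
            "mad": mad(X, axis=1),
            "variance": variance,
            "sd": sd,
            "iqr": q75 - q25,
            "cv": cv,
            "variance_test_p": var_p,
        },
        index=matrix.data.index,
    )


# ---------------------------------------------------------------------------
# gene filters
# ---------------------------------------------------------------------------

def _top_fraction_ids(series: pd.Series, fraction: float) -> list[str]:
    """Ids of the top `fraction` of genes by the statistic; ties at the cutoff kept."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = max(int(np.ceil(fraction * len(series))), 1)
    cutoff = np.sort(series.to_numpy())[::-1][n_keep - 1]
    return list(series.index[series.to_numpy() >= cutoff].astype(str))


def _top_n_ids(series: pd.Series, n: int) -> list[str]:
    n = min(n, len(series))
    cutoff = np.sort(series.to_numpy())[::-1][n - 1]
    return list(series.index[series.to_numpy() >= cutoff].astype(str))


@dataclass(frozen=True)
class FilterRule:
    """A named per-gene filter.

    kind:
      * ``"threshold"`` — keep genes with ``stat > value``;
      * ``"top_fraction"`` — keep the top ``value`` fraction by ``stat``;
      * ``"top_n"`` — keep the ``value`` genes with largest ``stat``;
      * ``"var_test_then_top_cv"`` — keep genes with variance-test
        p < ``p_threshold``, then the top ``value`` fraction of those by CV.

    Top-fraction/top-n filters keep all genes tied at the cutoff value, so the
    output is deterministic under gene reordering.
    """

    kind: str
    stat: str
    value: float
    p_threshold: float = 0.01

    def apply(self, table: pd.DataFrame) -> list[str]:
        if self.kind == "threshold":
            return list(table.index[table[self.stat].to_numpy() > self.value].astype(str))
        if self.kind == "top_fraction":
            return _top_fraction_ids(table[self.stat], self.value)
        if self.kind == "top_n":
            return _top_n_ids(table[self.stat], int(self.value))
        if self.kind == "var_test_then_top_cv":
            passing = table[table["variance_test_p"].to_numpy() < self.p_threshold]
            if len(passing) == 0:
                return []
            return _top_fraction_ids(passing["cv"], self.value)
        raise ValueError(f"unknown filter kind {self.kind!r}")


def filter_genes(matrix: ExpressionMatrix, rule: FilterRule) -> tuple[ExpressionMatrix, list[str]]:
    """Apply a gene filter; returns the sub-matrix (original gene order) and the retained ids."""
    table = gene_stats(matrix)
    keep = set(rule.apply(table))
    kept_ids = [g for g in matrix.gene_ids if g in keep]
    if len(kept_ids) < 2:
        raise EmptyFilterError(
            f"filter {rule} retained {len(kept_ids)} gene(s); need >=2"
        )
    return matrix.subset_genes(kept_ids), kept_ids
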