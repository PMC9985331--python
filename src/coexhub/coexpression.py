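"""Normalization and the prevalence-filtered Pearson co-expression matrix.

The pipeline mirrors how large bulk RNA-seq compendia are turned into a
global gene-gene correlation resource: drop genes with zero reads everywhere,
log2-transform with a pseudocount, quantile-normalize samples to a common
distribution, then correlate gene pairs — but only when at least one member
of the pair is expressed (normalized value > 0) in at least a fraction
``theta`` of samples. Pairs of two lowly-prevalent genes are set to exactly 0
to avoid misleading high correlations between barely-expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io_formats import ExpressionMatrix

__all__ = [
    "CorrelationMatrix",
    "drop_silent_genes",
    "quantile_normalize",
    "normalize",
    "correlation_matrix",
    "top_correlates",
]


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene Pearson correlation matrix with exact zeros where
    the prevalence filter suppressed a pair.

    ``data`` is a square DataFrame indexed by gene ids on both axes;
    ``prevalence`` holds each gene's fraction of samples with normalized
    expression > 0.
    """

    data: pd.DataFrame
    prevalence_threshold: float
    prevalence: pd.Series | None = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def r(self, a: str, b: str) -> float:
        return float(self.data.at[a, b])

    def row(self, gene: str) -> pd.Series:
        if gene not in self.data.index:
            raise KeyError(f"gene {gene!r} not in correlation matrix")
        return self.data.loc[gene]

    def save(self, path) -> None:
        """Persist as HDF5 (ids + dense symmetric matrix) or TSV by suffix."""
        path = str(path)
        if path.endswith((".h5", ".hdf5")):
            with h5py.File(path, "w") as f:
                f.create_dataset("gene_ids", data=np.array(self.gene_ids, dtype="S"))
                f.create_dataset("values", data=self.data.to_numpy())
                f.attrs["prevalence_threshold"] = self.prevalence_threshold
                if self.prevalence is not None:
                    f.create_dataset("prevalence", data=self.prevalence.to_numpy())
        else:
            self.data.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def load(cls, path) -> "CorrelationMatrix":
        path = str(path)
        if path.endswith((".h5", ".hdf5")):
            with h5py.File(path, "r") as f:
                genes = [g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][:]]
                values = f["values"][:]
                theta = float(f.attrs.get("prevalence_threshold", np.nan))
                prev = None
                if "prevalence" in f:
                    prev = pd.Series(f["prevalence"][:], index=genes)
            return cls(pd.DataFrame(values, index=genes, columns=genes), theta, prev)
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(df, float("nan"))


def drop_silent_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes with zero reads in every sample (raw stage only)."""
    if m.stage != "raw":
        raise ValueError(f"drop_silent_genes expects raw counts, got stage {m.stage!r}")
    keep = (m.data.to_numpy() > 0).any(axis=1)
    if not keep.any():
        raise ValueError("all genes are silent (zero reads in every sample)")
    if keep.all():
        return m
    return ExpressionMatrix(m.data.loc[keep], stage="raw")


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns (samples) to their common mean distribution.

    The reference distribution is the across-sample mean of the sorted value
    vectors; each entry is replaced by the reference value at its within-sample
    rank. Tied values receive the mean of the reference values at the tied
    rank positions. After normalization every column's sorted vector is
    identical.
    """
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        ranks = rankdata(values[:, j], method="average")  # 1-based, .5 for ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return out


def normalize(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount), then quantile normalization across samples."""
    if m.stage != "raw":
        raise ValueError(f"normalize expects raw counts, got stage {m.stage!r}")
    if m.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    logged = np.log2(m.values + pseudocount)
    qn = quantile_normalize(logged)
    return ExpressionMatrix(
        pd.DataFrame(qn, index=m.gene_ids, columns=m.sample_ids),
        stage="quantile_normalized",
    )


def correlation_matrix(m: ExpressionMatrix, theta: float = 0.3) -> CorrelationMatrix:
    """Pearson gene-gene correlations with the prevalence filter.

    A pair (i, j) is correlated only when max(prev_i, prev_j) >= ``theta``,
    where prev_g is the fraction of samples in which gene g has normalized
    expression > 0; otherwise the entry is exactly 0. Zero-variance genes get
    r = 0 with every partner. The diagonal is 1 for genes passing their own
    prevalence, 0 otherwise.
    """
    if m.stage != "quantile_normalized":
        raise ValueError(
            f"correlation_matrix expects quantile_normalized input, got {m.stage!r}"
        )
    if not (0.0 < theta <= 1.0):
        raise ValueError(f"prevalence threshold must be in (0, 1], got {theta}")

    X = m.values
    n_genes = X.shape[0]
    prevalence = (X > 0).mean(axis=1)

    sd = X.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r = np.nan_to_num(r, nan=0.0, posinf=0.0, neginf=0.0)
    np.clip(r, -1.0, 1.0, out=r)
    r[constant, :] = 0.0
    r[:, constant] = 0.0

    passing = prevalence >= theta
    # Pair kept iff at least one member passes.
    keep = passing[:, None] | passing[None, :]
    r[~keep] = 0.0
    np.fill_diagonal(r, 0.0)
    diag = np.where(passing & ~constant, 1.0, 0.0)
    r[np.arange(n_genes), np.arange(n_genes)] = diag

    df = pd.DataFrame(r, index=m.gene_ids, columns=m.gene_ids)
    return CorrelationMatrix(df, theta, pd.Series(prevalence, index=m.gene_ids))


def top_correlates(
    c: CorrelationMatrix,
    gene: str,
    k: int,
    direction: str = "positive",
    restrict: set[str] | None = None,
) -> tuple[list[tuple[str, float]], bool]:
    """The ``k`` most positively (or negatively) correlated partners of a gene.

    Ties in r break lexicographically by gene id. ``restrict`` limits the
    candidate pool (e.g. coding-only or lncRNA-only via annotation). Returns
    ``(pairs, truncated)`` where ``truncated`` flags that fewer than ``k``
    candidates were available.
    """
    if gene not in c:
        raise KeyError(f"gene {gene!r} not in correlation matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative', got {direction!r}")

    row = c.row(gene).drop(labels=[gene])
    if restrict is not None:
        row = row[row.index.isin(restrict)]
    reverse = direction == "positive"
    if reverse:
        ordered = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))
    else:
        ordered = sorted(row.items(), key=lambda kv: (kv[1], kv[0]))
    truncated = len(ordered) < k
    return [(g, float(r)) for g, r in ordered[:k]], truncated
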