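"""Unsupervised cytoplasm/nucleus localization scoring from co-expression.

For a query gene, every other gene in the shared universe is ranked by its
correlation with the query and the rank is scaled to [0, 1] (best correlate
-> 1). Each scaled rank is multiplied by that gene's measured CN RCI
(cytoplasm/nucleus relative concentration index; positive = cytoplasmic,
negative = nuclear) in a cell line, where measured, and summed. Queries whose
strong correlates are predominantly cytoplasmic accumulate a large positive
sum, nuclear ones a large negative sum. Raw sums are min-max normalized per
cell line across the scored queries and shifted to [-0.5, 0.5] so they read
like RCIs. Per-cell-line AUROC against genes with strong measured RCIs
(|RCI| > 1) quantifies how trustworthy each cell line's predictions are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .association import auroc
from .coexpression import CorrelationMatrix

__all__ = [
    "LocalizationResult",
    "CellLineEvaluation",
    "predict_localization",
    "evaluate_localization",
    "select_reporting_cell_lines",
]


@dataclass
class LocalizationResult:
    """Rank-weighted localization sums and normalized scores.

    ``raw_sums`` and ``scores`` are query x cell-line DataFrames; scores lie
    in [-0.5, 0.5] with the extremes attained per cell line whenever at least
    two queries were scored. ``n_weights`` counts the RCI values each sum
    used.
    """

    raw_sums: pd.DataFrame
    scores: pd.DataFrame
    n_weights: pd.DataFrame
    warnings: list[str]


@dataclass(frozen=True)
class CellLineEvaluation:
    cell_line: str
    auroc: float
    n_pos: int
    n_neg: int
    roc_points: list[tuple[float, float]]
    skipped: bool = False


def predict_localization(
    c: CorrelationMatrix,
    rci: pd.DataFrame,
    queries: set[str] | list[str],
    cell_lines: list[str] | None = None,
) -> LocalizationResult:
    """Score each query gene's predicted localization per cell line.

    The gene universe is (genes of ``c`` ∩ genes of ``rci``) ∪ queries. For a
    query q, all universe genes except q are ranked by r(q, ·) ascending with
    average ranks for ties, scaled to [0, 1]; the raw sum adds
    rank01(g) x RCI(g, cell line) over genes with a measured RCI — the query's
    own RCI, if measured, never contributes. Raw sums are then min-max
    normalized to [0, 1] per cell line across queries and shifted by -0.5.
    """
    queries = sorted(set(queries))
    missing = [q for q in queries if q not in c]
    if missing:
        raise KeyError(f"query genes not in correlation matrix: {missing[:5]}")
    if cell_lines is None:
        cell_lines = list(rci.columns)
    else:
        unknown = [cl for cl in cell_lines if cl not in rci.columns]
        if unknown:
            raise KeyError(f"cell lines not in RCI table: {unknown}")

    corr_genes = set(c.gene_ids)
    universe = sorted((corr_genes & set(rci.index)) | set(queries))
    absent = [g for g in universe if g not in corr_genes]
    if absent:
        raise KeyError(f"universe genes missing from correlation matrix: {absent[:5]}")
    n_universe = len(universe)
    if n_universe < 3:
        raise ValueError("universe too small to rank (need >= 3 genes)")

    # RCI weights aligned to the universe; genes without a measurement -> NaN.
    weights = rci.reindex(index=universe, columns=cell_lines).to_numpy(dtype=float)

    warnings_: list[str] = []
    for j, cl in enumerate(cell_lines):
        if not np.isfinite(weights[:, j]).any():
            raise ValueError(f"cell line {cl!r} has no measured RCI values in the universe")

    uni_index = {g: i for i, g in enumerate(universe)}
    corr_block = c.data.loc[universe, universe].to_numpy(dtype=float)

    raw = np.zeros((len(queries), len(cell_lines)))
    n_used = np.zeros((len(queries), len(cell_lines)), dtype=int)
    for qi, q in enumerate(queries):
        pos = uni_index[q]
        r_vec = np.delete(corr_block[pos], pos)
        w = np.delete(weights, pos, axis=0)
        ranks = rankdata(r_vec, method="average")  # ascending: best correlate highest
        rank01 = (ranks - 1.0) / (len(r_vec) - 1.0)
        for j in range(len(cell_lines)):
            present = np.isfinite(w[:, j])
            raw[qi, j] = float((rank01[present] * w[present, j]).sum())
            n_used[qi, j] = int(present.sum())

    scores = np.zeros_like(raw)
    for j, cl in enumerate(cell_lines):
        col = raw[:, j]
        lo, hi = col.min(), col.max()
        if len(queries) < 2 or hi == lo:
            scores[:, j] = 0.0
            warnings_.append(
                f"cell line {cl!r}: degenerate min-max normalization; scores fixed at 0"
            )
        else:
            scores[:, j] = (col - lo) / (hi - lo) - 0.5

    idx = pd.Index(queries, name="gene")
    cols = pd.Index(cell_lines, name="cell_line")
    return LocalizationResult(
        raw_sums=pd.DataFrame(raw, index=idx, columns=cols),
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        n_weights=pd.DataFrame(n_used, index=idx, columns=cols),
        warnings=warnings_,
    )


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> list[tuple[float, float]]:
    """(FPR, TPR) points sweeping the threshold from high to low."""
    order = np.argsort(-scores, kind="stable")
    labels = labels[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(~labels)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    pts = [(0.0, 0.0)]
    pts += [(float(fp) / n_neg, float(tp) / n_pos) for fp, tp in zip(fps, tps)]
    return pts


def evaluate_localization(
    predictions: pd.DataFrame,
    rci: pd.DataFrame,
    pos_cut: float = 1.0,
    neg_cut: float = -1.0,
) -> list[CellLineEvaluation]:
    """Per-cell-line ROC evaluation of localization predictions.

    ``predictions`` is a query x cell-line frame (raw sums or scores — AUROC
    is rank-invariant per column). Query genes with a measured RCI above
    ``pos_cut`` in that cell line are cytoplasmic positives, below ``neg_cut``
    nuclear negatives; intermediate or missing RCIs are excluded. A cell line
    with no positive or no negative is returned flagged as skipped.
    """
    out: list[CellLineEvaluation] = []
    for cl in predictions.columns:
        if cl not in rci.columns:
            out.append(CellLineEvaluation(cl, float("nan"), 0, 0, [], skipped=True))
            continue
        measured = rci[cl].reindex(predictions.index)
        mask = measured.notna() & ((measured > pos_cut) | (measured < neg_cut))
        genes = predictions.index[mask]
        if len(genes) == 0:
            out.append(CellLineEvaluation(cl, float("nan"), 0, 0, [], skipped=True))
            continue
        labels = (measured.loc[genes] > pos_cut).to_numpy(dtype=bool)
        scores = predictions.loc[genes, cl].to_numpy(dtype=float)
        n_pos = int(labels.sum())
        n_neg = int((~labels).sum())
        if n_pos == 0 or n_neg == 0:
            out.append(CellLineEvaluation(cl, float("nan"), n_pos, n_neg, [], skipped=True))
            continue
        value = auroc(list(zip(genes, scores)), set(genes[labels]))
        out.append(
            CellLineEvaluation(cl, value, n_pos, n_neg, _roc_points(scores, labels))
        )
    return out


def select_reporting_cell_lines(
    evaluations: list[CellLineEvaluation], k: int = 5
) -> tuple[list[str], bool]:
    """The top ``k`` cell lines by AUROC (descending, ties lexicographic).

    Returns ``(cell_lines, truncated)``; ``truncated`` flags fewer than ``k``
    usable evaluations.
    """
    usable = [e for e in evaluations if not e.skipped]
    ranked = sorted(usable, key=lambda e: (-e.auroc, e.cell_line))
    truncated = len(ranked) < k
    return [e.cell_line for e in ranked[:k]], truncated
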