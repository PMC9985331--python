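"""Mean-PCC gene-set association scoring and its benchmarking statistics.

The core prediction statistic: for a query gene, the mean Pearson correlation
between the query and the members of each gene set in a library. Because
gene sets differ in size, significance is assessed per term: the mean PCC of
every background gene with that term forms the term's own null, whose mean
and sample SD convert the query's mean PCC into a z-score; the normal CDF
then yields right- and left-tailed p-values. Small p_right flags sets the
query is unusually positively co-expressed with, small p_left unusually
negatively.

Also here: L1000-style up/down perturbation-signature prioritization and
inversion, the DEG-overlap Fisher benchmark, and tie-aware AUROC.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import CorrelationMatrix
from .io_formats import GeneSetLibrary

__all__ = [
    "TermScore",
    "DifferentialExpressionRecord",
    "mean_pcc",
    "score_library",
    "rank_genes_for_set",
    "prioritize_perturbations",
    "parse_signature_label",
    "deg_filter",
    "overlap_significance",
    "auroc",
]


@dataclass(frozen=True)
class TermScore:
    """Association of one query gene with one library term."""

    term: str
    mean_pcc: float
    z: float
    p_right: float
    p_left: float
    n_genes_used: int
    degenerate: bool = False  # sigma_term == 0: z undefined, p split 0.5/0.5

    @property
    def neg_log10_p_right(self) -> float:
        return -np.log10(self.p_right) if self.p_right > 0 else np.inf

    @property
    def neg_log10_p_left(self) -> float:
        return -np.log10(self.p_left) if self.p_left > 0 else np.inf


@dataclass(frozen=True)
class DifferentialExpressionRecord:
    """One row of a knockdown differential-expression table."""

    gene: str
    log2fc: float
    fdr: float
    zscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"FDR must be in [0, 1], got {self.fdr}")
        if not (np.isfinite(self.log2fc) and np.isfinite(self.zscore)):
            raise ValueError("log2FC and z-score must be finite")


def mean_pcc(
    c: CorrelationMatrix, query: str, genes: set[str] | list[str]
) -> tuple[float, int]:
    """Mean correlation of ``query`` with the set members present in ``c``.

    The query itself is excluded from the set; absent members are silently
    dropped (reflected in the returned count).
    """
    if query not in c:
        raise KeyError(f"query gene {query!r} not in correlation matrix")
    members = [g for g in genes if g != query and g in c]
    if not members:
        raise ValueError(f"empty effective set for query {query!r}")
    row = c.row(query)
    vals = row.loc[members].to_numpy(dtype=float)
    return float(vals.mean()), len(members)


def _term_background_means(
    c: CorrelationMatrix, term_genes: list[str], background: list[str]
) -> np.ndarray:
    """mean_pcc(g, term) for every background gene g, vectorized.

    Self-exclusion: when g belongs to the term, its diagonal entry is removed
    from its own average.
    """
    sub = c.data.loc[background, term_genes].to_numpy(dtype=float)
    n = len(term_genes)
    sums = sub.sum(axis=1)
    counts = np.full(len(background), n, dtype=float)
    term_index = {g: j for j, g in enumerate(term_genes)}
    for i, g in enumerate(background):
        j = term_index.get(g)
        if j is not None:
            sums[i] -= sub[i, j]
            counts[i] -= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / counts
    return means


def score_library(
    c: CorrelationMatrix,
    query: str,
    lib: GeneSetLibrary,
    background: set[str] | list[str],
) -> list[TermScore]:
    """Score every library term for one query gene against a per-term null.

    ``background`` is the set of query-eligible genes (all must be in ``c``
    and include the query). For each term, the null mean and sample SD
    (ddof=1) come from the mean PCCs of *all* background genes with that
    term; z = (query's mean PCC − μ_term)/σ_term; p_right = 1 − Φ(z),
    p_left = Φ(z). A term with σ_term = 0 is flagged degenerate with both
    tails at 0.5.
    """
    background = sorted(set(background))
    if query not in set(background):
        raise ValueError(f"query {query!r} must be in the background")
    missing = [g for g in background if g not in c]
    if missing:
        raise ValueError(f"background genes missing from correlation matrix: {missing[:5]}")

    qpos = background.index(query)
    scores: list[TermScore] = []
    for label, genes in lib.terms.items():
        present = [g for g in genes if g in c]
        if not present:
            raise ValueError(f"term {label!r} has no genes in the correlation matrix")
        means = _term_background_means(c, present, background)
        valid = np.isfinite(means)
        if not valid[qpos]:
            raise ValueError(f"empty effective set for query {query!r} in term {label!r}")
        query_mean = float(means[qpos])
        mu = float(means[valid].mean())
        sigma = float(means[valid].std(ddof=1)) if valid.sum() > 1 else 0.0
        n_used = len(present) - (1 if query in set(present) else 0)
        if sigma == 0.0:
            scores.append(TermScore(label, query_mean, float("nan"), 0.5, 0.5, n_used, True))
            continue
        z = (query_mean - mu) / sigma
        p_left = float(stats.norm.cdf(z))
        p_right = float(stats.norm.sf(z))
        scores.append(TermScore(label, query_mean, float(z), p_right, p_left, n_used))
    return scores


def rank_genes_for_set(
    c: CorrelationMatrix,
    candidates: set[str] | list[str],
    target_set: set[str] | list[str],
) -> list[tuple[str, float]]:
    """Rank candidate genes by their mean PCC with a target gene set,
    descending (ties lexicographic). Candidates inside the target set are
    still ranked, with self-exclusion applied by :func:`mean_pcc`."""
    cand = sorted({g for g in candidates if g in c})
    if not cand:
        raise ValueError("no candidate genes present in the correlation matrix")
    target = [g for g in dict.fromkeys(target_set) if g in c]
    if not target:
        raise ValueError("no target-set genes present in the correlation matrix")
    means = _term_background_means(c, target, cand)
    pairs = [
        (g, float(m)) for g, m in zip(cand, means) if np.isfinite(m)
    ]
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return pairs


_DIRECTION_RE = re.compile(r"^(?P<base>.+?)[\s_\-]+(?P<dir>up|down)$", re.IGNORECASE)


def parse_signature_label(label: str) -> tuple[str, str]:
    """Split ``"<signature> up"`` / ``"<signature>-down"`` into (base, direction)."""
    m = _DIRECTION_RE.match(label.strip())
    if not m:
        raise ValueError(f"signature label {label!r} lacks an up/down direction suffix")
    return m.group("base"), m.group("dir").lower()


def prioritize_perturbations(
    c: CorrelationMatrix,
    sigs: GeneSetLibrary,
    queries: set[str] | list[str],
    top_k: int = 1000,
    sort_by: str = "mean_pcc",
) -> tuple[dict[str, list[dict]], GeneSetLibrary]:
    """Match query genes to directional perturbation signatures.

    Every signature term must carry an up/down suffix. Per signature, the
    queries are ranked by mean PCC with the signature's genes and the top
    ``top_k`` retained. The retained (query, signature) pairs are then
    inverted: per query, an ordered list of matched signatures with direction,
    mean PCC and right-tailed p-value (per-signature null over the query
    cohort). A query matched to an "up" signature is predicted upregulated by
    that perturbation.

    Returns the per-query ranking (dict of rows, ordered by ``sort_by``:
    ``mean_pcc`` descending or ``p_right`` ascending) and the inverted
    ordered GMT (members ``"<base>|<direction>"``, ranked by mean PCC).
    """
    if sort_by not in ("mean_pcc", "p_right"):
        raise ValueError(f"sort_by must be 'mean_pcc' or 'p_right', got {sort_by!r}")
    queries = sorted({q for q in queries if q in c})
    if not queries:
        raise ValueError("no query genes present in the correlation matrix")

    per_query: dict[str, list[dict]] = {q: [] for q in queries}
    for label, genes in sigs.terms.items():
        base, direction = parse_signature_label(label)
        present = [g for g in genes if g in c]
        if not present:
            continue
        means = _term_background_means(c, present, queries)
        valid = np.isfinite(means)
        mu = float(means[valid].mean())
        sigma = float(means[valid].std(ddof=1)) if valid.sum() > 1 else 0.0
        ranked = sorted(
            (
                (q, float(m))
                for q, m in zip(queries, means)
                if np.isfinite(m)
            ),
            key=lambda kv: (-kv[1], kv[0]),
        )[:top_k]
        for q, m in ranked:
            if sigma > 0:
                z = (m - mu) / sigma
                p_right = float(stats.norm.sf(z))
            else:
                p_right = 0.5
            per_query[q].append(
                {
                    "signature": base,
                    "direction": direction,
                    "mean_pcc": m,
                    "p_right": p_right,
                }
            )

    key = (
        (lambda row: (-row["mean_pcc"], row["signature"], row["direction"]))
        if sort_by == "mean_pcc"
        else (lambda row: (row["p_right"], row["signature"], row["direction"]))
    )
    terms: dict[str, list[str]] = {}
    for q in queries:
        per_query[q].sort(key=key)
        members = [
            f"{row['signature']}|{row['direction']}"
            for row in sorted(
                per_query[q], key=lambda r: (-r["mean_pcc"], r["signature"], r["direction"])
            )
        ]
        if members:
            terms[q] = members
    per_query = {q: rows for q, rows in per_query.items() if rows}
    return per_query, GeneSetLibrary(terms)


def deg_filter(
    records: list[DifferentialExpressionRecord],
    top_n: int = 200,
    fc_cut: float = 0.5,
    fdr_cut: float = 0.05,
    z_cut: float = 1.645,
) -> tuple[list[str], list[str]]:
    """Select up/down differentially expressed genes from a knockdown table.

    A record passes when |log2FC| > ``fc_cut``, FDR < ``fdr_cut`` and
    |z| > ``z_cut``; passing records split by log2FC sign, each side truncated
    to its ``top_n`` largest |log2FC| (ties: smaller FDR, then gene name).
    Returns (up_genes, down_genes); either may be empty.
    """
    if not records:
        raise ValueError("no differential-expression records supplied")
    passing = [
        r
        for r in records
        if abs(r.log2fc) > fc_cut and r.fdr < fdr_cut and abs(r.zscore) > z_cut
    ]
    up = [r for r in passing if r.log2fc > 0]
    down = [r for r in passing if r.log2fc < 0]
    order = lambda r: (-abs(r.log2fc), r.fdr, r.gene)  # noqa: E731
    up.sort(key=order)
    down.sort(key=order)
    return [r.gene for r in up[:top_n]], [r.gene for r in down[:top_n]]


def overlap_significance(
    set_a: set[str], set_b: set[str], universe: set[str]
) -> tuple[int, float, float]:
    """Right-tailed Fisher exact test for enrichment of the overlap of two
    gene sets within a universe. Returns (overlap, p, -log10 p)."""
    if not universe:
        raise ValueError("empty universe")
    a = set_a & universe
    b = set_b & universe
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, len(universe) - len(a) - len(b) + k],
    ]
    p = float(stats.fisher_exact(table, alternative="greater")[1])
    neg_log = -np.log10(p) if p > 0 else np.inf
    return k, p, float(neg_log)


def auroc(scores: list[tuple[str, float]], positives: set[str]) -> float:
    """Area under the ROC curve by the Mann-Whitney rank identity:
    P(score_pos > score_neg) + 0.5 * P(tie), exact under average ranks."""
    labels = np.array([item in positives for item, _ in scores], dtype=bool)
    values = np.array([s for _, s in scores], dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC needs at least one positive and one negative")
    ranks = stats.rankdata(values, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
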