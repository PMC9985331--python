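"""Cis/trans assignment of a gene's top co-expressed partners.

A correlated partner is *cis* when it lies on the same chromosome as the
query gene and *trans* otherwise — chromosome identity only, no distance
threshold, strand ignored. Per-gene percentages over the top-k positive
correlates aggregate into cohort summaries (mean ± sample SD) by gene-class
pairing (all partners, coding-only, lncRNA-only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coexpression import CorrelationMatrix
from .io_formats import GeneAnnotation

__all__ = ["ModeResult", "ModeSummary", "assign_modes", "aggregate_modes"]

PARTNER_CLASSES = ("all", "coding", "lncRNA")


@dataclass(frozen=True)
class ModeResult:
    gene: str
    cis_pct: float
    trans_pct: float
    n_used: int


@dataclass(frozen=True)
class ModeSummary:
    partner_class: str
    n_genes: int
    cis_mean: float
    cis_sd: float
    trans_mean: float
    trans_sd: float


def assign_modes(
    c: CorrelationMatrix,
    ann: GeneAnnotation,
    gene: str,
    k: int = 100,
    partner_class: str = "all",
) -> ModeResult:
    """Percentage of the gene's top-k positive correlates on its own
    chromosome (cis) vs elsewhere (trans).

    Candidates are restricted to ``partner_class`` before truncation to k;
    partners without a chromosome annotation are excluded from both numerator
    and denominator (``n_used`` reports the count actually classified).
    """
    if partner_class not in PARTNER_CLASSES:
        raise ValueError(f"partner_class must be one of {PARTNER_CLASSES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    chrom = ann.chromosome(gene)
    if chrom is None:
        raise KeyError(f"gene {gene!r} lacks a chromosome annotation")
    if gene not in c:
        raise KeyError(f"gene {gene!r} not in correlation matrix")

    if partner_class == "coding":
        pool = ann.coding_ids()
    elif partner_class == "lncRNA":
        pool = ann.lncrna_ids()
    else:
        pool = set(ann.records)
    pool.discard(gene)

    row = c.row(gene).drop(labels=[gene])
    row = row[row.index.isin(pool) & (row > 0)]
    top = sorted(row.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    if not top:
        raise ValueError(f"gene {gene!r} has no eligible positive correlates")
    n_cis = sum(1 for g, _ in top if ann.chromosome(g) == chrom)
    n_used = len(top)
    cis_pct = 100.0 * n_cis / n_used
    return ModeResult(gene, cis_pct, 100.0 - cis_pct, n_used)


def aggregate_modes(results: list[ModeResult], partner_class: str = "all") -> ModeSummary:
    """Cohort mean ± sample SD (ddof=1) of per-gene cis/trans percentages."""
    if not results:
        raise ValueError("empty cohort")
    cis = np.array([r.cis_pct for r in results], dtype=float)
    trans = np.array([r.trans_pct for r in results], dtype=float)
    sd = float(cis.std(ddof=1)) if len(cis) > 1 else 0.0
    return ModeSummary(
        partner_class=partner_class,
        n_genes=len(results),
        cis_mean=float(cis.mean()),
        cis_sd=sd,
        trans_mean=float(trans.mean()),
        trans_sd=float(trans.std(ddof=1)) if len(trans) > 1 else 0.0,
    )
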