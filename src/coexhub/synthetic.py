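"""Synthetic fixtures with known ground truth.

Emulates the external corpora the engine normally consumes — a bulk RNA-seq
counts compendium, gene-set libraries, and a subcellular-localization RCI
table — with planted structure so that every downstream stage can be tested
end to end without external downloads.

Counts follow a latent-factor model: genes in a planted module share a
per-sample Gaussian factor, giving expected pairwise correlation rho on the
latent (log2) scale; the latent values are exponentiated and rounded to mimic
counts. Each module lives on a single chromosome (so co-expressed partners
are enriched for cis) and contains at least one lncRNA-flagged gene to serve
as a query. The RCI table plants alternating cytoplasmic (+effect) and
nuclear (-effect) modules. All randomness flows through one seeded generator;
a fixed seed reproduces every artifact bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneAnnotation, GeneRecord, GeneSetLibrary

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_counts", "generate_library", "generate_rci"]


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic corpus.

    ``rho`` is the expected within-module pairwise correlation on the latent
    scale; ``noise_sd`` the SD of latent log2 expression around each gene's
    baseline; ``rci_effect`` the mean |RCI| planted for nuclear/cytoplasmic
    module genes and ``rci_noise_sd`` its spread; ``rci_missingness`` the
    per-entry probability of a missing RCI measurement.
    """

    n_genes: int = 500
    n_samples: int = 200
    n_modules: int = 5
    module_size: int = 20
    rho: float = 0.9
    noise_sd: float = 1.0
    fraction_lncRNA: float = 0.3
    n_chromosomes: int = 10
    rci_cell_lines: int = 5
    rci_effect: float = 2.0
    rci_noise_sd: float = 0.2
    rci_missingness: float = 0.1
    random_seed: int = 0

    def validate(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("module_size * n_modules exceeds n_genes")
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must be in (0, 1)")
        if self.n_samples < 2 or self.n_genes < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if not (0.0 <= self.fraction_lncRNA <= 1.0):
            raise ValueError("fraction_lncRNA must be in [0, 1]")
        if not (0.0 <= self.rci_missingness < 1.0):
            raise ValueError("rci_missingness must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated corpus."""

    module_of: dict[str, int | None]
    chromosome_of: dict[str, str]
    is_lncrna: dict[str, bool]
    modules: dict[int, list[str]] = field(default_factory=dict)

    def to_annotation(self) -> GeneAnnotation:
        return GeneAnnotation(
            {
                g: GeneRecord(g, g, self.chromosome_of[g], self.is_lncrna[g])
                for g in self.module_of
            }
        )

    def lncrna_queries(self) -> list[str]:
        """lncRNA-flagged module members — the natural query genes."""
        return sorted(
            g for g, m in self.module_of.items() if m is not None and self.is_lncrna[g]
        )


def generate_counts(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Counts matrix with planted correlated modules plus ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.random_seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    width = len(str(cfg.n_samples))
    samples = [f"S{j:0{width}d}" for j in range(cfg.n_samples)]

    module_of: dict[str, int | None] = {g: None for g in genes}
    modules: dict[int, list[str]] = {}
    cursor = 0
    for m in range(cfg.n_modules):
        members = genes[cursor : cursor + cfg.module_size]
        modules[m] = members
        for g in members:
            module_of[g] = m
        cursor += cfg.module_size

    # Latent log2 expression: shared factor within a module, iid noise outside.
    baseline = rng.uniform(2.0, 9.0, size=cfg.n_genes)
    eps = rng.standard_normal((cfg.n_genes, cfg.n_samples))
    z = eps.copy()
    for m, members in modules.items():
        factor = rng.standard_normal(cfg.n_samples)
        rows = [genes.index(g) for g in members]
        z[rows] = np.sqrt(cfg.rho) * factor + np.sqrt(1.0 - cfg.rho) * eps[rows]
    latent = baseline[:, None] + cfg.noise_sd * z
    counts = np.rint(np.exp2(latent)).astype(float)

    # Chromosomes: one per module (cis structure); background genes random.
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    chromosome_of: dict[str, str] = {}
    for m, members in modules.items():
        c = chroms[m % len(chroms)]
        for g in members:
            chromosome_of[g] = c
    for g in genes:
        if g not in chromosome_of:
            chromosome_of[g] = chroms[rng.integers(len(chroms))]

    # lncRNA flags; each module keeps at least one lncRNA query.
    is_lnc = {g: bool(rng.random() < cfg.fraction_lncRNA) for g in genes}
    for members in modules.values():
        if not any(is_lnc[g] for g in members):
            is_lnc[members[0]] = True

    truth = SyntheticTruth(module_of, chromosome_of, is_lnc, modules)
    matrix = ExpressionMatrix(pd.DataFrame(counts, index=genes, columns=samples), stage="raw")
    return matrix, truth


def generate_library(
    truth: SyntheticTruth,
    n_background_terms: int = 20,
    term_size: int = 20,
    seed: int = 0,
) -> GeneSetLibrary:
    """One exact term per planted module plus random background terms.

    Background terms are rejection-sampled so none contains a complete
    planted module. Planted terms are labeled ``module_<i>``.
    """
    genes = sorted(truth.module_of)
    if term_size > len(genes):
        raise ValueError("term_size exceeds gene count")
    rng = np.random.default_rng(seed)
    terms: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for m, members in sorted(truth.modules.items()):
        terms[f"module_{m}"] = list(members)
        descriptions[f"module_{m}"] = "planted co-expression module"
    module_sets = [set(v) for v in truth.modules.values()]
    for j in range(n_background_terms):
        for _ in range(1000):
            pick = sorted(rng.choice(genes, size=term_size, replace=False))
            if not any(ms <= set(pick) for ms in module_sets):
                break
        else:  # pragma: no cover - would need near-total module coverage
            raise RuntimeError("could not sample a background term free of planted modules")
        terms[f"background_{j}"] = pick
        descriptions[f"background_{j}"] = "random background set"
    return GeneSetLibrary(terms, descriptions)


def generate_rci(
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
    designated: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """RCI table with planted nuclear/cytoplasmic module structure.

    ``designated`` maps module index -> ``"cytoplasmic"``/``"nuclear"`` and
    must name at least two modules; by default the first planted module is
    cytoplasmic (RCI ~ +effect) and the second nuclear (~ -effect). All other
    genes — background and non-designated modules alike — hover near 0, so
    the designated modules' compartments are the only localization signal.
    Entries go missing with probability ``cfg.rci_missingness``. Returns the
    gene x cell-line table and the compartment of every designated-module
    gene (labels for ROC evaluation).
    """
    if designated is None:
        ids = sorted(truth.modules)
        if len(ids) < 2:
            raise ValueError("need at least 2 planted modules for nuclear/cytoplasmic structure")
        designated = {ids[0]: "cytoplasmic", ids[1]: "nuclear"}
    if len(designated) < 2:
        raise ValueError("need at least 2 designated modules")
    bad = set(designated.values()) - {"cytoplasmic", "nuclear"}
    if bad:
        raise ValueError(f"unknown compartments: {sorted(bad)}")
    if not set(designated) <= set(truth.modules):
        raise ValueError("designated module not planted in the truth")
    rng = np.random.default_rng(cfg.random_seed + 1)
    genes = sorted(truth.module_of)
    cell_lines = [f"CL{i + 1}" for i in range(cfg.rci_cell_lines)]

    compartment: dict[str, str] = {}
    target = np.zeros(len(genes))
    for i, g in enumerate(genes):
        m = truth.module_of[g]
        comp = designated.get(m) if m is not None else None
        if comp is None:
            continue
        target[i] = cfg.rci_effect if comp == "cytoplasmic" else -cfg.rci_effect
        compartment[g] = comp

    values = target[:, None] + rng.normal(0.0, cfg.rci_noise_sd, (len(genes), len(cell_lines)))
    if cfg.rci_missingness > 0:
        mask = rng.random(values.shape) < cfg.rci_missingness
        # Keep every cell line usable.
        for j in range(mask.shape[1]):
            if mask[:, j].all():
                mask[0, j] = False
        values = np.where(mask, np.nan, values)
    rci = pd.DataFrame(values, index=genes, columns=cell_lines)
    return rci, compartment
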