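import numpy as np
import pandas as pd
import pytest

from coexhub import (
    CorrelationMatrix,
    SyntheticConfig,
    correlation_matrix,
    drop_silent_genes,
    generate_counts,
    generate_library,
    generate_rci,
    normalize,
)


def make_corr(pairs: dict[tuple[str, str], float], genes: list[str] | None = None) -> CorrelationMatrix:
    """Build a small symmetric correlation matrix from explicit pair values.

    Unlisted off-diagonal pairs default to 0; the diagonal is 1.
    """
    if genes is None:
        genes = sorted({g for pair in pairs for g in pair})
    df = pd.DataFrame(np.zeros((len(genes), len(genes))), index=genes, columns=genes)
    np.fill_diagonal(df.values, 1.0)
    for (a, b), r in pairs.items():
        df.at[a, b] = r
        df.at[b, a] = r
    return CorrelationMatrix(df, prevalence_threshold=0.3)


@pytest.fixture(scope="session")
def corpus():
    """A planted-module corpus shared by module tests: counts, truth,
    normalized matrix and correlation matrix (5 modules of 20 genes)."""
    cfg = SyntheticConfig(
        n_genes=300, n_samples=150, n_modules=5, module_size=20, rho=0.9, random_seed=11
    )
    counts, truth = generate_counts(cfg)
    norm = normalize(drop_silent_genes(counts))
    corr = correlation_matrix(norm, theta=0.3)
    lib = generate_library(truth, n_background_terms=10, term_size=20, seed=12)
    rci, compartment = generate_rci(truth, cfg)
    return {
        "cfg": cfg,
        "counts": counts,
        "truth": truth,
        "normalized": norm,
        "corr": corr,
        "library": lib,
        "rci": rci,
        "compartment": compartment,
    }
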