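"""Text-search sample labeling and per-group expression summaries.

Bulk RNA-seq compendium samples arrive with free-text descriptions rather
than structured tissue fields. A vocabulary-driven substring search assigns
each sample one label with a fixed precedence: known cell-type terms (mapped
to their tissue) first, then tissue names, then cell-line names. Short
cell-line names (<= 3 characters) are searched as "<name> cell" to avoid
false positives. Samples matching several terms at the same precedence tier
are left for manual resolution. Labeled groups then yield per-gene five-number
expression summaries, dropping groups below a minimum sample count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix

__all__ = ["SampleLabel", "label_samples", "group_stats", "normalize_text"]

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def normalize_text(text: str) -> str:
    """Lower-case, strip symbols to spaces, collapse whitespace."""
    return _NON_ALNUM.sub(" ", text.lower()).strip()


@dataclass(frozen=True)
class SampleLabel:
    sample_id: str
    kind: str  # tissue | cell_line | unlabeled
    value: str | None
    provenance: str  # matched_cell_type | matched_tissue | matched_cell_line | ambiguous | none


def _term_pattern(term: str) -> re.Pattern:
    # Word-boundary anchoring for short vocabulary entries limits false hits
    # (e.g. "eye" inside "monkey"); longer terms match as plain substrings.
    esc = re.escape(term)
    if len(term) < 5:
        return re.compile(rf"(?<![a-z0-9]){esc}(?![a-z0-9])")
    return re.compile(esc)


def label_samples(
    descriptions: dict[str, str],
    cell_type_to_tissue: dict[str, str],
    tissue_names: list[str],
    cell_lines: list[str],
) -> list[SampleLabel]:
    """Assign one tissue or cell-line label per sample by text search.

    Precedence: cell-type match (labeled with its tissue) beats tissue-name
    match beats cell-line match. Ties within one tier (distinct resulting
    labels) leave the sample unlabeled with provenance ``ambiguous``.
    Vocabularies and descriptions are normalized identically (lower-case,
    symbols stripped).
    """
    if not (cell_type_to_tissue or tissue_names or cell_lines):
        raise ValueError("all vocabularies are empty")

    ct_patterns = [
        (normalize_text(ct), tissue, _term_pattern(normalize_text(ct)))
        for ct, tissue in sorted(cell_type_to_tissue.items())
        if normalize_text(ct)
    ]
    tissue_patterns = [
        (normalize_text(t), _term_pattern(normalize_text(t)))
        for t in sorted(set(tissue_names))
        if normalize_text(t)
    ]
    line_patterns = []
    for cl in sorted(set(cell_lines)):
        norm = normalize_text(cl)
        if not norm:
            continue
        # Short cell-line names are searched with the word "cell" appended.
        query = f"{norm} cell" if len(norm) <= 3 else norm
        line_patterns.append((norm, _term_pattern(query)))

    labels: list[SampleLabel] = []
    for sid in sorted(descriptions):
        text = normalize_text(descriptions[sid])

        tissues = {tissue for _, tissue, pat in ct_patterns if pat.search(text)}
        if tissues:
            if len(tissues) == 1:
                labels.append(SampleLabel(sid, "tissue", tissues.pop(), "matched_cell_type"))
            else:
                labels.append(SampleLabel(sid, "unlabeled", None, "ambiguous"))
            continue

        hits = {t for t, pat in tissue_patterns if pat.search(text)}
        if hits:
            if len(hits) == 1:
                labels.append(SampleLabel(sid, "tissue", hits.pop(), "matched_tissue"))
            else:
                labels.append(SampleLabel(sid, "unlabeled", None, "ambiguous"))
            continue

        line_hits = {name for name, pat in line_patterns if pat.search(text)}
        if line_hits:
            if len(line_hits) == 1:
                labels.append(
                    SampleLabel(sid, "cell_line", line_hits.pop(), "matched_cell_line")
                )
            else:
                labels.append(SampleLabel(sid, "unlabeled", None, "ambiguous"))
            continue

        labels.append(SampleLabel(sid, "unlabeled", None, "none"))
    return labels


def group_stats(
    m: ExpressionMatrix,
    labels: list[SampleLabel],
    min_samples: int = 20,
) -> pd.DataFrame:
    """Five-number summary + count of normalized expression per (gene, group).

    Groups (label values) with fewer than ``min_samples`` labeled samples are
    dropped before any statistic is computed. Returns a long-format frame with
    columns gene, group, kind, count, min, q1, median, q3, max.
    """
    if m.stage != "quantile_normalized":
        raise ValueError(f"group_stats expects quantile_normalized input, got {m.stage!r}")
    sample_set = set(m.sample_ids)
    groups: dict[tuple[str, str], list[str]] = {}
    for lab in labels:
        if lab.kind == "unlabeled" or lab.sample_id not in sample_set:
            continue
        groups.setdefault((lab.kind, lab.value), []).append(lab.sample_id)
    kept = {k: v for k, v in groups.items() if len(v) >= min_samples}
    if not kept:
        raise ValueError(f"no group has >= {min_samples} labeled samples")

    rows = []
    for (kind, value), samples in sorted(kept.items()):
        block = m.data[samples].to_numpy()
        q1, med, q3 = np.percentile(block, [25, 50, 75], axis=1)
        lo = block.min(axis=1)
        hi = block.max(axis=1)
        for gi, gene in enumerate(m.gene_ids):
            rows.append(
                {
                    "gene": gene,
                    "group": value,
                    "kind": kind,
                    "count": len(samples),
                    "min": lo[gi],
                    "q1": q1[gi],
                    "median": med[gi],
                    "q3": q3[gi],
                    "max": hi[gi],
                }
            )
    return pd.DataFrame(rows)
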