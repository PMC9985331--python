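"""Readers and writers for the external formats the engine touches.

Formats: GMT gene-set libraries, gene x sample expression matrices (TSV or
HDF5), GENCODE-dialect GTF gene annotation, and lncAtlas-style RCI
(cytoplasm/nucleus relative concentration index) tables.

All genes are keyed internally by stable, version-stripped Ensembl-style ids;
gene symbols are display/join aliases that fall back to the stable id when no
symbol is annotated.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetLibrary",
    "GeneAnnotation",
    "GeneRecord",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_gene_annotation",
    "read_rci",
    "write_rci",
    "strip_version",
]

# Stages an expression matrix moves through.
STAGES = ("raw", "log2", "quantile_normalized")


class FormatError(ValueError):
    """A file violated its format contract."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a processing-stage tag.

    ``data`` is a genes-in-rows DataFrame; the index holds gene ids and the
    columns hold sample ids, both unique.
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene identifiers: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dupes[:5]}")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("expression matrix contains non-finite values")
        if self.stage == "raw" and (vals < 0).any():
            raise FormatError("raw counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class GeneSetLibrary:
    """Named gene sets (GMT-backed).

    ``terms`` maps a unique term label to an ordered list of unique gene
    symbols; ``descriptions`` carries the GMT description field, preserved but
    never used computationally. Order matters only for ranked ("ordered")
    libraries such as inverted perturbation predictions.
    """

    terms: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {label!r} has an empty gene set")
            if len(set(genes)) != len(genes):
                raise ValueError(f"term {label!r} repeats a gene")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def __getitem__(self, label: str) -> list[str]:
        return self.terms[label]

    def gene_sets(self) -> dict[str, set[str]]:
        return {label: set(genes) for label, genes in self.terms.items()}


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    chromosome: str
    is_lncRNA: bool


@dataclass
class GeneAnnotation:
    """Per-gene annotation: stable id, symbol, chromosome, lncRNA flag."""

    records: dict[str, GeneRecord]

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.records[gene_id]

    def chromosome(self, gene_id: str) -> str | None:
        rec = self.records.get(gene_id)
        return rec.chromosome if rec else None

    def symbol(self, gene_id: str) -> str:
        rec = self.records.get(gene_id)
        return rec.symbol if rec else gene_id

    def is_lncrna(self, gene_id: str) -> bool:
        rec = self.records.get(gene_id)
        return bool(rec and rec.is_lncRNA)

    def lncrna_ids(self) -> set[str]:
        return {g for g, r in self.records.items() if r.is_lncRNA}

    def coding_ids(self) -> set[str]:
        return {g for g, r in self.records.items() if not r.is_lncRNA}


_VERSION_RE = re.compile(r"\.\d+$")


def strip_version(gene_id: str) -> str:
    """Strip a trailing Ensembl version suffix (``ENSG...123.7`` -> ``ENSG...123``).

    Idempotent: applying twice equals applying once.
    """
    return _VERSION_RE.sub("", gene_id)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Parse a GMT file: one gene set per line, ``term<TAB>description<TAB>genes...``.

    Blank gene fields are dropped; symbols are case-sensitive. Duplicate term
    labels and lines with fewer than three fields are errors.
    """
    terms: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            label, desc = fields[0], fields[1]
            if label in terms:
                raise FormatError(f"{path}:{lineno}: duplicate term label {label!r}")
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {label!r} has no genes")
            terms[label] = genes
            descriptions[label] = desc
    if not terms:
        raise FormatError(f"{path}: no gene sets found")
    return GeneSetLibrary(terms, descriptions)


def write_gmt(library: GeneSetLibrary, path: str | Path, ordered: bool = False) -> None:
    """Write a library as GMT. With ``ordered``, member order is written exactly
    as stored (ranked sets); otherwise members are sorted for stable output."""
    if not library.terms:
        raise ValueError("refusing to write an empty library")
    with open(path, "w") as fh:
        for label, genes in library.terms.items():
            members = list(genes) if ordered else sorted(genes)
            desc = library.descriptions.get(label, "")
            fh.write("\t".join([label, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample matrix from TSV (header row of sample ids, first
    column of gene ids) or from an HDF5 container written by
    :func:`write_expression`. Returned in ``raw`` stage."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            genes = [g.decode() if isinstance(g, bytes) else str(g) for g in f["gene_ids"][:]]
            samples = [s.decode() if isinstance(s, bytes) else str(s) for s in f["sample_ids"][:]]
            values = f["values"][:]
        df = pd.DataFrame(values, index=genes, columns=samples)
        return ExpressionMatrix(df, stage="raw")

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dupes[:5]}")
    # Locate any non-numeric cell precisely before failing.
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any() and not df.isna().to_numpy().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise FormatError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        r, c = bad[0]
        raise FormatError(
            f"{path}: missing value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), stage="raw")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV (``.tsv``/``.txt``) or HDF5 (``.h5``/``.hdf5``) depending on suffix."""
    path = Path(path)
    if path.suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            f.create_dataset("gene_ids", data=np.array(m.gene_ids, dtype="S"))
            f.create_dataset("sample_ids", data=np.array(m.sample_ids, dtype="S"))
            f.create_dataset("values", data=m.values)
    else:
        m.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# GTF annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(
    path: str | Path,
    lncrna_gtf: str | Path | None = None,
    aliases: dict[str, str] | None = None,
) -> GeneAnnotation:
    """Build gene annotation from a GTF, optionally intersected with a
    dedicated long-non-coding-RNA GTF.

    A gene is flagged ``is_lncRNA`` when it appears in ``lncrna_gtf`` (if
    given) or, absent that file, when its ``gene_type``/``gene_biotype``
    attribute is a long-non-coding biotype. Version suffixes are stripped from
    gene ids; ``gene_name`` provides the symbol with fallback to the stable
    id. ``aliases`` optionally remaps stable id -> symbol after the fallback
    (stands in for manual symbol curation).
    """
    records = _scan_gtf_genes(path)
    if not records:
        raise FormatError(f"{path}: no gene records found")

    lnc_ids: set[str] | None = None
    if lncrna_gtf is not None:
        lnc_ids = {gid for gid, _, _, _ in _scan_gtf_genes(lncrna_gtf)}

    lnc_biotypes = {
        "lncRNA",
        "lincRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "3prime_overlapping_ncRNA",
        "bidirectional_promoter_lncRNA",
        "macro_lncRNA",
        "processed_transcript",
    }

    out: dict[str, GeneRecord] = {}
    for gid, name, chrom, biotype in records:
        if gid in out:
            if out[gid].chromosome != chrom:
                raise FormatError(
                    f"gene {gid} annotated on both {out[gid].chromosome} and {chrom}"
                )
            continue
        if lnc_ids is not None:
            is_lnc = gid in lnc_ids
        else:
            is_lnc = biotype in lnc_biotypes
        symbol = name if name else gid
        if aliases and gid in aliases:
            symbol = aliases[gid]
        out[gid] = GeneRecord(gid, symbol, chrom, is_lnc)
    return GeneAnnotation(out)


def _scan_gtf_genes(path: str | Path) -> list[tuple[str, str | None, str, str | None]]:
    """Yield (stable_id, gene_name, chromosome, biotype) per gene feature.

    Uses gffutils with an in-memory database; transcript/exon-only GTFs are
    handled through gffutils' gene inference.
    """
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_transcripts=True,
            disable_infer_genes=True,
        )
    feats = list(db.features_of_type("gene"))
    if not feats:
        # Some lncRNA GTF extracts carry only transcript records.
        seen: dict[str, tuple[str, str | None, str, str | None]] = {}
        for t in db.features_of_type("transcript"):
            gid_raw = (t.attributes.get("gene_id") or [None])[0]
            if gid_raw is None:
                continue
            gid = strip_version(gid_raw)
            if gid not in seen:
                name = (t.attributes.get("gene_name") or [None])[0]
                biotype = (
                    t.attributes.get("gene_type") or t.attributes.get("gene_biotype") or [None]
                )[0]
                seen[gid] = (gid, name, t.seqid, biotype)
        return list(seen.values())
    out = []
    for g in feats:
        gid_raw = (g.attributes.get("gene_id") or [None])[0]
        if gid_raw is None:
            raise FormatError(f"{path}: gene feature without gene_id at {g.seqid}:{g.start}")
        name = (g.attributes.get("gene_name") or [None])[0]
        biotype = (g.attributes.get("gene_type") or g.attributes.get("gene_biotype") or [None])[0]
        out.append((strip_version(gid_raw), name, g.seqid, biotype))
    return out


# ---------------------------------------------------------------------------
# RCI tables
# ---------------------------------------------------------------------------

def read_rci(path: str | Path) -> pd.DataFrame:
    """Read a gene x cell-line CN RCI table from TSV.

    Positive values are cytoplasmic, negative nuclear (log-scale
    cytoplasm/nucleus concentration ratio). Blank or ``NA`` cells stay missing
    (NaN) — missing is never zero. Returns a float DataFrame with genes in the
    index and unique cell-line columns.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NA", "NaN"])
    df.index = df.index.astype(str)
    if df.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate cell-line names")
    try:
        df = df.astype(float)
    except (TypeError, ValueError):
        for c in df.columns:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad = coerced.isna() & df[c].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().argmax()]
                raise FormatError(
                    f"{path}: non-numeric RCI {df.at[gene, c]!r} at gene {gene!r}, "
                    f"cell line {c!r}"
                ) from None
        raise
    vals = df.to_numpy()
    if np.isinf(vals).any():
        raise FormatError(f"{path}: infinite RCI value")
    return df


def write_rci(rci: pd.DataFrame, path: str | Path) -> None:
    rci.to_csv(path, sep="\t", index_label="gene", na_rep="")
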