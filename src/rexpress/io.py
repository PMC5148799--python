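"""Tabular I/O for the rEx pipeline.

Everything downstream consumes four plain-text formats:

* an FPKM matrix — TSV, header row, gene identifiers in column 1, one column
  per sample;
* a sample-metadata table — TSV with columns ``sample_id``, ``tissue``,
  ``day``, ``replicate``;
* gene lists — one identifier per line (an optional ``gene_id``/``gene``
  header line is tolerated);
* a flat gene→term annotation table — TSV with columns ``gene_id``,
  ``term_id``, ``term_name``, ``term_class``.

No NA tokens are allowed in FPKM matrices: undetected expression is encoded
as 0, matching what FPKM quantifiers emit. Gene identifiers are compared
case-sensitively after whitespace stripping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

META_COLUMNS = ("sample_id", "tissue", "day", "replicate")
ANNOTATION_COLUMNS = ("gene_id", "term_id", "term_name", "term_class")
TERM_CLASSES = ("GO", "pathway", "TF")


class ExpressionMatrixError(ValueError):
    """Raised when a matrix or its metadata violates a structural invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq sample: which tissue, which post-hatch day,
    which biological replicate."""

    sample_id: str
    tissue: str
    day: int
    replicate: int


class ExpressionMatrix:
    """A genes × samples FPKM table with per-sample tissue/day/replicate metadata.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns; entries are FPKM (non-negative, finite).
    samples
        Either a DataFrame with columns ``sample_id``, ``tissue``, ``day``,
        ``replicate`` or an iterable of :class:`SampleMeta`. Every column of
        ``values`` must be described.
    """

    def __init__(self, values: pd.DataFrame, samples) -> None:
        if isinstance(samples, pd.DataFrame):
            meta = samples.copy()
        else:
            meta = pd.DataFrame(
                [
                    (s.sample_id, s.tissue, s.day, s.replicate)
                    for s in samples
                ],
                columns=list(META_COLUMNS),
            )
        missing = set(META_COLUMNS) - set(meta.columns)
        if missing:
            raise ExpressionMatrixError(
                f"sample metadata missing columns: {sorted(missing)}"
            )
        meta = meta.loc[:, list(META_COLUMNS)]
        meta["sample_id"] = meta["sample_id"].astype(str).str.strip()
        meta["tissue"] = meta["tissue"].astype(str).str.strip()
        meta["day"] = meta["day"].astype(int)
        meta["replicate"] = meta["replicate"].astype(int)

        values = values.copy()
        values.index = values.index.astype(str).str.strip()
        values.columns = values.columns.astype(str).str.strip()

        dup_genes = values.index[values.index.duplicated()]
        if len(dup_genes):
            raise ExpressionMatrixError(
                f"duplicate gene id(s): {sorted(set(dup_genes))}"
            )
        dup_samples = values.columns[values.columns.duplicated()]
        if len(dup_samples):
            raise ExpressionMatrixError(
                f"duplicate sample id(s): {sorted(set(dup_samples))}"
            )
        if meta["sample_id"].duplicated().any():
            dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"]
            raise ExpressionMatrixError(
                f"duplicate sample metadata row(s): {sorted(set(dups))}"
            )
        described = set(meta["sample_id"])
        undescribed = [c for c in values.columns if c not in described]
        if undescribed:
            raise ExpressionMatrixError(
                f"sample column(s) without metadata: {undescribed}"
            )
        triple = meta[["tissue", "day", "replicate"]].apply(tuple, axis=1)
        if triple.duplicated().any():
            raise ExpressionMatrixError(
                "duplicate (tissue, day, replicate) triple in metadata: "
                f"{sorted(set(triple[triple.duplicated()]))}"
            )

        arr = values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ExpressionMatrixError("non-numeric FPKM values present")
        if arr.size:
            bad = ~np.isfinite(arr) | (arr < 0)
            if bad.any():
                gi, si = np.argwhere(bad)[0]
                raise ExpressionMatrixError(
                    "negative or non-finite FPKM at "
                    f"gene {values.index[gi]!r}, sample {values.columns[si]!r}"
                )

        values = values.astype(float)
        values.index.name = "gene_id"
        self.values = values
        # keep metadata ordered by matrix columns; extra rows are tolerated
        meta = meta.set_index("sample_id", drop=False)
        self.samples = meta.loc[list(values.columns)].reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    @property
    def days(self) -> list[int]:
        return sorted(self.samples["day"].unique())

    def select_samples(
        self,
        tissue: str | None = None,
        day: int | None = None,
        exclude_tissue: str | None = None,
    ) -> list[str]:
        """Sample ids matching the given tissue/day filters, in column order."""
        mask = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        if exclude_tissue is not None:
            mask &= self.samples["tissue"] != exclude_tissue
        if day is not None:
            mask &= self.samples["day"] == day
        return list(self.samples.loc[mask, "sample_id"])

    def values_for(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        return self.values.loc[:, list(sample_ids)]

    def equals(self, other: "ExpressionMatrix") -> bool:
        return self.values.equals(other.values) and self.samples.equals(
            other.samples
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_genes} genes × {self.n_samples} samples, "
            f"tissues={len(self.tissues)}, days={self.days})"
        )


@dataclass(frozen=True)
class GeneList:
    """A labelled set of gene identifiers (set semantics: no duplicates)."""

    label: str
    genes: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


class AnnotationTable:
    """Flat gene→term annotation with term metadata.

    ``gene_terms`` maps each gene to the set of term ids annotated to it;
    ``terms`` is a DataFrame indexed by term id with ``term_name`` and
    ``term_class`` (one of GO / pathway / TF). Every term referenced by a
    gene must exist in the term metadata.
    """

    def __init__(
        self, gene_terms: Mapping[str, Iterable[str]], terms: pd.DataFrame
    ) -> None:
        terms = terms.copy()
        if terms.index.duplicated().any():
            raise ValueError("duplicate term id in term metadata")
        bad_class = set(terms["term_class"]) - set(TERM_CLASSES)
        if bad_class:
            raise ValueError(f"unknown term class(es): {sorted(bad_class)}")
        self.gene_terms = {g: frozenset(ts) for g, ts in gene_terms.items()}
        referenced = set().union(*self.gene_terms.values()) if self.gene_terms else set()
        unknown = referenced - set(terms.index)
        if unknown:
            raise ValueError(
                f"term(s) referenced by genes but absent from metadata: {sorted(unknown)}"
            )
        self.terms = terms

    @property
    def term_ids(self) -> pd.Index:
        return self.terms.index

    def terms_for_gene(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())

    def genes_for_term(self, term_id: str) -> frozenset[str]:
        return frozenset(
            g for g, ts in self.gene_terms.items() if term_id in ts
        )

    def terms_of_class(self, term_class: str) -> list[str]:
        return list(self.terms.index[self.terms["term_class"] == term_class])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fpkm_table(matrix_path, meta_path) -> ExpressionMatrix:
    """Read a TSV FPKM matrix plus its sample-metadata table.

    The matrix file is tab-delimited with a mandatory header; column 1 holds
    gene identifiers. Raises :class:`ExpressionMatrixError` for duplicate
    gene ids, sample columns without a metadata row, or negative /
    non-numeric FPKM entries (naming the offending cell).
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str).str.strip()
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise ExpressionMatrixError(
            f"duplicate gene id(s) in {matrix_path}: {sorted(set(dup))}"
        )
    numeric = {}
    for col in raw.columns:
        try:
            # numpy's parser is correctly rounded, so write→read is exact
            converted = raw[col].to_numpy(dtype="U").astype(float)
        except ValueError:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            gene = raw.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise ExpressionMatrixError(
                f"non-numeric FPKM at gene {gene!r}, sample {col!r} "
                f"in {matrix_path}"
            ) from None
        numeric[col] = converted
    values = pd.DataFrame(numeric, index=raw.index) if len(raw.columns) else raw.astype(float)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "tissue": str})
    return ExpressionMatrix(values, meta)


def write_fpkm_table(matrix: ExpressionMatrix, matrix_path, meta_path) -> None:
    """Write the matrix and metadata in the dialect ``read_fpkm_table`` accepts.

    Values are rendered with full ``repr`` precision so a read/write
    round-trip is exact.
    """
    matrix.values.to_csv(
        matrix_path, sep="\t", index_label="gene_id", float_format="%.17g"
    )
    matrix.samples.to_csv(meta_path, sep="\t", index=False)


_HEADER_TOKENS = {"gene", "gene_id", "geneid", "gene_symbol"}


def read_gene_list(path, label: str) -> GeneList:
    """Read a one-gene-per-line list. Duplicates are collapsed with a logged
    warning; an empty file yields an empty list (not an error)."""
    genes: list[str] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            token = line.strip()
            if not token:
                continue
            if i == 0 and token.lower() in _HEADER_TOKENS:
                continue
            genes.append(token)
    unique = frozenset(genes)
    if len(unique) < len(genes):
        logger.warning(
            "gene list %s (%s): collapsed %d duplicate entries",
            path, label, len(genes) - len(unique),
        )
    return GeneList(label=label, genes=unique)


def write_gene_list(gene_list: GeneList, path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(gene_list.genes):
            fh.write(gene + "\n")


def read_annotation_table(path) -> AnnotationTable:
    """Read a TSV annotation table (gene_id, term_id, term_name, term_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    for col in ANNOTATION_COLUMNS:
        df[col] = df[col].astype(str).str.strip()
    gene_terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        gene_terms.setdefault(gene, set()).add(term)
    terms = (
        df[["term_id", "term_name", "term_class"]]
        .drop_duplicates("term_id")
        .set_index("term_id")
    )
    return AnnotationTable(gene_terms, terms)


def write_annotation_table(annotation: AnnotationTable, path) -> None:
    rows = []
    for gene in sorted(annotation.gene_terms):
        for term in sorted(annotation.gene_terms[gene]):
            meta = annotation.terms.loc[term]
            rows.append((gene, term, meta["term_name"], meta["term_class"]))
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def validate_files(matrix_path, meta_path) -> ExpressionMatrix:
    """Read + validate; convenience used by the CLI ``validate`` command."""
    matrix = read_fpkm_table(matrix_path, meta_path)
    logger.info(
        "valid matrix: %d genes, %d samples, tissues=%s, days=%s",
        matrix.n_genes, matrix.n_samples, matrix.tissues, matrix.days,
    )
    return matrix
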