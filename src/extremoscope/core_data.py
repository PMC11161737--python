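"""Domain containers, TSV readers/writers and cohort-level gene filtering.

The pipeline operates on dense gene × sample matrices (FPKM expression,
WES read depth, CpG β-values) plus small annotation tables.  All tabular
I/O goes through pandas; matrices are stored genes-in-rows,
samples-in-columns, and every writer emits that orientation.

Gene identifiers are matched on versionless Ensembl ids (``ENSG…`` with
any ``.N`` suffix stripped on load); the symbol is metadata only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneAnnotation",
    "SampleAnnotation",
    "DruggabilityTable",
    "NO_ACTIVITY_KINASES",
    "load_expression_matrix",
    "write_expression_matrix",
    "load_gene_annotation",
    "load_sample_annotation",
    "load_druggability_table",
    "filter_expression_genes",
    "exclude_sex_chromosomes",
    "annotate_druggability",
]

#: Human kinases annotated in Swiss-Prot as lacking detectable catalytic
#: activity; they are flagged as excluded when druggability is annotated.
NO_ACTIVITY_KINASES = frozenset(
    {"CAMKV", "EPHB6", "FAM20A", "GASK1B", "PRKY", "ROR1", "TRIB1"}
)

_VERSION_RE = re.compile(r"\.\d+$")


def strip_gene_version(gene_id: str) -> str:
    """Drop a trailing Ensembl ``.N`` version suffix, if present."""
    return _VERSION_RE.sub("", gene_id)


class MatrixValidationError(ValueError):
    """A gene × sample matrix violated a structural invariant."""


def _check_unique(labels: pd.Index, what: str) -> None:
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()
        raise MatrixValidationError(f"duplicate {what} identifiers: {dups[:10]}")


@dataclass
class ExpressionMatrix:
    """Dense FPKM matrix, genes in rows and samples in columns.

    Values must be finite and non-negative; missing cells are not
    allowed (the upstream quantification produces a dense matrix).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "gene")
        _check_unique(v.columns, "sample")
        arr = v.to_numpy(dtype=float, copy=False)
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise MatrixValidationError(
                f"missing FPKM value at gene {v.index[r]!r}, sample {v.columns[c]!r}"
            )
        if not np.isfinite(arr).all():
            raise MatrixValidationError("non-finite FPKM values present")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise MatrixValidationError(
                f"negative FPKM at gene {v.index[r]!r}, sample {v.columns[c]!r}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset preserving sample order and values."""
        return ExpressionMatrix(self.values.loc[list(genes)])

    def median_fpkm(self) -> pd.Series:
        """Per-gene median FPKM across all samples."""
        return self.values.median(axis=1)


@dataclass
class GeneAnnotation:
    """Per-gene annotation: symbol, chromosome, strand, TSSs, biotype.

    ``table`` is indexed by versionless gene id with columns ``symbol``,
    ``chromosome``, ``strand`` (+/−), ``tss_list`` (tuple of 1-based
    transcript start positions), ``biotype`` and boolean ``par_y``
    marking chrY pseudoautosomal-region genes (carried as an input flag,
    not computed from coordinates).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene")
        bad = set(self.table["strand"].unique()) - {"+", "-"}
        if bad:
            raise MatrixValidationError(f"invalid strand values: {sorted(bad)}")

    def require(self, genes: Iterable[str]) -> pd.DataFrame:
        """Annotation rows for *genes*; error listing any absentees."""
        genes = list(genes)
        missing = [g for g in genes if g not in self.table.index]
        if missing:
            raise KeyError(
                f"{len(missing)} gene(s) absent from annotation, e.g. {missing[:10]}"
            )
        return self.table.loc[genes]


@dataclass
class SampleAnnotation:
    """Per-sample CIMP class and MSI status (one record per sample)."""

    table: pd.DataFrame

    CIMP_CLASSES = ("CIMP-H", "CIMP-L", "CIMP3", "CIMP4", "NA")
    MSI_CLASSES = ("MSS", "MSI", "NA")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        for col, allowed in (("cimp_class", self.CIMP_CLASSES), ("msi_status", self.MSI_CLASSES)):
            bad = set(self.table[col].unique()) - set(allowed)
            if bad:
                raise MatrixValidationError(f"invalid {col} values: {sorted(bad)}")

    def cimp_positive_samples(self) -> pd.Index:
        """Samples in the CIMP-H or CIMP-L classes (the CIMP-positive set)."""
        t = self.table
        return t.index[t["cimp_class"].isin(["CIMP-H", "CIMP-L"])]

    def labeled_samples(self) -> pd.Index:
        """Samples with a known (non-NA) CIMP class."""
        return self.table.index[self.table["cimp_class"] != "NA"]


@dataclass
class DruggabilityTable:
    """Gene-level druggability knowledge: EC numbers, TDL class, kinase family."""

    table: pd.DataFrame
    TDL_CLASSES = ("Tclin", "Tchem", "Tbio", "Tdark")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene symbol")
        bad = set(self.table["tdl_class"].dropna().unique()) - set(self.TDL_CLASSES)
        if bad:
            raise MatrixValidationError(f"invalid TDL classes: {sorted(bad)}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _load_numeric_matrix(path: str | Path, value_name: str) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    out = pd.DataFrame(index=df.index.astype(str), columns=df.columns.astype(str), dtype=float)
    for col in df.columns:
        try:
            out[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            # locate the offending cell for a useful message
            conv = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[conv.isna() & df[col].notna()]
            row = bad_rows[0] if len(bad_rows) else "?"
            raise MatrixValidationError(
                f"malformed {value_name} value at row {row!r}, column {col!r} in {path}"
            ) from None
    return out


def load_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read an FPKM TSV (first column gene ids, header sample ids)."""
    df = _load_numeric_matrix(path, "FPKM")
    df.index = df.index.map(strip_gene_version)
    return ExpressionMatrix(df)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def load_gene_annotation(path: str | Path) -> GeneAnnotation:
    """Read the flattened annotation TSV.

    Columns: gene_id, symbol, chromosome, strand, tss_list
    (semicolon-joined 1-based positions), biotype, and optionally par_y
    (true/1 for chrY pseudoautosomal-region genes).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df["gene_id"] = df["gene_id"].map(strip_gene_version)
    df = df.set_index("gene_id")
    df["tss_list"] = [
        tuple(int(x) for x in str(s).split(";") if x not in ("", "nan"))
        for s in df["tss_list"]
    ]
    if "par_y" in df.columns:
        df["par_y"] = df["par_y"].str.lower().isin(["true", "1", "yes"])
    else:
        df["par_y"] = False
    return GeneAnnotation(df)


def write_gene_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    df = ann.table.copy()
    df["tss_list"] = [";".join(str(t) for t in ts) for ts in df["tss_list"]]
    df.to_csv(path, sep="\t", index_label="gene_id")


def load_sample_annotation(path: str | Path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    for col in ("cimp_class", "msi_status"):
        if col not in df.columns:
            df[col] = "NA"
        df[col] = df[col].fillna("NA")
    return SampleAnnotation(df)


def load_druggability_table(path: str | Path) -> DruggabilityTable:
    """Read the druggability TSV (gene, semicolon-joined EC numbers, TDL, kinase family)."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("gene")
    df["ec_numbers"] = [
        tuple(x for x in str(s).split(";") if x not in ("", "nan"))
        for s in df["ec_numbers"].fillna("")
    ]
    if "kinase_family" not in df.columns:
        df["kinase_family"] = pd.NA
    return DruggabilityTable(df)


# ---------------------------------------------------------------------------
# cohort-level gene filtering
# ---------------------------------------------------------------------------

def filter_expression_genes(
    m: ExpressionMatrix,
    ann: GeneAnnotation,
    min_fpkm: float = 1.0,
) -> ExpressionMatrix:
    """Apply the cohort-level expression-matrix filters.

    Removes, in order: (a) genes on chrM or flagged as chrY
    pseudoautosomal; (b) genes with FPKM < ``min_fpkm`` in every sample
    (not expressed anywhere in the cohort); (c) genes whose biotype is
    not protein_coding.  Sample order and retained values are untouched;
    the operation is idempotent.
    """
    rows = ann.require(m.genes)
    keep = ~(rows["chromosome"].isin(["chrM", "MT", "chrMT"]) | rows["par_y"])
    expressed = (m.values.to_numpy() >= min_fpkm).any(axis=1)
    keep &= expressed
    keep &= rows["biotype"].eq("protein_coding").to_numpy()
    return m.subset_genes(m.genes[keep.to_numpy()])


def exclude_sex_chromosomes(m: ExpressionMatrix, ann: GeneAnnotation) -> ExpressionMatrix:
    """Drop chrX/chrY genes ahead of outlier calling."""
    rows = ann.require(m.genes)
    keep = ~rows["chromosome"].isin(["chrX", "chrY", "X", "Y"]).to_numpy()
    return m.subset_genes(m.genes[keep])


def annotate_druggability(
    genes: Iterable[str],
    table: DruggabilityTable,
) -> pd.DataFrame:
    """Per-gene enzyme/TDL/kinase annotation.

    A gene is an enzyme when it carries at least one EC number.  Genes
    absent from the table are annotated unknown rather than rejected.
    Kinases on the no-detectable-activity exclusion list are flagged.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    recs = []
    for g in genes:
        if g in table.table.index:
            row = table.table.loc[g]
            ec = row["ec_numbers"]
            recs.append(
                {
                    "gene": g,
                    "known": True,
                    "enzyme": len(ec) > 0,
                    "tdl_class": row["tdl_class"],
                    "kinase_family": row["kinase_family"],
                    "excluded_no_activity": g in NO_ACTIVITY_KINASES,
                }
            )
        else:
            recs.append(
                {
                    "gene": g,
                    "known": False,
                    "enzyme": False,
                    "tdl_class": pd.NA,
                    "kinase_family": pd.NA,
                    "excluded_no_activity": g in NO_ACTIVITY_KINASES,
                }
            )
    return pd.DataFrame(recs).set_index("gene")
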