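"""Core in-memory containers for the ascites proteotranscriptomic pipeline.

The pipeline integrates three data layers per cohort:

* ``LFQ`` — label-free quantification intensities from shotgun proteomics
  (MaxQuant protein groups mapped to genes); ``0`` encodes *not detected*
  before imputation.
* ``TPM`` — transcripts per million from bulk RNA-seq of sorted cell
  populations.
* ``MEDIA`` — LFQ intensities measured in protein-free conditioned media
  (the secretome readout).

Samples come from three cell populations isolated from ovarian-cancer
ascites: tumor-cell spheroids (TU), tumor-associated macrophages (TAM) and
tumor-associated T cells (TAT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CELL_TYPES = ("TU", "TAM", "TAT")

#: Tumor (epithelial) marker genes used for purity QC of sorted samples.
TUMOR_MARKERS = ("EPCAM", "PAX8", "MSLN", "MUC16", "ITGB4")


class Layer(str, Enum):
    """Data layer of an expression matrix."""

    LFQ = "LFQ"
    TPM = "TPM"
    MEDIA = "MEDIA"


class Assay(str, Enum):
    PROTEOME = "proteome"
    TRANSCRIPTOME = "transcriptome"
    SECRETOME_MEDIA = "secretome_media"


class MatrixValidationError(ValueError):
    """Raised when an expression table violates container invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative abundances, tagged by layer.

    Wraps a :class:`pandas.DataFrame` (index = gene ids, columns = sample
    ids). Invariants: no duplicate gene or sample ids, all values >= 0
    (``allow_negative=True`` relaxes the sign check for imputed matrices
    produced without positivity truncation).
    """

    data: pd.DataFrame
    layer: Layer
    allow_negative: bool = False

    def __post_init__(self) -> None:
        self.layer = Layer(self.layer)
        self.data = self.data.astype(float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate gene id(s): {dup}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise MatrixValidationError(f"duplicate sample id(s): {dup}")
        vals = self.data.to_numpy()
        if np.isnan(vals).any():
            r, c = np.argwhere(np.isnan(vals))[0]
            raise MatrixValidationError(
                f"missing value at gene {idx[r]!r}, sample {cols[c]!r}"
            )
        if not self.allow_negative and (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise MatrixValidationError(
                f"negative value at gene {idx[r]!r}, sample {cols[c]!r}: {vals[r, c]}"
            )

    # -- conveniences -----------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [s for s in sample_ids if s in self.data.columns]
        return ExpressionMatrix(self.data[keep], self.layer, self.allow_negative)

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in gene_ids if g in self.data.index]
        return ExpressionMatrix(self.data.loc[keep], self.layer, self.allow_negative)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.layer == other.layer and self.data.equals(other.data)


@dataclass
class SampleAnnotation:
    """Per-sample metadata table.

    Columns: ``sample_id``, ``patient_id``, ``cell_type`` (TU/TAM/TAT),
    ``assay``, plus optional ``excluded`` / ``exclusion_reason``.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "patient_id", "cell_type", "assay")

    def __post_init__(self) -> None:
        t = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise MatrixValidationError(f"annotation missing column(s): {missing}")
        if "excluded" not in t.columns:
            t["excluded"] = False
        if "exclusion_reason" not in t.columns:
            t["exclusion_reason"] = ""
        t["excluded"] = t["excluded"].astype(bool)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise MatrixValidationError(f"duplicate sample annotation(s): {dup}")
        bad = set(t["cell_type"]) - set(CELL_TYPES)
        if bad:
            raise MatrixValidationError(f"unknown cell type(s): {sorted(bad)}")
        for a in t["assay"]:
            Assay(a)  # raises on unknown assay
        self.table = t.reset_index(drop=True)

    def resolve(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        """Annotation rows for the given samples; every id must resolve."""
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        if missing:
            raise MatrixValidationError(f"unannotated sample id(s): {missing}")
        return t.loc[list(sample_ids)].reset_index()

    def samples_of(
        self,
        cell_type: str | None = None,
        assay: str | Assay | None = None,
        include_excluded: bool = True,
    ) -> list[str]:
        t = self.table
        if cell_type is not None:
            t = t[t["cell_type"] == cell_type]
        if assay is not None:
            t = t[t["assay"] == Assay(assay).value]
        if not include_excluded:
            t = t[~t["excluded"]]
        return t["sample_id"].tolist()

    def cell_type_of(self) -> Mapping[str, str]:
        return dict(zip(self.table["sample_id"], self.table["cell_type"]))

    def patient_of(self) -> Mapping[str, str]:
        return dict(zip(self.table["sample_id"], self.table["patient_id"].astype(str)))


@dataclass
class ProteinGroupTable:
    """MaxQuant-style protein-group table reduced to the columns we use.

    ``table`` columns: ``group_id``, ``member_gene_ids`` (list of gene
    symbols), ``unique_peptides`` plus one LFQ column per sample.
    """

    table: pd.DataFrame
    sample_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("group_id", "member_gene_ids", "unique_peptides"):
            if col not in t.columns:
                raise MatrixValidationError(f"protein-group table missing {col!r}")
        if not self.sample_columns:
            reserved = {"group_id", "member_gene_ids", "unique_peptides"}
            self.sample_columns = [c for c in t.columns if c not in reserved]
        if (t["unique_peptides"].astype(int) < 1).any():
            bad = t.loc[t["unique_peptides"].astype(int) < 1, "group_id"].tolist()
            raise MatrixValidationError(f"group(s) with <1 unique peptide: {bad}")
        if t["member_gene_ids"].map(len).eq(0).any():
            bad = t.loc[t["member_gene_ids"].map(len) == 0, "group_id"].tolist()
            raise MatrixValidationError(f"group(s) with empty member list: {bad}")
        vals = t[self.sample_columns].to_numpy(dtype=float)
        if (vals < 0).any():
            raise MatrixValidationError("negative LFQ intensity in protein-group table")
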